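"""Shared fixtures: small, fast synthetic configurations.

Everything is generated at reduced sampling rates and trial counts so the
whole suite stays desk-scale; the statistical structure (bands, windows,
planted delays expressed in samples) mirrors the full-scale defaults.
"""

import numpy as np
import pytest

from dirflow.synth import CouplingSpec, SynthConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def quiet_config(**over) -> SynthConfig:
    """Noise-only config: no ERPs, no reset, no background, no coupling."""
    base = dict(
        fs=256.0,
        n_trials=20,
        pre=0.5,
        post=0.5,
        erp_components=(),
        phase_reset=None,
        background_osc=(),
        couplings=(),
        seed=7,
    )
    base.update(over)
    return SynthConfig(**base)


def coupled_config(delay_samples=16, fs=512.0, band=(20.0, 40.0), gain=1.5, **over) -> SynthConfig:
    """One L0->R0 coupling with a delay given in samples."""
    base = dict(
        fs=fs,
        n_trials=30,
        pre=0.5,
        post=0.5,
        erp_components=(),
        phase_reset=None,
        background_osc=(),
        couplings=(
            CouplingSpec(
                source="L0",
                target="R0",
                delay_ms=delay_samples * 1000.0 / fs,
                band=band,
                gain={"*": gain},
                window_ms=(-400.0, 400.0),
            ),
        ),
        seed=3,
    )
    base.update(over)
    return SynthConfig(**base)


@pytest.fixture()
def small_epochs():
    from dirflow.synth import generate_epochs

    return generate_epochs(quiet_config())
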