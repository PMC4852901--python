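import numpy as np
import pytest

from paleoprod.synthetic import CoreSimConfig, simulate_core


@pytest.fixture(scope="session")
def noiseless_core():
    """Deep noiseless constant-rate core: C(m) = 4·exp(-0.6216·m) Bq/g.

    Thin intervals (0.05 g/cm² each) keep the interval-quadrature age bias
    well under 1%; the core extends far beyond radiometric background so the
    missing-tail inventory is negligible.
    """
    cfg = CoreSimConfig(
        n_intervals=320,
        dry_mass_per_interval=0.05,
        interval_thickness_cm=0.25,
        pb210_flux=0.2,
        mass_accum_rate=0.05,
        counting_error_cv=0.0,
        chla_noise_sd=0.0,
        seed=1,
    )
    return simulate_core(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
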