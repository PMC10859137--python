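import numpy as np
import pandas as pd
import pytest

from limbmr.synthetic_cohort import SimulationConfig, default_config, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-person, 20-SNP cohort with moderate confounding (shared, read-only)."""
    cfg = default_config(
        2000,
        20,
        seed=42,
        causal_effect=np.log(1.5),
        outcome_intercept=-2.5,
        rare_carrier_freq=0.005,
        n_kinship_pairs=50,
    )
    return cfg, simulate_cohort(cfg)


def null_config(n=1000, m=5, seed=0, **kw):
    """Config with no genetic, confounder or causal effects unless overridden."""
    defaults = dict(
        n_individuals=n,
        n_snps=m,
        allele_freqs=np.full(m, 0.3),
        snp_weights=np.zeros(m),
        exposure_noise_sd=1.0,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def toy_records():
    """Hand-written records for three individuals (ids 0..4 exist)."""
    return pd.DataFrame(
        {
            "id": [0, 1, 2, 2],
            "vocabulary": ["ICD10", "GP", "ICD10", "SELF"],
            "code": ["M75.01", "N210.", "G560", "1541"],
            "source": ["HES", "GP", "HES", "SELF"],
        }
    )
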