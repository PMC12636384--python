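import numpy as np
import pandas as pd
import pytest

from glycoscreen import synthdata as sd


@pytest.fixture
def small_config():
    """Compact cohort with satellites and noise, for pipeline tests."""
    return sd.CohortConfig(
        n_per_group={"healthy": 12, "CRC": 6, "GC": 4, "EC": 2},
        n_true_egps=40,
        frac_differential=0.25,
        satellite_rates={"isotope": 0.4, "adduct": 0.3, "fragment": 0.3},
        n_noise_peaks=15,
        seed=7,
    )


@pytest.fixture
def clean_config():
    """Noise-free, satellite-free, jitter-free deterministic cohort."""
    return sd.CohortConfig(
        n_per_group={"healthy": 8, "CRC": 6, "GC": 0, "EC": 0},
        n_true_egps=25,
        frac_differential=0.2,
        noise_sd=0.0,
        jitter_rt_sd=0.0,
        jitter_mz_sd=0.0,
        qc_cv_intra_pct=0.0,
        qc_cv_inter_pct=0.0,
        satellite_rates={"isotope": 0.0, "adduct": 0.0, "fragment": 0.0},
        n_noise_peaks=0,
        seed=11,
    )


@pytest.fixture
def peak_frame():
    """Tiny hand-built two-sample peak table (identical peak lists)."""
    rows = []
    coords = [(2.0, 900.0, 1000.0), (5.0, 1200.0, 2000.0), (9.0, 1800.5, 500.0)]
    for s in ("s1", "s2"):
        for rt, mz, area in coords:
            rows.append((s, rt, mz, area))
    return pd.DataFrame(rows, columns=["sample_id", "rt_min", "mz", "area"])


def make_rng(seed=0):
    return np.random.default_rng(seed)
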