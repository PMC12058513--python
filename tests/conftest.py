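import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rohkit.cohortsim import SegmentLaw, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free singleton cohort with one planted 2 Mb segment each."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 10_000_000},
        seed=2,
        n_founders=12,
        site_density=100,
        het_error_rate=0.0,
        planted_segments=[SegmentLaw(count=1, law="fixed", length_bp=2_000_000)],
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def pedigree_cohort():
    """Three-generation families with systematic bad sites, no planted ROH."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 20_000_000},
        seed=5,
        site_density=100,
        pedigree_spec={"trio": 2, "septet": 3, "octet": 1},
        het_error_rate=0.0,
        bad_site_fraction=0.02,
        bad_site_error_prob=0.25,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
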