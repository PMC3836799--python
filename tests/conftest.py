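import numpy as np
import pandas as pd
import pytest

import mhcfinemap as mf


@pytest.fixture(scope="session")
def two_hap_pool():
    """Two haplotypes -> every pair of markers is in perfect LD (r^2 = 1)."""
    table = pd.DataFrame(
        {
            "frequency": [0.15, 0.85],
            "DRB1": ["15:01", "03:01"],
            "DQB1": ["06:02", "02:01"],
        }
    )
    return mf.build_haplotype_pool(table)


@pytest.fixture(scope="session")
def uniform4_pool():
    table = pd.DataFrame(
        {
            "frequency": [0.25, 0.25, 0.25, 0.25],
            "DRB1": ["15:01", "15:01", "03:01", "07:01"],
            "DQB1": ["06:02", "05:01", "02:01", "02:02"],
        }
    )
    return mf.build_haplotype_pool(table)


@pytest.fixture(scope="session")
def example_pool():
    return mf.example_mhc_pool()


@pytest.fixture(scope="session")
def aa_dict():
    return mf.example_aa_dictionary()


def _encode_all(cohort, include_two_digit=True):
    pool = cohort.pool
    parts = [mf.binarize_classical(cohort.calls, locus) for locus in pool.loci]
    four = mf.DosageMatrix.concat(parts)
    if include_two_digit:
        parts.append(mf.rollup_two_digit(four))
    if pool.snps:
        parts.append(mf.encode_snps(cohort.calls, pool.snps, pool.snp_meta))
    dm = mf.DosageMatrix.concat(parts)
    dm, _ = mf.maf_filter(dm)
    return dm


@pytest.fixture(scope="session")
def risk_cohort(example_pool):
    """Moderate cohort with one strong planted class II effect."""
    cfg = mf.SimulationConfig(
        strata=[
            mf.StratumSpec(name="s1", n_subjects=1500, intercept=-0.5),
            mf.StratumSpec(name="s2", n_subjects=1500, intercept=0.3),
        ],
        effects={"DRB1*15:01": float(np.log(2.9))},
        n_pcs=2,
        seed=2024,
    )
    return mf.sample_cohort(example_pool, cfg)


@pytest.fixture(scope="session")
def risk_data(risk_cohort):
    return mf.StudyData.from_cohort(risk_cohort, _encode_all(risk_cohort))


@pytest.fixture(scope="session")
def null_data(example_pool):
    """Cohort with no planted effects, single stratum, no PCs."""
    cfg = mf.SimulationConfig(
        strata=[mf.StratumSpec(name="all", n_subjects=800)], effects={}, n_pcs=0, seed=99
    )
    cohort = mf.sample_cohort(example_pool, cfg)
    return mf.StudyData.from_cohort(cohort, _encode_all(cohort))
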