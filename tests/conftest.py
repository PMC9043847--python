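import numpy as np
import pytest
from hypothesis import settings

import noarvas as na

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded dataset shared by read-only tests."""
    cfg = na.SimulationConfig(rng_seed=7, n_genes=60, n_trios=5, n_planted_risk_genes=3)
    return na.generate_cohort(cfg)


@pytest.fixture(scope="session")
def rvas_results(small_cohort):
    ds = small_cohort
    lof_idx = [j for j, v in enumerate(ds.variants) if v.is_lof and na.rare_filter(v)]
    hwe = na.apply_hwe_filter(
        [ds.variants[j] for j in lof_idx], ds.genotypes.dosage[:, lof_idx]
    )
    retained = [lof_idx[k] for k in hwe.retained_indices]
    return na.run_rvas(ds.genotypes, retained, ds.ne_table)


def make_genotypes(n_cases, n_controls, columns, variants):
    """Assemble a CohortGenotypes from explicit dosage columns."""
    dosage = np.stack(columns, axis=1).astype(np.int8)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    sample_ids = [f"s{i}" for i in range(n_cases + n_controls)]
    return na.CohortGenotypes(
        sample_ids=sample_ids, phenotype=phenotype, dosage=dosage, variants=variants
    )
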