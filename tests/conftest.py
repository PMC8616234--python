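import warnings

import numpy as np
import pandas as pd
import pytest

import leukotype as lk


@pytest.fixture(scope="session")
def cohort():
    """Default 60-sample study cohort (counts, gene metadata, ground truth)."""
    cfg = lk.default_cohort_config(seed=1)
    counts, meta, truth = lk.generate_expression(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def cohort_truth_labels(cohort):
    _, _, _, truth = cohort
    return pd.Series(truth.sample_truth["subtype"].values,
                     index=truth.sample_truth["sample_id"].values)


@pytest.fixture(scope="session")
def cohort_vst(cohort):
    _, counts, meta, _ = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = lk.gc_normalize(counts, meta["gc"])
        return lk.variance_stabilize(norm).values


@pytest.fixture(scope="session")
def fusion_cohort(cohort):
    cfg, *_ = cohort
    calls, truth = lk.generate_fusion_calls(cfg)
    return calls, truth


@pytest.fixture(scope="session")
def variant_cohort(cohort):
    cfg, *_ = cohort
    table, truth = lk.generate_variants(cfg)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, n_genes, n_samples, mean_log=np.log(100), sd_log=1.0,
              dispersion=0.1):
    """Plain NB count matrix with no group structure."""
    mu = np.exp(rng.normal(mean_log, sd_log, n_genes))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu[:, None] / shape, (n_genes, n_samples))
    y = rng.poisson(lam)
    return pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])
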