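"""Negative-binomial differential expression (subgroup vs rest and paired).

The test is an NB-Wald on a log-linear model with median-of-ratios size
factors as offsets and trended moment dispersion, with a t reference at the
residual degrees of freedom; p-values are BH-adjusted. It is an
approximation in the DESeq2 family whose operating characteristics
(type-I error, effect recovery) are simulation-calibrated rather than
package-equal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._glm import estimate_dispersions, nb_wald, size_factors


def _result_frame(genes: pd.Index, res, keep: np.ndarray) -> pd.DataFrame:
    out = pd.DataFrame({
        "base_mean": res.base_mean,
        "log2_fold_change": res.log2_fold_change,
        "se": res.se,
        "stat": res.stat,
        "pvalue": res.pvalue,
    }, index=genes[keep])
    ok = np.isfinite(out["pvalue"].to_numpy())
    qvals = np.full(len(out), np.nan)
    if ok.any():
        qvals[ok] = multipletests(out["pvalue"].to_numpy()[ok], method="fdr_bh")[1]
    out["qvalue"] = qvals
    out.index.name = "gene"
    return out


def differential_expression(counts: pd.DataFrame, group_mask,
                            min_mean_count: float = 0.0) -> pd.DataFrame:
    """Group-vs-rest NB-Wald test on a genes x samples count matrix.

    ``group_mask`` marks the foreground samples; log2 fold changes are
    foreground vs rest. Genes with mean raw count <= ``min_mean_count`` are
    excluded. Returns a per-gene table with log2_fold_change, pvalue and
    BH-adjusted qvalue.
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.shape[0] != counts.shape[1]:
        raise ValueError("group_mask length does not match number of samples")
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both the subgroup and the rest must be non-empty")
    y = counts.to_numpy(dtype=float)
    keep = y.mean(axis=1) > min_mean_count
    y = y[keep]
    X = np.column_stack([np.ones(mask.shape[0]), mask.astype(float)])
    sf = size_factors(counts.to_numpy(dtype=float))
    res = nb_wald(y, X, coef=1, sf=sf)
    return _result_frame(counts.index, res, keep)


def paired_differential_expression(counts: pd.DataFrame, design: pd.DataFrame,
                                   min_mean_count: float = 10.0,
                                   baseline_condition: str | None = None,
                                   ) -> pd.DataFrame:
    """Paired condition effect controlling per-patient baselines.

    ``design`` is indexed by sample_id with columns patient_id and condition
    (exactly two levels, each patient contributing one sample per
    condition). The model has free per-patient intercepts and one condition
    coefficient; genes with mean raw count <= ``min_mean_count`` (default:
    strictly more than 10 reads on average) are tested. Fold changes are
    condition-vs-``baseline_condition`` (default: lexicographically first
    level, so PAXgene vs EDTA for tube comparisons).
    """
    design = design.loc[counts.columns]
    conditions = sorted(design["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conditions}")
    per_patient = design.groupby("patient_id")["condition"].agg(lambda s: sorted(s))
    for pid, conds in per_patient.items():
        if conds != conditions:
            raise ValueError(f"patient {pid!r} is not paired across both conditions")
    if baseline_condition is None:
        baseline_condition = conditions[0]
    elif baseline_condition not in conditions:
        raise ValueError(f"baseline condition {baseline_condition!r} not in design")

    patients = sorted(design["patient_id"].unique())
    if len(patients) < 2:
        raise ValueError("paired analysis needs >= 2 patients")
    X = np.zeros((len(design), len(patients) + 1))
    for j, pid in enumerate(patients):
        X[(design["patient_id"] == pid).to_numpy(), j] = 1.0
    X[:, -1] = (design["condition"] != baseline_condition).to_numpy(dtype=float)

    y = counts.to_numpy(dtype=float)
    keep = y.mean(axis=1) > min_mean_count
    y = y[keep]
    sf = size_factors(counts.to_numpy(dtype=float))
    res = nb_wald(y, X, coef=X.shape[1] - 1, sf=sf)
    return _result_frame(counts.index, res, keep)
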