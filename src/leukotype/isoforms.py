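"""Differential isoform usage and cross-analysis direction concordance.

Usage of an isoform is its count as a fraction of its gene's total. The
subgroup-vs-rest test is a two-sample overdispersed (quasi-binomial) z-test
on per-sample usage proportions weighted by gene totals — a deliberately
simple stand-in for a full GLM whose operating characteristics are
simulation-calibrated. Direction concordance between two result sets
(e.g., a known subgroup and the unknown samples co-clustering with it)
counts shared isoforms whose usage shifts agree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def differential_isoform_usage(iso_counts: pd.DataFrame, iso_to_gene: pd.Series,
                               group_mask, min_gene_count: int = 10) -> pd.DataFrame:
    """Per-isoform usage comparison, subgroup vs rest.

    ``iso_counts`` is isoforms x samples; ``iso_to_gene`` maps isoform id to
    gene id. Single-isoform genes are excluded; genes must reach
    ``min_gene_count`` total in at least half of the samples. Returns a
    table with delta_proportion (group - rest), direction, p and BH q.
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    iso_to_gene = iso_to_gene.reindex(iso_counts.index)
    if iso_to_gene.isna().any():
        raise ValueError("iso_to_gene does not cover all isoforms")

    gene_totals = iso_counts.groupby(iso_to_gene).transform("sum")
    iso_per_gene = iso_to_gene.map(iso_to_gene.value_counts())
    enough = (gene_totals >= min_gene_count).mean(axis=1) >= 0.5
    testable = (iso_per_gene >= 2) & enough

    x = iso_counts.loc[testable].to_numpy(dtype=float)
    n = gene_totals.loc[testable].to_numpy(dtype=float)
    rows = []
    for i, iso in enumerate(iso_counts.index[testable]):
        xi, ni = x[i], n[i]
        ok = ni > 0
        g = mask & ok
        r = (~mask) & ok
        if g.sum() == 0 or r.sum() == 0:
            continue
        p1 = xi[g].sum() / ni[g].sum()
        p0 = xi[r].sum() / ni[r].sum()
        pbar = (xi[g].sum() + xi[r].sum()) / (ni[g].sum() + ni[r].sum())
        se = np.sqrt(max(pbar * (1 - pbar), 1e-12) * (1 / ni[g].sum() + 1 / ni[r].sum()))
        # overdispersion from per-sample Pearson residuals under the pooled rate
        exp = ni[ok] * pbar
        var = np.maximum(ni[ok] * pbar * (1 - pbar), 1e-12)
        pearson = np.sum((xi[ok] - exp) ** 2 / var)
        dof = max(int(ok.sum()) - 2, 1)
        phi = max(pearson / dof, 1.0)
        z = (p1 - p0) / (se * np.sqrt(phi))
        pval = 2.0 * stats.t.sf(abs(z), df=dof)
        rows.append({"isoform_id": iso, "gene_id": iso_to_gene.loc[iso],
                     "delta_proportion": p1 - p0,
                     "direction": int(np.sign(p1 - p0)),
                     "stat": z, "p": pval})
    out = pd.DataFrame(rows).set_index("isoform_id") if rows else pd.DataFrame(
        columns=["gene_id", "delta_proportion", "direction", "stat", "p", "q"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class ConcordanceReport:
    n_shared: int
    n_significant_shared: int
    direction_concordance: float | None  # None when no shared isoforms
    table: pd.DataFrame

    @property
    def defined(self) -> bool:
        return self.direction_concordance is not None


def concordance(set_a: pd.DataFrame, set_b: pd.DataFrame,
                loose_q: float = 1.0, strict_q: float = 0.05) -> ConcordanceReport:
    """Direction concordance between two isoform-usage result tables.

    Shared isoforms are those present in both tables with q < ``loose_q`` in
    both; significant shared isoforms additionally have q < ``strict_q`` in
    both. Concordance is the fraction of shared isoforms whose usage-change
    directions agree; with no shared isoforms it is reported as undefined
    (None), not 0.
    """
    a = set_a[set_a["q"] < loose_q]
    b = set_b[set_b["q"] < loose_q]
    shared = a.index.intersection(b.index)
    table = pd.DataFrame({
        "direction_a": a.loc[shared, "direction"],
        "direction_b": b.loc[shared, "direction"],
        "q_a": a.loc[shared, "q"],
        "q_b": b.loc[shared, "q"],
    })
    table["concordant"] = table["direction_a"] == table["direction_b"]
    n_sig = int(((table["q_a"] < strict_q) & (table["q_b"] < strict_q)).sum())
    conc = float(table["concordant"].mean()) if len(shared) else None
    return ConcordanceReport(n_shared=len(shared), n_significant_shared=n_sig,
                             direction_concordance=conc, table=table)
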