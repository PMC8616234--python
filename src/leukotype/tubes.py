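"""Paired tube-technology comparison (PAXgene vs EDTA).

Builds on the paired NB differential-expression test: effect-size tiers at
|log2FC| > 1, 2, 3 (q < 0.05), the rank score log2FC x (-log10 q) feeding
pre-ranked enrichment, correlation of condition-mean expression with
published mRNA decay constants, and hierarchical-clustering / PCA
diagnostics of the paired samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .de import paired_differential_expression  # noqa: F401  (re-exported surface)


def effect_size_tiers(results: pd.DataFrame, cutoffs: tuple[float, ...] = (1.0, 2.0, 3.0),
                      max_q: float = 0.05) -> pd.DataFrame:
    """Nested DEG tiers by effect size.

    Tier membership requires q < ``max_q`` and |log2FC| strictly greater
    than the cutoff, so tiers are nested (tier 3 within 2 within 1).
    Returns one row per cutoff with n_total/n_up/n_down and the gene lists.
    """
    sig = results[results["qvalue"] < max_q]
    rows = []
    for c in cutoffs:
        tier = sig[sig["log2_fold_change"].abs() > c]
        up = tier[tier["log2_fold_change"] > 0]
        down = tier[tier["log2_fold_change"] < 0]
        rows.append({"cutoff": c, "n_total": len(tier), "n_up": len(up),
                     "n_down": len(down), "genes": list(tier.index),
                     "up_genes": list(up.index), "down_genes": list(down.index)})
    return pd.DataFrame(rows).set_index("cutoff")


def rank_score(log2fc, q):
    """Expression rank score log2FC x (-log10 q); q = 0 is clamped to the
    smallest positive float with a warning."""
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        warnings.warn("q-values of 0 clamped to the smallest positive float",
                      stacklevel=2)
        q = np.maximum(q, np.finfo(float).tiny)
    out = log2fc * (-np.log10(q))
    return float(out) if out.ndim == 0 else out


def ranked_gene_list(results: pd.DataFrame) -> pd.Series:
    """Ranked list (descending score, ties lexicographic) from a DE table."""
    scores = rank_score(results["log2_fold_change"].to_numpy(),
                        results["qvalue"].to_numpy())
    df = pd.DataFrame({"gene": results.index, "score": scores})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


@dataclass
class DecayComparison:
    correlations: pd.DataFrame  # per condition: spearman rho, p, slope
    up_median: float
    down_median: float
    ranksum_stat: float
    ranksum_p: float
    direction: int  # sign(up_median - down_median)
    evaluable: bool = True


def decay_correlation(tpm: pd.DataFrame, decay_constants: pd.Series,
                      up_set: list[str], down_set: list[str],
                      min_genes: int = 10) -> DecayComparison:
    """Relate condition-mean expression to mRNA decay constants.

    ``tpm`` is genes x conditions (mean TPM per condition). Reports, per
    condition, the Spearman correlation of log TPM with the decay constant
    over the up/down DEGs, and a rank-sum comparison of decay constants
    between the up- and down-regulated sets.
    """
    up = [g for g in up_set if g in decay_constants.index and g in tpm.index]
    down = [g for g in down_set if g in decay_constants.index and g in tpm.index]
    if len(up) < min_genes or len(down) < min_genes:
        return DecayComparison(correlations=pd.DataFrame(), up_median=np.nan,
                               down_median=np.nan, ranksum_stat=np.nan,
                               ranksum_p=np.nan, direction=0, evaluable=False)
    genes = sorted(set(up) | set(down))
    dec = decay_constants.loc[genes]
    rows = {}
    for cond in tpm.columns:
        logtpm = np.log10(tpm.loc[genes, cond] + 1e-3)
        if np.ptp(logtpm.to_numpy()) == 0:  # degenerate: constant expression
            rows[cond] = {"spearman_rho": np.nan, "p": np.nan, "slope": np.nan}
            continue
        rho, p = stats.spearmanr(logtpm, dec)
        slope = stats.linregress(logtpm, dec).slope
        rows[cond] = {"spearman_rho": rho, "p": p, "slope": slope}
    up_vals = decay_constants.loc[up]
    down_vals = decay_constants.loc[down]
    if list(up) == list(down):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(up_vals, down_vals, alternative="two-sided")
    um, dm = float(up_vals.median()), float(down_vals.median())
    return DecayComparison(correlations=pd.DataFrame.from_dict(rows, orient="index"),
                           up_median=um, down_median=dm,
                           ranksum_stat=float(stat), ranksum_p=float(p),
                           direction=int(np.sign(um - dm)))


@dataclass
class ClusterProjection:
    dendrogram_order: list[str]
    linkage: np.ndarray
    pc_coordinates: pd.DataFrame
    variance_fractions: np.ndarray
    genes_used: list[str]


def cluster_and_project(vst: pd.DataFrame, n_top_variable: int = 1000) -> ClusterProjection:
    """Hierarchical clustering and PCA diagnostics of a genes x samples
    matrix. Uses the top-variance genes, average linkage on correlation
    distance for the dendrogram, and PCA of the gene-centered matrix."""
    if vst.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    n = min(n_top_variable, vst.shape[0])
    if n < n_top_variable:
        warnings.warn(f"only {n} genes available; n_top_variable clamped",
                      stacklevel=2)
    top = vst.loc[vst.var(axis=1).sort_values(ascending=False, kind="mergesort").index[:n]]
    X = top.T.to_numpy()  # samples x genes
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [top.columns[i] for i in hierarchy.leaves_list(Z)]
    centered = X - X.mean(axis=0, keepdims=True)
    k = min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=k)
    coords = pca.fit_transform(centered)
    pc = pd.DataFrame(coords, index=top.columns,
                      columns=[f"PC{i + 1}" for i in range(k)])
    return ClusterProjection(dendrogram_order=order, linkage=Z, pc_coordinates=pc,
                             variance_fractions=pca.explained_variance_ratio_,
                             genes_used=list(top.index))
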