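"""DEG panel construction, 2-D embedding and separation scoring.

The panel is built from the union of subgroup-vs-rest DEGs (BH FDR < 0.05,
subgroups with at least three samples), ranked by median absolute deviation
of variance-stabilized expression across all samples. Panel sizes from 300
to 3000 in steps of 50 are swept; for each size the samples are embedded
(t-SNE with perplexity 20, or UMAP with default parameters) and subgroup
separation is scored by the mean silhouette coefficient, the quantitative
stand-in for visual cluster separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .de import differential_expression


@dataclass
class PanelSweepConfig:
    sizes: tuple[int, ...] = tuple(range(300, 3001, 50))
    deg_fdr: float = 0.05
    min_subgroup_size: int = 3
    embedding: str = "tsne"
    tsne_perplexity: float = 20.0
    tsne_max_iter: int = 50000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) == 0 or list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be a non-empty increasing grid")
        if not (0.0 < self.deg_fdr < 1.0):
            raise ValueError("deg_fdr must be in (0, 1)")


@dataclass
class PanelSweepResult:
    panel_genes: list[str]
    best_size: int
    sweep: pd.DataFrame  # size, score
    deg_union: list[str]
    mad_ranking: pd.Series


def embed(matrix: pd.DataFrame, method: str = "tsne",
          cfg: PanelSweepConfig | None = None) -> pd.DataFrame:
    """Embed samples (rows) into 2-D; deterministic given cfg.seed.

    Perplexity exceeding (n_samples - 1) / 3 is reduced with a warning.
    """
    cfg = cfg or PanelSweepConfig()
    X = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding input contains non-finite values")
    n = X.shape[0]
    if n < 3:
        raise ValueError("embedding needs at least 3 samples")
    if method == "tsne":
        perplexity = cfg.tsne_perplexity
        limit = (n - 1) / 3.0
        if perplexity >= limit:
            perplexity = max(limit - 1e-6, 2.0)
            warnings.warn(f"perplexity reduced to {perplexity:.2f} for n={n}",
                          stacklevel=2)
        ts = TSNE(n_components=2, perplexity=perplexity,
                  max_iter=max(int(cfg.tsne_max_iter), 250),
                  init="pca", random_state=cfg.seed)
        coords = ts.fit_transform(X)
    elif method == "umap":
        import umap  # deferred: numba compilation is slow at import

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_components=2, random_state=cfg.seed)
            coords = reducer.fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=matrix.index, columns=["dim1", "dim2"])


def separation_score(coords: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette coefficient of the labeled samples in embedding
    space (Euclidean); unlabeled samples are excluded."""
    labels = labels.reindex(coords.index)
    mask = labels.notna()
    lab = labels[mask]
    counts = lab.value_counts()
    usable = counts[counts >= 2].index
    lab = lab[lab.isin(usable)]
    if lab.nunique() < 2:
        raise ValueError("separation score needs >= 2 labels with >= 2 samples each")
    return float(silhouette_score(coords.loc[lab.index].to_numpy(), lab.to_numpy()))


def deg_union(counts: pd.DataFrame, labels: pd.Series,
              cfg: PanelSweepConfig | None = None) -> list[str]:
    """Union of per-subgroup DEGs (subgroup vs all other samples, BH FDR
    below cfg.deg_fdr) over subgroups with >= min_subgroup_size samples.
    Unlabeled samples stay in the background of every comparison."""
    cfg = cfg or PanelSweepConfig()
    labels = labels.reindex(counts.columns)
    union: set[str] = set()
    for subgroup, n in labels.value_counts().items():
        if n < cfg.min_subgroup_size:
            continue
        mask = (labels == subgroup).to_numpy()
        res = differential_expression(counts, mask)
        union |= set(res.index[res["qvalue"] < cfg.deg_fdr])
    return sorted(union)


def build_deg_panel(counts: pd.DataFrame, vst: pd.DataFrame, labels: pd.Series,
                    cfg: PanelSweepConfig | None = None) -> PanelSweepResult:
    """Select the most-variable-DEG panel size that best separates the known
    subgroups.

    ``counts`` and ``vst`` are genes x samples; ``labels`` maps sample to
    known subtype (NaN/None = unknown). For each grid size the top-MAD DEGs
    are embedded and scored; the best-scoring size wins, ties to the
    smallest.
    """
    cfg = cfg or PanelSweepConfig()
    labels = labels.reindex(counts.columns)
    union = deg_union(counts, labels, cfg)
    if len(union) == 0:
        raise ValueError("no differentially expressed genes at the requested FDR")

    mad = vst.loc[union].apply(
        lambda row: stats.median_abs_deviation(row, scale="normal"), axis=1)
    ranking = mad.sort_values(ascending=False, kind="mergesort")

    sizes = [s for s in cfg.sizes if s <= len(union)]
    if len(sizes) < len(cfg.sizes):
        warnings.warn(
            f"DEG union has {len(union)} genes; grid truncated to {len(sizes)} sizes",
            stacklevel=2)
        if len(union) not in sizes:
            sizes.append(len(union))  # the full union is always a candidate

    rows = []
    for size in sizes:
        genes = list(ranking.index[:size])
        coords = embed(vst.loc[genes].T, method=cfg.embedding, cfg=cfg)
        score = separation_score(coords, labels)
        rows.append({"size": size, "score": score})
    sweep = pd.DataFrame(rows)
    best_size = int(sweep.loc[sweep["score"].idxmax(), "size"])
    # idxmax takes the first maximum; sizes are increasing, so ties already
    # resolve to the smallest panel
    return PanelSweepResult(panel_genes=list(ranking.index[:best_size]),
                            best_size=best_size, sweep=sweep,
                            deg_union=union, mad_ranking=ranking)
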