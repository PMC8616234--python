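"""Co-clustering classification of unknown samples and evidence integration.

Unknown (B-other) samples are assigned the subtype of the labeled samples
they embed among: each unknown's k nearest labeled neighbors under
correlation distance on the DEG-panel expression matrix vote, and the
majority label is assigned when its share reaches ``min_frac``. Final
labels integrate three evidence tiers with precedence
fusion > hotspot > co-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

EVIDENCE_ORDER = ["fusion", "hotspot", "co-clustering"]


@dataclass
class SubtypeAssignment:
    sample_id: str
    label: str | None
    evidence: str  # fusion | hotspot | co-clustering | unassigned
    confidence: float
    neighbor_breakdown: dict | None = None

    def __post_init__(self) -> None:
        assert (self.evidence == "unassigned") == (self.label is None)


class CoClusteringClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbor vote under correlation distance.

    Parameters
    ----------
    k : neighbors consulted per unknown sample (default 10).
    min_frac : minimum majority fraction to assign (default 0.5); below it
        the sample stays unassigned (predicted label None).
    """

    def __init__(self, k: int = 10, min_frac: float = 0.5):
        self.k = k
        self.min_frac = min_frac

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[0]} labeled samples")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _neighbor_votes(self, X) -> list[dict]:
        check_is_fitted(self, "X_")
        X = check_array(X)
        # correlation distance 1 - Pearson r across panel genes
        a = X - X.mean(axis=1, keepdims=True)
        b = self.X_ - self.X_.mean(axis=1, keepdims=True)
        a /= np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-12)
        b /= np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
        dist = 1.0 - a @ b.T
        votes = []
        for i in range(X.shape[0]):
            order = np.lexsort((np.arange(len(self.y_)), dist[i]))
            nn = self.y_[order[: self.k]]
            breakdown: dict = {}
            for lab in nn:
                breakdown[lab] = breakdown.get(lab, 0) + 1
            votes.append(breakdown)
        return votes

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-sample label (or None), confidence = majority fraction, and
        the neighbor label breakdown."""
        votes = self._neighbor_votes(X)
        rows = []
        for breakdown in votes:
            best = sorted(breakdown.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            frac = best[1] / self.k
            assigned = frac >= self.min_frac
            rows.append({"label": best[0] if assigned else None,
                         "confidence": frac,
                         "neighbor_breakdown": breakdown})
        return pd.DataFrame(rows)

    def predict(self, X):
        return self.predict_detail(X)["label"].to_numpy(dtype=object)


def assign_by_coclustering(vst_panel: pd.DataFrame, known_labels: pd.Series,
                           unknown_samples: list[str], k: int = 10,
                           min_frac: float = 0.5) -> pd.DataFrame:
    """Classify unknown samples against labeled ones on a genes x samples
    panel matrix. Returns a table indexed by sample_id with label,
    evidence, confidence and neighbor_breakdown."""
    known_labels = known_labels.dropna()
    labeled = [s for s in vst_panel.columns if s in known_labels.index]
    clf = CoClusteringClassifier(k=k, min_frac=min_frac)
    clf.fit(vst_panel[labeled].T.to_numpy(), known_labels.loc[labeled].to_numpy())
    detail = clf.predict_detail(vst_panel[unknown_samples].T.to_numpy())
    detail.index = pd.Index(unknown_samples, name="sample_id")
    detail["evidence"] = np.where(detail["label"].notna(), "co-clustering", "unassigned")
    return detail


def integrate_assignments(fusion: pd.DataFrame | None,
                          hotspot: pd.DataFrame | None,
                          coclustering: pd.DataFrame | None,
                          samples: list[str]) -> pd.DataFrame:
    """Combine evidence tiers into final per-sample assignments.

    Precedence is fusion > hotspot > co-clustering; lower-tier disagreement
    with the winning label is recorded in the ``conflicts`` column but does
    not override it. Samples without any evidence are unassigned.
    """

    def label_of(table: pd.DataFrame | None, sid: str, col: str) -> str | None:
        if table is None or sid not in table.index:
            return None
        val = table.loc[sid, col]
        return None if pd.isna(val) else val

    rows = {}
    for sid in samples:
        tier_labels = {
            "fusion": label_of(fusion, sid, "subtype"),
            "hotspot": label_of(hotspot, sid, "subtype"),
            "co-clustering": label_of(coclustering, sid, "label"),
        }
        final, evidence = None, "unassigned"
        for tier in EVIDENCE_ORDER:
            if tier_labels[tier] is not None:
                final, evidence = tier_labels[tier], tier
                break
        conflicts = [f"{t}={v}" for t, v in tier_labels.items()
                     if v is not None and v != final]
        confidence = 0.0
        if evidence == "fusion":
            confidence = float(fusion.loc[sid, "support_fraction"])
        elif evidence == "hotspot":
            confidence = 1.0
        elif evidence == "co-clustering":
            confidence = float(coclustering.loc[sid, "confidence"])
        rows[sid] = {"label": final, "evidence": evidence,
                     "confidence": confidence,
                     "conflicts": ";".join(conflicts)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
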