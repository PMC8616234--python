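"""Fusion-call triage and fusion-based subtype assignment.

A candidate fusion is retained if either partner belongs to a curated
whitelist of ALL-relevant genes, or — for all other fusions — if it has more
than 10 supporting reads (split/junction plus spanning) AND the unordered
gene pair is a known leukemia fusion (Mitelman-style list). Samples are then
assigned a fusion-defined subtype from the retained call with the highest
share of the sample's supporting reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ["sample", "gene5", "gene3", "split_reads", "spanning_reads"]

#: genes whose fusions define a subtype through a single partner
DEFAULT_PARTNER_SUBTYPES = {
    "ZNF384": "ZNF384-r",
    "NUTM1": "NUTM1-r",
    "KMT2A": "KMT2A-r",
    "PAX5": "PAX5 alt",
    "DUX4": "DUX4",
}

#: orientation-sensitive 5'/3' pair subtypes
DEFAULT_PAIR_SUBTYPES = {
    ("BCR", "ABL1"): "BCR-ABL1",
    ("ETV6", "RUNX1"): "ETV6-RUNX1",
    ("P2RY8", "CRLF2"): "P2RY8-CRLF2",
    ("IGH", "CRLF2"): "IGH-CRLF2",
    ("TCF3", "PBX1"): "TCF3-PBX1",
    ("TCF3", "HLF"): "TCF3-HLF",
    ("MEF2D", "BCL9"): "MEF2D-BCL9",
    ("EBF1", "PDGFRB"): "EBF1-PDGFRB",
    ("IGH", "EPOR"): "IGH-EPOR",
}

DEFAULT_WHITELIST = sorted(
    {g for pair in DEFAULT_PAIR_SUBTYPES for g in pair}
    | set(DEFAULT_PARTNER_SUBTYPES)
    | {"IKZF1", "EP300", "JAK2", "CREBBP", "ETV6"}
)

DEFAULT_KNOWN_FUSIONS = {frozenset(p) for p in DEFAULT_PAIR_SUBTYPES} | {
    frozenset(p) for p in [("KMT2A", "MLLT1"), ("KMT2A", "MLLT3"), ("KMT2A", "USP2"),
                           ("ETV6", "ABL1"), ("PAX5", "JAK2")]
}


@dataclass
class FusionRuleSet:
    """Filtering and subtype-mapping rules for fusion calls.

    ``min_supporting_reads_nonwhitelist`` is the minimum retained support for
    non-whitelist fusions; the default 11 encodes the strict "more than 10"
    rule. ``subtype_map`` keys are either an ordered (gene5, gene3) pair or a
    single partner gene symbol matching either side.
    """

    whitelist: set[str] = field(default_factory=lambda: set(DEFAULT_WHITELIST))
    known_fusions: set[frozenset] = field(default_factory=lambda: set(DEFAULT_KNOWN_FUSIONS))
    min_supporting_reads_nonwhitelist: int = 11
    subtype_map: dict = field(default_factory=lambda: {
        **{k: v for k, v in DEFAULT_PAIR_SUBTYPES.items()},
        **DEFAULT_PARTNER_SUBTYPES,
    })

    def __post_init__(self) -> None:
        if self.min_supporting_reads_nonwhitelist <= 0:
            raise ValueError("min_supporting_reads_nonwhitelist must be positive")

    def subtype_of(self, gene5: str, gene3: str) -> str | None:
        """Subtype label for a call; ordered pairs take precedence over
        single-partner rules."""
        label = self.subtype_map.get((gene5, gene3))
        if label is not None:
            return label
        for g in (gene5, gene3):
            if g in self.subtype_map:
                return self.subtype_map[g]
        return None


def _check_columns(calls: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"fusion table is missing required column(s): {', '.join(missing)}")


def filter_fusions(calls: pd.DataFrame, rules: FusionRuleSet | None = None,
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the whitelist / read-support / known-fusion filter.

    Returns (retained calls, drop reason per dropped row). A call is
    retained iff a partner is whitelisted, or it has strictly more than 10
    supporting reads and its unordered pair is a known fusion. The reason is
    the first violated rule in the order support -> known-fusion (whitelist
    membership is an exemption, not a reason).
    """
    rules = rules or FusionRuleSet()
    _check_columns(calls)
    support = calls["split_reads"].to_numpy() + calls["spanning_reads"].to_numpy()
    in_whitelist = calls["gene5"].isin(rules.whitelist) | calls["gene3"].isin(rules.whitelist)
    enough_support = support >= rules.min_supporting_reads_nonwhitelist
    known = [frozenset((g5, g3)) in rules.known_fusions
             for g5, g3 in zip(calls["gene5"], calls["gene3"])]
    known = pd.Series(known, index=calls.index)
    keep = in_whitelist | (pd.Series(enough_support, index=calls.index) & known)

    reasons = pd.Series("", index=calls.index, dtype=object)
    dropped = ~keep
    reasons[dropped & ~pd.Series(enough_support, index=calls.index)] = \
        "supporting_reads <= 10 and no whitelist partner"
    reasons[dropped & pd.Series(enough_support, index=calls.index) & ~known] = \
        "not a known fusion and no whitelist partner"
    return calls[keep].copy(), reasons[dropped]


def support_fraction(calls: pd.DataFrame) -> pd.Series:
    """Per-call share of the sample's total supporting reads.

    ``calls`` must be the retained calls; the denominator is the sum of
    supporting reads over each sample's retained calls.
    """
    support = calls["split_reads"] + calls["spanning_reads"]
    totals = support.groupby(calls["sample"]).transform("sum")
    return support / totals


@dataclass
class FusionAssignment:
    sample_id: str
    subtype: str | None
    winning_fusion: tuple[str, str] | None
    support_fraction: float

    def __post_init__(self) -> None:
        assert (self.subtype is None) == (self.winning_fusion is None)


def classify_by_fusion(retained: pd.DataFrame, rules: FusionRuleSet | None = None,
                       samples: list[str] | None = None) -> pd.DataFrame:
    """Assign each sample the subtype of its dominant subtype-mapped fusion.

    Among a sample's retained calls that resolve through ``subtype_map``, the
    call with the highest support fraction wins; ties go to higher absolute
    support, then the lexicographically smallest (gene5, gene3) pair.
    Samples without a matching call (or absent from the table) get subtype
    None. Returns a table indexed by sample_id.
    """
    rules = rules or FusionRuleSet()
    _check_columns(retained)
    work = retained.copy()
    work["support"] = work["split_reads"] + work["spanning_reads"]
    work["fraction"] = support_fraction(work)
    work["subtype"] = [rules.subtype_of(g5, g3)
                       for g5, g3 in zip(work["gene5"], work["gene3"])]

    rows = {}
    for sid, grp in work.groupby("sample", sort=True):
        cand = grp[grp["subtype"].notna()]
        if len(cand) == 0:
            rows[sid] = {"subtype": None, "gene5": None, "gene3": None,
                         "support_fraction": 0.0}
            continue
        cand = cand.sort_values(["fraction", "support", "gene5", "gene3"],
                                ascending=[False, False, True, True],
                                kind="mergesort")
        best = cand.iloc[0]
        rows[sid] = {"subtype": best["subtype"], "gene5": best["gene5"],
                     "gene3": best["gene3"],
                     "support_fraction": float(best["fraction"])}
    if samples is not None:
        for sid in samples:
            rows.setdefault(sid, {"subtype": None, "gene5": None, "gene3": None,
                                  "support_fraction": 0.0})
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "sample_id"
    return out
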