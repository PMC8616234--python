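"""Post-caller somatic-variant filtering on RNA-derived calls.

Two filter stages mirror a diagnostic RNA-seq workflow. The caller-level
cascade removes variants with (1) fewer than six alt-allele reads, (2) tumor
allele fraction <= 0.1, (3) identical-site recurrence in >= 40% of cohort
samples, and (4) indels within 20 bp of another indel in the same sample.
The annotation stage has two modes: ``strict`` (class removal, population
AF, CADD, predictor labels, impact) feeding hotspot classification, and
``spectrum`` (population AF only, silent variants retained) feeding the
substitution-spectrum summaries.

RNA-derived call sets are dominated by A-to-I editing, visible as an excess
of the collapsed T>C (A>G) substitution class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recurrent driver substitutions with their subtype labels
DEFAULT_HOTSPOTS = {
    ("PAX5", "p.P80R"): "PAX5 P80R",
    ("IKZF1", "p.N159Y"): "IKZF1 N159Y",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
COLLAPSED_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
DIRECTIONAL_CLASSES = [f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a]


@dataclass
class VariantFilterConfig:
    min_alt_reads: int = 6
    min_tumor_af_exclusive: float = 0.1
    max_cohort_fraction: float = 0.40
    indel_window_bp: int = 20
    max_pop_af: float = 0.0001
    min_cadd_phred: float = 15.0
    allowed_impacts: frozenset = frozenset({"HIGH", "MODERATE"})
    removed_classes_strict: frozenset = frozenset(
        {"intron", "IGR", "5'flank", "splice site", "silent"})

    def __post_init__(self) -> None:
        if not (0 <= self.min_tumor_af_exclusive <= 1 and 0 <= self.max_cohort_fraction <= 1
                and 0 <= self.max_pop_af <= 1):
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if self.min_alt_reads < 0 or self.indel_window_bp < 0:
            raise ValueError("count thresholds must be non-negative")


def _is_indel(variants: pd.DataFrame) -> pd.Series:
    return variants["ref"].str.len() != variants["alt"].str.len()


def apply_caller_filters(variants: pd.DataFrame, config: VariantFilterConfig | None = None,
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Caller-level filter cascade over one cohort's variants.

    The recurrence rule (3) is computed on the raw input cohort, so the four
    rules are order-independent. Both members of a close indel pair are
    removed. Returns (retained, per-dropped-row reason: the first violated
    rule in the order 1..4).
    """
    config = config or VariantFilterConfig()
    n_cohort = variants["sample_id"].nunique()
    if n_cohort == 1:
        warnings.warn("cohort recurrence filter computed over a single sample",
                      stacklevel=2)

    fail_alt = variants["alt_reads"] < config.min_alt_reads
    fail_af = variants["tumor_af"] <= config.min_tumor_af_exclusive

    key = list(zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"]))
    key = pd.Series(key, index=variants.index)
    site_samples = variants.assign(_key=key).groupby("_key")["sample_id"].nunique()
    frac = key.map(site_samples) / max(n_cohort, 1)
    fail_recur = frac >= config.max_cohort_fraction

    is_indel = _is_indel(variants)
    fail_indel = pd.Series(False, index=variants.index)
    indels = variants[is_indel]
    for (_, _), grp in indels.groupby(["sample_id", "chrom"]):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        sorted_pos = pos[order]
        close = np.zeros(len(pos), dtype=bool)
        if len(pos) > 1:
            gaps = np.diff(sorted_pos)
            near = gaps <= config.indel_window_bp
            close[:-1] |= near
            close[1:] |= near
        fail_indel.loc[grp.index[order[close]]] = True

    reasons = pd.Series("", index=variants.index, dtype=object)
    reasons[fail_indel] = "indel within 20 bp of another indel"
    reasons[fail_recur] = "recurrent in >= 40% of cohort samples"
    reasons[fail_af] = "tumor allele fraction <= 0.1"
    reasons[fail_alt] = "fewer than 6 alt-allele reads"
    dropped = fail_alt | fail_af | fail_recur | fail_indel
    return variants[~dropped].copy(), reasons[dropped]


def apply_annotation_filters(variants: pd.DataFrame,
                             config: VariantFilterConfig | None = None,
                             mode: str = "strict",
                             unknown_class: str = "warn") -> pd.DataFrame:
    """Annotation-level filtering.

    strict mode removes: variants in the removed consequence classes;
    population AF > 0.01% in any group (retention requires pop_af_max <=
    1e-4); CADD PHRED < 15; any predictor calling the variant
    benign/tolerated/neutral (missing labels do not count); impact outside
    HIGH/MODERATE. spectrum mode applies only the population-AF rule, so
    silent variants survive for spectrum summaries.
    """
    config = config or VariantFilterConfig()
    if mode not in ("strict", "spectrum"):
        raise ValueError(f"unknown mode {mode!r}")

    keep = variants["pop_af_max"] <= config.max_pop_af
    if mode == "strict":
        known = set(config.removed_classes_strict) | {
            "missense", "nonsense", "nonstop", "frameshift", "in-frame", "splice",
            "start_lost", "stop_lost"}
        unknown = ~variants["variant_class"].isin(known)
        if unknown.any() and unknown_class == "warn":
            warnings.warn(
                f"{int(unknown.sum())} variants with unrecognized class pass through",
                stacklevel=2)
        elif unknown.any() and unknown_class == "reject":
            raise ValueError("unrecognized variant class in input")
        keep &= ~variants["variant_class"].isin(config.removed_classes_strict)
        keep &= variants["cadd_phred"] >= config.min_cadd_phred
        keep &= ~(variants.get("polyphen", pd.Series("", index=variants.index)) == "benign")
        keep &= ~(variants.get("sift", pd.Series("", index=variants.index)) == "tolerated")
        keep &= ~(variants.get("condel", pd.Series("", index=variants.index)) == "neutral")
        keep &= variants["impact"].isin(config.allowed_impacts)
    return variants[keep].copy()


# ---------------------------------------------------------------------------
# spectrum


def collapse_class(ref: str, alt: str) -> str:
    """Map a substitution to its pyrimidine-reference collapsed class
    (A>G and T>C both report as T>C, etc.)."""
    if ref in "CT":
        return f"{ref}>{alt}"
    return f"{ref.translate(_COMPLEMENT)}>{alt.translate(_COMPLEMENT)}"


@dataclass
class SubstitutionSpectrum:
    directional: pd.DataFrame  # samples x 12 classes
    collapsed: pd.DataFrame  # samples x 6 classes
    variant_types: pd.DataFrame  # samples x {SNP, DNP, TNP, ONP, indel}
    cohort_median: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.cohort_median is None:
            self.cohort_median = self.collapsed.median(axis=0)


def substitution_spectrum(variants: pd.DataFrame) -> SubstitutionSpectrum:
    """Per-sample substitution spectra over directional and collapsed
    classes, plus variant-type counts (indels excluded from SBS classes)."""
    samples = sorted(variants["sample_id"].unique())
    ref_len = variants["ref"].str.len()
    alt_len = variants["alt"].str.len()
    is_indel = ref_len != alt_len
    mnv_len = ref_len.where(~is_indel)
    vt = pd.Series(np.where(is_indel, "indel",
                   np.where(mnv_len == 1, "SNP",
                   np.where(mnv_len == 2, "DNP",
                   np.where(mnv_len == 3, "TNP", "ONP")))), index=variants.index)

    sbs = variants[(~is_indel) & (ref_len == 1) & (variants["ref"] != variants["alt"])]
    directional = pd.DataFrame(0, index=samples, columns=DIRECTIONAL_CLASSES)
    collapsed = pd.DataFrame(0, index=samples, columns=COLLAPSED_CLASSES)
    for sid, grp in sbs.groupby("sample_id"):
        d = (grp["ref"] + ">" + grp["alt"]).value_counts()
        directional.loc[sid, d.index] = d.to_numpy()
        c = pd.Series([collapse_class(r, a) for r, a in zip(grp["ref"], grp["alt"])]
                      ).value_counts()
        collapsed.loc[sid, c.index] = c.to_numpy()
    types = pd.DataFrame(0, index=samples, columns=["SNP", "DNP", "TNP", "ONP", "indel"])
    for sid, grp in vt.groupby(variants["sample_id"]):
        t = grp.value_counts()
        types.loc[sid, t.index] = t.to_numpy()
    return SubstitutionSpectrum(directional=directional, collapsed=collapsed,
                                variant_types=types)


# ---------------------------------------------------------------------------
# hotspots and co-occurrence


def classify_by_hotspot(variants: pd.DataFrame,
                        hotspots: dict | None = None) -> pd.DataFrame:
    """Assign samples carrying exactly one distinct hotspot subtype.

    ``variants`` should already be strict-filtered. Samples with hotspots
    mapping to multiple subtypes are flagged as conflicts and unassigned.
    """
    hotspots = hotspots if hotspots is not None else dict(DEFAULT_HOTSPOTS)
    labels = pd.Series([hotspots.get((g, p))
                        for g, p in zip(variants["gene"], variants["protein_change"])],
                       index=variants.index, dtype=object)
    rows = {}
    for sid, grp in labels.groupby(variants["sample_id"]):
        found = sorted(set(grp.dropna()))
        if len(found) == 1:
            rows[sid] = {"subtype": found[0], "conflict": False}
        elif len(found) > 1:
            rows[sid] = {"subtype": None, "conflict": True}
        else:
            rows[sid] = {"subtype": None, "conflict": False}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "sample_id"
    return out


def top_mutated_and_cooccurrence(variants: pd.DataFrame,
                                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Genes ranked by number of mutated samples, and the symmetric gene x
    gene co-mutation sample-count matrix (diagonal = per-gene counts)."""
    incidence = (variants.groupby(["gene", "sample_id"]).size().unstack(fill_value=0) > 0)
    incidence = incidence.astype(int)
    counts = incidence.sum(axis=1).sort_values(ascending=False, kind="mergesort")
    co = incidence @ incidence.T
    return counts, co
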