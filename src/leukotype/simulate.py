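"""Synthetic BCP-ALL cohort generator with known ground truth.

Emulates the inputs consumed by the downstream modules: negative-binomial
gene- and isoform-level count matrices with subgroup expression signatures,
Arriba-style fusion-call tables whose read support scales with sequencing
depth and blast fraction, annotated RNA variant tables (drivers, passengers,
planted filter-violating artifacts and an A-to-I editing excess), and
patient-paired tube-comparison counts.

The dilution model for low-blast samples is a two-component mixture: the
observed expression profile is blast_fraction * leukemic + (1 - blast) *
shared normal baseline, and fusion read support scales linearly with
blast_fraction and library size.

Library sizes are expressed in read pairs and scaled by ``depth_scale``
(default 1/1000) so that a cohort emulating ~100 million read pairs per
sample stays desk-sized; all depth-dependent quantities (fusion support)
are computed from the unscaled depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Gene symbols relevant to BCP-ALL diagnostics; the first genes of the
# simulated universe carry these names so fusion/hotspot plumbing uses
# realistic identifiers.
DRIVER_SYMBOLS = [
    "BCR", "ABL1", "ETV6", "RUNX1", "KMT2A", "MLLT1", "MLLT3", "USP2",
    "P2RY8", "CRLF2", "PAX5", "IKZF1", "ZNF384", "EP300", "TCF3", "PBX1",
    "HLF", "DUX4", "IGH", "EPOR", "NUTM1", "MEF2D", "BCL9", "EBF1",
    "PDGFRB", "JAK2", "KRAS", "NRAS", "TYK2", "FLT3", "PTPN11", "ERG",
]

FUSION_COLUMNS = ["sample", "gene5", "gene3", "breakpoint5", "breakpoint3",
                  "split_reads", "spanning_reads"]

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "alt_reads", "tumor_af",
    "pop_af_max", "cadd_phred", "consequence", "variant_class", "impact",
    "polyphen", "sift", "condel", "gene", "protein_change",
]


@dataclass
class SubgroupSpec:
    """One simulated BCP-ALL subgroup.

    A subgroup is defined by at least one of: a fusion (5'/3' gene pair), a
    hotspot mutation (gene, HGVS-p), or an expression signature
    (n_signature_genes with log2 shift signature_log2fc). blast_fraction is
    the leukemic-cell proportion of its samples.
    """

    name: str
    size: int
    defining_fusion: tuple[str, str] | None = None
    defining_hotspot: tuple[str, str] | None = None
    n_signature_genes: int = 200
    signature_log2fc: float = 1.5
    blast_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"subgroup {self.name!r}: size must be positive")
        if not (0.0 < self.blast_fraction <= 1.0):
            raise ValueError(f"subgroup {self.name!r}: blast_fraction must be in (0, 1]")
        if (self.defining_fusion is None and self.defining_hotspot is None
                and self.n_signature_genes <= 0):
            raise ValueError(f"subgroup {self.name!r}: needs a fusion, hotspot or signature")


@dataclass
class CohortConfig:
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    n_genes: int = 2000
    isoforms_per_gene: tuple[int, int] = (1, 4)  # uniform inclusive range
    library_size_range: tuple[float, float] = (80e6, 130e6)  # read pairs
    depth_scale: float = 1e-3
    nb_dispersion: float = 0.1
    gc_bias_slope: float = 0.0  # log2-count change per unit GC fraction
    fusion_support_per_100m: float = 60.0  # expected reads at blast 1, 100M pairs
    fusion_noise_rate: float = 2.0  # spurious calls per sample
    noise_gene_pool: str = "non_driver"  # or "all"
    editing_excess: float = 30.0  # A-to-I editing variants per sample
    passenger_rate: float = 3.0
    artifact_rate: float = 5.0  # per-sample planted filter violations
    artifact_cooccurrence_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("editing_excess", "passenger_rate", "artifact_rate",
                     "fusion_noise_rate", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.artifact_cooccurrence_fraction <= 1.0):
            raise ValueError("artifact_cooccurrence_fraction must be in [0, 1]")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    @property
    def n_samples(self) -> int:
        return sum(s.size for s in self.subgroups)


@dataclass
class GroundTruth:
    """Truth labels for every generated record."""

    sample_truth: pd.DataFrame  # sample_id, subtype, blast_fraction
    de_truth: dict[str, pd.DataFrame] = field(default_factory=dict)  # subgroup -> gene, direction
    fusion_truth: pd.DataFrame | None = None  # emitted calls with class true|noise
    variant_truth: pd.DataFrame | None = None  # per variant: class, violated_rule
    isoform_truth: pd.DataFrame | None = None  # shifted (gene, subgroup) records


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The default 60-sample, 5-subgroup study cohort.

    Two fusion-defined, one hotspot-defined and two expression-only
    subgroups, each with a 200-gene signature, mirroring the structure of a
    diagnostic BCP-ALL cohort (fusion subtypes, a PAX5 P80R hotspot subtype
    and expression-defined subtypes such as DUX4-positive).
    """
    return CohortConfig(
        subgroups=[
            SubgroupSpec("BCR-ABL1", 15, defining_fusion=("BCR", "ABL1"),
                         n_signature_genes=200, signature_log2fc=1.5),
            SubgroupSpec("P2RY8-CRLF2", 12, defining_fusion=("P2RY8", "CRLF2"),
                         n_signature_genes=200, signature_log2fc=1.5),
            SubgroupSpec("PAX5 P80R", 9, defining_hotspot=("PAX5", "p.P80R"),
                         n_signature_genes=200, signature_log2fc=1.5),
            SubgroupSpec("DUX4", 14, n_signature_genes=200, signature_log2fc=2.0),
            SubgroupSpec("ETV6-RUNX1-like", 10, n_signature_genes=200, signature_log2fc=1.5),
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# gene universe and sample bookkeeping


def gene_universe(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene metadata: symbol, GC fraction, length, relative baseline expression."""
    n = config.n_genes
    names = list(DRIVER_SYMBOLS[: min(len(DRIVER_SYMBOLS), n)])
    names += [f"G{i:05d}" for i in range(len(names), n)]
    gc = np.clip(rng.beta(5.0, 5.0, size=n) * 0.5 + 0.25, 0.25, 0.75)
    length = np.exp(rng.normal(np.log(2000), 0.6, size=n)).round().astype(int)
    rel = np.exp(rng.normal(np.log(50.0), 1.2, size=n))
    rel /= rel.sum()
    return pd.DataFrame({"gene": names, "gc": gc, "length": length,
                         "rel_expression": rel}).set_index("gene")


def sample_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for sg in config.subgroups:
        for _ in range(sg.size):
            lib = rng.uniform(*config.library_size_range)
            rows.append({"sample_id": f"S{i:03d}", "subtype": sg.name,
                         "blast_fraction": sg.blast_fraction, "library_size": lib})
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# expression


def generate_expression(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the gene-level count matrix.

    Returns (counts genes x samples, gene metadata, ground truth). Signature
    genes are shifted by +/- signature_log2fc in the leukemic component only;
    the observed mean mixes the leukemic and shared baseline profiles in
    proportion blast : (1 - blast). Per-sample GC bias is a log-linear trend
    with sample-specific slope centered on ``gc_bias_slope``.
    """
    if not config.subgroups:
        raise ValueError("config must declare at least one subgroup")
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config, rng)
    samples = sample_table(config, rng)

    # assign disjoint signature gene sets, avoiding the named driver symbols
    candidates = [g for g in genes.index if g not in DRIVER_SYMBOLS]
    rng.shuffle(candidates)
    de_truth: dict[str, pd.DataFrame] = {}
    cursor = 0
    signature: dict[str, pd.Series] = {}
    for sg in config.subgroups:
        k = min(sg.n_signature_genes, len(candidates) - cursor)
        chosen = candidates[cursor: cursor + k]
        cursor += k
        direction = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        lfc = direction * sg.signature_log2fc
        signature[sg.name] = pd.Series(lfc, index=chosen)
        de_truth[sg.name] = pd.DataFrame({"gene": chosen, "log2fc": lfc}).set_index("gene")

    baseline = genes["rel_expression"].to_numpy()
    n_genes, n_samples = config.n_genes, len(samples)
    mean = np.empty((n_genes, n_samples))
    for j, (sid, row) in enumerate(samples.iterrows()):
        leuk = baseline.copy()
        sig = signature[row["subtype"]]
        if len(sig) and abs(sig.iloc[0]) > 0:
            idx = genes.index.get_indexer(sig.index)
            leuk[idx] = leuk[idx] * np.power(2.0, sig.to_numpy())
        profile = row["blast_fraction"] * leuk + (1.0 - row["blast_fraction"]) * baseline
        profile = profile / profile.sum()
        lib = row["library_size"] * config.depth_scale
        mu = profile * lib
        if config.gc_bias_slope != 0.0:
            slope = rng.normal(config.gc_bias_slope, 0.25 * abs(config.gc_bias_slope))
            bias = np.power(2.0, slope * (genes["gc"].to_numpy() - genes["gc"].mean()))
            mu = mu * bias
        mean[:, j] = np.maximum(mu, 1e-8)

    alpha = config.nb_dispersion
    if alpha > 0:
        # NB(mean mu, var mu + alpha mu^2) via gamma-Poisson mixture
        shape = 1.0 / alpha
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)
    counts_df = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    truth = GroundTruth(sample_truth=samples.reset_index()[["sample_id", "subtype", "blast_fraction"]],
                        de_truth=de_truth)
    return counts_df, genes, truth


# ---------------------------------------------------------------------------
# fusions


def generate_fusion_calls(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an Arriba-style fusion-call table.

    True subgroup-defining fusions get Poisson read support with expectation
    fusion_support_per_100m * (library / 100e6) * blast_fraction; calls with
    zero drawn support are not emitted (undetected). Spurious chimeras are
    added at ``fusion_noise_rate`` per sample with low support.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = gene_universe(config, np.random.default_rng(config.seed))
    samples = sample_table(config, np.random.default_rng(config.seed))
    spec_by_name = {s.name: s for s in config.subgroups}

    if config.noise_gene_pool == "all":
        noise_pool = list(genes.index)
    else:
        noise_pool = [g for g in genes.index if g not in DRIVER_SYMBOLS]

    rows, truth_rows = [], []
    for sid, row in samples.iterrows():
        sg = spec_by_name[row["subtype"]]
        if sg.defining_fusion is not None:
            g5, g3 = sg.defining_fusion
            lam = (config.fusion_support_per_100m * row["library_size"] / 100e6
                   * row["blast_fraction"])
            support = rng.poisson(lam)
            if support > 0:
                split = rng.binomial(support, 0.6)
                rows.append({"sample": sid, "gene5": g5, "gene3": g3,
                             "breakpoint5": f"chr{rng.integers(1, 23)}:{rng.integers(1e5, 1e8)}",
                             "breakpoint3": f"chr{rng.integers(1, 23)}:{rng.integers(1e5, 1e8)}",
                             "split_reads": int(split),
                             "spanning_reads": int(support - split)})
                truth_rows.append({"sample": sid, "gene5": g5, "gene3": g3, "class": "true"})
        n_noise = rng.poisson(config.fusion_noise_rate)
        for _ in range(n_noise):
            g5, g3 = rng.choice(noise_pool, size=2, replace=False)
            support = 1 + rng.poisson(2.0)
            split = rng.binomial(support, 0.6)
            rows.append({"sample": sid, "gene5": g5, "gene3": g3,
                         "breakpoint5": f"chr{rng.integers(1, 23)}:{rng.integers(1e5, 1e8)}",
                         "breakpoint3": f"chr{rng.integers(1, 23)}:{rng.integers(1e5, 1e8)}",
                         "split_reads": int(split),
                         "spanning_reads": int(support - split)})
            truth_rows.append({"sample": sid, "gene5": g5, "gene3": g3, "class": "noise"})
    calls = pd.DataFrame(rows, columns=FUSION_COLUMNS)
    truth = GroundTruth(
        sample_truth=samples.reset_index()[["sample_id", "subtype", "blast_fraction"]],
        fusion_truth=pd.DataFrame(truth_rows, columns=["sample", "gene5", "gene3", "class"]),
    )
    return calls, truth


# ---------------------------------------------------------------------------
# variants

_BASES = np.array(list("ACGT"))

# each artifact kind violates exactly the named downstream rule
ARTIFACT_KINDS = [
    "alt_reads", "tumor_af", "cohort_recurrent", "indel_cluster",
    "pop_af", "cadd", "predictor_benign", "impact", "removed_class",
]


def _passing_annotations(rng: np.random.Generator) -> dict:
    return {
        "alt_reads": int(6 + rng.poisson(15)),
        "tumor_af": float(rng.uniform(0.2, 0.6)),
        "pop_af_max": 0.0,
        "cadd_phred": float(rng.uniform(20, 35)),
        "consequence": "missense_variant",
        "variant_class": "missense",
        "impact": "MODERATE",
        "polyphen": "probably_damaging",
        "sift": "deleterious",
        "condel": "deleterious",
    }


def _random_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref = rng.choice(_BASES)
    alt = rng.choice([b for b in _BASES if b != ref])
    return str(ref), str(alt)


def generate_variants(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an annotated somatic-variant table.

    Emits, per sample: subgroup hotspot drivers (constructed to pass the full
    filter cascade), pathogenic-like passengers, planted artifacts each
    violating exactly one named filter rule, and an excess of A-to-I editing
    variants (T>C / A>G) that survive the caller-level filters.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = gene_universe(config, np.random.default_rng(config.seed))
    samples = sample_table(config, np.random.default_rng(config.seed))
    spec_by_name = {s.name: s for s in config.subgroups}
    gene_names = list(genes.index)
    non_driver = [g for g in gene_names if g not in DRIVER_SYMBOLS]

    # cohort-recurrent artifact sites, each planted in exactly
    # ceil(artifact_cooccurrence_fraction * n_samples) samples
    n_recurrent = rng.poisson(3) if (config.artifact_rate > 0
                                     and config.artifact_cooccurrence_fraction > 0) else 0
    n_carriers = int(np.ceil(config.artifact_cooccurrence_fraction * len(samples)))
    recurrent_sites = []
    for _ in range(n_recurrent):
        ref, alt = _random_substitution(rng)
        carriers = set(rng.choice(samples.index.to_numpy(), size=n_carriers, replace=False))
        recurrent_sites.append({
            "chrom": f"chr{rng.integers(1, 23)}", "pos": int(rng.integers(1e5, 1e8)),
            "ref": ref, "alt": alt, "gene": str(rng.choice(non_driver)),
            "carriers": carriers,
        })

    rows, truth_rows = [], []

    def emit(sid: str, record: dict, vclass: str, violated: str | None) -> None:
        rows.append({"sample_id": sid, **record})
        truth_rows.append({"sample_id": sid, "chrom": record["chrom"], "pos": record["pos"],
                           "ref": record["ref"], "alt": record["alt"],
                           "class": vclass, "violated_rule": violated})

    for sid, srow in samples.iterrows():
        sg = spec_by_name[srow["subtype"]]
        if sg.defining_hotspot is not None:
            gene, pchange = sg.defining_hotspot
            ref, alt = _random_substitution(rng)
            rec = {"chrom": f"chr{rng.integers(1, 23)}", "pos": int(rng.integers(1e5, 1e8)),
                   "ref": ref, "alt": alt, **_passing_annotations(rng),
                   "gene": gene, "protein_change": pchange}
            emit(sid, rec, "driver", None)
        for _ in range(rng.poisson(config.passenger_rate)):
            ref, alt = _random_substitution(rng)
            rec = {"chrom": f"chr{rng.integers(1, 23)}", "pos": int(rng.integers(1e5, 1e8)),
                   "ref": ref, "alt": alt, **_passing_annotations(rng),
                   "gene": str(rng.choice(non_driver)),
                   "protein_change": f"p.A{rng.integers(2, 900)}V"}
            emit(sid, rec, "passenger", None)
        # editing excess: A>G on the + strand reads, T>C on the - strand
        for _ in range(rng.poisson(config.editing_excess)):
            if rng.random() < 0.5:
                ref, alt = "A", "G"
            else:
                ref, alt = "T", "C"
            rec = {"chrom": f"chr{rng.integers(1, 23)}", "pos": int(rng.integers(1e5, 1e8)),
                   "ref": ref, "alt": alt, **_passing_annotations(rng),
                   "gene": str(rng.choice(non_driver)),
                   "protein_change": None}
            # editing events pass the caller-level filters but look benign to
            # the strict annotation cascade (mostly silent / low CADD)
            rec["tumor_af"] = max(float(rng.uniform(0.1, 0.6)), 0.10001)
            rec["variant_class"] = str(rng.choice(["silent", "missense", "intron", "IGR"],
                                                  p=[0.4, 0.2, 0.3, 0.1]))
            rec["consequence"] = ("synonymous_variant" if rec["variant_class"] == "silent"
                                  else "missense_variant")
            rec["cadd_phred"] = float(rng.uniform(0.0, 20.0))
            rec["polyphen"] = str(rng.choice(["benign", "possibly_damaging"]))
            emit(sid, rec, "editing", None)
        # artifacts: each violates exactly one rule
        for _ in range(rng.poisson(config.artifact_rate)):
            kind = str(rng.choice(ARTIFACT_KINDS[:2] + ARTIFACT_KINDS[4:]))
            ref, alt = _random_substitution(rng)
            rec = {"chrom": f"chr{rng.integers(1, 23)}", "pos": int(rng.integers(1e5, 1e8)),
                   "ref": ref, "alt": alt, **_passing_annotations(rng),
                   "gene": str(rng.choice(non_driver)), "protein_change": None}
            if kind == "alt_reads":
                rec["alt_reads"] = int(rng.integers(0, 6))
            elif kind == "tumor_af":
                rec["tumor_af"] = float(rng.uniform(0.0, 0.1))
            elif kind == "pop_af":
                rec["pop_af_max"] = float(rng.uniform(2e-4, 0.05))
            elif kind == "cadd":
                rec["cadd_phred"] = float(rng.uniform(0, 14.9))
            elif kind == "predictor_benign":
                which = rng.choice(["polyphen", "sift", "condel"])
                rec[str(which)] = {"polyphen": "benign", "sift": "tolerated",
                                   "condel": "neutral"}[str(which)]
            elif kind == "impact":
                rec["impact"] = str(rng.choice(["LOW", "MODIFIER"]))
            elif kind == "removed_class":
                rec["variant_class"] = str(rng.choice(["silent", "intron", "IGR",
                                                       "5'flank", "splice site"]))
                rec["consequence"] = "synonymous_variant"
            emit(sid, rec, "artifact", kind)
        # clustered indel pair (violates the indel-spacing rule)
        if config.artifact_rate > 0 and rng.random() < 0.5:
            chrom = f"chr{rng.integers(1, 23)}"
            pos = int(rng.integers(1e5, 1e8))
            gap = int(rng.integers(1, 21))
            for p in (pos, pos + gap):
                rec = {"chrom": chrom, "pos": p, "ref": "AT", "alt": "A",
                       **_passing_annotations(rng),
                       "gene": str(rng.choice(non_driver)), "protein_change": None}
                rec["variant_class"] = "frameshift"
                rec["consequence"] = "frameshift_variant"
                emit(sid, rec, "artifact", "indel_cluster")
        # cohort-recurrent artifacts
        for site in recurrent_sites:
            if sid in site["carriers"]:
                rec = {"chrom": site["chrom"], "pos": site["pos"], "ref": site["ref"],
                       "alt": site["alt"], **_passing_annotations(rng),
                       "gene": site["gene"], "protein_change": None}
                emit(sid, rec, "artifact", "cohort_recurrent")

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    truth = GroundTruth(
        sample_truth=samples.reset_index()[["sample_id", "subtype", "blast_fraction"]],
        variant_truth=pd.DataFrame(truth_rows),
    )
    return variants, truth


# ---------------------------------------------------------------------------
# paired tubes


def generate_paired_tubes(n_patients: int, n_genes: int = 2000,
                          n_tube_effect_genes: int = 100, tube_log2fc: float = 0.0,
                          patient_sd: float = 1.0, seed: int = 0,
                          mean_count: float = 100.0, nb_dispersion: float = 0.05,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired PAXgene/EDTA counts: two samples per patient sharing a
    patient-specific per-gene baseline (log-normal with log2-scale sd
    ``patient_sd``); a 2**tube_log2fc multiplicative effect is added to the
    designated genes in the PAXgene condition only.

    Returns (counts genes x samples, design table, ground truth).
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = np.exp(rng.normal(np.log(mean_count), 0.8, size=n_genes))
    effect_genes = list(rng.choice(genes, size=n_tube_effect_genes, replace=False)) \
        if tube_log2fc != 0.0 else []
    direction = np.where(np.arange(len(effect_genes)) % 2 == 0, 1.0, -1.0)

    cols, rows_meta = [], []
    counts = np.zeros((n_genes, 2 * n_patients), dtype=int)
    shape = 1.0 / nb_dispersion if nb_dispersion > 0 else None
    j = 0
    for p in range(n_patients):
        patient_effect = np.power(2.0, rng.normal(0.0, patient_sd, size=n_genes))
        for cond in ("PAXgene", "EDTA"):
            mu = base * patient_effect
            if cond == "PAXgene" and effect_genes:
                idx = pd.Index(genes).get_indexer(effect_genes)
                mu = mu.copy()
                mu[idx] = mu[idx] * np.power(2.0, direction * tube_log2fc)
            if shape is not None:
                lam = rng.gamma(shape, mu / shape)
                counts[:, j] = rng.poisson(lam)
            else:
                counts[:, j] = rng.poisson(mu)
            sid = f"P{p:02d}_{cond}"
            cols.append(sid)
            rows_meta.append({"sample_id": sid, "patient_id": f"P{p:02d}", "condition": cond})
            j += 1
    counts_df = pd.DataFrame(counts, index=genes, columns=cols)
    design = pd.DataFrame(rows_meta).set_index("sample_id")
    truth = GroundTruth(
        sample_truth=design.reset_index().assign(subtype=None, blast_fraction=1.0)[
            ["sample_id", "subtype", "blast_fraction"]],
        de_truth={"tube": pd.DataFrame({"gene": effect_genes,
                                        "log2fc": direction * tube_log2fc}).set_index("gene")},
    )
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# isoforms


@dataclass
class UsageShiftSpec:
    """Planted isoform-usage shift: in samples of ``subgroup``, gene ``gene``
    uses proportions ``shifted`` instead of the baseline proportions."""

    gene: str
    subgroup: str
    baseline: tuple[float, ...]
    shifted: tuple[float, ...]


def generate_isoform_counts(gene_counts: pd.DataFrame, shifts: list[UsageShiftSpec],
                            seed: int, sample_subtypes: pd.Series | None = None,
                            isoforms_per_gene: tuple[int, int] = (1, 4),
                            ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Split gene counts into isoform counts by per-gene multinomial draws.

    Isoform counts sum exactly to the gene count in every gene/sample.
    Returns (isoform counts, isoform->gene map, ground truth).
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_counts.index)
    n_iso = {g: int(rng.integers(isoforms_per_gene[0], isoforms_per_gene[1] + 1))
             for g in genes}
    base_props: dict[str, np.ndarray] = {}
    for g in genes:
        k = n_iso[g]
        base_props[g] = rng.dirichlet(np.full(k, 2.0)) if k > 1 else np.array([1.0])
    shift_by_gene: dict[str, dict[str, UsageShiftSpec]] = {}
    for sh in shifts:
        if sh.gene not in n_iso:
            raise ValueError(f"usage shift references unknown gene {sh.gene!r}")
        k = len(sh.baseline)
        if k < 2:
            raise ValueError(f"usage shift on single-isoform gene {sh.gene!r}")
        n_iso[sh.gene] = k
        base_props[sh.gene] = np.asarray(sh.baseline, dtype=float)
        shift_by_gene.setdefault(sh.gene, {})[sh.subgroup] = sh
    iso_names, iso_gene = [], []
    for g in genes:
        for t in range(n_iso[g]):
            iso_names.append(f"{g}.{t + 1}")
            iso_gene.append(g)
    iso_index = pd.Index(iso_names, name="isoform")
    out = np.zeros((len(iso_names), gene_counts.shape[1]), dtype=int)

    offsets = {}
    off = 0
    for g in genes:
        offsets[g] = off
        off += n_iso[g]

    for j, sample in enumerate(gene_counts.columns):
        subtype = None
        if sample_subtypes is not None and sample in sample_subtypes.index:
            subtype = sample_subtypes.loc[sample]
        for g in genes:
            total = int(gene_counts.iloc[gene_counts.index.get_loc(g), j])
            props = base_props[g]
            sh = shift_by_gene.get(g, {}).get(subtype)
            if sh is not None:
                props = np.asarray(sh.shifted, dtype=float)
            if total > 0:
                draw = rng.multinomial(total, props / props.sum())
            else:
                draw = np.zeros(len(props), dtype=int)
            out[offsets[g]: offsets[g] + n_iso[g], j] = draw

    iso_counts = pd.DataFrame(out, index=iso_index, columns=gene_counts.columns)
    iso_map = pd.DataFrame({"isoform": iso_names, "gene": iso_gene}).set_index("isoform")
    truth = GroundTruth(
        sample_truth=pd.DataFrame({"sample_id": gene_counts.columns,
                                   "subtype": [None] * gene_counts.shape[1],
                                   "blast_fraction": 1.0}),
        isoform_truth=pd.DataFrame([{"gene": sh.gene, "subgroup": sh.subgroup,
                                     "baseline": sh.baseline, "shifted": sh.shifted}
                                    for sh in shifts]),
    )
    return iso_counts, iso_map, truth
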