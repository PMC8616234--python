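# leukotype

Transcriptome-based subtyping of **B-other B-cell precursor acute
lymphoblastic leukemia (BCP-ALL)**.

A substantial fraction of childhood BCP-ALL carries none of the classical
risk-stratifying lesions (*ETV6-RUNX1*, *BCR-ABL1*, *KMT2A* rearrangements,
ploidy changes) detectable by conventional diagnostics — the "B-other"
group. Whole-transcriptome RNA-seq can resolve much of it: gene fusions are
read directly from chimeric reads, hotspot driver mutations (e.g. *PAX5*
p.P80R, *IKZF1* p.N159Y) from RNA-derived variant calls, and the remaining
samples can be assigned by how they co-cluster with validated subtypes in
expression space. `leukotype` implements that diagnostic workflow as a
tested, reusable library plus CLI, for bioinformaticians building or
evaluating RNA-seq-based leukemia diagnostics. Because clinical cohorts are
rarely shareable, the package ships a synthetic-cohort generator that
produces all inputs with known ground truth, so every step of the pipeline
is validated end to end.

## What it implements

**Fusion triage and classification.** A call from an Arriba-style table is
retained iff a partner gene is on a curated whitelist of ALL-relevant
genes, or — for other fusions — it has strictly more than 10 supporting
reads (junction + spanning) *and* the gene pair is a known leukemia fusion.
A sample is assigned the subtype of the retained, subtype-mapped call with
the highest share of the sample's supporting reads.

**RNA variant filter cascade.** Caller-level rules drop variants with
alt-read count < 6, tumor allele fraction ≤ 0.1, identical-site recurrence
in ≥ 40% of the cohort, or indels within 20 bp of each other; the strict
annotation stage additionally requires population AF ≤ 10⁻⁴ in every
group, CADD PHRED ≥ 15, no benign/tolerated/neutral predictor label, and
HIGH/MODERATE impact. A spectrum-mode dataset (population-AF rule only,
silent variants retained) feeds per-sample substitution spectra — dominated
in RNA by A-to-I editing, i.e. the collapsed T>C (A>G) class.

**Expression co-clustering.** Counts are GC-normalized within sample,
variance-stabilized (median-of-ratios size factors, log2), and a DEG panel
is built from the union of subgroup-vs-rest tests (NB-Wald, BH FDR < 0.05,
subgroups with ≥ 3 samples), ranked by median absolute deviation. Panel
sizes 300…3000 (step 50) are swept; each panel is embedded (t-SNE,
perplexity 20, or UMAP) and scored by mean silhouette; the best size wins.
Unknown samples take the majority label of their k = 10 nearest labeled
neighbors under correlation distance, when the majority reaches ≥ 50%.
Evidence tiers integrate with precedence fusion > hotspot > co-clustering.

**Differential isoform usage and concordance.** Per-isoform usage
(isoform / gene total) is compared subgroup-vs-rest with an overdispersed
proportion test; direction concordance between two result sets counts
shared isoforms with agreeing signs — the check used to corroborate that
unknown samples co-clustering with a subtype also share its splicing
profile.

**Paired tube comparison (PAXgene vs EDTA).** Paired NB differential
expression (per-patient intercepts + condition), effect-size tiers at
|log₂FC| > 1, 2, 3 (q < 0.05), rank score log₂FC × (−log₁₀ q) feeding
pre-ranked gene-set enrichment (weighted KS running sum, permutation null,
set sizes 15–500), correlation of expression with mRNA decay constants,
and hierarchical-clustering / PCA diagnostics.

## Worked example

```python
import pandas as pd, leukotype as lk

cfg = lk.default_cohort_config(seed=1)          # 60 samples, 5 subgroups
counts, gene_meta, truth = lk.generate_expression(cfg)
calls, _ = lk.generate_fusion_calls(cfg)
variants, _ = lk.generate_variants(cfg)

retained, dropped = lk.filter_fusions(calls)
print(f"fusion calls: {len(calls)} -> {len(retained)} retained")

labels = pd.Series(truth.sample_truth["subtype"].values,
                   index=truth.sample_truth["sample_id"].values)
known = labels[labels.isin(["DUX4", "ETV6-RUNX1-like"])].groupby(labels).head(6)
res = lk.classify_cohort(counts, gene_meta, calls, variants, known,
                         sweep_cfg=lk.PanelSweepConfig(seed=0, tsne_max_iter=1000))
print(f"selected panel size: {res.panel.best_size}")
print(res.assignments["evidence"].value_counts().to_string())
print(f"agreement with simulated truth: "
      f"{(res.assignments['label'] == labels).mean():.1%}")
```

Output:

```
fusion calls: 151 -> 27 retained
selected panel size: 983
evidence
fusion           27
reference        12
co-clustering    12
hotspot           9
agreement with simulated truth: 100.0%
```

The 151 raw calls contain 27 true subgroup-defining fusions plus simulated
chimeric artifacts; the filter keeps exactly the true ones. 27 samples are
then labeled by their fusion, 9 by the *PAX5* p.P80R hotspot, 12 were given
as validated references, and the remaining 12 unknowns are assigned by
co-clustering on the 983-gene panel — here all in agreement with the
simulated ground truth.

The same workflow is available from the shell:

```bash
leukotype simulate cohort --out cohort/ --seed 1
leukotype fusions filter --calls cohort/fusions.tsv --out retained.tsv
leukotype variants spectrum --table cohort/variants.tsv --out spectrum.tsv
```

## Layout

- `src/leukotype/simulate.py` — synthetic cohort generator (ground truth for everything below)
- `src/leukotype/fusions.py`, `variants.py` — fusion and variant filter cascades, hotspot/spectrum/co-occurrence summaries
- `src/leukotype/normalize.py`, `de.py`, `panel.py`, `classify.py`, `pipeline.py` — expression workflow (scikit-learn-style transformers and classifier)
- `src/leukotype/isoforms.py` — differential isoform usage and concordance
- `src/leukotype/tubes.py`, `gsea.py` — paired tube comparison and pre-ranked enrichment
- `docs/methods.md` — models, assumptions, parameter choices and limitations
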