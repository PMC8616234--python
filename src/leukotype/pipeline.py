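"""End-to-end cohort classification.

Chains the evidence tiers the way a diagnostic lab would: fusion triage
first, then hotspot mutations from the strict-filtered variant set, then
expression co-clustering of the remaining unknown samples against every
sample already labeled (validated references plus fusion/hotspot tiers)
on the swept DEG panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import fusions as fu
from . import variants as va
from .classify import assign_by_coclustering, integrate_assignments
from .normalize import gc_normalize, variance_stabilize
from .panel import PanelSweepConfig, PanelSweepResult, build_deg_panel


@dataclass
class CohortClassification:
    assignments: pd.DataFrame
    panel: PanelSweepResult
    fusion_tier: pd.DataFrame
    hotspot_tier: pd.DataFrame
    coclustering_tier: pd.DataFrame
    vst: pd.DataFrame


def classify_cohort(counts: pd.DataFrame, gene_meta: pd.DataFrame,
                    fusion_calls: pd.DataFrame, variant_table: pd.DataFrame,
                    known_labels: pd.Series,
                    rules: fu.FusionRuleSet | None = None,
                    hotspots: dict | None = None,
                    filter_config: va.VariantFilterConfig | None = None,
                    sweep_cfg: PanelSweepConfig | None = None,
                    k: int = 10, min_frac: float = 0.5) -> CohortClassification:
    """Run the full classification workflow over one cohort.

    ``known_labels`` holds validated reference subtypes for a subset of
    samples (NaN elsewhere). Returns final assignments for every sample
    (reference samples keep their label, marked evidence "reference").
    """
    rules = rules or fu.FusionRuleSet()
    samples = list(counts.columns)

    retained, _ = fu.filter_fusions(fusion_calls, rules)
    fusion_tier = fu.classify_by_fusion(retained, rules, samples=samples)

    caller_kept, _ = va.apply_caller_filters(variant_table, filter_config)
    strict = va.apply_annotation_filters(caller_kept, filter_config, mode="strict")
    hotspot_tier = va.classify_by_hotspot(strict, hotspots)

    # training labels: references take precedence, then fusion, then hotspot
    train = {}
    for sid in samples:
        if sid in known_labels.index and pd.notna(known_labels.get(sid)):
            train[sid] = known_labels[sid]
        elif sid in fusion_tier.index and pd.notna(fusion_tier.loc[sid, "subtype"]):
            train[sid] = fusion_tier.loc[sid, "subtype"]
        elif sid in hotspot_tier.index and pd.notna(hotspot_tier.loc[sid, "subtype"]):
            train[sid] = hotspot_tier.loc[sid, "subtype"]
    train_labels = pd.Series(train, dtype=object)

    norm = gc_normalize(counts, gene_meta["gc"])
    vst = variance_stabilize(norm)
    panel = build_deg_panel(counts, vst.values, train_labels, sweep_cfg)

    unknowns = [s for s in samples if s not in train_labels.index]
    panel_matrix = vst.values.loc[panel.panel_genes]
    if unknowns:
        cocluster = assign_by_coclustering(panel_matrix, train_labels, unknowns,
                                           k=min(k, len(train_labels)),
                                           min_frac=min_frac)
    else:
        cocluster = pd.DataFrame(columns=["label", "confidence",
                                          "neighbor_breakdown", "evidence"])

    final = integrate_assignments(fusion_tier, hotspot_tier, cocluster, samples)
    # validated references keep their label regardless of tiers
    for sid, lab in known_labels.dropna().items():
        if sid in final.index and final.loc[sid, "evidence"] == "unassigned":
            final.loc[sid, ["label", "evidence", "confidence"]] = [lab, "reference", 1.0]
        elif sid in final.index and final.loc[sid, "label"] is None:
            final.loc[sid, ["label", "evidence", "confidence"]] = [lab, "reference", 1.0]
    return CohortClassification(assignments=final, panel=panel,
                                fusion_tier=fusion_tier, hotspot_tier=hotspot_tier,
                                coclustering_tier=cocluster, vst=vst.values)
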