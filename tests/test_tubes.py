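"""Paired tube comparison: DE, tiers, rank scores, enrichment, decay, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import leukotype as lk
from leukotype.gsea import enrichment_score, _order_ranking


# ---------------------------------------------------------------------------
# paired DE


def test_paired_null_calibration():
    counts, design, _ = lk.generate_paired_tubes(6, n_genes=2000, tube_log2fc=0.0,
                                                 patient_sd=1.0, seed=31)
    res = lk.paired_differential_expression(counts, design)
    assert 0.02 <= (res["pvalue"] < 0.05).mean() <= 0.08


def test_paired_power_on_planted_tube_effect():
    counts, design, truth = lk.generate_paired_tubes(
        6, n_genes=2000, n_tube_effect_genes=100, tube_log2fc=3.0,
        patient_sd=1.0, seed=32)
    res = lk.paired_differential_expression(counts, design)
    eff = res.index.intersection(truth.de_truth["tube"].index)
    assert (res.loc[eff, "qvalue"] < 0.05).sum() >= 90


def test_paired_antisymmetry_and_patient_offset_invariance():
    counts, design, _ = lk.generate_paired_tubes(4, n_genes=300,
                                                 n_tube_effect_genes=30,
                                                 tube_log2fc=2.0, seed=33)
    res = lk.paired_differential_expression(counts, design)
    res_swap = lk.paired_differential_expression(counts, design,
                                                 baseline_condition="PAXgene")
    assert np.allclose(res["log2_fold_change"], -res_swap["log2_fold_change"],
                       atol=1e-6)
    # multiplying one patient's both samples by a constant leaves fold
    # changes unchanged
    scaled = counts.copy()
    cols = design.index[design["patient_id"] == "P00"]
    scaled[cols] = (scaled[cols] * 3).round().astype(int)
    res_scaled = lk.paired_differential_expression(scaled, design)
    common = res.index.intersection(res_scaled.index)
    assert np.abs(res.loc[common, "log2_fold_change"]
                  - res_scaled.loc[common, "log2_fold_change"]).median() < 0.02


def test_paired_design_errors():
    counts, design, _ = lk.generate_paired_tubes(3, n_genes=100, seed=1)
    broken = design.copy()
    broken.loc[broken.index[0], "condition"] = "EDTA"  # duplicate condition
    with pytest.raises(ValueError, match="paired"):
        lk.paired_differential_expression(counts, broken)


# ---------------------------------------------------------------------------
# tiers and rank score


def test_effect_size_tiers_boundaries_and_nesting():
    res = pd.DataFrame({
        "log2_fold_change": [1.0, 1.5, 2.5, -2.5, 3.5, -0.5, 4.0, -3.1, 2.0, 1.1],
        "qvalue": [0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.2, 0.03, 0.04, 0.06],
    }, index=[f"g{i}" for i in range(10)])
    tiers = lk.effect_size_tiers(res)
    # hand enumeration: q<0.05 & |lfc|>1: g1,g2,g3,g4,g7,g8; >2: g2,g3,g4,g7; >3: g4,g7
    assert tiers.loc[1.0, "n_total"] == 6
    assert tiers.loc[2.0, "n_total"] == 4
    assert tiers.loc[3.0, "n_total"] == 2
    assert "g0" not in tiers.loc[1.0, "genes"]  # |lfc| = 1.0 is excluded
    assert tiers.loc[1.0, "n_up"] == 4 and tiers.loc[1.0, "n_down"] == 2
    for lo, hi in ((2.0, 1.0), (3.0, 2.0)):
        assert set(tiers.loc[lo, "genes"]) <= set(tiers.loc[hi, "genes"])


def test_rank_score_values_and_clamping():
    assert lk.rank_score(2.0, 0.01) == pytest.approx(4.0)
    assert lk.rank_score(-1.0, 0.1) == pytest.approx(-1.0)
    assert lk.rank_score(5.0, 1.0) == 0.0
    with pytest.warns(UserWarning, match="clamped"):
        out = lk.rank_score(1.0, 0.0)
    assert np.isfinite(out) and out > 300


# ---------------------------------------------------------------------------
# pre-ranked enrichment


def normal_ranking(rng, n=1000):
    genes = [f"g{i}" for i in range(n)]
    return pd.Series(np.sort(rng.normal(0, 1, n))[::-1], index=genes)


def test_planted_set_enriched_and_size_filter(rng):
    ranking = normal_ranking(rng)
    sets = {"top": set(ranking.index[:20]), "small": set(ranking.index[:14]),
            "bottom": set(ranking.index[-20:])}
    res = lk.preranked_enrichment(ranking, sets, n_perm=200, seed=5)
    assert "small" not in res.index and "small" in res.attrs["skipped"]
    assert res.loc["top", "es"] > 0
    assert res.loc["top", "pvalue"] <= 2 / 100
    assert res.loc["top", "fdr"] < 0.05
    assert res.loc["bottom", "es"] < 0 and res.loc["bottom", "nes"] < 0


def test_null_pvalues_uniform_and_floored(rng):
    ranking = normal_ranking(rng)
    sets = {f"r{i}": set(rng.choice(ranking.index, 30, replace=False))
            for i in range(100)}
    res = lk.preranked_enrichment(ranking, sets, n_perm=500, seed=6)
    assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01
    assert res["pvalue"].min() >= 1.0 / 501
    # determinism under the seed
    res2 = lk.preranked_enrichment(ranking, sets, n_perm=500, seed=6)
    pd.testing.assert_frame_equal(res, res2)


def test_enrichment_score_against_gseapy(rng):
    """Cross-check the running-sum ES against an independent implementation."""
    gseapy = pytest.importorskip("gseapy")
    ranking = _order_ranking(normal_ranking(rng, 300))
    members = set(rng.choice(ranking.index, 25, replace=False))
    mask = np.array([g in members for g in ranking.index])
    ours = enrichment_score(ranking, mask)
    rnk = pd.DataFrame({"gene": ranking.index, "score": ranking.to_numpy()})
    pre = gseapy.prerank(rnk=rnk, gene_sets={"s": list(members)}, min_size=2,
                         max_size=500, permutation_num=10, seed=1,
                         outdir=None, no_plot=True)
    theirs = float(pre.res2d["ES"].iloc[0])
    assert ours == pytest.approx(theirs, abs=0.02)


# ---------------------------------------------------------------------------
# decay correlation


def test_decay_null_and_planted_shift(rng):
    genes = [f"g{i}" for i in range(500)]
    tpm = pd.DataFrame({"PAXgene": np.exp(rng.normal(3, 1, 500)),
                        "EDTA": np.exp(rng.normal(3, 1, 500))}, index=genes)
    decay = pd.Series(rng.normal(0.5, 0.15, 500), index=genes)  # independent
    up, down = genes[:250], genes[250:]
    cmp0 = lk.decay_correlation(tpm, decay, up, down)
    assert cmp0.evaluable
    assert (cmp0.correlations["spearman_rho"].abs() < 0.1).all()

    decay_shift = decay.copy()
    decay_shift.loc[up] -= 0.15  # planted lower decay in upregulated set
    cmp1 = lk.decay_correlation(tpm, decay_shift, up[:200], down[:200])
    assert cmp1.up_median < cmp1.down_median
    assert cmp1.direction == -1
    assert cmp1.ranksum_p < 0.05


def test_decay_identity_and_insufficient_overlap(rng):
    genes = [f"g{i}" for i in range(50)]
    tpm = pd.DataFrame({"PAXgene": np.ones(50), "EDTA": np.ones(50)}, index=genes)
    decay = pd.Series(rng.uniform(0, 1, 50), index=genes)
    same = lk.decay_correlation(tpm, decay, genes[:20], genes[:20])
    assert same.up_median == same.down_median and same.direction == 0
    short = lk.decay_correlation(tpm, decay, genes[:5], genes[5:25])
    assert not short.evaluable


# ---------------------------------------------------------------------------
# clustering / PCA diagnostics


def test_patients_cluster_together(cohort=None):
    counts, design, _ = lk.generate_paired_tubes(6, n_genes=1500,
                                                 n_tube_effect_genes=100,
                                                 tube_log2fc=1.0, patient_sd=1.5,
                                                 seed=41)
    vst = lk.variance_stabilize(counts).values
    proj = lk.cluster_and_project(vst, n_top_variable=1000)
    order = proj.dendrogram_order
    siblings = 0
    for pid in design["patient_id"].unique():
        pair = list(design.index[design["patient_id"] == pid])
        i, j = order.index(pair[0]), order.index(pair[1])
        siblings += int(abs(i - j) == 1)
    assert siblings >= 5
    vf = proj.variance_fractions
    assert (np.diff(vf) <= 1e-12).all() and vf.sum() <= 1.0 + 1e-9


def test_duplicate_sample_joined_first(rng):
    from tests.conftest import nb_counts
    counts = nb_counts(rng, 400, 6)
    counts["dup"] = counts["s0"]
    vst = lk.variance_stabilize(counts).values
    with pytest.warns(UserWarning, match="clamped"):
        proj = lk.cluster_and_project(vst, n_top_variable=1000)
    first_merge = proj.linkage[0]
    cols = list(vst.columns)
    merged = {cols[int(first_merge[0])], cols[int(first_merge[1])]}
    assert merged == {"s0", "dup"}
    assert first_merge[2] < 1e-6
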