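"""Enrichment, ROC/AUC, predictor table, expression linkage."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import methylctcf as m
from methylctcf.intervals import GenomicInterval, IntervalSet


def brute_force_auc(scores, labels):
    """All-pairs reference: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, roc = m.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0

    def test_worked_examples(self):
        assert m.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])[0] == 1.0
        assert m.roc_auc([1, 2, 3, 4], [0, 1, 0, 1])[0] == 0.75

    def test_all_ties_is_half(self):
        assert m.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])[0] == 0.5

    def test_matches_brute_force_with_ties(self, rng):
        scores = rng.integers(0, 20, 300).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 300)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        auc, _ = m.roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500)
        labels = (rng.random(500) < 0.3).astype(int)
        auc, _ = m.roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_negation_identity(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.5).astype(int)
        a1, _ = m.roc_auc(scores, labels)
        a2, _ = m.roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_direction_less_flips(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.5).astype(int)
        a1, _ = m.roc_auc(scores, labels, "greater")
        a2, _ = m.roc_auc(scores, labels, "less")
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.roc_auc([1, 2, 3], [1, 1, 1])


class TestFoldEnrichment:
    def test_all_inside_small_feature(self):
        feature = IntervalSet([GenomicInterval("chr1", 0, 50_000)])  # 5% of 1 Mb
        query = IntervalSet(
            [GenomicInterval("chr1", i * 400, i * 400 + 100) for i in range(100)]
        )
        res = m.fold_enrichment(query, feature, genome_size=1_000_000)
        assert res.observed == 100
        assert res.fold == pytest.approx(100 / (100 * 0.05))
        assert res.percent_overlap == 100.0

    def test_random_query_fold_near_one(self, rng):
        feature = IntervalSet([GenomicInterval("chr1", i * 10_000, i * 10_000 + 1000) for i in range(100)])
        starts = rng.integers(0, 999_000, 2000)
        query = IntervalSet([GenomicInterval("chr1", int(s), int(s) + 1) for s in starts])
        res = m.fold_enrichment(query, feature, genome_size=1_000_000)
        assert res.fold == pytest.approx(1.0, abs=0.15)

    def test_permutation_agrees_with_analytic(self, rng):
        """For point-like query elements the analytic expectation is exact."""
        feature = IntervalSet(
            [GenomicInterval("chr1", i * 20_000, i * 20_000 + 2000) for i in range(25)]
        )
        starts = rng.integers(0, 499_000, 300)
        query = IntervalSet([GenomicInterval("chr1", int(s), int(s) + 1) for s in starts])
        analytic = m.fold_enrichment(query, feature, genome_size=500_000)
        perm = m.fold_enrichment(
            query,
            feature,
            genome_size=500_000,
            method="permutation",
            n_perm=200,
            seed=1,
            chrom_lengths={"chr1": 500_000},
        )
        # permutation expectation within 3 Monte-Carlo SEs of the analytic one
        se = np.sqrt(analytic.expected) / np.sqrt(200)
        assert abs(perm.expected - analytic.expected) <= max(3 * se, 0.05 * analytic.expected)
        assert perm.p_value is not None

    def test_feature_covering_genome_rejected(self):
        feature = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        query = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            m.fold_enrichment(query, feature, genome_size=1000)


class TestPredictorTable:
    def test_columns_and_labels(self, default_sim, default_motif_sites, default_occupancy):
        occ_wt, occ_dko = default_occupancy
        table = m.build_predictor_table(
            default_motif_sites, occ_wt, occ_dko, default_sim.meth_wt, default_sim.bundle.sequences
        )
        assert set(table["label"]) == {0, 1}
        assert {"motif_score", "delta_nuc_occupancy", "methylation_level", "flank_cpg_density"} <= set(
            table.columns
        )

    def test_cpg_free_flank_density_zero(self, default_occupancy, default_sim):
        from methylctcf.ctcf_sites import SiteCall

        genome = {"chrX": "AT" * 2000}
        occ = m.SignalTrack({"chrX": np.zeros(4000)}, "per_million")
        site = SiteCall(
            GenomicInterval("chrX", 2000, 2019, strand="+"), "common", "motif", motif_score=10.0
        )
        lost = SiteCall(
            GenomicInterval("chrX", 1000, 1019, strand="+"), "lost", "motif", motif_score=5.0
        )
        table = m.build_predictor_table([site, lost], occ, occ, default_sim.meth_wt, genome)
        assert (table["flank_cpg_density"] == 0).all()

    def test_lost_sites_gain_occupancy_in_dko(
        self, default_sim, default_motif_sites, default_occupancy
    ):
        """Nucleosomes move onto vacated CTCF motifs: delta > 0 at lost sites."""
        occ_wt, occ_dko = default_occupancy
        table = m.build_predictor_table(
            default_motif_sites, occ_wt, occ_dko, default_sim.meth_wt, default_sim.bundle.sequences
        )
        lost = table[table["label"] == 1]["delta_nuc_occupancy"]
        common = table[table["label"] == 0]["delta_nuc_occupancy"]
        assert lost.mean() > 0
        assert lost.mean() > common.mean()

    def test_density_distributions_separate_labels(
        self, default_sim, default_motif_sites, default_occupancy
    ):
        occ_wt, occ_dko = default_occupancy
        table = m.build_predictor_table(
            default_motif_sites, occ_wt, occ_dko, default_sim.meth_wt, default_sim.bundle.sequences
        )
        assert (
            table[table["label"] == 0]["flank_cpg_density"].median()
            > table[table["label"] == 1]["flank_cpg_density"].median()
        )


class TestExpressionLinkage:
    def _toy(self):
        tads = IntervalSet([GenomicInterval("chr1", 0, 100_000), GenomicInterval("chr1", 100_000, 200_000)])
        loops = IntervalSet([GenomicInterval("chr1", 99_999, 100_001)])
        lost = IntervalSet([GenomicInterval("chr1", 99_000, 99_300)])
        rows = []
        # 10 up / 5 down scattered far from boundaries; 2 up / 8 down near the lost one
        for i in range(10):
            rows.append((f"u{i}", "chr1", 150_000 + 1500 * i, 152_000 + 1500 * i, "+", 1.0, "up"))
        for i in range(5):
            rows.append((f"d{i}", "chr1", 30_000 + 1500 * i, 32_000 + 1500 * i, "+", -1.0, "down"))
        for i in range(2):
            rows.append((f"bu{i}", "chr1", 95_000 + 100 * i, 104_000, "+", 1.0, "up"))
        for i in range(8):
            rows.append((f"bd{i}", "chr1", 95_000 + 100 * i, 104_000, "+", -1.0, "down"))
        tx = pd.DataFrame(
            rows, columns=["transcript_id", "chrom", "start", "end", "strand", "log2fc", "signif"]
        )
        return tx, tads, loops, lost

    def test_toy_ratios_and_chi_square(self):
        tx, tads, loops, lost = self._toy()
        res = m.expression_linkage(tx, tads, loops, lost).set_index("category")
        gw = res.loc["genome_wide"]
        assert (gw["n_up"], gw["n_down"]) == (12, 13)
        near = res.loc["near_lost_tad_boundary"]
        assert (near["n_up"], near["n_down"]) == (2, 8)
        assert near["down_up_ratio"] == pytest.approx(4.0)
        chi2, p, _, _ = chi2_contingency([[12, 13], [2, 8]], correction=False)
        assert near["chi2"] == pytest.approx(chi2)
        assert near["p_value"] == pytest.approx(p)

    def test_no_lost_sites_lost_categories_empty(self):
        tx, tads, loops, _ = self._toy()
        res = m.expression_linkage(tx, tads, loops, IntervalSet()).set_index("category")
        for cat in ("in_tad_with_lost_boundary", "near_lost_tad_boundary", "lost_ctcf_at_promoter"):
            assert res.loc[cat, "n_total"] == 0

    def test_transcript_outside_tads_not_in_tad_categories(self):
        tads = IntervalSet([GenomicInterval("chr1", 0, 50_000)])
        tx = pd.DataFrame(
            [("t1", "chr1", 80_000, 90_000, "+", 0.0, "ns")],
            columns=["transcript_id", "chrom", "start", "end", "strand", "log2fc", "signif"],
        )
        res = m.expression_linkage(tx, tads, IntervalSet(), IntervalSet()).set_index("category")
        assert res.loc["inside_tads", "n_total"] == 0
        assert res.loc["genome_wide", "n_total"] == 1

    def test_boosted_categories_exceed_genome_wide(self, default_sim, default_consensus):
        lost = IntervalSet(
            [c.interval for c in default_consensus if c.category == "lost"]
        )
        res = m.expression_linkage(
            default_sim.transcripts, default_sim.tads, default_sim.loops, lost
        ).set_index("category")
        gw = res.loc["genome_wide", "down_up_ratio"]
        assert res.loc["near_lost_tad_boundary", "down_up_ratio"] > gw
        assert res.loc["lost_ctcf_at_promoter", "down_up_ratio"] > gw
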