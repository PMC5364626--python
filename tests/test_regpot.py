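"""Binding scores, rank-product regulatory potential and direction tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulomekit import synth
from regulomekit.genome import GenomeLayout, PeakSet, tss_tes
from regulomekit.regpot import (
    binding_score,
    binding_scores,
    classify_expression,
    ks_direction_test,
    regulatory_potential,
    regulome_classify,
    tss_binding_enrichment,
)
from .conftest import make_gene, make_peak


class TestClassifyExpression:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "fpkm_1", "fpkm_2", "fpkm_3"])

    def test_all_zero_is_silenced(self):
        out = classify_expression(self.frame([("g1", 0.0, 0.0, 0.0)]))
        assert not out[0].expressed

    def test_single_nonzero_replicate_is_expressed(self):
        out = classify_expression(self.frame([("g1", 0.0, 0.0, 0.1)]))
        assert out[0].expressed

    def test_partition_property(self, rng):
        rows = [(f"g{i}", *np.where(rng.random(3) < 0.4, 0.0, rng.random(3)))
                for i in range(100)]
        out = classify_expression(self.frame(rows))
        assert len(out) == 100
        for e in out:
            assert e.expressed == (max(e.fpkm) > 0)

    def test_negative_fpkm_raises(self):
        with pytest.raises(ValueError):
            classify_expression(self.frame([("g1", -0.1, 0.0, 0.0)]))


class TestBindingScore:
    GENE = make_gene("g1", "chr1", 50_000, 60_000, strand="+")  # TSS 50 000

    def test_no_peaks_in_window(self):
        peaks = PeakSet([make_peak("chr1", 200_000, 200_300)])
        bs = binding_score(self.GENE, peaks, window=100_000)
        assert bs.k == 0 and bs.s_binding == 0.0

    def test_peak_at_tss(self):
        peaks = PeakSet([make_peak("chr1", 49_900, 50_100, summit_pos=50_000)])
        bs = binding_score(self.GENE, peaks, window=100_000)
        assert bs.k == 1
        assert bs.s_binding == pytest.approx(math.exp(-0.5), abs=1e-9)

    def test_two_peak_formula_evaluation(self):
        # summits 25 kb and 50 kb from the TSS, window 100 kb
        peaks = PeakSet(
            [make_peak("chr1", 74_900, 75_100, summit_pos=75_000),
             make_peak("chr1", 99_900, 100_100, summit_pos=100_000)]
        )
        bs = binding_score(self.GENE, peaks, window=100_000)
        assert bs.s_binding == pytest.approx(
            math.exp(-1.5) + math.exp(-2.5), abs=1e-9
        )

    def test_monotone_in_distance(self):
        scores = []
        for pos in (90_000, 70_000, 50_000):  # summits moving toward the TSS
            peaks = PeakSet([make_peak("chr1", pos - 100, pos + 100, summit_pos=pos)])
            scores.append(binding_score(self.GENE, peaks, window=100_000).s_binding)
        assert scores[0] < scores[1] < scores[2]

    def test_adding_a_peak_never_decreases(self):
        one = PeakSet([make_peak("chr1", 60_000, 60_200, summit_pos=60_100)])
        two = PeakSet([make_peak("chr1", 60_000, 60_200, summit_pos=60_100),
                       make_peak("chr1", 80_000, 80_200, summit_pos=80_100)])
        assert binding_score(self.GENE, two).s_binding > \
            binding_score(self.GENE, one).s_binding

    def test_batch_agrees_with_single(self, small_genome):
        layout, genes, _ = small_genome
        peaks, _ = synth.gen_peaks(genes, layout, 500, tss_bias=0.5, seed=1)
        batch = binding_scores(genes[:50], peaks).set_index("gene")
        for g in genes[:50]:
            single = binding_score(g, peaks)
            assert batch.loc[g.gene_id, "s_binding"] == pytest.approx(single.s_binding)
            assert batch.loc[g.gene_id, "k"] == single.k


class TestRegulatoryPotential:
    def make_inputs(self, s, q, lfc=None):
        genes = [f"g{i}" for i in range(len(s))]
        scores = pd.DataFrame({"gene": genes, "s_binding": s})
        de = pd.DataFrame(
            {"gene": genes, "log2fc": lfc if lfc is not None else [1.0] * len(s),
             "pvalue": q, "qvalue": q}
        )
        return scores, de

    def test_single_gene_rp_is_one(self):
        scores, de = self.make_inputs([0.5], [0.01])
        rec = regulatory_potential(scores, de)
        assert rec["rp"].iloc[0] == pytest.approx(1.0)

    def test_three_gene_hand_ranked(self):
        scores, de = self.make_inputs([0.6, 0.3, 0.1], [0.001, 0.5, 0.9])
        rec = regulatory_potential(scores, de).set_index("gene")
        np.testing.assert_allclose(
            rec.loc[["g0", "g1", "g2"], "rp"], [1 / 9, 4 / 9, 1.0]
        )

    def test_relabeling_permutes_without_changing_rp(self):
        scores, de = self.make_inputs([0.6, 0.3, 0.1], [0.001, 0.5, 0.9])
        rec1 = regulatory_potential(scores, de)
        perm = [2, 0, 1]
        scores2 = scores.iloc[perm].reset_index(drop=True)
        de2 = de.iloc[perm].reset_index(drop=True)
        rec2 = regulatory_potential(scores2, de2)
        merged = rec1.merge(rec2, on="gene", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["rp_a"], merged["rp_b"])

    def test_rp_in_unit_interval_and_minimum_attained(self, rng):
        n = 50
        s = rng.random(n)
        q = rng.random(n)
        scores, de = self.make_inputs(s, q)
        rec = regulatory_potential(scores, de)
        assert ((rec["rp"] > 0) & (rec["rp"] <= 1)).all()
        best = rec.loc[rec["rp"].idxmin(), "gene"]
        # the strongest-binding, most-significant gene wins when it is unique
        idx_best_s, idx_best_q = int(np.argmax(s)), int(np.argmin(q))
        if idx_best_s == idx_best_q:
            assert best == f"g{idx_best_s}"

    def test_q_zero_clamped_not_crashing(self):
        scores, de = self.make_inputs([0.6, 0.3], [0.0, 0.5])
        rec = regulatory_potential(scores, de)
        assert np.isfinite(rec["rp"]).all()

    def test_missing_gene_raises_with_name(self):
        scores, de = self.make_inputs([0.6, 0.3], [0.01, 0.5])
        with pytest.raises(ValueError, match="g1"):
            regulatory_potential(scores.iloc[:1], de)


class TestKsDirectionTest:
    def make_records(self, rp_by_class):
        rows = []
        for cls, rps in rp_by_class.items():
            rows += [{"gene": f"{cls}{i}", "rp": rp, "direction": cls}
                     for i, rp in enumerate(rps)]
        return pd.DataFrame(rows)

    def test_identical_samples_d_zero(self):
        vals = np.linspace(0.1, 0.9, 40)
        rec = self.make_records({"up": vals, "down": vals, "static": vals})
        res = ks_direction_test(rec)
        assert res.d_up == 0.0 and res.d_down == 0.0

    def test_null_false_positive_rate(self):
        """Labels independent of RP: direction calls at 1% stay rare."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rp = rng.random(600)
            labels = np.repeat(["up", "down", "static"], 200)
            rng.shuffle(labels)
            rec = pd.DataFrame({"gene": range(600), "rp": rp, "direction": labels})
            res = ks_direction_test(rec)
            if res.p_up < 0.01 or res.p_down < 0.01:
                hits += 1
        # two tests per seed at the 1% level: Binomial(100, ~0.02);
        # 8 allows for the familywise null rate with generous headroom
        assert hits <= 8

    def test_planted_down_enrichment_detected(self, small_genome):
        """Binding-driven downregulation yields a significant down-vs-static shift."""
        layout, genes, _ = small_genome
        peaks, _ = synth.gen_peaks(genes, layout, 800, tss_bias=0.5,
                                   proximity_window=500, seed=11)
        tables, truth = synth.plant_binding_dependent_de(
            genes, peaks, window=1000, bound_odds=5.0, down_bias=0.85, seed=11
        )
        # decay window matched to the toy genome's gene spacing
        scores = binding_scores(genes, peaks, window=5000)
        rec = regulatory_potential(scores, tables["NC_vs_A"])
        res = ks_direction_test(rec)
        assert res.p_down < 0.01
        assert res.stronger_down_fraction > 0.5

    def test_empty_class_raises(self):
        rec = self.make_records({"up": [0.1], "down": [0.2], "static": []})
        with pytest.raises(ValueError, match="static"):
            ks_direction_test(rec)

    def test_binding_independent_of_de_shows_no_binding_shift(self, small_genome):
        """When DE is planted without reference to peaks, the binding-score
        distributions of up/down/static genes are indistinguishable."""
        layout, genes, _ = small_genome
        peaks, _ = synth.gen_peaks(genes, layout, 800, tss_bias=0.5, seed=12)
        ids = [g.gene_id for g in genes]
        tables, _ = synth.gen_de_tables(ids, {"AC": 60}, 0, seed=12)
        scores = binding_scores(genes, peaks).set_index("gene")
        de = tables["NC_vs_A"].set_index("gene")
        sig = de["qvalue"] < 0.05
        d, p = stats.ks_2samp(scores.loc[sig[sig].index, "s_binding"],
                              scores.loc[sig[~sig].index, "s_binding"])
        assert p > 0.01


class TestTssBindingEnrichment:
    def test_uniform_peaks_near_unit_fold(self, small_genome):
        layout, genes, _ = small_genome
        peaks, _ = synth.gen_peaks(genes, layout, 3000, tss_bias=0.0, seed=13)
        folds = tss_binding_enrichment(peaks, {"all": genes}, layout, window=1000)
        # ~3000 uniform summits over an ~11% TSS footprint: fold ≈ 1 within
        # a few Monte-Carlo standard errors
        assert folds["all"] == pytest.approx(1.0, abs=0.35)

    def test_all_peaks_in_windows_closed_form(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        genes = [make_gene("g1", "chr1", 100_000, 110_000),
                 make_gene("g2", "chr1", 500_000, 510_000)]
        peaks = PeakSet(
            [make_peak("chr1", 99_900, 100_100, summit_pos=100_000),
             make_peak("chr1", 499_900, 500_100, summit_pos=500_000)]
        )
        window = 1000
        folds = tss_binding_enrichment(peaks, {"X": genes}, layout, window=window)
        footprint = 2 * (2 * window + 1)
        assert folds["X"] == pytest.approx(1_000_000 / footprint)

    def test_no_peaks_gives_zero_fold(self, small_genome):
        layout, genes, _ = small_genome
        folds = tss_binding_enrichment(PeakSet([]), {"all": genes}, layout)
        assert folds["all"] == 0.0

    def test_expressed_vs_silenced_contrast(self, small_genome):
        """Peaks planted only at expressed-gene TSSs: fold(expressed) wins."""
        layout, genes, _ = small_genome
        fpkm, _ = synth.gen_expression([g.gene_id for g in genes],
                                       silenced_fraction=0.4, seed=14)
        expressed_ids = {
            e.gene_id for e in classify_expression(fpkm) if e.expressed
        }
        expressed = [g for g in genes if g.gene_id in expressed_ids]
        silenced = [g for g in genes if g.gene_id not in expressed_ids]
        peaks, _ = synth.gen_peaks(expressed, layout, 600, tss_bias=0.9,
                                   proximity_window=500, seed=14)
        folds = tss_binding_enrichment(
            peaks, {"expressed": expressed, "silenced": silenced}, layout, window=1000
        )
        assert folds["expressed"] > folds["silenced"]
        assert folds["expressed"] > 2.0

    def test_empty_gene_set_raises(self, small_genome):
        layout, genes, _ = small_genome
        with pytest.raises(ValueError):
            tss_binding_enrichment(PeakSet([]), {"empty": []}, layout)


class TestRegulomeClassify:
    def test_no_peaks_empty_regulome(self, toy_layout):
        genes = [make_gene(f"g{i}", "chr1", 1000 * (i + 1), 1000 * (i + 1) + 400)
                 for i in range(5)]
        classes = {g.gene_id: cls for g, cls in
                   zip(genes, ["up", "down", "static", "static", "static"])}
        fractions, regulome = regulome_classify(PeakSet([]), genes, classes, toy_layout)
        assert all(v == 0 for v in fractions.values() if not np.isnan(v))
        assert len(regulome) == 0

    def test_hand_counted_toy(self, toy_layout):
        # 10 genes: 4 DE (3 bound), 6 static (1 bound); TSS at 2000·(i+1)
        genes = [make_gene(f"g{i}", "chr1", 2000 * (i + 1), 2000 * (i + 1) + 500)
                 for i in range(10)]
        classes = {f"g{i}": ("up" if i < 2 else "down" if i < 4 else "static")
                   for i in range(10)}
        bound_idx = [0, 1, 2, 4]  # 3 DE genes and 1 static gene
        peaks = PeakSet(
            [make_peak("chr1", 2000 * (i + 1) - 100, 2000 * (i + 1) + 100,
                       summit_pos=2000 * (i + 1)) for i in bound_idx]
        )
        fractions, regulome = regulome_classify(peaks, genes, classes, toy_layout,
                                                promoter_window=1000)
        de_bound = (fractions["up"] * 2 + fractions["down"] * 2) / 4
        assert de_bound == pytest.approx(0.75)
        assert fractions["static"] == pytest.approx(1 / 6)
        assert len(regulome) == 3

    def test_class_must_partition(self, toy_layout):
        genes = [make_gene("g0", "chr1", 1000, 2000)]
        with pytest.raises(ValueError):
            regulome_classify(PeakSet([]), genes, {}, toy_layout)
        with pytest.raises(ValueError):
            regulome_classify(PeakSet([]), genes, {"g0": "sideways"}, toy_layout)

    def test_planted_bound_fraction_gap_recovered(self, small_genome):
        layout, genes, _ = small_genome
        peaks, _ = synth.gen_peaks(genes, layout, 600, tss_bias=0.6,
                                   proximity_window=500, seed=15)
        tables, truth = synth.plant_binding_dependent_de(
            genes, peaks, window=1000, bound_odds=6.0, seed=15
        )
        de = tables["NC_vs_A"]
        sig = de["qvalue"] < 0.05
        sign = np.sign(de["log2fc"])
        classes = {
            g: ("static" if not s else "up" if sg > 0 else "down")
            for g, s, sg in zip(de["gene"], sig, sign)
        }
        fractions, _ = regulome_classify(peaks, genes, classes, layout,
                                         promoter_window=1000)
        de_frac = np.nanmean([fractions["up"], fractions["down"]])
        assert de_frac > fractions["static"]
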