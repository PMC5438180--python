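import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromloop as cl
from chromloop.enrichment import features_to_bins
from chromloop.tracks import BinTrack
from conftest import simple_calls


def track(values, bin_size=250, chrom="chr1"):
    return BinTrack(bin_size, {chrom: np.asarray(values, dtype=float)})


class TestChromatinState:
    def test_two_gaussian_mixture_recovery(self):
        """Log-ratio modes at +/-2 (sd 0.5) are separated with >= 98%
        label accuracy."""
        rng = np.random.default_rng(1)
        n = 4000
        lab = rng.random(n) < 0.5
        ratio = np.where(lab, 2.0, -2.0) + rng.normal(0, 0.5, n)
        k4 = np.exp2(ratio)
        k9 = np.ones(n)
        out = cl.classify_chromatin_state(track(k4), track(k9), pseudocount=0.0)
        acc = ((out["chromatin_state"] == "active") == lab).mean()
        assert acc >= 0.98

    def test_all_zero_k9_with_pseudocount_all_active(self):
        out = cl.classify_chromatin_state(track(np.full(2000, 8.0)),
                                          track(np.zeros(2000)))
        assert (out["chromatin_state"] == "active").all()

    def test_unimodal_fallback_warning(self):
        rng = np.random.default_rng(2)
        k4 = np.exp2(rng.normal(0, 0.3, 2000))
        with pytest.warns(UserWarning, match="unimodal"):
            cl.classify_chromatin_state(track(k4), track(np.ones(2000)),
                                        pseudocount=0.0)

    def test_empty_track_error(self):
        with pytest.raises(ValueError):
            cl.classify_chromatin_state(track([]), track([]))


class TestMethylationClass:
    def test_boundary_is_high(self):
        out = cl.classify_methylation(track([0.1, 0.0999, 0.5]), "meCHH")
        assert out["meth_class"].tolist() == ["high", "low", "high"]

    def test_threshold_zero_all_high(self):
        out = cl.classify_methylation(track([0.0, 0.3]), "meCG", threshold=0.0)
        assert (out["meth_class"] == "high").all()

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            cl.classify_methylation(track([1.2]), "meCG")

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(3)
        lab = rng.random(3000) < 0.5
        v = np.clip(np.where(lab, 0.9, 0.05) + rng.normal(0, 0.04, 3000), 0, 1)
        out = cl.classify_methylation(track(v), "meCG")
        assert ((out["meth_class"] == "high") == lab).mean() >= 0.99


class TestDmbClassification:
    # hand-evaluated worked table: (wt, mut, ratio, status); boundary
    # rows use binary-exact fractions so 0.25 / 0.75 are hit exactly
    WORKED = [
        (0.30, 0.03, "nrpe1_DMB"),     # 0.1
        (0.30, 0.30, "other_meCHH"),   # 1.0
        (0.30, 0.15, "neither"),       # 0.5
        (0.50, 0.125, "neither"),      # exactly 0.25 -> neither
        (0.50, 0.375, "neither"),      # exactly 0.75 -> neither
        (0.20, 0.19, "other_meCHH"),   # 0.95
        (0.20, 0.01, "nrpe1_DMB"),     # 0.05
        (0.50, 0.20, "neither"),       # 0.4
        (0.25, 0.24, "other_meCHH"),   # 0.96
        (0.60, 0.12, "nrpe1_DMB"),     # 0.2
        (0.80, 0.10, "nrpe1_DMB"),     # 0.125
        (0.80, 0.70, "other_meCHH"),   # 0.875
        (0.40, 0.12, "neither"),       # 0.3
        (0.40, 0.28, "neither"),       # 0.7
        (0.10, 0.09, "other_meCHH"),   # 0.9
        (0.10, 0.02, "nrpe1_DMB"),     # 0.2
        (0.64, 0.32, "neither"),       # 0.5
        (0.64, 0.64, "other_meCHH"),   # 1.0
        (0.32, 0.04, "nrpe1_DMB"),     # 0.125
        (0.32, 0.30, "other_meCHH"),   # 0.9375
    ]

    def test_worked_table(self):
        wt_v = [w for w, _, _ in self.WORKED]
        mut_v = [m for _, m, _ in self.WORKED]
        expected = [s for _, _, s in self.WORKED]
        high = pd.DataFrame({"chrom": "chr1", "bin": range(len(wt_v))})
        out = cl.classify_dmbs(track(wt_v), track(mut_v), high)
        assert out["dmb_status"].tolist() == expected

    def test_boundary_ratios_are_neither(self):
        high = pd.DataFrame({"chrom": "chr1", "bin": [0, 1]})
        out = cl.classify_dmbs(track([0.4, 0.4]), track([0.1, 0.3]), high)
        assert out["dmb_status"].tolist() == ["neither", "neither"]

    def test_zero_wt_excluded(self):
        high = pd.DataFrame({"chrom": "chr1", "bin": [0, 1]})
        out = cl.classify_dmbs(track([0.0, 0.4]), track([0.1, 0.04]), high)
        assert len(out) == 1 and out["dmb_status"].iloc[0] == "nrpe1_DMB"


class TestMappability:
    def test_zero_coverage_removed_and_identity(self):
        feats = pd.DataFrame({"chrom": "chr1", "start": [0, 500],
                              "end": [250, 750], "name": ["a", "b"]})
        ctrl = track([0.0, 0.0, 5.0])
        out = cl.mappability_filter(feats, ctrl)
        assert out["name"].tolist() == ["b"]
        full = cl.mappability_filter(feats, track([3.0, 3.0, 3.0]))
        assert len(full) == 2

    def test_active_inactive_control_comparable(self, small_genome, study):
        """With a uniform decrosslinked control, filtered active and
        inactive bins show indistinguishable control-read levels."""
        _, bundle, _ = study
        state = cl.classify_chromatin_state(bundle.h3k4me2, bundle.h3k9me2)
        ctrl = bundle.control_coverage
        lv = lambda sub: np.array([ctrl[c][b] for c, b in
                                   zip(sub["chrom"], sub["bin"])])
        act = lv(state[state["chromatin_state"] == "active"].sample(500, random_state=0))
        ina = lv(state[state["chromatin_state"] == "inactive"].sample(500, random_state=0))
        p = stats.mannwhitneyu(act[act > 0], ina[ina > 0]).pvalue
        assert p > 0.001


class TestOverlapEnrichment:
    def test_saturation_ratio_one(self, small_genome, study, wt_pairs):
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        r = cl.overlap_enrichment(calls, uni, uni, n_perm=100, seed=1)
        assert r["ratio"] == pytest.approx(1.0)

    def test_null_ratio_calibrated(self, small_genome, study):
        """Randomly placed features on uniformly spread calls show no
        enrichment (ratio within [0.9, 1.1] at n_perm=1000, >= 500
        feature bins)."""
        _, bundle, _ = study
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        rng = np.random.default_rng(4)
        idx = rng.integers(0, len(uni), size=(3000, 2))
        calls = pd.DataFrame({
            "chrom_a": uni["chrom"].to_numpy()[idx[:, 0]],
            "bin_a": uni["bin"].to_numpy()[idx[:, 0]],
            "chrom_b": uni["chrom"].to_numpy()[idx[:, 1]],
            "bin_b": uni["bin"].to_numpy()[idx[:, 1]],
            "count": 3})
        feat = uni.iloc[rng.choice(len(uni), size=600, replace=False)]
        r = cl.overlap_enrichment(calls, feat, uni, n_perm=1000, seed=2)
        assert 0.9 <= r["ratio"] <= 1.1

    def test_planted_direction(self, small_genome, study, wt_pairs, mut_pairs):
        """DMB bins are enriched for calls in the mutant (loops on) and
        depleted in wild-type (contacts suppressed)."""
        from conftest import dmb_bins
        _, bundle, _ = study
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        fb = dmb_bins(bundle)
        r_wt = cl.overlap_enrichment(
            simple_calls(wt_pairs, small_genome.restriction), fb, uni,
            n_perm=200, seed=3)
        r_mut = cl.overlap_enrichment(
            simple_calls(mut_pairs, small_genome.restriction), fb, uni,
            n_perm=200, seed=3)
        assert r_mut["ratio"] > 1.0
        assert r_wt["ratio"] < 1.0

    def test_empty_features_error(self, small_genome, study, wt_pairs):
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        with pytest.raises(ValueError):
            cl.overlap_enrichment(calls, uni.iloc[:0], uni, n_perm=100, seed=1)

    def test_deterministic(self, small_genome, study, wt_pairs):
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        fb = features_to_bins(bundle.features["dmrs"], 250)
        a = cl.overlap_enrichment(calls, fb, uni, n_perm=100, seed=9)
        b = cl.overlap_enrichment(calls, fb, uni, n_perm=100, seed=9)
        assert a["expected"] == b["expected"]


class TestMatchedComparison:
    def test_matching_removes_about_half(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        wt_chh = bundle.methylation["Col0"]["meCHH"]
        high = cl.classify_methylation(wt_chh, "meCHH")
        high = high[high["meth_class"] == "high"]
        labs = cl.classify_dmbs(wt_chh, bundle.methylation["nrpe1"]["meCHH"], high)
        dmb = labs[labs["dmb_status"] == "nrpe1_DMB"][["chrom", "bin"]]
        oth = labs[labs["dmb_status"] == "other_meCHH"][["chrom", "bin"]]
        calls = simple_calls(mut_pairs, small_genome.restriction)
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        res = cl.matched_comparison(dmb, oth, wt_chh, "low", calls, uni,
                                    n_perm=100, seed=1)
        # identical level distributions: matching keeps about half of the DMBs
        assert 0.3 <= res["dmb"]["n_features"] / len(dmb) <= 0.7

    def test_degenerate_mode_error(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        dmb = pd.DataFrame({"chrom": "chr1", "bin": [0, 1]})
        oth = pd.DataFrame({"chrom": "chr1", "bin": [10, 11]})
        levels = track([0.1, 0.2] + [0.0] * 8 + [0.8, 0.9])
        calls = simple_calls(mut_pairs, small_genome.restriction)
        uni = cl.mappable_universe(small_genome, bundle.control_coverage, 250)
        with pytest.raises(ValueError, match="low"):
            cl.matched_comparison(dmb, oth, levels, "low", calls, uni,
                                  n_perm=100, seed=1)


class TestReplicateTtest:
    def test_identical_is_one(self):
        assert cl.replicate_ttest([1, 2, 3], [1, 2, 3]) == 1.0

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert cl.replicate_ttest([2, 3, 4], [1, 2, 3]) == 0.0

    def test_closed_form_three_pairs(self):
        a = np.array([3.1, 4.5, 2.2])
        b = np.array([2.0, 3.1, 2.5])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p = 2 * stats.t.sf(abs(t), df=2)
        assert cl.replicate_ttest(a, b) == pytest.approx(p, abs=1e-12)

    def test_too_few(self):
        with pytest.raises(ValueError):
            cl.replicate_ttest([1.0], [2.0])


class TestDmrLoopCounts:
    def test_identical_calls_ratio_one(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        out = cl.dmr_loop_counts({"Col0": calls, "nrpe1": calls},
                                 bundle.features["dmrs"], [0.0], "Col0")
        assert (out["ratio_to_wt"] == 1.0).all()

    def test_mutant_direction_and_cutoffs(self, small_genome, study,
                                          wt_pairs, mut_pairs):
        _, bundle, _ = study
        wt_calls = simple_calls(wt_pairs, small_genome.restriction)
        mut_calls = simple_calls(mut_pairs, small_genome.restriction)
        cutoffs = [0.0, float(mut_calls["score"].median())]
        out = cl.dmr_loop_counts({"Col0": wt_calls, "nrpe1": mut_calls},
                                 bundle.features["dmrs"], cutoffs, "Col0")
        mut = out[out["genotype"] == "nrpe1"]
        assert (mut["ratio_to_wt"].dropna() > 1.0).all()

    def test_cutoff_above_max(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        out = cl.dmr_loop_counts({"Col0": calls, "nrpe1": calls},
                                 bundle.features["dmrs"],
                                 [calls["score"].max() + 1], "Col0")
        assert (out["n_dmrs_with_calls"] == 0).all()
        assert out["ratio_to_wt"].isna().all()


class TestNucleosomeStrata:
    def test_boundary_and_infinite_threshold(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        by_g = {"Col0": calls, "nrpe1": calls}
        dmrs = bundle.features["dmrs"]
        # threshold infinity: everything in the "not reduced" stratum
        out = cl.nucleosome_stratified_counts(by_g, dmrs, bundle.mnase_ratio,
                                              [0.0], "Col0", threshold=np.inf)
        assert set(out["stratum"]) == {"not_reduced"}

    def test_ratio_exactly_two_not_reduced(self):
        mnase = track([2.0, 2.0])
        dmrs = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [500],
                             "name": ["d"]})
        calls = pd.DataFrame({"chrom_a": ["chr1"], "bin_a": [0],
                              "chrom_b": ["chr1"], "bin_b": [40],
                              "count": [3], "score": [5.0]})
        out = cl.nucleosome_stratified_counts({"Col0": calls}, dmrs, mnase,
                                              [0.0], "Col0", threshold=2.0)
        assert set(out["stratum"]) == {"not_reduced"}
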