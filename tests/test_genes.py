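import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromloop as cl
import chromloop.genes as gm
from conftest import simple_calls


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "start", "end"])


SIZES = {"chr1": 100_000}


class TestPromoters:
    @pytest.mark.parametrize("strand,tss,expected", [
        ("+", 5000, (4000, 5000)),
        ("-", 5000, (5000, 6000)),
        ("+", 300, (0, 300)),          # clipped at the chromosome start
        ("-", 99_500, (99_500, 100_000)),  # clipped at the end
    ])
    def test_conventions(self, strand, tss, expected):
        genes = gene_frame([("g", "chr1", strand, tss, tss - 100, tss + 100)])
        out = cl.define_promoters(genes, SIZES)
        assert (out["start"].iloc[0], out["end"].iloc[0]) == expected

    def test_tss_outside_chromosome(self):
        genes = gene_frame([("g", "chr1", "+", 200_000, 0, 100)])
        with pytest.raises(ValueError):
            cl.define_promoters(genes, SIZES)


class TestExpressionGroups:
    def test_sizes(self):
        genes = pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(100)],
                              "rpkm": np.arange(100, dtype=float)})
        gr = cl.expression_groups(genes, "rpkm", fraction=0.05)
        assert all(len(v) == 5 for v in gr.values())
        assert gr["inactive"] == [f"g{i:03d}" for i in range(5)]
        assert gr["active"] == [f"g{i:03d}" for i in range(95, 100)]

    def test_ties_deterministic(self):
        genes = pd.DataFrame({"gene_id": [f"g{i:02d}" for i in range(40)],
                              "rpkm": 1.0})
        a = cl.expression_groups(genes, "rpkm", 0.1)
        b = cl.expression_groups(genes.sample(frac=1, random_state=3), "rpkm", 0.1)
        assert a == b

    def test_too_few_genes(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "rpkm": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cl.expression_groups(genes, "rpkm", fraction=0.05)


class TestPromoterStats:
    def test_shares_sum_and_saturation(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        prom = cl.define_promoters(bundle.genes, small_genome.chrom_sizes)
        all_genes = {"all": bundle.genes["gene_id"].tolist()}
        out = cl.promoter_interaction_stats(calls, prom, all_genes)
        assert out["observed_pct"].iloc[0] == pytest.approx(100.0)
        assert out["expected_pct"].iloc[0] == pytest.approx(100.0)

    def test_active_genes_more_connected(self, small_genome, study, wt_pairs):
        """Constitutively looped genes are expression-boosted by the
        generator, so the active 5% captures more than its share of
        promoter interactions."""
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        prom = cl.define_promoters(bundle.genes, small_genome.chrom_sizes)
        gr = cl.expression_groups(bundle.genes, "rpkm_Col0")
        out = cl.promoter_interaction_stats(calls, prom, gr).set_index("group")
        assert (out.loc["active", "observed_pct"]
                > out.loc["inactive", "observed_pct"])
        assert (out.loc["active", "observed_pct"]
                > out.loc["active", "expected_pct"])

    def test_no_promoter_calls_error(self, study, small_genome):
        _, bundle, _ = study
        prom = cl.define_promoters(bundle.genes, small_genome.chrom_sizes)
        empty = pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b", "bin_b",
                                      "count", "score"])
        with pytest.raises(ValueError):
            cl.promoter_interaction_stats(empty, prom, {"all": []})


class TestExpressionByInteraction:
    def test_coupled_scores_separate_groups(self):
        """When interaction signal is coupled to expression, the highest-
        signal promoters express more than the lowest (rank-sum p < 0.01
        at 2000 genes)."""
        rng = np.random.default_rng(0)
        n = 2000
        genes = pd.DataFrame({
            "gene_id": [f"g{i:05d}" for i in range(n)], "chrom": "chr1",
            "strand": "+", "tss": np.arange(n) * 40 + 1000,
            "start": np.arange(n) * 40 + 1000, "end": np.arange(n) * 40 + 1020,
            "rpkm": rng.lognormal(1, 1, n)})
        sizes = {"chr1": 200_000}
        prom = cl.define_promoters(genes, sizes, upstream=20)
        # one call per gene, score proportional to rpkm
        calls = pd.DataFrame({
            "chrom_a": "chr1", "bin_a": (genes["tss"] - 10) // 250,
            "chrom_b": "chr1", "bin_b": 700 + np.arange(n) % 50,
            "count": 3, "score": genes["rpkm"] * 10})
        out = cl.expression_by_interaction_level(calls, prom, genes, "rpkm",
                                                 resolution=250)
        assert out["median_rpkm"]["highest"] > out["median_rpkm"]["lowest"]
        assert out["p_lowest_vs_highest"] < 0.01

    def test_null_scores_no_separation(self):
        rng = np.random.default_rng(1)
        pvals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            genes = pd.DataFrame({
                "gene_id": [f"g{i:04d}" for i in range(n)], "chrom": "chr1",
                "strand": "+", "tss": np.arange(n) * 100 + 1000,
                "start": np.arange(n) * 100 + 1000,
                "end": np.arange(n) * 100 + 1050,
                "rpkm": rng.lognormal(1, 1, n)})
            prom = cl.define_promoters(genes, {"chr1": 100_000}, upstream=50)
            calls = pd.DataFrame({
                "chrom_a": "chr1", "bin_a": (genes["tss"] - 10) // 250,
                "chrom_b": "chr1", "bin_b": 390,
                "count": 3, "score": rng.lognormal(2, 1, n)})
            out = cl.expression_by_interaction_level(calls, prom, genes, "rpkm",
                                                     resolution=250)
            pvals.append(out["p_lowest_vs_highest"])
        assert min(pvals) > 1e-4 and max(pvals) > 0.05


class TestTfConnections:
    def test_wired_high_rpkm_genes(self, small_genome, study, wt_pairs):
        """Constitutive loops wire TF peaks to expression-boosted genes:
        connected genes out-express unconnected ones."""
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        prom = cl.define_promoters(bundle.genes, small_genome.chrom_sizes)
        out = cl.tf_connected_expression(calls, {"TF1": bundle.features["tf_peaks"]},
                                         prom, bundle.genes, "rpkm_Col0")
        row = out.iloc[0]
        assert row["n_connected"] > 0
        assert row["connected_median"] > row["unconnected_median"]

    def test_empty_peaks_skipped(self, small_genome, study, wt_pairs):
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        prom = cl.define_promoters(bundle.genes, small_genome.chrom_sizes)
        with pytest.warns(UserWarning):
            out = cl.tf_connected_expression(
                calls, {"none": bundle.features["tf_peaks"].iloc[:0]},
                prom, bundle.genes, "rpkm_Col0")
        assert len(out) == 0

    def test_no_peaks_covering_anything(self, small_genome, study, wt_pairs):
        _, bundle, _ = study
        calls = simple_calls(wt_pairs, small_genome.restriction)
        prom = cl.define_promoters(bundle.genes, small_genome.chrom_sizes)
        far = pd.DataFrame({"chrom": ["chr1"], "start": [499_000],
                            "end": [499_100], "name": ["x"]})
        out = cl.tf_connected_expression(calls, {"TFX": far}, prom,
                                         bundle.genes, "rpkm_Col0")
        assert out["n_connected"].iloc[0] == 0


class TestSurface:
    def test_mutant_peak_wildtype_flat(self, small_genome, study,
                                       wt_pairs, mut_pairs):
        """The TSS x DMR surface peaks near the planted offsets in the
        mutant and stays flat in wild-type."""
        _, bundle, _ = study
        mut_calls = simple_calls(mut_pairs, small_genome.restriction)
        wt_calls = simple_calls(wt_pairs, small_genome.restriction)
        s_mut = cl.tss_dmr_surface(mut_calls, bundle.genes,
                                   bundle.features["dmrs"], small_genome,
                                   n_random=10, seed=1)
        s_wt = cl.tss_dmr_surface(wt_calls, bundle.genes,
                                  bundle.features["dmrs"], small_genome,
                                  n_random=10, seed=1)
        n = len(s_mut.tss_offsets)
        c = n // 2
        central = s_mut.matrix[c - 8: c + 8, c - 8: c + 8]
        assert central.max() == s_mut.matrix.max()
        assert s_mut.matrix.max() > 10 * max(s_wt.matrix.max(), 1e-9)

    def test_window_validation(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        with pytest.raises(ValueError):
            cl.tss_dmr_surface(calls, bundle.genes, bundle.features["dmrs"],
                               small_genome, window=5010, n_random=10)
        with pytest.raises(ValueError):
            cl.tss_dmr_surface(calls, bundle.genes, bundle.features["dmrs"],
                               small_genome, n_random=5)

    def test_no_qualifying_interactions_zero_surface(self, small_genome, study):
        _, bundle, _ = study
        empty = pd.DataFrame(columns=["chrom_a", "bin_a", "chrom_b", "bin_b",
                                      "count", "score"])
        with pytest.warns(UserWarning):
            s = cl.tss_dmr_surface(empty, bundle.genes, bundle.features["dmrs"],
                                   small_genome, n_random=10, seed=2)
        assert not s.matrix.any()


class TestGeneDmrConnections:
    def test_identical_calls_ratio_one(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        gene_set = bundle.genes["gene_id"].iloc[:50].tolist()
        out = cl.gene_dmr_connections({"Col0": calls, "nrpe1": calls}, gene_set,
                                      bundle.genes, bundle.features["dmrs"],
                                      small_genome, "Col0", score_cutoff=0,
                                      n_control_sets=5, seed=1)
        assert out["ratios"]["nrpe1"] == 1.0

    def test_de_genes_gain_connections_in_mutant(self, small_genome, study,
                                                 wt_pairs, mut_pairs):
        """Up-regulated genes gain promoter-DMR connections in the
        mutant while random gene sets do not (ratio > control)."""
        _, bundle, _ = study
        wt_calls = simple_calls(wt_pairs, small_genome.restriction)
        mut_calls = simple_calls(mut_pairs, small_genome.restriction)
        de = bundle.genes[bundle.genes["de_label"] == "up"]["gene_id"].tolist()
        assert de, "generator must up-regulate loop-connected genes"
        out = cl.gene_dmr_connections({"Col0": wt_calls, "nrpe1": mut_calls},
                                      de, bundle.genes, bundle.features["dmrs"],
                                      small_genome, "Col0", score_cutoff=0,
                                      n_control_sets=10, seed=2)
        assert out["counts"]["nrpe1"] > out["counts"]["Col0"]

    def test_empty_gene_set(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        with pytest.raises(ValueError):
            cl.gene_dmr_connections({"Col0": calls}, [], bundle.genes,
                                    bundle.features["dmrs"], small_genome, "Col0")


class TestDeDirectionSplit:
    def test_coupling_detected(self):
        rng = np.random.default_rng(3)
        n = 300
        connected = {f"g{i:03d}" for i in range(100)}
        lfc = rng.normal(0.5, 0.5, n)
        lfc[:100] += 2.0   # connected genes more strongly up
        genes = pd.DataFrame({"gene_id": [f"g{i:03d}" for i in range(n)],
                              "log2fc": lfc})
        out = cl.de_direction_split(genes, connected)
        assert out["positive"]["median_connected"] > out["positive"]["median_unconnected"]
        assert out["positive"]["p_value"] < 0.01

    def test_all_connected_warns(self):
        genes = pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = cl.de_direction_split(genes, {"a", "b"})
        assert "positive" not in out


class TestAgo4Classes:
    def _setup(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        return bundle, calls

    def test_classes_exclusive_exhaustive(self, small_genome, study, mut_pairs):
        bundle, calls = self._setup(small_genome, study, mut_pairs)
        out = cl.ago4_localization_classes(calls, bundle.genes,
                                           bundle.features["ago4_peaks"],
                                           small_genome)
        g = out["genes"]
        assert not (set(g["promoter_only"]) & set(g["distal_only"]))
        assert not (set(g["promoter_only"]) & set(g["both"]))
        total = out["promoter_only"] + out["distal_only"] + out["both"]
        assert total == len(set().union(*map(set, g.values())))
        assert total > 0

    def test_distal_requires_min_sites(self):
        """An anchor 2 cut sites from the gene does not qualify as
        distal under the >= 3-sites rule."""
        import chromloop.genome as gn
        rmap = gn.RestrictionMap({"chr1": np.array([12_000, 13_000, 20_000,
                                                    30_000, 40_000])})
        genome = cl.SyntheticGenome({"chr1": 100_000}, rmap)
        genes = gene_frame([("g", "chr1", "+", 10_000, 10_000, 11_000)])
        # anchor at bin 56 (pos 14_125): sites 12k,13k between -> only 2
        calls = pd.DataFrame({"chrom_a": ["chr1"], "bin_a": [38],
                              "chrom_b": ["chr1"], "bin_b": [56],
                              "count": [3], "score": [5.0]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [14_000],
                              "end": [14_250], "name": ["p"]})
        out = cl.ago4_localization_classes(calls, genes, peaks, genome)
        assert out["distal_only"] == 0
        # moving the anchor beyond a third site qualifies it
        calls2 = calls.assign(bin_b=[90])  # pos 22_625: 3 sites away
        peaks2 = pd.DataFrame({"chrom": ["chr1"], "start": [22_500],
                               "end": [22_750], "name": ["p"]})
        out2 = cl.ago4_localization_classes(calls2, genes, peaks2, genome)
        assert out2["distal_only"] == 1


class TestUpstreamDistances:
    def test_abutting_peak_distance_zero(self):
        genes = gene_frame([("g", "chr1", "+", 5000, 5000, 6000)])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [4500],
                              "end": [5000], "name": ["p"]})
        out = cl.upstream_peak_distances(genes, peaks)
        assert out["distances"]["g"] == 0

    def test_all_beyond_cutoff(self):
        genes = gene_frame([("g", "chr1", "+", 50_000, 50_000, 51_000)])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                              "end": [1100], "name": ["p"]})
        out = cl.upstream_peak_distances(genes, peaks, cutoff=2500)
        assert out["fraction_within_cutoff"] == 0.0

    def test_poisson_peaks_mean_spacing(self):
        """Uniform peaks at density rho give mean nearest upstream
        distance ~ 1/rho (exponential spacing)."""
        rng = np.random.default_rng(5)
        rho = 1 / 2000  # one peak per 2 kb
        starts = np.sort(rng.integers(0, 10_000_000, size=5000))
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 10, "name": "p"})
        genes = gene_frame([(f"g{i}", "chr1", "+", int(t), int(t), int(t) + 10)
                            for i, t in enumerate(
                                rng.integers(100_000, 9_900_000, size=500))])
        out = cl.upstream_peak_distances(genes, peaks)
        mean_d = np.mean(list(out["distances"].values()))
        assert mean_d == pytest.approx(1 / rho, rel=0.25)


class TestDistanceOrientation:
    def test_sign_convention_minus_strand(self, small_genome):
        genes = gene_frame([("g", "chr1", "-", 100_000, 99_000, 100_000)])
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [120_000],
                             "end": [120_500], "name": ["d"]})
        calls = pd.DataFrame({"chrom_a": ["chr1"], "bin_a": [401],
                              "chrom_b": ["chr1"], "bin_b": [480],
                              "count": [3], "score": [5.0]})
        out = cl.dmr_gene_distance_orientation(calls, genes, dmrs, small_genome)
        # DMR is 20 kb to the right of a minus-strand TSS -> upstream
        assert out["orientation"].iloc[0] == "upstream"
        assert out["signed_distance"].iloc[0] < 0

    def test_symmetric_plant_balanced(self, small_genome, study, mut_pairs):
        _, bundle, _ = study
        calls = simple_calls(mut_pairs, small_genome.restriction)
        out = cl.dmr_gene_distance_orientation(calls, bundle.genes,
                                               bundle.features["dmrs"],
                                               small_genome)
        if len(out) >= 20:
            up = (out["orientation"] == "upstream").mean()
            assert 0.2 <= up <= 0.8
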