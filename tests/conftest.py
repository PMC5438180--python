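import numpy as np
import pandas as pd
import pytest

import chromloop as cl


def empty_truth(genotypes=("wt",)):
    """A truth ledger with no planted loops and no suppression."""
    loops = pd.DataFrame(columns=[
        "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
        "kind_a", "kind_b", "gene_id"] + [f"mult_{g}" for g in genotypes])
    sup = pd.DataFrame(columns=["chrom", "start", "end", "why"]
                       + [f"retain_{g}" for g in genotypes])
    return cl.SyntheticTruth(loops, sup, tuple(genotypes))


def make_truth(loops_rows, genotypes, sup_rows=None):
    cols = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
            "kind_a", "kind_b", "gene_id"] + [f"mult_{g}" for g in genotypes]
    loops = pd.DataFrame(loops_rows, columns=cols)
    scols = ["chrom", "start", "end", "why"] + [f"retain_{g}" for g in genotypes]
    sup = pd.DataFrame(sup_rows or [], columns=scols)
    return cl.SyntheticTruth(loops, sup, tuple(genotypes))


@pytest.fixture(scope="session")
def small_genome():
    return cl.generate_genome(n_chroms=3, chrom_length=500_000,
                              site_density=4.0, seed=11)


@pytest.fixture(scope="session")
def study(small_genome):
    """A small but complete synthetic study: tracks, features, truth."""
    cfg = cl.TrackConfig(n_dmrs=20, n_false_dmrs=10, n_other_mechh=20,
                         n_genes=150, n_tf_peaks=40, n_rddm_loops=12,
                         n_neutral_dmr_loops=8, n_constitutive_loops=8,
                         loop_distance=(15_000, 200_000))
    bundle, truth = cl.generate_tracks_and_features(small_genome, cfg, seed=12)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def wt_pairs(small_genome, study):
    _, _, truth = study
    return cl.simulate_read_pairs(small_genome, truth, "Col0", 120_000, seed=13)


@pytest.fixture(scope="session")
def mut_pairs(small_genome, study):
    _, _, truth = study
    return cl.simulate_read_pairs(small_genome, truth, "nrpe1", 120_000, seed=13)


def dmb_bins(bundle, wt="Col0", mut="nrpe1"):
    """Classified DMB bins (chrom, bin) from the methylation tracks."""
    from chromloop.enrichment import classify_dmbs, classify_methylation
    high = classify_methylation(bundle.methylation[wt]["meCHH"], "meCHH")
    high = high[high["meth_class"] == "high"]
    labs = classify_dmbs(bundle.methylation[wt]["meCHH"],
                         bundle.methylation[mut]["meCHH"], high)
    return labs[labs["dmb_status"] == "nrpe1_DMB"][["chrom", "bin"]]


def simple_calls(pairs, rmap, resolution=250, min_reads=2):
    """Filter, bin, call, score — the standard simple-caller chain."""
    filt = cl.filter_pairs_by_sites(pairs, rmap)
    binned = cl.bin_pairs(filt, resolution)
    t = cl.derive_count_threshold(binned)
    calls = cl.call_simple(binned, t, min_reads=min_reads)
    return cl.score_calls(calls, total_reads=len(filt))
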