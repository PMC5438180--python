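"""Bin classification and permutation-based overlap enrichment.

Bins (250 bp by default) are classified by chromatin state (bimodal
log2 H3K4me2/H3K9me2 ratio), by per-context methylation level, and into
differentially methylated bins (DMBs: high-CHH bins whose mutant /
wild-type CHH ratio falls below 0.25) versus "other meCHH" bins (ratio
above 0.75). Interaction enrichment at a feature set is observed
anchored-call counts over the mean of equal-size random bin draws from
the mappable non-centromeric universe, with per-replicate ratios and a
paired t-test across replicates.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

from .genome import SyntheticGenome
from .tracks import BinTrack

log = logging.getLogger(__name__)

DEFAULT_METH_THRESHOLDS = {"meCG": 0.8, "meCHG": 0.4, "meCHH": 0.1}


# ---------------------------------------------------------------------------
# classification

def bimodal_valley(values: np.ndarray, grid_points: int = 512) -> float:
    """Split point of a bimodal sample: the KDE minimum between the two
    largest modes. Falls back to 0.0 with a warning if the density is
    unimodal (degenerate separation)."""
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), grid_points)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if maxima.size < 2:
        warnings.warn("log-ratio distribution is unimodal; falling back to 0.0")
        return 0.0
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top2)
    valley = grid[lo + int(np.argmin(dens[lo:hi + 1]))]
    return float(valley)


def classify_chromatin_state(h3k4me2: BinTrack, h3k9me2: BinTrack,
                             pseudocount: float = 0.1) -> pd.DataFrame:
    """Label bins active/inactive by the bimodal log2(H3K4me2/H3K9me2)
    ratio, split at the KDE valley between the two modes."""
    frames = []
    for chrom in h3k4me2.chromosomes():
        k4 = h3k4me2[chrom]
        k9 = h3k9me2[chrom]
        if k4.size == 0:
            raise ValueError("empty track")
        ratio = np.log2((k4 + pseudocount) / (k9 + pseudocount))
        frames.append(pd.DataFrame({
            "chrom": chrom, "bin": np.arange(k4.size), "log_ratio": ratio}))
    df = pd.concat(frames, ignore_index=True)
    if not len(df):
        raise ValueError("empty tracks")
    valley = bimodal_valley(df["log_ratio"].to_numpy())
    df["chromatin_state"] = np.where(df["log_ratio"] > valley, "active", "inactive")
    df.attrs["valley"] = valley
    return df


def classify_methylation(track: BinTrack, context: str,
                         threshold: float | None = None) -> pd.DataFrame:
    """High/low label per bin: high iff level >= threshold.

    Default thresholds (0.8 / 0.4 / 0.1 for CG / CHG / CHH) are
    implementation defaults chosen to sit in the valley of typical
    bimodal per-context level distributions.
    """
    thr = DEFAULT_METH_THRESHOLDS[context] if threshold is None else threshold
    frames = []
    for chrom in track.chromosomes():
        v = track[chrom]
        if ((v < 0) | (v > 1)).any():
            raise ValueError("methylation fractions must be in [0, 1]")
        frames.append(pd.DataFrame({
            "chrom": chrom, "bin": np.arange(v.size), "level": v,
            "meth_class": np.where(v >= thr, "high", "low")}))
    return pd.concat(frames, ignore_index=True)


def classify_dmbs(wt_chh: BinTrack, mut_chh: BinTrack,
                  high_bins: pd.DataFrame,
                  dmb_ratio: float = 0.25, unchanged_ratio: float = 0.75,
                  dmb_label: str = "nrpe1_DMB") -> pd.DataFrame:
    """Differentially methylated bins among high-CHH wild-type bins.

    mutant/wild-type CHH ratio < ``dmb_ratio`` -> DMB; ratio >
    ``unchanged_ratio`` -> other_meCHH; in between (including the
    boundaries) -> neither. Bins with zero wild-type level are excluded
    (ratio undefined) and counted.
    """
    out = high_bins[["chrom", "bin"]].copy()
    wt = np.array([wt_chh[c][b] for c, b in zip(out["chrom"], out["bin"])])
    mut = np.array([mut_chh[c][b] for c, b in zip(out["chrom"], out["bin"])])
    nz = wt > 0
    if (~nz).any():
        log.info("excluded %d bins with zero wild-type CHH", int((~nz).sum()))
    out = out[nz].reset_index(drop=True)
    ratio = mut[nz] / wt[nz]
    out["ratio"] = ratio
    out["dmb_status"] = np.where(ratio < dmb_ratio, dmb_label,
                                 np.where(ratio > unchanged_ratio, "other_meCHH",
                                          "neither"))
    return out


def mappability_filter(features: pd.DataFrame, control: BinTrack,
                       min_reads: float = 1.0) -> pd.DataFrame:
    """Keep features overlapping at least ``min_reads`` of control
    coverage — the proxy for being observable in Hi-C at all."""
    if control is None:
        raise ValueError("control coverage track required")
    keep = []
    for r in features.itertuples(index=False):
        cov = control.interval_values(r.chrom, r.start, r.end)
        keep.append(cov.sum() >= min_reads)
    out = features[np.array(keep, dtype=bool)].reset_index(drop=True)
    log.info("mappability filter: kept %d/%d features", len(out), len(features))
    return out


def mappable_universe(genome: SyntheticGenome, control: BinTrack,
                      resolution: int, pericentromere_flank: int = 0) -> pd.DataFrame:
    """All mappable, non-centromeric bins — the permutation universe."""
    cent = genome.centromeric_bins(resolution, flank=pericentromere_flank)
    rows = []
    for chrom in genome.chromosomes:
        cov = control[chrom]
        for b in np.flatnonzero(cov > 0):
            if (chrom, int(b)) not in cent:
                rows.append((chrom, int(b)))
    return pd.DataFrame(rows, columns=["chrom", "bin"])


# ---------------------------------------------------------------------------
# enrichment

def features_to_bins(features: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Expand intervals to the set of (chrom, bin) they overlap."""
    rows = []
    for r in features.itertuples(index=False):
        for b in range(r.start // resolution, -(-r.end // resolution)):
            rows.append((r.chrom, b))
    return pd.DataFrame(rows, columns=["chrom", "bin"]).drop_duplicates()


def _anchored_count(calls: pd.DataFrame, bin_set: set[tuple[str, int]]) -> int:
    """Calls with at least one end in the bin set; a call with both ends
    inside counts once."""
    in_a = np.fromiter(((c, b) in bin_set for c, b in
                        zip(calls["chrom_a"], calls["bin_a"])), bool, len(calls))
    in_b = np.fromiter(((c, b) in bin_set for c, b in
                        zip(calls["chrom_b"], calls["bin_b"])), bool, len(calls))
    return int((in_a | in_b).sum())


def overlap_enrichment(calls: pd.DataFrame, feature_bins: pd.DataFrame,
                       universe: pd.DataFrame, n_perm: int = 1000,
                       seed: int = 0, name: str = "features") -> dict:
    """Observed/expected anchored-interaction enrichment at a bin set.

    Expected is the mean anchored count over ``n_perm`` equal-size
    random bin sets drawn (without replacement) from the universe.
    Ratios are reported pooled and per replicate (if present), plus a
    paired t-test of per-replicate observed vs expected counts.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not len(feature_bins):
        raise ValueError(f"feature set '{name}' empty after filtering")
    rng = np.random.default_rng(seed)

    # encode (chrom, bin) pairs as integers for vectorized membership
    chroms = sorted(set(universe["chrom"]) | set(feature_bins["chrom"])
                    | set(calls["chrom_a"]) | set(calls["chrom_b"]))
    cidx = {c: i for i, c in enumerate(chroms)}
    stride = 1 + max(int(universe["bin"].max()), int(feature_bins["bin"].max()),
                     int(calls["bin_a"].max(), ) if len(calls) else 0,
                     int(calls["bin_b"].max()) if len(calls) else 0)

    def code(chrom_col, bin_col):
        return (np.array([cidx[c] for c in chrom_col], dtype=np.int64) * stride
                + np.asarray(bin_col, dtype=np.int64))

    uni_codes = np.unique(code(universe["chrom"], universe["bin"]))
    feat_codes = np.unique(code(feature_bins["chrom"], feature_bins["bin"]))
    feat_codes = feat_codes[np.isin(feat_codes, uni_codes)]
    k = feat_codes.size
    if k == 0:
        raise ValueError(f"feature set '{name}' does not intersect the universe")
    n_codes = len(chroms) * stride

    groups = [("pooled", calls)]
    if "replicate" in calls.columns:
        groups += [(str(r), g) for r, g in calls.groupby("replicate")]
    group_codes = {label: (code(g["chrom_a"], g["bin_a"]), code(g["chrom_b"], g["bin_b"]))
                   for label, g in groups}

    perm_codes = [uni_codes[rng.choice(uni_codes.size, size=k, replace=False)]
                  for _ in range(n_perm)]

    def anchored(codes_ab, member: np.ndarray) -> int:
        ca, cb = codes_ab
        return int((member[ca] | member[cb]).sum())

    member = np.zeros(n_codes, dtype=bool)
    result: dict = {"name": name, "n_features": k, "n_perm": n_perm}
    per_rep_obs, per_rep_exp = [], []
    for label, g in groups:
        member[:] = False
        member[feat_codes] = True
        obs = anchored(group_codes[label], member)
        exp_counts = np.empty(n_perm)
        for j, pc in enumerate(perm_codes):
            member[:] = False
            member[pc] = True
            exp_counts[j] = anchored(group_codes[label], member)
        exp = exp_counts.mean()
        entry = {"observed": obs, "expected": exp, "expected_sd": exp_counts.std(),
                 "ratio": obs / exp if exp > 0 else np.nan}
        if label == "pooled":
            result.update(entry)
        else:
            result.setdefault("replicates", {})[label] = entry
            per_rep_obs.append(obs)
            per_rep_exp.append(exp)
    if len(per_rep_obs) >= 2:
        result["replicate_ratios"] = [o / e for o, e in zip(per_rep_obs, per_rep_exp)]
        result["p_value"] = replicate_ttest(per_rep_obs, per_rep_exp)
    return result


def matched_comparison(dmb_bins: pd.DataFrame, other_bins: pd.DataFrame,
                       levels: BinTrack, mode: str, calls: pd.DataFrame,
                       universe: pd.DataFrame, n_perm: int = 1000,
                       seed: int = 0) -> dict:
    """Enrichment at DMB vs other-meCHH bins after methylation matching.

    ``mode='low'`` keeps bins of both categories below the median DMB
    level; ``mode='high'`` keeps bins above the median other-meCHH
    level. Degenerate matching (an empty subset) is an error naming the
    mode.
    """
    if mode not in ("low", "high"):
        raise ValueError("mode must be 'low' or 'high'")
    lv = lambda df: np.array([levels[c][b] for c, b in zip(df["chrom"], df["bin"])])
    dmb_l, oth_l = lv(dmb_bins), lv(other_bins)
    if mode == "low":
        cut = np.median(dmb_l)
        dmb_sub = dmb_bins[dmb_l < cut]
        oth_sub = other_bins[oth_l < cut]
    else:
        cut = np.median(oth_l)
        dmb_sub = dmb_bins[dmb_l > cut]
        oth_sub = other_bins[oth_l > cut]
    if not len(dmb_sub) or not len(oth_sub):
        raise ValueError(f"matched subset empty in mode '{mode}'")
    return {
        "mode": mode, "level_cut": float(cut),
        "dmb": overlap_enrichment(calls, dmb_sub, universe, n_perm, seed,
                                  name=f"dmb_{mode}"),
        "other": overlap_enrichment(calls, oth_sub, universe, n_perm, seed + 1,
                                    name=f"other_{mode}"),
    }


def replicate_ttest(values_a, values_b) -> float:
    """Two-sided paired t-test p-value across biological replicates.

    Zero-variance nonzero differences are degenerate: reported as 0.0
    (the statistic diverges) rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 paired replicate values")
    d = a - b
    if np.allclose(d, 0):
        return 1.0
    if np.isclose(d.std(ddof=1), 0):
        warnings.warn("zero variance of paired differences; p reported as 0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# DMR-level loop counts

def dmrs_with_calls(calls: pd.DataFrame, dmrs: pd.DataFrame,
                    resolution: int, score_cutoff: float = 0.0) -> int:
    """Number of DMRs with at least one anchored call at or above the
    score cutoff (a DMR counts once however many calls touch it)."""
    use = calls if score_cutoff <= 0 else calls[calls["score"] >= score_cutoff]
    bins_by_chrom: dict[str, set[int]] = {}
    for r in use.itertuples(index=False):
        bins_by_chrom.setdefault(r.chrom_a, set()).add(r.bin_a)
        bins_by_chrom.setdefault(r.chrom_b, set()).add(r.bin_b)
    n = 0
    for r in dmrs.itertuples(index=False):
        hit = bins_by_chrom.get(r.chrom, set())
        if any(b in hit for b in range(r.start // resolution, -(-r.end // resolution))):
            n += 1
    return n


def dmr_loop_counts(calls_by_genotype: dict[str, pd.DataFrame], dmrs: pd.DataFrame,
                    score_cutoffs: list[float], wild_type: str,
                    resolution: int = 250) -> pd.DataFrame:
    """Per-genotype counts of DMRs with detectable interactions, as a
    ratio to wild-type, across score cutoffs. Wild-type counts of zero
    leave the ratio as NaN (undefined)."""
    rows = []
    for cutoff in score_cutoffs:
        wt_n = dmrs_with_calls(calls_by_genotype[wild_type], dmrs, resolution, cutoff)
        for g, calls in calls_by_genotype.items():
            n = dmrs_with_calls(calls, dmrs, resolution, cutoff)
            rows.append((g, cutoff, n, n / wt_n if wt_n else np.nan))
    return pd.DataFrame(rows, columns=["genotype", "score_cutoff", "n_dmrs_with_calls",
                                       "ratio_to_wt"])


def nucleosome_stratified_counts(calls_by_genotype: dict[str, pd.DataFrame],
                                 dmrs: pd.DataFrame, mnase_ratio: BinTrack,
                                 score_cutoffs: list[float], wild_type: str,
                                 threshold: float = 2.0,
                                 resolution: int = 250) -> pd.DataFrame:
    """DMR loop-count ratios split by nucleosome status: a DMR is in the
    "reduced" stratum iff any overlapping bin has wild-type/mutant MNase
    ratio strictly above ``threshold``."""
    reduced_mask = np.array([
        bool((mnase_ratio.interval_values(r.chrom, r.start, r.end) > threshold).any())
        for r in dmrs.itertuples(index=False)])
    out = []
    for label, sub in (("reduced_nucleosome", dmrs[reduced_mask]),
                       ("not_reduced", dmrs[~reduced_mask])):
        if not len(sub):
            continue
        t = dmr_loop_counts(calls_by_genotype, sub, score_cutoffs, wild_type, resolution)
        t.insert(0, "stratum", label)
        out.append(t)
    return pd.concat(out, ignore_index=True)
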