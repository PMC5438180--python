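"""Gene-centric interaction analyses.

Relates called interactions to gene models: promoter definition (1 kb
upstream of the TSS, strand-aware), expression stratification of
promoter contacts, transcription-factor connection statistics, the
TSS x DMR interaction surface with random-background subtraction,
gene–DMR connection ratios across genotypes, AGO4 promoter/distal
localization classes, and distance/orientation summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import RestrictionMap, SyntheticGenome


def ranksum(a, b) -> float:
    """Two-sided rank-sum p-value: exact for small groups (< 20 each),
    normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in rank-sum test")
    method = "exact" if (a.size < 20 and b.size < 20
                         and np.unique(np.concatenate([a, b])).size == a.size + b.size) \
        else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# promoters and groups

def define_promoters(genes: pd.DataFrame, chrom_sizes: dict[str, int],
                     upstream: int = 1000) -> pd.DataFrame:
    """Strand-aware promoter intervals: [tss-upstream, tss) on plus,
    [tss, tss+upstream) on minus, clipped at chromosome edges."""
    rows = []
    for r in genes.itertuples(index=False):
        L = chrom_sizes[r.chrom]
        if not (0 <= r.tss <= L):
            raise ValueError(f"TSS outside chromosome for {r.gene_id}")
        if r.strand == "+":
            s, e = max(0, r.tss - upstream), r.tss
        else:
            s, e = r.tss, min(L, r.tss + upstream)
        rows.append((r.gene_id, r.chrom, s, e, r.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def promoter_bin_index(promoters: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """(chrom, bin) -> gene_id lookup over promoter-overlapping bins."""
    rows = []
    for r in promoters.itertuples(index=False):
        for b in range(r.start // resolution, -(-r.end // resolution)):
            rows.append((r.chrom, b, r.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "bin", "gene_id"])


def expression_groups(genes: pd.DataFrame, rpkm_col: str,
                      fraction: float = 0.05) -> dict[str, list[str]]:
    """Lowest / middle / highest expression gene sets of equal size.

    Genes are ranked by RPKM with ties broken by gene id (deterministic);
    the middle set is the ``fraction`` centered at the median rank.
    """
    n = len(genes)
    k = int(round(n * fraction))
    if k < 1:
        raise ValueError(f"fewer than {int(1 / fraction)} genes")
    ranked = genes.sort_values([rpkm_col, "gene_id"]).reset_index(drop=True)
    mid_lo = (n - k) // 2
    return {
        "inactive": ranked["gene_id"].iloc[:k].tolist(),
        "middle": ranked["gene_id"].iloc[mid_lo:mid_lo + k].tolist(),
        "active": ranked["gene_id"].iloc[n - k:].tolist(),
    }


def _calls_gene_hits(calls: pd.DataFrame, pbi: pd.DataFrame) -> pd.DataFrame:
    """One row per (call index, gene) for calls with an end in that
    gene's promoter."""
    key_a = calls.reset_index().merge(
        pbi, left_on=["chrom_a", "bin_a"], right_on=["chrom", "bin"])
    key_b = calls.reset_index().merge(
        pbi, left_on=["chrom_b", "bin_b"], right_on=["chrom", "bin"])
    key_a["end"] = "a"
    key_b["end"] = "b"
    return pd.concat([key_a, key_b], ignore_index=True).drop_duplicates(
        subset=["index", "gene_id", "end"])


def promoter_interaction_stats(calls: pd.DataFrame, promoters: pd.DataFrame,
                               groups: dict[str, list[str]],
                               resolution: int = 250) -> pd.DataFrame:
    """Percent of promoter-anchored interactions landing in each gene
    group, against the even-distribution expectation (the group's share
    of all genes)."""
    pbi = promoter_bin_index(promoters, resolution)
    hits = _calls_gene_hits(calls, pbi).drop_duplicates(subset=["index", "gene_id"])
    if not len(hits):
        raise ValueError("no promoter-anchored calls")
    total = len(hits)
    n_genes = promoters["gene_id"].nunique()
    rows = []
    for name, ids in groups.items():
        obs = hits["gene_id"].isin(ids).sum()
        rows.append((name, len(ids), 100.0 * obs / total, 100.0 * len(ids) / n_genes))
    return pd.DataFrame(rows, columns=["group", "n_genes", "observed_pct", "expected_pct"])


def promoter_interaction_signal(calls: pd.DataFrame, promoters: pd.DataFrame,
                                resolution: int = 250) -> pd.Series:
    """Per-gene interaction signal: sum of anchored call scores."""
    pbi = promoter_bin_index(promoters, resolution)
    hits = _calls_gene_hits(calls, pbi).drop_duplicates(subset=["index", "gene_id"])
    sig = hits.groupby("gene_id")["score"].sum()
    return sig.reindex(promoters["gene_id"].unique(), fill_value=0.0)


def expression_by_interaction_level(calls: pd.DataFrame, promoters: pd.DataFrame,
                                    genes: pd.DataFrame, rpkm_col: str,
                                    fraction: float = 0.05,
                                    resolution: int = 250) -> dict:
    """Expression distributions of the promoters with lowest / middle /
    highest interaction signal, with pairwise two-sided rank-sum tests."""
    sig = promoter_interaction_signal(calls, promoters, resolution)
    tab = genes.set_index("gene_id").join(sig.rename("signal"))
    tab = tab.dropna(subset=["signal"]).reset_index()
    grp = expression_groups(
        tab.rename(columns={"signal": "_sig"}), "_sig", fraction)
    groups = {{"inactive": "lowest", "middle": "middle", "active": "highest"}[k]: v
              for k, v in grp.items()}
    rpkm = tab.set_index("gene_id")[rpkm_col]
    dists = {k: rpkm.loc[ids].to_numpy() for k, ids in groups.items()}
    return {
        "groups": groups,
        "rpkm": dists,
        "median_rpkm": {k: float(np.median(v)) for k, v in dists.items()},
        "p_lowest_vs_highest": ranksum(dists["lowest"], dists["highest"]),
        "p_middle_vs_highest": ranksum(dists["middle"], dists["highest"]),
    }


# ---------------------------------------------------------------------------
# transcription factors

def _interval_bin_set(df: pd.DataFrame, resolution: int) -> set[tuple[str, int]]:
    out = set()
    for r in df.itertuples(index=False):
        for b in range(r.start // resolution, -(-r.end // resolution)):
            out.add((r.chrom, b))
    return out


def tf_connected_expression(calls: pd.DataFrame, tf_peaks: dict[str, pd.DataFrame],
                            promoters: pd.DataFrame, genes: pd.DataFrame,
                            rpkm_col: str, resolution: int = 250) -> pd.DataFrame:
    """Median expression of genes whose promoter is looped to a binding
    site of each factor, versus unconnected genes and the genome-wide
    median."""
    pbi = promoter_bin_index(promoters, resolution)
    hits = _calls_gene_hits(calls, pbi)
    rpkm = genes.set_index("gene_id")[rpkm_col]
    genome_median = float(rpkm.median())
    rows = []
    for tf, peaks in tf_peaks.items():
        if not len(peaks):
            warnings.warn(f"TF {tf} has zero peaks; skipped")
            continue
        peak_bins = _interval_bin_set(peaks, resolution)
        connected = set()
        for r in hits.itertuples(index=False):
            other = (r.chrom_b, r.bin_b) if r.end == "a" else (r.chrom_a, r.bin_a)
            if other in peak_bins:
                connected.add(r.gene_id)
        conn = rpkm.loc[rpkm.index.isin(connected)]
        unconn = rpkm.loc[~rpkm.index.isin(connected)]
        rows.append((tf, len(connected),
                     float(conn.median()) if len(conn) else np.nan,
                     float(unconn.median()) if len(unconn) else np.nan,
                     genome_median))
    return pd.DataFrame(rows, columns=["tf", "n_connected", "connected_median",
                                       "unconnected_median", "genome_median"])


def distal_chip_enrichment(calls: pd.DataFrame, promoters: pd.DataFrame,
                           de_sets: dict[str, list[str]], chip_sample, chip_control,
                           score_cutoff: float = 15.0, bound_fold: float = 4.0,
                           resolution: int = 250) -> dict:
    """ChIP enrichment at the distal ends of promoter-anchored calls.

    Calls at or above ``score_cutoff`` with one end in a promoter give a
    distal 250 bp region (the other end); per-region enrichment is
    sample/control signal, a region is "bound" at >= ``bound_fold``.
    Distributions are compared between DE gene sets by two-sided
    rank-sum.
    """
    use = calls[calls["score"] >= score_cutoff]
    pbi = promoter_bin_index(promoters, resolution)
    hits = _calls_gene_hits(use, pbi)
    if not len(hits):
        raise ValueError("no qualifying promoter-anchored calls")
    out: dict = {"per_set": {}}
    dists = {}
    for name, ids in de_sets.items():
        sub = hits[hits["gene_id"].isin(ids)]
        enr = []
        for r in sub.itertuples(index=False):
            chrom, b = ((r.chrom_b, r.bin_b) if r.end == "a" else (r.chrom_a, r.bin_a))
            s = chip_sample[chrom][b]
            c = chip_control[chrom][b]
            enr.append(s / c if c > 0 else np.nan)
        enr = np.array([e for e in enr if np.isfinite(e)])
        dists[name] = enr
        out["per_set"][name] = {
            "n_regions": int(enr.size),
            "median_enrichment": float(np.median(enr)) if enr.size else np.nan,
            "fraction_bound": float((enr >= bound_fold).mean()) if enr.size else np.nan,
        }
    names = list(dists)
    if len(names) == 2 and all(dists[n].size for n in names):
        out["p_value"] = ranksum(dists[names[0]], dists[names[1]])
    return out


# ---------------------------------------------------------------------------
# TSS x DMR surface

@dataclass
class SurfaceMatrix:
    """Summed interaction signal on a grid of (offset from TSS, offset
    from DMR center), background-subtracted, plus a min–max scaled copy."""

    tss_offsets: np.ndarray
    dmr_offsets: np.ndarray
    matrix: np.ndarray
    scaled: np.ndarray
    background_sd: float


def _nearby(positions: np.ndarray, pos: int, window: int) -> np.ndarray:
    lo = np.searchsorted(positions, pos - window, side="left")
    hi = np.searchsorted(positions, pos + window, side="right")
    return np.arange(lo, hi)


def _accumulate_surface(calls, tss_by_chrom, centers_by_chrom, window, resolution,
                        min_distance, value_col):
    n_off = 2 * (window // resolution)
    acc = np.zeros((n_off, n_off))
    for r in calls.itertuples(index=False):
        if r.chrom_a != r.chrom_b:
            continue
        pa = r.bin_a * resolution + resolution // 2
        pb = r.bin_b * resolution + resolution // 2
        if abs(pb - pa) < min_distance:
            continue
        val = getattr(r, value_col)
        for (p_t, p_d) in ((pa, pb), (pb, pa)):
            tss_pos, tss_strand = tss_by_chrom.get(r.chrom_a, (None, None))
            cen = centers_by_chrom.get(r.chrom_a)
            if tss_pos is None or cen is None:
                continue
            ti = _nearby(tss_pos, p_t, window)
            di = _nearby(cen, p_d, window)
            if ti.size == 0 or di.size == 0:
                continue
            for t in ti:
                off_t = p_t - tss_pos[t]
                if tss_strand[t] == "-":
                    off_t = -off_t
                it = (off_t + window) // resolution
                if not 0 <= it < n_off:
                    continue
                for d in di:
                    idd = (p_d - cen[d] + window) // resolution
                    if 0 <= idd < n_off:
                        acc[it, idd] += val
    return acc


def tss_dmr_surface(calls: pd.DataFrame, genes: pd.DataFrame, dmrs: pd.DataFrame,
                    genome: SyntheticGenome, window: int = 5000,
                    min_distance: int = 10_000, n_random: int = 20,
                    seed: int = 0, resolution: int = 250,
                    value_col: str = "score") -> SurfaceMatrix:
    """Interaction surface around (TSS, DMR-center) anchor pairs.

    Interactions closer than ``min_distance`` are excluded; qualifying
    calls contribute their score to every (TSS, DMR) offset cell within
    ``window`` of their two ends (TSS offsets strand-flipped). The same
    accumulation with ``n_random`` size-matched random region sets gives
    the background, whose mean is subtracted; the scaled copy maps the
    result's range onto [0, 1].
    """
    if window % resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    if n_random < 10:
        raise ValueError("n_random must be >= 10")
    rng = np.random.default_rng(seed)
    tss_by_chrom = {}
    for chrom, g in genes.groupby("chrom"):
        order = np.argsort(g["tss"].to_numpy())
        tss_by_chrom[chrom] = (g["tss"].to_numpy()[order],
                               g["strand"].to_numpy()[order])
    centers = {c: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
               for c, g in dmrs.groupby("chrom")}
    obs = _accumulate_surface(calls, tss_by_chrom, centers, window, resolution,
                              min_distance, value_col)
    if not obs.any():
        warnings.warn("no qualifying TSS x DMR interactions; zero surface")
    bgs = []
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    n_dmrs = max(1, len(dmrs))
    for _ in range(n_random):
        ci = rng.choice(len(chroms), size=n_dmrs, p=lengths / lengths.sum())
        pos = rng.integers(0, lengths[ci].astype(np.int64))
        rand_centers = {chroms[k]: np.sort(pos[ci == k]) for k in range(len(chroms))
                        if (ci == k).any()}
        bgs.append(_accumulate_surface(calls, tss_by_chrom, rand_centers, window,
                                       resolution, min_distance, value_col))
    bg = np.mean(bgs, axis=0)
    bg_sd = float(np.std(bgs))
    mat = obs - bg
    rng_span = mat.max() - mat.min()
    scaled = (mat - mat.min()) / rng_span if rng_span > 0 else np.zeros_like(mat)
    offs = np.arange(-(window // resolution), window // resolution) * resolution
    return SurfaceMatrix(offs, offs, mat, scaled, bg_sd)


# ---------------------------------------------------------------------------
# gene–DMR connections

def _genes_connected_to_dmrs(calls, promoters, dmrs, resolution) -> set[str]:
    pbi = promoter_bin_index(promoters, resolution)
    dmr_bins = _interval_bin_set(dmrs, resolution)
    hits = _calls_gene_hits(calls, pbi)
    out = set()
    for r in hits.itertuples(index=False):
        other = (r.chrom_b, r.bin_b) if r.end == "a" else (r.chrom_a, r.bin_a)
        if other in dmr_bins:
            out.add(r.gene_id)
    return out


def gene_dmr_connections(calls_by_genotype: dict[str, pd.DataFrame],
                         gene_set: list[str], genes: pd.DataFrame,
                         dmrs: pd.DataFrame, genome: SyntheticGenome,
                         wild_type: str, score_cutoff: float = 5.0,
                         n_control_sets: int = 20, seed: int = 0,
                         promoter_bp: int = 1000, resolution: int = 250) -> dict:
    """Per-genotype counts of genes with promoter–DMR interactions.

    Counts genes in ``gene_set`` with at least one call (score >=
    ``score_cutoff``) joining their promoter to a DMR, expressed as a
    ratio to wild-type, alongside the same statistic averaged over
    ``n_control_sets`` size-matched random gene sets.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    rng = np.random.default_rng(seed)
    sub = genes[genes["gene_id"].isin(gene_set)]
    promoters = define_promoters(sub, genome.chrom_sizes, promoter_bp)
    counts = {}
    connected = {}
    for g, calls in calls_by_genotype.items():
        use = calls[calls["score"] >= score_cutoff] if "score" in calls.columns else calls
        conn = _genes_connected_to_dmrs(use, promoters, dmrs, resolution)
        counts[g] = len(conn)
        connected[g] = conn
    wt_n = counts[wild_type]
    ratios = {g: (n / wt_n if wt_n else np.nan) for g, n in counts.items()}

    ctrl_ratios = {g: [] for g in calls_by_genotype}
    all_ids = genes["gene_id"].to_numpy()
    for _ in range(n_control_sets):
        pick = rng.choice(all_ids, size=len(gene_set), replace=False)
        csub = genes[genes["gene_id"].isin(pick)]
        cprom = define_promoters(csub, genome.chrom_sizes, promoter_bp)
        cn = {}
        for g, calls in calls_by_genotype.items():
            use = calls[calls["score"] >= score_cutoff] if "score" in calls.columns else calls
            cn[g] = len(_genes_connected_to_dmrs(use, cprom, dmrs, resolution))
        for g in calls_by_genotype:
            if cn[wild_type]:
                ctrl_ratios[g].append(cn[g] / cn[wild_type])
    return {
        "counts": counts, "ratios": ratios, "connected_genes": connected,
        "control_ratios": {g: (float(np.mean(v)) if v else np.nan)
                           for g, v in ctrl_ratios.items()},
        "wild_type_count_zero": wt_n == 0,
    }


def de_direction_split(genes: pd.DataFrame, connected: set[str],
                       lfc_col: str = "log2fc") -> dict:
    """Fold-change comparison of DMR-connected vs unconnected genes,
    split by fold-change sign, two-sided rank-sum per stratum."""
    out = {}
    for sign, m in (("positive", genes[lfc_col] > 0), ("negative", genes[lfc_col] < 0)):
        sub = genes[m]
        conn = sub[sub["gene_id"].isin(connected)][lfc_col].to_numpy()
        unconn = sub[~sub["gene_id"].isin(connected)][lfc_col].to_numpy()
        if conn.size == 0 or unconn.size == 0:
            warnings.warn(f"{sign} stratum has an empty group; skipped")
            continue
        out[sign] = {
            "n_connected": int(conn.size), "n_unconnected": int(unconn.size),
            "median_connected": float(np.median(conn)),
            "median_unconnected": float(np.median(unconn)),
            "p_value": ranksum(conn, unconn),
        }
    return out


# ---------------------------------------------------------------------------
# AGO4 localization

def ago4_localization_classes(calls: pd.DataFrame, genes: pd.DataFrame,
                              ago4_peaks: pd.DataFrame, genome: SyntheticGenome,
                              min_sites: int = 3, promoter_bp: int = 1000,
                              resolution: int = 250) -> dict:
    """Classify genes with interactions by where AGO4 binds.

    A distal anchor qualifies iff at least ``min_sites`` restriction
    sites separate it from the gene body plus its promoter. Genes with
    AGO4 in the promoter region only, in a qualifying distal anchor
    only, or in both are counted; classes are mutually exclusive and
    exhaustive over genes with AGO4 at either end.
    """
    rmap = genome.restriction
    promoters = define_promoters(genes, genome.chrom_sizes, promoter_bp)
    pbi = promoter_bin_index(promoters, resolution)
    peak_bins = _interval_bin_set(ago4_peaks, resolution)
    hits = _calls_gene_hits(calls, pbi)
    gene_iv = {}
    for r in genes.itertuples(index=False):
        p = promoters[promoters["gene_id"] == r.gene_id].iloc[0]
        gene_iv[r.gene_id] = (r.chrom, min(r.start, p["start"]), max(r.end, p["end"]))
    promoter_hit, distal_hit = set(), set()
    for r in hits.itertuples(index=False):
        gid = r.gene_id
        chrom, giv_s, giv_e = gene_iv[gid]
        # promoter-side AGO4
        p = promoters[promoters["gene_id"] == gid].iloc[0]
        for b in range(p["start"] // resolution, -(-p["end"] // resolution)):
            if (chrom, b) in peak_bins:
                promoter_hit.add(gid)
        # distal-side AGO4 at a qualifying distal anchor
        oc, ob = (r.chrom_b, r.bin_b) if r.end == "a" else (r.chrom_a, r.bin_a)
        if oc != chrom:
            continue
        pos = ob * resolution + resolution // 2
        near_edge = giv_s if abs(pos - giv_s) < abs(pos - giv_e) else giv_e
        if giv_s <= pos < giv_e:
            continue
        if rmap.sites_between(chrom, pos, near_edge) >= min_sites and (oc, ob) in peak_bins:
            distal_hit.add(gid)
    both = promoter_hit & distal_hit
    return {
        "promoter_only": len(promoter_hit - distal_hit),
        "distal_only": len(distal_hit - promoter_hit),
        "both": len(both),
        "genes": {"promoter_only": sorted(promoter_hit - distal_hit),
                  "distal_only": sorted(distal_hit - promoter_hit),
                  "both": sorted(both)},
    }


def upstream_peak_distances(genes: pd.DataFrame, peaks: pd.DataFrame,
                            cutoff: int = 2500) -> dict:
    """Distance from each TSS to the nearest upstream peak edge
    (strand-aware); genes with no upstream peak are censored. Returns
    the distances, a log2 histogram, and the fraction of all genes with
    a peak within ``cutoff`` bp."""
    dists = {}
    censored = []
    by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    for r in genes.itertuples(index=False):
        g = by_chrom.get(r.chrom)
        if g is None:
            censored.append(r.gene_id)
            continue
        if r.strand == "+":
            up = g[g["end"] <= r.tss]
            d = r.tss - up["end"].max() if len(up) else None
        else:
            up = g[g["start"] >= r.tss]
            d = up["start"].min() - r.tss if len(up) else None
        if d is None:
            censored.append(r.gene_id)
        else:
            dists[r.gene_id] = int(d)
    vals = np.array(list(dists.values()), dtype=float)
    within = (vals <= cutoff).sum()
    hist_vals = np.log2(vals[vals > 0]) if vals.size else np.array([])
    return {
        "distances": dists, "n_censored": len(censored),
        "fraction_within_cutoff": within / len(genes) if len(genes) else np.nan,
        "log2_hist": np.histogram(hist_vals, bins=20) if hist_vals.size else None,
    }


def dmr_gene_distance_orientation(calls: pd.DataFrame, genes: pd.DataFrame,
                                  dmrs: pd.DataFrame, genome: SyntheticGenome,
                                  promoter_bp: int = 1000,
                                  resolution: int = 250) -> pd.DataFrame:
    """Signed TSS-relative distance of DMR anchors looped to promoters.

    Positive = downstream of the TSS in the gene's reading direction,
    negative = upstream. One row per (gene, call)."""
    promoters = define_promoters(genes, genome.chrom_sizes, promoter_bp)
    pbi = promoter_bin_index(promoters, resolution)
    dmr_bins = _interval_bin_set(dmrs, resolution)
    hits = _calls_gene_hits(calls, pbi)
    strand = genes.set_index("gene_id")["strand"]
    tss = genes.set_index("gene_id")["tss"]
    rows = []
    for r in hits.itertuples(index=False):
        oc, ob = (r.chrom_b, r.bin_b) if r.end == "a" else (r.chrom_a, r.bin_a)
        if (oc, ob) not in dmr_bins:
            continue
        pos = ob * resolution + resolution // 2
        d = pos - tss[r.gene_id]
        if strand[r.gene_id] == "-":
            d = -d
        rows.append((r.gene_id, int(d), "downstream" if d >= 0 else "upstream"))
    return pd.DataFrame(rows, columns=["gene_id", "signed_distance", "orientation"])
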