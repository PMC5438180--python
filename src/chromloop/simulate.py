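"""Synthetic Hi-C study generator with known planted structure.

Emulates the ingredients of an RdDM/Hi-C study without any sequencing
data: a multi-chromosome genome digested in silico with a 4-cutter,
chromatin and methylation tracks whose classification structure matches
what the downstream analyses expect, gene models with expression coupled
to loop status, and genotype-resolved read-pair tables containing

* an intra-chromosomal background whose contact probability decays as a
  power law ``(d + d0)^(-alpha)`` of genomic distance,
* an inter-chromosomal background with configurable telomere–telomere
  and centromere–centromere clustering,
* planted loops between "DMR" and "promoter" anchors whose intensity is
  genotype-specific (zero in wild-type at RdDM-repressed loops), and
* background suppression at configured regions per genotype, modelling
  the inhibition of chromosomal interactions at RdDM targets and in
  inactive chromatin.

Everything is a pure function of (config, seed): the same arguments give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import RestrictionMap, SyntheticGenome, intervals_to_bed
from .tracks import BinTrack

PAIR_COLUMNS = ["chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b", "strand_b", "replicate"]


# ---------------------------------------------------------------------------
# genome

def generate_genome(
    n_chroms: int = 5,
    chrom_length: int = 2_000_000,
    site_density: float = 4.0,
    seed: int = 0,
    centromere_frac: float = 0.10,
    telomere_bp: int = 40_000,
) -> SyntheticGenome:
    """Generate a genome with a Poisson-process restriction-site map.

    Parameters
    ----------
    site_density : expected cut sites per kb (a 4-cutter averages ~4/kb).
    centromere_frac : fraction of each chromosome masked as centromere,
        placed centrally.
    telomere_bp : width of the telomeric interval at each chromosome end.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    if site_density <= 0:
        raise ValueError("site_density must be positive")
    rng = np.random.default_rng(seed)
    chrom_sizes, sites, cents, teles = {}, {}, {}, {}
    for i in range(n_chroms):
        chrom = f"chr{i + 1}"
        chrom_sizes[chrom] = int(chrom_length)
        n_sites = rng.poisson(site_density * chrom_length / 1000)
        pos = np.unique(rng.integers(0, chrom_length, size=n_sites))
        sites[chrom] = pos
        half = int(chrom_length * centromere_frac / 2)
        cents[chrom] = (chrom_length // 2 - half, chrom_length // 2 + half)
        teles[chrom] = [(0, min(telomere_bp, chrom_length)),
                        (max(0, chrom_length - telomere_bp), chrom_length)]
    return SyntheticGenome(chrom_sizes, RestrictionMap(sites), cents, teles)


# ---------------------------------------------------------------------------
# tracks, features, truth

@dataclass
class TrackConfig:
    """Knobs of the synthetic chromatin / methylation / expression layer.

    Defaults describe the study conditions downstream analyses are
    validated against: DMR bins lose nearly all CHH methylation in the
    mutants (``chh_loss_ratio`` well under the 0.25 classification
    boundary), "other meCHH" bins retain it (> 0.75), and the active /
    inactive log2(H3K4me2 / H3K9me2) distribution is bimodal with a
    4-unit gap.
    """

    bin_size: int = 250
    genotypes: tuple[str, ...] = ("Col0", "nrpe1", "ago4")
    wild_type: str = "Col0"
    n_dmrs: int = 45
    n_false_dmrs: int = 30
    n_other_mechh: int = 60
    n_genes: int = 500
    n_tf_peaks: int = 80
    feature_size: int = 500
    chh_loss_ratio: float = 0.10
    bimodality_gap: float = 4.0
    log_ratio_sd: float = 0.5
    inactive_frac: float = 0.30
    unmappable_frac: float = 0.02
    n_rddm_loops: int = 15
    n_neutral_dmr_loops: int = 30
    n_constitutive_loops: int = 30
    rddm_loop_multiplier: float = 8.0
    neutral_multiplier: float = 3.0
    constitutive_multiplier: float = 4.0
    wt_detectable_frac: float = 0.4
    wt_loop_multiplier: float = 0.01
    neutral_loop_distance: tuple[int, int] = (3_000, 9_000)
    loop_distance: tuple[int, int] = (20_000, 500_000)
    dmr_background_retain: float = 0.30
    inactive_background_retain: float = 0.40
    expression_loop_boost: float = 4.0


@dataclass
class SyntheticTruth:
    """Ledger of planted structure against which recovery is scored.

    ``loops`` columns: anchor intervals plus one ``mult_<genotype>``
    intensity multiplier per genotype (>= 0; wild-type <= mutant at
    RdDM-repressed loops). ``suppression`` columns: intervals plus one
    ``retain_<genotype>`` background-retention probability per genotype.
    """

    loops: pd.DataFrame
    suppression: pd.DataFrame
    genotypes: tuple[str, ...]

    def __post_init__(self):
        for g in self.genotypes:
            m = self.loops[f"mult_{g}"].to_numpy(dtype=float)
            if not np.all(np.isfinite(m)) or (m < 0).any():
                raise ValueError("loop multipliers must be finite and >= 0")

    def multipliers(self, genotype: str) -> np.ndarray:
        col = f"mult_{genotype}"
        if col not in self.loops.columns:
            raise KeyError(f"unknown genotype: {genotype}")
        return self.loops[col].to_numpy(dtype=float)


@dataclass
class TrackBundle:
    """All non-Hi-C synthetic inputs: signal tracks, features, genes."""

    bin_size: int
    genotypes: tuple[str, ...]
    methylation: dict[str, dict[str, BinTrack]]  # genotype -> context -> track
    h3k4me2: BinTrack
    h3k9me2: BinTrack
    control_coverage: BinTrack
    chip_sample: BinTrack
    chip_control: BinTrack
    mnase_ratio: BinTrack
    genes: pd.DataFrame
    features: dict[str, pd.DataFrame] = field(default_factory=dict)


def _place_intervals(rng, genome, n, size, occupied, avoid_centromere=True,
                     max_tries=200, gap=300):
    """Place n non-overlapping intervals of the given size, avoiding
    `occupied` intervals (per-chrom list of (start, end)) and the
    centromere mask. A ``gap`` (bp, > one bin) keeps distinct features
    out of each other's bins. Raises if the genome cannot accommodate
    them."""
    out = []
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    for _ in range(n):
        for attempt in range(max_tries):
            ci = rng.choice(len(chroms), p=lengths / lengths.sum())
            chrom = chroms[ci]
            start = int(rng.integers(0, genome.chrom_sizes[chrom] - size))
            end = start + size
            if avoid_centromere and chrom in genome.centromeres:
                cs, ce = genome.centromeres[chrom]
                if start < ce and end > cs:
                    continue
            if any(start < e + gap and end > s - gap
                   for s, e in occupied.get(chrom, [])):
                continue
            occupied.setdefault(chrom, []).append((start, end))
            out.append((chrom, start, end))
            break
        else:
            raise ValueError("cannot place requested features: genome capacity exceeded")
    return out


def generate_tracks_and_features(
    genome: SyntheticGenome, config: TrackConfig | None = None, seed: int = 0
) -> tuple[TrackBundle, SyntheticTruth]:
    """Generate chromatin tracks, feature sets, gene models, and the
    planted-loop truth ledger for one genome."""
    cfg = config or TrackConfig()
    rng = np.random.default_rng(seed)
    bs = cfg.bin_size
    wt = cfg.wild_type
    mutants = [g for g in cfg.genotypes if g != wt]
    nbins = {c: genome.n_bins(c, bs) for c in genome.chromosomes}

    occupied: dict[str, list[tuple[int, int]]] = {}
    true_dmrs = _mk_bed(
        _place_intervals(rng, genome, cfg.n_dmrs, cfg.feature_size, occupied), "DMR")
    # a realistic DMR call set carries false positives: intervals in the
    # published list whose methylation does not actually change
    false_dmrs = _mk_bed(
        _place_intervals(rng, genome, cfg.n_false_dmrs, cfg.feature_size, occupied),
        "DMRF")
    other = _mk_bed(_place_intervals(rng, genome, cfg.n_other_mechh, cfg.feature_size, occupied),
                    "meCHH")

    # --- inactive-chromatin blocks: pericentromere plus random blocks
    inactive_mask = {c: np.zeros(nbins[c], dtype=bool) for c in genome.chromosomes}
    for chrom, (cs, ce) in genome.centromeres.items():
        inactive_mask[chrom][cs // bs: -(-ce // bs)] = True
    block_bins = max(1, int(20_000 / bs))
    for chrom in genome.chromosomes:
        n_blocks = int(cfg.inactive_frac * nbins[chrom] / block_bins)
        for start in rng.integers(0, max(1, nbins[chrom] - block_bins), size=n_blocks):
            inactive_mask[chrom][start: start + block_bins] = True

    # --- H3K4me2 / H3K9me2 with a bimodal log2 ratio
    if cfg.bimodality_gap < 0:
        raise ValueError("bimodality_gap must be >= 0")
    h3k4, h3k9 = {}, {}
    for chrom in genome.chromosomes:
        mode = np.where(inactive_mask[chrom], -cfg.bimodality_gap / 2, cfg.bimodality_gap / 2)
        ratio = mode + rng.normal(0, cfg.log_ratio_sd, size=nbins[chrom])
        base = rng.gamma(4.0, 0.5, size=nbins[chrom]) + 0.1
        h3k4[chrom] = base * np.exp2(ratio / 2)
        h3k9[chrom] = base * np.exp2(-ratio / 2)

    # --- per-context methylation per genotype
    meth = {g: {} for g in cfg.genotypes}
    dmr_bins = _interval_bins(true_dmrs, bs)
    other_bins = _interval_bins(pd.concat([other, false_dmrs], ignore_index=True), bs)
    for ctx, (lo_mu, hi_mu) in {"meCG": (0.05, 0.9), "meCHG": (0.03, 0.6),
                                "meCHH": (0.02, 0.4)}.items():
        wt_track = {}
        for chrom in genome.chromosomes:
            v = np.clip(rng.normal(lo_mu, lo_mu / 2, size=nbins[chrom]), 0, 1)
            hi = inactive_mask[chrom] if ctx != "meCHH" else np.zeros(nbins[chrom], bool)
            v[hi] = np.clip(rng.normal(hi_mu, hi_mu / 6, size=hi.sum()), 0, 1)
            wt_track[chrom] = v
        for chrom, b in dmr_bins.items():
            wt_track[chrom][b] = np.clip(rng.normal(hi_mu, hi_mu / 6, size=b.size), 0.05, 1)
        for chrom, b in other_bins.items():
            wt_track[chrom][b] = np.clip(rng.normal(hi_mu, hi_mu / 6, size=b.size), 0.05, 1)
        meth[wt][ctx] = BinTrack(bs, wt_track)
        for g in mutants:
            mut_track = {c: v.copy() for c, v in wt_track.items()}
            if ctx == "meCHH":
                # RdDM mutants lose CHH methylation at DMRs, keep it elsewhere
                for chrom, b in dmr_bins.items():
                    mut_track[chrom][b] *= cfg.chh_loss_ratio
                for chrom, b in other_bins.items():
                    mut_track[chrom][b] *= np.clip(
                        rng.normal(1.0, 0.05, size=b.size), 0.8, 1.0)
            meth[g][ctx] = BinTrack(bs, mut_track)

    # --- mappability control: uniform coverage with rare dropouts
    control = {}
    for chrom in genome.chromosomes:
        cov = rng.poisson(20, size=nbins[chrom]).astype(float) + 1
        drop = rng.random(nbins[chrom]) < cfg.unmappable_frac
        cov[drop] = 0.0
        control[chrom] = cov

    # --- genes
    gene_rows = []
    gi = 0
    # gap > promoter width keeps promoters clear of DMR / meCHH features
    for chrom, start, end in _place_intervals(rng, genome, cfg.n_genes, 2000,
                                              occupied, gap=1100):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end
        gene_rows.append((f"gene{gi:04d}", chrom, strand, tss, start, end))
        gi += 1
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "strand", "tss", "start", "end"])

    # --- planted loops: RdDM-repressed (DMR <-> promoter, mutant-only) and
    # constitutive (promoter <-> TF peak, all genotypes)
    loops, tf_rows, ago4_rows = [], [], []
    gene_loop_status = np.zeros(len(genes), dtype=bool)   # any active loop in wt
    gene_rddm_loop = np.full(len(genes), "", dtype=object)
    d_lo, d_hi = cfg.loop_distance

    def promoter_iv(row):
        if row.strand == "+":
            return max(0, row.tss - 1000), row.tss
        return row.tss, min(genome.chrom_sizes[row.chrom], row.tss + 1000)

    dmr_pool = list(true_dmrs.itertuples(index=False))
    rng.shuffle(dmr_pool)
    used_genes: set[int] = set()
    n_planted = 0
    for dmr in dmr_pool:
        if n_planted >= cfg.n_rddm_loops:
            break
        cand = genes.index[(genes["chrom"] == dmr.chrom) & ~genes.index.isin(used_genes)]
        cand = [i for i in cand
                if d_lo <= abs(genes.loc[i, "tss"] - (dmr.start + dmr.end) // 2) <= d_hi]
        if not cand:
            continue
        i = cand[int(rng.integers(len(cand)))]
        used_genes.add(i)
        ps, pe = promoter_iv(genes.loc[i])
        # most RdDM loops are fully repressed in wild-type; a fraction is
        # weakly (borderline-)detectable there, so mutant/wild-type
        # ratios stay finite while wild-type anchors remain contact-poor
        wt_mult = (cfg.wt_loop_multiplier
                   if rng.random() < cfg.wt_detectable_frac else 0.0)
        mult = {g: (wt_mult if g == wt else cfg.rddm_loop_multiplier)
                for g in cfg.genotypes}
        loops.append((dmr.chrom, dmr.start, dmr.end, dmr.chrom, ps, pe, "dmr", "promoter",
                      genes.loc[i, "gene_id"], *[mult[g] for g in cfg.genotypes]))
        gene_rddm_loop[i] = "rddm"
        # AGO4 binds the RdDM-targeted anchors (and some promoters)
        ago4_rows.append((dmr.chrom, dmr.start, dmr.end))
        if rng.random() < 0.3:
            ago4_rows.append((dmr.chrom, ps, pe))
        n_planted += 1

    # genotype-neutral promoter loops anchored at the stable-methylation
    # (false-positive) DMR calls: RdDM-independent connections that keep
    # random-gene connection ratios near one. They sit at short range
    # (below the interaction-surface distance floor) like most
    # constitutive promoter contacts.
    false_pool = list(false_dmrs.itertuples(index=False))
    rng.shuffle(false_pool)
    nd_lo, nd_hi = cfg.neutral_loop_distance
    n_neutral = 0
    for dmr in false_pool:
        if n_neutral >= cfg.n_neutral_dmr_loops:
            break
        cand = genes.index[(genes["chrom"] == dmr.chrom) & ~genes.index.isin(used_genes)]
        cand = [i for i in cand
                if nd_lo <= abs(genes.loc[i, "tss"] - (dmr.start + dmr.end) // 2) <= nd_hi]
        if not cand:
            continue
        i = cand[int(rng.integers(len(cand)))]
        used_genes.add(i)
        ps, pe = promoter_iv(genes.loc[i])
        loops.append((dmr.chrom, dmr.start, dmr.end, dmr.chrom, ps, pe,
                      "dmr_stable", "promoter", genes.loc[i, "gene_id"],
                      *[cfg.neutral_multiplier for _ in cfg.genotypes]))
        gene_loop_status[i] = True
        n_neutral += 1

    tf_sites = _place_intervals(rng, genome, cfg.n_tf_peaks, cfg.feature_size, occupied)
    tf_rows = list(tf_sites)
    n_const = 0
    for chrom, s, e in tf_sites:
        if n_const >= cfg.n_constitutive_loops:
            break
        cand = genes.index[(genes["chrom"] == chrom) & ~genes.index.isin(used_genes)]
        cand = [i for i in cand if d_lo <= abs(genes.loc[i, "tss"] - (s + e) // 2) <= d_hi]
        if not cand:
            continue
        i = cand[int(rng.integers(len(cand)))]
        used_genes.add(i)
        ps, pe = promoter_iv(genes.loc[i])
        loops.append((chrom, s, e, chrom, ps, pe, "tf", "promoter",
                      genes.loc[i, "gene_id"],
                      *[cfg.constitutive_multiplier for _ in cfg.genotypes]))
        gene_loop_status[i] = True
        n_const += 1

    loop_cols = (["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                  "kind_a", "kind_b", "gene_id"] + [f"mult_{g}" for g in cfg.genotypes])
    loops_df = pd.DataFrame(loops, columns=loop_cols)

    # --- expression: lognormal base; looped genes boosted where the loop is on
    base = rng.lognormal(mean=1.0, sigma=1.2, size=len(genes))
    rpkm = {}
    for g in cfg.genotypes:
        v = base * np.exp(rng.normal(0, 0.1, size=len(genes)))
        boosted = gene_loop_status.copy()       # constitutive loops: on everywhere
        if g != wt:
            boosted |= gene_rddm_loop == "rddm"  # RdDM loops: on in mutants only
        v[boosted] *= cfg.expression_loop_boost
        rpkm[g] = v
    for g in cfg.genotypes:
        genes[f"rpkm_{g}"] = rpkm[g]
    ref_mut = mutants[0] if mutants else wt
    lfc = np.log2((genes[f"rpkm_{ref_mut}"] + 0.01) / (genes[f"rpkm_{wt}"] + 0.01))
    genes["log2fc"] = lfc
    genes["de_label"] = np.where(lfc > 1, "up", np.where(lfc < -1, "down", "none"))

    # --- ChIP (sample enriched at TF peaks), MNase ratio (nucleosome loss at
    # a random half of the DMRs in the mutant)
    chip_s, chip_c, mnase = {}, {}, {}
    tf_df = _mk_bed(tf_rows, "TF")
    tf_bins = _interval_bins(tf_df, bs)
    for chrom in genome.chromosomes:
        c = rng.gamma(5.0, 1.0, size=nbins[chrom]) + 0.5
        s = c * np.exp(rng.normal(0, 0.2, size=nbins[chrom]))
        b = tf_bins.get(chrom, np.array([], dtype=int))
        s[b] *= 6.0
        chip_s[chrom], chip_c[chrom] = s, c
        mnase[chrom] = np.clip(rng.normal(1.0, 0.2, size=nbins[chrom]), 0.1, None)
    reduced = rng.random(len(true_dmrs)) < 0.5
    for red, r in zip(reduced, true_dmrs.itertuples(index=False)):
        if red:
            mnase[r.chrom][r.start // bs: -(-r.end // bs)] = 3.0

    # the published DMR call set mixes the true and the stable intervals
    dmrs = pd.concat([true_dmrs, false_dmrs], ignore_index=True)
    dmrs["name"] = [f"DMR{i:04d}" for i in range(len(dmrs))]

    # --- suppression ledger: methylated regions are contact-inhibited;
    # inhibition is released in mutants only where methylation is lost
    sup_rows = []
    for r in true_dmrs.itertuples(index=False):
        sup_rows.append((r.chrom, r.start, r.end, "dmr",
                         *[cfg.dmr_background_retain if g == wt else 1.0
                           for g in cfg.genotypes]))
    stable = pd.concat([other, false_dmrs], ignore_index=True)
    for r in stable.itertuples(index=False):
        sup_rows.append((r.chrom, r.start, r.end, "stable_mechh",
                         *[cfg.dmr_background_retain for _ in cfg.genotypes]))
    for chrom in genome.chromosomes:
        for s, e in _mask_to_intervals(inactive_mask[chrom], bs):
            sup_rows.append((chrom, s, e, "inactive",
                             *[cfg.inactive_background_retain for _ in cfg.genotypes]))
    sup_df = pd.DataFrame(sup_rows, columns=["chrom", "start", "end", "why"]
                          + [f"retain_{g}" for g in cfg.genotypes])

    truth = SyntheticTruth(loops_df, sup_df, cfg.genotypes)
    bundle = TrackBundle(
        bin_size=bs, genotypes=cfg.genotypes,
        methylation=meth,
        h3k4me2=BinTrack(bs, h3k4), h3k9me2=BinTrack(bs, h3k9),
        control_coverage=BinTrack(bs, control),
        chip_sample=BinTrack(bs, chip_s), chip_control=BinTrack(bs, chip_c),
        mnase_ratio=BinTrack(bs, mnase),
        genes=genes,
        features={"dmrs": dmrs, "other_mechh": other, "tf_peaks": tf_df,
                  "ago4_peaks": _mk_bed(ago4_rows, "AGO4")},
    )
    return bundle, truth


def _mk_bed(rows, prefix):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"{prefix}{i:04d}" for i in range(len(df))]
    return df


def _interval_bins(df: pd.DataFrame, bin_size: int) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for r in df.itertuples(index=False):
        bins = range(r.start // bin_size, -(-r.end // bin_size))
        out.setdefault(r.chrom, []).extend(bins)
    return {c: np.unique(np.array(v, dtype=int)) for c, v in out.items()}


def _mask_to_intervals(mask: np.ndarray, bin_size: int) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return [(int(edges[i] * bin_size), int(edges[i + 1] * bin_size))
            for i in range(0, edges.size, 2)]


# ---------------------------------------------------------------------------
# read pairs

def _sample_powerlaw(rng, n, alpha, d0, dmin, dmax):
    """Inverse-CDF sample of d on [dmin, dmax] with density ∝ (d+d0)^-alpha."""
    u = rng.random(n)
    a, b = dmin + d0, dmax + d0
    if abs(alpha - 1.0) < 1e-9:
        d = np.exp(u * (np.log(b) - np.log(a)) + np.log(a)) - d0
    else:
        e = 1.0 - alpha
        d = (u * (b ** e - a ** e) + a ** e) ** (1.0 / e) - d0
    return np.clip(d, dmin, dmax).astype(np.int64)


def _hotspots(chrom: str, start: int, end: int, k: int = 6) -> np.ndarray:
    """Deterministic contact-hotspot positions inside an interval.

    Telomeric / centromeric inter-chromosomal contacts concentrate at a
    few repeat loci rather than spreading uniformly; the hotspot set is
    a property of the interval (seeded from its coordinates), identical
    across replicates and genotypes so recurrent read support can
    accumulate."""
    import zlib
    seed = zlib.crc32(f"{chrom}:{start}-{end}".encode()) % (2 ** 31)
    return np.random.default_rng(seed).integers(start, end, size=k)


def _in_intervals(pos, starts, ends):
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def simulate_read_pairs(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    genotype: str,
    n_pairs: int,
    decay_alpha: float = 1.0,
    inter_frac: float = 0.05,
    loop_frac: float = 0.08,
    replicate: int = 1,
    seed: int = 0,
    d0: float = 1000.0,
    telomere_frac: float = 0.10,
    centromere_frac: float = 0.40,
    duplication_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one replicate of Hi-C read pairs for one genotype.

    ``n_pairs`` is the background budget before planted-loop pairs are
    added and before genotype-specific suppression thins the background.
    ``loop_frac`` scales planted-loop output: each loop contributes
    Poisson-distributed pairs with mean proportional to its intensity
    multiplier in this genotype, so excess counts are linear in the
    multiplier. ``telomere_frac`` / ``centromere_frac`` route that share
    of inter-chromosomal pairs through telomere–telomere and
    centromere–centromere anchor pairs.
    """
    if not 0 <= inter_frac < 1:
        raise ValueError("inter_frac must be in [0, 1)")
    if decay_alpha <= 0:
        raise ValueError("decay_alpha must be positive")
    if genotype not in truth.genotypes:
        raise KeyError(f"unknown genotype: {genotype}")
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)

    parts = []

    # planted loops
    mult = truth.multipliers(genotype)
    n_loops = max(1, len(mult))
    lam = loop_frac * n_pairs * mult / n_loops
    loop_counts = rng.poisson(lam) if lam.size else np.array([], dtype=int)
    for (_, row), k in zip(truth.loops.iterrows(), loop_counts):
        if k == 0:
            continue
        pa = rng.integers(row["start_a"], row["end_a"], size=k)
        pb = rng.integers(row["start_b"], row["end_b"], size=k)
        parts.append(pd.DataFrame({
            "chrom_a": row["chrom_a"], "pos_a": pa,
            "chrom_b": row["chrom_b"], "pos_b": pb}))

    # inter-chromosomal background
    n_inter = rng.binomial(n_pairs, inter_frac) if n_pairs else 0
    if n_inter and len(chroms) > 1:
        n_tel = rng.binomial(n_inter, telomere_frac)
        n_cen = rng.binomial(n_inter - n_tel, centromere_frac)
        n_uni = n_inter - n_tel - n_cen
        p = lengths / lengths.sum()
        ca = rng.choice(len(chroms), size=n_uni, p=p)
        cb = rng.choice(len(chroms), size=n_uni, p=p)
        same = ca == cb
        while same.any():
            cb[same] = rng.choice(len(chroms), size=same.sum(), p=p)
            same = ca == cb
        parts.append(pd.DataFrame({
            "chrom_a": np.array(chroms)[ca],
            "pos_a": rng.integers(0, lengths[ca]),
            "chrom_b": np.array(chroms)[cb],
            "pos_b": rng.integers(0, lengths[cb])}))
        for n_k, ivs in ((n_tel, [(c, s, e) for c in chroms for s, e in genome.telomeres.get(c, [])]),
                         (n_cen, [(c, s, e) for c, (s, e) in genome.centromeres.items()])):
            if n_k == 0 or len(ivs) < 2:
                continue
            ia = rng.integers(0, len(ivs), size=n_k)
            ib = rng.integers(0, len(ivs), size=n_k)
            clash = np.array([ivs[x][0] == ivs[y][0] for x, y in zip(ia, ib)])
            while clash.any():
                ib[clash] = rng.integers(0, len(ivs), size=clash.sum())
                clash = np.array([ivs[x][0] == ivs[y][0] for x, y in zip(ia, ib)])
            spots = [_hotspots(c, s, e) for c, s, e in ivs]
            pa = np.array([spots[x][rng.integers(len(spots[x]))] for x in ia])
            pb = np.array([spots[y][rng.integers(len(spots[y]))] for y in ib])
            parts.append(pd.DataFrame({
                "chrom_a": [ivs[x][0] for x in ia],
                "pos_a": pa,
                "chrom_b": [ivs[y][0] for y in ib],
                "pos_b": pb}))
    else:
        n_inter = 0

    # intra-chromosomal power-law background
    n_intra = n_pairs - n_inter
    if n_intra > 0:
        ci = rng.choice(len(chroms), size=n_intra, p=lengths / lengths.sum())
        pos_a = np.empty(n_intra, dtype=np.int64)
        pos_b = np.empty(n_intra, dtype=np.int64)
        for k, chrom in enumerate(chroms):
            m = ci == k
            n_k = int(m.sum())
            if n_k == 0:
                continue
            d = _sample_powerlaw(rng, n_k, decay_alpha, d0, 1, lengths[k] - 1)
            a = rng.integers(0, lengths[k] - d)
            pos_a[m], pos_b[m] = a, a + d
        df = pd.DataFrame({"chrom_a": np.array(chroms)[ci], "pos_a": pos_a,
                           "chrom_b": np.array(chroms)[ci], "pos_b": pos_b})
        # genotype-specific background suppression
        retain_col = f"retain_{genotype}"
        sup = truth.suppression
        if len(sup) and retain_col in sup.columns:
            keep = np.ones(len(df), dtype=bool)
            for (chrom, retain), g in sup.groupby(["chrom", retain_col]):
                if retain >= 1.0:
                    continue
                order = np.argsort(g["start"].to_numpy())
                starts = g["start"].to_numpy()[order]
                ends = g["end"].to_numpy()[order]
                m = (df["chrom_a"].to_numpy() == chrom)
                hit = np.zeros(len(df), dtype=bool)
                hit[m] = (_in_intervals(df["pos_a"].to_numpy()[m], starts, ends)
                          | _in_intervals(df["pos_b"].to_numpy()[m], starts, ends))
                drop = hit & (rng.random(len(df)) >= retain)
                keep &= ~drop
            df = df[keep]
        parts.append(df)

    if parts:
        pairs = pd.concat(parts, ignore_index=True)
    else:
        pairs = pd.DataFrame(columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])

    if duplication_rate > 0 and len(pairs):
        n_dup = rng.binomial(len(pairs), duplication_rate)
        dup = pairs.iloc[rng.integers(0, len(pairs), size=n_dup)]
        pairs = pd.concat([pairs, dup], ignore_index=True)

    n = len(pairs)
    pairs["strand_a"] = np.where(rng.random(n) < 0.5, "+", "-")
    pairs["strand_b"] = np.where(rng.random(n) < 0.5, "+", "-")
    pairs["replicate"] = replicate
    return canonicalize_pairs(pairs[PAIR_COLUMNS])


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair so (chrom_a, pos_a) <= (chrom_b, pos_b)."""
    if not len(pairs):
        return pairs.reset_index(drop=True)
    ca = pairs["chrom_a"].to_numpy()
    cb = pairs["chrom_b"].to_numpy()
    flip = (ca > cb) | ((ca == cb) & (pairs["pos_a"].to_numpy() > pairs["pos_b"].to_numpy()))
    out = pairs.copy()
    for a, b in (("chrom_a", "chrom_b"), ("pos_a", "pos_b"), ("strand_a", "strand_b")):
        if a in out.columns:
            va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
            out.loc[flip, a] = vb[flip]
            out.loc[flip, b] = va[flip]
    return out.reset_index(drop=True)


def simulate_replicates(genome, truth, genotype, n_pairs, n_replicates=3,
                        base_seed=0, **kwargs) -> pd.DataFrame:
    """Independent replicates via the seed-splitting rule base_seed + index."""
    reps = [simulate_read_pairs(genome, truth, genotype, n_pairs,
                                replicate=i + 1, seed=base_seed + i, **kwargs)
            for i in range(n_replicates)]
    return pd.concat(reps, ignore_index=True)


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(outdir, genome: SyntheticGenome, bundle: TrackBundle,
                  truth: SyntheticTruth,
                  pairs: dict[str, pd.DataFrame] | None = None) -> dict[str, int]:
    """Write every synthetic object as plain text; return {file: row count}."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    sizes = pd.DataFrame(list(genome.chrom_sizes.items()), columns=["chrom", "length"])
    sizes.to_csv(out / "chrom_sizes.tsv", sep="\t", index=False)
    manifest["chrom_sizes.tsv"] = len(sizes)

    genome.restriction.to_bed(out / "restriction_sites.bed")
    manifest["restriction_sites.bed"] = sum(
        a.size for a in genome.restriction.sites.values())

    masks = ([(c, s, e, "centromere") for c, (s, e) in genome.centromeres.items()]
             + [(c, s, e, "telomere") for c, ivs in genome.telomeres.items()
                for s, e in ivs])
    mdf = pd.DataFrame(masks, columns=["chrom", "start", "end", "name"])
    intervals_to_bed(mdf, out / "masks.bed")
    manifest["masks.bed"] = len(mdf)

    for name, df in bundle.features.items():
        intervals_to_bed(df, out / f"{name}.bed")
        manifest[f"{name}.bed"] = len(df)

    for g, ctxs in bundle.methylation.items():
        for ctx, tr in ctxs.items():
            f = f"{ctx}_{g}.bedgraph"
            manifest[f] = tr.to_bedgraph(out / f)
    for name in ("h3k4me2", "h3k9me2", "control_coverage",
                 "chip_sample", "chip_control", "mnase_ratio"):
        tr: BinTrack = getattr(bundle, name)
        manifest[f"{name}.bedgraph"] = tr.to_bedgraph(out / f"{name}.bedgraph")

    bundle.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    manifest["genes.tsv"] = len(bundle.genes)
    truth.loops.to_csv(out / "truth_loops.tsv", sep="\t", index=False)
    manifest["truth_loops.tsv"] = len(truth.loops)
    truth.suppression.to_csv(out / "truth_suppression.tsv", sep="\t", index=False)
    manifest["truth_suppression.tsv"] = len(truth.suppression)

    for name, df in (pairs or {}).items():
        f = f"pairs_{name}.tsv"
        df.to_csv(out / f, sep="\t", header=False, index=False)
        manifest[f] = len(df)

    pd.Series(manifest, name="rows").rename_axis("file").to_csv(
        out / "MANIFEST.tsv", sep="\t")
    return manifest
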