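"""Core Hi-C read-pair handling.

Ingests valid-pair tables, applies the restriction-site distance filter
("more than N cut sites apart"), bins contacts at arbitrary fixed
resolutions, and computes decay curves, dense contact matrices, and
depth-normalized replicate correlations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome import RestrictionMap, SyntheticGenome
from .simulate import PAIR_COLUMNS, canonicalize_pairs

log = logging.getLogger(__name__)

BIN_COLUMNS = ["chrom_a", "bin_a", "chrom_b", "bin_b", "count"]


def load_pairs(path, chrom_sizes: dict[str, int] | None = None,
               max_bad_fraction: float = 0.01) -> pd.DataFrame:
    """Read a pairs table (chromA posA strandA chromB posB strandB replicate).

    Malformed rows (unparseable positions, negative coordinates, out of
    chromosome bounds) are dropped and counted; more than
    ``max_bad_fraction`` of them is a hard error. Output is canonical:
    (chrom_a, pos_a) <= (chrom_b, pos_b).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=PAIR_COLUMNS,
                         dtype={"chrom_a": str, "chrom_b": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=PAIR_COLUMNS)
    if not len(df):
        warnings.warn(f"empty pairs file: {path}")
        return pd.DataFrame(columns=PAIR_COLUMNS)
    n_total = len(df)
    for c in ("pos_a", "pos_b"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df["pos_a"].isna() | df["pos_b"].isna() | (df["pos_a"] < 0) | (df["pos_b"] < 0)
    if chrom_sizes is not None:
        unknown = set(df["chrom_a"]) | set(df["chrom_b"]) - set(chrom_sizes)
        unknown -= set(chrom_sizes)
        if unknown:
            raise ValueError(f"unknown chromosomes in pairs file: {sorted(unknown)}")
        la = df["chrom_a"].map(chrom_sizes)
        lb = df["chrom_b"].map(chrom_sizes)
        bad |= (df["pos_a"] >= la) | (df["pos_b"] >= lb)
    n_bad = int(bad.sum())
    if n_total and n_bad / n_total > max_bad_fraction:
        raise ValueError(f"{n_bad}/{n_total} malformed rows in {path}")
    if n_bad:
        log.warning("dropped %d malformed rows from %s", n_bad, path)
    df = df[~bad].copy()
    df["pos_a"] = df["pos_a"].astype(np.int64)
    df["pos_b"] = df["pos_b"].astype(np.int64)
    return canonicalize_pairs(df)


def sites_between(rmap: RestrictionMap, chrom: str, a: int, b: int) -> int:
    """Cut sites strictly inside the open interval between two positions."""
    return rmap.sites_between(chrom, a, b)


def filter_pairs_by_sites(pairs: pd.DataFrame, rmap: RestrictionMap,
                          min_sites: int = 3) -> pd.DataFrame:
    """Keep intra-chromosomal pairs whose ends are more than ``min_sites``
    cut sites apart (strict >). Inter-chromosomal pairs always pass: the
    filter is a genomic-distance criterion with no meaning across
    chromosomes."""
    if not len(pairs):
        return pairs
    intra = pairs["chrom_a"].to_numpy() == pairs["chrom_b"].to_numpy()
    keep = ~intra
    for chrom in pd.unique(pairs.loc[intra, "chrom_a"]):
        if chrom not in rmap:
            raise KeyError(f"no restriction map for chromosome {chrom}")
        m = intra & (pairs["chrom_a"].to_numpy() == chrom)
        n = rmap.sites_between_many(chrom, pairs["pos_a"].to_numpy()[m],
                                    pairs["pos_b"].to_numpy()[m])
        keep[m] = n > min_sites
    out = pairs[keep].reset_index(drop=True)
    log.info("site filter: kept %d/%d pairs (min_sites=%d)", len(out), len(pairs), min_sites)
    return out


def bin_pairs(pairs: pd.DataFrame, resolution: int,
              by_replicate: bool = False) -> pd.DataFrame:
    """Aggregate pairs into bin-pair counts at the given resolution.

    Bin index is floor(position / resolution); bin pairs are canonical
    ((chrom_a, bin_a) <= (chrom_b, bin_b)). The counts sum to the number
    of input pairs.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    cols = ["chrom_a", "bin_a", "chrom_b", "bin_b"]
    if not len(pairs):
        return pd.DataFrame(columns=cols + (["replicate"] if by_replicate else []) + ["count"])
    ca = pairs["chrom_a"].to_numpy()
    cb = pairs["chrom_b"].to_numpy()
    ba = pairs["pos_a"].to_numpy() // resolution
    bb = pairs["pos_b"].to_numpy() // resolution
    flip = (ca > cb) | ((ca == cb) & (ba > bb))
    df = pd.DataFrame({
        "chrom_a": np.where(flip, cb, ca),
        "bin_a": np.where(flip, bb, ba),
        "chrom_b": np.where(flip, ca, cb),
        "bin_b": np.where(flip, ba, bb),
    })
    if by_replicate:
        df["replicate"] = pairs["replicate"].to_numpy()
        cols = cols + ["replicate"]
    out = df.groupby(cols, sort=True).size().rename("count").reset_index()
    return out


def combine_replicates(pair_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool pair tables; replicate ids are preserved in their column."""
    if not pair_sets:
        raise ValueError("no pair sets to combine")
    return pd.concat(pair_sets, ignore_index=True)


def decay_curve(pairs: pd.DataFrame, rmap: RestrictionMap | None = None,
                genome: SyntheticGenome | None = None,
                resolution: int = 250, min_sites: int = 3,
                fragment_assign: bool = True) -> pd.DataFrame:
    """Distance histogram of intra-chromosomal contacts.

    Reads are optionally first assigned to their containing restriction
    fragment (represented by its midpoint), then to fixed-width bins;
    the site-distance filter is applied when a map is given. Returns a
    table (distance, count) where distance is the bin-midpoint
    separation in bp; counts sum to the retained intra pair count.
    """
    intra = pairs[pairs["chrom_a"] == pairs["chrom_b"]]
    if rmap is not None:
        intra = filter_pairs_by_sites(intra, rmap, min_sites=min_sites)
    if not len(intra):
        return pd.DataFrame(columns=["distance", "count"])
    pos_a = intra["pos_a"].to_numpy().copy()
    pos_b = intra["pos_b"].to_numpy().copy()
    if fragment_assign and rmap is not None and genome is not None:
        chroms = intra["chrom_a"].to_numpy()
        for chrom in pd.unique(chroms):
            m = chroms == chrom
            length = genome.chrom_sizes[chrom]
            pos_a[m] = rmap.assign_to_fragments(chrom, pos_a[m], length)
            pos_b[m] = rmap.assign_to_fragments(chrom, pos_b[m], length)
    d = np.abs(pos_b // resolution - pos_a // resolution) * resolution
    vals, counts = np.unique(d, return_counts=True)
    return pd.DataFrame({"distance": vals, "count": counts})


def fit_decay_exponent(curve: pd.DataFrame, chrom_sizes: dict[str, int],
                       d_min: float = 2_000, d_max: float = 200_000,
                       d0: float = 1_000) -> float:
    """Fit the power-law exponent of a decay curve by weighted log-log
    regression of availability-corrected counts on (d + d0).

    The number of position pairs at separation d on a chromosome of
    length L scales as (L - d); dividing counts by that availability
    removes the finite-chromosome truncation so the fitted slope is the
    decay exponent itself (returned positive).
    """
    c = curve[(curve["distance"] >= d_min) & (curve["distance"] <= d_max)
              & (curve["count"] > 0)]
    if len(c) < 5:
        raise ValueError("too few distance bins to fit a decay exponent")
    d = c["distance"].to_numpy(dtype=float)
    avail = np.zeros_like(d)
    for L in chrom_sizes.values():
        avail += np.maximum(L - d, 0)
    y = np.log(c["count"].to_numpy() / avail)
    x = np.log(d + d0)
    slope = np.polyfit(x, y, 1, w=np.sqrt(c["count"].to_numpy()))[0]
    return float(-slope)


def contact_matrix(source: pd.DataFrame, resolution: int,
                   genome: SyntheticGenome, chrom: str,
                   binned_resolution: int | None = None) -> np.ndarray:
    """Dense symmetric intra-chromosomal contact matrix for one chromosome.

    ``source`` is either a raw pairs table or a bin-pair count table (then
    ``binned_resolution`` gives its resolution, which must divide the
    target). Total mass equals the number of contributing pairs; each
    off-diagonal pair adds one to both symmetric entries' shared count.
    """
    n = genome.n_bins(chrom, resolution)
    mat = np.zeros((n, n))
    if binned_resolution is None:
        sub = source[(source["chrom_a"] == chrom) & (source["chrom_b"] == chrom)]
        bi = sub["pos_a"].to_numpy() // resolution
        bj = sub["pos_b"].to_numpy() // resolution
        w = np.ones(len(sub))
    else:
        if resolution % binned_resolution != 0:
            raise ValueError("binned resolution must divide target resolution")
        f = resolution // binned_resolution
        sub = source[(source["chrom_a"] == chrom) & (source["chrom_b"] == chrom)]
        bi = sub["bin_a"].to_numpy() // f
        bj = sub["bin_b"].to_numpy() // f
        w = sub["count"].to_numpy(dtype=float)
    np.add.at(mat, (bi, bj), w)
    np.add.at(mat, (bj, bi), w)
    mat[np.diag_indices(n)] /= 2
    return mat


def replicate_correlation(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame,
                          resolution: int = 25_000) -> float:
    """Pearson correlation of depth-normalized bin-pair contact counts.

    Each sample's counts are divided by its total pair count before
    correlating over the union of observed bin pairs.
    """
    ba = bin_pairs(pairs_a, resolution)
    bb = bin_pairs(pairs_b, resolution)
    if not len(ba) or not len(bb):
        raise ValueError("cannot correlate empty samples")
    key = ["chrom_a", "bin_a", "chrom_b", "bin_b"]
    merged = ba.merge(bb, on=key, how="outer", suffixes=("_a", "_b")).fillna(0.0)
    va = merged["count_a"].to_numpy() / len(pairs_a)
    vb = merged["count_b"].to_numpy() / len(pairs_b)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero-variance contact counts: correlation undefined")
    return float(stats.pearsonr(va, vb)[0])
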