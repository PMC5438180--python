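"""Genome-scale organization summaries.

Compartment analysis via the first principal component of the
contact-correlation matrix, metaplots of inter-chromosomal contacts
around telomeres, and the centromere–centromere share of
inter-chromosomal interactions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import SyntheticGenome


def compartment_eigenvector(matrix: np.ndarray, min_bins: int = 10) -> np.ndarray:
    """First principal component of the bin-profile correlation matrix.

    Bins with zero contact mass are masked (NaN in the output). The
    correlation matrix of bin contact profiles is eigendecomposed and
    the leading eigenvector returned, with the sign convention that the
    larger cluster (more bins) is positive. Loadings separate
    self-associating domains such as chromosome arms.
    """
    m = np.asarray(matrix, dtype=float)
    mask = m.sum(axis=1) > 0
    if mask.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} usable bins, have {int(mask.sum())}")
    sub = m[np.ix_(mask, mask)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if np.isnan(corr).all() or np.allclose(corr, corr.flat[0]):
        raise ValueError("degenerate (constant) correlation matrix")
    corr = np.nan_to_num(corr)
    vals, vecs = np.linalg.eigh(corr)
    ev = vecs[:, -1]
    n_pos, n_neg = np.sum(ev > 0), np.sum(ev < 0)
    if n_pos < n_neg or (n_pos == n_neg and ev.sum() < 0):
        ev = -ev
    out = np.full(m.shape[0], np.nan)
    out[mask] = ev
    return out


def telomere_metaplot(inter_calls: pd.DataFrame, genome: SyntheticGenome,
                      bin_size: int = 20_000, flank: int = 200_000,
                      resolution: int = 250) -> pd.DataFrame:
    """Mean inter-chromosomal interaction count by offset from telomeres.

    Call anchors are positioned at bin centers (``resolution`` is the
    calls' bin width). For each chromosome end the profile covers
    ``flank`` bp inward in ``bin_size`` steps; offsets are distances
    from the telomere-proximal end, averaged over all telomeres.
    Columns: offset (bp, bin start), mean_count.
    """
    n_off = flank // bin_size
    sums = np.zeros(n_off)
    inter = inter_calls[inter_calls["chrom_a"] != inter_calls["chrom_b"]]
    if not len(inter):
        warnings.warn("no inter-chromosomal calls: empty telomere profile")
        return pd.DataFrame({"offset": np.arange(n_off) * bin_size,
                             "mean_count": np.zeros(n_off)})
    anchors = pd.concat([
        inter[["chrom_a", "bin_a"]].rename(columns={"chrom_a": "chrom", "bin_a": "bin"}),
        inter[["chrom_b", "bin_b"]].rename(columns={"chrom_b": "chrom", "bin_b": "bin"}),
    ], ignore_index=True)
    anchors["pos"] = anchors["bin"] * resolution + resolution // 2
    n_telomeres = 0
    for chrom, ivs in genome.telomeres.items():
        sub = anchors[anchors["chrom"] == chrom]
        length = genome.chrom_sizes[chrom]
        for s, e in ivs:
            # distance inward from the chromosome-proximal edge of the telomere
            if s == 0:
                off = sub["pos"].to_numpy()
            else:
                off = length - 1 - sub["pos"].to_numpy()
            off = off[(off >= 0) & (off < flank)] // bin_size
            np.add.at(sums, off, 1)
            n_telomeres += 1
    if n_telomeres == 0:
        raise ValueError("no telomere intervals in genome")
    return pd.DataFrame({"offset": np.arange(n_off) * bin_size,
                         "mean_count": sums / n_telomeres})


def centromere_fractions(inter_calls: pd.DataFrame, genome: SyntheticGenome,
                         resolution: int = 250, pericentromere_flank: int = 0,
                         by_replicate: bool = True) -> pd.DataFrame:
    """Share of inter-chromosomal calls with both ends centromeric.

    Reported as a percentage of all inter-chromosomal calls, pooled and
    (when a replicate column is present) per replicate. The centromere
    mask is widened by ``pericentromere_flank`` bp on each side.
    """
    inter = inter_calls[inter_calls["chrom_a"] != inter_calls["chrom_b"]]
    if not len(inter):
        raise ValueError("no inter-chromosomal calls")
    cent = genome.centromeric_bins(resolution, flank=pericentromere_flank)

    def frac(df: pd.DataFrame) -> float:
        in_a = [(c, b) in cent for c, b in zip(df["chrom_a"], df["bin_a"])]
        in_b = [(c, b) in cent for c, b in zip(df["chrom_b"], df["bin_b"])]
        both = np.array(in_a) & np.array(in_b)
        return 100.0 * both.sum() / len(df)

    rows = [("pooled", frac(inter), len(inter))]
    if by_replicate and "replicate" in inter.columns:
        for rep, g in inter.groupby("replicate"):
            rows.append((str(rep), frac(g), len(g)))
    return pd.DataFrame(rows, columns=["sample", "centromeric_pct", "n_inter_calls"])
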