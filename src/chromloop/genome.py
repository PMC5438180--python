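"""Genome containers: chromosome sizes, restriction maps, interval masks.

Coordinates are 0-based, half-open everywhere in memory; BED I/O is native
(already 0-based half-open). Restriction cut sites are single positions,
strictly increasing within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class RestrictionMap:
    """Per-chromosome sorted arrays of restriction cut positions.

    Supports binary-search queries for the number of cut sites strictly
    between two coordinates — the primitive behind the "more than N sites
    apart" read-pair filter and the distal-region definition.
    """

    def __init__(self, sites: dict[str, np.ndarray]):
        self.sites = {}
        for chrom, arr in sites.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"sites for {chrom} must be 1-D")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"sites for {chrom} not strictly increasing")
            self.sites[chrom] = arr

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sites

    def chromosomes(self) -> list[str]:
        return list(self.sites)

    def sites_between(self, chrom: str, a: int, b: int) -> int:
        """Number of cut sites strictly inside the open interval (min(a,b), max(a,b))."""
        if chrom not in self.sites:
            raise KeyError(f"unknown chromosome: {chrom}")
        lo, hi = (a, b) if a <= b else (b, a)
        arr = self.sites[chrom]
        n = np.searchsorted(arr, hi, side="left") - np.searchsorted(arr, lo, side="right")
        return int(max(n, 0))

    def sites_between_many(self, chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`sites_between` for arrays of positions on one chromosome."""
        if chrom not in self.sites:
            raise KeyError(f"unknown chromosome: {chrom}")
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        arr = self.sites[chrom]
        n = np.searchsorted(arr, hi, side="left") - np.searchsorted(arr, lo, side="right")
        return np.maximum(n, 0)

    def fragment_midpoints(self, chrom: str, length: int) -> np.ndarray:
        """Midpoints of the restriction fragments tiling [0, length)."""
        cuts = self.sites.get(chrom)
        if cuts is None:
            raise KeyError(f"unknown chromosome: {chrom}")
        edges = np.concatenate([[0], cuts, [length]])
        return (edges[:-1] + edges[1:]) // 2

    def assign_to_fragments(self, chrom: str, pos: np.ndarray, length: int) -> np.ndarray:
        """Map positions to the midpoint of their containing restriction fragment."""
        cuts = self.sites[chrom]
        mids = self.fragment_midpoints(chrom, length)
        idx = np.searchsorted(cuts, pos, side="right")
        return mids[idx]

    def to_bed(self, path) -> None:
        rows = []
        for chrom, arr in self.sites.items():
            for p in arr:
                rows.append((chrom, p, p + 1))
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path) -> "RestrictionMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                         usecols=[0, 1, 2])
        return cls({c: g["start"].to_numpy() for c, g in df.groupby("chrom", sort=False)})


@dataclass
class SyntheticGenome:
    """A multi-chromosome genome with a restriction-site map and masks.

    Stands in for a real assembly digested with a 4-cutter: the cut-site
    map defines fragments, the centromere mask excludes pericentromeric
    bins from feature analyses, and telomere intervals anchor metaplots.
    """

    chrom_sizes: dict[str, int]
    restriction: RestrictionMap
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    telomeres: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            sites = self.restriction.sites.get(chrom)
            if sites is not None and sites.size:
                if sites[0] < 0 or sites[-1] >= length:
                    raise ValueError(f"cut sites out of bounds on {chrom}")
        for chrom, (s, e) in self.centromeres.items():
            if not (0 <= s < e <= self.chrom_sizes[chrom]):
                raise ValueError(f"centromere out of bounds on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self.chrom_sizes[chrom] // resolution)

    def centromeric_bins(self, resolution: int, flank: int = 0) -> set[tuple[str, int]]:
        """Bins overlapping the centromere mask, optionally widened by a
        pericentromeric flank (bp) on each side."""
        out: set[tuple[str, int]] = set()
        for chrom, (s, e) in self.centromeres.items():
            s = max(0, s - flank)
            e = min(self.chrom_sizes[chrom], e + flank)
            for b in range(s // resolution, -(-e // resolution)):
                out.add((chrom, b))
        return out


def intervals_to_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def bed_to_intervals(path, names=("chrom", "start", "end", "name", "score", "strand")) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names[:3]))
    df.columns = list(names[: df.shape[1]])
    return df
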