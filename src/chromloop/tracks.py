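"""Fixed-width binned genomic signal tracks with bedGraph I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd


class BinTrack:
    """A genome-wide signal sampled in fixed-width bins.

    Holds one float array per chromosome; bin ``i`` covers
    ``[i*bin_size, (i+1)*bin_size)``. This is the in-memory form of a
    bedGraph track (ChIP RPM, methylation fraction, MNase ratio, ...).
    """

    def __init__(self, bin_size: int, data: dict[str, np.ndarray]):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def chromosomes(self) -> list[str]:
        return list(self.data)

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.bin_size])

    def interval_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values of all bins overlapping [start, end)."""
        arr = self.data[chrom]
        b0 = start // self.bin_size
        b1 = -(-end // self.bin_size)
        return arr[b0:b1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, arr in self.data.items():
            starts = np.arange(arr.size, dtype=np.int64) * self.bin_size
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts,
                "end": starts + self.bin_size, "value": arr,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_bedgraph(self, path) -> int:
        df = self.to_frame()
        df.to_csv(path, sep="\t", header=False, index=False)
        return len(df)

    @classmethod
    def from_bedgraph(cls, path, bin_size: int, chrom_sizes: dict[str, int]) -> "BinTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        data = {c: np.zeros(-(-length // bin_size)) for c, length in chrom_sizes.items()}
        for chrom, g in df.groupby("chrom", sort=False):
            data[chrom][g["start"].to_numpy() // bin_size] = g["value"].to_numpy()
        return cls(bin_size, data)
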