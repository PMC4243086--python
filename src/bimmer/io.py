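"""Binned read-count containers and BED-like text I/O.

Count tracks are fixed-width genomic bins (100 bp by default) carrying one
non-negative integer read count per sample, stored as one 4-column
tab-separated file per sample: chrom, start, end, count with 0-based
half-open coordinates.  All samples in a cohort must share an identical bin
grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["BinnedCounts", "read_binned_counts", "write_binned_counts"]

_BED_COLS = ["chrom", "start", "end", "count"]


@dataclass
class BinnedCounts:
    """An M-bin x N-sample count matrix with its genomic grid.

    Bins are fixed-width, sorted, non-overlapping and contiguous within a
    chromosome; coordinates are 0-based half-open.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    counts: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        M = len(self.start)
        if not (len(self.chrom) == len(self.end) == M == self.counts.shape[0]):
            raise ValueError("chrom/start/end/counts lengths disagree")
        if len(self.samples) != self.counts.shape[1]:
            raise ValueError("sample names do not match count columns")
        if M == 0:
            raise ValueError("empty track")
        widths = self.end - self.start
        if np.any(widths <= 0):
            raise ValueError("bins must satisfy start < end")
        if len(np.unique(widths)) != 1:
            raise ValueError("bin width must be constant")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        # sorted / contiguous / non-overlapping within each chromosome
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (self.start[1:] != self.end[:-1])):
            i = int(np.nonzero(same & (self.start[1:] != self.end[:-1]))[0][0]) + 1
            raise ValueError(
                f"bins must be sorted and contiguous: offending bin "
                f"{self.chrom[i]}:{self.start[i]}-{self.end[i]}"
            )

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_width(self) -> int:
        return int(self.end[0] - self.start[0])

    def same_grid(self, other: "BinnedCounts") -> bool:
        return (
            self.n_bins == other.n_bins
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )


def read_binned_counts(
    paths: Sequence[str | Path], bin_width: int | None = None
) -> BinnedCounts:
    """Assemble one cohort's count matrix from per-sample BED-like files.

    All files must share an identical bin grid; the first disagreeing bin is
    named in the error.  Non-integer counts are rejected.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", header=None, names=_BED_COLS, comment="#")
        if not np.issubdtype(df["count"].dtype, np.number):
            raise ValueError(f"{p}: non-numeric count column")
        if np.any(df["count"] != df["count"].astype(np.int64)):
            raise ValueError(f"{p}: counts must be integers")
        frames.append(df)
    ref = frames[0]
    for p, df in zip(paths[1:], frames[1:]):
        if len(df) != len(ref):
            raise ValueError(f"{p}: bin count {len(df)} != {len(ref)} in {paths[0]}")
        mismatch = (
            (df["chrom"].to_numpy() != ref["chrom"].to_numpy())
            | (df["start"].to_numpy() != ref["start"].to_numpy())
            | (df["end"].to_numpy() != ref["end"].to_numpy())
        )
        if mismatch.any():
            i = int(np.nonzero(mismatch)[0][0])
            raise ValueError(
                f"{p}: bin grid mismatch at row {i} "
                f"({df['chrom'][i]}:{df['start'][i]}-{df['end'][i]} vs "
                f"{ref['chrom'][i]}:{ref['start'][i]}-{ref['end'][i]})"
            )
    counts = np.column_stack([df["count"].to_numpy(np.int64) for df in frames])
    bc = BinnedCounts(
        chrom=ref["chrom"].to_numpy(object),
        start=ref["start"].to_numpy(np.int64),
        end=ref["end"].to_numpy(np.int64),
        counts=counts,
        samples=[p.stem for p in paths],
    )
    if bin_width is not None and bc.bin_width != bin_width:
        raise ValueError(f"expected {bin_width} bp bins, found {bc.bin_width}")
    return bc


def write_binned_counts(bc: BinnedCounts, outdir: str | Path) -> list[Path]:
    """Write one 4-column BED-like file per sample; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for j, name in enumerate(bc.samples):
        path = outdir / f"{name}.bed"
        pd.DataFrame(
            {
                "chrom": bc.chrom,
                "start": bc.start,
                "end": bc.end,
                "count": bc.counts[:, j],
            }
        ).to_csv(path, sep="\t", header=False, index=False)
        written.append(path)
    return written
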