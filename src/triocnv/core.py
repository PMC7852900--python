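"""Core containers shared across the pipeline.

A :class:`MarkerMap` is the ordered autosomal SNP map (name, chromosome,
1-based position, population B-allele frequency).  A :class:`SignalMatrix`
holds per-sample Log R Ratio (LRR) and B Allele Frequency (BAF) values over
one marker map, samples on rows.

The canonical LRR level per integer copy number follows the usual SNP-array
calibration (total intensity is roughly log-linear in copy number, with a
deep drop for homozygous deletions).  Fractional copy numbers — mosaic
gains — interpolate linearly between the flanking integer states.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarkerMap", "SignalMatrix", "LRR_STATE_MEANS", "lrr_mean_for_copies"]

# Expected LRR per copy-number state (copy number 0..4).
LRR_STATE_MEANS: dict[int, float] = {0: -3.5, 1: -0.66, 2: 0.0, 3: 0.40, 4: 0.68}

_CN_GRID = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
_LRR_GRID = np.array([LRR_STATE_MEANS[i] for i in range(5)])


def lrr_mean_for_copies(copies: np.ndarray, means: dict[int, float] | None = None) -> np.ndarray:
    """Expected LRR for (possibly fractional) total copy numbers.

    Linear interpolation on the integer-state grid; preserves float32
    input dtype (the simulator's working precision).
    """
    t = np.asarray(copies)
    if means is None:
        grid = _LRR_GRID
    else:
        grid = np.array([means[i] for i in range(5)])
    dtype = t.dtype if np.issubdtype(t.dtype, np.floating) else np.float64
    grid = grid.astype(dtype)
    tc = np.clip(t, 0.0, 4.0).astype(dtype)
    lo = np.minimum(tc.astype(np.int64), 3)
    frac = tc - lo
    return grid[lo] + frac * (grid[lo + 1] - grid[lo])


@dataclass
class MarkerMap:
    """Ordered marker map: positions strictly increasing within a chromosome."""

    names: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    pfb: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.names) == len(self.chrom) == len(self.pfb) == n):
            raise ValueError("marker arrays must have equal length")
        if n == 0:
            raise ValueError("empty marker map")
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.pfb = np.asarray(self.pfb, dtype=float)
        if len(np.unique(np.asarray(self.names))) != n:
            raise ValueError("duplicate marker names")
        for sl in self.chrom_slices().values():
            if np.any(np.diff(self.pos[sl]) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
        if np.any((self.pfb <= 0) | (self.pfb >= 1)):
            raise ValueError("pfb must lie in (0, 1) for polymorphic markers")

    def __len__(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice per chromosome, in file order."""
        out: dict[str, slice] = {}
        chrom = np.asarray(self.chrom)
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                key = str(chrom[start])
                if key in out:
                    raise ValueError(f"chromosome {key} is not contiguous in the map")
                out[key] = slice(start, i)
                start = i
        return out

    def span_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of markers inside [start, end] (1-based inclusive)."""
        sl = self.chrom_slices().get(str(chrom))
        if sl is None:
            return np.array([], dtype=np.int64)
        pos = self.pos[sl]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.int64)


@dataclass
class SignalMatrix:
    """LRR/BAF values for a set of samples over one marker map."""

    markers: MarkerMap
    samples: list[str] = field(default_factory=list)
    lrr: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    baf: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr)
        self.baf = np.asarray(self.baf)
        if not np.issubdtype(self.lrr.dtype, np.floating):
            self.lrr = self.lrr.astype(float)
        if not np.issubdtype(self.baf.dtype, np.floating):
            self.baf = self.baf.astype(float)
        n = len(self.markers)
        if self.lrr.shape != (len(self.samples), n) or self.baf.shape != self.lrr.shape:
            raise ValueError("lrr/baf must be (n_samples, n_markers)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset(self, samples: list[str]) -> "SignalMatrix":
        idx = [self.sample_index(s) for s in samples]
        return SignalMatrix(self.markers, list(samples), self.lrr[idx], self.baf[idx])
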