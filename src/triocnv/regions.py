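"""Recurrent NDD regions and interval blacklists.

Thirteen autosomal low-copy-repeat flanked regions are repeatedly deleted or
duplicated through nonallelic homologous recombination and are collectively
associated with neurodevelopmental disorders (NDDs).  Their GRCh37 reference
coordinates are packaged with the library (``data/ndd_regions_grch37.bed``)
and loaded by :func:`load_ndd_regions`.

Coordinates are 1-based inclusive internally; conversion to/from BED's
0-based half-open convention happens only at the file boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "NddRegion",
    "load_ndd_regions",
    "read_regions_bed",
    "write_regions_bed",
    "load_synthetic_blacklist",
]


@dataclass(frozen=True)
class NddRegion:
    """One recurrent NDD region (1-based inclusive GRCh37 span)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name}: start must be < end")
        if self.start < 1:
            raise ValueError(f"region {self.name}: coordinates are 1-based")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        """Span in megabases, matching the convention (end − start)/1e6."""
        return (self.end - self.start) / 1e6


def read_regions_bed(path: str | Path) -> list[NddRegion]:
    """Read regions from a BED file (0-based half-open → 1-based inclusive).

    Only the first four columns (chrom, start, end, name) are used.
    """
    regions: list[NddRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            regions.append(NddRegion(name=name, chrom=chrom, start=start + 1, end=end))
    return regions


def write_regions_bed(regions: list[NddRegion], path: str | Path) -> None:
    """Write regions as 4-column BED (1-based inclusive → 0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def _packaged(name: str) -> Path:
    return Path(str(resources.files("triocnv").joinpath("data", name)))


def load_ndd_regions() -> list[NddRegion]:
    """The 13 packaged recurrent NDD regions (GRCh37)."""
    return read_regions_bed(_packaged("ndd_regions_grch37.bed"))


def load_synthetic_blacklist() -> list[NddRegion]:
    """Packaged synthetic blacklist intervals for the simulated genome.

    These are constructed stand-ins for centromeric/telomeric and other
    copy-number-susceptible intervals, placed in the flanks of the simulated
    region windows; they are NOT real GRCh37 annotation.
    """
    return read_regions_bed(_packaged("blacklist_synthetic.bed"))
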