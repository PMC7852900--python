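import numpy as np
import pytest

from triocnv.core import MarkerMap, SignalMatrix
from triocnv.regions import NddRegion


def make_map(n: int = 200, chrom: str = "1", start: int = 1,
             spacing: int = 20_000, pfb: float | None = None,
             seed: int = 0) -> MarkerMap:
    """Evenly spaced single-chromosome marker map."""
    rng = np.random.default_rng(seed)
    pos = start + spacing * np.arange(n, dtype=np.int64)
    pfb_arr = np.full(n, pfb) if pfb is not None else rng.uniform(0.1, 0.9, n)
    return MarkerMap(
        names=np.array([f"snp_{chrom}_{i}" for i in range(n)]),
        chrom=np.full(n, chrom, dtype=object),
        pos=pos,
        pfb=pfb_arr,
    )


def diploid_signals(mm: MarkerMap, samples: list[str], baf_pattern: str = "het",
                    seed: int = 0) -> SignalMatrix:
    """Noise-free diploid signals; BAF drawn from the 0/0.5/1 bands."""
    rng = np.random.default_rng(seed)
    n = len(mm)
    lrr = np.zeros((len(samples), n))
    if baf_pattern == "het":
        baf = np.full((len(samples), n), 0.5)
    else:
        p = mm.pfb[None, :]
        g = rng.random((len(samples), 2, n))
        baf = ((g[:, 0] < p).astype(float) + (g[:, 1] < p)) / 2.0
    return SignalMatrix(mm, samples, lrr, baf)


@pytest.fixture
def marker_map() -> MarkerMap:
    return make_map()


@pytest.fixture
def region_1q() -> NddRegion:
    return NddRegion(name="1q21.1", chrom="1", start=146578858, end=147396590)
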