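"""Synthetic SNP-array trio cohorts with known CNV ground truth.

The generator emulates the data a genome-wide genotyping array produces for
mother-father-child trios: per-marker LRR/BAF signals on an ordered marker
map, Mendelian allele transmission, and implanted recurrent CNVs (copy
number 0/1/3/4) at the packaged NDD regions — inherited events (implanted
in a parent, then transmitted), de novo events with a known parental
homolog of origin, untransmitted parental carriers, and one-sample mosaic
gains.  Every implanted event is recorded in a truth table so downstream
calling, classification and parent-of-origin inference can be scored
against known answers.

Alleles are biallelic (0 = A, 1 = B).  Copy state is represented as
per-marker allele copy counts (copies of A, copies of B); a mosaic gain of
cell fraction f contributes fractionally, shifting the heterozygous BAF
bands to 1/(2+f) and (1+f)/(2+f).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MarkerMap, SignalMatrix, lrr_mean_for_copies
from .regions import NddRegion, load_ndd_regions
from .stats import load_published_counts

__all__ = [
    "NoiseModel",
    "TruthEvent",
    "TrioGenotypes",
    "AlleleCounts",
    "CohortConfig",
    "Cohort",
    "build_marker_map",
    "simulate_trio_genotypes",
    "base_allele_counts",
    "implant_cnv",
    "render_signals",
    "generate_cohort",
]


@dataclass(frozen=True)
class NoiseModel:
    """Array noise: LRR Gaussian SD, within-band BAF SD, outlier-marker rate
    and long-range sinusoidal LRR wave amplitude.

    Defaults are calibrated to a clean genotyping batch (QC-passing samples
    have LRR SD near 0.1 on real arrays).
    """

    lrr_sd: float = 0.10
    baf_sd: float = 0.03
    outlier_rate: float = 0.002
    wave_amplitude: float = 0.01

    def __post_init__(self) -> None:
        if min(self.lrr_sd, self.baf_sd, self.outlier_rate, self.wave_amplitude) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.outlier_rate >= 0.05:
            raise ValueError("outlier_rate must be < 0.05")


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth record for one implanted offspring CNV."""

    family: str
    carrier: str
    region: str
    chrom: str
    start: int
    end: int
    copy_number: int
    mode: str                 # "inherited" | "de_novo"
    origin_parent: str        # "maternal" | "paternal"
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.copy_number == 2 or self.copy_number not in (0, 1, 3, 4):
            raise ValueError("copy_number must be one of {0, 1, 3, 4}")
        if self.mode not in ("inherited", "de_novo"):
            raise ValueError("mode must be inherited or de_novo")
        if self.origin_parent not in ("maternal", "paternal"):
            raise ValueError("origin_parent must be maternal or paternal")
        if not 0.0 < self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in (0, 1]")

    @property
    def svclass(self) -> str:
        return "del" if self.copy_number < 2 else "dup"


@dataclass
class TrioGenotypes:
    """Parental haplotypes and per-marker transmitted homolog indices.

    mother/father: (n_trios, 2, n_markers) int8 allele matrices;
    trans_mat/trans_pat: (n_trios, n_markers) int8 indices (0 or 1) of the
    homolog each parent transmitted to the child.
    """

    markers: MarkerMap
    mother: np.ndarray
    father: np.ndarray
    trans_mat: np.ndarray
    trans_pat: np.ndarray

    @property
    def n_trios(self) -> int:
        return self.mother.shape[0]

    def child_alleles(self, trio: int, span: np.ndarray | slice = slice(None)) -> tuple[np.ndarray, np.ndarray]:
        """(maternal allele, paternal allele) transmitted at each marker."""
        idx = np.arange(self.mother.shape[2])[span]
        vm = self.mother[trio][self.trans_mat[trio, idx].astype(np.int64), idx]
        vp = self.father[trio][self.trans_pat[trio, idx].astype(np.int64), idx]
        return vm, vp


@dataclass
class AlleleCounts:
    """Per-sample, per-marker copies of the A and B allele (float: mosaic
    contributions are fractional)."""

    samples: list[str]
    a: np.ndarray
    b: np.ndarray

    def row(self, sample: str) -> int:
        return self.samples.index(sample)

    @property
    def total(self) -> np.ndarray:
        return self.a + self.b


def build_marker_map(
    chrom_windows: dict[str, tuple[int, int] | int],
    n_markers: int,
    boost_regions: list[NddRegion] | None = None,
    region_density_boost: float = 1.0,
    seed: int = 0,
    pfb_range: tuple[float, float] = (0.1, 0.9),
) -> MarkerMap:
    """Draw an ordered marker map over chromosome windows.

    ``chrom_windows`` maps a chromosome to either its length (window starts
    at 1) or an explicit 1-based inclusive window.  ``n_markers`` is the
    genome-wide total, allocated across chromosomes proportionally to
    density-weighted window length; markers inside ``boost_regions`` are
    ``region_density_boost`` times denser (array designs enrich clinically
    relevant regions).
    """
    if n_markers < len(chrom_windows):
        raise ValueError("need at least one marker per chromosome")
    if region_density_boost < 1.0:
        raise ValueError("region_density_boost must be >= 1")
    boost_regions = boost_regions or []
    rng = np.random.default_rng(seed)

    windows: dict[str, tuple[int, int]] = {}
    for chrom, w in chrom_windows.items():
        lo, hi = (1, int(w)) if np.isscalar(w) else (int(w[0]), int(w[1]))
        if hi <= lo:
            raise ValueError(f"chromosome {chrom}: zero-length window")
        windows[str(chrom)] = (lo, hi)

    # Piecewise-constant density per chromosome: breakpoints at region edges.
    plan: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
    weights = {}
    for chrom, (lo, hi) in windows.items():
        edges = {float(lo), float(hi + 1)}
        for r in boost_regions:
            if str(r.chrom) == chrom:
                edges.add(float(np.clip(r.start, lo, hi + 1)))
                edges.add(float(np.clip(r.end + 1, lo, hi + 1)))
        edges_arr = np.array(sorted(edges))
        mids = (edges_arr[:-1] + edges_arr[1:]) / 2
        dens = np.ones(len(mids))
        for r in boost_regions:
            if str(r.chrom) == chrom:
                dens[(mids >= r.start) & (mids <= r.end)] = region_density_boost
        seg_w = dens * np.diff(edges_arr)
        plan[chrom] = (edges_arr, seg_w, float(seg_w.sum()))
        weights[chrom] = float(seg_w.sum())

    total_w = sum(weights.values())
    alloc = {c: max(1, int(round(n_markers * w / total_w))) for c, w in weights.items()}
    # Adjust rounding drift on the largest chromosome.
    drift = n_markers - sum(alloc.values())
    if drift:
        big = max(alloc, key=lambda c: alloc[c])
        alloc[big] = max(1, alloc[big] + drift)

    names, chroms, poss, pfbs = [], [], [], []
    for chrom in windows:
        edges_arr, seg_w, w_sum = plan[chrom]
        k = alloc[chrom]
        positions: set[int] = set()
        guard = 0
        while len(positions) < k:
            need = k - len(positions)
            seg = rng.choice(len(seg_w), size=need, p=seg_w / w_sum)
            u = rng.random(need)
            pts = edges_arr[seg] + u * (edges_arr[seg + 1] - edges_arr[seg])
            positions.update(int(p) for p in np.floor(pts))
            guard += 1
            if guard > 200:
                raise RuntimeError("window too small for requested marker count")
        pos_sorted = np.array(sorted(positions), dtype=np.int64)
        names.extend(f"snp_{chrom}_{i}" for i in range(k))
        chroms.extend([chrom] * k)
        poss.append(pos_sorted)
        pfbs.append(rng.uniform(*pfb_range, size=k))
    return MarkerMap(
        names=np.array(names),
        chrom=np.array(chroms),
        pos=np.concatenate(poss),
        pfb=np.concatenate(pfbs),
    )


def simulate_trio_genotypes(markers: MarkerMap, trio_count: int, seed: int = 0) -> TrioGenotypes:
    """Hardy-Weinberg parental haplotypes and random Mendelian transmission.

    Parental alleles are drawn per marker with probability pfb of carrying
    the B allele on each homolog; each child allele pair is one transmitted
    maternal and one transmitted paternal homolog, recorded per marker.
    """
    if trio_count < 1:
        raise ValueError("trio_count must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(markers)
    p = markers.pfb[None, None, :]
    mother = (rng.random((trio_count, 2, m)) < p).astype(np.int8)
    father = (rng.random((trio_count, 2, m)) < p).astype(np.int8)
    trans_mat = rng.integers(0, 2, size=(trio_count, m), dtype=np.int8)
    trans_pat = rng.integers(0, 2, size=(trio_count, m), dtype=np.int8)
    return TrioGenotypes(markers, mother, father, trans_mat, trans_pat)


def trio_sample_ids(i: int) -> tuple[str, str, str]:
    """(child, father, mother) sample ids for trio index i."""
    return f"c{i:05d}", f"f{i:05d}", f"m{i:05d}"


def base_allele_counts(gt: TrioGenotypes) -> AlleleCounts:
    """Diploid allele copy counts for all samples, children first, then
    fathers, then mothers (rows c0..cT-1, f0..fT-1, m0..mT-1)."""
    t, m = gt.n_trios, len(gt.markers)
    samples = (
        [trio_sample_ids(i)[0] for i in range(t)]
        + [trio_sample_ids(i)[1] for i in range(t)]
        + [trio_sample_ids(i)[2] for i in range(t)]
    )
    a = np.empty((3 * t, m), dtype=np.float32)
    b = np.empty((3 * t, m), dtype=np.float32)
    idx = np.arange(m)
    vm = np.take_along_axis(gt.mother, gt.trans_mat[:, None, :].astype(np.int64), axis=1)[:, 0, :]
    vp = np.take_along_axis(gt.father, gt.trans_pat[:, None, :].astype(np.int64), axis=1)[:, 0, :]
    b[:t] = vm + vp
    a[:t] = 2.0 - b[:t]
    b[t:2 * t] = gt.father.sum(axis=1)
    a[t:2 * t] = 2.0 - b[t:2 * t]
    b[2 * t:] = gt.mother.sum(axis=1)
    a[2 * t:] = 2.0 - b[2 * t:]
    del idx
    return AlleleCounts(samples, a, b)


def _recompute_child_span(
    counts: AlleleCounts, gt: TrioGenotypes, trio: int, span: np.ndarray,
    drop_parent: str | None = None,
) -> None:
    """Rebuild the child's base counts over a span from current transmission
    indices; a parent in ``drop_parent`` contributes nothing (its transmitted
    homolog carries a deletion)."""
    vm = gt.mother[trio][gt.trans_mat[trio, span].astype(np.int64), span]
    vp = gt.father[trio][gt.trans_pat[trio, span].astype(np.int64), span]
    contrib = []
    if drop_parent not in ("maternal", "both"):
        contrib.append(vm)
    if drop_parent not in ("paternal", "both"):
        contrib.append(vp)
    b = np.sum(contrib, axis=0) if contrib else np.zeros(len(span))
    n = float(len(contrib))
    counts.b[trio, span] = b
    counts.a[trio, span] = n - b


def implant_cnv(
    counts: AlleleCounts,
    gt: TrioGenotypes,
    trio: int,
    event: TruthEvent,
    rng: np.random.Generator,
    interchromosomal: bool = True,
    parent_transmits: bool = True,
) -> None:
    """Implant one offspring CNV (and, for inherited events, the carrying
    parent's CNV first) into the allele-count matrices.

    Within the span the carrier child's allele multiset reflects the copy
    number: deletions remove the origin parent's transmitted contribution,
    duplications add one extra copy drawn from the origin parent's homologs
    (either homolog when ``interchromosomal``, the transmitted one
    otherwise).  Transmission indices are made constant across the span so
    the event is a coherent haplotype segment.
    """
    span = gt.markers.span_indices(event.chrom, event.start, event.end)
    if len(span) == 0:
        raise ValueError(f"event span {event.chrom}:{event.start}-{event.end} contains no markers")
    t_n = gt.n_trios
    maternal = event.origin_parent == "maternal"
    trans = gt.trans_mat if maternal else gt.trans_pat
    hap = gt.mother if maternal else gt.father
    parent_row = 2 * t_n + trio if maternal else t_n + trio

    # Coherent transmitted homolog over the span.
    tsel = int(rng.integers(0, 2))
    other_trans = gt.trans_pat if maternal else gt.trans_mat
    other_trans[trio, span] = int(rng.integers(0, 2))

    if event.svclass == "del":
        if event.copy_number == 0:
            if event.mode == "inherited":
                raise ValueError("homozygous deletions are supported as de novo only")
            trans[trio, span] = tsel
            _recompute_child_span(counts, gt, trio, span, drop_parent="both")
            return
        if event.mode == "inherited":
            # Parent is hemizygous on homolog d; child inherits iff d is transmitted.
            d = int(rng.integers(0, 2))
            keep = hap[trio, 1 - d, span]
            counts.b[parent_row, span] = keep
            counts.a[parent_row, span] = 1.0 - keep
            trans[trio, span] = d if parent_transmits else 1 - d
            _recompute_child_span(
                counts, gt, trio, span,
                drop_parent=(event.origin_parent if parent_transmits else None),
            )
        else:
            trans[trio, span] = tsel
            _recompute_child_span(counts, gt, trio, span, drop_parent=event.origin_parent)
        return

    # Duplications.
    attach = int(rng.integers(0, 2))            # homolog the extra copy rides on
    donor = int(rng.integers(0, 2)) if interchromosomal else attach
    extra = hap[trio, donor, span].astype(np.float32)
    n_extra = 2 if event.copy_number == 4 else 1
    extra2 = hap[trio, 1 - donor, span].astype(np.float32) if n_extra == 2 else None

    if event.mode == "inherited":
        counts.b[parent_row, span] += extra
        counts.a[parent_row, span] += 1.0 - extra
        if extra2 is not None:
            counts.b[parent_row, span] += extra2
            counts.a[parent_row, span] += 1.0 - extra2
        trans[trio, span] = attach if parent_transmits else 1 - attach
        _recompute_child_span(counts, gt, trio, span)
        if not parent_transmits:
            return
    else:
        trans[trio, span] = attach
        _recompute_child_span(counts, gt, trio, span)

    f = event.mosaic_fraction
    counts.b[trio, span] += f * extra
    counts.a[trio, span] += f * (1.0 - extra)
    if extra2 is not None:
        counts.b[trio, span] += f * extra2
        counts.a[trio, span] += f * (1.0 - extra2)


def render_signals(
    counts: AlleleCounts,
    markers: MarkerMap,
    noise: NoiseModel,
    seed: int = 0,
    state_means: dict[int, float] | None = None,
) -> SignalMatrix:
    """Render LRR/BAF signals from allele copy counts.

    LRR is the canonical state mean for the total copy number (linear
    interpolation for fractional/mosaic totals) plus a per-sample sinusoidal
    wave and Gaussian noise.  BAF is the allele-ratio band b/(a+b) plus
    band noise, clipped to [0, 1]; copy-number-0 markers and outlier markers
    emit uniform BAF.
    """
    total = np.asarray(counts.total, dtype=np.float32)
    if np.any(total > 4.0 + 1e-6):
        raise ValueError("total copy number above 4 is not supported")
    rng = np.random.default_rng(seed)
    n_s, n_m = total.shape
    # Almost all markers are diploid; interpolate LRR means only off-diploid.
    means2 = (state_means or {}).get(2, 0.0) if state_means else 0.0
    lrr = np.full((n_s, n_m), np.float32(means2), dtype=np.float32)
    off = total != np.float32(2.0)
    if off.any():
        lrr[off] = lrr_mean_for_copies(total[off], state_means)

    if noise.wave_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_s).astype(np.float32)
        for sl in markers.chrom_slices().values():
            pos = markers.pos[sl]
            period = max(int(pos[-1] - pos[0]), 1)
            theta = (2 * np.pi * (pos - pos[0]) / period).astype(np.float32)
            lrr[:, sl] += np.float32(noise.wave_amplitude) * np.sin(
                theta[None, :] + phase[:, None])
    if noise.lrr_sd > 0:
        lrr += np.float32(noise.lrr_sd) * rng.standard_normal((n_s, n_m), dtype=np.float32)

    zero = total <= 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(zero, np.float32(0.5),
                       np.asarray(counts.b, dtype=np.float32)
                       / np.where(zero, np.float32(1.0), total))
    if noise.baf_sd > 0:
        baf = baf + np.float32(noise.baf_sd) * rng.standard_normal((n_s, n_m), dtype=np.float32)
    if zero.any():
        baf[zero] = rng.random(int(zero.sum()), dtype=np.float32)
    if noise.outlier_rate > 0:
        out = rng.random((n_s, n_m)) < noise.outlier_rate
        baf[out] = rng.random(int(out.sum()), dtype=np.float32)
    np.clip(baf, 0.0, 1.0, out=baf)
    return SignalMatrix(markers, list(counts.samples), lrr, baf)


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------

def _default_rates() -> dict[tuple[str, str], float]:
    """Per-region, per-class offspring event rates from the published
    12,252-trio screen (events / trios)."""
    counts = load_published_counts()
    n = counts["n_trios"]
    return {(r["region"], r["svclass"]): r["n"] / n for r in counts["rows"]}


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Default event rates, the de novo fraction (20/59), the maternal shares
    of inherited (24/39) and de novo (10/19) events, the mosaic rate among
    de novo duplications (1/7) and the untransmitted parental carrier rates
    (19 maternal / 29 paternal per 12,252) reproduce the published cohort;
    marker density and flank size control problem size only.
    """

    n_trios: int = 200
    regions: list[NddRegion] = field(default_factory=load_ndd_regions)
    rates: dict = field(default_factory=_default_rates)
    flank_bp: int = 500_000
    marker_spacing_bp: float = 5_000.0
    region_density_boost: float = 2.0
    de_novo_fraction: float = 20 / 59
    maternal_inherited_share: float = 24 / 39
    maternal_de_novo_share: float = 10 / 19
    mosaic_prob_de_novo_dup: float = 1 / 7
    mosaic_fraction_range: tuple[float, float] = (0.3, 0.7)
    untransmitted_maternal_rate: float = 19 / 12252
    untransmitted_paternal_rate: float = 29 / 12252
    breakpoint_jitter_bp: int = 100_000
    noise: NoiseModel = field(default_factory=NoiseModel)
    interchromosomal: bool = True
    pfb_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        for key, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {key} outside [0, 1]")
        if self.breakpoint_jitter_bp > self.flank_bp:
            raise ValueError("breakpoint jitter must fit inside the flank")

    def chrom_windows(self) -> dict[str, tuple[int, int]]:
        """Union of region ± flank windows per chromosome (merged)."""
        wins: dict[str, list[list[int]]] = {}
        for r in self.regions:
            lo = max(1, r.start - self.flank_bp)
            hi = r.end + self.flank_bp
            wins.setdefault(str(r.chrom), []).append([lo, hi])
        out: dict[str, tuple[int, int]] = {}
        for chrom, spans in wins.items():
            spans.sort()
            lo = min(s[0] for s in spans)
            hi = max(s[1] for s in spans)
            out[chrom] = (lo, hi)
        return out

    def n_markers(self) -> int:
        wins = self.chrom_windows()
        total = sum(hi - lo for lo, hi in wins.values())
        boosted = sum(r.length_bp * (self.region_density_boost - 1) for r in self.regions)
        return max(len(wins), int((total + boosted) / self.marker_spacing_bp))


@dataclass
class Cohort:
    """A generated cohort: map, pedigree, genotypes, truth and signals."""

    config: CohortConfig
    markers: MarkerMap
    pedigree: pd.DataFrame
    genotypes: TrioGenotypes
    counts: AlleleCounts
    signals: SignalMatrix
    truth: pd.DataFrame
    parent_truth: pd.DataFrame

    @property
    def children(self) -> list[str]:
        return list(self.pedigree["child"])

    @property
    def parents(self) -> list[str]:
        return list(self.pedigree["father"]) + list(self.pedigree["mother"])


_TRUTH_COLS = ["family", "carrier", "region", "chrom", "start", "end",
               "copy_number", "svclass", "mode", "origin_parent", "mosaic_fraction"]
_PARENT_COLS = ["family", "carrier", "parent", "region", "chrom", "start", "end",
                "copy_number", "svclass", "transmitted"]


def generate_cohort(config: CohortConfig, seed: int = 0) -> Cohort:
    """Generate a full trio cohort under the configured study conditions.

    Deterministic for a fixed (config, seed).  Child events are drawn per
    region/class with the configured rates; each is de novo or inherited
    (implanted in the parent, then transmitted), with mosaic de novo gains
    at the configured rate.  Additional untransmitted parental carriers are
    implanted so transmission statistics are nondegenerate.
    """
    rng = np.random.default_rng(seed)
    markers = build_marker_map(
        config.chrom_windows(), config.n_markers(),
        boost_regions=config.regions, region_density_boost=config.region_density_boost,
        seed=int(rng.integers(2**31)), pfb_range=config.pfb_range,
    )
    gt = simulate_trio_genotypes(markers, config.n_trios, seed=int(rng.integers(2**31)))
    counts = base_allele_counts(gt)

    regions = {r.name: r for r in config.regions}
    occupied: dict[int, set[str]] = {}
    truth_rows, parent_rows = [], []

    def span_for(region: NddRegion) -> tuple[int, int]:
        j1 = int(rng.integers(0, config.breakpoint_jitter_bp + 1))
        j2 = int(rng.integers(0, config.breakpoint_jitter_bp + 1))
        return max(1, region.start - j1), region.end + j2

    for (rname, svclass), rate in sorted(config.rates.items()):
        if rate <= 0 or rname not in regions:
            continue
        region = regions[rname]
        carriers = np.flatnonzero(rng.random(config.n_trios) < rate)
        for trio in carriers:
            if rname in occupied.setdefault(int(trio), set()):
                continue
            occupied[int(trio)].add(rname)
            de_novo = rng.random() < config.de_novo_fraction
            if de_novo:
                origin = "maternal" if rng.random() < config.maternal_de_novo_share else "paternal"
            else:
                origin = "maternal" if rng.random() < config.maternal_inherited_share else "paternal"
            mosaic = 1.0
            if de_novo and svclass == "dup" and rng.random() < config.mosaic_prob_de_novo_dup:
                mosaic = float(rng.uniform(*config.mosaic_fraction_range))
            start, end = span_for(region)
            cid, fid, mid = trio_sample_ids(int(trio))
            event = TruthEvent(
                family=f"fam{trio:05d}", carrier=cid, region=rname,
                chrom=str(region.chrom), start=start, end=end,
                copy_number=1 if svclass == "del" else 3,
                mode="de_novo" if de_novo else "inherited",
                origin_parent=origin, mosaic_fraction=mosaic,
            )
            implant_cnv(counts, gt, int(trio), event, rng,
                        interchromosomal=config.interchromosomal)
            truth_rows.append([event.family, event.carrier, event.region, event.chrom,
                               event.start, event.end, event.copy_number, event.svclass,
                               event.mode, event.origin_parent, event.mosaic_fraction])
            if not de_novo:
                pid = mid if origin == "maternal" else fid
                parent_rows.append([event.family, pid,
                                    "mother" if origin == "maternal" else "father",
                                    rname, event.chrom, start, end,
                                    event.copy_number, svclass, True])

    # Untransmitted parental carriers, allocated across region/class rates.
    total_rate = sum(config.rates.values())
    if total_rate > 0:
        for parent_label, total_unt in (("maternal", config.untransmitted_maternal_rate),
                                        ("paternal", config.untransmitted_paternal_rate)):
            for (rname, svclass), rate in sorted(config.rates.items()):
                if rate <= 0 or rname not in regions:
                    continue
                region = regions[rname]
                r_unt = total_unt * rate / total_rate
                carriers = np.flatnonzero(rng.random(config.n_trios) < r_unt)
                for trio in carriers:
                    if rname in occupied.setdefault(int(trio), set()):
                        continue
                    occupied[int(trio)].add(rname)
                    start, end = span_for(region)
                    cid, fid, mid = trio_sample_ids(int(trio))
                    event = TruthEvent(
                        family=f"fam{trio:05d}", carrier=cid, region=rname,
                        chrom=str(region.chrom), start=start, end=end,
                        copy_number=1 if svclass == "del" else 3,
                        mode="inherited", origin_parent=parent_label,
                    )
                    implant_cnv(counts, gt, int(trio), event, rng,
                                interchromosomal=config.interchromosomal,
                                parent_transmits=False)
                    pid = mid if parent_label == "maternal" else fid
                    parent_rows.append([event.family, pid,
                                        "mother" if parent_label == "maternal" else "father",
                                        rname, event.chrom, start, end,
                                        event.copy_number, svclass, False])

    # Transmitted parental carriers also appear in the parent table above.
    signals = render_signals(counts, markers, config.noise,
                             seed=int(rng.integers(2**31)))
    pedigree = pd.DataFrame({
        "family": [f"fam{i:05d}" for i in range(config.n_trios)],
        "child": [trio_sample_ids(i)[0] for i in range(config.n_trios)],
        "father": [trio_sample_ids(i)[1] for i in range(config.n_trios)],
        "mother": [trio_sample_ids(i)[2] for i in range(config.n_trios)],
    })
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLS)
    parent_truth = pd.DataFrame(parent_rows, columns=_PARENT_COLS)
    return Cohort(config, markers, pedigree, gt, counts, signals, truth, parent_truth)
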