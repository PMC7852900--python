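"""Copy-number segmentation of LRR/BAF signals with a 6-state HMM.

States are CN0, CN1, CN2 (neutral), CN2-LOH (copy-neutral loss of
heterozygosity), CN3 and CN4.  Emissions combine a Gaussian LRR term per
state with a BAF band mixture whose weights follow from the marker's
population B-allele frequency (the number of B alleles among c copies is
taken as Binomial(c, pfb) under Hardy-Weinberg); band densities are
normals truncated to [0, 1] plus a small uniform outlier component, and
copy-number-0 BAF is uniform.  Transitions are distance-dependent: the
probability of leaving a state over an inter-marker gap of d bp is
eps * (1 - exp(-d/D)), split uniformly over the five other states.

Decoding is exact Viterbi, vectorized over samples, with ties broken
toward CN2 (conservative calling).  Maximal runs of non-neutral states are
emitted as calls; CN2-LOH runs are decoded but dropped from the output,
which analyses deletions and duplications only.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import LRR_STATE_MEANS, SignalMatrix

__all__ = ["HmmParams", "CnvCall", "viterbi_segment", "decode_states",
           "merge_adjacent", "refine_breakpoints", "calls_to_frame"]

STATE_NAMES = ("CN0", "CN1", "CN2", "LOH", "CN3", "CN4")
STATE_COPIES = (0, 1, 2, 2, 3, 4)
_CN2 = 2
_LOH = 3
# Tie preference: CN2 first, then the mildest alternatives.
_PREF = np.array([2, 1, 4, 0, 5, 3])


@dataclass(frozen=True)
class HmmParams:
    """Emission and transition parameters of the 6-state caller."""

    lrr_means: tuple[float, ...] = (
        LRR_STATE_MEANS[0], LRR_STATE_MEANS[1], LRR_STATE_MEANS[2],
        LRR_STATE_MEANS[2], LRR_STATE_MEANS[3], LRR_STATE_MEANS[4],
    )
    lrr_sds: tuple[float, ...] = (1.0, 0.22, 0.18, 0.18, 0.22, 0.26)
    baf_sd: float = 0.04
    outlier_weight: float = 0.01
    change_rate: float = 1e-4       # eps: asymptotic per-gap change probability
    length_scale_bp: float = 1e5    # D in the distance term 1 - exp(-d/D)
    neutral_prior: float = 0.995

    def __post_init__(self) -> None:
        if len(self.lrr_means) != 6 or len(self.lrr_sds) != 6:
            raise ValueError("need 6 per-state LRR means and SDs")
        if min(self.lrr_sds) <= 0 or self.baf_sd <= 0:
            raise ValueError("emission SDs must be positive")
        if not 0.0 < self.change_rate < 1.0 / 5:
            raise ValueError("change_rate must be in (0, 0.2)")

    def log_prior(self) -> np.ndarray:
        prior = np.full(6, (1.0 - self.neutral_prior) / 5.0)
        prior[_CN2] = self.neutral_prior
        return np.log(prior)

    def log_change_terms(self, gaps_bp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-gap (log off-diagonal, log diagonal) transition terms."""
        change = self.change_rate * (1.0 - np.exp(-np.asarray(gaps_bp, float) / self.length_scale_bp))
        change = np.clip(change, 1e-300, 1.0 - 1e-12)
        return np.log(change / 5.0), np.log(1.0 - change)

    def log_transitions(self, gaps_bp: np.ndarray) -> np.ndarray:
        """(n_gaps, 6, 6) log transition matrices; rows sum to one."""
        log_off, log_diag = self.log_change_terms(gaps_bp)
        out = np.empty((len(log_off), 6, 6))
        out[:] = log_off[:, None, None]
        for k in range(6):
            out[:, k, k] = log_diag
        return out


@dataclass
class CnvCall:
    """One contiguous copy-number call (1-based inclusive span)."""

    sample: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_markers: int
    mean_lrr: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.copy_number == 2:
            raise ValueError("neutral segments are not calls")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def svclass(self) -> str:
        return "del" if self.copy_number < 2 else "dup"


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    cols = ["sample", "chrom", "start", "end", "copy_number", "n_markers", "mean_lrr"]
    df = pd.DataFrame([[getattr(c, f) for f in cols] for c in calls], columns=cols)
    if not df.empty:
        df["svclass"] = np.where(df["copy_number"] < 2, "del", "dup")
    else:
        df["svclass"] = pd.Series(dtype=str)
    return df


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def _trunc_norm_pdf(x: np.ndarray, centre: float, sd: float) -> np.ndarray:
    z_norm = sps.norm.cdf((1.0 - centre) / sd) - sps.norm.cdf((0.0 - centre) / sd)
    scale = float(sd * _SQRT_2PI * z_norm)
    arg = (x - centre) / sd
    arg = -0.5 * arg * arg
    dens = np.exp(arg, out=arg) if isinstance(arg, np.ndarray) else np.exp(arg)
    return dens / scale


def _band_weights(pfb: np.ndarray, state: int) -> list[tuple[float, np.ndarray]]:
    """(band centre, per-marker weight) pairs for one state's BAF mixture."""
    copies = STATE_COPIES[state]
    p = np.asarray(pfb, dtype=float)
    if copies == 0:
        return []
    if state == _LOH:
        return [(0.0, 1.0 - p), (1.0, p)]
    from math import comb
    return [(b / copies, comb(copies, b) * p**b * (1.0 - p) ** (copies - b))
            for b in range(copies + 1)]


def baf_band_density(baf: np.ndarray, pfb: np.ndarray, state: int,
                     params: HmmParams) -> np.ndarray:
    """BAF emission density for one state, (n_samples, n_markers)."""
    bands = _band_weights(pfb, state)
    if not bands:                      # CN0: no allele, uniform BAF
        dens = np.ones_like(baf)
    else:
        dens = np.zeros_like(baf)
        for centre, weight in bands:
            dens += weight[None, :] * _trunc_norm_pdf(baf, centre, params.baf_sd)
    w = params.outlier_weight
    return (1.0 - w) * dens + w * 1.0


def log_emissions(lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray,
                  params: HmmParams) -> np.ndarray:
    """(n_samples, n_markers, 6) joint LRR+BAF log emission densities.

    Band centres recur across states (0, 1/4, 1/3, 1/2, 2/3, 3/4, 1), so
    each truncated-normal factor is evaluated once and reused; intermediate
    work runs in float32 for speed, output is float64.
    """
    n_s, n_m = lrr.shape
    lrr32 = np.asarray(lrr, dtype=np.float32)
    baf32 = np.asarray(baf, dtype=np.float32)
    out = np.empty((n_s, n_m, 6), dtype=np.float32)
    w = np.float32(params.outlier_weight)

    pdf_cache: dict[float, np.ndarray] = {}

    def centre_pdf(centre: float) -> np.ndarray:
        if centre not in pdf_cache:
            pdf_cache[centre] = _trunc_norm_pdf(baf32, centre, params.baf_sd)
        return pdf_cache[centre]

    for k in range(6):
        sd = params.lrr_sds[k]
        ll = -0.5 * ((lrr32 - params.lrr_means[k]) / np.float32(sd)) ** 2 \
            - np.float32(np.log(sd * _SQRT_2PI))
        bands = _band_weights(pfb, k)
        if not bands:              # CN0: uniform BAF, density 1, log 0
            out[:, :, k] = ll
            continue
        dens = np.zeros((n_s, n_m), dtype=np.float32)
        for centre, weight in bands:
            dens += np.asarray(weight, dtype=np.float32)[None, :] * centre_pdf(centre)
        dens *= np.float32(1.0) - w
        dens += w
        np.log(dens, out=dens)
        dens += ll
        out[:, :, k] = dens
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _viterbi_batch(log_em: np.ndarray, log_off: np.ndarray, log_diag: np.ndarray,
                   log_prior: np.ndarray) -> np.ndarray:
    """Exact MAP paths for a batch, ties broken by the _PREF state order.

    Exploits the transition structure (a shared off-diagonal mass per gap):
    the best predecessor of any state is either the state itself (diagonal)
    or the globally best-scoring state (off-diagonal), so each step is
    O(samples x states) instead of O(samples x states^2).

    log_em: (S, M, 6); log_off/log_diag: (M-1,); returns (S, M) int8 paths.
    """
    n_s, n_m, k = log_em.shape
    score = log_prior[None, :] + log_em[:, 0, :]
    ptr = np.empty((n_m, n_s, k), dtype=np.int8)
    rows = np.arange(n_s)
    all_states = np.arange(k, dtype=np.int8)[None, :]
    for j in range(1, n_m):
        sp = score[:, _PREF]
        gm_pref = np.argmax(sp, axis=1)               # first maximizer in pref order
        gm_state = _PREF[gm_pref].astype(np.int8)
        gm = sp[rows, gm_pref]
        cand_off = gm + log_off[j - 1]                # (S,) best jump-in score
        cand_diag = score + log_diag[j - 1]           # (S, 6) stay score
        stay = cand_diag >= cand_off[:, None]
        ptr[j] = np.where(stay, all_states, gm_state[:, None])
        score = np.maximum(cand_diag, cand_off[:, None]) + log_em[:, j, :]
    paths = np.empty((n_s, n_m), dtype=np.int8)
    paths[:, -1] = _PREF[np.argmax(score[:, _PREF], axis=1)]
    for j in range(n_m - 1, 0, -1):
        paths[:, j - 1] = ptr[j][rows, paths[:, j]]
    return paths


def decode_states(signals: SignalMatrix, params: HmmParams | None = None,
                  batch_size: int = 1024) -> np.ndarray:
    """Viterbi state paths (n_samples, n_markers), decoded per chromosome."""
    params = params or HmmParams()
    mm = signals.markers
    n_s = len(signals.samples)
    paths = np.empty((n_s, len(mm)), dtype=np.int8)
    log_prior = params.log_prior()
    for sl in mm.chrom_slices().values():
        gaps = np.diff(mm.pos[sl])
        log_off, log_diag = params.log_change_terms(gaps) if len(gaps) else (
            np.empty(0), np.empty(0))
        for lo in range(0, n_s, batch_size):
            hi = min(lo + batch_size, n_s)
            em = log_emissions(signals.lrr[lo:hi, sl], signals.baf[lo:hi, sl],
                               mm.pfb[sl], params)
            paths[lo:hi, sl] = _viterbi_batch(em, log_off, log_diag, log_prior)
    return paths


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, first_idx, last_idx) for maximal constant runs."""
    breaks = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks - 1, [len(path) - 1]])
    return [(int(path[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def viterbi_segment(signals: SignalMatrix, params: HmmParams | None = None,
                    batch_size: int = 1024) -> list[CnvCall]:
    """Decode all samples and emit maximal non-neutral runs as calls.

    The decoded path's posterior score is by construction at least that of
    the all-CN2 path.  CN2 and CN2-LOH runs produce no output calls.
    """
    if len(signals.samples) == 0:
        return []
    params = params or HmmParams()
    mm = signals.markers
    paths = decode_states(signals, params, batch_size=batch_size)
    calls: list[CnvCall] = []
    slices = mm.chrom_slices()
    for si, sample in enumerate(signals.samples):
        for chrom, sl in slices.items():
            for state, i0, i1 in _runs(paths[si, sl]):
                if state in (_CN2, _LOH):
                    continue
                g0, g1 = sl.start + i0, sl.start + i1
                calls.append(CnvCall(
                    sample=sample, chrom=chrom,
                    start=int(mm.pos[g0]), end=int(mm.pos[g1]),
                    copy_number=STATE_COPIES[state],
                    n_markers=g1 - g0 + 1,
                    mean_lrr=float(signals.lrr[si, g0:g1 + 1].mean()),
                ))
    return calls


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def merge_adjacent(calls: list[CnvCall], gap_fraction: float = 0.20) -> list[CnvCall]:
    """Merge same-copy-number neighbours separated by small gaps.

    Two adjacent calls of one sample/chromosome with equal copy number merge
    iff gap_length / merged_span <= gap_fraction; the rule is applied
    iteratively until no pair merges (idempotent fixpoint).
    """
    by_key: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample, c.chrom), []).append(c)
    out: list[CnvCall] = []
    for key, group in sorted(by_key.items()):
        group = sorted(group, key=lambda c: (c.start, c.end))
        for prev, nxt in zip(group, group[1:]):
            if nxt.start <= prev.end and nxt.copy_number != prev.copy_number:
                raise ValueError(
                    f"overlapping calls of different copy number for {key[0]} on {key[1]}")
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            for c in group:
                if merged and merged[-1].copy_number == c.copy_number:
                    prev = merged[-1]
                    gap = max(0, c.start - prev.end - 1)
                    span = c.end - prev.start + 1
                    if gap / span <= gap_fraction:
                        n = prev.n_markers + c.n_markers
                        mlrr = (prev.mean_lrr * prev.n_markers + c.mean_lrr * c.n_markers) / n
                        merged[-1] = replace(prev, end=max(prev.end, c.end),
                                             n_markers=n, mean_lrr=mlrr)
                        changed = True
                        continue
                merged.append(c)
            group = merged
        out.extend(group)
    return out


def refine_breakpoints(call: CnvCall, signals: SignalMatrix,
                       params: HmmParams | None = None,
                       margin: float = 0.0) -> CnvCall:
    """Greedily extend a call while flanking markers favour its state.

    Each boundary is pushed outward while the per-marker emission log-odds
    of the call state over CN2 exceed ``margin``; the call never shrinks.
    Mirrors the manual practice of extending a call whose flanking signal
    continues the CNV.
    """
    params = params or HmmParams()
    mm = signals.markers
    sl = mm.chrom_slices()[str(call.chrom)]
    si = signals.sample_index(call.sample)
    state = STATE_COPIES.index(call.copy_number)   # CN3 -> index 4, CN4 -> 5

    pos = mm.pos[sl]
    i0 = int(np.searchsorted(pos, call.start, side="left"))
    i1 = int(np.searchsorted(pos, call.end, side="right")) - 1

    def log_odds(idx: int) -> float:
        g = sl.start + idx
        em = log_emissions(signals.lrr[si:si + 1, g:g + 1],
                           signals.baf[si:si + 1, g:g + 1],
                           mm.pfb[g:g + 1], params)[0, 0]
        return float(em[state] - em[_CN2])

    while i0 > 0 and log_odds(i0 - 1) > margin:
        i0 -= 1
    n_chrom = sl.stop - sl.start
    while i1 < n_chrom - 1 and log_odds(i1 + 1) > margin:
        i1 += 1

    g0, g1 = sl.start + i0, sl.start + i1
    return replace(call, start=int(pos[i0]), end=int(pos[i1]),
                   n_markers=g1 - g0 + 1,
                   mean_lrr=float(signals.lrr[si, g0:g1 + 1].mean()))
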