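"""Per-sample signal QC metrics and the all-three-members trio gate.

Four metrics gate each sample: the standard deviation of autosomal LRR
(LRR_SD), the fraction of markers whose BAF drifts off the canonical
0 / 0.5 / 1 bands (BAF_drift, operationalized as the fraction of BAF
values in (0.2, 0.25) or (0.75, 0.8)), the signed amplitude of a fitted
long-range sinusoidal LRR wave (WF), and the number of post-merge CNV
calls.  A trio passes only when mother, father and child each pass all
four thresholds; the default thresholds are LRR_SD < 0.3,
BAF_drift < 0.001, |WF| < 0.05 and n_calls < 100 (a denser-array batch
profile raises the call-count limit to 130).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SignalMatrix

__all__ = ["QcMetrics", "QcThresholds", "compute_qc_metrics", "qc_table",
           "apply_trio_gate"]

_DRIFT_WINDOWS = ((0.2, 0.25), (0.75, 0.8))


@dataclass(frozen=True)
class QcMetrics:
    sample: str
    lrr_sd: float
    baf_drift: float
    wf: float
    n_calls: int

    def __post_init__(self) -> None:
        if self.lrr_sd < 0 or not 0.0 <= self.baf_drift <= 1.0 or self.n_calls < 0:
            raise ValueError("malformed QC metrics")


@dataclass(frozen=True)
class QcThresholds:
    """Pass criteria; ``batch2()`` gives the denser-array profile."""

    max_lrr_sd: float = 0.3
    max_baf_drift: float = 0.001
    max_abs_wf: float = 0.05
    max_n_calls: int = 100

    @classmethod
    def batch2(cls) -> "QcThresholds":
        return cls(max_n_calls=130)

    def failures(self, m: QcMetrics) -> list[str]:
        out = []
        if not m.lrr_sd < self.max_lrr_sd:
            out.append("LRR_SD")
        if not m.baf_drift < self.max_baf_drift:
            out.append("BAF_drift")
        if not abs(m.wf) < self.max_abs_wf:
            out.append("WF")
        if not m.n_calls < self.max_n_calls:
            out.append("NumCNV")
        return out


def _wave_factor(lrr: np.ndarray, signals: SignalMatrix,
                 keep: np.ndarray | None = None) -> float:
    """Signed amplitude of a least-squares one-period sinusoid per
    chromosome window, averaged over chromosomes weighted by marker count.

    The sign is that of the dominant sine coefficient, so a flipped wave
    flips WF; the gate uses |WF|.  ``keep`` masks out markers carrying
    genuine copy-number signal, which would otherwise steer the fit.
    """
    mm = signals.markers
    amp_sum, n_sum = 0.0, 0
    for sl in mm.chrom_slices().values():
        pos = mm.pos[sl]
        y = lrr[sl]
        if keep is not None:
            sel = keep[sl]
            pos, y = pos[sel], y[sel]
        n = len(pos)
        if n < 4:
            continue
        span = max(int(pos[-1] - pos[0]), 1)
        theta = 2 * np.pi * (pos - pos[0]) / span
        design = np.column_stack([np.sin(theta), np.cos(theta), np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        amp = float(np.hypot(coef[0], coef[1])) * np.sign(coef[0] if coef[0] else 1.0)
        amp_sum += amp * n
        n_sum += n
    return amp_sum / n_sum if n_sum else 0.0


def _span_mask(signals: SignalMatrix,
               spans: list[tuple[str, int, int]] | None) -> np.ndarray:
    """Boolean mask of markers inside any of the given (chrom, start, end)."""
    mask = np.zeros(len(signals.markers), dtype=bool)
    for chrom, start, end in spans or []:
        mask[signals.markers.span_indices(str(chrom), int(start), int(end))] = True
    return mask


def compute_qc_metrics(signals: SignalMatrix, sample: str, n_calls: int,
                       call_spans: list[tuple[str, int, int]] | None = None) -> QcMetrics:
    """QC metrics for one sample; ``n_calls`` is the sample's post-merge,
    pre-frequency-filter call count.

    ``call_spans`` are the sample's own called CNV spans: LRR SD and BAF
    drift are noise metrics, so markers carrying genuine copy-number signal
    are excluded from them (a true CNV's shifted BAF bands would otherwise
    masquerade as drift).
    """
    if len(signals.markers) < 100:
        raise ValueError("QC metrics require at least 100 markers")
    si = signals.sample_index(sample)
    keep = ~_span_mask(signals, call_spans)
    lrr = signals.lrr[si, keep]
    baf = signals.baf[si, keep]
    drift = np.zeros(len(baf), dtype=bool)
    for lo, hi in _DRIFT_WINDOWS:
        drift |= (baf > lo) & (baf < hi)
    return QcMetrics(
        sample=sample,
        lrr_sd=float(np.std(lrr, ddof=1)),
        baf_drift=float(drift.mean()),
        wf=_wave_factor(signals.lrr[si], signals,
                        keep if call_spans else None),
        n_calls=int(n_calls),
    )


def qc_table(signals: SignalMatrix, call_counts: dict[str, int],
             thresholds: QcThresholds | None = None,
             call_spans: dict[str, list[tuple[str, int, int]]] | None = None) -> pd.DataFrame:
    """One QC row per sample with metrics, per-criterion flags and pass.

    Vectorized across samples; equivalent to calling
    :func:`compute_qc_metrics` per sample.  ``call_spans`` maps a sample to
    its own called CNV spans, which are excluded from the LRR SD and BAF
    drift noise metrics.
    """
    if len(signals.markers) < 100:
        raise ValueError("QC metrics require at least 100 markers")
    thresholds = thresholds or QcThresholds()
    mm = signals.markers
    lrr, baf = signals.lrr, signals.baf
    lrr_sd = np.std(lrr, axis=1, ddof=1)
    drift = np.zeros(baf.shape, dtype=bool)
    for lo, hi in _DRIFT_WINDOWS:
        drift |= (baf > lo) & (baf < hi)
    baf_drift = drift.mean(axis=1)
    # Re-derive the noise metrics on copy-neutral markers for call carriers.
    wf_override: dict[int, float] = {}
    for sample, spans in (call_spans or {}).items():
        if not spans or sample not in signals.samples:
            continue
        si = signals.sample_index(sample)
        keep = ~_span_mask(signals, spans)
        if keep.sum() < 2:
            continue
        lrr_sd[si] = np.std(lrr[si, keep], ddof=1)
        drift_i = np.zeros(int(keep.sum()), dtype=bool)
        for lo, hi in _DRIFT_WINDOWS:
            drift_i |= (baf[si, keep] > lo) & (baf[si, keep] < hi)
        baf_drift[si] = drift_i.mean()
        wf_override[si] = _wave_factor(lrr[si], signals, keep)

    amp_sum = np.zeros(len(signals.samples))
    n_sum = 0
    for sl in mm.chrom_slices().values():
        pos = mm.pos[sl]
        n = len(pos)
        if n < 4:
            continue
        span = max(int(pos[-1] - pos[0]), 1)
        theta = 2 * np.pi * (pos - pos[0]) / span
        design = np.column_stack([np.sin(theta), np.cos(theta), np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, lrr[:, sl].T, rcond=None)   # (3, S)
        amp = np.hypot(coef[0], coef[1]) * np.where(coef[0] >= 0, 1.0, -1.0)
        amp_sum += amp * n
        n_sum += n
    wf = amp_sum / n_sum if n_sum else amp_sum

    rows = []
    for i, sample in enumerate(signals.samples):
        m = QcMetrics(sample, float(lrr_sd[i]), float(baf_drift[i]),
                      float(wf_override.get(i, wf[i])),
                      int(call_counts.get(sample, 0)))
        fails = thresholds.failures(m)
        rows.append({
            "sample": sample, "lrr_sd": m.lrr_sd, "baf_drift": m.baf_drift,
            "wf": m.wf, "n_calls": m.n_calls,
            "fail_reasons": ";".join(fails), "pass": not fails,
        })
    return pd.DataFrame(rows)


def apply_trio_gate(mother: QcMetrics, father: QcMetrics, child: QcMetrics,
                    thresholds: QcThresholds | None = None) -> tuple[bool, list[tuple[str, str]]]:
    """Trio passes iff all three members pass all four criteria.

    Returns (passed, reasons) where reasons lists (member, criterion) for
    each violation.  Tightening any threshold can only turn passes into
    failures (the gate is monotone).
    """
    thresholds = thresholds or QcThresholds()
    reasons: list[tuple[str, str]] = []
    for member, metrics in (("mother", mother), ("father", father), ("child", child)):
        if metrics is None:
            raise ValueError(f"missing QC metrics for {member}")
        reasons.extend((member, crit) for crit in thresholds.failures(metrics))
    return not reasons, reasons
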