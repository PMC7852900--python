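"""Trio classification: inherited vs de novo, and mosaic-gain detection.

An offspring CNV is inherited from a parent when that parent carries a
same-class call with at least 50% reciprocal overlap; if neither parent
does, the event is de novo.  The (never-observed-in-practice) case where
both parents carry a matching call is reported with a distinct flag and
excluded from per-parent tallies rather than guessed.

A mosaic copy-number gain in a fraction f of cells moves the heterozygous
BAF bands from {1/3, 2/3} to {1/(2+f), (1+f)/(2+f)}; inverting the lower
band centre b gives f = 1/b - 2.  ``detect_mosaic`` estimates b robustly
from the BAF values inside the call and flags the event as mosaic when the
estimated fraction falls below a threshold.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SignalMatrix
from .filters import reciprocal_overlap, _check_calls

__all__ = ["classify_inheritance", "detect_mosaic", "classify_cohort"]


def _parent_match(child_row: pd.Series, parent_calls: pd.DataFrame,
                  min_recip: float = 0.5) -> bool:
    if parent_calls.empty:
        return False
    same = parent_calls[
        (parent_calls["chrom"].astype(str) == str(child_row["chrom"]))
        & (parent_calls["svclass"] == child_row["svclass"])
    ]
    for _, p in same.iterrows():
        if reciprocal_overlap(child_row["start"], child_row["end"],
                              p["start"], p["end"]) >= min_recip:
            return True
    return False


def classify_inheritance(child_call: pd.Series, mother_calls: pd.DataFrame,
                         father_calls: pd.DataFrame,
                         min_recip: float = 0.5) -> str:
    """'inherited_maternal' | 'inherited_paternal' | 'de_novo' | 'ambiguous_both'."""
    mat = _parent_match(child_call, _check_calls(mother_calls) if len(mother_calls) else mother_calls, min_recip) if len(mother_calls) else False
    pat = _parent_match(child_call, _check_calls(father_calls) if len(father_calls) else father_calls, min_recip) if len(father_calls) else False
    if mat and pat:
        return "ambiguous_both"
    if mat:
        return "inherited_maternal"
    if pat:
        return "inherited_paternal"
    return "de_novo"


def detect_mosaic(child_call: pd.Series, signals: SignalMatrix,
                  min_het_markers: int = 10, mosaic_threshold: float = 0.9,
                  het_window: tuple[float, float] = (0.2, 0.8),
                  lower_band_window: tuple[float, float] = (0.30, 0.5)) -> float | None:
    """Estimate the cell fraction of a duplication from its BAF bands.

    Returns f-hat in (0, 1] (1 = constitutional) or None when the call is
    not a duplication or has too few heterozygous-band markers.  The lower
    heterozygous band centre b is estimated as the median BAF inside
    ``lower_band_window``; since 1/(2+f) lies in [1/3, 1/2) for any f, the
    window starts at 0.30, which keeps the target band while excluding the
    secondary f/(2+f) band that a mosaic gain adds below 1/3.
    f-hat = 1/b - 2 clipped to [0, 1]; a constitutional trisomic band at
    1/3 gives f-hat = 1, a diploid band at 1/2 gives 0 (no gain).
    """
    if child_call["copy_number"] < 3:
        return None
    si = signals.sample_index(child_call["sample"])
    span = signals.markers.span_indices(
        str(child_call["chrom"]), int(child_call["start"]), int(child_call["end"]))
    baf = signals.baf[si, span]
    het = baf[(baf > het_window[0]) & (baf < het_window[1])]
    if len(het) < min_het_markers:
        return None
    lower = het[(het > lower_band_window[0]) & (het <= lower_band_window[1])]
    if len(lower) < max(3, min_het_markers // 2):
        return None
    b_hat = float(np.median(lower))
    f_hat = 1.0 / b_hat - 2.0
    return float(np.clip(f_hat, 0.0, 1.0))


def classify_cohort(matched_calls: pd.DataFrame, pedigree: pd.DataFrame,
                    all_calls: pd.DataFrame,
                    signals: SignalMatrix | None = None,
                    min_recip: float = 0.5,
                    mosaic_threshold: float = 0.9) -> pd.DataFrame:
    """Classify every matched offspring call against its parents' call set.

    ``matched_calls`` is the region-matched offspring call table (one row
    per call x region); ``all_calls`` the post-filter call set for the
    whole cohort (used to look up parental calls).  Adds columns status,
    mosaic_fraction_estimate and mosaic.  Origin of inherited events equals
    the carrying parent; de novo origin is resolved separately by the
    parent-of-origin module.
    """
    all_calls = _check_calls(all_calls)
    ped = pedigree.set_index("child")
    rows = []
    for _, call in matched_calls.iterrows():
        child = call["sample"]
        if child not in ped.index:
            continue
        mother = ped.loc[child, "mother"]
        father = ped.loc[child, "father"]
        status = classify_inheritance(
            call,
            all_calls[all_calls["sample"] == mother],
            all_calls[all_calls["sample"] == father],
            min_recip,
        )
        rec = call.to_dict()
        rec["status"] = status
        rec["origin"] = {"inherited_maternal": "maternal",
                         "inherited_paternal": "paternal"}.get(status, "unresolved")
        f_hat = None
        if signals is not None and call["svclass"] == "dup":
            f_hat = detect_mosaic(call, signals, mosaic_threshold=mosaic_threshold)
        rec["mosaic_fraction_estimate"] = f_hat
        rec["mosaic"] = bool(f_hat is not None and 0.0 < f_hat < mosaic_threshold)
        rows.append(rec)
    cols = list(matched_calls.columns) + ["status", "origin",
                                          "mosaic_fraction_estimate", "mosaic"]
    return pd.DataFrame(rows, columns=cols)
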