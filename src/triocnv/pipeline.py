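"""End-to-end trio CNV pipeline over an in-memory cohort.

Stages, in study order: per-sample HMM segmentation, fragment merging,
sample QC metrics and the all-members trio gate, parental frequency
filter, blacklist and size filters, NDD-region matching for offspring and
parents, inheritance classification with mosaic screening, parent-of-origin
inference for de novo events, and the summary statistics tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import classify as _classify
from . import filters as _filters
from .core import SignalMatrix
from .hmm import HmmParams, calls_to_frame, merge_adjacent, viterbi_segment
from .origin import infer_origin
from .qc import QcThresholds, qc_table
from .regions import NddRegion, load_ndd_regions
from .stats import build_summary_tables

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    calls: pd.DataFrame                 # merged, pre-frequency-filter
    qc: pd.DataFrame
    passing_trios: pd.DataFrame
    filtered_calls: pd.DataFrame        # post frequency/blacklist/size
    matched_children: pd.DataFrame
    matched_parents: pd.DataFrame
    classified: pd.DataFrame
    tables: dict = field(default_factory=dict)

    @property
    def n_trios(self) -> int:
        return len(self.passing_trios)


def run_pipeline(
    signals: SignalMatrix,
    pedigree: pd.DataFrame,
    regions: list[NddRegion] | None = None,
    blacklist: list[NddRegion] | None = None,
    hmm_params: HmmParams | None = None,
    qc_thresholds: QcThresholds | None = None,
    max_parental_freq: float = 0.01,
    min_bp: int = 100_000,
    min_markers: int = 10,
    min_region_fraction: float = 0.5,
    min_recip: float = 0.5,
    gap_fraction: float = 0.20,
    infer_de_novo_origin: bool = True,
    batch_size: int = 1024,
) -> PipelineResult:
    """Run the full chain on a cohort signal matrix and pedigree."""
    regions = regions if regions is not None else load_ndd_regions()
    blacklist = blacklist or []

    raw = viterbi_segment(signals, hmm_params, batch_size=batch_size)
    merged = merge_adjacent(raw, gap_fraction)
    calls = calls_to_frame(merged)

    counts = calls["sample"].value_counts().to_dict() if not calls.empty else {}
    spans: dict[str, list[tuple[str, int, int]]] = {}
    for c in merged:
        spans.setdefault(c.sample, []).append((c.chrom, c.start, c.end))
    qc = qc_table(signals, counts, qc_thresholds, call_spans=spans)
    passing = set(qc.loc[qc["pass"], "sample"])
    trio_ok = pedigree[
        pedigree["child"].isin(passing)
        & pedigree["father"].isin(passing)
        & pedigree["mother"].isin(passing)
    ].reset_index(drop=True)

    kept_samples = set(trio_ok["child"]) | set(trio_ok["father"]) | set(trio_ok["mother"])
    calls_kept = calls[calls["sample"].isin(kept_samples)].reset_index(drop=True)
    parent_ids = list(trio_ok["father"]) + list(trio_ok["mother"])

    if calls_kept.empty:
        filtered = calls_kept
    else:
        filtered = _filters.parental_frequency_filter(
            calls_kept, parent_ids, max_parental_freq, min_recip)
        filtered = _filters.exclude_blacklist(filtered, blacklist)
        filtered = _filters.size_marker_filter(filtered, min_bp, min_markers)

    children = set(trio_ok["child"])
    matched = _filters.match_ndd_regions(filtered, regions, min_region_fraction)
    matched_children = matched[matched["sample"].isin(children)].reset_index(drop=True)
    matched_parents = matched[matched["sample"].isin(set(parent_ids))].reset_index(drop=True)

    classified = _classify.classify_cohort(
        matched_children, trio_ok, filtered, signals, min_recip)

    if infer_de_novo_origin and not classified.empty:
        ped = trio_ok.set_index("child")
        origins = []
        for _, row in classified.iterrows():
            if row["status"] != "de_novo" or row["copy_number"] not in (1, 3):
                origins.append(row["origin"])
                continue
            res = infer_origin(row, signals,
                               mother=str(ped.loc[row["sample"], "mother"]),
                               father=str(ped.loc[row["sample"], "father"]))
            origins.append(res.origin)
        classified = classified.assign(origin=origins)

    tables: dict = {}
    if len(trio_ok):
        stat_rows = classified[classified["status"] != "ambiguous_both"]
        mother_ids = set(trio_ok["mother"])
        mother_carriers = int(matched_parents["sample"].isin(mother_ids).sum())
        father_carriers = int((~matched_parents["sample"].isin(mother_ids)).sum())
        mat_trans = int((stat_rows["status"] == "inherited_maternal").sum())
        pat_trans = int((stat_rows["status"] == "inherited_paternal").sum())
        tables = build_summary_tables(
            stat_rows, regions, len(trio_ok),
            mother_carriers=max(mother_carriers, 1),
            maternal_transmitted=min(mat_trans, mother_carriers) if mother_carriers else 0,
            father_carriers=max(father_carriers, 1),
            paternal_transmitted=min(pat_trans, father_carriers) if father_carriers else 0,
        )

    return PipelineResult(
        calls=calls, qc=qc, passing_trios=trio_ok, filtered_calls=filtered,
        matched_children=matched_children, matched_parents=matched_parents,
        classified=classified, tables=tables,
    )
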