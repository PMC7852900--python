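"""Cohort-level call filters defining the final recurrent NDD CNV set.

Order of application in the pipeline: parental frequency filter (> 1%
carrier frequency among unrelated parents, cohort-wide removal), blacklist
exclusion (any overlap with centromeric/telomeric or otherwise
copy-number-susceptible intervals), size filter (>= 100 kb and >= 10
markers) and finally matching against the reference NDD regions (a call
counts for a region when it covers at least 50% of the region's length).

Calls are passed as DataFrames with columns sample, chrom, start, end,
copy_number, n_markers (1-based inclusive coordinates) and an 'svclass'
column ('del'/'dup').
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .regions import NddRegion

__all__ = [
    "reciprocal_overlap",
    "cluster_calls",
    "parental_frequency_filter",
    "exclude_blacklist",
    "size_marker_filter",
    "match_ndd_regions",
]

CALL_COLUMNS = ["sample", "chrom", "start", "end", "copy_number", "n_markers"]


def _check_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table lacks columns {missing}")
    if "svclass" not in calls.columns:
        calls = calls.copy()
        calls["svclass"] = np.where(calls["copy_number"] < 2, "del", "dup")
    return calls


def reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """Reciprocal overlap of two 1-based inclusive spans: the overlap length
    divided by the longer span (so >= f means each span is covered >= f)."""
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return inter / max(e1 - s1 + 1, e2 - s2 + 1)


def cluster_calls(calls: pd.DataFrame, min_recip: float = 0.5) -> np.ndarray:
    """Union-find clustering of same-class calls by >= 50% reciprocal overlap.

    Returns an integer cluster label per row.  Calls of opposite sign
    (deletion vs duplication) never share a cluster.
    """
    calls = _check_calls(calls)
    n = len(calls)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    df = calls.reset_index(drop=True)
    for (_, _), grp in df.groupby(["chrom", "svclass"], sort=False):
        idx = grp.index.to_numpy()
        order = idx[np.argsort(grp["start"].to_numpy())]
        starts = df.loc[order, "start"].to_numpy()
        ends = df.loc[order, "end"].to_numpy()
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                if starts[b] > ends[a]:
                    break
                if reciprocal_overlap(starts[a], ends[a], starts[b], ends[b]) >= min_recip:
                    union(int(order[a]), int(order[b]))
    return np.array([find(i) for i in range(n)])


def parental_frequency_filter(
    calls: pd.DataFrame,
    parent_ids: Iterable[str],
    max_freq: float = 0.01,
    min_recip: float = 0.5,
) -> pd.DataFrame:
    """Drop call clusters whose carrier frequency among parents exceeds 1%.

    Calls are clustered cohort-wide by >= 50% reciprocal overlap and sign;
    a cluster's frequency is its number of distinct parental carriers over
    the number of parents (offspring never contribute to the frequency).
    Clusters above ``max_freq`` are removed for every sample, parents and
    offspring alike.
    """
    parents = set(parent_ids)
    if not parents:
        raise ValueError("parent set must be nonempty")
    calls = _check_calls(calls)
    if calls.empty:
        return calls
    labels = cluster_calls(calls, min_recip)
    df = calls.reset_index(drop=True)
    keep = np.ones(len(df), dtype=bool)
    for lab in np.unique(labels):
        rows = np.flatnonzero(labels == lab)
        carriers = set(df.loc[rows, "sample"]) & parents
        if len(carriers) / len(parents) > max_freq:
            keep[rows] = False
    return df.loc[keep].reset_index(drop=True)


def exclude_blacklist(calls: pd.DataFrame, blacklist: list[NddRegion]) -> pd.DataFrame:
    """Remove any call overlapping a blacklist interval by >= 1 bp."""
    calls = _check_calls(calls)
    if calls.empty or not blacklist:
        return calls.reset_index(drop=True)
    keep = np.ones(len(calls), dtype=bool)
    df = calls.reset_index(drop=True)
    for iv in blacklist:
        hit = (
            (df["chrom"].astype(str) == str(iv.chrom))
            & (df["start"] <= iv.end)
            & (df["end"] >= iv.start)
        )
        keep &= ~hit.to_numpy()
    return df.loc[keep].reset_index(drop=True)


def size_marker_filter(calls: pd.DataFrame, min_bp: int = 100_000,
                       min_markers: int = 10) -> pd.DataFrame:
    """Retain calls spanning at least 100 kb AND at least 10 markers."""
    calls = _check_calls(calls)
    if calls.empty:
        return calls.reset_index(drop=True)
    span = calls["end"] - calls["start"] + 1
    keep = (span >= min_bp) & (calls["n_markers"] >= min_markers)
    return calls.loc[keep].reset_index(drop=True)


def match_ndd_regions(calls: pd.DataFrame, regions: list[NddRegion],
                      min_region_fraction: float = 0.5) -> pd.DataFrame:
    """Match calls to reference NDD regions.

    A call matches a region iff the overlap covers at least half of the
    region's length; one call may match every region it covers.  Returns
    one row per (call, region) match with the call columns plus 'region'
    and 'region_fraction'.
    """
    calls = _check_calls(calls)
    rows = []
    for _, call in calls.iterrows():
        for region in regions:
            if str(call["chrom"]) != str(region.chrom):
                continue
            inter = min(call["end"], region.end) - max(call["start"], region.start) + 1
            frac = inter / region.length_bp if inter > 0 else 0.0
            if frac >= min_region_fraction:
                rec = call.to_dict()
                rec["region"] = region.name
                rec["region_fraction"] = float(frac)
                rows.append(rec)
    cols = list(calls.columns) + ["region", "region_fraction"]
    return pd.DataFrame(rows, columns=cols)
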