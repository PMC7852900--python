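"""Parental homolog of origin for de novo CNVs, from trio genotypes.

Within a deletion (child copy number 1) each marker retains a single
allele.  If one parent could not have transmitted that allele, the
retained homolog must come from the other parent — so the deleted homolog
originated in the first parent, and the marker votes for that parent.

Within a duplication (child copy number 3) the child carries three
alleles.  A maternal duplication means two of them form a 2-allele
multiset drawn from the mother's homologs plus one paternal allele (the
paternal hypothesis is symmetric).  A marker votes for whichever single
hypothesis can reproduce the observed child allele counts; markers
compatible with both are uninformative, with neither inconsistent
(a genotyping-error proxy).  By default the duplicated pair may combine
both parental homologs (interchromosomal NAHR); ``strict_same_homolog``
restricts it to two copies of one homolog.

Child allele counts and parental genotypes are read off the BAF bands:
child CN3 markers are assigned the nearest of {0, 1/3, 2/3, 1} and CN1
markers the nearest of {0, 1}, parents the nearest of {0, 1/2, 1}, each
within a configurable tolerance; markers outside tolerance are discarded.
Votes are aggregated by majority over informative markers (at least 3
informative and 80% concordance required, else unresolved).
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .core import SignalMatrix

__all__ = [
    "MarkerEvidence",
    "deletion_verdict",
    "duplication_verdict",
    "extract_trio_evidence",
    "infer_deletion_origin",
    "infer_duplication_origin",
    "infer_origin",
    "OriginCall",
]

VERDICTS = ("maternal", "paternal", "uninformative", "inconsistent")


@dataclass(frozen=True)
class MarkerEvidence:
    """Per-marker trio evidence inside a CNV span.

    child counts are copies of allele A and B (summing to the call's copy
    number); parental genotypes are allele pairs, e.g. (0, 1) = AB.
    """

    marker: str
    child_a: int
    child_b: int
    mother: tuple[int, int]
    father: tuple[int, int]

    @property
    def verdict(self) -> str:
        total = self.child_a + self.child_b
        if total == 1:
            return deletion_verdict(self.child_a, self.child_b, self.mother, self.father)
        if total == 3:
            return duplication_verdict(self.child_a, self.child_b, self.mother, self.father)
        raise ValueError("evidence requires child copy number 1 or 3")


def deletion_verdict(child_a: int, child_b: int,
                     mother: tuple[int, int], father: tuple[int, int]) -> str:
    """Vote of one hemizygous marker: which parent lost a homolog."""
    if child_a + child_b != 1:
        raise ValueError("deletion evidence requires exactly one retained allele")
    retained = 0 if child_a == 1 else 1
    can_mother = retained in mother
    can_father = retained in father
    if can_mother and can_father:
        return "uninformative"
    if can_father:       # mother could not have supplied the retained allele
        return "maternal"
    if can_mother:
        return "paternal"
    return "inconsistent"


def _dup_compatible(child_counts: Counter, dup_parent: tuple[int, int],
                    other_parent: tuple[int, int], strict_same_homolog: bool) -> bool:
    if strict_same_homolog:
        pairs = {(h, h) for h in dup_parent}
    else:
        pairs = set(combinations_with_replacement(sorted(set(dup_parent)), 2))
    for pair in pairs:
        for single in set(other_parent):
            if Counter(pair) + Counter((single,)) == child_counts:
                return True
    return False


def duplication_verdict(child_a: int, child_b: int,
                        mother: tuple[int, int], father: tuple[int, int],
                        strict_same_homolog: bool = False) -> str:
    """Vote of one trisomic marker: which parent contributed two alleles."""
    if child_a + child_b != 3:
        raise ValueError("duplication evidence requires three child alleles")
    counts = Counter({0: child_a, 1: child_b})
    counts = +counts   # drop zero entries
    h_mat = _dup_compatible(counts, mother, father, strict_same_homolog)
    h_pat = _dup_compatible(counts, father, mother, strict_same_homolog)
    if h_mat and h_pat:
        return "uninformative"
    if h_mat:
        return "maternal"
    if h_pat:
        return "paternal"
    return "inconsistent"


def _nearest_band(values: np.ndarray, bands: np.ndarray, tol: float) -> np.ndarray:
    """Index of the nearest band per value; -1 where outside tolerance."""
    diffs = np.abs(values[:, None] - bands[None, :])
    idx = np.argmin(diffs, axis=1)
    idx[np.min(diffs, axis=1) > tol] = -1
    return idx


def extract_trio_evidence(child_call: pd.Series, signals: SignalMatrix,
                          mother: str, father: str,
                          band_tol: float = 0.08) -> list[MarkerEvidence]:
    """Build per-marker evidence for a CN1 or CN3 child call from BAF bands."""
    cn = int(child_call["copy_number"])
    if cn not in (1, 3):
        raise ValueError("evidence extraction supports child copy number 1 or 3")
    mm = signals.markers
    span = mm.span_indices(str(child_call["chrom"]),
                           int(child_call["start"]), int(child_call["end"]))
    ci = signals.sample_index(child_call["sample"])
    mi = signals.sample_index(mother)
    fi = signals.sample_index(father)

    child_bands = np.array([0.0, 1.0]) if cn == 1 else np.array([0.0, 1 / 3, 2 / 3, 1.0])
    child_idx = _nearest_band(signals.baf[ci, span], child_bands, band_tol)
    parent_bands = np.array([0.0, 0.5, 1.0])
    mot_idx = _nearest_band(signals.baf[mi, span], parent_bands, band_tol)
    fat_idx = _nearest_band(signals.baf[fi, span], parent_bands, band_tol)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}

    evidence = []
    for j, g in enumerate(span):
        if child_idx[j] < 0 or mot_idx[j] < 0 or fat_idx[j] < 0:
            continue
        n_b = int(child_idx[j])   # band index equals the B-allele copy count
        evidence.append(MarkerEvidence(
            marker=str(mm.names[g]),
            child_a=cn - n_b, child_b=n_b,
            mother=gt_of[int(mot_idx[j])], father=gt_of[int(fat_idx[j])],
        ))
    return evidence


@dataclass(frozen=True)
class OriginCall:
    origin: str                  # "maternal" | "paternal" | "unresolved"
    counts: dict

    @property
    def n_informative(self) -> int:
        return self.counts.get("maternal", 0) + self.counts.get("paternal", 0)


def _aggregate(verdicts: list[str], min_informative: int = 3,
               min_concordance: float = 0.8) -> OriginCall:
    counts = dict(Counter(verdicts))
    n_total = len(verdicts)
    n_inc = counts.get("inconsistent", 0)
    if n_total and n_inc / n_total > 0.10:
        warnings.warn(
            f"{n_inc}/{n_total} markers give Mendelian-inconsistent verdicts; "
            "possible genotyping error or wrong trio", stacklevel=3)
    n_mat = counts.get("maternal", 0)
    n_pat = counts.get("paternal", 0)
    informative = n_mat + n_pat
    if informative < min_informative:
        return OriginCall("unresolved", counts)
    top, n_top = ("maternal", n_mat) if n_mat >= n_pat else ("paternal", n_pat)
    if n_top / informative >= min_concordance:
        return OriginCall(top, counts)
    return OriginCall("unresolved", counts)


def infer_deletion_origin(evidence: list[MarkerEvidence],
                          min_informative: int = 3,
                          min_concordance: float = 0.8) -> OriginCall:
    """Aggregate per-marker deletion votes into a parental origin."""
    for ev in evidence:
        if ev.child_a + ev.child_b != 1:
            raise ValueError("deletion origin requires child copy number 1 evidence")
    return _aggregate([ev.verdict for ev in evidence], min_informative, min_concordance)


def infer_duplication_origin(evidence: list[MarkerEvidence],
                             min_informative: int = 3,
                             min_concordance: float = 0.8,
                             strict_same_homolog: bool = False) -> OriginCall:
    """Aggregate per-marker duplication votes into a parental origin."""
    verdicts = []
    for ev in evidence:
        if ev.child_a + ev.child_b != 3:
            raise ValueError("duplication origin requires child copy number 3 evidence")
        verdicts.append(duplication_verdict(ev.child_a, ev.child_b, ev.mother,
                                            ev.father, strict_same_homolog))
    return _aggregate(verdicts, min_informative, min_concordance)


def infer_origin(child_call: pd.Series, signals: SignalMatrix,
                 mother: str, father: str, band_tol: float = 0.08,
                 min_informative: int = 3, min_concordance: float = 0.8) -> OriginCall:
    """Parent-of-origin for one call; CN4 events are reported unresolved."""
    cn = int(child_call["copy_number"])
    if cn not in (1, 3):
        warnings.warn(f"parent-of-origin not implemented for copy number {cn}",
                      stacklevel=2)
        return OriginCall("unresolved", {})
    evidence = extract_trio_evidence(child_call, signals, mother, father, band_tol)
    if cn == 1:
        return infer_deletion_origin(evidence, min_informative, min_concordance)
    return infer_duplication_origin(evidence, min_informative, min_concordance)
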