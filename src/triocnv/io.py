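"""Readers and writers for the on-disk formats.

Signal files use the tab-delimited genotyping-array export dialect: one
row per marker with columns ``Name``, ``Chr``, ``Position`` and, per
sample, ``<sample>.Log R Ratio`` and ``<sample>.B Allele Freq``; an
optional ``PFB`` column carries the population B-allele frequency.
Pedigrees are whitespace-delimited ``family child father mother`` rows.
Calls are written as TSV (1-based inclusive) and optionally as BED
(0-based half-open).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MarkerMap, SignalMatrix
from .hmm import CnvCall

__all__ = [
    "read_signal_file", "write_signal_file",
    "read_pedigree", "write_pedigree",
    "read_calls", "write_calls", "write_calls_bed",
    "write_cohort", "read_cohort_signals",
]

_LRR_SUFFIX = ".Log R Ratio"
_BAF_SUFFIX = ".B Allele Freq"


def write_signal_file(signals: SignalMatrix, path: str | Path,
                      float_fmt: str = "%.4f") -> None:
    mm = signals.markers
    df = pd.DataFrame({"Name": mm.names, "Chr": mm.chrom, "Position": mm.pos,
                       "PFB": mm.pfb})
    for i, sample in enumerate(signals.samples):
        df[f"{sample}{_LRR_SUFFIX}"] = signals.lrr[i]
        df[f"{sample}{_BAF_SUFFIX}"] = signals.baf[i]
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_signal_file(path: str | Path, default_pfb: float = 0.5) -> SignalMatrix:
    """Read a signal TSV; markers are sorted by (Chr, Position) if needed."""
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    for col in ("Name", "Chr", "Position"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["Name"].duplicated().any():
        dup = df.loc[df["Name"].duplicated(), "Name"].iloc[0]
        raise ValueError(f"{path}: duplicate marker name {dup!r}")
    lrr_samples = [c[: -len(_LRR_SUFFIX)] for c in df.columns if c.endswith(_LRR_SUFFIX)]
    baf_samples = [c[: -len(_BAF_SUFFIX)] for c in df.columns if c.endswith(_BAF_SUFFIX)]
    if set(lrr_samples) != set(baf_samples):
        odd = set(lrr_samples) ^ set(baf_samples)
        raise ValueError(f"{path}: samples missing an LRR or BAF column: {sorted(odd)}")
    if not lrr_samples:
        raise ValueError(f"{path}: no sample signal columns found")

    out_of_order = (
        df.groupby("Chr", sort=False)["Position"].apply(lambda s: (s.diff().dropna() <= 0).any()).any()
    )
    if out_of_order:
        import warnings
        warnings.warn(f"{path}: markers not sorted by position; sorting", stacklevel=2)
        df = df.sort_values(["Chr", "Position"], kind="stable").reset_index(drop=True)

    pfb = df["PFB"].to_numpy(float) if "PFB" in df.columns else np.full(len(df), default_pfb)
    mm = MarkerMap(names=df["Name"].to_numpy(), chrom=df["Chr"].to_numpy(),
                   pos=df["Position"].to_numpy(np.int64), pfb=pfb)
    lrr = np.vstack([df[f"{s}{_LRR_SUFFIX}"].to_numpy(float) for s in lrr_samples])
    baf = np.vstack([df[f"{s}{_BAF_SUFFIX}"].to_numpy(float) for s in lrr_samples])
    return SignalMatrix(mm, lrr_samples, lrr, baf)


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree[["family", "child", "father", "mother"]].to_csv(
        path, sep=" ", index=False, header=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["family", "child", "father", "mother"], dtype=str)
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed pedigree row")
    return df


def write_calls(calls: pd.DataFrame | list[CnvCall], path: str | Path) -> None:
    if isinstance(calls, list):
        from .hmm import calls_to_frame
        calls = calls_to_frame(calls)
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if df.empty:
        return df
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_calls_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """BED export: 0-based half-open, name = sample|cn, score = n_markers."""
    with open(path, "w") as fh:
        for _, c in calls.iterrows():
            fh.write(f"{c['chrom']}\t{c['start'] - 1}\t{c['end']}\t"
                     f"{c['sample']}|CN{c['copy_number']}\t{c['n_markers']}\n")


def write_cohort(cohort, outdir: str | Path, per_trio_files: bool = True) -> None:
    """Serialize a simulated cohort: signals, pedigree and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(cohort.pedigree, outdir / "pedigree.ped")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.parent_truth.to_csv(outdir / "parent_truth.tsv", sep="\t", index=False)
    sigdir = outdir / "signals"
    sigdir.mkdir(exist_ok=True)
    if per_trio_files:
        for _, row in cohort.pedigree.iterrows():
            trio = [row["child"], row["father"], row["mother"]]
            write_signal_file(cohort.signals.subset(trio),
                              sigdir / f"{row['family']}.tsv")
    else:
        write_signal_file(cohort.signals, sigdir / "cohort.tsv")


def read_cohort_signals(outdir: str | Path) -> SignalMatrix:
    """Re-assemble a cohort signal matrix written by :func:`write_cohort`."""
    outdir = Path(outdir)
    files = sorted((outdir / "signals").glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no signal files under {outdir}/signals")
    parts = [read_signal_file(f) for f in files]
    mm = parts[0].markers
    samples: list[str] = []
    lrr, baf = [], []
    for p in parts:
        if not np.array_equal(p.markers.pos, mm.pos):
            raise ValueError("signal files disagree on the marker map")
        samples.extend(p.samples)
        lrr.append(p.lrr)
        baf.append(p.baf)
    return SignalMatrix(mm, samples, np.vstack(lrr), np.vstack(baf))
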