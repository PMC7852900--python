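"""Cohort statistics: prevalence, Wilson intervals, Z-tests and the TDT.

Prevalence is the number of events over the number of QC-passing trios,
``NCNVs / Ntrios``.  Confidence intervals use the Wilson score interval,
which behaves well at the small (including zero) counts typical of
individually rare recurrent CNVs.  Deletion and duplication counts are
compared with a pooled two-proportion Z-test, and transmission bias is
tested with the classic 1-df transmission disequilibrium test (TDT),
chi-square (T - NT)^2 / (T + NT) on transmitted vs untransmitted parental
variants.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats as sps

__all__ = [
    "wilson_ci",
    "two_prop_z",
    "tdt",
    "TdtResult",
    "PrevalenceEstimate",
    "prevalence",
    "load_published_counts",
    "table1_from_counts",
    "table2_from_counts",
    "transmission_from_counts",
    "build_summary_tables",
]


def wilson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion x/n.

    Returns (low, high) on the proportion scale.  With z the standard-normal
    quantile at (1+conf)/2, the interval is centred at
    (x + z^2/2)/(n + z^2) with half-width z*sqrt(x(n-x)/n + z^2/4)/(n + z^2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    z = sps.norm.ppf((1.0 + conf) / 2.0)
    denom = n + z * z
    centre = (x + z * z / 2.0) / denom
    half = z * math.sqrt(x * (n - x) / n + z * z / 4.0) / denom
    # Degenerate counts hit the boundary exactly (rounding can undershoot).
    lo = 0.0 if x == 0 else max(0.0, centre - half)
    hi = 1.0 if x == n else min(1.0, centre + half)
    return lo, hi


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test; returns (Z, two-sided p)."""
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie within their sample sizes")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1)")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return z, 2.0 * sps.norm.sf(abs(z))


@dataclass(frozen=True)
class TdtResult:
    transmitted: int
    parental_total: int
    chi2: float
    p: float

    @property
    def untransmitted(self) -> int:
        return self.parental_total - self.transmitted

    @property
    def rate(self) -> float:
        return self.transmitted / self.parental_total


def tdt(transmitted: int, parental_total: int, exact: bool = False) -> TdtResult:
    """Transmission disequilibrium test on T transmitted of n parental CNVs.

    Default is the 1-df chi-square (T - NT)^2 / n; ``exact=True`` uses the
    two-sided exact binomial test at rate 1/2 instead.
    """
    if parental_total < 1:
        raise ValueError("parental_total must be >= 1")
    if not 0 <= transmitted <= parental_total:
        raise ValueError("transmitted must lie in [0, parental_total]")
    nt = parental_total - transmitted
    chi2 = (transmitted - nt) ** 2 / parental_total
    if exact:
        p = sps.binomtest(transmitted, parental_total, 0.5).pvalue
    else:
        p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    # Guard against underflow at extreme chi-square: p stays in (0, 1].
    p = max(p, 5e-324)
    return TdtResult(transmitted, parental_total, chi2, p)


@dataclass(frozen=True)
class PrevalenceEstimate:
    n_cnvs: int
    n_trios: int
    point: float
    ci_low: float
    ci_high: float

    def per_10000(self, ndigits: int | None = 2) -> tuple[float, float, float]:
        vals = (self.point * 1e4, self.ci_low * 1e4, self.ci_high * 1e4)
        if ndigits is None:
            return vals
        return tuple(round(v, ndigits) for v in vals)  # type: ignore[return-value]


def prevalence(n_cnvs: int, n_trios: int, conf: float = 0.95) -> PrevalenceEstimate:
    lo, hi = wilson_ci(n_cnvs, n_trios, conf)
    return PrevalenceEstimate(n_cnvs, n_trios, n_cnvs / n_trios, lo, hi)


# ---------------------------------------------------------------------------
# Count-table summaries.  These operate on plain count dictionaries so that
# published cohort counts can be run through the exact same code path as
# counts measured from a simulated cohort.
# ---------------------------------------------------------------------------

def load_published_counts() -> dict:
    """Counts fixture from the published 12,252-trio population screen."""
    path = resources.files("triocnv").joinpath("data", "published_cohort_counts.json")
    return json.loads(Path(str(path)).read_text())


def _prev_cols(n: int, n_trios: int) -> dict:
    est = prevalence(n, n_trios)
    p, lo, hi = est.per_10000(None)
    return {"prev_per_10000": p, "ci_low": lo, "ci_high": hi}


def table1_from_counts(
    del_all: int, dup_all: int, del_inh: int, dup_inh: int,
    del_dn: int, dup_dn: int, n_trios: int,
) -> pd.DataFrame:
    """Cumulative del/dup/total prevalence rows with del-vs-dup Z-tests."""
    rows = []
    for label, d, u in (
        ("all", del_all, dup_all),
        ("inherited", del_inh, dup_inh),
        ("de_novo", del_dn, dup_dn),
    ):
        if d + u > 0:
            z, p = two_prop_z(d, n_trios, u, n_trios)
        else:
            z, p = math.nan, math.nan   # no events in the stratum: test undefined
        row = {"stratum": label, "del": d, "dup": u, "total": d + u}
        for cls, n in (("del", d), ("dup", u), ("total", d + u)):
            est = prevalence(n, n_trios)
            pt, lo, hi = est.per_10000(None)
            row[f"{cls}_prev"] = pt
            row[f"{cls}_ci_low"] = lo
            row[f"{cls}_ci_high"] = hi
        row["z"] = z
        row["p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def table2_from_counts(rows: Iterable[dict], n_trios: int) -> pd.DataFrame:
    """Per-region, per-class prevalence table from count records.

    Each record needs keys region, svclass, n, de_novo, inherited_maternal,
    inherited_paternal.  Wilson CIs (per 10,000) are added for the de novo,
    maternal, paternal and total counts of each row.
    """
    out = []
    for r in rows:
        rec = dict(r)
        for key, n in (
            ("de_novo", r["de_novo"]),
            ("maternal", r["inherited_maternal"]),
            ("paternal", r["inherited_paternal"]),
            ("all", r["n"]),
        ):
            est = prevalence(n, n_trios)
            pt, lo, hi = est.per_10000(None)
            rec[f"{key}_prev"] = pt
            rec[f"{key}_ci_low"] = lo
            rec[f"{key}_ci_high"] = hi
        out.append(rec)
    df = pd.DataFrame(out)
    if not df.empty:
        check = df["de_novo"] + df["inherited_maternal"] + df["inherited_paternal"]
        if (check > df["n"]).any():
            raise ValueError("row counts exceed total n")
    return df


def transmission_from_counts(
    mother_carriers: int, maternal_transmitted: int,
    father_carriers: int, paternal_transmitted: int,
) -> pd.DataFrame:
    """Maternal / paternal / combined transmission rates with 1-df TDT."""
    rows = []
    for label, t, n in (
        ("maternal", maternal_transmitted, mother_carriers),
        ("paternal", paternal_transmitted, father_carriers),
        ("combined", maternal_transmitted + paternal_transmitted,
         mother_carriers + father_carriers),
    ):
        res = tdt(t, n)
        rows.append({
            "parent": label, "carriers": n, "transmitted": t,
            "untransmitted": res.untransmitted,
            "rate_percent": 100.0 * res.rate, "chi2": res.chi2, "p": res.p,
        })
    return pd.DataFrame(rows).set_index("parent")


def build_summary_tables(
    classified: pd.DataFrame,
    regions: Iterable,
    n_trios: int,
    mother_carriers: int | None = None,
    maternal_transmitted: int | None = None,
    father_carriers: int | None = None,
    paternal_transmitted: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Summarise a classified offspring call set into report tables.

    ``classified`` is the trio-classification output: one row per matched
    offspring CNV with columns region, svclass ('del'/'dup'), status
    ('inherited_maternal' / 'inherited_paternal' / 'de_novo'), origin
    ('maternal' / 'paternal' / 'unresolved') and mosaic (bool).  Parental
    carrier/transmission counts, when provided, feed the TDT table.

    Returns {"table1": ..., "table2": ..., "transmission": ...} where the
    transmission table is present only if parental counts were given.
    Reconciliation identities (inherited + de novo = all per class) hold by
    construction and are asserted.
    """
    req = {"region", "svclass", "status"}
    if not req.issubset(classified.columns):
        raise ValueError(f"classified table needs columns {sorted(req)}")
    cls = classified

    def _count(svclass: str, status: str | None = None) -> int:
        m = cls["svclass"] == svclass
        if status is not None:
            m &= cls["status"] == status
        return int(m.sum())

    del_all, dup_all = _count("del"), _count("dup")
    del_dn, dup_dn = _count("del", "de_novo"), _count("dup", "de_novo")
    del_inh, dup_inh = del_all - del_dn, dup_all - dup_dn
    t1 = table1_from_counts(del_all, dup_all, del_inh, dup_inh, del_dn, dup_dn, n_trios)

    rows = []
    for region in regions:
        rname = region.name if hasattr(region, "name") else str(region)
        for svclass in ("del", "dup"):
            sub = cls[(cls["region"] == rname) & (cls["svclass"] == svclass)]
            rows.append({
                "region": rname, "svclass": svclass, "n": len(sub),
                "de_novo": int((sub["status"] == "de_novo").sum()),
                "inherited_maternal": int((sub["status"] == "inherited_maternal").sum()),
                "inherited_paternal": int((sub["status"] == "inherited_paternal").sum()),
            })
    t2 = table2_from_counts(rows, n_trios)
    if int(t2["n"].sum()) != len(cls):
        raise ValueError("region mismatch: classified calls outside the region list")

    out = {"table1": t1, "table2": t2}
    if mother_carriers is not None and father_carriers is not None:
        out["transmission"] = transmission_from_counts(
            mother_carriers, maternal_transmitted or 0,
            father_carriers, paternal_transmitted or 0,
        )
    return out
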