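#!/usr/bin/env python
"""Filter calls to the recurrent NDD CNV set and classify inheritance.

Applies the trio QC gate, the parental frequency filter (threshold scaled
with the demonstration cohort's inflated event rates), blacklist and size
filters, matches the surviving calls against the 13 reference regions and
classifies each offspring event as inherited (maternal/paternal) or
de novo, with mosaic screening.  Writes filtered_calls.tsv, matched.tsv
and classified.tsv under results/.
"""
import argparse
from pathlib import Path

import pandas as pd

from triocnv import filters as F
from triocnv.classify import classify_cohort
from triocnv.io import read_calls, read_cohort_signals, read_pedigree
from triocnv.regions import load_ndd_regions, load_synthetic_blacklist

# The demo cohort inflates event rates 20x, so the population-scale 1%
# parental frequency cutoff is scaled accordingly.
MAX_PARENTAL_FREQ = 0.20


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    calls = read_calls(args.results / "calls.tsv")
    qc = pd.read_csv(args.results / "qc.tsv", sep="\t")
    ped = read_pedigree(args.cohort / "pedigree.ped")

    passing = set(qc.loc[qc["pass"], "sample"])
    trio_ok = ped[ped["child"].isin(passing) & ped["father"].isin(passing)
                  & ped["mother"].isin(passing)]
    parents = list(trio_ok["father"]) + list(trio_ok["mother"])
    kept = calls[calls["sample"].isin(
        set(trio_ok["child"]) | set(parents))].reset_index(drop=True)

    filtered = F.parental_frequency_filter(kept, parents, MAX_PARENTAL_FREQ)
    filtered = F.exclude_blacklist(filtered, load_synthetic_blacklist())
    filtered = F.size_marker_filter(filtered)
    filtered.to_csv(args.results / "filtered_calls.tsv", sep="\t", index=False)

    regions = load_ndd_regions()
    matched = F.match_ndd_regions(filtered, regions)
    matched.to_csv(args.results / "matched.tsv", sep="\t", index=False)

    signals = read_cohort_signals(args.cohort)
    children = matched[matched["sample"].isin(set(trio_ok["child"]))]
    classified = classify_cohort(children, trio_ok, filtered, signals)
    classified.to_csv(args.results / "classified.tsv", sep="\t", index=False)

    n_dn = int((classified["status"] == "de_novo").sum())
    n_mos = int(classified["mosaic"].sum()) if len(classified) else 0
    print(f"{len(trio_ok)}/{len(ped)} trios pass QC; "
          f"{len(filtered)}/{len(calls)} calls survive filtering")
    print(f"{len(classified)} offspring NDD CNVs: {n_dn} de novo, "
          f"{len(classified) - n_dn} inherited, {n_mos} mosaic")


if __name__ == "__main__":
    main()
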