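#!/usr/bin/env python
"""Decompose every SV junction into NTS / microhomology / clean.

Reads the cohort and the RSS calls, decomposes each assembled junction
against its reference flanks, and summarizes NTS prevalence, mean length and
G:C content stratified by category and RSS status — the TdT footprint.
"""

import argparse
from pathlib import Path

import pandas as pd
import pyfaidx

from ragprint.junctions import call_junction, summarize_nts
from ragprint.sv_catalog import fetch_flanks, read_sv_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cohort_dir = args.outdir / "cohort"

    svs = read_sv_table(cohort_dir / "svs.tsv")
    ref = pyfaidx.Fasta(str(cohort_dir / "reference.fa"))
    rss = pd.read_csv(args.outdir / "rss_calls.tsv", sep="\t").set_index("sv_id")

    calls = []
    for sv in svs:
        flanks = fetch_flanks(sv, ref, retained_len=50)
        calls.append(call_junction(sv, flanks))
    pd.DataFrame(
        [dict(sv_id=c.sv_id, kind=c.kind.value, nts_seq=c.nts_seq,
              nts_len=c.nts_len, mh_len=c.mh_len, gc_count=c.gc_count)
         for c in calls]
    ).to_csv(args.outdir / "junctions.tsv", sep="\t", index=False)

    category = {sv.sv_id: sv.category.value for sv in svs}
    strata = {
        "cooperating RSS+": lambda c: category[c.sv_id] == "cooperating"
        and rss.loc[c.sv_id, "status"] == "RSS_plus",
        "cooperating RSS-": lambda c: category[c.sv_id] == "cooperating"
        and rss.loc[c.sv_id, "status"] == "RSS_minus",
        "translocation   ": lambda c: category[c.sv_id] == "bcr_abl1_associated",
    }
    print("stratum            n    %NTS   mean_len   %GC")
    for name, pred in strata.items():
        s = summarize_nts(calls, subset=pred)
        pct = 100 * s.n_with_nts / s.n_total
        mlen = f"{s.mean_len:.2f}" if s.mean_len is not None else "   -"
        gc = f"{100 * s.gc_fraction:.1f}" if s.gc_fraction is not None else "   -"
        print(f"{name}  {s.n_total:4d}  {pct:5.1f}   {mlen:>7}   {gc:>5}")
    print(f"per-SV calls -> {args.outdir / 'junctions.tsv'}")


if __name__ == "__main__":
    main()
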