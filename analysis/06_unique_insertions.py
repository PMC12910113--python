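#!/usr/bin/env python
"""Strain-unique insertion landscape.

Pools the per-strain call tables, removes calls shared within +/- 5 kb
across strains, and summarizes allele frequencies (TAF), length classes
and per-family unique counts.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from tedyn import insertions

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"

library = {r.id: str(r.seq) for r in SeqIO.parse(SIM / "library.fa", "fasta")}
calls = pd.concat(
    [pd.read_csv(p, sep="\t") for p in sorted(SIM.glob("calls_strain_*.tsv"))],
    ignore_index=True,
)
flagged = insertions.unique_insertions(calls)
summary = insertions.summarize_insertions(flagged, {f: len(s) for f, s in library.items()})

summary["unique_counts_by_family"].to_csv(OUT / "unique_by_family.tsv", sep="\t")
flagged[flagged["unique"]].to_csv(OUT / "unique_insertions.tsv", sep="\t", index=False)

uniq = flagged[flagged["unique"]]
print(f"{len(calls)} calls across {calls['strain'].nunique()} strains; "
      f"{len(uniq)} unique ({100 * len(uniq) / len(calls):.0f}%)")
print("unique per strain:")
print(summary["unique_counts_by_strain"].to_string())
print(f"full-length fraction: {100 * summary['full_length_fraction']:.0f}%  "
      f"heterozygous (TAF < 0.7): {100 * summary['heterozygous_fraction']:.0f}%")
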