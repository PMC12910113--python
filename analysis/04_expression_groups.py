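#!/usr/bin/env python
"""TE-family expression, four-group classification and correlations.

RPKM-normalizes the TE count table, classifies each family per strain by
the expression (log2 RPKM > 0) and antisense-piRNA (log10 RPM >= 2)
thresholds, and correlates copy number, full-length copy number,
expression and piRNA abundance.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from tedyn import expression, smallrna
from tedyn._util import rng_for

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"

te_counts = pd.read_csv(SIM / "counts_te.tsv", sep="\t", header=[0, 1], index_col=0)
truth = pd.read_csv(SIM / "truth.tsv", sep="\t")
library = {r.id: str(r.seq) for r in SeqIO.parse(SIM / "library.fa", "fasta")}
lengths = pd.Series({f: len(s) for f, s in library.items()})

rpkm = expression.rpkm_table(te_counts, lengths)
mean_rpkm = rpkm.T.groupby(level="strain").mean().T

# antisense piRNA RPM per family x strain: proportional to copy number with
# sampling noise (stands in for per-strain small-RNA libraries)
rng = rng_for(4)
strains = mean_rpkm.columns
mem = truth["strains"].apply(lambda s: set(str(s).split(",")))
rpm = pd.DataFrame(index=mean_rpkm.index, columns=strains, dtype=float)
for strain in strains:
    cn = truth[mem.apply(lambda m: strain in m)]["family"].value_counts()
    for fam in rpm.index:
        lam = 12.0 * cn.get(fam, 0)
        rpm.loc[fam, strain] = smallrna.rpm_normalize(rng.poisson(lam), 1e6)

groups = pd.DataFrame(
    [
        {
            "family": fam, "strain": strain,
            "group": g.group if (g := expression.classify_te_group(
                mean_rpkm.loc[fam, strain], rpm.loc[fam, strain], fam, strain)) else None,
        }
        for fam in mean_rpkm.index
        for strain in strains
    ]
)
groups.to_csv(OUT / "groups.tsv", sep="\t", index=False)

per_strain = {}
for strain in strains:
    cn_all = truth[mem.apply(lambda m: strain in m)]["family"].value_counts()
    cn_full = truth[mem.apply(lambda m: strain in m) & truth["full_length"]][
        "family"].value_counts()
    per_strain[strain] = pd.DataFrame({
        "copies_all": cn_all.reindex(mean_rpkm.index).fillna(0),
        "copies_full": cn_full.reindex(mean_rpkm.index).fillna(0),
        "expression": mean_rpkm[strain],
        "pirna": rpm[strain],
    })
r_by, p_by, mean_r = expression.correlation_matrix(per_strain)
mean_r.round(3).to_csv(OUT / "correlations.tsv", sep="\t")

print("four-group counts (families x strains):")
print(groups["group"].value_counts().sort_index().to_string())
print("\ncross-strain mean Pearson R (log2 scale):")
print(mean_r.round(2).to_string())
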