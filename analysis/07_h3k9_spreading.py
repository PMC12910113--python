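#!/usr/bin/env python
"""H3K9me3 spreading and its effect on nearby gene expression.

Loads per-strain ChIP/input bedGraph tracks, calls spreading around
unique insertions (present strain vs mean of absent strains, BH FDR
0.05, full-length and truncated analysed separately), tests the
distance-dependence of gene expression changes and the association
between spreading and gene downregulation.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from tedyn import epigenome

SIM = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT = Path(__file__).resolve().parents[1] / "results"

genome_len = {r.id: len(r.seq) for r in SeqIO.parse(SIM / "genome.fa", "fasta")}
truth = pd.read_csv(SIM / "truth.tsv", sep="\t")
strains = sorted(p.stem.replace("chip_", "") for p in SIM.glob("chip_*.bedGraph"))
tracks = {
    s: (
        epigenome.SignalTrack.from_bedgraph(SIM / f"chip_{s}.bedGraph"),
        epigenome.SignalTrack.from_bedgraph(SIM / f"input_{s}.bedGraph"),
    )
    for s in strains
}

ins = truth[truth["unique"]]
spread = {}
for label, subset in (("full_length", ins[ins["full_length"]]),
                      ("truncated", ins[~ins["full_length"]])):
    results = epigenome.spreading_analysis(tracks, subset, contig_lengths=genome_len)
    spread[label] = pd.DataFrame(
        [
            {"insertion_id": r.insertion_id, "spreading": r.spreading,
             "max_distance_kb": r.max_distance_kb, "direction": r.direction_bias}
            for r in results
        ]
    )
    n = len(spread[label])
    k = int(spread[label]["spreading"].sum())
    print(f"{label}: {k}/{n} insertions with detected spreading "
          f"(max extent {spread[label]['max_distance_kb'].max()} kb)")
pd.concat(spread, names=["class"]).to_csv(OUT / "spread.tsv", sep="\t")

# distance-dependent gene effects
counts = pd.read_csv(SIM / "counts_gene.tsv", sep="\t", header=[0, 1], index_col=0)
meta = pd.read_csv(SIM / "gene_meta.tsv", sep="\t")
bins, genes = epigenome.gene_effects_by_distance(counts, meta)
bins.to_csv(OUT / "gene_effects_bins.tsv", sep="\t", index=False)
genes.to_csv(OUT / "gene_effects.tsv", sep="\t", index=False)
print("\ngene expression vs distance to insertion:")
print(bins.round(4).to_string(index=False))

# spreading x downregulation association on insertion-gene pairs
flags = pd.concat(spread.values()).set_index("insertion_id")["spreading"]
paired = genes.merge(meta[["gene_id", "insertion_id"]], on="gene_id")
paired = paired[paired["insertion_id"].isin(flags.index)]
assoc = epigenome.associate_spreading_downregulation(
    flags.reindex(paired["insertion_id"]).to_numpy(),
    paired["downregulated"].to_numpy(),
)
pd.DataFrame(assoc.table,
             index=["spreading", "no_spreading"],
             columns=["downregulated", "not_downregulated"]).to_csv(
    OUT / "association.tsv", sep="\t")
print(f"\nspreading x downregulation: chi2 = {assoc.chi2:.2f}, p = {assoc.p:.2g} "
      f"({'reliable' if assoc.reliable else 'low expected counts'})")
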