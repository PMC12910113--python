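#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the consensus library, a genome with TE copies planted in three
divergence waves, the RepeatMasker-style hit table, per-strain insertion
calls, small-RNA reads for the most copy-rich family, ChIP/input tracks
and RNA-seq-like count tables.  Everything downstream (02-07) reads from
results/sim/.
"""

from pathlib import Path

import pandas as pd

from tedyn import repeatio, synthio

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260201

params = synthio.SimParams(seed=SEED)
library = synthio.gen_library(params)
genome, truth, hits = synthio.build_genome(params, library)
truth, calls = synthio.sim_strain_calls(truth, params.shared_insertion_fraction,
                                        seed=SEED, strains=params.strains)
gene_counts, te_counts, gene_meta = synthio.sim_expression(
    truth, {0: -1.0, 1: -0.4}, seed=SEED, strains=params.strains
)

synthio.write_fasta(library, OUT / "library.fa")
synthio.write_fasta(genome, OUT / "genome.fa")
repeatio.write_rm_out(hits, OUT / "hits.out",
                      {f: c.canonical_length for f, c in library.items()})
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
for strain, df in calls.items():
    df.to_csv(OUT / f"calls_{strain}.tsv", sep="\t", index=False)
gene_counts.to_csv(OUT / "counts_gene.tsv", sep="\t")
te_counts.to_csv(OUT / "counts_te.tsv", sep="\t")
gene_meta.to_csv(OUT / "gene_meta.tsv", sep="\t", index=False)

# small RNAs for the family with the most planted copies
top_family = truth["family"].value_counts().idxmax()
reads = synthio.sim_small_rnas(library[top_family], 20_000, params.pingpong_fraction,
                               params.bias_1U, seed=SEED)
reads[["sequence", "count"]].groupby("sequence", as_index=False).sum().to_csv(
    OUT / "smallrna.tsv", sep="\t", index=False
)
(OUT / "smallrna_family.txt").write_text(top_family + "\n")

# ChIP + input tracks around unique insertions
ins = truth[truth["unique"]]
clen = {c: len(s) for c, s in genome.items()}
tracks = synthio.sim_tracks(ins, params.strains, clen, params.spread_amplitude,
                            params.spread_decay, seed=SEED)
for strain, (chip, inp) in tracks.items():
    chip.to_bedgraph(OUT / f"chip_{strain}.bedGraph")
    inp.to_bedgraph(OUT / f"input_{strain}.bedGraph")

print(f"library: {len(library)} families "
      f"({pd.Series([c.subclass for c in library.values()]).value_counts().to_dict()})")
print(f"genome: {sum(clen.values()):,} bp, {len(truth)} planted copies, "
      f"{int(truth['unique'].sum())} unique insertions")
print(f"small RNAs: {len(reads)} reads for {top_family}")
print(f"wrote inputs to {OUT}")
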