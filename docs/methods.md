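# Methods

This note documents the models, parameters and numerical choices behind
`tedyn`. It covers what the synthetic data emulate (and what they do
not), the exact form of every statistic, and the design decisions made
where more than one reasonable construction existed.

## Units and coordinate conventions

Two Kimura scales coexist in the repeat-annotation world. The low-level
estimator `landscape.kimura_distance` and the mutation sampler
`synthio.mutate_k2p` work in substitutions/site, the natural scale of the
two-parameter closed form. Copy tables, divergence landscapes and the
generator's wave parameters use the percent scale familiar from
RepeatMasker landscapes (K = 25 means 0.25 substitutions/site), with
1-point bins over [0, 50). `repeatio.annotate_kimura` converts.

Coordinates are 0-based half-open everywhere in memory. RepeatMasker
`.out` files (1-based inclusive, 'C' for minus strand) are converted on
parse and write; BED-style outputs are 0-based half-open; insertion
calls are point breakpoints.

## The K2P substitution sampler

`mutate_k2p(seq, K, kappa)` draws, per site, a transition with
probability `P(t) = 1/4 + 1/4 e^{-4βt} − 1/2 e^{-2(α+β)t}` and each of
the two transversions with probability `Q(t)/2`,
`Q(t) = 1/2 − 1/2 e^{-4βt}`, where `βt = K/(κ+2)` and `αt = κβt` so that
the expected divergence is exactly K with transition/transversion rate
ratio κ (default 2, a typical Drosophila nuclear value). These are the
standard K80 transition probabilities, so no numeric inversion is
needed; fidelity is verified by the mutate-and-re-estimate round trip
(median recovered K within 10% of targets 0.5–25 on 5-kb sequences, in
practice within ~1%).

The model is substitution-only. No indels are simulated, so a copy is
positionally aligned to its consensus by construction and every
divergence or ORF oracle is exact. This is the generator's largest
departure from real data: real TE copies accumulate indels and nested
insertions, and real alignments carry alignment error. Passing tests
therefore demonstrate correctness of the statistics and the plumbing,
not robustness to alignment noise.

## The synthetic study and its conditions

`SimParams` defaults define one synthetic study, chosen once:

* 30 families (subclass mix 14% DNA, 5% RC, 30% LINE, 50% LTR, 1% PLE,
  echoing the curated library composition; status mix 0.44 intact /
  0.26 partial / 0.30 remnant), 10 copies each, in a 2-Mb uniform-ACGT
  background.
* Three divergence waves at K (percent) of 0.5 ± 0.3, 11 ± 2 and 25 ± 3
  with equal weights — a recent wave (K ≤ 1), a speciation-associated
  wave and an ancient wave. Families belong to exactly one wave.
* Truncation probability 0.5/0.7/0.9 by wave (older copies more often
  fragmentary); a truncated copy keeps a uniform 0.2–0.85 fraction cut
  from a uniformly chosen end. ORF disruption probability 0.5 (a
  premature stop planted at 40% of the ORF), matching the observation
  that roughly half of full-length copies are coding-defective.
* piRNA reads: half sense / half antisense, lengths uniform on 23–29 nt,
  1U bias 0.8, ping-pong fraction 0.5. The 1U bias is planted by
  *position selection* (a read starts at a consensus T/A with the bias
  probability), which keeps every read an exact substring of the
  consensus so the 0-mismatch mapper recovers it; partner selection at
  A-bearing offsets simultaneously plants the sense-side 10A signal.
* ChIP tracks: 10-bp bins, baseline 1.0 with Gaussian noise (sd 0.2),
  enrichment amplitude 5.0 decaying as exp(−d/1500 bp) from the
  insertion edges, present only in carrier strains; matched independent
  input tracks. Signal is planted only at full-length insertions.
* Five strains; 30% of insertions shared by all strains, the rest unique
  to one; TAF near 1 (sd 0.02) with a 15% heterozygous component uniform
  on 0.25–0.65.
* Expression: negative-binomial counts (dispersion 0.1), two replicates
  per strain, gene base means log-normal; TE-family means proportional
  to per-strain copy number. Planted gene effects are log2 fold-changes
  by distance bin, applied only in the carrier strain.
* Species panel: four relatives; orthologous genes (50 × 300 codons)
  mutated at K = 0.15 substitutions/site — inter-species synonymous
  divergences in this clade are typically reported as 12–20, a figure
  whose units are ambiguous and read here as per 100 sites, hence
  0.12–0.20 substitutions/site; horizontally transferred families copied at identity
  0.999; vertical families mutated like genes. Codons that mutate into
  stops are reverted so coding frames stay clean.

The truth table records the *realized* state of each planted copy — its
length fraction and its post-mutation ORF status — because the K2P
sampler itself occasionally creates premature stops; recovery tests
compare pipeline labels against what was actually planted.

## Hit processing and classification

Filtering follows the stated thresholds exactly: identity strictly
> 90%, length strictly > 50 bp, low-complexity overlap strictly < 50% of
the hit. Low-complexity intervals are found by a windowed dinucleotide
Shannon-entropy screen (64-bp windows, threshold 1.2 nats) so the filter
is testable without external annotation tracks.

Defragmentation chains same-family/contig/strand fragments when the
consensus intervals progress without overlap along the strand and the
genomic gap is at most `insert_tolerance × max(consensus gap, 1)`
(tolerance 11), capped at 5 kb. This declared rule is oracle-tested; the
exact internal heuristics of the commonly wrapped merging script are not
documented and may differ on edge cases. One known conflict is kept
visible rather than resolved silently: applied literally, the > 90%
identity filter would remove every ancient copy (K ≈ 25 implies raw
divergence > 20%), yet divergence landscapes are expected to span K up
to 50 — so the landscape chain runs on defragmented, unfiltered hits and
`filter_hits` is applied where insertion-level precision matters.

Length class: full-length iff fraction ≥ 0.9 (inclusive) *and* the
family's canonical copy is intact; partial and remnant families are
always truncated. ORF completeness: within the copy's overlap with a
canonical ORF, the longest ATG-initiated, in-frame, stop-free stretch
must reach ≥ 90% of the canonical coding length and every annotated
domain interval must be covered without an internal stop ("domain
structure preservation" operationalized as coverage without
frameshift/stop, since no computational definition is given elsewhere).
Remnant families are not assessed.

## Wave clustering

The clustered object is the family × K-bin occupancy matrix (bp per
bin), row-standardized; per-copy K vectors would have been an
alternative reading, and the profile form is chosen because it directly
mirrors landscape semantics and gives k-means scale-free shapes.
k-means runs with 10 seeded restarts for k = 2..10, k selected by mean
silhouette width, and clusters relabelled by ascending occupancy-
weighted mean K so cluster 1 is always the youngest wave. Saturated
copies (K2P log-domain violation) are excluded and counted, not
clamped. Constant or identical profiles abort clustering with an
explicit error.

## Ping-pong statistics

Pair counts at offset o are multiplicity-weighted products of sense and
antisense 5′-position counts whose 5′ ends are separated by o − 1 nt,
counted symmetrically in the strand labels (the separation, not its
sign, defines the offset) so that exchanging sense/antisense labels
leaves the histogram and Z10 unchanged. Z10 uses the sample standard
deviation of the offsets 1–20 excluding 10 (both the offset range and
the sd convention vary between published pipelines; these are declared
and configurable). A zero background sd yields Z10 = 0 for a flat
histogram and +inf for an excess; no pairs at all yields a missing Z10.
Multi-family exact mappers count fully toward each family by default.

## Horizontal transfer

The species search is a minimal seed-and-extend aligner: exact 15-mer
anchors, clustered on diagonals within the band (16), the best cluster
extended to the full consensus where the target allows, and a banded
global alignment (unit-cost edit distance, band widened by the length
difference) over the chained span. Identity = (columns − distance) /
columns with columns = max of the two lengths; coverage = chained query
span / canonical length. Both strands are searched. The banded distance
is exact for the divergences involved (verified against full dynamic
programming). dS is fixed to NG86 counting with Jukes–Cantor correction;
pathways through stop codons are excluded from the per-codon averaging
(with a nonsynonymous fallback when all paths are blocked) and changes
to stop codons count as nonsynonymous. TE dS is computed on each
family's longest ORF. The Mann–Whitney dS contrast is exact when the
smaller sample has ≤ 8 values and normal-approximated with tie
correction otherwise; BH correction runs across families.

## Unique insertions

A call is unique iff no call from another strain lies within ± 5 kb
(inclusive) on the same contig; matching is coordinate-only by default
(`match_family=True` adds the family requirement) since the described
procedure intersects coordinates. The sorted-scan implementation is
verified against a quadratic oracle. Heterozygous: TAF < 0.7 strictly;
full-length: fraction ≥ 0.9 inclusive.

## Spreading and gene effects

Enrichment is chip − input per 10-bp bin (negative values retained),
in 1-kb windows tiled exactly over [edge, edge + 4 kb) on each side,
TE body excluded; windows crossing contig ends are truncated and
flagged. The control for each window is the per-bin *mean* across all
absent strains (mean-then-test, rather than pooling the absent strains'
bins); per-window Mann–Whitney (exact for ≤ 20 samples a side),
BH across all windows × insertions at FDR 0.05. Spreading = at least
one significant flanking window with present > absent; extent = the
farthest significant window contiguous from the TE edge; direction bias
compares the numbers of significant windows per flank. Full-length and
truncated insertions form separate multiple-testing families — pooling
them would let the strong full-length discoveries relax the BH
threshold and inflate the flag rate among truncated nulls.
H3K9me2 is handled identically to H3K9me3; the mark is a column, not a
code path.

Gene counts are normalized by median-of-ratios size factors (robust to
the minority of genuinely affected genes; total-count scaling leaks
planted effects into every gene of a strain). The per-bin test pools,
across the genes of a distance bin, per-strain means scaled by each
gene's grand mean — these are exchangeable across strains under the
null, and the measured null rate of significant bins is ~2% at FDR
0.05. Distance bins are half-open [k, k+1) kb, a gene overlapping its
insertion falls in bin 0–1 kb. The per-gene downregulated flag requires
log2FC < 0 and q < 0.05; the per-gene p is a Welch t on log2 normalized
counts rather than a rank test because with two replicates versus eight
the exact Mann–Whitney p can never go below 2/45 ≈ 0.044, which BH
correction can never bring under 0.05 — a rank test is structurally
unable to call genes at this replicate count. The
spreading × downregulation association is a Pearson chi-squared without
continuity correction on the 2 × 2 table, with a reliability flag when
any expected cell is below 1.

Feature context uses the precedence exon (5UTR/CDS/3UTR) > promoter
(≤ 1 kb upstream of the TSS, strand-aware) > intron (near = within 1 kb
of an exon of the same gene, else distal) > intergenic; overlapping
genes resolve to the nearest TSS.

## Study sizes

The verification studies are sized for stable estimates at interactive
runtimes: 200 alignment pairs for the estimator oracle, 100 × 5-kb
copies per round-trip target, 30 families / 300 copies for wave
recovery, 10,000 reads and 100 null simulations for ping-pong, a sparse
16-family / 24-Mb layout (insertions ~100 kb apart on average) for
spreading sensitivity so neighbouring insertions' windows do not
confound each other, 100 amplitude-zero simulations for the spreading
null, 1,000 random calls for the unique-insertion oracle, and a
4-species / 13-family panel for the HT screen. `scripts/acceptance.py`
runs all of them from one seed in about half a minute.

## Known limitations

* No indels, nested insertions, satellite arrays or sequencing-error
  models; FASTQ-level simulation is out of scope.
* The background genome is i.i.d. uniform ACGT; real base composition,
  isochores and low-complexity structure are absent (low-complexity
  stretches are planted explicitly only where the filter is tested).
* piRNA contaminant classes (rRNA/tRNA/miRNA) are assumed removed
  upstream; only a generic out-of-range length contaminant is simulated.
* The CpG-adjusted divergence variant offered by some landscape tools is
  deliberately not implemented; plain K2P only.
* Expression modelling is family-level; multi-mapper-aware read counting
  and model-based differential expression engines are out of scope, so
  absolute log2FC values are not comparable to published per-gene
  estimates.
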