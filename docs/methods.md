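# Methods

## Model and assumptions

`spliceflow` treats transcript reconstruction as a *sparse flow
decomposition* problem on a splice graph. The assumptions are:

- reads are sampled from transcripts roughly uniformly, so the number of
  read alignments crossing a node boundary or splice junction is
  proportional to the summed abundance of the transcripts using it;
- a splice graph built per gene locus is a DAG whose source-to-sink paths
  are candidate transcripts (edges always point downstream in genomic
  coordinates; trans-splicing and fusions are out of scope);
- among all path sets consistent with the edge weights, the one with the
  fewest paths is the best explanation (parsimony), with observed node
  triples ("known paths") breaking ties.

Coordinates are 0-based half-open internally; donors/acceptors are
reported 1-based (donor = last base of the upstream exon, acceptor = first
base of the downstream exon), so a split alignment with blocks
`[s1,e1) [s2,e2)` yields donor `e1` and acceptor `s2+1`.

## Splice graph construction

**Split.** Exon regions are maximal intervals with ≥1× coverage. Every
junction donor/acceptor strictly inside a region cuts it, so alternative
linkages always coincide with node boundaries. A junction is called from a
single supporting split alignment by default (`min_junction_support=1`);
false junctions from noise reads get weight-1 edges that the downstream
decomposition and the `min_tx_weight` filter suppress.

**Merge.** Adjacent regions are re-joined when the gap is ≤ `small_gap`
(default 10 bp — gaps this short are almost never real introns, which are
essentially always ≥ 20 bp) or ≤ `moderate_gap` (default 50 bp) with both
coverages ≥ `high_cov` (default 20×). No merge happens when a donor or
acceptor boundary lies in the closed interval between the two regions:
the splice event implies the gap is genuinely intronic in some transcript.
The moderate-gap and high-coverage values are package choices exposed in
`GraphConfig`. Merged coverage is covered-base mass over the merged span
(the gap counts as zero depth).

**Connect.** An edge's weight is the raw count of read alignments whose
node chain contains the pair consecutively (constant of proportionality
1 — the simplest count-proportional weighting). Mate pairs whose two
alignments end/start in adjacent nodes with no node in between add a
`pair_augmented` edge weighted by fragment count, only where no read
already crosses. Known paths are stored as node triples; longer chains
contribute every width-3 window. Reads touching a node by ≥1 base count as
crossing; only primary alignments are used, so weights are integer read
counts; deletions shorter than `min_intron` (20 bp) are absorbed rather
than treated as splice gaps.

## Sparse flow decomposition

At each node the local problem min ‖f‖₀ subject to row sums = in-weights,
column sums = out-weights, f ≥ 0, is relaxed to the LP
min Σ f_ij·r_ij with r_ij ~ Uniform(0.5, 1.5) i.i.d., solved with HiGHS
(`scipy.optimize.linprog`). The optimum lies at a vertex of the
transportation polytope, which has at most m+n−1 and often fewer positive
entries; drawing `trials` (default 5) independent r and keeping the
sparsest thresholded solution approximates the L0 optimum well (the
brute-force oracle test shows ≥95% exact agreement at m,n ≤ 3).

Two deterministic candidates join the random portfolio:

- a **marginal-matching** assignment that repeatedly pairs an in-weight
  with an exactly equal out-weight (realisable as a single flow) and
  otherwise routes largest-to-largest. With integer read counts the true
  pairing frequently leaves matching residuals, and this candidate makes
  recovery of such degenerate (extra-sparse) vertices independent of the
  random draws;
- when known paths touch the node, one extra LP with r = 1 discounted to
  0.6 on the known pairs, so the witnessed pairing is always represented
  among the candidates before the tie-break.

Selection order: smallest support, then most known pairs covered, then
lexicographically smallest support set (full determinism).

**Thresholding.** Entries below max(`abs_eps`=1e-6, `rel_eps`=0.01 ×
total weight) are zeroed — except each row's and column's largest entry,
so every marginal stays representable — and marginals are restored by
iterative proportional fitting; if IPF cannot restore them to 1e-6
relative accuracy the unthresholded LP solution is kept.

**Balancing.** Counting noise makes a node's in- and out-sums differ. If
the relative imbalance is ≤ `balance_tol` the smaller side is scaled up to
match; beyond it an auxiliary sentinel edge carries the surplus (becoming
a transcript end inside the locus). The default 0.5 reflects that
junction-support counts at typical depth fluctuate by 5–15% per side, so
sub-1.5× discrepancies are noise while larger ones (e.g. an alternative
transcription start) are real unexplained flow.

**Traversal.** A sentinel source feeds every node without in-edges
(weight = the node's out-sum) and a sentinel sink drains nodes without
out-edges; isolated nodes get both, weighted by coverage. Internal nodes
are processed in genomic start order (topological, since edges point
downstream). Each in-flow carries its full path history; the local
solution pairs in-flows with out-edges and forwards extended paths, so
after the last node the flow set is exactly a set of source-to-sink paths.
Known-path triples (u, v, x) are applied at node v to in-flows whose
history ends at u. Per-node LP seeds are drawn from a generator seeded by
`FlowConfig.seed`, making output byte-identical for fixed input and seed.

Transcripts shorter than `min_tx_len` (200 bp) or lighter than
`min_tx_weight` (1 read) are dropped; setting both to 0 plus
`min_junction_support=1` is the max-sensitivity preset.

## Evaluation

Matching is co-linear exon-interval overlap on shared coordinates: the
match fraction of reference t by reconstruction r is the intersected
exonic length over t's length; t is recovered when the best fraction
exceeds the threshold (default 0.9, strict `>`). A reconstruction is a
false positive when below threshold against every reference and not
contained in any (containment: ≥ `cont_threshold`=0.95 of the
reconstruction's bases inside the reference — the tolerance is a package
choice). An optional k-mer sequence mode was considered and rejected:
coordinate overlap is exact on shared references and needs no external
matcher. The oracle set keeps references with no zero-depth transcript
base outside `end_tol` (default 25 bp) of either end.

## Synthetic data

`simulate_reads` draws an isoform with probability ∝ abundance × length,
a start position uniform along the transcript, and maps the read through
the exon chain to genomic blocks with exact split CIGARs — emulating an
error-free aligner on error-free reads. No sequencing errors, indels,
coverage bias or fragment-length distribution are modelled (fragment
length is fixed in paired mode), so passing tests demonstrate the
graph/flow logic, not robustness to alignment artefacts; real data add
soft-clips, multi-mappers and junction noise that only enter here through
the configurable filters.

The builtin `three_isoform_gene` locus has five 80-bp exons and three
isoforms at abundances 1:2:4 sharing the first and last exon with
mutually exclusive middle exons. Equal isoform lengths are deliberate: a
path's recovered flow is a junction-crossing read count, which for
unequal lengths is biased by the per-transcript junction window
(length/(length−read_len+1)); with equal lengths the flow ratios estimate
the abundance ratios directly, to roughly ±10% at ~6000 reads.
`skipped_exon_gene` provides the unequal-length variant. Exon/intron
sizes (80 bp each) keep junction-crossing counts high at desk scale while
staying above the moderate-gap merge window and the 200-bp length filter.

## Problem sizes and numerics

Default test and acceptance runs use single loci with ~2000–6000 reads,
local problems up to 3×3, and the brute-force oracle capped at m·n ≤ 12 —
sizes chosen so the whole suite runs in well under a minute while still
exercising every code path. LPs run in double precision; marginal checks
use 1e-6 relative tolerance; support counts use a 1e-9 floor.

## Known limitations

- Graphs are unstranded; transcripts are reported with strand `.` and
  sequences emitted 5'→3' on the reference strand.
- Flow weights are raw read-support counts, not normalized abundances
  (no TPM/FPKM, no EM re-estimation).
- Alternative transcription starts/ends inside a node rely on the
  balance-tolerance heuristic rather than coverage change-point splits.
- Per-node decomposition is a relaxation: globally minimal path covers
  are not guaranteed, and ambiguous loci without known-path evidence are
  resolved deterministically but arbitrarily.
- Cross-chromosome mate pairs are treated as single-end.
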