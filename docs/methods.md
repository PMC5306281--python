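# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `pangest`. It is the place where design decisions that
were genuinely open are recorded, in the package's own words.

## Alignment evidence and coverage

All clustering decisions rest on merged pairwise-alignment summaries, not on
single HSPs. For one ordered pair (query q, subject s):

1. HSPs on the minority strand (by summed bitscore) are discarded —
   biologically one orientation is real, and mixed-strand hit sets are
   almost always spurious palindromic matches.
2. The retained HSPs' query intervals are unioned; overlapping intervals
   count once. `coverage = 100 · union / min(Lq, Ls)` in the default
   *shortest* mode, `/ max(Lq, Ls)` in *longest* mode (used when both
   sequences are declared full-length cDNAs, where a short fragment fully
   contained in a long model should *not* count as a full match).
3. Pair identity is the alignment-length-weighted mean of HSP identities.
   An unweighted mean would let a 40 bp fragment at 100 % drag the value of
   a 2 kb alignment; length weighting was chosen for that reason. How
   overlapping HSPs that disagree in identity should be reconciled is
   genuinely underdetermined; interval union + length weighting is the
   documented convention here.

Thresholds are inclusive throughout (identity ≥ 95, coverage ≥ 50,
isoform overlap ≥ 40 bp). The intron-flagging length rule is the one strict
inequality (alignments must be *longer than* 100 nt), matching its
definition.

### Built-in aligner

`local_align` is a seed-and-extend scheme: exact k-mer seeds (default
k = 12) identify diagonals, and each seeded diagonal is swept for
maximal-scoring **ungapped** segments (match +1, mismatch −2, X-drop 20; N
never matches). Indel events — retained introns, split genes — shift the
diagonal and therefore surface as separate HSPs, which is precisely the
representation the coverage-merging step expects, and ungapped segments are
directly checkable against an exhaustive local-alignment oracle in the
tests. The trade-off: a pair differing by many small scattered indels would
fragment into short segments and could fall below the per-HSP length floor
(30 bp). That regime does not occur in same-species CDS/transcript
comparisons at the identity levels the tool targets.

The surrogate E-value is `Lq · Ls · 2^(−bitscore)` (Karlin–Altschul shape
with fixed constants). Only its ordering matters: it feeds the best-hit
index and the −log10 edge weights (capped at 300, with E = 0 mapped to the
cap). `all_vs_all_hsps` aligns only sequence pairs sharing ≥ 3 distinct
canonical k-mers (k-mers occurring in > 200 sequences are ignored as
uninformative); at ≤ 2 % divergence, genuinely related pairs share hundreds.

## Clustering

**Isoform collapse** runs before anything else: within one accession,
sequences whose merged alignment spans ≥ 40 bp at ≥ 95 % identity (and
passes the graph's coverage threshold) form redundancy groups by transitive
closure; the longest member represents the group, ties broken by
lexicographic id. Whether collapse should precede or follow in-paralog
detection is not externally determined; collapsing first keeps the best-hit
index clean and is the convention here.

**In-paralogs** are same-accession reciprocal best hits whose supporting
edges score at least as high as any cross-accession hit of either partner
(bitscore, then lower E-value, then lexicographic id — the same
deterministic tie-break used everywhere).

**BDBH** emits one candidate cluster per non-redundant reference sequence;
other accessions contribute their bidirectional best hit with the seed, in
input order; in-paralogs of added members join their representative's
cluster, contested ones resolved by strongest supporting edge. By
construction every cluster contains a reference sequence and reference-absent
genes stay unclustered — BDBH is a fast core-genome tool, not a general
clusterer.

**OMCL-style Markov clustering.** Directed weights are symmetrized as the
mean of both directions, with a missing reciprocal contributing 0 rather
than vetoing the pair: truncated transcripts often produce adequate coverage
in one direction only, and demanding strict reciprocity would discard them
(a flag restores strictness). Weights are then normalized by the mean weight
of their accession pair — without this, closely related accessions dominate
the inflation dynamics — self-loops are set to each node's maximum incident
weight, and the column-stochastic matrix is iterated through expansion
(squaring) and inflation (element-wise power, default 1.5, the customary
default) with pruning below 1e-5 until the matrix changes by < 1e-6 or 100
iterations (non-convergence emits a warning and the current partition).
Clusters are the connected components of the converged attractor structure;
singletons are emitted as clusters, so the output is always a partition of
the non-redundant nodes.

## Matrices and classes

The pan-genome matrix (PM) is accessions × clusters, each cell the number of
that accession's sequences in the cluster (collapsed isoforms map to their
representative's column; a flag excludes them). Occupancy classes:

| class | occupancy |
|---|---|
| core | N |
| soft-core | ≥ round(0.95 · N), < N |
| shell | remainder |
| cloud | ≤ 2 |

The soft-core bound uses **nearest-integer** rounding of 0.95 N: for N = 19
and N = 16 this admits clusters absent from exactly one accession (18 and
15), which is the intended meaning of "core genes that may be missing from
one input"; for N = 4 the band coincides with core. Ceiling rounding would
empty the soft band at N = 19 and was rejected. The same rounding defines
the soft-core growth curve.

ANI between accessions A and B averages the merged-pair identities of
co-clustered A/B sequence pairs (both hit directions of one pair average to
one value first). Merged hits, not raw HSPs, are used so fragmented
alignments are not double-counted; a flag exposes the raw-HSP alternative
reading. Accession pairs never co-clustered under a strict filter are
reported as missing and are an error for dendrograms — silent imputation
would fabricate similarity. Dendrograms use scipy hierarchical clustering
(complete or average linkage) on either d = 100 − ANI or Euclidean distances
between ANI columns; Newick branch lengths are half the merge-height
difference so cophenetic distances equal merge heights.

The non-redundant PM greedily collapses clusters whose representatives
(longest members) match at the graph thresholds, in descending representative
length — the longest model is the most complete one, so it should absorb
fragments, not vice versa. The greedy order makes the collapse idempotent.
The reference comparison reports recall (matched references / references),
precision (matching clusters / clusters) and clusters-per-matched-reference.

## Growth simulation and fits

Accessions are merged in random order (20 permutations by default). A
sequence is *novel* when no pool member matches it at identity ≥ 70 % and
shortest-mode coverage ≥ 50 % — deliberately permissive so retained introns
and fragments do not inflate the pan count. Novelty is checked sequentially
against the growing pool, including same-step additions, which also removes
within-accession redundancy at these thresholds; pan(1) is therefore the
first accession's non-redundant size under the same rule. The core at step n
counts first-accession pool members with a qualifying match in every
accession seen so far (computed by sequence-level matching, not via
clusters — the cluster-based core can differ and both are reported);
soft-core relaxes "every" to the rounded 0.95 fraction.

Fits use `y(n) = κ·exp(−n/τ) + Ω` on **all** permutation points, not their
means. The core curve is fitted directly; the pan curve is fitted on
per-step novel counts (n ≥ 2), whose asymptote Ω is the novel-genes-per-
accession rate, and the fitted pan curve is rebuilt by cumulative summation.
Exponential fits are initialization-sensitive, so a small multi-start grid
is used (Ω₀ ∈ {final mean, mean of last values}, τ₀ ∈ {1, N/3},
κ₀ = first − Ω₀) with bounds τ > 0, Ω ≥ 0; best SSE wins. A constant curve
short-circuits to κ = 0, Ω = constant rather than failing.

## dN/dS (NG86)

Codon alignments are built by center-star alignment of the member peptides
(longest peptide as center, BLOSUM62, gap open −10 / extend −0.5),
back-translated codon-wise; rows cover the coding part only (terminal stop
codons are not aligned). Members with internal stops or lengths not
divisible by 3 are excluded with a warning. For synthetic clusters without
indels the center-star result equals the exhaustive pairwise alignment; with
indels it is a heuristic, adequate at within-species divergence.

Pairwise dN/dS follows Nei–Gojobori counting: per-codon synonymous-site
fractions from the standard genetic code (changes to stop codons count as
non-synonymous, so S + N = 3 per codon; site totals average the two
sequences), multiple-hit codons averaged over all minimal mutational
pathways with stop-passing pathways excluded (if every pathway is blocked,
all are averaged — degenerate but finite), and Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). Proportions ≥ 3/4 make the correction undefined;
such estimates are flagged unusable, never returned as numbers. ω is
undefined when dS = 0 and such pairs are *excluded* from cluster means
rather than capped — caps would manufacture arbitrary magnitudes. Cluster ω
is the mean of defined pairwise ω values (the alternative — ω of mean dN
over mean dS — is a one-line change and deliberately not the default);
clusters with mean ω > 1.5 are flagged poorly aligned and excluded from
downstream summaries. NG86 was chosen over transition/transversion-aware
estimators because it is fully specified and verifiable against an
exhaustive enumeration oracle; ω *rankings* across occupancy classes, not
absolute values, are the quantity of interest.

Notched box summaries use median ± 1.58·IQR/√n; non-overlapping notches
between occupancy levels are the significance criterion.

## Tree distances

Unrooted split semantics: each edge contributes the bipartition of the leaf
set below it, canonicalized as the side not containing the lexicographically
smallest taxon; the two root edges of a rooted binary input map to the same
split and their lengths are summed. The symmetric (Robinson–Foulds) distance
counts non-trivial splits present in exactly one tree. The branch score sums
squared branch-length differences over *all* splits (absent splits
contribute 0); because the cited conventions disagree on whether the root is
taken, both the sum and its square root are reported. Pruning to common
leaves suppresses degree-2 nodes with branch lengths summed.

## Consensus CDS

Evidence: a six-frame ORF scan (stop-free codon runs, anchored at their
first in-frame ATG; ATG-less runs are reported only when truncated by the
sequence edge, since an internal ATG-less run has no plausible start; codons
containing N terminate runs) and frame-resolved protein-homology hits.
Rules, in order: same frame + overlapping spans → union span ("assembled
into a larger CDS"), tag `both`; disagreement in frame/strand → homology
span, tag `homology`; single evidence source → that source; none →
non-coding. Emitted spans are snapped to codon boundaries of their frame and
clipped to the largest stop-free stretch (preferring the one overlapping the
ORF), so output always translates cleanly and has length divisible by 3.
The precedence table is a reconstruction from the documented behaviour of
combining ORF and homology evidence and is pinned by fixtures.

## Enrichment and expression

Domain enrichment builds one 2×2 table per domain (with/without ×
experiment/control cluster sets), counting each domain at most once per
cluster so multi-isoform clusters are not over-weighted, tests it with the
Fisher exact test (one-sided `greater` by default; enrichment and depletion
are reported separately), and adjusts across domains with Benjamini–Hochberg
FDR. Cluster expression is the mean TPM of members *with data*; members
without a TPM value are missing, not zero (a flag flips this), and clusters
with no expressed member are tallied separately rather than imputed.

## Synthetic data generator

The generator emulates the input of a same-species clustering run: gene
families with programmed occupancy classes (defaults: 6 accessions, 50 core
+ 30 shell + 20 cloud families), ancestral CDS of 300–2400 bp (random sense
codons, start/stop present), per-accession copies mutated codon-aware
(no internal stops; start/stop codons untouched), and the degeneracies real
transcript sets show: redundant 3′-truncated isoforms (rate 0.10), fragments
(0.07), split genes (0.06), retained introns of 120–300 random bases at a
codon boundary (0.07) — about 20 % of copies degraded in total, each
recorded in a truth table. Expression is log-normal with class-ordered
means (core > shell > cloud in log-TPM: 3.5 / 2.5 / 0.5, σ = 0.8), so
expression-by-occupancy analyses have a programmed effect direction.

`divergence` (default 0.01) is the **expected pairwise divergence between
two accessions' copies**; each copy is mutated at `divergence/2` from the
ancestor. A copy is never split when it is its family's only copy: two split
halves share no alignment, so an occupancy-1 split family would be
unclusterable by construction — a degenerate fixture, not a property of the
method under test.

What the generator does *not* emulate: assembly chimeras, allelic isoform
structure, sequencing error profiles, codon-usage bias, paralogous gene
families with intermediate (70–95 %) identity, and expression noise across
tissues. Passing tests on this fixture therefore demonstrate the
correctness of the graph/clustering/matrix machinery under controlled
divergence and degradation, not robustness to every artifact of real
RNA-seq assemblies.

## Problem sizes

The default fixture (≈ 510 sequences over 6 accessions) was sized so a full
pipeline run — generation, all-vs-all alignment, clustering, ANI, growth
with 20 permutations, and dN/dS over the single-copy clusters — completes in
about a minute on one CPU, which keeps the test suite and the acceptance
script comfortably interactive while still exercising every code path at
realistic within-species divergence.

## Known limitations

- The built-in aligner is for fixture-scale data; genome-scale runs should
  supply precomputed tabular hits (`--hits`).
- Center-star codon alignment is heuristic in the presence of indels.
- NG86 ignores transition/transversion and codon-usage bias; absolute ω
  values are conservative, rankings are robust.
- The Markov-clustering implementation uses a dense matrix; it is intended
  for the tens-of-thousands-of-nodes regime at most.
- PAV-based (presence/absence) trees are intentionally not produced: the PM
  is exported, but transcript-based PAV patterns largely reflect
  differential expression and make unreliable phylogenies.
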