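# Methods

This note documents the models and procedures `bridgescan` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the choices made where the design was genuinely open.

## Base-pairing concordance

For row-matched alignments of bridge RNAs (columns *i*) and DNA windows
(columns *j*), the concordance statistic is

C_ij = absmax(Σ_k CheckEqual(s_ki, t_kj), Σ_k CheckComplementary(s_ki, t_kj)) / n,

where CheckEqual(a,b) = 1 when a = b (identity with the written top strand
implies pairing with the bottom strand; positive), CheckComplementary = −1
when a and b are Watson–Crick complements (top-strand pairing; negative),
and any row with a gap at either position is ignored and discounted from
n. U and T compare as equal throughout.

Choices the statistic's definition leaves open:

* **absmax ties** (match sum equal to |complement sum|) return the positive
  value and set a `tie` flag; ties carry no strand information either way.
* **Ambiguity codes** (N and friends) are treated like gaps — excluded and
  discounted — because they carry no pairing information.
* **Complementarity is strict Watson–Crick**; G:U wobble can be enabled
  with `wobble=True` but is off by default, so top-strand signal is not
  diluted by the weaker wobble geometry.

### Permutation nulls and z-scores

Two nulls are computed with `n_perm = 1000` by default: shuffling the
*rows* of the RNA alignment (per-cell exchangeability null) and shuffling
its *columns* (position-identity null). Per cell, z = (C_obs − μ_perm)/σ_perm;
cells with σ = 0 are masked. The **column null supplies the sign** for the
strand projection; the row null is the better-calibrated significance
reference (with uncoupled synthetic families, ~5% of cells exceed
|z| = 1.96). The choice of which null feeds which consumer is exposed via
`mode=` rather than hard-wired.

### Covariation and the signed map

The default covariation score is column-pair **mutual information with
average-product correction** (nats, gaps excluded pairwise, floored at 0).
A pseudo-likelihood contact predictor would serve the same role; an
external-matrix adapter (`method="external"`) ingests any
whitespace-delimited matrix of matching shape, so such scores can be used
verbatim when available. Min–max normalization divides each sign class by
its extreme value (positives by the maximum, negatives by |minimum|),
which preserves zeros and is idempotent; normalization is global per
matrix, not per row. The signed map is minmax(raw) × sign(z_columns).

### Guide-segment detection

Bottom-strand guides appear as runs along ascending diagonals with signed
≥ +threshold; top-strand guides as runs along anti-diagonals with signed
≤ −threshold (the RNA is antiparallel to whichever strand it pairs, which
flips the traversal direction in genome coordinates). Defaults: min_run 4,
threshold 0.5 on the [−1,1] scale; overlapping same-strand runs are
merged. A dot-bracket string, when supplied, restricts detection to loop
(unpaired) RNA positions.

## Site geometry

A site read on the top strand is LT (9 nt) fused with RT (4–7 nt) over a
2-nt core at site positions 8–9 (1-based): 11 nt with the short RT, 14 nt
with the 7-nt RT. The left guide reads identically to the top strand
(bottom-strand pairing); the right guide is the reverse complement of the
RT segment (top-strand pairing). Both guides overlap the core, and
`TargetGeometry.site_from_guides` refuses guide pairs that disagree on it.

## Element boundaries

A pre-insertion candidate must align both distal 1,000-nt flanks of a
locus contiguously (subject gap ≤ 20 nt, ≥ 90% flank coverage) with no hit
from the CDS region; breakpoints are the inner edges of the flank hits.
Core identification then searches near the breakpoints for the longest
repeat (2–10 nt) whose placement *reconciles the junctions*: deleting
[left+d, right+d) must reproduce the pre-insertion joint, which constrains
the two copies to a common shift d reachable through a contiguous junction
repeat. This constraint is what distinguishes a 2-nt CT core from chance
repeats nearby; a loose same-shift window search (window 30 nt) remains as
a fallback for degraded breakpoints, and "no repeat found" is reported
rather than guessed. The element convention places one core copy at the
element's 5′ end, with the target's copy immediately downstream.

The iterative search aligns every newly accepted element against all loci
(internal seed-and-extend matcher, k = 13); a hit is admitted only when
hits cover ≥ 90% of each terminal 100 nt at ≥ 80% identity and the implied
interval starts with the query's core and is followed by another copy of
it. Coordinates come from extrapolating the anchor alignment to the full
query, elements are deduplicated exactly and within ±5 bp, and the set
grows monotonically until a fixed point (convergence) or `max_iter`.
CT-core boundary solutions are preferred when alternatives exist, then
earlier-iteration provenance.

## Insertion-site calling

Donor termini are the 20-mers immediately inside each recombination
junction, excluding the 2-nt core (the inserted donor is the plasmid
opened at its core). Both strands of each read are scanned at Hamming
distance ≤ 2; each hit splits the read. Flanks map to genome and plasmid
through the same internal matcher (band 16, enough for nanopore-scale
indel drift across a 400-nt flank); origin goes to the strictly higher
score, with **ties left unassigned** (conservative) and the junction
coordinate extrapolated to the flank's junction-adjacent end. Site
coordinates are reported as the start of the 11-nt top-strand site.
Junctions within 5 bp merge (single linkage); the representative is the
modal coordinate, ties to the leftmost; per-read duplicates of the same
(read, coordinate) count once.

A supporting read counts as *clipped* when > 20% of its genome flank is
unaligned; a site's clipped fraction is the share of such reads. The two
exclusion rules are conjunctive — rule 1: frequency
< 1% AND Levenshtein > 2 from both 11-nt target and donor AND clipped
fraction > 25%; rule 2: frequency < 1% AND distance > 2 AND the identical
coordinate present in another sample at > 1% with distance < 3 there.
Excluded sites stay in the output with flags. The k-mer analysis reports,
per 14-nt off-target, the maximum k with a k-mer shared with target or
donor, against a null of 1,000 per-sequence character shuffles (empirical
p = fraction of shuffle means ≥ the observed mean). REP annotation uses
the three known REP consensus queries at ≥ 80% identity over ≥ 90% coverage,
merged, with ±5 nt slop around site coordinates. Downsampling interprets
depth as base coverage (reads × length / genome size).

## Screen quantification

CPM_k = 10⁶·count_k/Σcounts per replicate; replicates are averaged
arithmetically; factor_k = (10⁶/K)/control_CPM_k so that factor·control
CPM is exactly 10⁶/K; corrected CPM = recombinant CPM × factor. Keys with
zero control CPM are dropped and logged. "Efficiency" of a key means its
replicate-averaged corrected recombinant CPM. Barcode assignment tolerates
one mismatch and requires the design's pairwise Hamming ≥ 3 (verified
before counting); UMIs map to an oligo when ≥ 90% of their reads agree on
the variable fields, otherwise they are dropped as conflicted. Mismatch
tolerance ranks each 4×4 set by its maximum member, keeps the top quintile
(boundary ties included), converts each set to percent-of-set CPM and
averages per position; corrected CPM is used for both ranking and display.
Enrichment is log2(top-quintile frequency / whole-set frequency) over
mismatch-free pairs with a single shared pseudocount floor of 0.5/n_top,
which pins positions that are invariant in the library to exactly 0.

## Motif consensus

Groups are keyed by exact (LTG, RTG) after three filters: gap-free guides,
guides that encode the CT core, and **more than 20** member sites (i.e.
≥ 21, reading the cutoff literally). Consensus is the modal base per
position, ties written N; concordance counts positions where consensus and
guide-encoded site differ, N matching anything. Greedy clustering
(identity ≥ 0.8, mutual coverage ≥ 0.8) processes sequences longest-first
with lexicographic tie-breaks, so it is deterministic for a given input
set.

## Synthetic data: what it emulates, and what it does not

* **Orthologue families**: rows descend from one ancestor; each guide/
  partner pairing unit co-substitutes (pairing preserved) with probability
  `coupling` per unit, with one substitution event at `sub_rate`;
  otherwise all members drift independently at `sub_rate`. Core DNA
  positions couple to *both* adjacent guide ends. Expected pairing
  concordance is coupling + (1−coupling)·((1−s)² + s²/3), which the
  generator reproduces. Defaults (500 orthologues, coupling 0.9,
  sub_rate 0.2, 70-nt RNA, 50-nt windows) give planted signal comparable
  to a few-thousand-row natural family. Not emulated: alignment gaps and
  misalignment, phylogenetic correlation between rows (rows are i.i.d.
  given the ancestor), indels, GC skew. Passing recovery tests therefore
  demonstrates the statistics, not robustness to alignment error.
* **Junction reads**: `depth` junction-spanning reads (the quantity the
  frequency estimates see) plus genome-only background reads; flanks
  150–400 nt; errors 3%/2%/2% substitution/insertion/deletion,
  independent per base. Not emulated: signal-level artifacts, chimeras,
  PCR duplicates, homopolymer-specific error. At these error rates a
  20-mer survives intact in ~45% of reads, so junction detection thins
  reads without biasing site frequencies (independent thinning).
* **Screens**: control weights are log-normal (σ = 0.5) around uniform
  (the real library skew is empirical); recombinant weights are control ×
  planted efficiency (per-set log-normal scale × per-position penalties,
  log-uniform on [0.03, 0.5] × optional nucleotide preferences × core
  penalty 0.02); counts are multinomial at 10⁶ per replicate. The
  null-enrichment check uses 10,000 matched pairs so that composition
  sampling noise sits well below the 0.2 log2 bound being asserted.
* **Boundary sets**: one ancestral element (800 nt, CT core, CDS interval)
  copied into each locus with ≤ 6% substitution divergence (terminal 20 nt
  and core kept exact); flank bases adjacent to the junctions are adjusted
  so the planted core is the *maximal* junction repeat, making boundaries
  and core unambiguous ground truth. Decoys carry a discordant core or
  pure random sequence.

A single global seed fans out to per-stage streams by CRC-hashing the
stage name, so stages are independently reproducible; fixed seed means
byte-identical files.

## Numerical and scale choices

Concordance and its row-permutation null are computed as one-hot matrix
products (float32 accumulation, float64 moments), making 1,000
permutations on a 300 × (70 × 50) family a ~1 s operation; the column null
reuses the observed matrix by gathering permuted column indices. The
internal seed-and-extend matcher anchors on exact k-mers (k ≥ 8) and runs
a banded local Smith–Waterman (+1/−1/−2, band 8 by default) around each
anchor diagonal: for gap-free optima containing an exact k-mer it is exact
with respect to full Smith–Waterman, which the test suite verifies
directly. Edit distances use edlib, cross-checked against a DP oracle.
Problem sizes in the test and acceptance runs (500-orthologue families, 20
calibration seeds, 100-kb genome at 500 junction reads, ~3,000-oligo
screens at 10⁶ reads, 20-locus boundary sets) were chosen as the smallest
scales at which the planted effects are statistically unambiguous.

## Known limitations

* The MI+APC covariation score is a generic coevolution statistic; on
  natural alignments with strong phylogenetic structure it is noisier than
  a pseudo-likelihood model — use the external-matrix adapter for parity
  with such tools.
* Pre-insertion discovery assumes breakpoints recoverable by flank
  alignment; heavily degraded junctions fall back to a loose repeat search
  whose shifted placements are only locally consistent (an inherent
  ambiguity when the true core region carries chance repeats).
* The insertion caller reports top-strand site-start coordinates and
  infers orientation from flank strand; nested or multi-copy insertions
  in one read are emitted as independent junctions.
* `build_umi_map` requires fixed-length amplicons matching the template;
  length-variant reads are skipped and counted rather than realigned.
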