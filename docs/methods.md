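# Methods

This note documents the models and numerical choices behind nlrkit, the
defaults and why they were chosen, and what the synthetic benchmarks do
and do not demonstrate.

## Profile HMM

A domain family is modelled by `L` match states with per-state emission
distributions over the 20 amino acids, insert states emitting at
background frequency, and delete states. Transitions follow the
plan7-style topology (M→M/I/D, I→M/I, D→M/D). Probabilities are
estimated from a seed alignment:

- **Match columns.** Alignment columns with gap fraction ≤ 0.5
  (configurable) become match states — the standard occupancy heuristic.
  A manual curation step (inspecting each candidate in an interactive
  domain browser) is not reproducible; `select_conserved_block` offers
  an objective substitute that keeps the longest contiguous run of
  well-occupied columns.
- **Emissions.** Per-column residue counts with uniform sequence
  weights, smoothed by `pseudocount_weight` (default 1.0) × the
  background vector. Unknown residues (`X`) are ignored in counting and
  score at exactly background (zero bits) during search. Full
  Dirichlet-mixture priors are deliberately out of scope; with typical
  seed alignments of ~10–30 sequences the single background pseudocount
  is adequate and much easier to reason about.
- **Transitions.** Counted from each row's implied state path
  (leading/trailing deletes and flanking inserts are trimmed, matching
  the local model) with Laplace smoothing of `transition_pseudocount`
  per move. The default is 1.0; the synthetic domain library uses 0.2
  because with only 10 seed rows add-one smoothing implies implausibly
  indel-prone domains — short repeats (LRR, 24 residues) sampled from
  such a model occasionally score near the detection threshold even
  noise-free.
- **Local entry/exit.** Entry is uniform (1/L) over match states. Exit
  from state k (0-indexed) has probability 1/(L−k), which makes the
  exit point uniform given the entry point while keeping every outgoing
  distribution a proper probability distribution — the simplest local
  model with exact normalization. Paths may enter the final delete
  state but cannot terminate there; the DP excludes them (a negligible
  probability leak, acceptable for scoring).

Scores are log₂-odds ("bits") of the local alignment against an i.i.d.
background; residues outside the aligned span contribute zero.
Viterbi (best path) and forward (all paths, `logaddexp2`) are exact
dynamic programs; both are verified bit-exactly against brute-force
path enumeration on small profiles. The delete-state recursion is
vectorized with prefix sums when all D→D transitions are finite, and
falls back to an explicit loop for degenerate hand-built models.

## Significance calibration

hmmer-style E-value theory is not reproduced. Instead, each profile is
calibrated empirically: `n_shuffles` (default 500, min 100) random
background sequences with lengths drawn from a configurable
distribution are scored, and a Gumbel (type-I extreme value)
distribution is fitted by the method of moments (scale = s·√6/π,
location = mean − γ·scale). The detection threshold is the score at
fitted tail probability `alpha` (default 10⁻³); each reported hit also
carries its fitted exceedance probability. One fit covers the
configured length range — a deliberate simplification; calibrate with a
length distribution matching the proteome for best accuracy. If the
null scores are (near-)constant the threshold falls back to
max(null) + 1 bit with a warning.

Multi-copy domains are found by iterative mask-and-rescan: take the
best significant hit, mask its span, rescan the unmasked segments.
This is an approximation to a full multi-domain dynamic program but is
exact for non-overlapping instances separated by any linker, which is
the regime tandem LRR counting needs.

## Architecture grammar

Per protein, hits are overlap-resolved greedily by descending bit score
(ties: earlier start, earlier end, model name); a candidate overlapping
an accepted hit by more than `max_overlap_frac` (default 0.5) of the
shorter span is dropped, smaller overlaps are kept and flagged. The
greedy rule selects, among all subsets satisfying the pairwise
constraint, the one whose descending score vector is lexicographically
maximal — the property the exhaustive-subset oracle in the tests
checks.

Classification relative to the most N-terminal NACHT hit: ≥ 1 LRR
C-terminal of it makes the gene bona fide (CARD anywhere N-terminal →
NLRC, else DEATH → NLRD, else NLRX); a NACHT with other recognized
domains but no C-terminal LRR is `NACHT_OTHER`; a bare NACHT is
`NACHT_ONLY`. CARD takes precedence over DEATH when both are
N-terminal (the categories must be mutually exclusive and no tiebreak
is standard; the choice is flagged in the output for audit). Multiple
NACHT hits are flagged. All LRR-family profiles (LRR_1…LRR_6
equivalents) collapse to one `LRR` token for the grammar; the hit table
keeps the distinct models. The grammar is total: every token string
maps to exactly one category.

LRR-repeat bins default to 2–4, 7–22 and 15–30 repeats — the repeat
count clusters observed among sponge NLRX genes; bins may overlap and a
gene lands in every bin containing its count.

## Genome map

Clusters are maximal same-chromosome, same-category runs of genes with
consecutive gaps ≤ `max_gap_bp` and size ≥ `min_size`. The defaults
(100 kb, 2) quantify "close together on the chromosome"; no standard
distance exists, so both are config-exposed. The gap is
`next.start − prev.end − 1`, floored at zero for overlapping spans.

Near-duplicate detection aligns protein pairs globally
(Needleman–Wunsch via Biopython's `PairwiseAligner`, BLOSUM62, gap open
−11 / extend −1). Identity = identical columns / total alignment
columns × 100 (gap columns count in the denominator), reported to
0.1%; the computation is protein-level, which matters when comparing
against nucleotide-level similarity figures. Co-optimal alignments are
disambiguated by canonical argument ordering so identity is symmetric.

## Phylogeny

The tree pipeline is distance-based by design: maximum-likelihood
search is heavy machinery orthogonal to the annotation method, and the
alignment can be exported in relaxed PHYLIP for external ML tools.

- **Alignment.** Progressive: UPGMA guide tree on 3-mer set distances,
  profile–profile Needleman–Wunsch merges scored by mean sum-of-pairs
  (BLOSUM62; residue-vs-gap pairs cost the gap penalty −4, gap–gap
  zero; the gap-move cost scales with column occupancy so merges
  optimize the same objective the final alignment is judged by).
  Deterministic tie rule: diagonal over up over left.
- **Distances.** p-distance over mutually ungapped columns, optionally
  Poisson-corrected (d = −ln(1−p)). Saturated pairs are capped at
  p = 1 − 0.5/(comparable columns) so bootstrap replicates of highly
  diverged pairs remain finite; pairs sharing no ungapped column are an
  error.
- **Neighbor joining.** Canonical Saitou–Nei with the Q-criterion.
  Ties resolve to the lexicographically smallest label pair, so results
  are reproducible. A negative branch length is clamped to zero with
  the deficit moved to its sibling (pair sum preserved). NJ recovers
  any additive matrix exactly (tested on random 4–12 leaf trees and
  cross-checked against an independent NJ implementation).
- **Bootstrap.** Column resampling with replacement, default 100
  replicates; support of each internal edge of the point tree is the
  percentage of replicates containing the same bipartition, stored as
  the internal node label. Trees are unrooted; outgroup rooting is
  display-only.
- **Grouping statistic.** Fraction of leaves whose nearest leaf (tree
  path length) shares an attribute (species or category). Ties break
  toward non-matching, making the statistic conservative: a clade of
  equidistant mixed-attribute leaves never counts as grouped.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
multi-domain proteins are concatenations of profile-sampled domain
instances joined by uniform background linkers (length 5–25 residues by
default), with i.i.d. substitution noise applied to domain residues
(default benchmark level 5%, one knob controlling detection
difficulty); decoys are i.i.d. background sequences length-matched to
the plants; the default background is uniform 1/20 with a hook for
empirical frequencies. The emulated domain lengths (NACHT 60, CARD and
DEATH 45, LRR 24, WD40 40 residues, etc.) are desk-scale stand-ins
chosen to preserve the relative detectability of long vs. short
domains. Genome layouts place genes uniformly on 15 chromosomes of
5 Mb (gene span 3 bp per residue, no introns), with cluster specs
pinning chosen same-category genes inside a stated window. Everything
is byte-reproducible from (config, seed).

What passing the benchmarks shows: the search is calibrated (decoy
false-hit rate ≈ alpha), sensitive at 5% divergence, and the grammar,
cluster, duplicate and phylogeny machinery are exact or near-exact on
data satisfying their assumptions. What it does not show: performance
on real proteomes, where domain families have informative residue
composition, repeats diverge much further, gene models are fragmented,
and background composition is not i.i.d. — the calibration hook
(empirical backgrounds, user seed alignments) exists precisely because
those differences matter.

## Benchmark problem sizes

The standard benchmark battery uses 100 planted architectures plus 100
decoys at 5% noise for recovery, 2000 decoys for calibration, 100
random trees (4–12 leaves) for NJ recovery, a 12-leaf × 500-column
alignment with per-branch substitution probability 0.05 and 100
bootstrap replicates for support behaviour, 100 mutation seeds for
duplicate identity, and 200 random layouts for cluster detection —
sizes at which the measured rates are stable to a few percent while the
full battery completes in minutes on one core.

## Known limitations

- Iterative mask-and-rescan can in principle split a single true domain
  into two flanking hits when an internal segment is masked first; not
  observed with the default linker regime.
- The Gumbel fit uses moments, not maximum likelihood; at very small
  alpha (≪ 10⁻⁴) the threshold inherits the moment estimator's tail
  error.
- Progressive alignment has no optimality guarantee; the guide tree
  only orders merges.
- The repertoire counts follow the independent-per-domain convention (a
  gene may contribute to several domain columns); they are not a
  partition of the gene set.
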