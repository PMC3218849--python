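# Methods

## Scope and data model

The package analyses band-level karyotype records. A record is one
clone: an identifier, a case (patient) identifier, a clone index, an
ISCN string, a tumor class label and a selected/unselected flag. CGH
input is a table of gained/lost segments named by start and end bands.
Aberrations are identified by event kind plus band-level locations
(`+8`, `-7`, `t(9;22)(q34;q11)`, `del(5)(q13q33)`, …); sub-band
resolution is truncated (`q34.1` → `q34`) because identity is defined at
band level.

## ISCN subset

The parser accepts: modal count (a range such as `46-48` takes the
first value — the convention is not standardised, so a deterministic
choice is documented here), sex designation, `+N`/`-N`, `t()()`,
`del()()`, `dup()()`, `i()()`, `inv()()`, and `der()` composed of listed
translocations. Uncertainty markers (`?`), `mar`, `inc`, `add` and any
unrecognised token set `well_defined = False`; a malformed modal count
sets `valid = False`. No parse failure raises: all defects are flags so
the filter cascade can report per-reason exclusion counts. Records that
are invalid or not well-defined are excluded from analysis, mirroring
how registry analyses drop partially characterised karyotypes rather
than guessing at them.

## Filter cascade

Fixed order, idempotent, each stage reporting (n_in, n_out, reasons):

1. **unselected** — records flagged as selected (reported *because* of
   their karyotype) are removed to avoid frequency bias; a bypass flag
   re-admits them for robustness runs;
2. **parse validity** — invalid / not-well-defined records out;
3. **clone/case dedupe** — per case, the first (lowest clone index)
   surviving clone is kept, removing within-patient dependence;
4. **near-diploid** — keep 35 ≤ modal count ≤ 57 (inclusive survival of
   35 and 57; the exclusion statement uses strict <35 and >57);
5. **class size** — classes with fewer than 50 karyotypes (default) are
   dropped with their records, after all other filters.

Whether near-diploid filtering precedes or follows case dedupe is not
fixed by any constraint we know of; this order follows the narrative
order of the source procedures and is pinned by tests.

## Event vocabulary and reconstruction

The greedy reconstructor undoes one event at a time, always choosing
the lowest-rank (simplest) applicable undo, until the state is the
normal karyotype. Gains and losses move the modal count by ±1; every
undo removes one abnormality token, so progress is monotone and
termination guaranteed. The 11-kind default vocabulary and ranking —

rank 0: whole-chromosome gain, whole-chromosome loss;
rank 1: reciprocal translocation;
rank 2: terminal deletion, interstitial deletion, tandem duplication;
rank 3: isochromosome;
rank 4: paracentric inversion, pericentric inversion;
rank 5: derivative-resolved translocation, three-break rearrangement

— is a documented assumption: the exact historical list and its
tie-breaking are not available to us, so the vocabulary is configurable
and only this default is pinned by tests. A derivative chromosome
written as `der(C)t(...)` contributes its constituent translocation
events, deduplicated so that a reciprocal pair of derivatives counts as
one event. An n-break translocation (n ≥ 3) is decomposed into n−1
two-break translocations sharing bands.

A reconstruction is **ambiguous** when (a) the final modal count does
not return to 46, or (b) a gain and a loss of the same chromosome
compete at equal rank (the pair could equally be a net no-op). Ambiguous
karyotypes are excluded from all downstream statistics. Soundness is
enforced by tests: replaying the reconstructed events forward from
46,XX/XY must regenerate the observed tokens and modal count exactly.

## Permutation null

All co-occurrence statistics share one null: binary matrices with the
observed row sums, column sums and per-stratum row sums, sampled
uniformly by checkerboard swaps (pick two rows and two columns within
one stratum; flip `10/01 ↔ 01/10` when present). Because strata
factorise the constraint set, within-stratum swaps connect the whole
space, and the test suite checks uniformity of visit counts against
exhaustive enumeration on small matrices (chi-square) and exactness of
margin conservation on large ones.

Chain schedule (configurable, logged): burn-in = 10 × (number of ones)
*accepted* swaps, spacing = 2 × (number of ones) *attempted* swaps
between samples — standard swap-randomisation mixing heuristics. The
p-value is r/N with floor 1/N when r = 0; we deliberately follow that
convention rather than (r+1)/(N+1), because the floor rule is what the
reported minimum p-value of 1/N encodes. Exceedance is ≥, so ties count
against significance. The kernel is numba-compiled; one chain serves
all candidate pairs of a fit.

Two degeneracies worth knowing about:

* pruning the matrix to the rows appearing in candidate pairs (done
  before permutation, as specified for the karyotype test) can make a
  *very* small matrix over-constrained — e.g. with only two rows, every
  column of sum 2 is frozen and the pair's count is invariant (p = 1 is
  then the exact answer). With realistic row counts this does not
  occur.
* a matrix with no legal swap (e.g. all ones) never moves; every sample
  ties and p = 1, which is again exact.

## Tests and corrections

* Enrichment: one-sided hypergeometric over-representation tail,
  exact (scipy), validated against brute-force draw enumeration for all
  parameter combinations with M ≤ 12. Depletion is out of scope.
* FDR = Benjamini–Hochberg (the procedure behind a stated "FDR" level
  is assumed to be BH; documented assumption). Bonferroni: adjusted
  = min(1, p·m).
* Correction families: enrichment over all observed aberration–class
  pairs; the karyotype pair test Bonferroni over the prefilter
  survivors; the CGH pair test BH over all co-occurring pairs.
* Confusion metrics: sensitivity, specificity, PPV and
  F = 2·PPV·Sens/(PPV+Sens); zero-denominator ratios are reported as 0
  with an `undefined` flag rather than NaN.

## Class similarity and clustering

M_t[Ab, C] = 1 iff the enrichment p of Ab in C is ≤ t (t = 0.05
default; an FDR-selected variant is available). The class-pair
statistic is the shared t-correlative aberration count under the
unstratified swap null (N = 10⁷ by default; test suites use reduced N —
the floor rule is unchanged). S[C1,C2] = −log p, S[C,C] = log N; p = 1
contributes 0 with no pseudocount. Classes with no FDR-significant
partner are removed, then average-linkage clustering runs on
1 − Pearson(S rows), the pair's own entries included as ordinary
coordinates (no masking). The log base of S is a global positive
rescaling under which Pearson correlation is exactly invariant, so the
clustering computes it once on the natural-log S — merge order is
base-independent by construction. Ties follow scipy's deterministic
lowest-index convention. A retained class whose S row is constant has
undefined correlation and is treated as uncorrelated. The dendrogram is
exported as Newick.

## CGH calling

The centromere is delimited by the p10/q10 bands. A segment spans it
iff its inclusive band interval (resolved against the cytoband model)
contains at least one p-arm and one q-arm band; such segments become
whole-chromosome calls, arm-internal segments are ignored, duplicate
calls collapse. Acrocentric p arms get no special-casing. The shipped
default cytoband model is a synthetic band ladder (bands p15…p10,
q10…q26 per chromosome) because only arm membership and order are
consumed; a loader for UCSC-style cytoband tables is provided for real
data.

## Trisomy index

Hyperdiploid MM ground truth: modal count 48–74 inclusive. A TI-T with
chromosome set and threshold k predicts H-MM when ≥ k of the set are
gained; a tetrasomy satisfies the criterion (presence of the gain
aberration is all that is asked). The default search pool
{3,5,7,9,11,15,19} is the recurrent H-MM gain set, with set size 3 and
k ∈ {1,2,3}; the full autosome pool is available by flag. Ranking is by
F-score with deterministic tie-breaks (specificity, then lexicographic
chromosomes, then k). Sensitivity is non-increasing and specificity
non-decreasing in k (tested).

## Synthetic study conditions

The generator is the package's test bed and defines its default study
conditions:

* **Default cohort** — 1,200 core karyotypes in 6 classes across the
  four categories (260/180/300/200/160/100); one gain block of 8
  trisomies at base frequency 0.08 and one loss block of 5 monosomies at
  0.07, both with within-block multiplier 6 and activation probability
  1/6; class-specific structural aberrations (translocations, deletions,
  isochromosome, inversions at 0.04–0.18) and rare independent
  background events. Contamination: 8% selected-flagged, 5% unparsable,
  4% non-near-diploid, 5% extra clones on existing cases.
* **Block planting** is a latent-indicator construction: one activation
  coin per block per karyotype; active members occur at multiplier ×
  base, inactive members at a compensating lower rate, so the marginal
  frequency is exactly the base value and the joint distribution is
  analytically known. Multiplier 1 gives exact independence — the
  type-I-control condition. Infeasible (probability > 1) combinations
  are rejected at config validation.
* **Aberration counts per karyotype** are a Poisson-binomial mixture
  over the latent activations, giving the over-dispersed, geometric-like
  tail of real registries without introducing co-occurrence outside the
  blocks (burst-style background draws would contaminate the null).
* **CGH cohort** — 400 samples, 5 planted gains (base 0.15) and 3
  losses (0.12), multiplier 4, activation 0.2, plus Poisson(1.2)
  arm-internal decoy segments per sample; roughly 60% of samples end up
  with non-empty call sets.
* **MM cohort** — 385 karyotypes, 29% hyperdiploid. Hyperdiploid
  records gain each of {9,15,19} with probability 0.8 and other
  autosomes at 0.06 (with at least two gains so the modal count reaches
  48); non-hyperdiploid records carry at most one stray trisomy
  (probability 0.25, tilted 4:1 toward the preference set) and a few
  losses. The stray-trisomy tilt is what makes k = 2 beat k = 1 on
  specificity, reproducing the structure of the published index.
* Generation is a pure function of (config, seed); identical inputs
  give byte-identical files.

What the generator does **not** emulate: breakpoint hotspots, clone
phylogenies, ploidy shifts beyond the near-diploid window, and the
long tail of rare structural variants. Passing tests demonstrate the
statistical machinery — margin-exact permutation, calibrated type-I
error, power against planted blocks — not fidelity to any real
registry's frequencies.

## Problem sizes and defaults in the shipped checks

The acceptance checks run the pair test at N = 4,000 permutations per
replicate (20 replicates per arm), the class test at N = 20,000, and
Monte-Carlo/enumeration comparisons at N = 100,000 on matrices small
enough to enumerate exhaustively; these sizes give Bonferroni/FDR
resolution comfortably below the decision thresholds while keeping a
full run around a minute. Production defaults remain N = 10⁶ (pair
test) and N = 10⁷ (class test).

## Known limitations

* The ISCN subset is deliberate: derivative algebra beyond composed
  translocations, ploidy-range normalisation and the full grammar are
  out of scope; such records are flagged and excluded, not guessed.
* The greedy reconstructor is not a minimum-event sorter; it mirrors
  the "undo the simplest step" heuristic and its ranking is an
  assumption (configurable).
* Monte-Carlo p-values at the 1/N floor understate significance for
  very strong pairs; N bounds the achievable resolution.
* The hypergeometric prefilter's universe is all karyotypes, not
  class-restricted (the candidate-pair count bookkeeping matches the
  all-karyotype reading).
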