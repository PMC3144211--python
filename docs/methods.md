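# Methods notes

## Model

`tmhseg` predicts transmembrane-helix (TMH) segments from sequence alone in
four stages.

1. **Index training.** Residues of annotated training proteins are split
   into a TMH pool and a non-TMH pool. For amino acid *i* the index is the
   log-ratio of pool frequencies, λ_i = ln(f_non,i / f_tmh,i), computed
   after adding a pseudocount (default 1) to every count so λ is always
   finite. The orientation makes helix-enriched residues negative, the same
   sign convention used by linker-propensity indices of the DomCut family.
   No mean/variance standardization is applied: the trained λ values are
   used raw in the per-residue products. Masked residues (`X` and other
   ambiguity codes under the default `mask` policy) are excluded from pool
   counts and from composition, and score 0.

2. **Per-residue scoring.** For a query sequence, position *j* scores
   I_j = AAC(a_j) · λ(a_j), where AAC is the amino-acid composition *of the
   query itself*, carried in percent (0–100). Both choices are forced by
   the published worked example (1LGH:B), whose printed composition values
   (15.556, 8.889, …) are exactly the query's percent composition.

3. **Smoothing.** A centered moving average of odd width *w*, truncated at
   the chain ends with the denominator equal to the number of included
   positions. Profiles for all odd *w* from `w_min` to `w_max` (defaults
   5 and 19) are fused by an unweighted mean, with an optional per-window
   weight hook. The published worked example fixes the truncated-mean
   convention (its rows for positions 2–5 divide by 4 and 5 included
   positions respectively); its first row is internally inconsistent with
   its own printed formula and is excluded from the test fixture. The cap
   of 19 matches the thickness of the bilayer's hydrocarbon core; the
   fusion rule and the lower bound 5 are configurable because only the
   upper bound is well determined.

4. **Segmentation.** Position *j* is transmembrane iff fused_j < t(j).
   The "below threshold" direction follows from the sign convention of λ.
   Maximal transmembrane runs shorter than `min_length` (default 5, about
   the shortest half-TM pore helix worth reporting; 1 disables filtering)
   are discarded. Nearby runs are not merged by default — splitting/joining
   is the threshold profile's job — though `merge_segments` exists as an
   explicit post-process.

## Piecewise thresholds and the GA

A single threshold cannot simultaneously separate helices joined by 1–3
residue loops and helices separated by long loops. The search object is a
chromosome: genes (t, u) with strictly increasing boundaries u, the last
equal to L; gene k applies threshold t_k to positions u_{k−1}+1 … u_k
(the boundary position itself belongs to its gene). Operators:

* **One-cut crossover** — parent A is cut after a uniformly drawn gene;
  parent B is cut before its first gene whose boundary exceeds A's cut
  boundary; suffixes are swapped. A repair pass drops genes whose boundary
  does not advance and re-pins the final boundary to L, so children are
  valid by construction.
* **Mutation** — each gene independently with probability p_m either
  shifts its threshold by up to `mutation_step` (clamped to
  `threshold_range`) or moves its boundary by up to `boundary_step`
  positions, clamped strictly between its neighbours; the last boundary
  never moves.
* **Selection and elitism** — fitness-proportional (roulette) parent
  selection; the `elite_count` fittest chromosomes are cloned into the next
  generation, which makes the best-so-far fitness non-decreasing.

Fitness is Q_AA, the fraction of correctly labeled residues, measured
against the protein's reference intervals. This mirrors the original
protocol, and it is circular for genuinely unknown proteins; the package
therefore exposes two modes: per-protein refinement (`mode="ga"`, the
benchmark protocol) and `fit_threshold_template`, which optimizes one
shared template (boundaries expressed on a virtual 100-position axis and
rescaled per protein) across an annotated training set, applicable to
unannotated queries.

Defaults: population 50, generations 100, p_crossover 0.8, p_mutation 0.1,
elite count 2, 2 genes at initialization (plus the single-gene threshold-0
baseline always seeded into the population), threshold range = fused
min/max padded by 5 %, mutation step = 10 % of that range, boundary step =
⌈L/20⌉. The original tuned values are not recoverable from the source
text, so these are the package's own choices, exposed in `GAConfig`.
`threshold_grid` / `boundary_grid` restrict the search to finite sets,
which makes the chromosome space enumerable; the test suite uses this to
verify that the GA attains the exhaustively enumerated optimum on a small
instance. All randomness flows from `rng_seed` through one
`numpy.random.Generator`, so results are bit-reproducible.

## Evaluation conventions

* A known helix counts as correctly predicted when a predicted segment
  overlaps it by at least `min_overlap` residues (default 9; 5 ≈ one
  helical turn). By default any predicted segment qualifies
  (`counting="overlap"`): this is the standard segment-recall convention,
  and the only one under which high Q_htm can coexist with moderate
  residue-level specificity — a prediction that runs through a very short
  loop still recovers both flanking helices. The stricter
  `counting="paired"` mode requires a greedy one-to-one pairing (by
  descending overlap, ties toward the leftmost known helix).
* N-/C-scores are always computed on the greedy one-to-one pairs and
  averaged over matched pairs; unmatched segments are reported as counts
  rather than folded into the mean.
* Q_p counts a protein as correct when all its known helices are correct;
  extra (false-positive) predictions do not break it unless
  `strict=True`. A protein with no known helices is vacuously correct
  unless strict.
* Sensitivity/specificity are pooled over the residues of all proteins by
  default (`per_protein=True` averages per-protein rates instead); an
  empty denominator yields `None`, never 0.
* Q_AA always equals (TP+TN)/(TP+TN+FP+FN); the test suite cross-checks
  the two computation paths.

## Synthetic data

The generator emulates the documented properties of the classic benchmark
sets, which are no longer hosted anywhere: proteins of ~50–500 residues
containing 1–14 helices, helix lengths from a discretized normal
(mean 21, sd 5, truncated to 5–40, covering half-TMs), loops geometric
with mean 12 and minimum 1 (so very short inter-helix connections occur
naturally), residues i.i.d. within each block. Helix blocks draw from a
composition placing 65 % of mass on A, I, L, V, F, M, W; loop blocks place
60 % on D, E, K, R, N, Q, S, P — round figures consistent with observed
enrichment in real TM helices vs. loops. A `contrast` knob interpolates
both toward uniform (0 = indistinguishable, useful as a negative control);
`hard_mode` forces about half of the inter-helix loops down to 1–3
residues, the regime that motivates piecewise thresholds.

What the generator does *not* emulate: helical periodicity and
amphipathicity, position-specific boundary signatures (aromatic belt,
positive-inside rule), sequence correlations, and real loop-length
tails. Passing the synthetic round-trip therefore demonstrates that the
estimator, optimizer and metrics are internally correct and that the
pipeline recovers planted architecture under compositional contrast — not
that the shipped defaults reach any particular accuracy on real proteins,
for which the index should be retrained on a current annotated set.

Under these conditions (train 40 proteins / test 20, seeds 1–5), GA-mode
prediction recovers ≥ 95 % of planted helices (≥ 9-residue overlap) with
residue accuracy ≥ 0.85; the suite asserts exactly this. The
fixed-threshold-0 baseline reaches only ~0.82 residue accuracy on the same
data because windows up to 19 smear short loops; the GA's advantage over
that baseline on `hard_mode` data is asserted over 20 replicate proteins.

## Numerical and degenerate-input choices

* Window averages use an exact full convolution with a centered slice, so
  windows wider than the sequence (allowed up to 2L−1) are handled
  correctly.
* Intervals are 1-based inclusive everywhere in memory; BED conversion
  happens only at file boundaries. Empty prediction lists serialize as an
  `id<TAB>.<TAB>.` sentinel so ids survive round trips.
* Index tables serialize at 17 significant digits (`%.17g`) and round-trip
  to better than 1e-12.
* `train_index` with pseudocount 0 refuses pools with zero counts rather
  than emitting infinite λ.
* Chromosome validity is enforced in the constructor, so any operator bug
  surfaces immediately rather than as a corrupt search state.
* Ties and tie-breaks: segment matching sorts candidates by descending
  overlap, then leftmost known, then leftmost predicted segment;
  `threshold_at` assigns a boundary position to the gene that ends on it.

## Problem sizes

The test suite and the worked-example script run on one CPU in well under
a minute of compute for the deterministic parts; the synthetic round-trip
and GA-superiority checks use 40/20-protein datasets and 20 replicate
proteins respectively, sizes at which the GA (50 × 100 fitness
evaluations per protein) completes in a few seconds per dataset while
leaving enough helices (~160 per test set) for stable pooled rates.

## Known limitations

* Membrane orientation (in/out topology) and signal-peptide discrimination
  are out of scope.
* The exact functional form of the published index is not recoverable from
  the source text; the log-ratio reproduces its sign structure but not
  necessarily its magnitudes, and the original training data are gone, so
  published benchmark figures are not reproducible desk-side.
* Per-protein GA refinement requires reference intervals; the template
  mode is the deployment path for unknown proteins and is weaker.
* The AAC factor ties a residue's score to global sequence composition:
  two proteins sharing a helix sequence can score it differently.
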