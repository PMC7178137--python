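# Methods

## Problem and model

Given a two-chain protein complex, the task is to predict which surface
residues of a chain belong to the binding interface, using only per-residue
evolutionary-conservation descriptors (no partner information at prediction
time). The pipeline has five stages: geometric labeling, window encoding,
re-balancing, boosted-tree classification, and six-measure evaluation.

## Geometric labeling

**ASA.** Accessible surface area is computed with the Shrake–Rupley
method: each atom's solvent-accessible sphere (van der Waals radius +
probe radius 1.4 Å) is sampled with 960 points and the exposed fraction
integrated. ProtOr van der Waals radii are used, with a per-element
fallback for atoms outside the ProtOr set. Both probe radius and point
count are configurable. ASA is computed on each chain in isolation
(monomer state): the pipeline defines surface residues *before* asking
which of them touch the partner, so residues occluded only by the partner
chain must keep their accessibility.

Two numerical caveats are deliberate:

- The sphere-point set is deterministic and globally oriented, so ASA is
  exactly invariant under translation but only approximately (≈ 1–2 % at
  960 points) invariant under rotation. Tests assert translation
  invariance at 1e-6 relative and rotation invariance at 2 %.
- The RASA reference (Tien et al. 2013 theoretical maxima, shipped as a
  swappable TSV) is defined for X in a Gly-X-Gly tripeptide. An isolated
  residue with no flanking peptide therefore has RASA > 1; the sparse
  synthetic fixtures exploit this (every residue is surface). RASA is not
  clamped.

**Surface.** RASA strictly greater than 0.16. The threshold is a
parameter; the strict inequality is part of the definition (exactly 16 %
is buried).

**Interface.** A surface residue is interface iff its distance to *any*
residue of the partner chain is ≤ 12 Å (only distances strictly beyond
1.2 nm make a residue non-interface). Two distance modes ship: `ca_ca`
(Cα–Cα, the default) and `min_carbon` (minimum over all carbon pairs),
because "distance between residue carbon atoms" admits both readings; the
mode is recorded in output headers. Residues lacking a Cα fall back to
their first carbon atom, logged. Buried residues are never interface.

Structure input: PDB, first model only, highest-occupancy altloc,
hydrogens and HETATM dropped except selenomethionine (MSE → MET, SE → SD).
Residues are keyed by (chain, author number, insertion code).

## Window encoding

Each residue's 24-dim descriptor is 20 profile frequencies (alphabetical
one-letter order, summing to 1) + information entropy + relative entropy +
sequence weight + conservation score. This 20+3+1 layout is declared in
the table header so alternative layouts remain loadable.

A sample is the concatenation of the target residue's descriptor and those
of its 10 nearest *surface* residues of the same chain by Cα Euclidean
distance, in increasing order, ties broken by ascending residue number
(determinism). Chains with fewer than 11 surface residues are zero-padded
and the pad count emitted per row so downstream users can filter. Windows
never cross chain boundaries. Raw feature values are preserved in the
sample matrix; standardization happens where it matters (below).

## Re-balancing

Both methods operate on z-scored copies of the features (column statistics
from the input set; zero-variance columns pass through) because profile
frequencies and entropies live on incommensurate scales; the returned
sample sets keep raw values.

**RENN.** k = 3 neighbours (configurable); a sample is marked when ≥ 2 of
its 3 nearest neighbours (self excluded, exact duplicates handled by index
not by distance) carry a different label; all marked samples are removed
*simultaneously* at the end of a sweep, so the result is independent of
sample order; sweeps repeat to a fixed point. The termination condition
makes the fixed point exact under a fixed metric: re-running on the output
with the same standardization removes nothing. Default
`target="negatives_only"` restricts removal to the majority class (the
minority class is never touched); `target="all"` is the literal editing
rule and is what the planted-overlap recovery experiments use. Emptying a
class raises rather than returning a degenerate set.

**IHT.** Instance hardness IH = 1 − p(y_i | x_i, h) with h a
logistic-regression estimator; probabilities are taken out-of-fold under a
stratified 5-fold split (default seed 42) so no sample is scored by a
model that saw it — the obvious in-sample alternative underestimates the
hardness of exactly the points IHT exists to find. Majority samples are
sorted by hardness descending (ties by provenance key, for determinism)
and the top N_maj − ⌈N_min · ratio⌉ removed; ratio 1.0 gives an exact 1:1
balance.

## Classification and cross-validation

XGBoost with the binary-logistic objective; the prediction for a sample is
the logistic link applied to the sum of its per-tree leaf values
(base_score pinned at 0.5, i.e. zero margin offset, so the additive
contract is exact and testable by walking the dumped trees). The reference
protocol reports no hyperparameters, so the defaults — K = 200 trees,
learning rate 0.1, depth 4, λ = 1, γ = 0, threshold 0.5, seed 42 — are
package choices, all in `BoostedModelConfig` and serialisable to JSON.

Folds are stratified by a round-robin assignment within each class with a
continuing counter, which guarantees both overall and per-class fold sizes
differ by at most one; the assignment is a partition for every seed.

Two CV × resampling orders ship because the historical protocol is
ambiguous and the natural reading leaks: `resample_then_split` resamples
the full dataset once and folds its output (this reproduces whole-dataset
balanced counts, but held-out samples influenced the resampling — a
warning is logged, and with IHT it also means the evaluated pool has had
its hardest negatives removed, flattering every measure);
`split_then_resample` (the recommendation) resamples the nine training
folds inside each round and evaluates on untouched test folds. Pooled
confusion matrices accumulate all held-out predictions, so pooled TP+FN
equals total positives exactly; per-fold metrics and their mean are
reported alongside.

## Evaluation

Acc, Sen, Pre, Spe, F (harmonic mean of Pre and Sen), MCC — the closed
forms on TP/TN/FP/FN. A zero denominator yields a 0.0 sentinel plus a flag
rather than an exception, so one degenerate fold cannot abort a run; the
all-zero matrix is an error. Reports carry full precision and 3-decimal
rounding. Pooled-over-folds is the primary aggregation (it reproduces the
reference worked arithmetic exactly); the per-fold mean is emitted
alongside for comparison.

## Synthetic data: what it emulates, and what it does not

**Structures.** Two poly-alanine chains with Cα atoms on parallel lines
(20 Å spacing, 30 Å gap by default); requested contact pairs are realised
by relocating the chain-B residue opposite its partner at 8 Å. The
generator brute-force-verifies that the emitted coordinates realise
*exactly* the requested Cα contact set at 12 Å and raises on any
contradictory request. The wide spacing makes every residue
solvent-exposed, so surface labeling is trivially known. These fixtures
exercise parsing, ASA, thresholding and interface geometry — not packing,
secondary structure, or realistic interface shapes.

**Samples.** Two isotropic Gaussian clouds in feature space at an
imbalance of 300 positives to 1100 negatives (the ≈ 3.6 : 1 ratio of the
reference corpus), of which 100 negatives are *planted*: drawn from the
positive-class distribution but labeled negative. The planted points model
the overlap hypothesis — the geometric surface/interface definitions are
hard thresholds, so many negatives are functionally indistinguishable from
positives — and, because they are known, resamplers can be scored by
parameter recovery (fraction of planted negatives removed vs clean
negatives sacrificed) instead of only by downstream metrics.

The class-contrast direction alternates sign across the 20 profile
positions and is uniform across the 4 scalar features: interface residues
differ in residue *composition*, and a softmax (applied per profile block
so rows satisfy the sum-to-one invariant) cancels any uniform logit shift,
so a composition contrast is the only kind that survives normalisation.

The free parameters — class-mean separation 4.0 (in units of the
within-class spread, raw space) and spread 1.0 — were fixed once, by a
small design study, to place the generator in the qualitative regime
observed on the real corpus: an unbalanced baseline that is majority-biased
(depressed sensitivity, specificity near 1) although the classes are
separable enough that clean class cores are k-NN-consistent. At these
settings, averaged over five seeds: RENN (target=all) removes ≈ 79 % of
planted negatives and ≈ 4 % of clean negatives; per-fold IHT balancing
raises pooled CV sensitivity by ≈ 0.27 while pooled specificity drops by
≈ 0.12.

What passing these tests does *not* show: real conservation features are
not Gaussian, not isotropic, and not i.i.d. across window positions;
real overlap is not a clean two-population mixture; and absolute metric
values on synthetic data say nothing about attainable performance on real
complexes. The synthetic results validate the *mechanics* (the algorithms
remove what they should, the protocol measures what it should), not the
biology.

## Numerical and design choices

- Distances and coordinates are Å internally; the CLI accepts the
  interface cutoff in nm and converts.
- Neighbour searches use exact pairwise distances (the problem sizes are
  hundreds of surface residues per chain); all tie-breaks are by residue
  number or provenance key, never by input order.
- Test-suite and acceptance problem sizes (1,400-sample scenarios,
  ≤ 50-point oracle instances, 40-residue structure fixtures, K ≤ 200
  trees) are chosen so the full suite runs in well under a minute while
  keeping every statistical margin comfortable at five seeds.
- Sample tables are dense TSV: at ~10⁴ rows × 264 columns a sparse
  container buys nothing.

## Known limitations

- Only the first NMR model is read; no symmetry mates are generated.
- RASA normalisation recovers no experimental consensus; a different
  max-ASA table shifts the surface set and is therefore swappable.
- The RENN fixed point is exact under a fixed metric; if the z-scoring is
  re-estimated on the edited output, the metric itself shifts slightly and
  a further sweep can in principle remove additional points.
- `resample_then_split` is provided for protocol fidelity only; its
  metrics are optimistic by construction and should not be compared
  against externally validated predictors.
- The conservation descriptors are taken as given; computing profiles
  from alignments, or querying conservation servers, is out of scope.
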