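# Methods

## Problem and coordinates

Calpain cleaves substrate proteins at specific peptide bonds. A cleavage
site is addressed by its bond index *i* (1-based): the bond between residue
*i* (position P1) and residue *i+1* (P1′). A window specification
`WindowSpec(left, right)` covers `left` P-side residues (…P2, P1) and
`right` P′-side residues (P1′, P2′…), so the window length is
`left + right`. Windows that run past a sequence terminus are padded with
neutral symbols — `X` (unknown residue) for sequence, `C` (coil) for
secondary structure, `B` (buried) for accessibility — rather than
discarded, because near-terminal sites are too valuable to drop from small
substrate collections. `X` encodes as an all-zero one-hot block and never
matches in the string/spectrum kernels, so sequence padding cannot create
similarity; the `C`/`B` pads are ordinary track symbols.

Secondary-structure and accessibility tracks are *inputs*: in production
they come from upstream predictors (e.g. PSIPRED-style 3-class SS and a
25%-threshold accessibility call); the synthetic generator stands in for
those predictors during testing.

## Training-set construction

Every annotated bond contributes one positive instance. Negatives are drawn
uniformly without replacement from the pool of all other internal bonds,
pooled across substrates, at a 10:1 negative:positive ratio (the
convention for this problem; configurable). No exclusion buffer is applied
around true sites. Instances store windows cut at the elementwise maximum
of all sub-kernel window specs; each sub-kernel re-cuts its own slice, so
per-kernel window lengths can be optimized independently.

Redundancy filtering is a greedy first-kept-wins pass in input order: a
substrate is kept only if its global-alignment identity (matches divided by
alignment length, scored match=1/mismatch=0/gap=−1) to every kept substrate
is ≤ 0.95. Greedy-in-order makes the filter deterministic and idempotent;
alignment is delegated to Biopython's `PairwiseAligner`.

## Kernels

* `linear`/`rbf` operate on one-hot encodings (alphabet-sized binary block
  per position; 20 for sequence, 3 for SS, 2 for SA). The RBF convention is
  `exp(−‖x−y‖²/(2σ²))`.
* `string` counts identical k-mers at identical offsets for k = 1..d, all
  lengths weighted equally. On X-free identical strings of length L it
  equals Σₖ (L−k+1); at d = 1 it coincides with the linear kernel on
  encodings.
* `spectrum` is the inner product of gapped-pattern occurrence profiles: for
  every pattern length m ≤ d′ and every choice of up to g interior wildcard
  positions (never the first or last position; m ≤ 2 admits none), each
  wildcard placement is a distinct feature, counted at every start
  position. At d′ = 1, g = 0 it reduces to the residue-composition dot
  product. Gram matrices are computed through explicit sparse feature maps
  (per-window feature dictionaries stacked into CSR and multiplied), which
  is exactly equivalent to the pairwise definition and fast enough for a
  few thousand instances.

Each sub-kernel matrix is cosine-normalized, K′(i,j) =
K(i,j)/√(K(i,i)K(j,j)), before combination; rows with zero self-similarity
get a unit diagonal and zero off-diagonals. Normalizing sub-kernels (rather
than the combined kernel) keeps the learned weights comparable across
kernels of very different scales. Queries at scoring time are normalized by
their own self-similarity under the same formula.

## MKL optimization

Weights β live on the probability simplex. We use the semi-infinite-LP
view: for fixed β, libsvm (scikit-learn `SVC`, precomputed kernel,
KKT tolerance 1e−6) solves the dual; the dual iterate contributes a cutting
plane `Σαᵢ − Σₖ βₖ Tₖ(α) ≤ θ` with Tₖ(α) = ½ (αy)ᵀKₖ(αy); the restricted
master LP (scipy HiGHS) proposes the next β. Because the raw cutting-plane
sequence need not be monotone, a halving line search between the incumbent
and the LP proposal accepts the first point that does not increase the
objective — the objective history is therefore non-increasing by
construction. Convergence is declared when the relative objective change
drops below 1e−4 (default), capped at 100 outer iterations; hitting the cap
returns the best iterate with a warning flag rather than raising.

Degeneracy: sub-kernels with identical Gram matrices make the optimal β
non-unique. We break the tie deterministically to maximum entropy — weights
are averaged within groups of identical matrices (which provably leaves the
combined kernel, and hence the objective, unchanged) and the SVM is
re-solved once at the symmetrized β.

Reported weights: internally β sums to 1; `display_weights` rescales so the
largest weight is 1, the common convention for printing MKL weight tables.

## Evaluation protocol

AUC is the Mann–Whitney statistic (ties count ½), via scikit-learn.
`cross_validate` runs `repeats` independent rounds of stratified k-fold CV
at the instance level (10×10 by default → 100 fold AUCs), re-sampling
negatives once per repeat with seed `seed + repeat`; the report carries all
fold AUCs, their mean and SEM = sd/√n. Instance-level splitting is the
default; `split_by_sequence=True` switches to grouped stratified folds so
windows from one substrate never straddle a fold boundary (guards against
homolog leakage, at the price of noisier folds on small sets). Folds that
lose a class are skipped and counted.

Configuration comparisons use a two-sample pooled-variance t-test on the
two fold-AUC lists of equal length. This follows the established practice
for this protocol even though CV folds are not independent samples —
fidelity to the protocol over statistical orthodoxy; interpret the p-values
accordingly. Two degenerate cases are defined explicitly: identical-mean
zero-variance lists give (0, 1), different-mean zero-variance give (±∞, 0).

Grid search enumerates integer parameters exhaustively (string order d,
spectrum d′ and g) and refines continuous ones (C, σ) in two stages — a
coarse log-spaced grid over the full range, then a fine linear grid around
the coarse optimum — selecting maximal mean CV AUC with ties broken toward
smaller values. Window optimization is coordinate descent: one sub-kernel's
(left, right) pair is grid-searched while the others are frozen, sweeping
until a full sweep improves the best AUC by < 1e−3 or 10 sweeps elapse;
the objective sequence is non-decreasing by construction. `window_sweep`
exports the full (left × right) AUC table for heat-map inspection.

## Scanner

`scan` evaluates the decision function at every internal bond (windows cut
at the model's stored spec with terminal padding), min-max normalizes the
profile per sequence (a constant profile maps to 0.5), and thresholds at
the top 5% of bonds. The threshold is placed just below the k-th largest
score, k = ceil(fraction·n), so at least one bond always qualifies and
scores tied with the k-th largest are all included. Normalization and the
threshold are per-sequence. Annotations on the scanned substrate are
ignored — scanning is pure prediction.

## Synthetic data

The generator emulates a curated substrate collection: uniform-background
residues; planted sites whose footprint residues are re-drawn from the
softmax of strength-scaled log-odds over the background; SS/SA tracks drawn
as geometric runs (mean ≈ 5 residues) from background frequencies
H/E/C = 0.35/0.20/0.45 and B/A = 0.55/0.45, with the footprint biased to
coil (probability 0.9) and exposed (0.8) — cleavage happens in accessible
loops. The default motif puts log-odds +1.5 on one preferred residue per
column: at the default strength 2.0 the modal residue reaches ≈ 51% per
column (the scale of real calpain sub-site preferences); at strength 5 it
reaches ≈ 99%, and strength 0 is exact background. Planted sites are
non-overlapping and their footprints always fit inside the sequence.

`default_curated_scale_config` encodes the isoform contrast of a curated
calpain set: a calpain-1-like subset (~46 sequences, ~94 sites, short
N-terminal footprint: left 6 / right 5) and a calpain-2-like subset (~49
sequences, ~114 sites, long footprint: left 14 / right 5); `all` is their
union (~95 sequences, ~215 sites).

What the generator does **not** model: real calpain motif content (PEST
regions, true position-specific preferences), homology between substrates,
realistic amino-acid composition, or errors in predicted SS/SA tracks.
Passing tests therefore demonstrate that the machinery recovers planted
signal of realistic shape and strength — not a performance claim on real
substrates.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run on reduced substrate sets
(15–30 sequences of 60–120 residues, 10×2 CV) chosen so the full pipeline —
generation, kernels, MKL, repeated CV, scanning — is exercised end to end
in seconds while leaving the planted signal comfortably detectable;
protocol constants (10:1 sampling, the 100-AUC 10×10 protocol) are
recomputed at their canonical values. Exhaustive kernel-oracle comparisons
cover the full short-string space and seeded random samples of longer
strings.

## Known limitations

* libsvm's KKT tolerance bounds the accuracy of α; dual objectives agree
  with a generic QP solve to ~1e−5, which is ample for AUC ranking but not
  for reproducing α bit-exactly across BLAS builds.
* ℓp-norm MKL (p > 1) is not implemented; β is ℓ1-simplex only.
* The spectrum kernel's gapped-pattern semantics (interior-only wildcards,
  each placement a distinct feature) is one concrete member of the gapped
  k-mer family; other published variants weight or collapse patterns
  differently.
* Instance-level CV mildly overestimates generalization to unseen
  substrates when homologs are present; use `split_by_sequence=True` for
  the conservative protocol.
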