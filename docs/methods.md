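# Methods

This note documents the statistical machinery implemented in `nnaaindex`,
the choices made where the procedures admit more than one convention, and
what the synthetic fixtures do and do not demonstrate.

## Scale derivation (`nnaaindex.scales`)

A property table (residues × physicochemical properties) is
column-standardized (n−1 variance) and its correlation matrix is
eigendecomposed.  The `m` leading components, scaled by the square roots of
their eigenvalues, form the unrotated loadings; communalities are their row
sums of squares and are invariant under all subsequent rotation.  The
explained-variance fraction is the sum of retained eigenvalues over the
number of properties.

Rotation is varimax with Kaiser row-normalization followed by a promax
oblique step: the varimax solution is raised elementwise to the promax power
(default 4, the common statistical-package default; the power is exposed
because reasonable analyses use 2–6) to form a simple-structure target, and
the least-squares oblique transform to that target is applied with columns
rescaled so the implied factor correlation matrix Φ = (UᵀU)⁻¹ has a unit
diagonal.  Power 1 leaves the varimax solution unchanged (Φ = I).  Both the
pattern matrix (regression coefficients, may exceed 1) and the structure
matrix (pattern × Φ) are reported, since published loading tables do not
always say which they print.

Two indeterminacies are resolved deterministically: factors keep the
descending-eigenvalue order of extraction, and each rotated factor is
flipped so its largest-|loading| entry is positive.

The varimax sweep uses the SVD-based algorithm of base R's `varimax`.  Its
plateau stopping rule (relative criterion increase < 1e−8) can keep creeping
indefinitely when the normalized loading rows form a few tight clusters (the
criterion landscape is then almost flat); in that case the rotation after
1000 sweeps is returned with a warning, matching base R's behaviour, rather
than raising.  The rotations were cross-checked against R `stats::varimax`
and `stats::promax` on identical inputs (agreement ~1e−4, limited by the
respective stopping rules).

Factor scores use the regression (Thurstone) estimator B = R⁻¹ S with S the
structure matrix, so scoring the training table yields exactly mean-zero
score columns; a Bartlett estimator is available behind a flag but is
ill-conditioned under principal-component extraction (uniquenesses near
zero are clipped at 1e−6).

The number of factors is an explicit argument; `eigenvalue_profile` reports
the full spectrum so users can apply scree/eigenvalue reasoning.  No
automatic selection is performed.

Known limitation: promax systematically shrinks moderate factor
correlations (a planted inter-factor correlation of 0.4 is typically
recovered as ≈0.30–0.33 even at large sample sizes); this is a property of
the promax target, not an implementation artifact, and R's promax behaves
identically.

## Peptide encoding (`nnaaindex.encoding`)

Sequences mix one-letter natural codes and numeric catalog identifiers for
non-natural residues.  Two dialects are parsed: compact (`TLTRV108W`, a
maximal digit run is one token) and hyphen-separated (`512-439`).  The
canonical rendering is hyphen-separated whenever a numeric token is present,
compact otherwise.  Natural codes are case-insensitive and normalized to
uppercase.  Numeric identifiers are opaque keys into the scale table; no
chemical meaning is attached.

A peptide of length L against an m-factor scale encodes to an m·L vector,
position-major (`pos1.f1 … pos1.fm, pos2.f1 …`), 1-based from the
N-terminus.  A dataset of equal-length peptides becomes an n × mL
descriptor matrix with stable row order.

## PLS regression (`nnaaindex.pls`)

Univariate-response NIPALS: X columns and y are autoscaled (centered, unit
n−1 variance — the convention most peptide-QSAR software uses, adopted here
as the default since the procedure is otherwise underdetermined), components
are extracted with weight vectors from the X–y covariance, and both blocks
are deflated per component.  The inner loop runs to tolerance 1e−12 (max
500 iterations) although with a univariate response it converges in one
pass.  The regression vector is folded back to the original scale, so
predictions are plain affine functions of raw descriptors and are invariant
to affine rescaling of any X column.

Q² follows the PRESS form: Q² = 1 − Σ(yᵢ − ŷ₍ᵢ₎)² / Σ(yᵢ − ȳ)², with ŷ₍ᵢ₎
from a full refit (including re-autoscaling) on the n−1 remaining samples
and ȳ the full-sample mean.  RMS is reported as √(SS/n): calibration
residuals for the calibration row, CV residuals for the CV row.  The LOO
loop is computed for all folds simultaneously with batched linear algebra;
a unit test verifies bit-level agreement with literal per-fold refits.
Zero-variance columns inside a fold are dropped for that fold with a
warning.

Component selection minimizes LOO PRESS over 1..A_max with ties to the
smaller count.  Note that this rule is greedy about even marginal PRESS
improvements: with independent noise columns alongside one informative
column it will legitimately select 4–6 components (later components remove
the chance-correlation contamination of the first weight vector), whereas
collinear descriptor blocks select 1–2.  Deeper selection is not an error
of the rule but a property of it.

At full rank, PLS equals OLS; this is used as an exact oracle in tests, and
fitted values are additionally cross-checked against scikit-learn's
`PLSRegression`.

## GA variable selection (`nnaaindex.gapls`)

Chromosomes are binary masks over descriptor columns.  Fitness is the LOO
Q² of a PLS model on the selected columns with the component count chosen
by minimal LOO PRESS (capped at `a_max`, default 3); evaluations are
memoized by mask.  Defaults follow the standard GA-PLS parameterization:
population 200, up to 200 generations, generation gap 0.8 (fraction of the
population replaced per generation), crossover probability 0.5, per-bit
mutation 0.005.  Unstated operators are filled with robust conventions:
linear-rank parent selection, uniform crossover (single-point available),
elitism (the best chromosome always survives), empty masks repaired by
switching one random bit on, and early stopping after 30 generations
without improvement (the 200-generation ceiling remains).  Runs are a pure
function of the seed.

## Stepwise LDA (`nnaaindex.lda`)

Forward stepwise selection with backward elimination on the partial-F
statistic from the Wilks' Λ ratio, F = (n−g−p)/(g−1) · (Λ_p/Λ_{p+1} − 1),
with the conventional thresholds F-to-enter 3.84 and F-to-remove 2.71.
Ties resolve to the lower column index.  Entry stops when separation is
already perfect (Λ ≈ 0) and when adding another variable would leave the
pooled within-class covariance rank-deficient in a leave-one-out refit
(p ≤ n − 4 for two classes) — a feasibility cap, not a tuning parameter.
With many candidate descriptors and few samples the fixed thresholds admit
chance variables (a multiple-testing effect inherent to the procedure);
users should treat large selections on small n as a warning sign.

The classifier is the two-class Fisher discriminant with pooled covariance,
equal priors by default (proportional available), coefficients reported raw
and standardized (scaled by pooled within-class standard deviations).  The
positive class for sensitivity is the biologically active one; by default
the lexicographically larger label, which makes "strong" positive against
"moderate".  LOO metrics by default keep the variable subset fixed at the
full-data selection and cross-validate only the discriminant fit
("paper" mode — on 20-sample datasets per-fold re-selection is too unstable
to characterize a single model); a "strict" mode re-selects per fold.  MCC
returns 0 when any confusion-matrix marginal is empty.

## Validation (`nnaaindex.validation`)

Y-randomization refits a fixed modeler (typically PLS on a fixed variable
subset and component count) on shuffled responses and regresses R² and Q²
on |r(y_perm, y)|, including the unpermuted model at r = 1 (a mode without
it exists).  The reported intercepts are compared with the conventional
limits 0.300 (R²) and 0.050 (Q²).  `passes` reports exactly those intercept
flags.  Because an underfit chance model produces a low-lying cloud and
therefore low intercepts, a separate verdict `validates_model` additionally
requires the unpermuted model to clear the Q² limit itself and to beat
every permuted refit; simulation shows this composite refuses pure-noise
models in ≥95% of trials, which intercepts alone cannot.

The rational split runs k-means (k = 2, scikit-learn, 10 restarts, seeded)
on autoscaled descriptors, sorts each cluster by ascending activity (ties
by sample id) and sends odd ranks to training, even ranks to test.
External validation computes Q²_ext against the training-set mean (the
stricter of the two common conventions) and RMS over test residuals.

## Design (`nnaaindex.design`)

Rules constrain 1-based template positions with conjunctions of
factor-score thresholds; constrained positions range over all qualifying
residues in the scale table, unconstrained positions keep the template
residue, and the Cartesian product is deduplicated and ordered
lexicographically.  Candidates are ranked by predicted activity (PLS) or
positive-class posterior (LDA; posterior > 0.5 means predicted strong
binding), ties broken lexicographically.  "Above training maximum" filters
on the best *observed* training activity by default; filtering on fitted
values is available since either reading is defensible.  Rule sets for new
systems must be supplied explicitly — there are no silent default rules.

## Synthetic fixtures (`nnaaindex.synthetic`)

The property-table generator plants X = scores · loadingsᵀ + Gaussian
noise: each property loads `loading_value` (default 0.9) on exactly one
factor, factors are spread evenly over properties, inter-factor correlation
is planted through a Cholesky transform, and `loading_sparsity` makes a
fraction of properties pure noise.  Defaults (300 entities × 40 properties,
4 factors, noise sd 0.05) give a clean recovery problem: congruence > 0.95
and score correlations > 0.9 are expected and tested.

The QSAR generator draws uniform random sequences from a scale table and
sets activity = descriptors · β + Gaussian noise with a sparse β (default
3 informative positions, magnitudes 0.5–1.5, random signs).  Conditions
used by the tests and the acceptance script mirror the scale of the three
study datasets: 48 dipeptides (12 descriptors, noise sd 0.2,
5 informative), 50 dipeptides for GA recovery (noise sd 0.1,
3 informative), and 20 heptapeptides (42 descriptors) for classification,
where the latent activity is thresholded at its median and noise sd 0.5
leaves the classes genuinely overlapping, as real binding data are.

What these fixtures do not emulate: correlated descriptors within and
between sequence positions, non-Gaussian activity noise, class structure
beyond a thresholded linear latent, or the chemical realism of non-natural
side chains.  Passing recovery tests therefore demonstrates correctness of
the algorithms under their own assumptions, not predictive performance on
laboratory data.

Published per-dataset results (the original scale table, the three activity
datasets, and the statistics derived from them) cannot be recomputed here:
those tables are distributed as word-processor supplements without a
machine-readable form.  The loaders in `nnaaindex.io` accept them directly
once converted to CSV (`id,sequence,activity` / `class`, and `id,f1..f6`
for the scale table placed under `src/nnaaindex/data/`), and the
corresponding acceptance check remains red until then.

## Problem sizes and runtime

All shipped computations are sized for interactive use on one core: factor
recovery on 300 × 40, PLS/GA-PLS on 48–58 × 12 (GA fitness memoization
makes a full run a few seconds), LDA on 20 × 42, 50-permutation
randomization tests.  The full test suite runs in well under a minute; the
acceptance script in under a minute.
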