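# Methods

## Model and estimator

The package treats a dataset as an observations × variables matrix of
continuous, already log-transformed measurements, with each variable
labeled `input` (signaling species) or `output` (released product).
Dependence between two variables is quantified by mutual information in
nats, estimated by plugging Gaussian kernel density estimates into

    I(X,Y) = (1/n) Σⱼ ln[ f(xⱼ,yⱼ) / (f(xⱼ) f(yⱼ)) ],

with the joint and both marginals sharing one bandwidth *h* and evaluated
at the observations themselves (resubstitution). The estimator is
consistent but positively biased at small *n*, and can be slightly
negative for independent data; raw values are kept, and clamping at zero
happens only where values are compared with a threshold or pooled into a
null. Every column is standardized (zero mean, unit SD) before any
KDE/MI computation — this is what makes a single shared *h* across
variables meaningful. Rows with any missing value are dropped before
analysis (listwise deletion, the default); a pairwise-deletion mode
retains more rows per pair at the cost of varying effective *n* across
the MI matrix.

Implementation note: the bivariate Gaussian kernel factorizes, so one
n×n kernel matrix per column suffices; each pair's joint density is an
elementwise product of two such matrices, and a column permutation acts
on a kernel matrix by simultaneous row/column gather. Unit tests pin
this optimized path against literal loop transcriptions of the defining
formulas at 1e−10.

## Bandwidth selection

*h* minimizes the unbiased cross-validation criterion

    UCV(h) = ∫ f_h²(x) dx − (2/n) Σᵢ f₍₋ᵢ₎,h(xᵢ),

where the squared-density integral has a closed form for Gaussian
kernels (a pairwise double sum at bandwidth h√2; cross-checked against
numerical quadrature in the tests) and f₍₋ᵢ₎ is the leave-one-out
density. UCV is evaluated on the *bivariate* KDE per variable pair; the
dataset bandwidth is the arithmetic mean of per-pair optima. Defaults:
all input–output pairs when there are ≤ 200, else 100 seeded random
pairs (`n_pairs` is configurable; a mean over a few dozen pairs is
already stable). Each per-pair minimization scans a 40-point log grid on
[0.02, 2.0] — UCV objectives are prone to local minima, so the global
grid scan comes first — then refines by golden-section search between
the neighboring grid points. Zero-variance columns are dropped with a
warning (standardization is undefined for them).

## Threshold calibration

The null distribution of MI under independence is generated by shuffling
every column independently (preserving marginals, destroying all
dependence) and recomputing the full MI matrix per round; entries are
pooled across pairs and rounds (100 rounds by default; a per-pair null
mode exists for when exchangeability across standardized pairs is in
doubt). The empirical survival function is evaluated on 200 equally
spaced points between 0 and the null's 99.9th percentile, restricted to
points with survival probability in [10/N_null, 0.5] and at least 10
supporting draws (the log of a tinier empirical probability is too
noisy), and ln P = a + b·I₀ is fitted by least squares. The slope *b* is
negative, with magnitude growing with the observation count. Inverting
at a p-value (default 0.005) gives the threshold I₀ = (ln p − a)/b.
Edges are retained on strict inequality MI > I₀ (boundary ties are
discarded — the conservative reading of "discard insignificant
coefficients").

When the null sample is small (few permutations, or a single-output
restriction in node-by-node mode), the requested p-value can lie below
the smallest resolvable survival probability; the fitted line is then an
extrapolation. Fit R² is reported so this is visible; with the defaults
(100 rounds × 154 pairs) the fit rests on thousands of draws and R²
typically exceeds 0.98.

## Networks

Bipartite mode thresholds the inputs × outputs MI matrix; full mode
thresholds all variable pairs with the same single I₀, excluding the
diagonal always and output–output edges from default reports (the
reconstruction is input-centric; they can be included by flag).
Combining two dataset-specific networks takes the edge union: a node
with edges in both datasets is tagged `both`, an edge found in both
keeps both MI weights (its scalar weight is the maximum, used for
ranking). Node-by-node reconstruction restricts the MI matrix *and* the
permutation null to one output column, recalibrates I₀ there, and
unions the per-output stars; it agrees with the jointly calibrated
network except for edges whose MI sits within calibration noise of I₀.
Edges rank by descending MI with lexicographic tie-breaks, so orderings
are stable across runs. MI is symmetric: edges are undirected, and the
input→output reading is a role convention, not an inferred causal
direction.

## Linear predictive model

Per output, the significant inputs form the design matrix X
(standardized with training-set parameters, also when transforming test
rows), the output is mean-centered, and coefficients come from a
numerically stable least-squares solve (SVD) — identical to the
normal-equations solution on full-rank problems, with rank deficiency
reported by naming the collinear columns via pivoted QR. Rows are split
3:1 train:test (seeded, after per-output listwise deletion). R² uses
the test-set mean in its denominator, exactly as the evaluation formula
is written, and may be negative.

## Synthetic data

`gaussian_pair` supplies the one family with closed-form MI
(−½ln(1−ρ²)), used to measure estimator accuracy and bias decay.
`generate_planted` emulates the target experimental design: 22 inputs ×
7 outputs × a configurable number of conditions, a sparse planted edge
list with linear (z), quadratic (z²−1, mean-zero and Pearson-silent)
and saturating (tanh 2z) links, unit effect sizes, additive Gaussian
noise (default SD 0.3), outputs standardized post-generation so the
noise level reads against unit scale, and an optional fraction of rows
given one missing cell each. The reference spec plants 20 edges, one of
them the sole (quadratic) parent of its output — the canonical
dependence a correlation-based method cannot see.

Inputs in the reference spec are mutually independent, deliberately:
with correlated inputs, decoy–output pairs become genuinely (indirectly)
dependent, so the planted adjacency no longer coincides with the
independence structure and precision against it stops measuring the
estimator. The method applies no indirect-edge pruning (no data
processing inequality step) by design — each output is explicitly a
terminal variable — so under correlated inputs it will, correctly,
report those indirect dependencies too. `input_correlation` remains
available on custom specs for studying exactly that regime.

What the generator does not emulate: heavy-tailed or heteroscedastic
noise, time-course structure (the method targets time-averaged values),
feedback between outputs, and realistic inter-input correlation in the
reference spec (see above). Passing tests therefore demonstrate
correctness of the estimator and calibration under the stated model, not
performance on any particular real signaling panel.

## Problem sizes and numerical choices

The validation suite uses n = 1000 Gaussian pairs (20 seeds), 20
independent 78 × 29 matrices for false-positive control, and one
n = 500 planted run plus 10 reduced-bandwidth-budget (`n_pairs=30`)
repeats for the nonlinear-edge detection rate; the acceptance script
uses the same designs with slightly fewer repeats. These sizes give
stable means while keeping a full run in minutes on one core. Other
numerics: survival grids never take log of zero (points with < 10 tail
draws are excluded); resubstitution guarantees strictly positive
densities at sample points (the self-kernel term), so the MI logarithm
is always defined; degenerate UCV inputs (duplicated points) remain
finite; seeds for pipeline stages derive from one master seed via
`numpy.random.SeedSequence` spawning, making every artifact byte-stable
under a fixed seed.

## Known limitations

- The resubstitution MI bias is absorbed by the permutation threshold
  but still inflates *reported* edge weights at small n; weights are
  comparable within a dataset, less so across datasets of different n.
- One pooled null across pairs assumes post-standardization
  exchangeability; strongly non-Gaussian marginals may warrant the
  per-pair null mode.
- The linear model is intentionally minimal; low R² on detected edges
  signals nonlinearity, not absence of dependence.
- No indirect-edge pruning: with correlated inputs, indirect
  dependencies are reported as edges (see Synthetic data).
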