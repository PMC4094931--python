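# minet

Mutual-information reconstruction of input–output biological networks from
continuous measurement matrices — for systems biologists who have a panel
of upstream signals (e.g. 22 phosphoproteins) and downstream responses
(e.g. 7 secreted cytokines) measured across conditions, and want the
parsimonious set of statistically significant input→output (and
input–input) connections without assuming linearity.

## Method

For every variable pair the package estimates mutual information with a
Gaussian kernel density estimator evaluated at the sample points
(resubstitution), using a single shared bandwidth *h*:

```
f(x)    = 1/(√(2π) n h)  Σᵢ exp(−(x−xᵢ)²/(2h²))
f(x,y)  = 1/(2π n h²)    Σᵢ exp(−[(x−xᵢ)²+(y−yᵢ)²]/(2h²))
I(X,Y)  = 1/n Σⱼ ln [ f(xⱼ,yⱼ) / (f(xⱼ) f(yⱼ)) ]          (nats)
```

*h* is chosen by unbiased cross-validation (UCV): for each of a set of
variable pairs, minimize `∫f_h² − (2/n) Σᵢ f₍₋ᵢ₎,h(xᵢ)` over *h* and take
the mean of the per-pair optima.

Raw MI values are biased upward at small *n*, so significance is
calibrated by permutation: shuffling every column independently destroys
all dependencies, the recomputed MI values form the null, and
large-deviation theory gives the null tail `P(I > I₀) ≈ exp(a + b·I₀)`
with slope *b* proportional to the sample size. Fitting (a, b) and
inverting at a desired p-value (default 0.005) yields the MI threshold
I₀; coefficients above it become weighted edges. Networks from separate
stimulation conditions can be combined with per-node/per-edge provenance,
or rebuilt output-by-output with individually recalibrated thresholds.

Finally, each output's significant inputs define a linear model
`Y = X b + ε` (X standardized, Y centered, least squares on a 3:1
train/test split) scored by RMSE and R² — a deliberately simple predictor
whose shortfall on nonlinear links is itself informative.

## Worked example

`examples/03_planted_network.py` plants a known 22-input/7-output network
(20 edges mixing linear, quadratic and saturating links, noise on top),
runs the full pipeline and scores the reconstruction:

```
h = 0.366, I0 = 0.0939 at p = 0.005
edges found: 22 (true edges: 20)
precision = 0.91, recall = 1.00

strongest five edges (MI in nats):
  P17 -- C6: 0.623
  P04 -- C1: 0.304
  ...
```

The bandwidth 0.366 is the mean of per-pair UCV optima; I₀ = 0.094 nats
is the MI value that independent columns would exceed with probability
0.005; the top edge P17–C6 is a *purely quadratic* dependence with ~zero
Pearson correlation — detected here precisely because MI makes no
linearity assumption. The other examples cover the Gaussian-MI oracle,
threshold calibration on edge-free data, combining two condition-specific
networks, and the per-output linear models.

A thin CLI mirrors the library:

```
minet simulate --n-observations 300 --seed 2 --out data/
minet run --inputs data/inputs.tsv --outputs data/outputs.tsv \
          --label Toll --seed 1 --out results/
```

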