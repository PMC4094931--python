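"""Permutation-null calibration of the mutual information threshold.

Even for independent variables the resubstitution MI estimator returns
small positive values, so raw MI coefficients cannot be compared with an
absolute cutoff.  Instead the null distribution of MI under independence
is generated by permuting every variable column independently (destroying
all dependencies while preserving marginals) and recomputing the MI matrix
for each permutation round.  Large-deviation theory predicts the null
tail decays exponentially,

    P(I > I0 | independence) ~ exp(-c N I0),

so the log of the empirical survival function is linear in I0:
ln P = a + b * I0 with slope b proportional to the number of observations
N.  Fitting (a, b) on the pooled null sample converts any desired p-value
into an MI threshold I0 = (ln p - a) / b; coefficients below I0 are
statistically insignificant and discarded during network reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidInputError, InvalidParameterError
from .kde import Bandwidth, _check_h
from .mi import _mi_from_kernels, column_kernels
from .sample import SampleMatrix


@dataclass
class NullFit:
    """A fitted large-deviation null: ln P(I > I0) = a + b * I0."""

    null_mi: np.ndarray
    a: float
    b: float
    fit_range: tuple[float, float]
    fit_r2: float
    n_permutations: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null_mi = np.asarray(self.null_mi, dtype=float)
        if self.null_mi.size == 0:
            raise InvalidInputError("null_mi must be non-empty")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "fit_range": list(self.fit_range),
            "fit_r2": self.fit_r2,
            "n_permutations": self.n_permutations,
            "n_null": int(self.null_mi.size),
            "seed": self.seed,
        }


def _pairs_for_mode(prep: SampleMatrix, mode: str) -> list[tuple[str, str]]:
    from itertools import combinations, product

    if mode == "bipartite":
        return list(product(prep.input_names, prep.output_names))
    if mode == "full":
        return list(combinations(prep.variable_names, 2))
    raise InvalidParameterError(f"unknown mode: {mode!r}")


def permutation_null(
    data: SampleMatrix,
    mode: str = "bipartite",
    h: float | Bandwidth = 0.3,
    n_permutations: int = 100,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    pool: bool = True,
):
    """Pooled null MI sample from independent column permutations.

    For each round every column is row-shuffled independently (seeded), the
    MI of every pair under ``mode`` is recomputed, and all entries are
    pooled.  Returned values are clamped at 0: negative resubstitution
    estimates are indistinguishable from independence.

    With ``pool=False`` a dict mapping each pair to its own null sample is
    returned instead (per-pair calibration).
    """
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    h_val = _check_h(h.h if isinstance(h, Bandwidth) else h)

    kernels, prep = column_kernels(data, h_val)
    if pairs is None:
        pairs = _pairs_for_mode(prep, mode)
    if not pairs:
        raise InvalidInputError("no pairs to permute")
    n = prep.n_observations
    rng = np.random.default_rng(seed)

    cols = sorted({c for p in pairs for c in p})
    out = {p: np.empty(n_permutations) for p in pairs}
    for r in range(n_permutations):
        perm_k = {}
        for c in cols:
            p = rng.permutation(n)
            perm_k[c] = kernels[c][np.ix_(p, p)]
        for pair in pairs:
            a, b = pair
            out[pair][r] = _mi_from_kernels(perm_k[a], perm_k[b], h_val)
    for pair in pairs:
        np.maximum(out[pair], 0.0, out=out[pair])
    if pool:
        return np.concatenate([out[p] for p in pairs])
    return out


def fit_large_deviation(
    null_mi,
    p_range: tuple[float, float] | None = None,
    n_grid: int = 200,
    min_tail_count: int = 10,
    n_permutations: int = 0,
    seed: int | None = None,
) -> NullFit:
    """Least-squares fit of ln P(I > I0) = a + b * I0 on the empirical null.

    The survival function is evaluated on ``n_grid`` equally spaced I0
    values between 0 and the null's 99.9th percentile; the fit is
    restricted to grid points whose empirical P lies in ``p_range``
    (default [10/|null|, 0.5]) and rests on at least ``min_tail_count``
    draws, because the log of a tiny empirical probability is unstable.
    """
    null = np.asarray(null_mi, dtype=float).ravel()
    if null.size == 0:
        raise InvalidInputError("null_mi must be non-empty")
    if p_range is None:
        p_range = (min(min_tail_count / null.size, 0.5), 0.5)
    p_lo, p_hi = p_range
    if not (0 < p_lo < p_hi <= 1):
        raise InvalidParameterError(f"invalid p_range: {p_range}")

    hi = np.quantile(null, 0.999)
    if hi <= 0:
        raise CalibrationError("null MI sample is degenerate (all <= 0)")
    grid = np.linspace(0.0, hi, n_grid)
    sorted_null = np.sort(null)
    # P(I > I0): count of strictly greater draws
    counts = null.size - np.searchsorted(sorted_null, grid, side="right")
    surv = counts / null.size

    use = (surv >= p_lo) & (surv <= p_hi) & (counts >= min_tail_count)
    if use.sum() < 3:
        raise CalibrationError(
            f"only {int(use.sum())} usable survival points in p-range {p_range}; "
            "increase n_permutations"
        )
    x = grid[use]
    y = np.log(surv[use])
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return NullFit(
        null_mi=null,
        a=float(a),
        b=float(b),
        fit_range=(float(x.min()), float(x.max())),
        fit_r2=r2,
        n_permutations=n_permutations,
        seed=seed,
    )


def threshold_for_pvalue(fit: NullFit, p_value: float) -> float:
    """Invert the fitted null tail: I0 = (ln p - a) / b.

    Monotone by construction: a smaller p-value yields a larger threshold.
    """
    if not (0 < p_value < 1):
        raise InvalidParameterError(f"p_value must be in (0, 1), got {p_value}")
    if fit.b >= 0:
        raise CalibrationError(
            f"null fit has non-negative slope b={fit.b}; calibration failed"
        )
    return float((np.log(p_value) - fit.a) / fit.b)


def calibrate_threshold(
    data: SampleMatrix,
    mode: str = "bipartite",
    h: float | Bandwidth = 0.3,
    p_value: float = 0.005,
    n_permutations: int = 100,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[NullFit, float]:
    """Permutation null + large-deviation fit + p-value inversion in one call."""
    null = permutation_null(
        data, mode=mode, h=h, n_permutations=n_permutations, seed=seed, pairs=pairs
    )
    fit = fit_large_deviation(null, n_permutations=n_permutations, seed=seed)
    return fit, threshold_for_pvalue(fit, p_value)
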