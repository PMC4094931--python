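"""Linear input-output model on the thresholded network's significant inputs.

For one output Y and its significant inputs X the model is Y = X b + eps,
with X standardized per column, Y mean-centered, and b estimated by least
squares on a training split.  Test rows reuse the *training*
standardization parameters.  Prediction quality is scored by RMSE and the
coefficient of determination R^2 = 1 - SSE / SST, where SST uses the
test-set mean; R^2 can be negative for a model worse than that mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .errors import (
    DegenerateDesignError,
    InvalidInputError,
    UndefinedMetricError,
)
from .network import Network
from .sample import SampleMatrix


@dataclass
class LinearModel:
    input_names: list[str]
    x_means: np.ndarray
    x_stds: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    trained_on: int

    def __post_init__(self) -> None:
        self.x_means = np.asarray(self.x_means, dtype=float)
        self.x_stds = np.asarray(self.x_stds, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k = len(self.input_names)
        if not (self.x_means.size == self.x_stds.size == self.coefficients.size == k):
            raise InvalidInputError("model parameter sizes disagree")
        if np.any(self.x_stds <= 0):
            raise InvalidInputError("all input standard deviations must be positive")


def fit_linear(
    x_train, y_train, input_names: list[str] | None = None
) -> LinearModel:
    """Least-squares fit of the standardized linear model.

    The normal-equations solution b = (X'X)^-1 X'Y is computed with a
    numerically stable least-squares solve (SVD via ``numpy.linalg.lstsq``)
    rather than an explicit inverse — identical on full-rank problems.
    Rank deficiency raises :class:`DegenerateDesignError` naming the
    collinear columns (found by pivoted QR).
    """
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if x.ndim != 2:
        raise InvalidInputError("x_train must be a 2-D matrix")
    n, k = x.shape
    if input_names is None:
        input_names = [f"x{i}" for i in range(k)]
    if len(input_names) != k:
        raise InvalidInputError("input_names length does not match columns")
    if y.size != n:
        raise InvalidInputError(f"{n} rows in X but {y.size} responses")
    if n < k + 1:
        raise InvalidInputError(f"need >= {k + 1} rows to fit {k} coefficients")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("training data contain non-finite values")

    means = x.mean(axis=0)
    stds = x.std(axis=0)
    zero_var = [input_names[i] for i in range(k) if stds[i] <= 0]
    if zero_var:
        raise DegenerateDesignError(f"zero-variance input columns: {zero_var}")
    xs = (x - means) / stds
    y_mean = float(y.mean())
    yc = y - y_mean

    rank = np.linalg.matrix_rank(xs)
    if rank < k:
        _, _, piv = sla.qr(xs, mode="economic", pivoting=True)
        collinear = sorted(input_names[i] for i in piv[rank:])
        raise DegenerateDesignError(
            f"design matrix rank {rank} < {k}; collinear columns: {collinear}"
        )
    coef, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    return LinearModel(
        input_names=list(input_names),
        x_means=means,
        x_stds=stds,
        y_mean=y_mean,
        coefficients=coef,
        trained_on=n,
    )


def predict(model: LinearModel, x_test) -> np.ndarray:
    """Apply training standardization, multiply by b, add back the Y mean."""
    x = np.asarray(x_test, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(model.input_names):
        raise InvalidInputError(
            f"x_test must have {len(model.input_names)} columns"
        )
    xs = (x - model.x_means) / model.x_stds
    return xs @ model.coefficients + model.y_mean


def rmse(y, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    a = np.asarray(y, dtype=float).ravel()
    b = np.asarray(y_pred, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidInputError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise InvalidInputError("empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def r_squared(y, y_pred) -> float:
    """Coefficient of determination, with SST around the mean of ``y`` itself."""
    a = np.asarray(y, dtype=float).ravel()
    b = np.asarray(y_pred, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidInputError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise InvalidInputError("need at least 2 points for R^2")
    sst = float(((a - a.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedMetricError("R^2 undefined for a constant response")
    return 1.0 - float(((a - b) ** 2).sum()) / sst


def split_train_test(
    data: SampleMatrix, test_fraction: float = 0.25, seed: int = 0
) -> tuple[SampleMatrix, SampleMatrix]:
    """Seeded uniform row split after listwise deletion (default 3:1 ratio)."""
    if not (0 < test_fraction < 1):
        raise InvalidInputError(f"test_fraction must be in (0,1), got {test_fraction}")
    complete = data.dropna()
    n = complete.n_observations
    n_test = int(round(n * test_fraction))
    if n < 4 or n_test < 1 or n - n_test < 2:
        raise InvalidInputError(f"too few complete rows ({n}) for a split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    from dataclasses import replace

    train = replace(complete,
                    values=complete.values.iloc[train_idx].reset_index(drop=True))
    test = replace(complete,
                   values=complete.values.iloc[test_idx].reset_index(drop=True))
    return train, test


def significant_inputs(net: Network, output_name: str) -> list[str]:
    """Input variables adjacent to ``output_name`` in a reconstructed network."""
    roles = {n.name: n.role for n in net.nodes}
    if output_name not in roles:
        raise InvalidInputError(f"unknown output: {output_name!r}")
    partners = []
    for e in net.edges:
        if e.source == output_name and roles.get(e.target) == "input":
            partners.append(e.target)
        elif e.target == output_name and roles.get(e.source) == "input":
            partners.append(e.source)
    return sorted(set(partners))


def fit_output_models(
    data: SampleMatrix,
    net: Network,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-output linear models on each output's significant inputs.

    Listwise deletion is applied per output (over that output and its own
    inputs only), so each output uses as many rows as its variables allow.
    Outputs with no significant inputs or too few rows are reported with a
    ``"skipped"`` reason instead of metrics.
    """
    results: dict[str, dict] = {}
    for out in data.output_names:
        inputs = significant_inputs(net, out)
        if not inputs:
            results[out] = {"skipped": "no significant inputs"}
            continue
        sub = data.subset(inputs + [out])
        try:
            train, test = split_train_test(sub, test_fraction=test_fraction, seed=seed)
            model = fit_linear(
                train.values[inputs].to_numpy(float),
                train.values[out].to_numpy(float),
                input_names=inputs,
            )
        except (InvalidInputError, DegenerateDesignError) as exc:
            results[out] = {"skipped": str(exc)}
            continue
        yhat_train = predict(model, train.values[inputs].to_numpy(float))
        yhat_test = predict(model, test.values[inputs].to_numpy(float))
        y_train = train.values[out].to_numpy(float)
        y_test = test.values[out].to_numpy(float)
        results[out] = {
            "inputs": inputs,
            "coefficients": model.coefficients.tolist(),
            "n_train": train.n_observations,
            "n_test": test.n_observations,
            "rmse_train": rmse(y_train, yhat_train),
            "rmse_test": rmse(y_test, yhat_test),
            "r2_train": r_squared(y_train, yhat_train),
            "r2_test": r_squared(y_test, yhat_test),
        }
    return results
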