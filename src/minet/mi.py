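"""Entropy and the KDE-resubstitution mutual information estimator.

Mutual information between two continuous variables is estimated by
plugging Gaussian kernel density estimates (one shared bandwidth for the
joint and both marginals) into

    I(X, Y) = (1/n) * sum_j ln[ f(x_j, y_j) / (f(x_j) f(y_j)) ]

with the densities evaluated at the sample points themselves
(resubstitution).  The estimate is positively biased at small n — which is
exactly what the permutation-null calibration in
:mod:`minet.threshold` corrects for — and can be slightly negative for
independent data; raw values are reported.

Because the bivariate Gaussian kernel factorizes, the joint density at the
sample points is an elementwise product of the two univariate kernel
matrices.  The matrix of all pairwise MI values (the MIM) therefore needs
only one n x n kernel matrix per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .kde import Bandwidth, _check_h, _check_sample
from .sample import SampleMatrix

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def entropy(probabilities, atol: float = 1e-8) -> float:
    """Shannon entropy H = -sum p_i ln p_i of a discrete distribution, in nats.

    The convention 0 * ln 0 = 0 applies.  Probabilities must be
    non-negative and sum to 1 within ``atol``.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    if p.size == 0:
        raise InvalidInputError("empty distribution")
    if np.any(p < 0) or np.any(~np.isfinite(p)):
        raise InvalidInputError("probabilities must be finite and non-negative")
    total = p.sum()
    if abs(total - 1.0) > atol:
        raise InvalidInputError(f"probabilities sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _kernel_matrix(values: np.ndarray, h: float) -> np.ndarray:
    """n x n Gaussian kernel matrix K_ij = exp(-(v_i - v_j)^2 / (2 h^2))."""
    d2 = (values[:, None] - values[None, :]) ** 2
    return np.exp(-d2 / (2.0 * h * h))


def _mi_from_kernels(kx: np.ndarray, ky: np.ndarray, h: float) -> float:
    """Resubstitution MI from two per-column kernel matrices.

    The normalization constants of joint and marginals cancel except for
    the 2*pi / (sqrt(2*pi))^2 factor, which is 1 — so MI reduces to the
    mean log of (n * joint kernel sum) / (marginal sums product).
    """
    n = kx.shape[0]
    fx = kx.sum(axis=1) / (_SQRT_2PI * n * h)
    fy = ky.sum(axis=1) / (_SQRT_2PI * n * h)
    fxy = (kx * ky).sum(axis=1) / (2.0 * np.pi * n * h * h)
    return float(np.mean(np.log(fxy) - np.log(fx) - np.log(fy)))


def mutual_information(x_sample, y_sample, h: float) -> float:
    """KDE-resubstitution mutual information of a paired sample, in nats.

    Joint and marginal densities all use the same bandwidth ``h`` and are
    evaluated at the observations.  Symmetric in x and y by construction.
    """
    h = _check_h(h)
    x = _check_sample(x_sample, min_n=2)
    y = _check_sample(y_sample, min_n=2)
    if x.size != y.size:
        raise InvalidInputError("x and y samples must have equal length")
    return _mi_from_kernels(_kernel_matrix(x, h), _kernel_matrix(y, h), h)


@dataclass
class MIMatrix:
    """Pairwise mutual information coefficients (nats).

    ``mode="bipartite"`` gives a rectangular inputs x outputs matrix;
    ``mode="full"`` a symmetric all-variables matrix with NaN on the
    diagonal (self-information is not an edge and is excluded from all
    thresholding downstream).
    """

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    mode: str
    bandwidth: float
    n_observations: int
    roles: dict[str, str] = field(default_factory=dict)
    dataset_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise InvalidInputError("MIM shape does not match name lists")
        if self.mode not in ("bipartite", "full"):
            raise InvalidParameterError(f"unknown MIM mode: {self.mode!r}")
        if self.mode == "full" and self.row_names != self.col_names:
            raise InvalidInputError("full-mode MIM must be square with equal names")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_names, columns=self.col_names)

    def entries(self):
        """Iterate (row_name, col_name, mi) over the thresholdable entries.

        Bipartite: every cell.  Full: strict upper triangle (each unordered
        pair once, diagonal excluded).  NaN sentinels are skipped.
        """
        if self.mode == "bipartite":
            for i, r in enumerate(self.row_names):
                for j, c in enumerate(self.col_names):
                    v = self.values[i, j]
                    if np.isfinite(v):
                        yield r, c, float(v)
        else:
            for i, r in enumerate(self.row_names):
                for j in range(i + 1, len(self.col_names)):
                    v = self.values[i, j]
                    if np.isfinite(v):
                        yield r, self.col_names[j], float(v)


def column_kernels(
    data: SampleMatrix, h: float, deletion: str = "listwise"
) -> tuple[dict[str, np.ndarray], SampleMatrix]:
    """Per-column kernel matrices of the prepared (complete, standardized) data.

    Only valid under listwise deletion, where all columns share the same
    rows; returns the kernel dict and the prepared matrix.
    """
    if deletion != "listwise":
        raise InvalidParameterError("column_kernels requires listwise deletion")
    prep = data.prepared(deletion="listwise")
    if prep.n_observations < 2:
        raise InvalidInputError("need at least 2 complete observations")
    kernels = {
        c: _kernel_matrix(prep.values[c].to_numpy(dtype=float), h)
        for c in prep.variable_names
    }
    return kernels, prep


def compute_mim(
    data: SampleMatrix,
    mode: str = "bipartite",
    h: float | Bandwidth = 0.3,
    deletion: str = "listwise",
) -> MIMatrix:
    """Mutual information matrix of a sample matrix.

    Data are standardized per column (after listwise deletion by default,
    or per pair under ``deletion="pairwise"``).  Pairs with fewer than two
    complete observations get a NaN sentinel with a warning.
    """
    h_val = _check_h(h.h if isinstance(h, Bandwidth) else h)
    if mode not in ("bipartite", "full"):
        raise InvalidParameterError(f"unknown mode: {mode!r}")

    if deletion == "listwise":
        kernels, prep = column_kernels(data, h_val)
        n_obs = prep.n_observations
        if mode == "bipartite":
            rows, cols = prep.input_names, prep.output_names
        else:
            rows = cols = prep.variable_names
        values = np.full((len(rows), len(cols)), np.nan)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                if mode == "full":
                    if j <= i:
                        continue
                    values[i, j] = _mi_from_kernels(kernels[r], kernels[c], h_val)
                else:
                    values[i, j] = _mi_from_kernels(kernels[r], kernels[c], h_val)
        if mode == "full":
            iu = np.triu_indices(len(rows), k=1)
            values[(iu[1], iu[0])] = values[iu]
        roles = dict(prep.roles)
    elif deletion == "pairwise":
        prep = data.standardize()
        if mode == "bipartite":
            rows, cols = prep.input_names, prep.output_names
        else:
            rows = cols = prep.variable_names
        values = np.full((len(rows), len(cols)), np.nan)
        n_list = []
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                if mode == "full" and j <= i:
                    continue
                x, y = prep.pair(r, c)
                if x.size < 2:
                    warnings.warn(
                        f"pair ({r}, {c}) has <2 complete observations", stacklevel=2
                    )
                    continue
                values[i, j] = mutual_information(x, y, h_val)
                n_list.append(x.size)
        if mode == "full":
            iu = np.triu_indices(len(rows), k=1)
            values[(iu[1], iu[0])] = values[iu]
        n_obs = int(np.median(n_list)) if n_list else 0
        roles = dict(prep.roles)
    else:
        raise InvalidParameterError(f"unknown deletion policy: {deletion!r}")

    return MIMatrix(
        values=values,
        row_names=list(rows),
        col_names=list(cols),
        mode=mode,
        bandwidth=h_val,
        n_observations=n_obs,
        roles=roles,
        dataset_label=data.dataset_label,
    )
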