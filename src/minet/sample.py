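"""The :class:`SampleMatrix` container: observations x named variables.

Every analysis stage in this package operates on a ``SampleMatrix`` — a
rectangular block of continuous measurements whose columns carry a role
label (``"input"`` for signaling variables such as phosphoproteins,
``"output"`` for released products such as cytokines) and whose missing
entries are NaN.  The container is a thin, immutable-by-convention wrapper
around a :class:`pandas.DataFrame`; methods return new instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError

ROLE_INPUT = "input"
ROLE_OUTPUT = "output"
_VALID_ROLES = frozenset({ROLE_INPUT, ROLE_OUTPUT})


@dataclass
class SampleMatrix:
    """Observations x variables with per-variable roles and a missing mask.

    Parameters
    ----------
    values
        Numeric frame; rows are observations (conditions), columns are
        variables.  Missing measurements are NaN.
    roles
        Mapping from variable name to ``"input"`` or ``"output"``.  Every
        column must be covered.
    dataset_label
        Free-text provenance tag (e.g. ``"Toll"``, ``"non-Toll"``) carried
        into networks built from this matrix.
    """

    values: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    dataset_label: str = ""

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise InvalidInputError(f"duplicate variable names: {dupes}")
        missing_roles = [c for c in cols if c not in self.roles]
        if missing_roles:
            raise InvalidInputError(f"variables without a role: {missing_roles}")
        bad = {c: r for c, r in self.roles.items() if r not in _VALID_ROLES}
        if bad:
            raise InvalidInputError(f"invalid roles (need input/output): {bad}")
        if not all(np.issubdtype(d, np.number) for d in self.values.dtypes):
            raise InvalidInputError("all columns must be numeric")
        # keep only roles for present columns, in column order
        self.roles = {c: self.roles[c] for c in cols}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_blocks(
        cls,
        inputs: pd.DataFrame,
        outputs: pd.DataFrame,
        dataset_label: str = "",
    ) -> "SampleMatrix":
        """Join an input block and an output block sharing the row axis."""
        if len(inputs) != len(outputs):
            raise InvalidInputError(
                f"input block has {len(inputs)} rows, output block {len(outputs)}"
            )
        overlap = set(inputs.columns) & set(outputs.columns)
        if overlap:
            raise InvalidInputError(f"names in both blocks: {sorted(overlap)}")
        values = pd.concat(
            [inputs.reset_index(drop=True), outputs.reset_index(drop=True)], axis=1
        )
        roles = {c: ROLE_INPUT for c in inputs.columns}
        roles.update({c: ROLE_OUTPUT for c in outputs.columns})
        return cls(values=values, roles=roles, dataset_label=dataset_label)

    # -- basic views ------------------------------------------------------

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def input_names(self) -> list[str]:
        return [c for c in self.values.columns if self.roles[c] == ROLE_INPUT]

    @property
    def output_names(self) -> list[str]:
        return [c for c in self.values.columns if self.roles[c] == ROLE_OUTPUT]

    @property
    def n_observations(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset(self, names: list[str]) -> "SampleMatrix":
        unknown = [n for n in names if n not in self.roles]
        if unknown:
            raise InvalidInputError(f"unknown variables: {unknown}")
        return replace(
            self,
            values=self.values[names].copy(),
            roles={n: self.roles[n] for n in names},
        )

    def column(self, name: str, drop_missing: bool = True) -> np.ndarray:
        if name not in self.roles:
            raise InvalidInputError(f"unknown variable: {name}")
        col = self.values[name].to_numpy(dtype=float)
        return col[~np.isnan(col)] if drop_missing else col

    def pair(self, x_name: str, y_name: str) -> tuple[np.ndarray, np.ndarray]:
        """Paired observations for two variables, pairwise-complete rows only."""
        for n in (x_name, y_name):
            if n not in self.roles:
                raise InvalidInputError(f"unknown variable: {n}")
        x = self.values[x_name].to_numpy(dtype=float)
        y = self.values[y_name].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        return x[keep], y[keep]

    # -- preparation ------------------------------------------------------

    def dropna(self) -> "SampleMatrix":
        """Listwise deletion: drop every row with any missing value."""
        return replace(self, values=self.values.dropna(axis=0).reset_index(drop=True))

    def standardize(self) -> "SampleMatrix":
        """Per-column zero mean, unit standard deviation (missing ignored).

        Zero-variance columns cannot be standardized; they are dropped with
        a warning because a constant carries no information about anything.
        """
        out = {}
        dropped = []
        for c in self.values.columns:
            col = self.values[c].to_numpy(dtype=float)
            mean = np.nanmean(col)
            sd = np.nanstd(col)
            if not np.isfinite(sd) or sd <= 0:
                dropped.append(c)
                continue
            out[c] = (col - mean) / sd
        if dropped:
            warnings.warn(
                f"dropping zero-variance columns: {dropped}", stacklevel=2
            )
        return replace(
            self,
            values=pd.DataFrame(out),
            roles={c: self.roles[c] for c in out},
        )

    def prepared(self, deletion: str = "listwise") -> "SampleMatrix":
        """Standardized matrix ready for KDE/MI (listwise deletion first)."""
        if deletion not in ("listwise", "pairwise"):
            raise InvalidInputError(f"unknown deletion policy: {deletion!r}")
        base = self.dropna() if deletion == "listwise" else self
        return base.standardize()
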