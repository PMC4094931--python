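"""Delimited matrix readers/writers and run configuration.

Matrices are plain TSV/CSV files with a header row of variable names; the
delimiter is inferred from the extension (``.tsv`` tab, ``.csv`` comma).
Missing values use a configurable token (default ``"NA"``).  Parse errors
name the offending row/column.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, ParseError
from .sample import SampleMatrix


def _delimiter_for(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_table(path, missing_token: str = "NA") -> pd.DataFrame:
    """Read one delimited numeric block, validating shape and cell contents."""
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h.strip() for h in header]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ParseError(f"{path.name}: duplicate column names: {dupes}")
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                          skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    out = {}
    for col in raw.columns:
        cells = raw[col].str.strip()
        vals = pd.to_numeric(cells.mask(cells == missing_token), errors="coerce")
        bad = vals.isna() & (cells != missing_token) & (cells != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric cell {cells.iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
        out[col] = vals.astype(float)
    return pd.DataFrame(out)


def read_matrix(path, role_map, missing_token: str = "NA",
                dataset_label: str = "") -> SampleMatrix:
    """Read one file into a SampleMatrix.

    ``role_map`` is either a dict variable -> role or a single role string
    applied to every column.
    """
    frame = read_table(path, missing_token=missing_token)
    if isinstance(role_map, str):
        roles = {c: role_map for c in frame.columns}
    else:
        roles = dict(role_map)
    return SampleMatrix(values=frame, roles=roles, dataset_label=dataset_label)


def load_dataset(inputs_path, outputs_path, missing_token: str = "NA",
                 dataset_label: str = "") -> SampleMatrix:
    """Read an input block and an output block sharing the row axis."""
    inputs = read_table(inputs_path, missing_token=missing_token)
    outputs = read_table(outputs_path, missing_token=missing_token)
    return SampleMatrix.from_blocks(inputs, outputs, dataset_label=dataset_label)


def write_matrix(data: SampleMatrix | pd.DataFrame, path,
                 missing_token: str = "NA") -> None:
    path = Path(path)
    frame = data.values if isinstance(data, SampleMatrix) else data
    frame.to_csv(path, sep=_delimiter_for(path), index=False,
                 na_rep=missing_token, float_format="%.12g")


def write_mim_tsv(mim, path) -> None:
    """MI matrix as TSV with row/column headers, values in nats."""
    mim.to_frame().to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_mim_tsv(path, mode: str, bandwidth: float, n_observations: int = 0,
                 roles: dict | None = None, dataset_label: str = ""):
    from .mi import MIMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return MIMatrix(
        values=frame.to_numpy(dtype=float),
        row_names=[str(i) for i in frame.index],
        col_names=[str(c) for c in frame.columns],
        mode=mode,
        bandwidth=bandwidth,
        n_observations=n_observations,
        roles=roles or {},
        dataset_label=dataset_label,
    )


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, serializable to YAML."""

    p_value: float = 0.005
    n_permutations: int = 100
    n_pairs: int | None = None
    h_override: float | None = None
    deletion: str = "listwise"
    mode: str = "bipartite"
    test_fraction: float = 0.25
    seed: int = 0
    fit_models: bool = True
    missing_token: str = "NA"
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p_value < 1):
            raise InvalidParameterError(f"p_value out of (0,1): {self.p_value}")
        if self.n_permutations < 1:
            raise InvalidParameterError("n_permutations must be >= 1")
        if self.h_override is not None and self.h_override <= 0:
            raise InvalidParameterError("h_override must be positive")
        if self.deletion not in ("listwise", "pairwise"):
            raise InvalidParameterError(f"unknown deletion: {self.deletion!r}")
        if self.mode not in ("bipartite", "full"):
            raise InvalidParameterError(f"unknown mode: {self.mode!r}")
        if not (0 < self.test_fraction < 1):
            raise InvalidParameterError("test_fraction must be in (0,1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
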