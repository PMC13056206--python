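"""File I/O: reading univariate series, writing results and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["read_series", "write_result_json", "write_profile_csv"]


def read_series(path, column=None) -> np.ndarray:
    """Read a univariate series from CSV or whitespace-delimited text.

    One observation per row, in time order.  ``column`` selects a column by
    name or 0-based index; by default the single column (or, for multi-column
    files, the first numeric column) is used.  Rows that do not parse as
    numbers raise an error naming the offending line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                          skip_blank_lines=True, comment="#")
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"empty series file: {path}") from None

    header_offset = 0
    first = pd.to_numeric(raw.iloc[0], errors="coerce")
    if first.isna().any():  # first row is a header
        raw.columns = [str(c).strip() for c in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
        header_offset = 1
    if raw.empty:
        raise InvalidInputError(f"empty series file: {path}")

    if column is None:
        col = raw.columns[0]
        if raw.shape[1] > 1:
            for c in raw.columns:
                if not pd.to_numeric(raw[c], errors="coerce").isna().all():
                    col = c
                    break
    elif isinstance(column, int):
        if not 0 <= column < raw.shape[1]:
            raise InvalidInputError(f"column index {column} out of range")
        col = raw.columns[column]
    else:
        if column not in raw.columns:
            raise InvalidInputError(
                f"column {column!r} not found; available: {list(raw.columns)}"
            )
        col = column

    values = pd.to_numeric(raw[col], errors="coerce")
    bad = values.index[~np.isfinite(values.astype(float))].tolist()
    if bad:
        lines = [i + 1 + header_offset for i in bad[:10]]
        raise InvalidInputError(
            f"non-numeric or non-finite entries in {path} at line(s) {lines}"
        )
    if len(values) == 0:
        raise InvalidInputError(f"empty series file: {path}")
    return values.to_numpy(dtype=float)


def write_result_json(result_dict: dict, path, manifest: dict | None = None) -> None:
    payload = dict(result_dict)
    if manifest:
        payload["manifest"] = manifest
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def write_profile_csv(profile, path) -> None:
    pd.DataFrame({"k": profile.k_values, "gn": profile.gn_values}).to_csv(
        path, index=False
    )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
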