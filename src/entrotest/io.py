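"""Count-table file I/O, report writing, and run configuration.

Count tables are plain CSV/TSV, either two columns ``label,count`` (header
optional) or a single data row of integers.  File order is authoritative and
preserved; nothing is sorted.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .exceptions import InvalidInputError

__all__ = [
    "read_count_table",
    "write_count_table",
    "write_report",
    "AnalysisConfig",
    "format_pvalue",
]


def _sniff_delimiter(sample: str) -> str:
    if "\t" in sample:
        return "\t"
    if "," in sample:
        return ","
    return None  # whitespace


def _parse_count(token: str, lineno: int, path) -> int:
    token = token.strip()
    try:
        value = int(token)
    except ValueError:
        raise InvalidInputError(
            f"{path}: line {lineno}: {token!r} is not an integer count"
        ) from None
    if value < 0:
        raise InvalidInputError(f"{path}: line {lineno}: negative count {value}")
    return value


def read_count_table(path: str | Path, dialect: str | None = None) -> CountTable:
    """Read an ordered count table from a CSV/TSV file.

    Accepted layouts:

    * two columns ``label,count``, with an optional header row;
    * a single data row of integers (comma, tab or whitespace separated).

    ``dialect`` may force the delimiter (``','`` or ``'\\t'``); by default it
    is sniffed.  Errors name the offending line.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InvalidInputError(f"{path}: empty file")
    delim = dialect or _sniff_delimiter(lines[0])

    def split(line: str) -> list[str]:
        return line.split(delim) if delim else line.split()

    first = split(lines[0])
    if len(lines) == 1 and len(first) > 1:
        counts = [_parse_count(tok, 1, path) for tok in first]
        return CountTable(counts)

    labels, counts = [], []
    for lineno, line in enumerate(lines, start=1):
        fields = split(line)
        if len(fields) != 2:
            raise InvalidInputError(
                f"{path}: line {lineno}: expected 'label{delim or ' '}count', "
                f"got {line!r}"
            )
        label, token = fields
        if lineno == 1:
            try:
                int(token.strip())
            except ValueError:
                continue  # header row
        counts.append(_parse_count(token, lineno, path))
        labels.append(label.strip())
    if not counts:
        raise InvalidInputError(f"{path}: no data rows found")
    return CountTable(counts, labels=labels)


def write_count_table(counts: CountTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a count table in the two-column layout the reader accepts."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        labels = counts.labels or [f"cat{i + 1}" for i in range(counts.k)]
        for label, c in zip(labels, counts.counts):
            writer.writerow([label, int(c)])


def format_pvalue(p: float) -> str:
    """Print p-values in scientific notation below 1e-4 to avoid truncating
    small values to a row of zeros."""
    if np.isnan(p):
        return "nan"
    return f"{p:.4e}" if p < 1e-4 else f"{p:.4f}"


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(result: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a result object to JSON (machine) or TSV (tabular).

    Means are printed with 3 decimals and variances with 7 in TSV table
    output; JSON keeps full precision.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(result), indent=2, allow_nan=True) + "\n")
        return
    if format == "tsv":
        if isinstance(result, pd.DataFrame):
            df = result.copy()
            for col in df.columns:
                if col.lower().startswith("mean"):
                    df[col] = df[col].map(lambda v: f"{v:.3f}")
                elif col.lower().startswith("var"):
                    df[col] = df[col].map(lambda v: f"{v:.7f}")
                elif "p_value" in col.lower() or col.lower().startswith("p-"):
                    df[col] = df[col].map(format_pvalue)
            df.to_csv(path, sep="\t", index=False)
            return
        raise InvalidInputError("TSV output requires a DataFrame result")
    raise InvalidInputError(f"unknown report format {format!r}")


_CONFIG_FIELDS = {
    "family",
    "q",
    "normalized",
    "fisher_constant",
    "fisher_variance_mode",
    "renyi_variance_convention",
    "zero_floor",
    "seed",
    "out",
    "format",
}


@dataclasses.dataclass
class AnalysisConfig:
    """Run configuration loadable from YAML/JSON; unknown keys are rejected."""

    family: str = "shannon"
    q: float | None = None
    normalized: bool = True
    fisher_constant: float = 4.0
    fisher_variance_mode: str = "delta"
    renyi_variance_convention: str = "power_sum"
    zero_floor: float | None = 1e-10
    seed: int = 0
    out: str | None = None
    format: str = "json"

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise InvalidInputError(f"{path}: config must be a mapping")
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise InvalidInputError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"allowed: {sorted(_CONFIG_FIELDS)}"
            )
        return cls(**data)
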