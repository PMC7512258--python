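"""Readers and writers for RR-interval series and SampEn results.

Input formats are deliberately plain: one value per line (blank lines
ignored), or an RFC-4180 CSV with a chosen numeric column.  Results are
serialised to JSON or TSV documents carrying the full parameter set and the
raw counts, so a reported entropy can always be re-derived from the counts
it shipped with.

The ectopic-beat filter here implements a running-median rule that is a
common-practice stand-in: outlier removal before HRV analysis is standard,
but the specific rule (centered running median, fractional threshold) is
this package's own choice and is flagged as such in the output metadata.
"""

from __future__ import annotations

import json
import math
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import SampEnResult, TimeSeries, as_series

__all__ = ["read_series", "filter_ectopics", "write_result", "read_result"]

_RESULT_FIELDS = (
    "algorithm", "m", "r_input", "r_mode", "r_abs", "rsplit", "n",
    "a_pairs", "b_pairs", "a_norm", "b_norm", "sampen",
    "degenerate_flag", "element_comparisons",
)


def read_series(
    path: str,
    format: Optional[str] = None,
    column: Union[str, int, None] = None,
) -> TimeSeries:
    """Read a series from a plain-text or CSV file.

    ``format`` is ``"plain_text"`` or ``"csv"``; when omitted it is inferred
    from the file extension (``.csv`` -> csv).  For CSV, ``column`` selects
    the numeric column by name or 0-based index (default: first column).
    Non-numeric or non-finite entries raise a ``ValueError`` naming the
    offending line.
    """
    if format is None:
        format = "csv" if str(path).lower().endswith(".csv") else "plain_text"
    if format == "plain_text":
        return _read_plain(path)
    if format == "csv":
        return _read_csv(path, column)
    raise ValueError(f"unknown format {format!r}; expected 'plain_text' or 'csv'")


def _read_plain(path: str) -> TimeSeries:
    values = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                v = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: not a number: {text!r}"
                ) from None
            if not math.isfinite(v):
                raise ValueError(f"{path}: line {lineno}: non-finite value {text!r}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no values found")
    return TimeSeries(np.asarray(values, dtype=float))


def _read_csv(path: str, column: Union[str, int, None]) -> TimeSeries:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: no rows found")
    if column is None:
        col = frame.columns[0]
    elif isinstance(column, int):
        try:
            col = frame.columns[column]
        except IndexError:
            raise ValueError(f"{path}: no column with index {column}") from None
    else:
        if column not in frame.columns:
            raise ValueError(f"{path}: no column named {column!r}")
        col = column
    raw = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(raw))
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(
            f"{path}: line {int(bad[0]) + 2}: non-numeric or non-finite value "
            f"in column {col!r}"
        )
    return TimeSeries(raw)


def filter_ectopics(
    series: TimeSeries,
    threshold_fraction: float = 0.2,
    window: int = 11,
) -> Tuple[TimeSeries, np.ndarray]:
    """Remove intervals far from their centered running median.

    A value is removed when it deviates from the running median of its
    ``window`` neighbours (centered, truncated at the edges) by more than
    ``threshold_fraction`` times that median.  Intended for positive series
    (RR intervals).  Returns the filtered series and the removed indices.

    This rule is a pragmatic surrogate for ectopic-beat removal; it is not a
    clinically validated detector.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    v = as_series(series).values
    med = (
        pd.Series(v).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    removed = np.flatnonzero(np.abs(v - med) > threshold_fraction * med)
    keep = np.ones(v.size, dtype=bool)
    keep[removed] = False
    if not keep.any():
        raise ValueError("filter removed every value; threshold too aggressive")
    return TimeSeries(v[keep]), removed


def _result_record(result: SampEnResult) -> dict:
    return {
        "algorithm": result.algorithm,
        "m": result.params.m,
        "r_input": result.params.r_input,
        "r_mode": result.params.r_mode,
        "r_abs": result.params.r_abs,
        "rsplit": result.params.rsplit,
        "n": result.n,
        "a_pairs": result.counts.a_pairs,
        "b_pairs": result.counts.b_pairs,
        "a_norm": result.a_norm,
        "b_norm": result.b_norm,
        "sampen": "inf" if result.is_infinite else result.value,
        "degenerate_flag": result.degenerate_flag,
        "element_comparisons": result.counts.element_comparisons,
    }


def write_result(result: SampEnResult, format: str = "json") -> str:
    """Serialise a result to a JSON object or a two-row TSV document.

    An infinite entropy is written as the string ``"inf"``.  Reading the
    document back with :func:`read_result` recovers identical counts.
    """
    record = _result_record(result)
    if format == "json":
        return json.dumps(record, indent=2)
    if format == "tsv":
        header = "\t".join(_RESULT_FIELDS)
        row = "\t".join(str(record[f]) for f in _RESULT_FIELDS)
        return header + "\n" + row + "\n"
    raise ValueError(f"unknown format {format!r}; expected 'json' or 'tsv'")


def read_result(document: str, format: str = "json") -> dict:
    """Parse a serialised result document back into a plain dict."""
    if format == "json":
        record = json.loads(document)
    elif format == "tsv":
        lines = [ln for ln in document.splitlines() if ln.strip()]
        if len(lines) != 2:
            raise ValueError("TSV result must have exactly a header and one row")
        header = lines[0].split("\t")
        row = lines[1].split("\t")
        record = dict(zip(header, row))
        for key in ("m", "rsplit", "n", "a_pairs", "b_pairs", "element_comparisons"):
            record[key] = int(record[key])
        for key in ("r_input", "r_abs", "a_norm", "b_norm"):
            record[key] = float(record[key])
    else:
        raise ValueError(f"unknown format {format!r}")
    if record.get("sampen") == "inf":
        record["sampen"] = math.inf
    else:
        record["sampen"] = float(record["sampen"])
    return record
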