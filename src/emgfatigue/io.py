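"""Reading sEMG sample streams and label tables; writing per-segment reports.

Sample streams are plain delimited text (CSV/TSV/whitespace), one sample per
row, optionally with a leading time column.  The time column, when present and
not explicitly selected, is validated for approximate uniformity (maximum
deviation 1% of the sample interval) and then discarded: the sampling rate is
always supplied by the caller (default 2000 Hz).
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .record import EMGRecord, DEFAULT_FS
from .classifier import (
    FatigueReport,
    SegmentClassification,
    SubBandAnalysis,
    LABEL_FATIGUE,
    LABEL_NON_FATIGUE,
)

LABEL_NOT_EXAMINED = "not-examined"
_LABEL_VOCABULARY = {LABEL_FATIGUE, LABEL_NON_FATIGUE, LABEL_NOT_EXAMINED}

# %.17g round-trips IEEE doubles exactly through text
_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "," in line:
                    return ","
                if "\t" in line:
                    return "\t"
                return r"\s+"
    raise ValueError(f"{path}: file is empty")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def read_signal(
    path: str,
    fs: float = DEFAULT_FS,
    column: int | str | None = None,
    delimiter: str | None = None,
    label: str = "",
) -> EMGRecord:
    """Read a single-channel sample stream from delimited text.

    Parameters
    ----------
    path : str
        File with one sample per row; an optional header row and an optional
        leading time column are handled.
    fs : float
        Sampling rate in Hz (must be positive).
    column : int, str, optional
        Amplitude column, by 0-based position or header name.  When omitted:
        single-column files use that column; multi-column files treat the
        first column as time (validated for uniformity against ``fs``) and
        the second as amplitude.
    delimiter : str, optional
        Field delimiter; sniffed from the file when omitted.
    """
    if not (fs > 0):
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such signal file: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, header=None, dtype=str, skip_blank_lines=True,
        engine="python",
    )
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df = df.apply(lambda c: c.str.strip() if c.dtype == object else c)

    first_row = [str(v) for v in df.iloc[0]]
    has_header = not all(_is_number(v) for v in first_row)
    if has_header:
        names = first_row
        df = df.iloc[1:].reset_index(drop=True)
        df.columns = names
        if df.empty:
            raise ValueError(f"{path}: header but no data rows")
    header_offset = 1 if has_header else 0

    def to_numeric(col: pd.Series, colname) -> np.ndarray:
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            pos = int(np.argmax(bad))
            raise ValueError(
                f"{path}: non-numeric value {col.iloc[pos]!r} in column "
                f"{colname} at row {pos + 1 + header_offset}"
            )
        out = vals.to_numpy(dtype=float)
        if not np.all(np.isfinite(out)):
            pos = int(np.argmax(~np.isfinite(out)))
            raise ValueError(f"{path}: non-finite value at row {pos + 1 + header_offset}")
        return out

    ncol = df.shape[1]
    if column is not None:
        if isinstance(column, str):
            if not has_header or column not in df.columns:
                raise ValueError(f"{path}: no column named {column!r}")
            amp_col = df[column]
            colname = column
        else:
            if not (0 <= int(column) < ncol):
                raise ValueError(f"{path}: column index {column} out of range")
            amp_col = df.iloc[:, int(column)]
            colname = column
        samples = to_numeric(amp_col, colname)
    elif ncol == 1:
        samples = to_numeric(df.iloc[:, 0], 0)
    else:
        times = to_numeric(df.iloc[:, 0], 0)
        samples = to_numeric(df.iloc[:, 1], 1)
        dt = np.diff(times)
        if dt.size and np.max(np.abs(dt - 1.0 / fs)) > 0.01 / fs:
            raise ValueError(
                f"{path}: time column is not uniform at fs={fs} Hz "
                "(max deviation exceeds 1% of the sample interval)"
            )
    return EMGRecord(samples=samples, fs=fs, label=label)


# ---------------------------------------------------------------------------
# label tables
# ---------------------------------------------------------------------------


@dataclass
class MuscleLabels:
    """Ordered per-segment labels for one muscle."""

    muscle_id: str
    labels: tuple[str, ...]
    examined: bool


@dataclass
class LabelTable:
    """Per-muscle reference/predicted segment labels (e.g. a study's accounting table)."""

    rows: list[MuscleLabels]

    def __len__(self) -> int:
        return len(self.rows)

    def usable_rows(self) -> list[MuscleLabels]:
        """Rows with at least one examined segment."""
        return [r for r in self.rows if r.examined]


def _normalise_label(raw: str) -> str:
    lab = str(raw).strip().lower().replace(" ", "-").replace("_", "-")
    if lab not in _LABEL_VOCABULARY:
        raise ValueError(
            f"unknown label {raw!r}; expected one of {sorted(_LABEL_VOCABULARY)}"
        )
    return lab


def read_label_table(path: str) -> LabelTable:
    """Read a per-muscle segment-label table from CSV.

    Columns whose header starts with ``seg`` hold the ordered labels (vocabulary:
    fatigue / non-fatigue / not-examined, case-insensitive); the remaining
    columns form the muscle identifier.  Fully not-examined rows are retained
    but flagged unusable.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such label table: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty label table") from None
    if df.empty:
        raise ValueError(f"{path}: label table has no rows")
    label_cols = [c for c in df.columns if str(c).lower().startswith("seg")]
    if not label_cols:
        raise ValueError(f"{path}: no segment label columns (headers starting with 'seg')")
    id_cols = [c for c in df.columns if c not in label_cols]
    rows: list[MuscleLabels] = []
    for _, r in df.iterrows():
        labels = tuple(_normalise_label(r[c]) for c in label_cols)
        muscle_id = " ".join(str(r[c]) for c in id_cols) if id_cols else f"row{len(rows) + 1}"
        examined = any(l != LABEL_NOT_EXAMINED for l in labels)
        if examined and sum(l != LABEL_NOT_EXAMINED for l in labels) < 2:
            raise ValueError(f"{path}: muscle {muscle_id!r} has fewer than 2 labelled segments")
        rows.append(MuscleLabels(muscle_id=muscle_id, labels=labels, examined=examined))
    return LabelTable(rows=rows)


# ---------------------------------------------------------------------------
# per-segment reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "segment_index", "t_start_s", "iemg", "gate_passed",
    "ima_lfss", "ima_hfss", "fatigue_index", "label",
)


def _segment_row(s: SegmentClassification) -> dict:
    return {
        "segment_index": s.index + 1,  # reported 1-based
        "t_start_s": s.t_start,
        "iemg": s.iemg,
        "gate_passed": s.gate_passed,
        "ima_lfss": None if s.subband is None else s.subband.ima_lfss,
        "ima_hfss": None if s.subband is None else s.subband.ima_hfss,
        "fatigue_index": None if s.subband is None else s.subband.fatigue_index,
        "label": s.label,
    }


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return str(v)


def write_report(report: FatigueReport, path: str, format: str = "csv") -> None:
    """Write a fatigue report to CSV (one row per segment) or JSON.

    Numeric fields are written with full double precision so the file
    round-trips bit-for-bit through :func:`read_report`.
    """
    if not report.segments:
        raise ValueError("cannot write an empty report")
    if format == "csv":
        lines = [",".join(REPORT_COLUMNS)]
        for s in report.segments:
            row = _segment_row(s)
            lines.append(",".join(_fmt(row[c]) for c in REPORT_COLUMNS))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "segments": [_segment_row(s) for s in report.segments],
            "summary": report.summary(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r} (use 'csv' or 'json')")


def _classification_from_row(row: dict) -> SegmentClassification:
    sub = None
    if row.get("ima_lfss") not in (None, ""):
        sub = SubBandAnalysis(
            ima_lfss=float(row["ima_lfss"]), ima_hfss=float(row["ima_hfss"])
        )
    gate = row["gate_passed"]
    if isinstance(gate, str):
        gate = gate.strip().lower() == "true"
    return SegmentClassification(
        index=int(row["segment_index"]) - 1,
        t_start=float(row["t_start_s"]),
        iemg=float(row["iemg"]),
        gate_passed=bool(gate),
        subband=sub,
        label=str(row["label"]),
    )


def read_report(path: str) -> FatigueReport:
    """Read back a report written by :func:`write_report` (format inferred)."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("{"):
        payload = json.loads(text)
        segs = [_classification_from_row(r) for r in payload["segments"]]
        return FatigueReport(segments=segs, iemg_initial=float(payload["summary"]["iemg_initial"]))
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split(",")
    segs = []
    for line in lines[1:]:
        row = dict(zip(header, line.split(",")))
        segs.append(_classification_from_row(row))
    if not segs:
        raise ValueError(f"{path}: empty report")
    # the baseline is the first segment's IEMG by construction
    return FatigueReport(segments=segs, iemg_initial=segs[0].iemg)
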