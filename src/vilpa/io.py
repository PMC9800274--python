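"""Reading and writing the pipeline's tabular formats.

Epoch series, covariates, outcomes and exposure tables travel as CSV
(gzip-compressed files are accepted transparently by suffix); timestamps
are ISO-8601. Epoch tables can reach tens of millions of rows, so they go
through pyarrow's CSV engine. Schema violations raise
:class:`~vilpa.errors.InputError` naming the offending columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.csv as pacsv

from .bouts import EpochSeries
from .errors import InputError

EPOCH_COLUMNS = ["participant_id", "timestamp", "state", "accel_mg"]


def read_table(path, required_columns=(), name: str = "table") -> pd.DataFrame:
    """Read a CSV table (optionally gzipped), checking required columns."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{name} file not found: {path}")
    try:
        df = pacsv.read_csv(str(path)).to_pandas()
    except pa.ArrowInvalid as err:
        raise InputError(f"{name} file {path} is empty or malformed: {err}") from err
    if df.empty:
        raise InputError(f"{name} file has no rows: {path}")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(f"{name} file {path} missing columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = pa.Table.from_pandas(df, preserve_index=False)
    if path.suffix == ".gz":
        with pa.CompressedOutputStream(str(path), "gzip") as out:
            pacsv.write_csv(table, out)
    else:
        pacsv.write_csv(table, str(path))


def read_epochs(path) -> list[EpochSeries]:
    """Read an epoch CSV into per-participant :class:`EpochSeries`.

    Columns: participant_id, timestamp (ISO-8601), state, accel_mg.
    Validation (state labels, non-negative acceleration, strictly
    increasing constant-spaced timestamps within a day) happens per
    participant and reports the participant id on failure.
    """
    df = read_table(path, EPOCH_COLUMNS, name="epoch")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as err:
        raise InputError(f"epoch file {path}: unparseable timestamps ({err})") from err

    # whole-frame validation (much faster than per-participant checks)
    from .bouts import EPOCH_SECONDS, STATES

    bad_states = set(df["state"].unique()) - set(STATES)
    if bad_states:
        raise InputError(f"epoch file {path}: unknown state labels {sorted(bad_states)}")
    accel = df["accel_mg"].to_numpy(dtype=float)
    if not np.all(np.isfinite(accel)) or (accel < 0).any():
        raise InputError(f"epoch file {path}: accel_mg must be finite and non-negative")
    same_participant = df["participant_id"].eq(df["participant_id"].shift())
    same_day = df["timestamp"].dt.normalize().diff().eq(pd.Timedelta(0))
    step = df["timestamp"].diff()
    bad = same_participant & same_day & step.ne(pd.Timedelta(seconds=EPOCH_SECONDS))
    if bad.any():
        pids = sorted(df.loc[bad, "participant_id"].unique().tolist())
        raise InputError(
            f"epoch file {path}: non-monotone or irregular timestamps for "
            f"participants {pids[:5]}"
        )
    return [
        EpochSeries(pid, sub[["timestamp", "state", "accel_mg"]], validate=False)
        for pid, sub in df.groupby("participant_id", sort=True)
    ]


def write_epochs(series_list, path) -> None:
    """Write one or many epoch series to a single CSV (ISO-8601 timestamps)."""
    if isinstance(series_list, EpochSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        frame = s.data.copy()
        frame.insert(0, "participant_id", s.participant_id)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    # accelerations carry device noise far below 0.01 mg resolution
    out["accel_mg"] = out["accel_mg"].round(2)
    table = pa.Table.from_pandas(out, preserve_index=False)
    i = table.schema.get_field_index("timestamp")
    table = table.set_column(
        i, "timestamp", table.column("timestamp").cast(pa.timestamp("s"))
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".gz":
        with pa.CompressedOutputStream(str(path), "gzip") as fh:
            pacsv.write_csv(table, fh)
    else:
        pacsv.write_csv(table, str(path))
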