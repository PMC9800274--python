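"""Epoch-level bout detection and VILPA exposure construction.

This module turns a per-participant series of 10-second accelerometer epochs
(each carrying an activity-class label and a mean acceleration in
milli-gravity) into the exposure variables used by the survival models:

* intensity assignment from activity class and acceleration
  (walking/running: <100 mg light, 100-<400 mg moderate, >=400 mg vigorous);
* maximal runs of consecutive vigorous epochs ("raw bouts"), categorised as
  short (<=1 min, i.e. <=6 epochs), short (<=2 min, 7-12 epochs) or long VPA
  (>12 consecutive vigorous windows);
* length standardization of short bouts by a rolling sum (each completed
  standard length of 60 or 120 s counts as one analytic bout, excess at a
  completion is discarded, the terminal remainder counts fractionally);
* wear-validity filtering (a monitoring day is valid if worn-time exceeds
  16 h; a participant is included with >=3 valid days of which >=1 falls on
  a weekend);
* per-valid-day aggregation averaged across valid days, and winsorization of
  the exposure distribution at an upper percentile (97.5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

EPOCH_SECONDS = 10
#: epochs per bout-category boundary: <=6 epochs is a <=1-min bout,
#: 7..12 epochs a <=2-min bout, >12 epochs counts as a long VPA session
MAX_EPOCHS_1MIN = 6
MAX_EPOCHS_2MIN = 12

STATES = ("nonwear", "sleep", "sedentary", "standing", "walking", "running")
INTENSITIES = ("nonwear", "sleep", "sedentary", "light", "moderate", "vigorous")

LIGHT_THRESHOLD_MG = 100.0
VIGOROUS_THRESHOLD_MG = 400.0

MIN_WEAR_HOURS = 16.0
MIN_VALID_DAYS = 3
MIN_VALID_WEEKEND_DAYS = 1

#: exposure columns subject to percentile capping
VILPA_EXPOSURE_COLUMNS = (
    "vilpa_min_per_day_1min",
    "vilpa_min_per_day_2min",
    "freq_std_1min",
    "freq_std_2min",
)

EXPOSURE_COLUMNS = VILPA_EXPOSURE_COLUMNS + (
    "long_vpa_min_per_day",
    "long_vpa_freq",
    "light_min_per_day",
    "moderate_min_per_day",
    "sleep_h_per_day",
)


class EpochSeries:
    """Ordered 10-s epochs for one participant.

    Parameters
    ----------
    participant_id
        Identifier carried through to every derived record.
    data
        DataFrame with columns ``timestamp`` (datetime64), ``state`` (one of
        :data:`STATES`) and ``accel_mg`` (mean acceleration, milli-gravity).
        Timestamps must be strictly increasing with constant 10-s spacing
        within each calendar day.
    """

    def __init__(self, participant_id, data: pd.DataFrame, *, validate: bool = True):
        self.participant_id = participant_id
        self.data = data.reset_index(drop=True)
        self.epoch_seconds = EPOCH_SECONDS
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.data
        missing = {"timestamp", "state", "accel_mg"} - set(df.columns)
        if missing:
            raise InputError(f"epoch series missing columns: {sorted(missing)}")
        bad_states = set(df["state"].unique()) - set(STATES)
        if bad_states:
            raise InputError(f"unknown state labels: {sorted(bad_states)}")
        accel = df["accel_mg"].to_numpy(dtype=float)
        if not np.all(np.isfinite(accel)) or (accel < 0).any():
            raise InputError("accel_mg must be finite and non-negative")
        ts = pd.to_datetime(df["timestamp"])
        day = ts.dt.normalize()
        step = ts.diff()
        same_day = day.eq(day.shift())
        within = step[same_day]
        if len(within) and not (within == pd.Timedelta(seconds=EPOCH_SECONDS)).all():
            raise InputError(
                "timestamps must be strictly increasing with constant "
                f"{EPOCH_SECONDS}-s spacing within a day"
            )
        self.data = df.assign(timestamp=ts)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def days(self) -> pd.Series:
        """Calendar date (normalized timestamp) of every epoch."""
        return self.data["timestamp"].dt.normalize()


@dataclass(frozen=True)
class DayValidity:
    """Wear-rule outcome for one participant."""

    valid_days: pd.DatetimeIndex
    participant_included: bool
    wear_hours: pd.Series  # indexed by date, all monitored days


def classify_intensity(state, accel_mg):
    """Map an activity class + acceleration to an intensity label.

    The activity class takes precedence: sedentary epochs stay sedentary and
    standing maps to light regardless of acceleration; sleep and nonwear pass
    through. Ambulatory classes (walking, running) are split by the mean
    acceleration of the window: <100 mg light, 100-<400 mg moderate,
    >=400 mg vigorous.

    Accepts scalars or equal-length array-likes and returns a scalar string
    or an object-dtype numpy array accordingly.
    """
    scalar = np.isscalar(state) or isinstance(state, str)
    states = np.atleast_1d(np.asarray(state, dtype=object))
    accel = np.atleast_1d(np.asarray(accel_mg, dtype=float))
    unknown = set(np.unique(states)) - set(STATES)
    if unknown:
        raise InputError(f"unknown state labels: {sorted(unknown)}")
    if (accel < 0).any() or not np.all(np.isfinite(accel)):
        raise InputError("accel_mg must be finite and non-negative")

    out = np.empty(states.shape, dtype=object)
    for passthrough in ("nonwear", "sleep", "sedentary"):
        out[states == passthrough] = passthrough
    out[states == "standing"] = "light"
    ambulatory = (states == "walking") | (states == "running")
    out[ambulatory & (accel < LIGHT_THRESHOLD_MG)] = "light"
    out[ambulatory & (accel >= LIGHT_THRESHOLD_MG) & (accel < VIGOROUS_THRESHOLD_MG)] = "moderate"
    out[ambulatory & (accel >= VIGOROUS_THRESHOLD_MG)] = "vigorous"
    return out[0] if scalar else out


def _categorize(n_epochs: np.ndarray) -> np.ndarray:
    cat = np.where(
        n_epochs <= MAX_EPOCHS_1MIN,
        "short_1min",
        np.where(n_epochs <= MAX_EPOCHS_2MIN, "short_2min", "long_vpa"),
    )
    return cat.astype(object)


def detect_bouts(series: EpochSeries) -> pd.DataFrame:
    """Find maximal runs of consecutive vigorous epochs within each day.

    Runs never cross a calendar-day boundary (a run spanning midnight is
    split). Returns a DataFrame with one row per raw bout and columns
    ``participant_id, day_index, start_epoch, n_epochs, duration_s,
    category``; ``start_epoch`` indexes into the participant's epoch series.
    """
    df = series.data
    intensity = classify_intensity(
        df["state"].to_numpy(dtype=object), df["accel_mg"].to_numpy(dtype=float)
    )
    vig = np.asarray(intensity == "vigorous")
    days = series.days
    day0 = days.iloc[0] if len(days) else pd.Timestamp(0)
    day_index = ((days - day0).dt.days).to_numpy() if len(days) else np.array([], dtype=int)

    if not vig.any():
        return pd.DataFrame(
            columns=[
                "participant_id",
                "day_index",
                "start_epoch",
                "n_epochs",
                "duration_s",
                "category",
            ]
        )

    # run boundaries: a new run starts where vigorous begins or the day changes
    start = vig & (
        ~np.roll(vig, 1) | (day_index != np.roll(day_index, 1))
    )
    start[0] = vig[0]
    end = vig & (
        ~np.roll(vig, -1) | (day_index != np.roll(day_index, -1))
    )
    end[-1] = vig[-1]

    starts = np.flatnonzero(start)
    ends = np.flatnonzero(end)
    n_epochs = ends - starts + 1
    return pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "day_index": day_index[starts],
            "start_epoch": starts,
            "n_epochs": n_epochs,
            "duration_s": n_epochs * EPOCH_SECONDS,
            "category": _categorize(n_epochs),
        }
    )


def standardize_bouts(durations_s, standard_s: int) -> float:
    """Length-standardized bout count from raw bout durations.

    Accumulates the durations (seconds, temporal order) in a rolling sum;
    each time the sum reaches or exceeds ``standard_s`` the count is
    incremented by one and the sum reset to zero, so excess beyond the
    standard length is discarded. The terminal remainder contributes
    fractionally as ``remainder / standard_s``. Full precision is retained;
    round only for display.

    >>> round(standardize_bouts([20, 30, 20, 40, 10], 60), 2)
    1.83
    """
    if standard_s not in (60, 120):
        raise InputError(f"standard_s must be 60 or 120, got {standard_s}")
    count = 0
    running = 0.0
    for d in durations_s:
        d = float(d)
        if d <= 0:
            raise InputError(f"bout duration must be positive, got {d}")
        if d > standard_s:
            raise InputError(
                f"bout duration {d} s exceeds standard length {standard_s} s "
                "(category mismatch)"
            )
        running += d
        if running >= standard_s:
            count += 1
            running = 0.0
    return count + running / standard_s


def validate_days(series: EpochSeries) -> DayValidity:
    """Apply the wear-validity rules to one participant.

    A monitoring day is valid iff worn (non-nonwear) time strictly exceeds
    16 h; the participant is included iff they have at least three valid days
    of which at least one is a Saturday or Sunday.
    """
    df = series.data
    worn = df["state"].to_numpy(dtype=object) != "nonwear"
    days = series.days
    wear_seconds = (
        pd.Series(worn.astype(float) * EPOCH_SECONDS).groupby(days.to_numpy()).sum()
    )
    wear_hours = wear_seconds / 3600.0
    wear_hours.index = pd.DatetimeIndex(wear_hours.index)
    valid = wear_hours[wear_hours > MIN_WEAR_HOURS].index
    n_weekend = int((valid.dayofweek >= 5).sum())
    included = len(valid) >= MIN_VALID_DAYS and n_weekend >= MIN_VALID_WEEKEND_DAYS
    return DayValidity(valid_days=valid, participant_included=included, wear_hours=wear_hours)


def compute_exposures(
    series: EpochSeries,
    bouts: pd.DataFrame | None = None,
    validity: DayValidity | None = None,
) -> pd.Series:
    """Per-participant exposure record averaged over valid days.

    Durations, standardized frequencies, light/moderate minutes and sleep
    hours are computed within each valid day and then averaged across valid
    days; invalid days contribute nothing. Raises :class:`InputError` when
    the participant has zero valid days (an exclusion, not a record).
    """
    if bouts is None:
        bouts = detect_bouts(series)
    if validity is None:
        validity = validate_days(series)
    valid_days = validity.valid_days
    n_valid = len(valid_days)
    if n_valid == 0:
        raise InputError(
            f"participant {series.participant_id} has zero valid days"
        )

    df = series.data
    days = series.days
    day0 = days.iloc[0]
    valid_day_idx = np.array(sorted((valid_days - day0).days))

    intensity = classify_intensity(
        df["state"].to_numpy(dtype=object), df["accel_mg"].to_numpy(dtype=float)
    )
    day_index = (days - day0).dt.days.to_numpy()
    on_valid = np.isin(day_index, valid_day_idx)

    minutes = EPOCH_SECONDS / 60.0
    light_min = float(np.sum(on_valid & (intensity == "light"))) * minutes / n_valid
    moderate_min = float(np.sum(on_valid & (intensity == "moderate"))) * minutes / n_valid
    sleep_h = float(np.sum(on_valid & (intensity == "sleep"))) * minutes / 60.0 / n_valid

    # per-valid-day bout aggregation
    dur_1 = dur_2 = 0.0
    f1 = f2 = 0.0
    long_min = 0.0
    long_n = 0.0
    for d in valid_day_idx:
        day_bouts = bouts[bouts["day_index"] == d]
        short1 = day_bouts[day_bouts["n_epochs"] <= MAX_EPOCHS_1MIN]
        short2 = day_bouts[day_bouts["n_epochs"] <= MAX_EPOCHS_2MIN]
        long_b = day_bouts[day_bouts["n_epochs"] > MAX_EPOCHS_2MIN]
        dur_1 += short1["duration_s"].sum() / 60.0
        dur_2 += short2["duration_s"].sum() / 60.0
        f1 += standardize_bouts(short1["duration_s"].tolist(), 60)
        f2 += standardize_bouts(short2["duration_s"].tolist(), 120)
        long_min += long_b["duration_s"].sum() / 60.0
        long_n += len(long_b)

    return pd.Series(
        {
            "participant_id": series.participant_id,
            "n_valid_days": n_valid,
            "vilpa_min_per_day_1min": dur_1 / n_valid,
            "vilpa_min_per_day_2min": dur_2 / n_valid,
            "freq_std_1min": f1 / n_valid,
            "freq_std_2min": f2 / n_valid,
            "long_vpa_min_per_day": long_min / n_valid,
            "long_vpa_freq": long_n / n_valid,
            "light_min_per_day": light_min,
            "moderate_min_per_day": moderate_min,
            "sleep_h_per_day": sleep_h,
        }
    )


def extract_exposures(series_list) -> tuple[pd.DataFrame, dict]:
    """Run wear validation + exposure construction over a cohort.

    Returns the exposure table (participants passing the wear rules) and a
    log of counts in/out mirroring a sample-derivation flow diagram.
    """
    records = []
    n_in = 0
    n_excluded = 0
    for series in series_list:
        n_in += 1
        validity = validate_days(series)
        if not validity.participant_included:
            n_excluded += 1
            continue
        records.append(compute_exposures(series, validity=validity))
    table = pd.DataFrame(records).reset_index(drop=True)
    log = {"n_input": n_in, "n_excluded_wear_rules": n_excluded, "n_retained": len(table)}
    return table, log


def cap_exposures(records: pd.DataFrame, percentile: float = 97.5) -> pd.DataFrame:
    """Winsorize the VILPA exposure columns at an upper percentile.

    Each exposure column is capped at its own empirical percentile (linear
    interpolation definition), limiting the influence of sparse data in the
    upper tail. Returns a new DataFrame; the input is untouched. With fewer
    than 40 records the percentile is not meaningful: a warning is issued and
    the records are returned uncapped.
    """
    if not 0 < percentile < 100:
        raise InputError(f"percentile must be in (0, 100), got {percentile}")
    if len(records) < 40:
        warnings.warn(
            f"only {len(records)} records: percentile capping skipped",
            stacklevel=2,
        )
        return records.copy()
    out = records.copy()
    for col in VILPA_EXPOSURE_COLUMNS:
        if col in out.columns:
            cap = float(np.percentile(out[col].to_numpy(dtype=float), percentile))
            out[col] = out[col].clip(upper=cap)
    return out
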