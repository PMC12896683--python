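"""Epoch and trial-table data model.

The core containers mirror the conventions of epoched M/EEG analysis:

* a **trial table** (:class:`pandas.DataFrame`) with one row per trial,
  carrying the experimental condition labels (distractor presence and
  location, target location, the session's high-probability hemifield) and
  the derived previous-trial (N-1) labels;
* an :class:`EpochSet` holding a ``trials x sensors x samples`` array with a
  uniform time axis in seconds.

Time conventions: 0.0 s marks placeholder-display onset and 1.5 s marks
search-display onset.  All time intervals in this package are half-open
``[t0, t1)``: a sample at time t belongs to the interval iff ``t0 <= t < t1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "EpochSet",
    "validate_trial_table",
    "attach_previous_labels",
    "read_trial_table_csv",
    "write_epochs",
    "read_epochs",
    "slice_time",
    "baseline_correct",
]

#: Required trial-table columns, in canonical order.
TRIAL_COLUMNS = [
    "session",
    "block",
    "trial",
    "distractor_present",
    "distractor_hemifield",
    "distractor_position",
    "target_hemifield",
    "target_position",
    "high_prob_hemifield",
    "prev_distractor_hemifield",
    "prev_target_hemifield",
]

_HEMIFIELDS = {"left", "right"}
_POSITIONS = {"upper", "lower"}

#: Sampling-grid tolerance, in fractions of one sample.
_GRID_TOL = 1e-6


class TrialTableError(ValueError):
    """Raised when a trial table violates its invariants."""


def _normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with canonical dtypes and column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns: {missing}")
    out = table.loc[:, TRIAL_COLUMNS].copy()
    for col in ("session", "block", "trial"):
        out[col] = out[col].astype(np.int64)
    out["distractor_present"] = out["distractor_present"].astype(bool)
    for col in TRIAL_COLUMNS[4:]:
        vals = out[col].astype(object)
        vals[pd.isna(vals)] = np.nan
        out[col] = vals
    out.reset_index(drop=True, inplace=True)
    return out


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate trial-table invariants; return the normalized table.

    Checks column presence, strict ordering by (session, block, trial),
    the presence/hemifield consistency rule (``distractor_hemifield ==
    'absent'`` iff ``distractor_present`` is False), and category values.
    """
    out = _normalize_table(table)
    keys = list(zip(out["session"], out["block"], out["trial"]))
    if keys != sorted(set(keys)):
        raise TrialTableError(
            "rows must be strictly ordered by (session, block, trial) "
            "with no duplicate keys"
        )
    absent_hemi = out["distractor_hemifield"].eq("absent")
    if not (absent_hemi == ~out["distractor_present"]).all():
        raise TrialTableError(
            "distractor_hemifield must be 'absent' exactly on "
            "distractor-absent trials"
        )
    if not (out["distractor_position"].eq("absent") == ~out["distractor_present"]).all():
        raise TrialTableError(
            "distractor_position must be 'absent' exactly on "
            "distractor-absent trials"
        )
    for col, allowed in [
        ("distractor_hemifield", _HEMIFIELDS | {"absent"}),
        ("distractor_position", _POSITIONS | {"absent"}),
        ("target_hemifield", _HEMIFIELDS),
        ("target_position", _POSITIONS),
        ("high_prob_hemifield", _HEMIFIELDS),
    ]:
        bad = set(out[col].dropna()) - allowed
        if bad:
            raise TrialTableError(f"{col} contains invalid values {bad}")
    for col in ("prev_distractor_hemifield", "prev_target_hemifield"):
        bad = set(out[col].dropna()) - (_HEMIFIELDS | {"absent"})
        if bad:
            raise TrialTableError(f"{col} contains invalid values {bad}")
    return out


def attach_previous_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``prev_*`` columns with the previous trial's labels.

    Previous-trial (N-1) labels are shifted by one within each
    (session, block) group: the first trial of every block has no
    predecessor and gets NA.  Idempotent.
    """
    out = _normalize_table(table)
    keys = list(zip(out["session"], out["block"], out["trial"]))
    if keys != sorted(set(keys)):
        raise TrialTableError(
            "rows must be strictly ordered by (session, block, trial) "
            "with no duplicate keys"
        )
    grp = out.groupby(["session", "block"], sort=False)
    out["prev_distractor_hemifield"] = (
        grp["distractor_hemifield"].shift(1).astype(object)
    )
    out["prev_target_hemifield"] = grp["target_hemifield"].shift(1).astype(object)
    for col in ("prev_distractor_hemifield", "prev_target_hemifield"):
        vals = out[col].astype(object)
        vals[pd.isna(vals)] = np.nan
        out[col] = vals
    return out


def write_trial_table_csv(table: pd.DataFrame, path_or_buf) -> None:
    """Write a trial table as CSV with ``NA`` for missing values."""
    table.to_csv(path_or_buf, index=False, na_rep="NA")


def read_trial_table_csv(path_or_buf) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial_table_csv`."""
    df = pd.read_csv(path_or_buf, keep_default_na=False, na_values=["NA"])
    return _normalize_table(df)


@dataclass
class EpochSet:
    """Epoched multichannel data: ``trials x sensors x samples``.

    Parameters
    ----------
    data
        Real array of shape ``(n_trials, n_sensors, n_samples)``.
    times
        Strictly increasing, uniformly spaced time axis in seconds
        (length ``n_samples``); spacing must equal ``1/sfreq``.
    sfreq
        Sampling rate in Hz.
    trial_table
        Trial table with one row per trial (validated on construction).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    trial_table: pd.DataFrame = field(repr=False)

    #: placeholder-display onset, by convention
    t_placeholder: float = 0.0
    #: search-display onset, by convention
    t_search: float = 1.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        if self.times.ndim != 1 or len(self.times) != self.data.shape[2]:
            raise ValueError("times length must equal the number of samples")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt * self.sfreq - 1.0)) > _GRID_TOL:
                raise ValueError("times spacing inconsistent with sfreq")
        self.trial_table = validate_trial_table(self.trial_table)
        if len(self.trial_table) != self.data.shape[0]:
            raise ValueError(
                f"trial table has {len(self.trial_table)} rows but data has "
                f"{self.data.shape[0]} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (must lie on the grid)."""
        idx = int(np.round((t - self.times[0]) * self.sfreq))
        if idx < 0 or idx >= self.n_samples:
            raise ValueError(f"time {t} s outside epoch span")
        if abs(self.times[idx] - t) * self.sfreq > 0.5 + _GRID_TOL:
            raise ValueError(f"time {t} s does not lie on the sampling grid")
        return idx


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to an HDF5 container.

    Layout: ``/data`` (trials x sensors x samples, float64), ``/times``
    (seconds), ``/sfreq`` (scalar Hz), ``/trial_table`` (UTF-8 CSV bytes),
    plus scalar convention attributes.  Dataset timestamps are disabled so
    two writes of the same EpochSet produce identical payloads.
    """
    buf = io.StringIO()
    write_trial_table_csv(epochs.trial_table, buf)
    csv_bytes = buf.getvalue().encode("utf-8")
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("times", data=epochs.times, track_times=False)
        f.create_dataset("sfreq", data=float(epochs.sfreq), track_times=False)
        f.create_dataset(
            "trial_table",
            data=np.frombuffer(csv_bytes, dtype=np.uint8),
            track_times=False,
        )
        f["data"].attrs["t_placeholder"] = epochs.t_placeholder
        f["data"].attrs["t_search"] = epochs.t_search


def read_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`."""
    with h5py.File(path, "r") as f:
        for key in ("data", "times", "sfreq", "trial_table"):
            if key not in f:
                raise ValueError(f"epoch container missing dataset '{key}'")
        data = f["data"][()]
        times = f["times"][()]
        sfreq = float(f["sfreq"][()])
        csv_bytes = bytes(f["trial_table"][()])
        t_placeholder = float(f["data"].attrs.get("t_placeholder", 0.0))
        t_search = float(f["data"].attrs.get("t_search", 1.5))
    table = read_trial_table_csv(io.StringIO(csv_bytes.decode("utf-8")))
    return EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        trial_table=table,
        t_placeholder=t_placeholder,
        t_search=t_search,
    )


def _interval_indices(times: np.ndarray, sfreq: float, t0: float, t1: float):
    """Sample indices with ``t0 <= t < t1`` on a uniform grid (half-open)."""
    # work in sample units to make the boundary insensitive to float jitter
    rel0 = (t0 - times[0]) * sfreq
    rel1 = (t1 - times[0]) * sfreq
    i0 = max(0, int(np.ceil(rel0 - _GRID_TOL)))
    i1 = min(len(times), int(np.ceil(rel1 - _GRID_TOL)))
    return i0, i1


def slice_time(epochs: EpochSet, t0: float, t1: float) -> EpochSet:
    """Restrict an EpochSet to samples in the half-open window ``[t0, t1)``."""
    if not t0 < t1:
        raise ValueError("t0 must be < t1")
    i0, i1 = _interval_indices(epochs.times, epochs.sfreq, t0, t1)
    if i1 <= i0:
        raise ValueError(f"window [{t0}, {t1}) selects no samples")
    return replace(
        epochs, data=epochs.data[:, :, i0:i1].copy(), times=epochs.times[i0:i1].copy()
    )


def baseline_correct(epochs: EpochSet, b0: float, b1: float) -> EpochSet:
    """Subtract the per-trial, per-sensor mean over ``[b0, b1)``."""
    i0, i1 = _interval_indices(epochs.times, epochs.sfreq, b0, b1)
    span = (epochs.times[0], epochs.times[-1] + 1.0 / epochs.sfreq)
    if i1 <= i0 or b0 < span[0] - _GRID_TOL / epochs.sfreq or b1 > span[1] + _GRID_TOL / epochs.sfreq:
        raise ValueError(
            f"baseline window [{b0}, {b1}) outside epoch span [{span[0]}, {span[1]})"
        )
    base = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)
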