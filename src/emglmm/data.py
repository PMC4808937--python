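"""Domain types and long-format CSV I/O for bilateral shoulder EMG studies.

The unit of observation is one EMG reading (natural-log millivolts) of one
muscle, on one side (affected / unaffected arm), during one movement
(upward / downward), at one 10-degree increment of humeral elevation.  A
*series* is the ordered vector of readings over elevation for a fixed
(patient, muscle, side, movement); series are the blocks on which the AR(1)
residual covariance acts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

MUSCLES = ("PM", "UT", "SA", "RH")
SIDES = ("affected", "unaffected")
MOVEMENTS = ("up", "down")

#: Patient-level covariates.  `dominant_side_measured` is the indicator that
#: the patient's dominant hand is on the affected side; the series-level
#: "measured side is dominant" design column is derived from it.
COVARIATES = (
    "hand_left",
    "dominant_side_measured",
    "age_years",
    "duration_days",
    "spadi_pain_mm",
    "spadi_disability_mm",
    "wle",
    "chemo",
    "exercise_6m",
    "exercise_now",
    "physio_now",
    "physio_ever",
)

KEY_COLUMNS = ("patient_id", "muscle", "side", "movement", "elevation_deg")

_SERIES_KEY = ["patient_id", "muscle", "side", "movement"]


@dataclass(frozen=True)
class SeriesLayout:
    """Ordered bookkeeping of the series stacking.

    One row per (patient, muscle, side, movement) series with its
    half-open row range [start, stop) into the canonical observation table
    and its length ``n_i``.  The ranges partition the table exactly.
    """

    frame: pd.DataFrame  # columns: patient_id, muscle, muscle_idx, side, movement, start, stop, n_i

    def __post_init__(self):
        f = self.frame
        if len(f):
            starts = f["start"].to_numpy()
            stops = f["stop"].to_numpy()
            if starts[0] != 0 or not np.all(starts[1:] == stops[:-1]):
                raise ValueError("series index ranges must partition the table")
            if np.any(f["n_i"].to_numpy() < 1):
                raise ValueError("every series must have n_i >= 1")

    @property
    def n_obs(self) -> int:
        return 0 if not len(self.frame) else int(self.frame["stop"].iloc[-1])

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def patient_slices(self):
        """Yield (patient_id, slice, sub-layout frame) per patient, in order."""
        for pid, grp in self.frame.groupby("patient_id", sort=False):
            yield pid, slice(int(grp["start"].iloc[0]), int(grp["stop"].iloc[-1])), grp


def _canonical_sort(frame: pd.DataFrame) -> pd.DataFrame:
    f = frame.copy()
    f["_m"] = f["muscle"].map({m: i for i, m in enumerate(MUSCLES)})
    f["_s"] = f["side"].map({s: i for i, s in enumerate(SIDES)})
    f["_v"] = f["movement"].map({m: i for i, m in enumerate(MOVEMENTS)})
    f = f.sort_values(["patient_id", "_m", "_s", "_v", "elevation_deg"], kind="mergesort")
    return f.drop(columns=["_m", "_s", "_v"]).reset_index(drop=True)


@dataclass
class ObservationTable:
    """Validated long-format observation table in canonical row order.

    Canonical order is patient, then muscle (PM, UT, SA, RH), side
    (affected first), movement (up first), elevation ascending — the
    stacking order assumed by the design and covariance builders.
    """

    frame: pd.DataFrame
    layout: SeriesLayout = field(init=False, repr=False)

    def __post_init__(self):
        self.frame = self._validate(self.frame)
        self.layout = self._build_layout(self.frame)

    # -- validation -------------------------------------------------------
    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in KEY_COLUMNS + ("log_emg",) if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        f = frame.copy()
        for col, levels in (("muscle", MUSCLES), ("side", SIDES), ("movement", MOVEMENTS)):
            bad = set(f[col].unique()) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} level(s) {sorted(map(str, bad))}; allowed: {levels}")
        y = pd.to_numeric(f["log_emg"], errors="coerce")
        if not np.all(np.isfinite(y)):
            idx = f.index[~np.isfinite(y)][0]
            raise ValueError(f"non-finite log_emg at input row {idx}")
        f["log_emg"] = y.astype(float)
        elev = pd.to_numeric(f["elevation_deg"], errors="coerce")
        if np.any(~np.isfinite(elev)) or np.any(elev <= 0) or np.any(elev % 10 != 0):
            raise ValueError("elevation_deg must be positive multiples of 10 degrees")
        f["elevation_deg"] = elev.astype(int)

        f = _canonical_sort(f)

        # one averaged reading per increment: duplicates within a series are rejected
        dup = f.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            r = f.loc[dup.idxmax()]
            raise ValueError(
                "duplicate elevation within a series: patient "
                f"{r['patient_id']!r} {r['muscle']}/{r['side']}/{r['movement']} at {r['elevation_deg']} deg"
            )

        present_cov = [c for c in COVARIATES if c in f.columns]
        if present_cov:
            nun = f.groupby("patient_id", sort=False)[present_cov].nunique(dropna=False)
            bad = nun[(nun > 1).any(axis=1)]
            if len(bad):
                pid = bad.index[0]
                cols = list(nun.columns[(nun.loc[pid] > 1)])
                raise ValueError(f"covariates {cols} vary within patient {pid!r}")
        return f

    @staticmethod
    def _build_layout(frame: pd.DataFrame) -> SeriesLayout:
        if not len(frame):
            return SeriesLayout(
                pd.DataFrame(
                    columns=["patient_id", "muscle", "muscle_idx", "side", "movement", "start", "stop", "n_i"]
                )
            )
        # series boundaries = change points of the sorted key columns
        change = np.zeros(len(frame), dtype=bool)
        change[0] = True
        for c in _SERIES_KEY:
            a = frame[c].to_numpy()
            change[1:] |= a[1:] != a[:-1]
        starts = np.flatnonzero(change)
        stops = np.append(starts[1:], len(frame))
        head = frame.iloc[starts]
        return SeriesLayout(
            pd.DataFrame(
                {
                    "patient_id": head["patient_id"].to_numpy(),
                    "muscle": head["muscle"].to_numpy(),
                    "muscle_idx": head["muscle"].map({m: i for i, m in enumerate(MUSCLES)}).to_numpy(),
                    "side": head["side"].to_numpy(),
                    "movement": head["movement"].to_numpy(),
                    "start": starts.astype(int),
                    "stop": stops.astype(int),
                    "n_i": (stops - starts).astype(int),
                }
            )
        )

    # -- conveniences -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patients(self) -> pd.Index:
        return pd.Index(self.frame["patient_id"].unique())

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def covariate_frame(self) -> pd.DataFrame:
        """One row per patient with the patient-level covariates."""
        present = [c for c in COVARIATES if c in self.frame.columns]
        return self.frame.groupby("patient_id", sort=False)[present].first()

    def equals(self, other: "ObservationTable") -> bool:
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return a.reset_index(drop=True).equals(b.reset_index(drop=True))


def read_observations(path, schema: dict | None = None) -> ObservationTable:
    """Read a long-format CSV into a validated :class:`ObservationTable`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.  Must carry the key columns
        (patient_id, muscle, side, movement, elevation_deg) and exactly one
        of ``log_emg`` (pre-logged, ln mV) or ``emg_mv`` (raw millivolts, a
        natural log is applied on read).  Patient-level covariate columns
        are optional; patients with missing covariate values are dropped
        (complete-case) with a warning.
    schema : dict, optional
        Mapping of canonical role names to the column names used in the
        file, e.g. ``{"patient_id": "subject", "emg_mv": "emg"}``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if schema:
        rename = {src: role for role, src in schema.items() if src in frame.columns}
        missing = [src for src in schema.values() if src not in frame.columns]
        if missing:
            raise SchemaError(f"schema names columns absent from the file: {missing}")
        frame = frame.rename(columns=rename)

    missing = [c for c in KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    has_log = "log_emg" in frame.columns
    has_raw = "emg_mv" in frame.columns
    if has_log == has_raw:
        raise SchemaError("exactly one of 'log_emg' or 'emg_mv' must be present")
    if has_raw:
        raw = pd.to_numeric(frame["emg_mv"], errors="coerce")
        bad = ~(raw > 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"emg_mv must be > 0 to log-transform; offending value {frame['emg_mv'].iloc[i]!r} "
                f"at data row {i} (patient {frame['patient_id'].iloc[i]!r})"
            )
        frame = frame.drop(columns=["emg_mv"])
        frame["log_emg"] = np.log(raw.to_numpy(dtype=float))

    present_cov = [c for c in COVARIATES if c in frame.columns]
    if present_cov and len(frame):
        miss = frame[present_cov].isna().any(axis=1)
        if miss.any():
            dropped = frame.loc[miss, "patient_id"].unique()
            warnings.warn(
                f"dropping {len(dropped)} patient(s) with missing covariate values "
                f"(complete-case): {list(dropped)[:5]}{'...' if len(dropped) > 5 else ''}",
                UserWarning,
                stacklevel=2,
            )
            frame = frame[~frame["patient_id"].isin(dropped)]
    return ObservationTable(frame)


def _replace_response(table: ObservationTable, y) -> ObservationTable:
    """Internal fast path: same keys/covariates/layout, new log_emg values."""
    frame = table.frame.copy()
    frame["log_emg"] = np.asarray(y, dtype=float)
    out = object.__new__(ObservationTable)
    out.frame = frame
    out.layout = table.layout
    return out


def write_observations(table: ObservationTable, path) -> None:
    """Write a table as CSV that round-trips losslessly through
    :func:`read_observations` (floats at full repr precision)."""
    table.frame.to_csv(path, index=False)
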