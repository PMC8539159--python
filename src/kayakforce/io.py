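"""Data containers and delimited-text I/O for footrest force analysis.

All on-disk formats are plain CSV with a required header, comma separator
and dot decimal:

* force log:          ``time_s,left_N,right_N``
* velocity trace:     ``time_s,velocity_kmh``
* feature table:      one row per paddler-bout (see :class:`FeatureRecord`)
* normalized profile: ``percent,left_mean_N,left_sd_N,right_mean_N,right_sd_N``

Units follow the measurement conventions throughout: time in seconds from
bout start, force in newtons, velocity in km/h.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kayakforce")

#: Recognised age/sex groups of the cohort design.
GROUPS = ("girls U16", "boys U18", "senior women", "senior men")

#: Recognised bout labels: two fixed-velocity bouts and one all-out trial.
BOUTS = ("12 km/h", "15 km/h", "maximal")

_TIME_UNIFORMITY_TOL = 1e-9


class FormatError(ValueError):
    """A file does not conform to the expected delimited-text layout."""


class DataError(ValueError):
    """A file parses but its values violate a data invariant."""


class InsufficientDataError(ValueError):
    """Not enough signal (peaks, cycles, samples) to compute a quantity."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled two-channel (left/right) footrest force signal.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing and uniform.
    left, right : ndarray
        Force in newtons on the left and right footrest plates.
    sampling_rate : float
        Samples per second; must match the time step to within 1e-9 s.
    """

    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if not (len(time) == len(left) == len(right)):
            raise DataError(
                f"channel lengths differ: time={len(time)}, "
                f"left={len(left)}, right={len(right)}"
            )
        if len(time) >= 2:
            dt = np.diff(time)
            if np.any(dt <= 0):
                idx = int(np.argmax(dt <= 0)) + 1
                raise DataError(f"time not strictly increasing at row {idx}")
            if np.max(np.abs(dt - dt[0])) > _TIME_UNIFORMITY_TOL + 1e-12 * abs(time[-1]):
                idx = int(np.argmax(np.abs(dt - dt[0]) > _TIME_UNIFORMITY_TOL)) + 1
                raise DataError(f"non-uniform sampling near row {idx}")
            if abs(1.0 / dt[0] - self.sampling_rate) > _TIME_UNIFORMITY_TOL * self.sampling_rate**2:
                raise DataError(
                    f"sampling_rate {self.sampling_rate} Hz inconsistent with "
                    f"time step {dt[0]} s"
                )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def channel(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.left if side == "left" else self.right


@dataclass(frozen=True)
class VelocityTrace:
    """GPS boat-velocity samples in km/h."""

    time: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        if len(time) != len(vel):
            raise DataError("time and velocity lengths differ")
        if len(time) >= 2 and np.any(np.diff(time) <= 0):
            idx = int(np.argmax(np.diff(time) <= 0)) + 1
            raise DataError(f"time not strictly increasing at row {idx}")
        if np.any(vel < 0):
            raise DataError("negative velocity sample")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "velocity", vel)

    def __len__(self) -> int:
        return len(self.time)

    def mean_over(self, start: float, end: float) -> float:
        """Mean velocity over the closed time window [start, end]."""
        mask = (self.time >= start) & (self.time <= end)
        if not mask.any():
            raise InsufficientDataError(
                f"no velocity samples in window [{start}, {end}] s"
            )
        return float(np.mean(self.velocity[mask]))


@dataclass
class FeatureRecord:
    """Leg-force characteristics of one paddler in one bout.

    The five force characteristics are stroke rate (strokes/min counting
    both sides), mean push force, peak push force (mean of per-cycle
    per-side maxima), force impulse over one stroke cycle, and force
    impulse over 10 s (left + right summed).
    """

    paddler_id: str
    group: str
    bout: str
    velocity_kmh: float
    stroke_rate_spm: float
    mean_force_n: float
    peak_force_n: float
    impulse_cycle_ns: float
    impulse_10s_ns: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.bout not in BOUTS:
            raise DataError(f"unknown bout label {self.bout!r}; expected one of {BOUTS}")
        for name in ("mean_force_n", "peak_force_n", "impulse_cycle_ns", "impulse_10s_ns"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


FEATURE_COLUMNS = [f.name for f in dataclasses.fields(FeatureRecord)]


# ---------------------------------------------------------------------------
# Force logs
# ---------------------------------------------------------------------------

def write_force_log(trace: ForceTrace, path: str | Path) -> None:
    """Write a force trace as CSV with columns time_s,left_N,right_N."""
    df = pd.DataFrame(
        {"time_s": trace.time, "left_N": trace.left, "right_N": trace.right}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_force_log(path: str | Path) -> ForceTrace:
    """Read a force log CSV, validating the header and uniform time base."""
    df = _read_csv(path, required=("time_s", "left_N", "right_N"))
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) >= 2:
        dt = np.diff(time)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise DataError(
                f"{path}: time_s not strictly increasing at data row {bad[0] + 1}"
            )
        fs = 1.0 / float(np.median(dt))
    else:
        fs = 1.0
    return ForceTrace(
        time=time,
        left=df["left_N"].to_numpy(dtype=float),
        right=df["right_N"].to_numpy(dtype=float),
        sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# Velocity traces
# ---------------------------------------------------------------------------

def write_velocity_trace(trace: VelocityTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "velocity_kmh": trace.velocity}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_velocity_trace(path: str | Path) -> VelocityTrace:
    df = _read_csv(path, required=("time_s", "velocity_kmh"))
    return VelocityTrace(
        time=df["time_s"].to_numpy(dtype=float),
        velocity=df["velocity_kmh"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Feature records as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=FEATURE_COLUMNS
    )


def write_feature_table(records: Sequence[FeatureRecord] | pd.DataFrame,
                        path: str | Path) -> None:
    """Write feature records as CSV; an empty list yields a header-only file."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing column(s): {', '.join(missing)}")
    # 17 significant digits so read_feature_table round-trips exactly
    df[FEATURE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> list[FeatureRecord]:
    """Read a feature CSV back into validated :class:`FeatureRecord` objects."""
    df = _read_csv(path, required=tuple(FEATURE_COLUMNS))
    records = []
    for _, row in df.iterrows():
        records.append(
            FeatureRecord(
                paddler_id=str(row["paddler_id"]),
                group=str(row["group"]),
                bout=str(row["bout"]),
                velocity_kmh=float(row["velocity_kmh"]),
                stroke_rate_spm=float(row["stroke_rate_spm"]),
                mean_force_n=float(row["mean_force_n"]),
                peak_force_n=float(row["peak_force_n"]),
                impulse_cycle_ns=float(row["impulse_cycle_ns"]),
                impulse_10s_ns=float(row["impulse_10s_ns"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Normalized profiles
# ---------------------------------------------------------------------------

def write_profile(profile, path: str | Path) -> None:
    """Write a :class:`~kayakforce.preprocess.NormalizedProfile` as CSV."""
    pd.DataFrame(
        {
            "percent": profile.percent,
            "left_mean_N": profile.left_mean,
            "left_sd_N": profile.left_sd,
            "right_mean_N": profile.right_mean,
            "right_sd_N": profile.right_sd,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_profile_frame(path: str | Path) -> pd.DataFrame:
    return _read_csv(
        path,
        required=("percent", "left_mean_N", "left_sd_N", "right_mean_N", "right_sd_N"),
    )


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message suffices
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    non_numeric = [
        c for c in required
        if c in df.columns and df[c].dtype == object and c not in ("paddler_id", "group", "bout")
    ]
    for col in non_numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: column {col!r} is not numeric") from exc
    return df
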