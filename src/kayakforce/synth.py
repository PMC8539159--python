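"""Synthetic force sessions, velocity traces, and paddler cohorts.

The generator emulates the signal morphology of on-water sprint-kayak
footrest recordings: the left and right legs push alternately, each push is
a sinus-like force pulse riding on a small residual pre-load from the foot
strap, and one full stroke cycle spans one left plus one right push.  Every
output carries closed-form ground truth (peak forces, impulses, stroke
rate) so downstream signal processing and statistics can be tested by
parameter recovery instead of against non-public study data.

Conventions
-----------
* ``stroke_rate`` counts pushes on *both* sides: one left push plus one
  right push is two strokes, so a cycle lasts ``2 * 60 / stroke_rate``
  seconds.  Competitive regimes run roughly 74-125 strokes/min.
* Each push is a half-sine of amplitude ``push_peak - baseline`` above the
  baseline, occupying a fraction ``push_duty`` of the half-cycle.  A
  half-sine of amplitude A and width w has area ``2 A w / pi`` above the
  baseline — the closed form the reported truth uses.
* The right-side pulse train is offset by half a cycle, so the left peak
  sits at 0% of the normalized stroke cycle and the right peak near 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ForceTrace, VelocityTrace, FeatureRecord, GROUPS

__all__ = [
    "SessionSpec",
    "SessionTruth",
    "CohortSpec",
    "generate_force_session",
    "generate_velocity_trace",
    "generate_cohort",
]

#: Predictor names a cohort linear map may use.
COHORT_PREDICTORS = (
    "peak_force_n",
    "impulse_10s_ns",
    "stroke_rate_spm",
    "mean_force_n",
    "impulse_cycle_ns",
)


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic on-water bout.

    Parameters
    ----------
    duration : float
        Bout length in seconds.
    stroke_rate : float
        Strokes per minute, counting each side's push as one stroke.
    push_peak_left, push_peak_right : float
        Absolute peak force (N) of each side's push, baseline included.
    push_duty : float
        Fraction of the half-cycle occupied by the push pulse, in (0, 1].
    baseline : float
        Residual strapped-foot force (N) between pushes.
    noise_sd : float
        SD of additive white Gaussian measurement noise (N).
    sampling_rate : float
        Samples per second (default 1000, the acquisition rate emulated).
    seed : int
        Seed for the noise stream.
    """

    duration: float = 20.0
    sampling_rate: float = 1000.0
    stroke_rate: float = 125.0
    push_peak_left: float = 400.0
    push_peak_right: float = 400.0
    push_duty: float = 0.85
    baseline: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("duration", self.duration > 0, "must be > 0"),
            ("sampling_rate", self.sampling_rate > 0, "must be > 0"),
            ("stroke_rate", self.stroke_rate > 0, "must be > 0"),
            ("push_duty", 0 < self.push_duty <= 1, "must be in (0, 1]"),
            ("noise_sd", self.noise_sd >= 0, "must be >= 0"),
            ("baseline", self.baseline >= 0, "must be >= 0"),
            ("push_peak_left", self.push_peak_left >= self.baseline,
             "must be >= baseline"),
            ("push_peak_right", self.push_peak_right >= self.baseline,
             "must be >= baseline"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValueError(f"SessionSpec.{name} {msg} (got {getattr(self, name)})")

    @property
    def cycle_period(self) -> float:
        """Duration of one full left+right stroke cycle in seconds."""
        return 2.0 * 60.0 / self.stroke_rate

    @property
    def push_width(self) -> float:
        """Width of each half-sine push pulse in seconds."""
        return self.push_duty * self.cycle_period / 2.0


@dataclass(frozen=True)
class SessionTruth:
    """Analytically known characteristics of a generated session."""

    stroke_rate_spm: float
    peak_force_left_n: float
    peak_force_right_n: float
    mean_force_n: float
    impulse_cycle_ns: float
    impulse_10s_ns: float
    peak_times_left: np.ndarray
    peak_times_right: np.ndarray

    @property
    def peak_force_n(self) -> float:
        """Mean of the two per-side peak forces (the pooled peak statistic)."""
        return 0.5 * (self.peak_force_left_n + self.peak_force_right_n)


def generate_force_session(spec: SessionSpec) -> tuple[ForceTrace, SessionTruth]:
    """Synthesize a two-channel footrest force trace with known truth.

    The left pulse train starts at t = 0 (first left peak at half a pulse
    width); the right train is delayed by half a cycle.  Identical specs
    give bit-identical traces.

    Returns
    -------
    (ForceTrace, SessionTruth)
        The trace and its closed-form characteristics.  ``mean_force_n``
        is the per-channel average ((left + right) / 2) of the periodic
        signal; impulses are left + right sums above zero (baseline
        included), per cycle and per 10 s of steady paddling.
    """
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    T = spec.cycle_period
    w = spec.push_width

    left = _pulse_train(t, period=T, offset=0.0, width=w,
                        amplitude=spec.push_peak_left - spec.baseline,
                        baseline=spec.baseline, duration=spec.duration)
    right = _pulse_train(t, period=T, offset=T / 2.0, width=w,
                         amplitude=spec.push_peak_right - spec.baseline,
                         baseline=spec.baseline, duration=spec.duration)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        left = left + rng.normal(0.0, spec.noise_sd, size=n)
        right = right + rng.normal(0.0, spec.noise_sd, size=n)

    trace = ForceTrace(time=t, left=left, right=right,
                       sampling_rate=spec.sampling_rate)

    amp_l = spec.push_peak_left - spec.baseline
    amp_r = spec.push_peak_right - spec.baseline
    # Half-sine area above baseline: 2 A w / pi per pulse.
    pulse_area_l = 2.0 * amp_l * w / np.pi
    pulse_area_r = 2.0 * amp_r * w / np.pi
    impulse_cycle = pulse_area_l + pulse_area_r + 2.0 * spec.baseline * T
    mean_force = spec.baseline + (pulse_area_l + pulse_area_r) / (2.0 * T)
    impulse_10s = impulse_cycle * (10.0 / T)

    peaks_left = _peak_times(offset=0.0, period=T, width=w, duration=spec.duration)
    peaks_right = _peak_times(offset=T / 2.0, period=T, width=w,
                              duration=spec.duration)

    truth = SessionTruth(
        stroke_rate_spm=spec.stroke_rate,
        peak_force_left_n=spec.push_peak_left,
        peak_force_right_n=spec.push_peak_right,
        mean_force_n=mean_force,
        impulse_cycle_ns=impulse_cycle,
        impulse_10s_ns=impulse_10s,
        peak_times_left=peaks_left,
        peak_times_right=peaks_right,
    )
    return trace, truth


def _pulse_train(t: np.ndarray, period: float, offset: float, width: float,
                 amplitude: float, baseline: float, duration: float) -> np.ndarray:
    """Baseline plus a periodic half-sine pulse train starting at ``offset``."""
    out = np.full_like(t, baseline)
    if amplitude <= 0 or width <= 0:
        return out
    k = 0
    while True:
        t0 = offset + k * period
        if t0 >= duration:
            break
        phase = (t - t0) / width
        mask = (phase >= 0) & (phase <= 1)
        out[mask] += amplitude * np.sin(np.pi * phase[mask])
        k += 1
    return out


def _peak_times(offset: float, period: float, width: float,
                duration: float) -> np.ndarray:
    """Times of pulse maxima (pulse start + half width) within the bout."""
    times = []
    k = 0
    while True:
        t0 = offset + k * period
        if t0 >= duration:
            break
        tp = t0 + width / 2.0
        if tp < duration:
            times.append(tp)
        k += 1
    return np.asarray(times)


def generate_velocity_trace(
    duration: float,
    target_velocity: float,
    ramp_time: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 1.0,
) -> VelocityTrace:
    """Boat-velocity trace: a monotone ramp to a noisy plateau.

    Emulates a rolling start into a fixed-pace or all-out bout: velocity
    rises linearly from zero over ``ramp_time`` seconds, then holds at
    ``target_velocity`` km/h plus white Gaussian noise.  GPS-like 1 Hz
    sampling by default.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0 (got {duration})")
    if not (0 <= ramp_time < duration):
        raise ValueError(
            f"ramp_time must satisfy 0 <= ramp_time < duration "
            f"(got {ramp_time} vs duration {duration})"
        )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    if ramp_time > 0:
        v = np.minimum(t / ramp_time, 1.0) * target_velocity
    else:
        v = np.full_like(t, target_velocity)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    return VelocityTrace(time=t, velocity=np.clip(v, 0.0, None))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic paddler cohort with a known linear map.

    Two directions are supported:

    * ``direction="velocity_on_features"`` — predictors are drawn from
      independent normals with the stated means/SDs, and velocity is the
      stated linear combination plus Gaussian residual.  This is the
      regime of the maximal-velocity prediction model.
    * ``direction="feature_on_velocity"`` — velocity is drawn uniformly
      over ``velocity_range`` and each named feature is
      ``intercept + slope * velocity`` plus residual.  This is the regime
      of the explanatory (feature-on-velocity) models.

    ``group_offsets`` adds a per-group additive shift to the response,
    with paddlers assigned to groups round-robin.
    """

    n_paddlers: int
    coefficients: Mapping[str, float]
    intercept: float = 0.0
    direction: str = "velocity_on_features"
    predictor_means: Mapping[str, float] = field(default_factory=dict)
    predictor_sds: Mapping[str, float] = field(default_factory=dict)
    velocity_range: tuple[float, float] = (12.0, 20.0)
    residual_sd: float = 0.0
    group_offsets: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("velocity_on_features", "feature_on_velocity"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.coefficients:
            raise ValueError("coefficients must name at least one predictor")
        unknown = set(self.coefficients) - set(COHORT_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictor name(s): {sorted(unknown)}")
        if self.residual_sd < 0:
            raise ValueError(f"residual_sd must be >= 0 (got {self.residual_sd})")
        n_params = len(self.coefficients) + 1
        if self.n_paddlers < n_params + 1:
            raise ValueError(
                f"n_paddlers must be >= {n_params + 1} for a "
                f"{len(self.coefficients)}-predictor model (got {self.n_paddlers})"
            )
        if self.direction == "velocity_on_features" and len(self.coefficients) > 1:
            for name in self.coefficients:
                if self.predictor_sds.get(name, 1.0) == 0:
                    raise ValueError(
                        f"singular design: predictor {name!r} has zero SD "
                        f"with multiple coefficients"
                    )
        if self.group_offsets is not None:
            unknown_groups = set(self.group_offsets) - set(GROUPS)
            if unknown_groups:
                raise ValueError(f"unknown group label(s): {sorted(unknown_groups)}")


#: Default predictor scales for velocity-on-features cohorts: the
#: maximal-effort regime (means and SDs of Fpeak, J10s and SR).
MAXIMAL_EFFORT_SCALE = {
    "peak_force_n": (398.2, 106.2),
    "impulse_10s_ns": (2383.6, 86.9),
    "stroke_rate_spm": (125.0, 12.0),
    "mean_force_n": (289.5, 82.7),
    "impulse_cycle_ns": (554.8, 17.4),
}


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a paddler feature table from a known linear ground truth.

    Returns a DataFrame with one row per paddler carrying ``paddler_id``,
    ``group``, every feature column, and ``velocity_kmh``.  The true
    parameters are attached under ``df.attrs["truth"]`` as a dict with
    keys ``coefficients``, ``intercept``, ``residual_sd``, ``direction``.
    Identical specs (and seeds) give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_paddlers
    groups = (list(spec.group_offsets) if spec.group_offsets else list(GROUPS))
    assigned = [groups[i % len(groups)] for i in range(n)]
    offsets = np.array(
        [spec.group_offsets.get(g, 0.0) if spec.group_offsets else 0.0
         for g in assigned]
    )

    data: dict[str, np.ndarray] = {}
    if spec.direction == "velocity_on_features":
        for name in spec.coefficients:
            mu, sd = MAXIMAL_EFFORT_SCALE.get(name, (0.0, 1.0))
            mu = spec.predictor_means.get(name, mu)
            sd = spec.predictor_sds.get(name, sd)
            data[name] = rng.normal(mu, sd, size=n) if sd > 0 else np.full(n, mu)
        response = spec.intercept + offsets
        for name, coef in spec.coefficients.items():
            response = response + coef * data[name]
        if spec.residual_sd > 0:
            response = response + rng.normal(0.0, spec.residual_sd, size=n)
        data["velocity_kmh"] = response
    else:
        lo, hi = spec.velocity_range
        vel = rng.uniform(lo, hi, size=n)
        data["velocity_kmh"] = vel
        for name, coef in spec.coefficients.items():
            feat = spec.intercept + coef * vel + offsets
            if spec.residual_sd > 0:
                feat = feat + rng.normal(0.0, spec.residual_sd, size=n)
            data[name] = feat

    df = pd.DataFrame(data)
    df.insert(0, "paddler_id", [f"P{i:05d}" for i in range(n)])
    df.insert(1, "group", assigned)
    df.attrs["truth"] = {
        "coefficients": dict(spec.coefficients),
        "intercept": spec.intercept,
        "residual_sd": spec.residual_sd,
        "direction": spec.direction,
    }
    return df
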