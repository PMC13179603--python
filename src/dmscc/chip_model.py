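"""Model of the oscillating-glucose environment inside a dMSCC chip.

The cultivation device drives a square-wave alternation between a glucose
excess medium and a glucose limitation medium with a fixed 30 s period.  The
wave is not delivered with perfect fidelity everywhere on the chip: moving the
laminar flow boundary takes a few seconds, so arrays further from the chip
centre see the switch later (and with distorted phase durations), and finite
medium exchange smooths the profile progressively along each cultivation
array.  This module represents the nominal forcing profile, the chip layout,
a first-order exchange model of the in-chamber concentration, and an
estimator that recovers effective pulse metrics from a measured (dye) trace.

Units: seconds for all durations, g/L for concentrations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "OscillationProfile",
    "ChipLayout",
    "ChamberTrace",
    "PulseMetrics",
    "make_profile",
    "glucose_at",
    "shift_profile",
    "chamber_response",
    "estimate_pulse_metrics",
]

_TOL = 1e-9


@dataclass(frozen=True)
class OscillationProfile:
    """Square-wave glucose forcing: ``excess_s`` seconds at ``c_excess``
    followed by ``limitation_s`` seconds at ``c_limitation`` in every period.

    ``phase_shift_s`` delays the wave (positive = later switch), which is how
    the lateral position of a cultivation array on the chip is encoded.
    """

    excess_s: float
    limitation_s: float
    period_s: float = 30.0
    c_excess: float = 50.0
    c_limitation: float = 0.01
    phase_shift_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("excess_s", "limitation_s", "period_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")
        if abs(self.excess_s + self.limitation_s - self.period_s) > _TOL:
            raise ValueError(
                "excess_s + limitation_s must equal period_s: "
                f"{self.excess_s} + {self.limitation_s} != {self.period_s}"
            )
        if self.c_excess < 0 or self.c_limitation < 0:
            raise ValueError("concentrations must be non-negative")
        if not self.c_excess > self.c_limitation:
            raise ValueError("c_excess must exceed c_limitation")

    @property
    def duty_cycle(self) -> float:
        """Fraction of each period spent at excess glucose (f)."""
        return self.excess_s / self.period_s

    @property
    def amplitude(self) -> float:
        return self.c_excess - self.c_limitation

    @property
    def mean_concentration(self) -> float:
        """Duty-cycle-weighted time average over one period."""
        f = self.duty_cycle
        return f * self.c_excess + (1.0 - f) * self.c_limitation

    def to_dict(self) -> dict:
        return {
            "excess_s": self.excess_s,
            "limitation_s": self.limitation_s,
            "period_s": self.period_s,
            "c_excess": self.c_excess,
            "c_limitation": self.c_limitation,
            "phase_shift_s": self.phase_shift_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OscillationProfile":
        return cls(**d)


@dataclass(frozen=True)
class ChipLayout:
    """Geometry of the cultivation device.

    Arrays are numbered 1..n_arrays across the chip width; chambers are
    numbered 1..chambers_per_array along each array with 1 nearest the inlet.
    Each step away from the central array shifts the oscillation onset by
    ``array_shift_step_s``; the outermost arrays never see the oscillation and
    act as constant-condition controls.
    """

    n_arrays: int = 7
    chambers_per_array: int = 27
    chamber_dims_um: tuple[float, float, float] = (80.0, 90.0, 4.0)
    array_shift_step_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_arrays < 3 or self.n_arrays % 2 == 0:
            raise ValueError("n_arrays must be odd and >= 3")
        if self.chambers_per_array < 1:
            raise ValueError("chambers_per_array must be >= 1")

    @property
    def central_array(self) -> int:
        return (self.n_arrays + 1) // 2


@dataclass
class ChamberTrace:
    """Concentration (or dye fluorescence) sampled on a uniform time grid
    inside one growth chamber.  Time zero coincides with a nominal period
    boundary of the unshifted driving wave."""

    times: np.ndarray
    concentration: np.ndarray
    array_index: int = 1
    chamber_index: int = 1
    nominal: OscillationProfile | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must be 1-D arrays of equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("times must be strictly increasing with uniform step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def save(self, path: str | Path) -> None:
        """Two-column CSV (time_s, value) plus a JSON sidecar with indices
        and the nominal profile."""
        path = Path(path)
        arr = np.column_stack([self.times, self.concentration])
        header = "time_s,value"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        meta = {
            "array_index": self.array_index,
            "chamber_index": self.chamber_index,
            "nominal": self.nominal.to_dict() if self.nominal is not None else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ChamberTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        nominal = meta.get("nominal")
        return cls(
            times=arr[:, 0],
            concentration=arr[:, 1],
            array_index=meta.get("array_index", 1),
            chamber_index=meta.get("chamber_index", 1),
            nominal=OscillationProfile.from_dict(nominal) if nominal else None,
        )


@dataclass(frozen=True)
class PulseMetrics:
    """Effective pulse characteristics recovered from a chamber trace.

    ``definition`` is the achieved concentration amplitude relative to the
    nominal amplitude of the driving wave (1 = perfectly sharp pulses, 0 =
    fully smoothed).  Effective durations are NaN when the trace never
    crosses the half-amplitude threshold.
    """

    effective_excess_s: float
    effective_limitation_s: float
    onset_shift_s: float
    definition: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.definition <= 1.0 + 1e-9):
            raise ValueError("definition must lie in [0, 1]")


def make_profile(
    excess_s: float,
    limitation_s: float,
    period_s: float = 30.0,
    c_excess: float = 50.0,
    c_limitation: float = 0.01,
) -> OscillationProfile:
    """Construct a validated square-wave oscillation profile."""
    return OscillationProfile(
        excess_s=excess_s,
        limitation_s=limitation_s,
        period_s=period_s,
        c_excess=c_excess,
        c_limitation=c_limitation,
    )


def glucose_at(profile: OscillationProfile, t, onset: float = 0.0):
    """Channel glucose concentration at time ``t`` (seconds).

    Before ``onset`` the medium is held at excess (the pre-dynamics growth
    phase); afterwards the square wave runs with the excess phase first in
    each period, delayed by the profile's phase shift.  Accepts scalars or
    arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = np.mod(t - onset - profile.phase_shift_s, profile.period_s)
    dynamic = np.where(tau < profile.excess_s, profile.c_excess, profile.c_limitation)
    out = np.where(t < onset, profile.c_excess, dynamic)
    return float(out) if out.ndim == 0 else out


def shift_profile(
    profile: OscillationProfile, layout: ChipLayout, array_index: int
) -> OscillationProfile:
    """Profile actually experienced by a given array.

    The central array carries the nominal wave.  Each step outward adds
    ``array_shift_step_s`` to the onset delay (signed by chip side) and
    transfers the same amount between the two phase durations (the left side
    lengthens the excess phase, the right side shortens it).  The outermost
    arrays are held at constant conditions and serve as the excess (left) and
    limitation (right) controls.
    """
    if not 1 <= array_index <= layout.n_arrays:
        raise ValueError(
            f"array_index must be in 1..{layout.n_arrays}, got {array_index}"
        )
    steps = array_index - layout.central_array
    if array_index == 1:
        return replace(
            profile, excess_s=profile.period_s, limitation_s=0.0, phase_shift_s=0.0
        )
    if array_index == layout.n_arrays:
        return replace(
            profile, excess_s=0.0, limitation_s=profile.period_s, phase_shift_s=0.0
        )
    delta = -steps * layout.array_shift_step_s  # left side (steps<0) lengthens excess
    excess = min(max(profile.excess_s + delta, 0.0), profile.period_s)
    return replace(
        profile,
        excess_s=excess,
        limitation_s=profile.period_s - excess,
        phase_shift_s=steps * layout.array_shift_step_s,
    )


def chamber_response(
    profile: OscillationProfile,
    chamber_index: int,
    k0: float,
    decay: float = 0.8,
    dt: float = 0.1,
    n_periods: int = 5,
    burn_in_periods: int | None = None,
    array_index: int = 4,
) -> ChamberTrace:
    """Concentration trace inside chamber ``chamber_index`` under first-order
    medium exchange.

    The chamber relaxes towards the channel concentration with rate
    ``k(n) = k0 * decay**(n - 1)``: exchange is fastest in the first chamber
    and decays geometrically along the array as the diffusion gradient
    diminishes.  The trace covers ``n_periods`` after discarding a burn-in
    long enough to reach the periodic steady state.
    """
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if not 0 < decay <= 1:
        raise ValueError("decay must lie in (0, 1]")
    if chamber_index < 1:
        raise ValueError("chamber_index must be >= 1")
    if dt > 0.5:
        raise ValueError("dt must be <= 0.5 s")
    k = k0 * decay ** (chamber_index - 1)
    if burn_in_periods is None:
        # ~8 relaxation times, at least one full period
        burn_in_periods = int(min(1000, max(1, math.ceil(8.0 / (k * profile.period_s)))))
    total_t = (burn_in_periods + n_periods) * profile.period_s
    n_steps = int(round(total_t / dt))
    t_full = np.arange(n_steps + 1) * dt
    # channel concentration evaluated at step midpoints (piecewise constant)
    channel = glucose_at(profile, t_full[:-1] + dt / 2.0, onset=0.0)
    c = profile.mean_concentration
    decay_step = math.exp(-k * dt)
    conc = np.empty(n_steps + 1)
    conc[0] = c
    for i in range(n_steps):
        c = channel[i] + (c - channel[i]) * decay_step
        conc[i + 1] = c
    keep = t_full >= burn_in_periods * profile.period_s - 1e-12
    times = t_full[keep] - burn_in_periods * profile.period_s
    return ChamberTrace(
        times=times,
        concentration=conc[keep],
        array_index=array_index,
        chamber_index=chamber_index,
        nominal=profile,
    )


def _crossings(times: np.ndarray, values: np.ndarray, threshold: float, upward: bool):
    """Linearly interpolated threshold-crossing times."""
    v = values - threshold
    if upward:
        idx = np.nonzero((v[:-1] < 0) & (v[1:] >= 0))[0]
    else:
        idx = np.nonzero((v[:-1] >= 0) & (v[1:] < 0))[0]
    out = []
    for i in idx:
        frac = -v[i] / (v[i + 1] - v[i])
        out.append(times[i] + frac * (times[i + 1] - times[i]))
    return np.asarray(out)


def estimate_pulse_metrics(
    trace: ChamberTrace, nominal: OscillationProfile, min_relative_amplitude: float = 0.05
) -> PulseMetrics:
    """Recover effective pulse durations, onset shift and definition from a
    measured chamber trace.

    Per cycle, the effective excess duration is the time spent above the
    50 %-of-achieved-amplitude threshold between an upward crossing and the
    next downward crossing, averaged over cycles; the onset shift is the mean
    lag of upward crossings relative to the nominal (unshifted) period
    boundaries, wrapped to (-period/2, period/2].  Definition is the achieved
    amplitude over the nominal amplitude.  Traces whose amplitude stays below
    ``min_relative_amplitude`` of nominal get NaN durations.
    """
    span = trace.times[-1] - trace.times[0]
    if span < 3 * nominal.period_s - 1e-9:
        raise ValueError("trace must span at least 3 full periods")
    v = trace.concentration
    amp = float(v.max() - v.min())
    definition = min(max(amp / nominal.amplitude, 0.0), 1.0)
    if amp < min_relative_amplitude * nominal.amplitude:
        return PulseMetrics(math.nan, math.nan, math.nan, definition)
    thr = v.min() + 0.5 * amp
    ups = _crossings(trace.times, v, thr, upward=True)
    downs = _crossings(trace.times, v, thr, upward=False)
    if len(ups) == 0 or len(downs) == 0:
        return PulseMetrics(math.nan, math.nan, math.nan, definition)
    p = nominal.period_s
    # pair each upward crossing with the next downward crossing
    durations = []
    for u in ups:
        later = downs[downs > u]
        if len(later):
            durations.append(later[0] - u)
    if not durations:
        return PulseMetrics(math.nan, math.nan, math.nan, definition)
    eff_excess = float(np.mean(durations))
    eff_excess = min(eff_excess, p)
    shifts = np.mod(ups + p / 2.0, p) - p / 2.0
    onset_shift = float(np.mean(shifts))
    return PulseMetrics(
        effective_excess_s=eff_excess,
        effective_limitation_s=p - eff_excess,
        onset_shift_s=onset_shift,
        definition=definition,
    )
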