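"""Agent-based generator of dMSCC single-cell measurement tables.

The generator emulates the statistical structure the analysis pipeline
assumes in real segmented microscopy data from oscillating-glucose
cultivations of *S. cerevisiae*:

* monolayer chambers seeded with 1-3 cells, a 4 h pre-phase at glucose
  excess, then a 30 s square-wave oscillation between 50 g/L and 10 mg/L;
* two-phase growth adaptation -- after onset the colony grows at a reduced
  initial rate for an adaptation period before settling at the adapted rate,
  both set by condition-dependent dose-response curves of the excess
  fraction f;
* deterministic exponential area growth with threshold division and
  asymmetric budding (total colony area is conserved at division, producing
  the small-cell shoulder of budding populations);
* ratiometric biosensor readouts (QUEEN-2m ATP sensor = uvGFP/GFP, GlyRNA
  FBP sensor = CFP/RFP) whose condition means follow calibrated
  dose-response curves, with multiplicative lognormal noise;
* a heritable bimodal ATP subpopulation for the Ethanol Red strain;
* phase-contrast sampling every 8 min and fluorescence every 32 min, with
  fresh per-frame cell identities (cells are not tracked across frames,
  matching segmentation output).

Dose-response curves are shape-preserving monotone cubics (PCHIP) through
calibration anchors expressed relative to the constant-excess control.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .chip_model import OscillationProfile, make_profile
from .growth_analysis import GrowthSeries

__all__ = [
    "StrainParams",
    "AtpSubpopulations",
    "SimConfig",
    "STRAINS",
    "effective_excess_fraction",
    "monotone_map",
    "default_strain_params",
    "condition_role",
    "simulate_experiment",
    "ground_truth",
    "export_cell_table",
    "read_ground_truth",
    "piecewise_growth_series",
    "two_phase_scenario_series",
    "CELL_TABLE_COLUMNS",
    "FLUOR_COLUMNS",
]

logger = logging.getLogger(__name__)

#: CSV schema of the interchange cell table (long format, one row per
#: detected cell per frame).  Fluorescence columns are empty ("") at frames
#: without fluorescence acquisition.
CELL_TABLE_COLUMNS = [
    "strain",
    "condition_id",
    "array_index",
    "chamber_index",
    "frame",
    "time_h",
    "cell_id",
    "area_um2",
    "gray_rfp",
    "gray_gfp",
    "gray_cfp",
    "gray_uvgfp",
]
FLUOR_COLUMNS = ["gray_rfp", "gray_gfp", "gray_cfp", "gray_uvgfp"]

# baseline gray levels and base sensor ratios of the excess control;
# normalisation cancels these, so only their positivity matters
_GFP_BASE = 400.0
_RFP_BASE = 500.0
_QUEEN_BASE = 0.8  # uvGFP/GFP of the excess control
_GLY_BASE = 0.6  # CFP/RFP of the excess control


def effective_excess_fraction(profile: OscillationProfile) -> float:
    """Fraction f of each oscillation period spent at glucose excess."""
    return profile.duty_cycle


def monotone_map(anchors) -> Callable[[float], float]:
    """Shape-preserving cubic interpolant through (f, value) anchors.

    PCHIP never overshoots its anchors, so monotone anchor sequences yield
    monotone curves.  Input is clipped to the anchored f range.
    """
    pts = sorted(anchors)
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    interp = PchipInterpolator(xs, ys)

    def f(x):
        return float(interp(np.clip(x, xs[0], xs[-1])))

    f.anchors = tuple((float(a), float(b)) for a, b in pts)  # type: ignore[attr-defined]
    return f


@dataclass(frozen=True)
class AtpSubpopulations:
    """Heritable bimodal ATP-level structure (fractions of cells whose QUEEN
    ratio sits at a low or high multiple of the condition mean)."""

    fraction_high: float = 0.5
    level_low: float = 0.7
    level_high: float = 1.3

    def __post_init__(self) -> None:
        if not 0 < self.fraction_high < 1:
            raise ValueError("fraction_high must lie in (0, 1)")
        if not 0 < self.level_low < self.level_high:
            raise ValueError("need 0 < level_low < level_high")


@dataclass(frozen=True)
class StrainParams:
    """Generator ground truth for one strain.

    All dose-response maps take the excess fraction f in [0, 1] and return a
    value normalised to the constant-excess control (value 1 at f = 1).
    ``dose_response_fbp`` is non-increasing (a higher GlyRNA ratio means a
    lower glycolytic flux); ``dose_response_size`` exceeds 1 at f = 0
    because all strains enlarge under constant limitation.
    """

    name: str
    mu_excess: float  # adapted mu under constant excess, 1/h
    mu_limitation: float  # mu under constant limitation, 1/h
    dose_response_mu: Callable[[float], float]
    dose_response_atp: Callable[[float], float]
    dose_response_fbp: Callable[[float], float]
    dose_response_size: Callable[[float], float]
    mu_ini_fraction: Callable[[float], float]  # mu_ini / mu_adapted
    t_adapt: Callable[[float], float]  # adaptation duration, h
    division_area: float = 40.0  # um^2
    bud_fraction: float = 0.35  # daughter share of area at division
    atp_subpops: AtpSubpopulations | None = None
    fbp_outlier_fraction: float = 0.0  # occasional high-FBP-ratio cells
    fbp_outlier_level: float = 1.5
    noise_cv_area: float = 0.05
    noise_cv_fluor: float = 0.05
    division_jitter_cv: float = 0.05  # per-division threshold jitter

    def __post_init__(self) -> None:
        if not 0 < self.bud_fraction < 0.5:
            raise ValueError("bud_fraction must lie in (0, 0.5)")
        if self.mu_excess <= 0 or self.mu_limitation < 0:
            raise ValueError("growth rates must be positive")
        if self.mu_limitation > self.mu_excess:
            raise ValueError("mu_limitation must not exceed mu_excess")


# Calibration anchors of the three default strains, relative to the excess
# control.  Common features: ~50 % of mu_max preserved at f = 0.1; a ~40 %
# higher GlyRNA ratio at constant limitation than at constant excess; cell
# enlargement under constant limitation.  Strain-specific features: Ethanol
# Red keeps only ~70 % of the maximal ATP level at constant limitation and
# shrinks to ~70 % size at short excess (the other two plateau near 90 %),
# and carries a heritable bimodal ATP subpopulation; PE2 shows occasional
# high-FBP-ratio outlier cells and the longest adaptation phases.
_DEFAULTS: dict[str, dict] = {
    "CEN.PK113-7D": dict(
        mu_excess=0.18,
        mu=[(0.0, 0.15), (0.1, 0.5), (0.3, 0.68), (0.6, 0.85), (1.0, 1.0)],
        atp=[(0.0, 0.90), (0.5, 0.95), (1.0, 1.0)],
        fbp=[(0.0, 1.40), (0.5, 1.18), (1.0, 1.0)],
        size=[(0.0, 1.10), (0.1, 0.90), (0.3, 0.91), (0.567, 0.98), (1.0, 1.0)],
        mu_ini=[(0.0, 0.40), (0.3, 0.50), (0.7, 0.80), (0.9, 0.97), (1.0, 1.0)],
        t_adapt=[(0.0, 3.3), (0.3, 3.0), (0.7, 2.3), (1.0, 2.0)],
    ),
    "Ethanol Red": dict(
        mu_excess=0.20,
        mu=[(0.0, 0.15), (0.1, 0.5), (0.3, 0.68), (0.6, 0.85), (1.0, 1.0)],
        atp=[(0.0, 0.70), (0.5, 0.85), (1.0, 1.0)],
        fbp=[(0.0, 1.40), (0.5, 1.18), (1.0, 1.0)],
        size=[
            (0.0, 1.10),
            (0.1, 0.70),
            (0.3, 0.74),
            (0.5, 0.90),
            (0.767, 0.97),
            (1.0, 1.0),
        ],
        mu_ini=[(0.0, 0.40), (0.3, 0.50), (0.7, 0.80), (0.9, 0.97), (1.0, 1.0)],
        t_adapt=[(0.0, 3.4), (0.3, 3.1), (0.7, 2.4), (1.0, 2.0)],
        subpops=AtpSubpopulations(),
    ),
    "PE2": dict(
        mu_excess=0.16,
        mu=[(0.0, 0.15), (0.1, 0.5), (0.3, 0.68), (0.6, 0.85), (1.0, 1.0)],
        atp=[(0.0, 0.90), (0.5, 0.95), (1.0, 1.0)],
        fbp=[(0.0, 1.40), (0.5, 1.18), (1.0, 1.0)],
        size=[(0.0, 1.10), (0.1, 0.90), (0.3, 0.91), (0.567, 0.98), (1.0, 1.0)],
        mu_ini=[(0.0, 0.40), (0.3, 0.50), (0.7, 0.80), (0.9, 0.97), (1.0, 1.0)],
        t_adapt=[(0.0, 3.5), (0.1, 3.4), (0.3, 3.2), (0.7, 2.5), (1.0, 2.0)],
        fbp_outliers=0.03,
    ),
}

STRAINS = tuple(_DEFAULTS)


def default_strain_params(strain: str) -> StrainParams:
    """Calibrated default parameter set for one of the three strains."""
    if strain not in _DEFAULTS:
        raise ValueError(f"unknown strain {strain!r}; known: {', '.join(STRAINS)}")
    d = _DEFAULTS[strain]
    mu_map = monotone_map(d["mu"])
    return StrainParams(
        name=strain,
        mu_excess=d["mu_excess"],
        mu_limitation=mu_map(0.0) * d["mu_excess"],
        dose_response_mu=mu_map,
        dose_response_atp=monotone_map(d["atp"]),
        dose_response_fbp=monotone_map(d["fbp"]),
        dose_response_size=monotone_map(d["size"]),
        mu_ini_fraction=monotone_map(d["mu_ini"]),
        t_adapt=monotone_map(d["t_adapt"]),
        atp_subpops=d.get("subpops"),
        fbp_outlier_fraction=d.get("fbp_outliers", 0.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Experiment-level configuration of a simulated condition."""

    profile: OscillationProfile
    seed: int = 0
    n_chambers: int = 10
    cells_per_chamber_init: tuple[int, int] = (1, 3)
    t_end_h: float = 18.0
    t_onset_h: float = 4.0
    dt_phase_min: int = 8
    dt_fluor_min: int = 32
    chamber_capacity_area: float = 0.5 * 80.0 * 90.0  # um^2 of a monolayer chamber
    array_index: int = 4
    condition_id: str | None = None

    def __post_init__(self) -> None:
        if self.dt_fluor_min % self.dt_phase_min != 0:
            raise ValueError("dt_fluor_min must be an integer multiple of dt_phase_min")
        if not self.t_onset_h < self.t_end_h:
            raise ValueError("t_onset_h must precede t_end_h")
        if self.n_chambers < 1:
            raise ValueError("n_chambers must be >= 1")
        lo, hi = self.cells_per_chamber_init
        if not 1 <= lo <= hi:
            raise ValueError("cells_per_chamber_init must be a (lo, hi) range with lo >= 1")


def condition_role(profile: OscillationProfile) -> str:
    """Classify a profile as dynamic or as one of the two constant controls."""
    f = profile.duty_cycle
    if f >= 1.0 - 1e-12:
        return "excess_control"
    if f <= 1e-12:
        return "limitation_control"
    return "dynamic"


def _log_growth_fn(config: SimConfig, params: StrainParams):
    """Cumulative specific growth L(t) = integral of mu; the colony's total
    area is A0 * exp(L(t)) exactly, because division conserves area.

    The limitation control is never given the excess pre-phase (it is held
    at limitation from inoculation), so it grows at mu_limitation throughout.
    """
    role = condition_role(config.profile)
    f = config.profile.duty_cycle
    t_on = config.t_onset_h
    if role == "excess_control":
        return lambda t: params.mu_excess * t, params.mu_excess, params.mu_excess, 0.0
    if role == "limitation_control":
        return (
            lambda t: params.mu_limitation * t,
            params.mu_limitation,
            params.mu_limitation,
            0.0,
        )
    mu_adapted = params.dose_response_mu(f) * params.mu_excess
    mu_initial = params.mu_ini_fraction(f) * mu_adapted
    t_ad = params.t_adapt(f)

    def L(t: float) -> float:
        pre = params.mu_excess * min(t, t_on)
        ini = mu_initial * min(max(t - t_on, 0.0), t_ad)
        ad = mu_adapted * max(t - t_on - t_ad, 0.0)
        return pre + ini + ad

    return L, mu_initial, mu_adapted, t_ad


def _size_factor_fn(config: SimConfig, params: StrainParams):
    """Time course of the division-threshold scale.

    The size target relaxes to the condition's dose-response value only in
    the last 10 % of the adaptation window: cell size changes once growth
    starts to recover, not at the onset of the oscillation.
    """
    role = condition_role(config.profile)
    f = config.profile.duty_cycle
    if role == "excess_control":
        return lambda t: 1.0
    if role == "limitation_control":
        target = params.dose_response_size(0.0)
        return lambda t: target
    target = params.dose_response_size(f)
    t_ad = params.t_adapt(f)
    t_start = config.t_onset_h + 0.9 * t_ad
    t_done = config.t_onset_h + t_ad

    def factor(t: float) -> float:
        if t <= t_start:
            return 1.0
        if t >= t_done:
            return target
        w = (t - t_start) / (t_done - t_start)
        return 1.0 + w * (target - 1.0)

    return factor


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv <= 0:
        return np.ones(n)
    s = _lognormal_sigma(cv)
    return np.exp(rng.normal(-0.5 * s * s, s, size=n))


def simulate_experiment(config: SimConfig, params: StrainParams) -> pd.DataFrame:
    """Simulate one condition and return a long-format cell table.

    The returned frame has the :data:`CELL_TABLE_COLUMNS` plus a ``subpop``
    ground-truth column (stripped on export).  Chambers exceeding the
    capacity area are truncated at that frame with a warning.
    """
    role = condition_role(config.profile)
    f = config.profile.duty_cycle
    cond_id = config.condition_id or (
        f"{params.name}_e{config.profile.excess_s:g}_l{config.profile.limitation_s:g}_{role}"
    )
    L, _, _, _ = _log_growth_fn(config, params)
    size_factor = _size_factor_fn(config, params)

    n_frames = int(round(config.t_end_h * 60.0 / config.dt_phase_min)) + 1
    frames = np.arange(n_frames)
    times_h = (frames * config.dt_phase_min) / 60.0
    fluor_every = config.dt_fluor_min // config.dt_phase_min

    sub_levels = {None: 1.0}
    if params.atp_subpops is not None:
        sub_levels = {"low": params.atp_subpops.level_low, "high": params.atp_subpops.level_high}

    streams = np.random.SeedSequence(config.seed).spawn(config.n_chambers)
    chamber_frames: list[pd.DataFrame] = []
    cell_counter = 0

    for ch in range(1, config.n_chambers + 1):
        rng = np.random.default_rng(streams[ch - 1])
        lo, hi = config.cells_per_chamber_init
        n0 = int(rng.integers(lo, hi + 1))
        areas = rng.uniform(0.4, 0.8, n0) * params.division_area
        if params.atp_subpops is not None:
            subpop = np.where(
                rng.random(n0) < params.atp_subpops.fraction_high, "high", "low"
            ).astype(object)
        else:
            subpop = np.full(n0, None, dtype=object)
        fbp_out = rng.random(n0) < params.fbp_outlier_fraction
        jitter = _noise(rng, params.division_jitter_cv, n0)

        cols: dict[str, list] = {k: [] for k in ("frame", "time_h", "cell_id", "area_um2",
                                                 "gray_rfp", "gray_gfp", "gray_cfp",
                                                 "gray_uvgfp", "subpop")}
        prev_t = 0.0
        for i, t in zip(frames, times_h):
            # grow, then divide, then record
            areas = areas * math.exp(L(t) - L(prev_t))
            prev_t = t
            thr_scale = params.division_area * size_factor(t)
            while True:
                dividing = areas >= thr_scale * jitter
                if not dividing.any():
                    break
                idx = np.nonzero(dividing)[0]
                daughters = params.bud_fraction * areas[idx]
                areas[idx] *= 1.0 - params.bud_fraction
                jitter[idx] = _noise(rng, params.division_jitter_cv, len(idx))
                areas = np.concatenate([areas, daughters])
                subpop = np.concatenate([subpop, subpop[idx]])
                fbp_out = np.concatenate([fbp_out, fbp_out[idx]])
                jitter = np.concatenate(
                    [jitter, _noise(rng, params.division_jitter_cv, len(idx))]
                )
            if areas.sum() > config.chamber_capacity_area:
                logger.warning(
                    "chamber %d of %s exceeded capacity at %.2f h; truncating",
                    ch, cond_id, t,
                )
                break
            n = len(areas)
            cols["frame"].append(np.full(n, i))
            cols["time_h"].append(np.full(n, t))
            cols["cell_id"].append(np.arange(cell_counter, cell_counter + n))
            cell_counter += n
            cols["area_um2"].append(areas * _noise(rng, params.noise_cv_area, n))
            cols["subpop"].append(subpop.copy())
            if i % fluor_every == 0:
                if role == "limitation_control":
                    f_eff = 0.0
                elif role == "excess_control" or t < config.t_onset_h:
                    f_eff = 1.0
                else:
                    f_eff = f
                q = params.dose_response_atp(f_eff) * np.array(
                    [sub_levels.get(s, 1.0) for s in subpop]
                )
                gly = params.dose_response_fbp(f_eff) * np.where(
                    fbp_out, params.fbp_outlier_level, 1.0
                )
                cols["gray_gfp"].append(_GFP_BASE * _noise(rng, params.noise_cv_fluor, n))
                cols["gray_uvgfp"].append(
                    q * _QUEEN_BASE * _GFP_BASE * _noise(rng, params.noise_cv_fluor, n)
                )
                cols["gray_rfp"].append(_RFP_BASE * _noise(rng, params.noise_cv_fluor, n))
                cols["gray_cfp"].append(
                    gly * _GLY_BASE * _RFP_BASE * _noise(rng, params.noise_cv_fluor, n)
                )
            else:
                for c in FLUOR_COLUMNS:
                    cols[c].append(np.full(n, np.nan))

        df = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
        df.insert(0, "strain", params.name)
        df.insert(1, "condition_id", cond_id)
        df.insert(2, "array_index", config.array_index)
        df.insert(3, "chamber_index", ch)
        chamber_frames.append(df)

    table = pd.concat(chamber_frames, ignore_index=True)
    table["frame"] = table["frame"].astype(int)
    table["cell_id"] = table["cell_id"].astype(int)
    return table[CELL_TABLE_COLUMNS + ["subpop"]]


def ground_truth(config: SimConfig, params: StrainParams) -> dict:
    """Generator ground truth for recovery tests, matching the condition."""
    L, mu_initial, mu_adapted, t_ad = _log_growth_fn(config, params)
    role = condition_role(config.profile)
    f = config.profile.duty_cycle
    return {
        "strain": params.name,
        "role": role,
        "excess_fraction": f,
        "seed": config.seed,
        "t_onset_h": config.t_onset_h,
        "mu_excess": params.mu_excess,
        "mu_limitation": params.mu_limitation,
        "mu_adapted": mu_adapted,
        "mu_ini": mu_initial,
        "t_adapt": t_ad if role == "dynamic" else 0.0,
        "atp_level": params.dose_response_atp(0.0 if role == "limitation_control" else f),
        "fbp_level": params.dose_response_fbp(0.0 if role == "limitation_control" else f),
        "size_level": params.dose_response_size(0.0 if role == "limitation_control" else f),
    }


def export_cell_table(
    table: pd.DataFrame,
    path: str | Path,
    sidecar: dict | None = None,
    include_subpop: bool = False,
) -> Path:
    """Write the cell table as CSV; optionally a ground-truth JSON sidecar.

    Fluorescence columns are empty strings at non-fluorescence frames; the
    ``subpop`` ground-truth label is stripped unless requested.
    """
    if table.empty:
        raise ValueError("refusing to export an empty cell table")
    path = Path(path)
    cols = CELL_TABLE_COLUMNS + (["subpop"] if include_subpop else [])
    out = table[[c for c in cols if c in table.columns]]
    try:
        out.to_csv(path, index=False, na_rep="")
    except OSError as exc:
        raise OSError(f"failed to write cell table to {path}: {exc}") from exc
    if sidecar is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )
    return path


def read_ground_truth(path: str | Path) -> dict:
    """Read the ground-truth sidecar written next to an exported table."""
    path = Path(path)
    return json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())


def piecewise_growth_series(
    mu_pre: float,
    mu_initial: float,
    mu_adapted: float,
    t_onset_h: float = 4.0,
    t_adapt_h: float = 3.1,
    t_end_h: float = 18.0,
    dt_phase_min: int = 8,
    a0: float = 100.0,
) -> GrowthSeries:
    """Noise-free piecewise log-linear total-area series.

    Closed-form construction of the two-phase adaptation scenario used as an
    exact oracle for the growth estimators: ln(total area) has slope
    ``mu_pre`` before onset, ``mu_initial`` during the adaptation window and
    ``mu_adapted`` afterwards.
    """
    frames = np.arange(int(round(t_end_h * 60.0 / dt_phase_min)) + 1)
    t = (frames * dt_phase_min) / 60.0
    ln_a = (
        math.log(a0)
        + mu_pre * np.minimum(t, t_onset_h)
        + mu_initial * np.clip(t - t_onset_h, 0.0, t_adapt_h)
        + mu_adapted * np.maximum(t - t_onset_h - t_adapt_h, 0.0)
    )
    return GrowthSeries(times=t, total_area=np.exp(ln_a), cell_count=np.ones_like(t))


def two_phase_scenario_series() -> GrowthSeries:
    """The canonical adaptation scenario: onset at 4 h, growth at a reduced
    initial rate for 3.1 h, then a 100 % increase to the adapted rate."""
    return piecewise_growth_series(mu_pre=0.20, mu_initial=0.05, mu_adapted=0.10)
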