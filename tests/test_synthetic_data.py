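"""Calibration and statistical structure of the synthetic-data generator."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from dmscc.chip_model import make_profile
from dmscc.ingest import read_cell_table
from dmscc.synthetic_data import (
    STRAINS,
    SimConfig,
    default_strain_params,
    effective_excess_fraction,
    export_cell_table,
    ground_truth,
    piecewise_growth_series,
    read_ground_truth,
    simulate_experiment,
    two_phase_scenario_series,
)


def noise_free(params):
    return dataclasses.replace(
        params, noise_cv_area=0.0, noise_cv_fluor=0.0, division_jitter_cv=0.0
    )


@pytest.mark.parametrize(
    "excess,f", [(3.0, 0.10), (30.0, 1.0), (9.0, 0.30), (0.0, 0.0)]
)
def test_effective_excess_fraction(excess, f):
    assert effective_excess_fraction(make_profile(excess, 30.0 - excess)) == pytest.approx(f)


def test_default_calibration_anchors():
    for strain in STRAINS:
        p = default_strain_params(strain)
        # ~50 % of the adapted rate survives at 10 % excess, for every strain
        assert p.dose_response_mu(0.1) == pytest.approx(0.5)
        assert p.dose_response_mu(1.0) == pytest.approx(1.0)
        # the limitation-to-excess GlyRNA increase is ~40 % for every strain
        assert p.dose_response_fbp(0.0) / p.dose_response_fbp(1.0) == pytest.approx(1.4)
        # all strains enlarge under constant limitation
        assert p.dose_response_size(0.0) > 1.0
    assert default_strain_params("CEN.PK113-7D").dose_response_atp(0.0) == pytest.approx(0.9)
    assert default_strain_params("PE2").dose_response_atp(0.0) == pytest.approx(0.9)
    assert default_strain_params("Ethanol Red").dose_response_atp(0.0) == pytest.approx(0.7)
    assert default_strain_params("Ethanol Red").atp_subpops is not None


def test_unknown_strain_rejected():
    with pytest.raises(ValueError, match="unknown strain"):
        default_strain_params("S288C")


def test_dose_response_shapes():
    grid = np.linspace(0.0, 1.0, 101)
    for strain in STRAINS:
        p = default_strain_params(strain)
        mu = [p.dose_response_mu(f) for f in grid]
        atp = [p.dose_response_atp(f) for f in grid]
        fbp = [p.dose_response_fbp(f) for f in grid]
        ini = [p.mu_ini_fraction(f) for f in grid]
        tad = [p.t_adapt(f) for f in grid]
        assert np.all(np.diff(mu) >= -1e-12)
        assert np.all(np.diff(atp) >= -1e-12)
        assert np.all(np.diff(fbp) <= 1e-12)
        assert np.all(np.diff(ini) >= -1e-12)
        assert np.all(np.diff(tad) <= 1e-12)


def test_noise_free_constant_excess_is_exactly_exponential(cenpk_params):
    cfg = SimConfig(profile=make_profile(30.0, 0.0), seed=5, n_chambers=1,
                    cells_per_chamber_init=(1, 1))
    table = simulate_experiment(cfg, noise_free(cenpk_params))
    total = table.groupby("time_h")["area_um2"].sum()
    slopes = np.diff(np.log(total.to_numpy())) / np.diff(total.index.to_numpy())
    np.testing.assert_allclose(slopes, cenpk_params.mu_excess, rtol=1e-9)


def test_total_area_follows_piecewise_closed_form(er_params):
    """Noise-free dynamic run: ln(total area) is piecewise linear with
    breakpoints at the onset and at onset + t_adapt, despite divisions
    (area is conserved at each budding event)."""
    cfg = SimConfig(profile=make_profile(9.0, 21.0), seed=6, n_chambers=2)
    params = noise_free(er_params)
    table = simulate_experiment(cfg, params)
    gt = ground_truth(cfg, params)
    assert gt["t_adapt"] == pytest.approx(3.1)
    assert gt["mu_ini"] / gt["mu_adapted"] == pytest.approx(0.5)
    total = table.groupby("time_h")["area_um2"].sum()
    t = total.index.to_numpy()
    expected = (
        params.mu_excess * np.minimum(t, 4.0)
        + gt["mu_ini"] * np.clip(t - 4.0, 0.0, gt["t_adapt"])
        + gt["mu_adapted"] * np.maximum(t - 4.0 - gt["t_adapt"], 0.0)
    )
    np.testing.assert_allclose(
        np.log(total.to_numpy() / total.iloc[0]), expected, atol=1e-9
    )
    # divisions did happen
    counts = table.groupby("time_h")["cell_id"].size()
    assert counts.iloc[-1] > counts.iloc[0]


def test_same_seed_byte_identical(tmp_path, cenpk_params):
    cfg = SimConfig(profile=make_profile(9.0, 21.0), seed=9, n_chambers=3)
    paths = []
    for name in ("a.csv", "b.csv"):
        table = simulate_experiment(cfg, cenpk_params)
        paths.append(export_cell_table(table, tmp_path / name))
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_end_area_monotone_in_excess_fraction(cenpk_params):
    totals = []
    for excess in (3.0, 15.0, 27.0):
        cfg = SimConfig(profile=make_profile(excess, 30.0 - excess), seed=12,
                        n_chambers=3)
        table = simulate_experiment(cfg, cenpk_params)
        totals.append(table[table["frame"] == table["frame"].max()]["area_um2"].sum())
    assert totals[0] < totals[1] < totals[2]


def test_atp_subpopulations_bimodal_and_heritable(er_params):
    cfg = SimConfig(profile=make_profile(30.0, 0.0), seed=13, n_chambers=10)
    table = simulate_experiment(cfg, er_params)
    fluor = table.dropna(subset=["gray_uvgfp"])
    sp = er_params.atp_subpops
    for t in (0.0, 8.0, 16.0):
        frame = fluor[fluor["time_h"] == t]
        ratios = frame["gray_uvgfp"] / frame["gray_gfp"]
        # two clusters separated by more than 4x the within-cluster spread;
        # the mixture mean sits between the two modes
        low = ratios[ratios < ratios.mean()]
        high = ratios[ratios >= ratios.mean()]
        gap = high.median() - low.median()
        assert gap > 4.0 * max(low.std(), high.std())
    # heritability: subpopulation fractions stable over the cultivation
    first = table[table["frame"] == 0]
    last = table[table["frame"] == table["frame"].max()]
    f0 = (first["subpop"] == "high").mean()
    f1 = (last["subpop"] == "high").mean()
    assert abs(f0 - f1) < 0.15


def test_export_roundtrip_and_fluorescence_cadence(tmp_path, dynamic_table):
    cfg = SimConfig(profile=make_profile(9.0, 21.0), seed=44, n_chambers=10)
    path = export_cell_table(
        dynamic_table, tmp_path / "t.csv",
        sidecar=ground_truth(cfg, default_strain_params("CEN.PK113-7D")),
    )
    loaded = read_cell_table(path)
    assert len(loaded) == len(dynamic_table)
    np.testing.assert_allclose(loaded["area_um2"], dynamic_table["area_um2"])
    assert "subpop" not in loaded.columns  # ground truth stripped on export
    # fluorescence present exactly every 32 min (every 4th 8-min frame)
    has_fluor = loaded.groupby("frame")["gray_gfp"].apply(lambda s: s.notna().all())
    no_fluor = loaded.groupby("frame")["gray_gfp"].apply(lambda s: s.isna().all())
    for frame, ok in has_fluor.items():
        assert ok if frame % 4 == 0 else no_fluor[frame]
    # sidecar carries the generator ground truth for recovery assertions
    gt = read_ground_truth(path)
    assert gt["t_adapt"] == pytest.approx(3.0)
    assert 0 < gt["mu_ini"] < gt["mu_adapted"]


def test_capacity_truncation_warns(cenpk_params, caplog):
    cfg = SimConfig(profile=make_profile(30.0, 0.0), seed=3, n_chambers=1,
                    chamber_capacity_area=100.0)
    with caplog.at_level("WARNING", logger="dmscc.synthetic_data"):
        table = simulate_experiment(cfg, cenpk_params)
    assert "capacity" in caplog.text
    assert table["time_h"].max() < 18.0


def test_scenario_series_breakpoints():
    s = two_phase_scenario_series()
    lna = np.log(s.total_area)
    t = s.times
    pre = (t >= 0) & (t < 4.0)
    low = (t >= 4.0) & (t <= 7.0)
    high = t >= 7.2
    for mask, mu in ((pre, 0.20), (low, 0.05), (high, 0.10)):
        slopes = np.diff(lna[mask]) / np.diff(t[mask])
        np.testing.assert_allclose(slopes, mu, rtol=1e-9)


def test_piecewise_series_rejects_nothing_valid():
    s = piecewise_growth_series(0.3, 0.1, 0.2, t_adapt_h=2.0)
    assert s.times[0] == 0.0 and s.times[-1] == pytest.approx(18.0)
    assert np.all(s.total_area > 0)
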