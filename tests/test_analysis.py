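"""Profiles, bilayer detection/thickness, drift, convergence, conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesodpd.analysis import (DensityProfile, UnitConversion,
                              bilayer_thickness, classify_tension_rise,
                              conversion_radius, convergence_step,
                              density_profile, detect_bilayers,
                              physical_time, temperature_drift)

BOX = (5.0, 5.0, 10.0)


def _profile(density, L=10.0):
    n = len(density)
    return DensityProfile(axis="z", bin_edges=np.linspace(0.0, L, n + 1),
                          density=np.asarray(density, float),
                          n_selected=float(np.sum(density)), n_frames=1)


def test_density_profile_localizes_and_conserves():
    pos = np.array([[1.0, 1.0, 5.0]])
    prof = density_profile([pos], np.array([0]), BOX, {0}, n_bins=10)
    assert np.argmax(prof.density) == 5
    bin_vol = (10.0 / 10) * 25.0
    assert np.sum(prof.density * bin_vol) == pytest.approx(1.0)


def test_density_profile_integral_equals_count_multi_frame():
    rng = np.random.default_rng(2)
    frames = [rng.random((200, 3)) * BOX for _ in range(7)]
    tids = np.zeros(200, int)
    prof = density_profile(frames, tids, BOX, None, n_bins=16)
    bin_vol = (10.0 / 16) * 25.0
    assert np.sum(prof.density * bin_vol) == pytest.approx(200.0, abs=1e-9)


def test_density_profile_uniform_within_poisson_bands():
    rng = np.random.default_rng(7)
    frames = [rng.random((3000, 3)) * BOX for _ in range(4)]
    prof = density_profile(frames, np.zeros(3000, int), BOX, None, n_bins=10)
    per_bin = 3000 / 10
    counts = prof.density * (25.0 * 1.0)
    assert np.all(np.abs(counts - per_bin) < 4 * np.sqrt(per_bin / 4))


def test_density_profile_empty_selection():
    with pytest.raises(ValueError, match="empty selection"):
        density_profile([np.zeros((3, 3))], np.zeros(3, int), BOX, {5})


def test_detect_bilayers_square_wave():
    d = np.zeros(40)
    for k in range(4):
        d[2 + 10 * k: 8 + 10 * k] = 1.0
    rep = detect_bilayers(_profile(d))
    assert rep.n_bilayers == 4
    assert rep.slabs[0][0] < rep.slabs[0][1]


def test_detect_bilayers_flat_profile_is_zero():
    rep = detect_bilayers(_profile(np.full(40, 2.0)))
    assert rep.n_bilayers == 0 and "not bimodal" in rep.diagnostic
    rng = np.random.default_rng(0)
    noisy = 2.0 + 0.05 * rng.standard_normal(40)
    assert detect_bilayers(_profile(noisy)).n_bilayers == 0


def test_detect_bilayers_robust_to_noise():
    rng = np.random.default_rng(42)
    base = np.zeros(40)
    for k in range(4):
        base[2 + 10 * k: 8 + 10 * k] = 1.0
    for _ in range(100):
        noisy = base + 0.1 * rng.standard_normal(40) * (base + 0.1)
        assert detect_bilayers(_profile(noisy)).n_bilayers == 4


def test_detect_bilayers_periodic_wrap_merges():
    d = np.zeros(40)
    d[:4] = 1.0
    d[-4:] = 1.0
    d[18:24] = 1.0
    assert detect_bilayers(_profile(d), periodic=True).n_bilayers == 2
    assert detect_bilayers(_profile(d), periodic=False).n_bilayers == 3


def _twin_gaussian(n_bins, L, c1, c2, fwhm):
    z = (np.arange(n_bins) + 0.5) * (L / n_bins)
    s = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return (np.exp(-0.5 * ((z - c1) / s) ** 2)
            + np.exp(-0.5 * ((z - c2) / s) ** 2))


@pytest.mark.parametrize("r_c", [1.0, 4.5])
def test_bilayer_thickness_twin_gaussian_oracle(r_c):
    """Two headgroup peaks separated by d with FWHM w measure (d + w) r_c."""
    L, d, w = 20.0, 6.0, 1.5
    head = _twin_gaussian(400, L, 7.0, 13.0, w)
    surf = np.zeros(400)
    surf[120:280] = 1.0                       # slab spanning both peaks
    rep = detect_bilayers(_profile(surf, L))
    assert rep.n_bilayers == 1
    th = bilayer_thickness(_profile(head, L), rep, UnitConversion(r_c=r_c))
    assert th[0] == pytest.approx((d + w) * r_c, rel=0.03)


def test_bilayer_thickness_translation_and_mirror_invariant():
    L = 20.0
    head = _twin_gaussian(400, L, 7.0, 13.0, 1.5)
    surf = np.zeros(400)
    surf[120:280] = 1.0
    conv = UnitConversion(r_c=2.0)
    t0 = bilayer_thickness(_profile(head, L),
                           detect_bilayers(_profile(surf, L)), conv)[0]
    shift = 40  # 2 DPD lengths
    t1 = bilayer_thickness(_profile(np.roll(head, shift), L),
                           detect_bilayers(_profile(np.roll(surf, shift), L)),
                           conv)[0]
    t2 = bilayer_thickness(_profile(head[::-1].copy(), L),
                           detect_bilayers(_profile(surf[::-1].copy(), L)),
                           conv)[0]
    bin_A = (20.0 / 400) * 2.0                # one bin, in Å
    assert t1 == pytest.approx(t0, abs=2 * bin_A)
    assert t2 == pytest.approx(t0, abs=2 * bin_A)


def test_bilayer_thickness_needs_two_peaks():
    L = 20.0
    head = _twin_gaussian(400, L, 10.0, 10.0, 1.5)   # single central peak
    surf = np.zeros(400)
    surf[150:250] = 1.0
    head[:200] = 0.0    # kill the left flank entirely
    with pytest.raises(ValueError):
        bilayer_thickness(_profile(head, L),
                          detect_bilayers(_profile(surf, L)),
                          UnitConversion(r_c=1.0))


def test_temperature_drift_windows():
    assert temperature_drift(np.full(100, 298.0), 298.0) == 0.0
    assert temperature_drift(np.full(100, 301.2), 298.0) == pytest.approx(3.2)
    series = np.concatenate([np.full(50, 400.0), np.full(50, 300.5)])
    assert temperature_drift(series, 298.0) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        temperature_drift(series, 298.0, window=(90, 80))


def test_convergence_step_saturating_curve():
    tau = 100.0
    t = np.arange(0.0, 1000.0, 2.0)
    y = 1.0 - np.exp(-t / tau)
    tol = np.exp(-3.0) / tau          # slope of the curve at t = 3 tau
    onset = convergence_step(y, t, slope_tol=tol, window=5)
    assert onset == pytest.approx(3 * tau, rel=0.10)


def test_convergence_step_edge_cases():
    t = np.arange(50.0)
    assert convergence_step(0.01 * t, t, slope_tol=1e-4) is None
    assert convergence_step(np.full(50, 3.3), t, slope_tol=1e-4) == 0.0


def test_conversion_radius_values_and_invariances():
    assert conversion_radius([100], [30.0]) == pytest.approx(90.0 ** (1 / 3))
    assert conversion_radius([5, 7], [40.0, 40.0]) == pytest.approx(
        120.0 ** (1 / 3))
    a = conversion_radius([10, 20, 30], [30.0, 50.0, 70.0])
    b = conversion_radius([30, 10, 20], [70.0, 30.0, 50.0])
    assert a == pytest.approx(b, rel=1e-12)
    assert conversion_radius([10, 20], [30.0, 50.0], rho=6.0) == pytest.approx(
        conversion_radius([10, 20], [30.0, 50.0], rho=3.0) * 2 ** (1 / 3))
    with pytest.raises(ValueError):
        conversion_radius([10], [-1.0])


def test_physical_time_scaling_and_units():
    counts, masses, vols = [100], [18.0], [30.0]
    assert physical_time(0.0, counts, masses, vols, 298.0) == 0.0
    t1 = physical_time(1.0, counts, masses, vols, 298.0)
    t2 = physical_time(2.0, counts, masses, vols, 298.0)
    assert t2 == pytest.approx(2 * t1)
    # hand evaluation: f_soft * r_c[m] * sqrt(M[kg/mol] / (R T))
    r_c = (3.0 * 30.0) ** (1 / 3) * 1e-10
    expect = 1000.0 * r_c * np.sqrt(0.018 / (8.31446261815324 * 298.0))
    assert t1 == pytest.approx(expect, rel=1e-12)


@pytest.mark.parametrize("rise, label", [
    (-1.0, "no_change"), (0.0, "no_change"), (3.0, "rise"),
    (6.5, "ambiguous"), (9.0, "strong_rise"),
])
def test_classify_tension_rise_labels(rise, label):
    out = classify_tension_rise(rise)
    assert out["label"] == label
    assert out["rise"] == rise and out["boundaries"] == (6.0, 7.0)
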