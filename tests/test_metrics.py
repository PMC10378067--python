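"""Summary-metric extraction checked against independent brute-force passes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoparam.io import TemperatureMesh, ThermogramCurve
from thermoparam.metrics import (
    METRIC_COLUMNS,
    PeakWindows,
    compute_metric_set,
    find_peaks_monotonic,
    find_peaks_windowed,
    find_valley,
    first_moment_temperature,
    max_and_tmax,
    median_cp,
    metrics_table,
    total_area,
    width_at_half_height,
)

from conftest import gaussian_mix_curve


# ---------------------------------------------------------------------------
# Independent brute-force oracles (pure-python scans over mesh points)
# ---------------------------------------------------------------------------

def brute_local_maxima(t, cp, min_up=3, min_down=3):
    out = []
    for i in range(len(cp)):
        ups = 0
        j = i
        while j - 1 >= 0 and cp[j] > cp[j - 1]:
            ups += 1
            j -= 1
        downs = 0
        j = i
        while j + 1 < len(cp) and cp[j] > cp[j + 1]:
            downs += 1
            j += 1
        if ups >= min_up and downs >= min_down:
            out.append((t[i], cp[i]))
    return out


def brute_window_max(t, cp, lo, hi):
    best = None
    for ti, ci in zip(t, cp):
        if lo - 1e-9 <= ti <= hi + 1e-9:
            if best is None or ci > best[1]:
                best = (ti, ci)
    return best


def brute_valley(t, cp, left, right):
    best = None
    for ti, ci in zip(t, cp):
        if left + 1e-9 < ti < right - 1e-9:
            if best is None or ci < best[1]:
                best = (ti, ci)
    return best


def brute_width(t, cp):
    half = max(cp) / 2.0
    crossings = []
    for i in range(len(cp) - 1):
        lo, hi_ = cp[i], cp[i + 1]
        if (lo - half) * (hi_ - half) < 0:
            crossings.append(t[i] + (half - lo) / (hi_ - lo) * (t[i + 1] - t[i]))
        elif lo == half:
            crossings.append(t[i])
    if cp[-1] == half:
        crossings.append(t[-1])
    above = [ti for ti, ci in zip(t, cp) if ci >= half]
    first = min(crossings + above[:1])
    last = max(crossings + above[-1:])
    return last - first


def brute_trapezoid(t, cp):
    area = 0.0
    for i in range(len(cp) - 1):
        area += 0.5 * (cp[i] + cp[i + 1]) * (t[i + 1] - t[i])
    return area


def brute_metric_set(curve):
    t = list(curve.temperatures)
    cp = list(curve.cp)
    w = PeakWindows()
    p1 = brute_window_max(t, cp, *w.peak1)
    p2 = brute_window_max(t, cp, *w.peak2)
    p3 = brute_window_max(t, cp, *w.peak3)
    v = brute_valley(t, cp, p1[0], p2[0])
    cmax = max(cp)
    tmax = t[cp.index(cmax)]
    total = sum(cp)
    return {
        "Width": brute_width(t, cp),
        "Area": brute_trapezoid(t, cp),
        "Max": cmax,
        "Median": sorted(cp)[len(cp) // 2],
        "TMax": tmax,
        "Peak1": p1[1], "Peak2": p2[1], "Peak3": p3[1], "V1.2": v[1],
        "TPeak1": p1[0], "TPeak2": p2[0], "TPeak3": p3[0], "TV1.2": v[0],
        "Peak1.2": p1[1] / p2[1], "Peak1.3": p1[1] / p3[1], "Peak2.3": p2[1] / p3[1],
        "V1.2.Peak1": v[1] / p1[1], "V1.2.Peak2": v[1] / p2[1], "V1.2.Peak3": v[1] / p3[1],
        "TFM": sum(ti * ci for ti, ci in zip(t, cp)) / total,
    }


def random_three_gaussian(rng):
    """Random well-separated three-transition fixture: each of the first two
    windows contains a genuine interior local maximum (no shoulders)."""
    centers = (
        rng.uniform(61.5, 63.5),
        rng.uniform(68.8, 71.2),
        rng.uniform(74.5, 77.0),
    )
    sigmas = (rng.uniform(1.2, 1.6), rng.uniform(1.2, 1.6), rng.uniform(1.5, 2.4))
    amps = (rng.uniform(0.20, 0.35), rng.uniform(0.22, 0.38), rng.uniform(0.05, 0.15))
    return gaussian_mix_curve(centers, sigmas, amps)


# ---------------------------------------------------------------------------
# Peak finding
# ---------------------------------------------------------------------------

class TestMonotonicPeaks:
    def test_single_gaussian(self):
        curve = gaussian_mix_curve(centers=(70.0,), sigmas=(1.5,), amps=(0.3,))
        peaks = find_peaks_monotonic(curve)
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(70.0)

    def test_monotone_curve_has_no_peaks(self, canonical_mesh):
        curve = ThermogramCurve("mono", canonical_mesh, np.linspace(0, 1, 451))
        assert find_peaks_monotonic(curve) == []

    def test_two_gaussians_match_brute_force(self):
        curve = gaussian_mix_curve(centers=(63.0, 70.0), sigmas=(1.5, 1.5), amps=(0.25, 0.30))
        peaks = find_peaks_monotonic(curve)
        oracle = brute_local_maxima(list(curve.temperatures), list(curve.cp))
        assert peaks == oracle
        assert [round(p[0], 1) for p in peaks] == [63.0, 70.0]

    def test_plateau_breaks_run(self, canonical_mesh):
        cp = np.zeros(451)
        cp[100:104] = [0.1, 0.2, 0.3, 0.4]
        cp[104] = 0.4  # plateau before the drop
        cp[105:108] = [0.3, 0.2, 0.1]
        curve = ThermogramCurve("plateau", canonical_mesh, cp)
        assert find_peaks_monotonic(curve) == []


class TestWindowedPeaks:
    def test_gaussian_at_63(self):
        curve = gaussian_mix_curve(centers=(63.0,), sigmas=(1.5,), amps=(0.26,))
        (t1, h1), _, _ = find_peaks_windowed(curve)
        assert t1 == pytest.approx(63.0)
        assert h1 == pytest.approx(0.26)

    def test_flat_curve_ties_to_lowest_temperature(self, canonical_mesh):
        curve = ThermogramCurve("flat", canonical_mesh, np.full(451, 0.1))
        peaks = find_peaks_windowed(curve)
        assert [p[0] for p in peaks] == [60.0, 67.0, 73.0]
        assert all(p[1] == 0.1 for p in peaks)

    def test_methods_agree_on_peaks_1_and_2(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            curve = random_three_gaussian(rng)
            windowed = find_peaks_windowed(curve)
            mono = find_peaks_monotonic(curve)
            w = PeakWindows()
            for k, window in ((0, w.peak1), (1, w.peak2)):
                inside = [p for p in mono if window[0] <= p[0] <= window[1]]
                if inside:
                    assert windowed[k] in inside


class TestValley:
    def test_two_gaussian_valley(self):
        curve = gaussian_mix_curve(centers=(63.0, 70.0), sigmas=(1.5, 1.5), amps=(0.25, 0.30))
        tv, hv = find_valley(curve, 63.0, 70.0)
        assert tv == pytest.approx(
            brute_valley(list(curve.temperatures), list(curve.cp), 63.0, 70.0)[0]
        )
        assert hv < 0.25 and 65.0 < tv < 68.0

    def test_v_shape_vertex(self, canonical_mesh):
        t = canonical_mesh.values
        curve = ThermogramCurve("v", canonical_mesh, np.abs(t - 66.0))
        assert find_valley(curve, 60.0, 72.0) == (66.0, 0.0)

    def test_flat_segment_ties_to_lowest_temperature(self, canonical_mesh):
        cp = np.full(451, 0.5)
        curve = ThermogramCurve("flat", canonical_mesh, cp)
        tv, hv = find_valley(curve, 63.0, 70.0)
        assert tv == pytest.approx(63.1)

    def test_requires_interior_points(self):
        curve = gaussian_mix_curve()
        with pytest.raises(ValueError):
            find_valley(curve, 63.0, 63.1)


# ---------------------------------------------------------------------------
# Scalar descriptors
# ---------------------------------------------------------------------------

class TestScalars:
    def test_triangle_width(self, canonical_mesh):
        t = canonical_mesh.values
        cp = np.clip(np.minimum((t - 60.0) / 5.0, (70.0 - t) / 5.0), 0.0, None)
        curve = ThermogramCurve("tri", canonical_mesh, cp)
        assert width_at_half_height(curve) == pytest.approx(5.0, abs=1e-9)

    def test_gaussian_fwhm(self):
        curve = gaussian_mix_curve(centers=(67.5,), sigmas=(2.0,), amps=(0.3,))
        fwhm = 2.0 * 2.0 * np.sqrt(2.0 * np.log(2.0))
        assert width_at_half_height(curve) == pytest.approx(fwhm, abs=0.1)

    def test_rectangle_width(self, canonical_mesh):
        t = canonical_mesh.values
        cp = np.where((t >= 60.0) & (t <= 70.0), 0.4, 0.0)
        curve = ThermogramCurve("rect", canonical_mesh, cp)
        assert width_at_half_height(curve) == pytest.approx(10.0, abs=0.1)

    def test_constant_curve_area_max_median(self, canonical_mesh):
        curve = ThermogramCurve("const", canonical_mesh, np.full(451, 0.1))
        assert total_area(curve) == pytest.approx(4.5)
        assert max_and_tmax(curve) == (pytest.approx(0.1), 45.0)
        assert median_cp(curve) == pytest.approx(0.1)
        assert first_moment_temperature(curve) == pytest.approx(67.5)

    def test_median_invariant_to_antisymmetric_perturbation(self, canonical_mesh):
        base = np.full(451, 0.2)
        pert = np.zeros(451)
        pert[10] = 0.05
        pert[440] = -0.05
        curve = ThermogramCurve("p", canonical_mesh, base + pert)
        assert median_cp(curve) == pytest.approx(0.2)

    def test_three_gaussian_area_analytic(self):
        sigmas = (1.2, 1.2, 1.2)  # narrow: negligible tail truncation
        amps = (0.26, 0.30, 0.10)
        curve = gaussian_mix_curve(sigmas=sigmas, amps=amps)
        analytic = sum(a * s * np.sqrt(2.0 * np.pi) for a, s in zip(amps, sigmas))
        assert total_area(curve) == pytest.approx(analytic, abs=1e-3)

    def test_tfm_symmetry(self):
        sym = gaussian_mix_curve(centers=(67.5,), sigmas=(2.0,), amps=(0.3,))
        assert first_moment_temperature(sym) == pytest.approx(67.5, abs=1e-6)
        two = gaussian_mix_curve(centers=(60.0, 75.0), sigmas=(1.5, 1.5), amps=(0.3, 0.3))
        assert first_moment_temperature(two) == pytest.approx(67.5, abs=1e-6)

    def test_tfm_requires_positive_total(self, canonical_mesh):
        curve = ThermogramCurve("neg", canonical_mesh, np.full(451, -0.1))
        with pytest.raises(ValueError):
            first_moment_temperature(curve)


# ---------------------------------------------------------------------------
# Full metric set
# ---------------------------------------------------------------------------

class TestMetricSet:
    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            curve = random_three_gaussian(rng)
            ms = compute_metric_set(curve)
            oracle = brute_metric_set(curve)
            for name in METRIC_COLUMNS:
                assert ms[name] == pytest.approx(oracle[name], abs=1e-9), name

    def test_invariants(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            ms = compute_metric_set(random_three_gaussian(rng))
            assert ms["V1.2"] <= min(ms["Peak1"], ms["Peak2"])
            assert ms["Peak1.2"] * ms["Peak2.3"] == pytest.approx(ms["Peak1.3"], abs=1e-9)
            assert ms["TPeak1"] < ms["TV1.2"] < ms["TPeak2"]
            for key in ("TMax", "TFM", "TPeak1", "TPeak2", "TPeak3", "TV1.2"):
                assert 45.0 <= ms[key] <= 90.0

    def test_equal_peaks_give_unit_ratio(self):
        curve = gaussian_mix_curve(amps=(0.3, 0.3, 0.001), sigmas=(1.2, 1.2, 1.8))
        ms = compute_metric_set(curve)
        assert ms["Peak1.2"] == pytest.approx(1.0, abs=1e-3)

    def test_shoulder_peak3_disagrees(self):
        # peak 3 only a shoulder on peak 2's tail: windowed pins an edge/max,
        # the monotonic method finds nothing there, agreement flag is False
        curve = gaussian_mix_curve(
            centers=(63.0, 70.0, 74.0), sigmas=(1.5, 2.5, 3.5), amps=(0.26, 0.30, 0.02)
        )
        ms = compute_metric_set(curve)
        assert ms.agreement["peak1"] and ms.agreement["peak2"]
        assert not ms.agreement["peak3"]

    def test_error_names_the_metric_and_sample(self, canonical_mesh):
        curve = ThermogramCurve("flatliner", canonical_mesh, np.full(451, -0.1))
        with pytest.raises(ValueError, match="flatliner"):
            compute_metric_set(curve)

    def test_table_columns(self, default_cohort):
        table = metrics_table(default_cohort.curves[:5])
        assert list(table.columns[:20]) == METRIC_COLUMNS
        assert table.shape[0] == 5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        mu2=st.floats(68.8, 71.2),
        a1=st.floats(0.20, 0.35),
        a2=st.floats(0.22, 0.38),
        a3=st.floats(0.05, 0.15),
        s2=st.floats(1.2, 1.6),
    )
    def test_property_invariants_hold(self, mu2, a1, a2, a3, s2):
        curve = gaussian_mix_curve(centers=(63.0, mu2, 75.5), sigmas=(1.5, s2, 2.0),
                                   amps=(a1, a2, a3))
        ms = compute_metric_set(curve)
        assert ms["V1.2"] <= min(ms["Peak1"], ms["Peak2"]) + 1e-12
        assert ms["Peak1.2"] * ms["Peak2.3"] == pytest.approx(ms["Peak1.3"], abs=1e-9)
        assert ms["Area"] == pytest.approx(
            brute_trapezoid(list(curve.temperatures), list(curve.cp)), abs=1e-9
        )
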