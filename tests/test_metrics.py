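"""The 19-metric panel: peak/valley finders, global summaries, oracle
agreement on analytic curves, and equivariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlbkit.errors import DomainError
from tlbkit.grid import TEMP_GRID
from tlbkit.io import Thermogram
from tlbkit.metrics import (METRIC_NAMES, compute_panel, find_peak, find_valley,
                            global_metrics, panels_to_frame)

from conftest import gaussian, make_thermogram, random_three_gaussian


def oracle_panel(components, step=0.001):
    """Brute-force metric evaluation of an analytic Gaussian mixture on a
    densely oversampled grid, independent of the package's grid code path."""
    t = np.arange(45.0, 90.0 + step / 2, step)
    cp = sum(gaussian(t, c, s, a) for c, s, a in components)
    out = {}
    for name, (lo, hi) in (("1", (60.0, 66.0)), ("2", (67.0, 73.0)),
                           ("3", (73.0, 81.0))):
        m = (t >= lo) & (t < hi)
        i = np.argmax(cp[m])
        out[f"Peak{name}"], out[f"TPeak{name}"] = cp[m][i], t[m][i]
    v = (t > out["TPeak1"]) & (t < out["TPeak2"])
    i = np.argmin(cp[v])
    out["V12"], out["TV12"] = cp[v][i], t[v][i]
    imax = np.argmax(cp)
    out["Max"], out["TMax"] = cp[imax], t[imax]
    out["TFM"] = (t * cp).sum() / cp.sum()
    out["Area"] = np.trapezoid(cp, t)
    above = np.flatnonzero(cp >= out["Max"] / 2)
    out["Width"] = t[above[-1]] - t[above[0]]
    out["P1.P2"] = out["Peak1"] / out["Peak2"]
    out["P1.P3"] = out["Peak1"] / out["Peak3"]
    out["P2.P3"] = out["Peak2"] / out["Peak3"]
    for k in ("1", "2", "3"):
        out[f"V12.P{k}"] = out["V12"] / out[f"Peak{k}"]
    return out


class TestFindPeak:
    def test_gaussian_inside_window(self, unit_gaussian_tg):
        amp, t = find_peak(unit_gaussian_tg, (60.0, 66.0))
        assert t == 63.0
        assert amp == pytest.approx(1.0)

    def test_monotone_curve_hits_half_open_boundary(self):
        tg = Thermogram("ramp", TEMP_GRID - 45.0)
        amp, t = find_peak(tg, (60.0, 66.0))
        assert t == pytest.approx(65.9)
        assert amp == pytest.approx(65.9 - 45.0)

    def test_tie_breaks_to_lowest_temperature(self):
        cp = np.zeros_like(TEMP_GRID)
        cp[TEMP_GRID == 61.0] = 0.5
        cp[TEMP_GRID == 64.0] = 0.5
        amp, t = find_peak(Thermogram("tie", cp), (60.0, 66.0))
        assert (amp, t) == (0.5, 61.0)

    def test_empty_window_raises(self, unit_gaussian_tg):
        with pytest.raises(DomainError):
            find_peak(unit_gaussian_tg, (60.0, 60.0))


class TestFindValley:
    def test_bimodal_equal_gaussians(self):
        tg = make_thermogram([(63.0, 2.0, 1.0), (70.0, 2.0, 1.0)])
        amp, t = find_valley(tg, 63.0, 70.0)
        assert t == pytest.approx(66.5, abs=0.1)

    def test_monotone_segment_valley_at_first_interior_point(self):
        tg = Thermogram("ramp", TEMP_GRID.copy())
        amp, t = find_valley(tg, 63.0, 70.0)
        assert t == pytest.approx(63.1)

    def test_constant_profile_tie_break(self):
        tg = Thermogram("flat", np.full_like(TEMP_GRID, 0.2))
        amp, t = find_valley(tg, 63.0, 70.0)
        assert (amp, t) == (0.2, pytest.approx(63.1))

    def test_no_interior_points_raises(self, unit_gaussian_tg):
        with pytest.raises(DomainError):
            find_valley(unit_gaussian_tg, 63.0, 63.05)


class TestGlobalMetrics:
    def test_gaussian_closed_forms(self, unit_gaussian_tg):
        g = global_metrics(unit_gaussian_tg)
        sigma = 2.0
        assert g.t_fm == pytest.approx(63.0, abs=0.05)
        assert g.width == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)), abs=0.01)
        assert g.area == pytest.approx(sigma * np.sqrt(2 * np.pi), rel=1e-3)
        assert g.max_amp == pytest.approx(1.0)
        assert g.t_max == 63.0

    def test_symmetric_profile_centered_tfm(self):
        tg = make_thermogram([(67.5, 2.5, 1.0)])
        assert global_metrics(tg).t_fm == pytest.approx(67.5, abs=1e-9)

    def test_homogeneity_under_scaling(self, trimodal_tg):
        g1 = global_metrics(trimodal_tg)
        g2 = global_metrics(Thermogram("x5", 5.0 * trimodal_tg.cp_excess))
        assert g2.max_amp == pytest.approx(5 * g1.max_amp)
        assert g2.area == pytest.approx(5 * g1.area)
        assert (g2.t_max, g2.t_fm, g2.width) == \
            (g1.t_max, pytest.approx(g1.t_fm), pytest.approx(g1.width))

    def test_nonpositive_profile_flags_tfm(self):
        tg = Thermogram("neg", np.full_like(TEMP_GRID, -0.1))
        with pytest.warns(UserWarning, match="first-moment"):
            g = global_metrics(tg)
        assert np.isnan(g.t_fm)


class TestComputePanel:
    def test_template_roundtrip(self, trimodal_tg):
        p = compute_panel(trimodal_tg)
        assert p.t_peak1 == pytest.approx(63.0, abs=0.1)
        assert p.t_peak2 == pytest.approx(70.0, abs=0.1)
        assert p.t_peak3 == pytest.approx(77.0, abs=0.1)

    def test_flat_zero_profile_degenerate(self):
        tg = Thermogram("zero", np.zeros_like(TEMP_GRID))
        with pytest.warns(UserWarning):
            p = compute_panel(tg)
        assert p.peak1 == p.peak2 == p.peak3 == p.max_amp == 0.0
        assert np.isnan(p.r_p1p2) and np.isnan(p.r_v12p3)
        assert p.area == 0.0

    def test_recomputation_is_bit_identical(self, trimodal_tg):
        a = compute_panel(trimodal_tg).to_dict()
        b = compute_panel(trimodal_tg).to_dict()
        assert a == b

    def test_ratio_consistency_invariant(self, trimodal_tg):
        p = compute_panel(trimodal_tg)
        assert p.r_p1p3 == pytest.approx(p.r_p1p2 * p.r_p2p3, rel=1e-9)
        assert p.r_v12p2 == pytest.approx(p.v12 / p.peak2, rel=1e-12)

    def test_panel_ordering_invariants(self, trimodal_tg):
        p = compute_panel(trimodal_tg)
        assert 60.0 <= p.t_peak1 < 66.0
        assert 67.0 <= p.t_peak2 < 73.0
        assert 73.0 <= p.t_peak3 < 81.0
        assert p.t_peak1 < p.t_v12 < p.t_peak2
        assert p.v12 <= min(p.peak1, p.peak2)
        assert p.max_amp >= max(p.peak1, p.peak2, p.peak3)

    def test_frame_has_canonical_columns(self, trimodal_tg):
        frame = panels_to_frame([compute_panel(trimodal_tg)])
        assert list(frame.columns) == list(METRIC_NAMES)
        assert frame.shape == (1, 19)


class TestOracleAgreement:
    def test_random_profiles_match_dense_oracle(self):
        """Every metric agrees with brute-force evaluation of the analytic
        mixture on a 0.001 degC grid."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            comps = random_three_gaussian(rng)
            panel = compute_panel(make_thermogram(comps)).to_dict()
            oracle = oracle_panel(comps)
            for name in METRIC_NAMES:
                got, want = panel[name], oracle[name]
                if name.startswith("T") or name == "Width":
                    assert got == pytest.approx(want, abs=0.06), name
                elif name == "Area":
                    assert got == pytest.approx(want, rel=5e-3), name
                else:
                    assert got == pytest.approx(want, rel=1e-2, abs=1e-4), name


class TestEquivariance:
    @given(c=st.floats(0.1, 20.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c):
        comps = [(63.0, 1.8, 0.15), (70.0, 2.0, 0.095), (77.0, 1.6, 0.05)]
        base = compute_panel(make_thermogram(comps)).to_dict()
        scaled = compute_panel(
            Thermogram("s", c * make_thermogram(comps).cp_excess)).to_dict()
        for name in ("Peak1", "Peak2", "Peak3", "V12", "Max", "Area"):
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-12)
        for name in ("TPeak1", "TPeak2", "TPeak3", "TV12", "TMax", "TFM",
                     "Width", "P1.P2", "P1.P3", "P2.P3", "V12.P1", "V12.P2",
                     "V12.P3"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)

    def test_small_shift_equivariance(self):
        comps = [(63.0, 1.8, 0.15), (70.0, 2.0, 0.095), (77.0, 1.6, 0.05)]
        base = compute_panel(make_thermogram(comps)).to_dict()
        rng = np.random.default_rng(7)
        for delta in rng.uniform(-0.5, 0.5, 20):
            shifted = compute_panel(
                make_thermogram([(c + delta, s, a) for c, s, a in comps])).to_dict()
            for name in ("TPeak1", "TPeak2", "TPeak3", "TV12", "TMax", "TFM"):
                assert shifted[name] - base[name] == pytest.approx(delta, abs=0.1), name
            for name in ("Peak1", "Peak2", "Peak3", "Max"):
                assert shifted[name] == pytest.approx(base[name], rel=2e-3), name
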