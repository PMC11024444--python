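"""Non-parametric statistics: Kruskal–Wallis family tests with adjustment,
pairwise Wilcoxon forms, within-patient deltas and profile summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tlbkit.errors import DomainError, PairingError
from tlbkit.grid import TEMP_GRID
from tlbkit.io import Thermogram
from tlbkit.metrics import METRIC_NAMES
from tlbkit.stats import (delta_metrics, kruskal_wallis_panel,
                          mean_difference_profile, pairwise_wilcoxon,
                          profile_band, results_to_frame)
from tlbkit.synthetic import NoiseModel, simulate_cohort


def random_panels(rng, n_per_group, groups=("A", "B", "C"), shift=None):
    """Null metric panels (all groups share one distribution); ``shift``
    optionally displaces one group on one metric."""
    frames, labels = [], []
    for g in groups:
        block = pd.DataFrame(rng.normal(size=(n_per_group, 19)),
                             columns=METRIC_NAMES)
        if shift and g == shift[0]:
            block[shift[1]] += shift[2]
        frames.append(block)
        labels += [g] * n_per_group
    panels = pd.concat(frames, ignore_index=True)
    panels.index = [f"s{i}" for i in range(len(panels))]
    return panels, labels


class TestKruskalWallisPanel:
    def test_shape_and_p_ordering(self):
        rng = np.random.default_rng(0)
        panels, labels = random_panels(rng, 12)
        results = kruskal_wallis_panel(panels, labels)
        assert len(results) == 19
        assert [r.metric_name for r in results] == list(METRIC_NAMES)
        for r in results:
            assert 0.0 <= r.p_unadjusted <= r.p_adjusted <= 1.0

    def test_constant_metric_yields_p_one(self):
        rng = np.random.default_rng(1)
        panels, labels = random_panels(rng, 6)
        panels["Area"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            results = kruskal_wallis_panel(panels, labels)
        assert dict((r.metric_name, r.p_adjusted) for r in results)["Area"] == 1.0

    def test_identical_constant_groups_adjusted_p_one(self):
        panels = pd.DataFrame(1.0, index=range(8), columns=METRIC_NAMES)
        with pytest.warns(UserWarning):
            results = kruskal_wallis_panel(panels, ["A"] * 4 + ["B"] * 4)
        assert all(r.p_adjusted == 1.0 for r in results)

    def test_holm_monotone_in_unadjusted_order(self):
        rng = np.random.default_rng(2)
        panels, labels = random_panels(rng, 10, shift=("A", "TFM", 2.0))
        frame = results_to_frame(kruskal_wallis_panel(panels, labels))
        ordered = frame.sort_values("p_unadjusted")
        assert ordered["p_adjusted"].is_monotonic_increasing
        assert (frame["p_adjusted"] >= frame["p_unadjusted"]).all()

    def test_power_against_three_sd_shift(self):
        """A 3-pooled-SD shift on one metric is detected after Holm
        adjustment in at least 95% of replicates."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            panels, labels = random_panels(rng, 20, shift=("B", "Peak1", 3.0))
            res = kruskal_wallis_panel(panels, labels)
            p = dict((r.metric_name, r.p_adjusted) for r in res)["Peak1"]
            hits += p < 0.05
        assert hits / reps >= 0.95

    def test_monotone_transform_invariance(self):
        """Rank tests are unchanged by strictly monotone metric transforms."""
        rng = np.random.default_rng(4)
        panels, labels = random_panels(rng, 9)
        transformed = panels.apply(lambda c: np.exp(c / 2))
        a = results_to_frame(kruskal_wallis_panel(panels, labels))
        b = results_to_frame(kruskal_wallis_panel(transformed, labels))
        np.testing.assert_allclose(a["p_unadjusted"], b["p_unadjusted"], rtol=1e-12)

    def test_too_small_group_rejected(self):
        rng = np.random.default_rng(5)
        panels, _ = random_panels(rng, 2, groups=("A", "B"))
        with pytest.raises(DomainError):
            kruskal_wallis_panel(panels, ["A", "A", "A", "B"])


class TestPairwiseWilcoxon:
    @staticmethod
    def panel_from(values_by_group, metric="TFM"):
        rows, labels = [], []
        for g, vals in values_by_group.items():
            for v in vals:
                rows.append(v)
                labels.append(g)
        panels = pd.DataFrame({m: rows for m in METRIC_NAMES})
        panels.index = [f"s{i}" for i in range(len(rows))]
        return panels, labels

    def test_exact_rank_sum_enumeration_value(self):
        """Groups (1,2,3) vs (4,5,6): all 20 rank splits, two-sided p = 0.1."""
        panels, labels = self.panel_from({"A": [1, 2, 3], "B": [4, 5, 6]})
        p = pairwise_wilcoxon(panels, labels, "TFM")[("A", "B")]
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        panels, labels = self.panel_from({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert pairwise_wilcoxon(panels, labels, "TFM")[("A", "B")] == 1.0

    def test_paired_all_zero_differences(self):
        panels, labels = self.panel_from({"T0": [2.0, 3.0, 4.0],
                                          "Tfu": [2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="zero"):
            p = pairwise_wilcoxon(panels, labels, "TFM", paired=True,
                                  patient_ids=["p1", "p2", "p3"] * 2)
        assert p[("T0", "Tfu")] == 1.0

    def test_paired_requires_matching_patients(self):
        panels, labels = self.panel_from({"T0": [1.0, 2.0], "Tfu": [1.5, 2.5]})
        with pytest.raises(PairingError):
            pairwise_wilcoxon(panels, labels, "TFM", paired=True,
                              patient_ids=["p1", "p2", "p3", "p4"])

    def test_all_pairs_returned_for_three_groups(self):
        rng = np.random.default_rng(6)
        vals = {g: rng.normal(size=5).tolist() for g in ("A", "B", "C")}
        panels, labels = self.panel_from(vals)
        out = pairwise_wilcoxon(panels, labels, "TFM")
        assert set(out) == {("A", "B"), ("A", "C"), ("B", "C")}


class TestDeltaMetrics:
    def test_identical_timepoints_all_zero(self):
        t0 = pd.DataFrame(np.arange(38.0).reshape(2, 19), columns=METRIC_NAMES,
                          index=["p1", "p2"])
        delta = delta_metrics(t0, t0.copy())
        assert (delta == 0).all().all()

    def test_unit_shift_arithmetic_and_unpaired_drop(self):
        t0 = pd.DataFrame(np.zeros((2, 19)), columns=METRIC_NAMES,
                          index=["p1", "p2"])
        tfu = pd.DataFrame(np.ones((2, 19)), columns=METRIC_NAMES,
                          index=["p1", "p3"])
        delta = delta_metrics(t0, tfu)
        assert list(delta.index) == ["p1"]
        assert (delta.loc["p1"] == 1.0).all()

    def test_no_overlap_raises(self):
        t0 = pd.DataFrame(np.zeros((1, 19)), columns=METRIC_NAMES, index=["a"])
        tfu = pd.DataFrame(np.zeros((1, 19)), columns=METRIC_NAMES, index=["b"])
        with pytest.raises(DomainError):
            delta_metrics(t0, tfu)

    def test_tmi_recovery_direction(self):
        """TMI patients regain Peak 1 and lose Peak 3 from baseline to
        follow-up (median delta signs)."""
        ds = simulate_cohort({"TMI": 12}, timepoints=("T0", "Tfu"), seed=8)
        ds.compute_panels()
        m = ds.manifest
        t0 = m.loc[m["timepoint"] == "T0"]
        tfu = m.loc[m["timepoint"] == "Tfu"]
        delta = delta_metrics(ds.panels.loc[t0["sample_id"]],
                              ds.panels.loc[tfu["sample_id"]],
                              t0["patient_id"], tfu["patient_id"])
        assert delta["Peak1"].median() > 0
        assert delta["Peak3"].median() < 0


class TestProfileBand:
    def test_single_curve_band_collapses(self, trimodal_tg):
        band = profile_band([trimodal_tg])
        np.testing.assert_array_equal(band.center_curve, trimodal_tg.cp_excess)
        np.testing.assert_array_equal(band.lower_curve, band.upper_curve)

    def test_order_statistics_invariant(self):
        rng = np.random.default_rng(10)
        mat = rng.normal(size=(40, 451))
        band = profile_band(mat)
        assert (band.lower_curve <= band.center_curve).all()
        assert (band.center_curve <= band.upper_curve).all()

    def test_normal_quantile_band_width(self):
        rng = np.random.default_rng(11)
        mat = rng.normal(0.0, 1.0, size=(1000, 451))
        band = profile_band(mat)
        half_width = (band.upper_curve - band.lower_curve) / 2
        assert np.mean(half_width) == pytest.approx(1.96, abs=0.15)

    def test_reordering_commutes(self):
        rng = np.random.default_rng(12)
        mat = rng.normal(size=(15, 451))
        a = profile_band(mat)
        b = profile_band(mat[::-1])
        np.testing.assert_array_equal(a.center_curve, b.center_curve)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            profile_band([])


class TestMeanDifferenceProfile:
    @staticmethod
    def cohort_from(curves_by_sample, rows):
        thermo = {sid: Thermogram(sid, cp) for sid, cp in curves_by_sample.items()}
        from tlbkit.cohort import CohortDataset
        return CohortDataset(manifest=pd.DataFrame(rows), thermograms=thermo)

    def test_identical_timepoints_zero_curve(self):
        cp = np.ones_like(TEMP_GRID)
        ds = self.cohort_from(
            {"a_T0": cp, "a_Tfu": cp},
            [{"sample_id": "a_T0", "patient_id": "a", "phenotype": "TMI",
              "timepoint": "T0"},
             {"sample_id": "a_Tfu", "patient_id": "a", "phenotype": "TMI",
              "timepoint": "Tfu"}])
        out = mean_difference_profile(ds)
        np.testing.assert_array_equal(out["TMI"].to_numpy(), 0.0)

    def test_opposite_differences_cancel(self):
        base = np.zeros_like(TEMP_GRID)
        d = np.sin(TEMP_GRID / 4)
        ds = self.cohort_from(
            {"a_T0": base, "a_Tfu": d, "b_T0": base, "b_Tfu": -d},
            [{"sample_id": f"{p}_{tp}", "patient_id": p, "phenotype": "TMI",
              "timepoint": tp} for p in ("a", "b") for tp in ("T0", "Tfu")])
        np.testing.assert_allclose(mean_difference_profile(ds)["TMI"], 0.0,
                                   atol=1e-15)

    def test_tmi_difference_signature(self):
        """Recovered-minus-acute TMI curves rise in the Peak 1 window and
        fall in the Peak 3 window."""
        ds = simulate_cohort({"TMI": 10}, timepoints=("T0", "Tfu"), seed=13,
                             frac_tmi_80c=0.0)
        out = mean_difference_profile(ds)
        p1 = (TEMP_GRID >= 60) & (TEMP_GRID < 66)
        p3 = (TEMP_GRID >= 73) & (TEMP_GRID < 81)
        assert out["TMI"].to_numpy()[p1].mean() > 0
        assert out["TMI"].to_numpy()[p3].mean() < 0

    def test_phenotype_without_pairs_omitted(self):
        cp = np.ones_like(TEMP_GRID)
        ds = self.cohort_from(
            {"a_T0": cp, "a_Tfu": cp, "b_T0": cp},
            [{"sample_id": "a_T0", "patient_id": "a", "phenotype": "TMI",
              "timepoint": "T0"},
             {"sample_id": "a_Tfu", "patient_id": "a", "phenotype": "TMI",
              "timepoint": "Tfu"},
             {"sample_id": "b_T0", "patient_id": "b", "phenotype": "cCAD",
              "timepoint": "T0"}])
        with pytest.warns(UserWarning, match="cCAD"):
            out = mean_difference_profile(ds)
        assert list(out.columns) == ["TMI"]
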