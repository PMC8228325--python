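"""Shape metrics, proximity rule, robust outliers, nested inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import synaptomito as sm
from synaptomito.morphometry import (
    DataError,
    add_shape_metrics,
    remove_outliers,
    robust_outlier_mask,
)

from conftest import morpho_frame


class TestShapeMetrics:
    def test_circle_is_unit(self):
        r = 0.2
        m = sm.shape_metrics(math.pi * r**2, 2 * math.pi * r)
        assert m.circularity[0] == pytest.approx(1.0, abs=1e-12)
        assert m.elongation[0] == pytest.approx(1.0, abs=1e-12)

    def test_unit_square(self):
        m = sm.shape_metrics(1.0, 4.0)
        assert m.circularity[0] == pytest.approx(math.pi / 4, abs=1e-12)
        assert m.elongation[0] == pytest.approx(4 / math.pi, abs=1e-12)

    def test_ellipse_against_numeric_perimeter(self):
        a, b = 0.4, 0.2
        area = math.pi * a * b
        # exact perimeter by numeric integration of the arc length
        perim, _ = integrate.quad(
            lambda t: math.hypot(a * math.sin(t), b * math.cos(t)), 0, 2 * math.pi
        )
        exact = sm.shape_metrics(area, perim).elongation[0]
        # Ramanujan's approximation as the measured perimeter
        h = ((a - b) / (a + b)) ** 2
        ram = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        approx = sm.shape_metrics(area, ram).elongation[0]
        assert approx == pytest.approx(exact, rel=0.01)
        assert approx == pytest.approx(1.19, abs=0.02)

    def test_isoperimetric_violation_raises(self):
        with pytest.raises(DataError):
            sm.shape_metrics(1.0, 3.0)  # circle of area 1 needs P >= 3.545

    @settings(max_examples=50, deadline=None)
    @given(
        area=st.floats(0.01, 10.0),
        elong=st.floats(1.0, 5.0),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, area, elong, k):
        perim = math.sqrt(4 * math.pi * area * elong)
        m1 = sm.shape_metrics(area, perim)
        m2 = sm.shape_metrics(area * k**2, perim * k)
        assert m2.elongation[0] == pytest.approx(m1.elongation[0], rel=1e-9)
        assert m1.elongation[0] >= 1.0


class TestProximityFilter:
    def _records(self, distances):
        rows = []
        for i, d in enumerate(distances):
            rows.append(("a1", "WT", f"s{i}", "post", True, 0.1, 1.2, d, 300.0))
        return morpho_frame(rows)

    def test_threshold_is_inclusive_at_500(self):
        rec = sm.proximity_filter(self._records([499.0, 500.0, 501.0]))
        assert rec["has_mito"].tolist() == [True, True, False]

    def test_infinite_threshold_is_identity(self):
        rec = self._records([100.0, 400.0, 999.0])
        out = sm.proximity_filter(rec, max_distance=np.inf)
        assert out["has_mito"].all()

    def test_negative_distance_rejected(self):
        with pytest.raises(DataError):
            sm.proximity_filter(self._records([-1.0]))

    def test_uniform_distances_five_sixths_survive(self):
        rng = np.random.default_rng(0)
        rec = self._records(rng.uniform(0, 600, 3000))
        out = sm.proximity_filter(rec)
        assert out["has_mito"].mean() == pytest.approx(5 / 6, abs=0.03)

    def test_synapse_rows_kept(self):
        rec = self._records([900.0])
        out = sm.proximity_filter(rec)
        assert len(out) == 1 and not out["has_mito"].iloc[0]


class TestRobustOutliers:
    def test_planted_extreme_point_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20)
        x[7] = 10.0
        flags = robust_outlier_mask(x, q=0.01)
        assert flags[7]
        assert flags.sum() == 1

    def test_constant_vector_no_outliers(self):
        assert robust_outlier_mask(np.ones(10)).sum() == 0

    def test_false_positive_rate_controlled(self):
        rng = np.random.default_rng(2)
        ok = 0
        for _ in range(200):
            flags = robust_outlier_mask(rng.normal(0, 1, 100), q=0.01)
            ok += flags.sum() <= 2
        assert ok / 200 >= 0.95

    def test_clean_flagged_partition(self):
        x = np.concatenate([np.zeros(19), [50.0]])
        clean, flagged = sm.robust_outliers(x + np.arange(20) * 1e-3)
        assert len(clean) + len(flagged) == 20
        assert flagged.max() > 49

    def test_contaminated_simulation_cleaned(self):
        cfg = sm.MorphoSimConfig(outlier_rate=0.05, outlier_scale=10.0,
                                 synapses_per_animal=60, seed=3)
        rec, _ = sm.simulate_morphometry(cfg)
        cleaned = remove_outliers(rec)
        mito_in = rec["has_mito"].sum()
        mito_out = cleaned["has_mito"].sum()
        assert mito_out < mito_in  # some contamination removed
        assert cleaned["area_um2"].max() < rec["area_um2"].max()


class TestNestedTest:
    @staticmethod
    def _sim(beta1=0.0, sa=0.01, se=0.03, n_animals=6, n_obs=15, seed=0):
        r = np.random.default_rng(seed)
        rows = []
        for g in ("WT", "KO"):
            for a in range(n_animals):
                u = r.normal(0, sa)
                mu = 0.1 + (beta1 if g == "KO" else 0.0) + u
                for k in range(n_obs):
                    rows.append((f"{g}_a{a}", g, f"{g}{a}_{k}", "post", True,
                                 mu + r.normal(0, se), np.nan, 100.0, 300.0))
        return morpho_frame(rows)

    def test_zero_animal_variance_matches_mean_difference(self):
        d = self._sim(beta1=-0.02, sa=0.0, seed=4)
        res = sm.nested_genotype_test(d, "area_um2")
        wt = d[d.genotype == "WT"]["area_um2"].mean()
        ko = d[d.genotype == "KO"]["area_um2"].mean()
        assert res.estimate == pytest.approx(ko - wt, abs=1e-6)

    def test_animal_relabeling_invariance(self):
        d = self._sim(beta1=-0.02, seed=5)
        res1 = sm.nested_genotype_test(d, "area_um2")
        d2 = d.copy()
        d2["animal_id"] = d2["animal_id"].map(lambda s: f"zz_{s}")
        res2 = sm.nested_genotype_test(d2, "area_um2")
        assert res1.estimate == pytest.approx(res2.estimate, rel=1e-9)
        assert res1.p == pytest.approx(res2.p, rel=1e-9)

    def test_elongation_response_derived_on_the_fly(self):
        cfg = sm.MorphoSimConfig(synapses_per_animal=40, seed=6)
        rec, _ = sm.simulate_morphometry(cfg)
        res = sm.nested_genotype_test(rec, "elongation", compartment="post")
        assert np.isfinite(res.p) and res.estimate < 0  # planted KO reduction


class TestPresence:
    def test_saturated_presence_flagged(self):
        rows = []
        for g in ("WT", "KO"):
            for a in range(3):
                for s in range(5):
                    rows.append((f"{g}{a}", g, f"{g}{a}s{s}", "post", True,
                                 0.1, 1.2, 100.0, 300.0))
        res = sm.mito_presence_test(morpho_frame(rows))
        assert res.zero_variance
        assert res.p == 1.0
        assert res.group_mean_pct["WT"] == pytest.approx(100.0)

    def test_planted_presence_rates_recovered(self):
        cfg = sm.MorphoSimConfig(synapses_per_animal=200, seed=7)
        rec, _ = sm.simulate_morphometry(cfg)
        res = sm.mito_presence_test(rec)
        assert res.group_mean_pct["WT"] == pytest.approx(36.0, abs=4.0)
        assert res.group_mean_pct["KO"] == pytest.approx(42.0, abs=4.0)


class TestAnalyzePipeline:
    def test_full_analysis_detects_postsynaptic_deficit(self):
        cfg = sm.MorphoSimConfig(synapses_per_animal=80, seed=8)
        rec, _ = sm.simulate_morphometry(cfg)
        out = sm.morphometry.analyze(rec) if hasattr(sm, "morphometry") else None
        from synaptomito.morphometry import analyze

        out = analyze(rec)
        assert out["nested"]["post:area_um2"].estimate < 0
        assert out["nested"]["post:area_um2"].p < 0.05
        # presynaptic area has no planted effect
        assert out["nested"]["pre:area_um2"].p > 0.05
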