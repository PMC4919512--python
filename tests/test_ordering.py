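"""Hierarchical matrix, vulnerability weights, factor curves and ranking."""

import numpy as np
import pandas as pd
import pytest

from mfdpm.abnormality import AbnormalityCurve, total_abnormality_index
from mfdpm.cohort import imaging_biomarker_id
from mfdpm.ordering import (
    FactorCurveSet,
    factor_average_curves,
    group_regional_curves,
    hierarchical_matrix,
    rank_factors,
    regional_vulnerability,
)

GRID = np.linspace(40, 70, 120)


def _curve(values, bm):
    return AbnormalityCurve(bm, "HC-LOAD", GRID, np.asarray(values, float))


def _regional(levels: dict[str, float], n_regions=3, jitter=0.0, seed=0):
    """Constant regional curves at a per-factor level (optionally jittered)."""
    rng = np.random.default_rng(seed)
    out = {}
    for f, lvl in levels.items():
        for r in range(n_regions):
            vals = np.full_like(GRID, lvl) + jitter * rng.normal(size=len(GRID))
            bm = imaging_biomarker_id(f, r)
            out[bm] = _curve(np.abs(vals), bm)
    return group_regional_curves(out)


class TestHierarchicalMatrix:
    def test_strict_dominance_gives_100_0(self):
        reg = _regional({"a": 2.0, "b": 1.0})
        h = hierarchical_matrix(reg).percentages
        assert h.loc["b", "a"] == 100.0
        assert h.loc["a", "b"] == 0.0

    def test_identical_factors_split_50_50(self):
        reg = _regional({"a": 1.0, "b": 1.0})
        h = hierarchical_matrix(reg).percentages
        assert h.loc["a", "b"] == 50.0 and h.loc["b", "a"] == 50.0

    def test_five_factors_give_5x5_complementary_matrix(self):
        levels = dict(zip("abcde", [5.0, 4.0, 3.0, 2.0, 1.0]))
        reg = _regional(levels, jitter=1.0, seed=1)
        hm = hierarchical_matrix(reg)
        h = hm.percentages
        assert h.shape == (5, 5)
        for i in h.index:
            assert h.loc[i, i] == 0.0
            for j in h.columns:
                if i != j:
                    assert h.loc[i, j] + h.loc[j, i] == pytest.approx(100.0)

    def test_ordering_matches_pairwise_means_on_separable_input(self):
        levels = {"w": 0.5, "x": 3.0, "y": 2.0, "z": 1.0}
        hm = hierarchical_matrix(_regional(levels))
        assert hm.ordering == ["x", "y", "z", "w"]

    def test_region_mismatch_rejected(self):
        reg = _regional({"a": 1.0, "b": 2.0})
        del reg["a"][0]
        with pytest.raises(ValueError, match="region"):
            hierarchical_matrix(reg)


def _index_table(totals: dict[str, float]):
    df = pd.DataFrame(
        {"biomarker_id": list(totals), "total": list(totals.values())}
    ).set_index("biomarker_id")
    return df


class TestVulnerability:
    def test_raw_sums_3_to_1_normalize_to_075_025(self):
        table = _index_table(
            {
                imaging_biomarker_id("a", 0): 2.0,
                imaging_biomarker_id("b", 0): 1.0,
                imaging_biomarker_id("a", 1): 0.5,
                imaging_biomarker_id("b", 1): 0.5,
            }
        )
        w = regional_vulnerability(table)
        assert w.weights[0] == pytest.approx(0.75)
        assert w.weights[1] == pytest.approx(0.25)

    def test_uniform_indices_give_equal_weights(self):
        table = _index_table(
            {
                imaging_biomarker_id(f, r): 0.4
                for f in ("a", "b")
                for r in range(4)
            }
        )
        w = regional_vulnerability(table)
        np.testing.assert_allclose(w.weights.to_numpy(), 0.25)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        table = _index_table(
            {
                imaging_biomarker_id(f, r): float(rng.uniform(0, 1))
                for f in ("a", "b", "c")
                for r in range(5)
            }
        )
        assert regional_vulnerability(table).weights.sum() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_missing_pair_rejected(self):
        table = _index_table(
            {
                imaging_biomarker_id("a", 0): 1.0,
                imaging_biomarker_id("a", 1): 1.0,
                imaging_biomarker_id("b", 0): 1.0,
            }
        )
        with pytest.raises(ValueError, match="missing"):
            regional_vulnerability(table)


class TestFactorCurves:
    def test_single_factor_single_region_peaks_at_one(self):
        bm = imaging_biomarker_id("a", 0)
        reg = group_regional_curves({bm: _curve(np.abs(np.sin(GRID)), bm)})
        table = total_abnormality_index(
            {bm: _curve(np.abs(np.sin(GRID)), bm)}
        )
        w = regional_vulnerability(table)
        cs = factor_average_curves(reg, w)
        assert cs.curves["a"].max() == pytest.approx(1.0)

    def test_weighted_average_of_constant_curves(self):
        # regions weighted 0.75/0.25 with constant curves 4 and 0 -> constant 3
        curves = {
            imaging_biomarker_id("a", 0): _curve(
                np.full_like(GRID, 4.0), imaging_biomarker_id("a", 0)
            ),
            imaging_biomarker_id("a", 1): _curve(
                np.zeros_like(GRID), imaging_biomarker_id("a", 1)
            ),
        }
        reg = group_regional_curves(curves)
        table = _index_table(
            {imaging_biomarker_id("a", 0): 3.0, imaging_biomarker_id("a", 1): 1.0}
        )
        w = regional_vulnerability(table)
        cs = factor_average_curves(reg, w)
        np.testing.assert_allclose(cs.curves["a"] * cs.global_max, 3.0)

    def test_weighted_curve_is_convex_combination(self):
        rng = np.random.default_rng(3)
        curves = {}
        for r in range(4):
            bm = imaging_biomarker_id("a", r)
            curves[bm] = _curve(np.abs(rng.normal(size=len(GRID))), bm)
        reg = group_regional_curves(curves)
        table = total_abnormality_index(curves)
        w = regional_vulnerability(table)
        cs = factor_average_curves(reg, w)
        stack = np.stack([c.values for c in curves.values()])
        unnorm = cs.curves["a"] * cs.global_max
        assert np.all(unnorm <= stack.max(axis=0) + 1e-12)
        assert np.all(unnorm >= stack.min(axis=0) - 1e-12)

    def test_all_zero_curves_warn(self):
        bm = imaging_biomarker_id("a", 0)
        reg = group_regional_curves({bm: _curve(np.zeros_like(GRID), bm)})
        w = regional_vulnerability(_index_table({bm: 0.0}))
        with pytest.warns(UserWarning, match="zero"):
            cs = factor_average_curves(reg, w)
        assert cs.global_max == 0.0


class TestRankFactors:
    def test_descending_area_order(self):
        cs = FactorCurveSet(
            ages=GRID,
            curves={
                "a": np.full_like(GRID, 1.0),
                "b": np.full_like(GRID, 0.6),
                "c": np.full_like(GRID, 0.2),
            },
            global_max=1.0,
        )
        order, ties = rank_factors(cs)
        assert order == ["a", "b", "c"] and not ties

    def test_exact_tie_flagged(self):
        cs = FactorCurveSet(
            ages=GRID,
            curves={"a": np.full_like(GRID, 0.5), "b": np.full_like(GRID, 0.5)},
            global_max=1.0,
        )
        order, ties = rank_factors(cs)
        assert ties and order == ["a", "b"]

    def test_rank_at_fixed_age(self):
        cs = FactorCurveSet(
            ages=GRID,
            curves={"a": (GRID - 40) / 30.0, "b": 1.0 - (GRID - 40) / 30.0},
            global_max=1.0,
        )
        order, _ = rank_factors(cs, by="at_age", at_age=41.0)
        assert order == ["b", "a"]
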