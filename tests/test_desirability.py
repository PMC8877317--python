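"""Desirability ramps, overall-D optimization and design-space mapping."""

import numpy as np
import pytest

from formulab import datasets
from formulab.design import scheffe_terms
from formulab.desirability import (
    DesirabilitySpec,
    ResponseGoal,
    design_space,
    desirability,
    optimize_composition,
    overall_desirability,
)
from formulab.scheffe import to_pseudo


@pytest.fixture(scope="module")
def spec():
    return DesirabilitySpec((
        ResponseGoal("size_nm", "minimize", *datasets.OBSERVED_RANGES["size_nm"]),
        ResponseGoal("ee_pct", "maximize", *datasets.OBSERVED_RANGES["ee_pct"]),
    ))


@pytest.fixture(scope="module")
def fits(size_fit, ee_fit):
    return {"size_nm": size_fit, "ee_pct": ee_fit}


class TestRamp:
    def test_hand_arithmetic_example(self):
        goal = ResponseGoal("size", "minimize", 37.5, 47.55)
        assert desirability(37.53, goal) == pytest.approx(
            (47.55 - 37.53) / (47.55 - 37.5), abs=1e-12)
        assert desirability(37.53, goal) == pytest.approx(0.997, abs=0.001)

    @pytest.mark.parametrize("y,expected", [(37.5, 1.0), (47.55, 0.0)])
    def test_minimize_boundaries(self, y, expected):
        assert desirability(y, ResponseGoal("s", "minimize", 37.5, 47.55)) == expected

    @pytest.mark.parametrize("y,expected", [(68.22, 0.0), (86.84, 1.0)])
    def test_maximize_boundaries(self, y, expected):
        assert desirability(y, ResponseGoal("e", "maximize", 68.22, 86.84)) == expected

    def test_weight_is_exponent(self):
        goal = ResponseGoal("s", "minimize", 0.0, 10.0, weight=2.0)
        assert desirability(5.0, goal) == pytest.approx(0.25)

    def test_invalid_goal_rejected(self):
        with pytest.raises(ValueError):
            ResponseGoal("s", "target", 0.0, 1.0)
        with pytest.raises(ValueError):
            ResponseGoal("s", "minimize", 2.0, 1.0)


class TestOverallD:
    def test_zero_component_zeroes_overall(self, spec):
        assert overall_desirability({"size_nm": 0.0, "ee_pct": 0.9}, spec) == 0.0

    def test_relabeling_invariance(self):
        d = {"a": 0.3, "b": 0.8}
        s1 = DesirabilitySpec((ResponseGoal("a", "minimize", 0, 1),
                               ResponseGoal("b", "minimize", 0, 1)))
        s2 = DesirabilitySpec((ResponseGoal("b", "minimize", 0, 1),
                               ResponseGoal("a", "minimize", 0, 1)))
        assert overall_desirability(d, s1) == pytest.approx(
            overall_desirability(d, s2), abs=1e-14)

    @pytest.mark.parametrize("scale", [0.5, 1.0, 3.0])
    def test_common_weight_rescaling_invariance(self, scale):
        d = {"a": 0.3, "b": 0.8}
        base = DesirabilitySpec((ResponseGoal("a", "minimize", 0, 1, 1.0),
                                 ResponseGoal("b", "minimize", 0, 1, 2.0)))
        scaled = DesirabilitySpec((ResponseGoal("a", "minimize", 0, 1, scale),
                                   ResponseGoal("b", "minimize", 0, 1, 2 * scale)))
        assert overall_desirability(d, base) == pytest.approx(
            overall_desirability(d, scaled), abs=1e-12)


class TestOptimization:
    def test_reproduces_published_optimum_desirability(self, fits, spec, constraints):
        """With observed-range limits the optimizer reaches D ≈ 0.812 at the
        published optimum composition (63.78, 30, 6.22)%."""
        res = optimize_composition(fits, spec, constraints, seed=0)
        assert res.D_overall == pytest.approx(0.812, abs=0.002)
        assert np.allclose(100 * res.composition, datasets.OPTIMUM_PCT, atol=0.2)

    def test_reported_D_matches_recomputation(self, fits, spec, constraints):
        from formulab.desirability import _evaluate

        res = optimize_composition(fits, spec, constraints, seed=0)
        _, _, D = _evaluate(fits, spec, res.composition)
        assert res.D_overall == pytest.approx(D, abs=1e-12)

    def test_single_response_reduces_to_size_minimum(self, fits, constraints):
        spec1 = DesirabilitySpec(
            (ResponseGoal("size_nm", "minimize", 37.5, 47.55),))
        res = optimize_composition({"size_nm": fits["size_nm"]}, spec1, constraints,
                                   seed=0)
        assert res.D_overall == pytest.approx(res.d_per_response["size_nm"], abs=1e-12)

    def test_brute_force_grid_never_beats_optimizer(self, fits, spec, constraints,
                                                    coding):
        """Grid oracle: no feasible point of a fine pseudo-space grid attains
        higher overall D than the returned optimum (tolerance 1e-3)."""
        res = optimize_composition(fits, spec, constraints, seed=0)
        step = 0.001
        a = np.arange(0.0, 1.0 + step, step)
        A, B = np.meshgrid(a, a, indexing="ij")
        mask = A + B <= 1.0 + 1e-12
        A, B = A[mask], B[mask]
        P = np.column_stack([A, B, 1.0 - A - B])
        comp = P * coding.span + np.array(coding.lower)
        lo, up = np.array(constraints.lower), np.array(constraints.upper)
        feas = np.all((comp >= lo - 1e-12) & (comp <= up + 1e-12), axis=1)
        X = scheffe_terms(P[feas], "scheffe-quadratic")
        size = X @ fits["size_nm"].coefficients
        ee = X @ fits["ee_pct"].coefficients
        ds = np.clip((47.55 - size) / (47.55 - 37.5), 0, 1)
        de = np.clip((ee - 68.22) / (86.84 - 68.22), 0, 1)
        D = np.sqrt(ds * de)
        assert D.max() <= res.D_overall + 1e-3

    def test_impossible_goals_flagged(self, fits, constraints):
        spec0 = DesirabilitySpec((ResponseGoal("size_nm", "minimize", -10.0, 0.0),))
        res = optimize_composition({"size_nm": fits["size_nm"]}, spec0, constraints,
                                   seed=0)
        assert res.D_overall == 0.0
        assert not res.feasible_optimum


class TestDesignSpace:
    def test_range_bound_thresholds_accept_everything(self, fits, constraints):
        ds = design_space(fits, {"size_nm": ("<=", 47.55), "ee_pct": (">=", 68.22)},
                          constraints, grid_resolution=24)
        assert ds.n_accepted == len(ds.grid) > 0

    def test_impossible_threshold_accepts_nothing(self, fits, constraints):
        ds = design_space(fits, {"size_nm": ("<=", 0.0)}, constraints,
                          grid_resolution=24)
        assert ds.n_accepted == 0

    def test_published_optimum_inside_qtpp_region(self, fits, constraints,
                                                  optimum_fraction):
        thresholds = {"size_nm": ("<=", 39.25), "ee_pct": (">=", 80.0)}
        ds = design_space(fits, thresholds, constraints, grid_resolution=40)
        acc = ds.grid[ds.grid["accepted"]]
        dist = np.linalg.norm(
            acc[["P123", "P407", "TPGS"]].to_numpy() - optimum_fraction, axis=1)
        assert dist.min() < 0.02  # a grid point next to the optimum is accepted

    def test_acceptance_flag_consistent_with_predictions(self, fits, constraints):
        ds = design_space(fits, {"size_nm": ("<=", 40.0)}, constraints,
                          grid_resolution=24)
        acc = ds.grid[ds.grid["accepted"]]
        assert np.all(acc["pred_size_nm"] <= 40.0 + 1e-12)

    def test_tightening_shrinks_the_region(self, fits, constraints):
        loose = design_space(fits, {"size_nm": ("<=", 42.0)}, constraints,
                             grid_resolution=24)
        tight = design_space(fits, {"size_nm": ("<=", 39.0)}, constraints,
                             grid_resolution=24)
        assert tight.n_accepted <= loose.n_accepted
        # subset relation, not just a count comparison
        keys = ["P123", "P407", "TPGS"]
        merged = tight.grid[tight.grid["accepted"]][keys].merge(
            loose.grid[loose.grid["accepted"]][keys], on=keys, how="left",
            indicator=True)
        assert (merged["_merge"] == "both").all()
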