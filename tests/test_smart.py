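"""Joint acceptability and SMART boundary surfaces."""

import numpy as np
import pytest

import smartmar as sm
from smartmar import fixtures as fx
from smartmar.fixtures import hypothetical_model
from tests.conftest import BLEED, DEATH


def classify_against_boundary(surface, names, axes, focal_axis=0):
    """Acceptability of every grid point implied by the boundary: the focal
    value must not exceed the boundary at its conditioning tuple."""
    cond_axes = [axes[i] for i in range(len(axes)) if i != focal_axis]
    acc = np.zeros([a.size for a in axes], dtype=bool)
    it = np.ndindex(*[a.size for a in cond_axes])
    for idx in it:
        point = tuple(float(cond_axes[k][i]) for k, i in enumerate(idx))
        p, censored, unreachable = surface.focal_at(point)
        if unreachable:
            col = np.zeros(axes[focal_axis].size, dtype=bool)
        else:
            col = axes[focal_axis] <= p + 1e-9
        sl = list(idx)
        sl.insert(focal_axis, slice(None))
        acc[tuple(sl)] = col
    return acc


class TestJointAcceptability:
    @pytest.mark.parametrize(
        "shape,point,acceptable",
        [
            ("constant", (3.5, 3.5), True),
            ("constant", (5, 5), True),
            ("constant", (7, 7), False),
            ("increasing", (3.5, 3.5), True),
            ("increasing", (5, 5), True),
            ("increasing", (7.5, 7.5), True),
            ("decreasing", (3.5, 3.5), False),
            ("decreasing", (5, 5), False),
        ],
    )
    def test_acceptance_patterns_by_curvature(self, shape, point, acceptable):
        model = hypothetical_model(shape)
        d = sm.joint_acceptability(
            model, sm.BenefitDelta(5.0), {"AE1": point[0], "AE2": point[1]}
        )
        assert d.acceptable is acceptable

    def test_margin_is_benefit_minus_total_disutility(self):
        model = hypothetical_model("constant")
        d = sm.joint_acceptability(model, sm.BenefitDelta(5.0), {"AE1": 3.5, "AE2": 3.5})
        assert d.utility_margin == pytest.approx(5.0 - 2 * 1.75)

    def test_indifference_counts_as_acceptable(self):
        model = hypothetical_model("constant")
        d = sm.joint_acceptability(model, sm.BenefitDelta(5.0), {"AE1": 5.0, "AE2": 5.0})
        assert d.utility_margin == pytest.approx(0.0) and d.acceptable

    def test_uncovered_risks_held_at_baseline(self, hf_model):
        d = sm.joint_acceptability(hf_model, sm.BenefitDelta(7.75), {DEATH: 4.0})
        assert d.utility_margin == pytest.approx(7.75 - 2.61)


class TestSmartBoundary:
    def test_collapses_to_single_mar_at_baseline(self, hf_model, nyha_transitions):
        for tr in nyha_transitions:
            delta = sm.benefit_delta(hf_model, [tr])
            for focal, other in ((DEATH, BLEED), (BLEED, DEATH)):
                single = sm.compute_mar(hf_model.risk(focal), delta, 1.0)
                surf = sm.smart_boundary(hf_model, delta, focal, {other: [1.0]})
                p, censored, unreachable = surf.focal_at((1.0,))
                assert not unreachable
                assert censored == single.censored
                assert p == pytest.approx(single.absolute_p, abs=1e-9)

    def test_linear_boundary_is_a_line(self):
        model = hypothetical_model("constant")
        grid = {"AE2": np.arange(0.0, 10.0 + 1e-9, 0.5)}
        surf = sm.smart_boundary(model, sm.BenefitDelta(5.0), "AE1", grid)
        for (p2,), (p1, censored, unreachable) in surf.boundary.items():
            assert not censored and not unreachable
            assert p1 == pytest.approx(10.0 - p2, abs=1e-9)

    def test_conditioning_beyond_benefit_is_unreachable(self):
        model = hypothetical_model("constant")
        surf = sm.smart_boundary(model, sm.BenefitDelta(5.0), "AE1", {"AE2": [12.0]})
        p, _, unreachable = surf.focal_at((12.0,))
        assert unreachable and np.isnan(p)

    def test_zero_residual_touches_baseline(self):
        model = hypothetical_model("constant")
        surf = sm.smart_boundary(model, sm.BenefitDelta(5.0), "AE1", {"AE2": [10.0]})
        p, _, unreachable = surf.focal_at((10.0,))
        assert not unreachable and p == pytest.approx(0.0, abs=1e-12)

    def test_boundary_nonincreasing_in_conditioning_risk(self, hf_model):
        delta = sm.BenefitDelta(7.75)
        grid = {BLEED: np.arange(1.0, 10.0, 0.5)}
        surf = sm.smart_boundary(hf_model, delta, DEATH, grid)
        # bleeding is non-monotone below 2%, so check from 2% upward
        vals = [surf.focal_at((p,))[0] for p in np.arange(2.0, 10.0, 0.5)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_curvature_of_two_risk_boundary(self):
        # decreasing marginal disutility -> boundary convex toward the origin;
        # increasing -> concave (discrete second differences)
        # grids stop where the conditioning risk alone exhausts the benefit
        for shape, sign, pmax in (("decreasing", 1, 4.5), ("increasing", -1, 6.0)):
            model = hypothetical_model(shape)
            grid = np.arange(0.0, pmax + 1e-9, 0.25)
            surf = sm.smart_boundary(model, sm.BenefitDelta(5.0), "AE1", {"AE2": grid})
            ys = np.array([surf.focal_at((p,))[0] for p in grid])
            second = np.diff(ys, 2)
            assert np.all(sign * second >= -1e-9)

    def test_focal_in_grid_rejected(self, hf_model):
        with pytest.raises(sm.ValidationError):
            sm.smart_boundary(hf_model, sm.BenefitDelta(1.0), DEATH, {DEATH: [1.0]})

    def test_empty_grid_rejected(self, hf_model):
        with pytest.raises(sm.ValidationError):
            sm.smart_boundary(hf_model, sm.BenefitDelta(1.0), DEATH, {})

    def test_frame_export(self, hf_model):
        surf = sm.smart_boundary(
            hf_model, sm.BenefitDelta(7.75), DEATH, {BLEED: [1.0, 2.0, 4.0]}
        )
        df = surf.to_frame()
        assert set(df.columns) == {
            "benefit", "focal_risk", BLEED, "boundary_p", "censored", "unreachable"
        }
        assert len(df) == 3


class TestLinearSlope:
    def test_equal_mars_give_slope_minus_one(self):
        assert sm.linear_slope(10, 10) == -1.0

    def test_ratio(self):
        assert sm.linear_slope(4, 8) == -0.5

    def test_nonpositive_mar_rejected(self):
        with pytest.raises(sm.ContractError):
            sm.linear_slope(0, 8)

    def test_matches_finite_difference_of_linear_boundary(self):
        model = hypothetical_model("constant")
        d = sm.BenefitDelta(5.0)
        mar1 = sm.compute_mar(model.risk("AE1"), d, 0.0).incremental_mar
        mar2 = sm.compute_mar(model.risk("AE2"), d, 0.0).incremental_mar
        grid = np.arange(0.0, 10.0 + 1e-9, 0.5)
        surf = sm.smart_boundary(model, d, "AE1", {"AE2": grid})
        ys = np.array([surf.focal_at((p,))[0] for p in grid])
        fd = np.diff(ys) / np.diff(grid)
        assert np.allclose(fd, sm.linear_slope(mar1, mar2), atol=1e-6)


class TestBruteForceOracle:
    def test_linear_region_is_a_half_plane(self):
        model = hypothetical_model("constant")
        names, axes, acc = sm.brute_force_acceptance_region(model, sm.BenefitDelta(5.0), 0.5)
        p1, p2 = np.meshgrid(axes[0], axes[1], indexing="ij")
        expected = p1 + p2 <= 10.0 + 1e-9
        np.testing.assert_array_equal(acc, expected)

    def test_zero_benefit_keeps_only_baseline(self):
        model = hypothetical_model("constant")
        _, axes, acc = sm.brute_force_acceptance_region(model, sm.BenefitDelta(0.0), 0.5)
        assert acc.sum() == 1 and acc[0, 0]

    def test_benefit_above_total_importance_accepts_everything(self):
        model = hypothetical_model("constant")
        _, _, acc = sm.brute_force_acceptance_region(model, sm.BenefitDelta(15.0), 0.5)
        assert acc.all()

    def test_resource_guard(self):
        model = hypothetical_model("constant")
        with pytest.raises(sm.ValidationError):
            sm.brute_force_acceptance_region(
                model, sm.BenefitDelta(5.0), 1e-4, max_points=10_000
            )

    @pytest.mark.parametrize("seed,n_risks", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_boundary_separates_region(self, seed, n_risks):
        model = fx.random_model(seed, n_risks=n_risks, curvature=(seed % 3 - 1) * 0.6)
        delta = sm.benefit_delta(model, [("outcome", "worse", "better")])
        names, axes, acc = sm.brute_force_acceptance_region(model, delta, 0.5)
        grid = {n: axes[i] for i, n in enumerate(names) if i != 0}
        surf = sm.smart_boundary(model, delta, names[0], grid)
        implied = classify_against_boundary(surf, names, axes, focal_axis=0)
        np.testing.assert_array_equal(acc, implied)
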