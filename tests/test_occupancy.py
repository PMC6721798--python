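"""Tests of the three-state occupancy model and the exclusivity test."""

import numpy as np
import pydantic
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftlrep import occupancy as occ


def draw_params(rng: np.random.Generator, with_x3: bool = True) -> occ.OccupancyParams:
    """Random parameter set satisfying all model constraints."""
    x = rng.dirichlet([1.0, 1.0, 1.0])
    a = rng.uniform(0, 1)
    b = rng.uniform(0, 1 - a)
    return occ.OccupancyParams(
        x1=x[0], x2=x[1], x3=x[2] if with_x3 else None,
        y1=rng.uniform(0, 1), y2=rng.uniform(0, 1), alpha=a, beta=b,
    )


unit = st.floats(0.0, 1.0, allow_nan=False)


class TestPredictions:
    def test_no_repression_makes_all_constructs_identical(self, rng):
        for _ in range(20):
            x = rng.dirichlet([1, 1, 1])
            p = occ.OccupancyParams(x1=x[0], x2=x[1], x3=x[2], y1=1, y2=1)
            raw = occ.predict_raw(p)
            assert np.allclose(raw, x.sum())
            assert np.allclose(occ.predict_reduced(p), 1.0)

    def test_full_repression_of_bound_fractions(self):
        p = occ.OccupancyParams(x1=0.4, x2=0.4, x3=0.2, y1=0, y2=0)
        raw = occ.predict_raw(p)
        assert raw.ftl == pytest.approx(0.2)
        assert raw.double == pytest.approx(1.0)

    def test_reduced_double_direct_arithmetic(self):
        p = occ.OccupancyParams(x1=0.3, x2=0.3, y1=0, y2=0)
        assert occ.predict_reduced(p).double == pytest.approx(1.6)

    def test_raw_matches_independent_retyped_equations(self, rng):
        """Duplicate-implementation oracle for the four raw outputs."""
        for _ in range(200):
            p = draw_params(rng)
            x1, x2, x3, y1, y2, a, b = p.x1, p.x2, p.x3, p.y1, p.y2, p.alpha, p.beta
            expected = (
                y1 * x1 + y2 * x2 + x3,
                y1 * (x1 + a) + x2 - a + x3,
                x1 - b + y2 * (x2 + b) + x3,
                x1 + x2 + x3,
            )
            assert np.allclose(occ.predict_raw(p), expected, atol=1e-12, rtol=0)

    def test_reduced_agrees_with_raw_after_x3_elimination(self, rng):
        """Algebraic-identity oracle: substitute x3 = 1 - y1 x1 - y2 x2."""
        checked = 0
        while checked < 1000:
            p = draw_params(rng, with_x3=False)
            x3 = 1.0 - p.y1 * p.x1 - p.y2 * p.x2
            if x3 < 0:
                continue
            full = occ.OccupancyParams(
                x1=p.x1, x2=p.x2, x3=None, y1=p.y1, y2=p.y2,
                alpha=p.alpha, beta=p.beta,
            )
            raw = (
                p.y1 * (p.x1 + p.alpha) + p.x2 - p.alpha + x3,
                p.x1 - p.beta + p.y2 * (p.x2 + p.beta) + x3,
                p.x1 + p.x2 + x3,
            )
            assert np.allclose(occ.predict_reduced(full), raw, atol=1e-12, rtol=0)
            checked += 1

    def test_raw_requires_explicit_free_fraction(self):
        p = occ.OccupancyParams(x1=0.3, x2=0.3, y1=0.5, y2=0.5)
        with pytest.raises(occ.ConstraintError, match="x3"):
            occ.predict_raw(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(x1=-0.1, x2=0.5, x3=0.6, y1=0.5, y2=0.5),
            dict(x1=0.2, x2=0.3, x3=0.5, y1=1.5, y2=0.5),
            dict(x1=0.2, x2=0.3, x3=0.5, y1=0.5, y2=0.5, alpha=0.7, beta=0.7),
            dict(x1=0.5, x2=0.5, x3=0.5, y1=0.5, y2=0.5),  # simplex violation
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(pydantic.ValidationError):
            occ.OccupancyParams(**kwargs)


class TestBracketTerm:
    def test_no_redistribution_gives_minus_one(self):
        assert occ.bracket_term(0.3, 0.9, 0.0, 0.0) == -1.0

    def test_full_redistribution_fully_repressed_gives_zero(self):
        assert occ.bracket_term(0.0, 0.0, 0.4, 0.6) == 0.0

    def test_extrema_over_constraint_grid(self):
        """Brute-force extrema over a 20^4 grid are exactly -1 and 0."""
        g = np.linspace(0.0, 1.0, 20)
        y1, y2, a, b = np.meshgrid(g, g, g, g, indexing="ij")
        mask = a + b <= 1.0
        vals = (a + b - y1 * a - y2 * b - 1.0)[mask]
        assert abs(vals.min() - (-1.0)) <= 1e-12
        assert abs(vals.max() - 0.0) <= 1e-12

    @given(y1=unit, y2=unit, a=unit, frac=unit)
    @settings(max_examples=200, deadline=None)
    def test_identity_with_reduced_predictions(self, y1, y2, a, frac):
        """double - loop - d3re equals the bracket term, exactly."""
        b = (1.0 - a) * frac
        p = occ.OccupancyParams(x1=0.4, x2=0.3, y1=y1, y2=y2, alpha=a, beta=b)
        red = occ.predict_reduced(p)
        lhs = red.double - red.loop - red.d3re
        assert lhs == pytest.approx(occ.bracket_term(y1, y2, a, b), abs=1e-12)

    def test_constraint_violations_named(self):
        with pytest.raises(occ.ConstraintError, match="alpha \\+ beta"):
            occ.bracket_term(0.5, 0.5, 0.6, 0.6)
        with pytest.raises(occ.ConstraintError, match="y1"):
            occ.bracket_term(1.2, 0.5, 0.1, 0.1)


class TestRhsBounds:
    def test_printed_means_give_upper_bound(self):
        lower, upper = occ.rhs_bounds(12.5, 4.4)
        assert upper == pytest.approx(16.9)
        assert lower == pytest.approx(15.9)

    def test_unit_means(self):
        assert occ.rhs_bounds(1.0, 1.0) == pytest.approx((1.0, 2.0))

    def test_bounds_differ_by_bracket_range(self):
        lower, upper = occ.rhs_bounds(3.7, 2.2)
        assert upper - lower == pytest.approx(1.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(occ.ConstraintError):
            occ.rhs_bounds(0.0, 4.4)


class TestExclusivityTest:
    def test_published_readouts_are_inconsistent(self, paper_readouts):
        v = occ.test_exclusivity(paper_readouts)
        assert v.rhs_upper == pytest.approx(16.9)
        assert not v.point_consistent
        assert v.p_consistent < 0.001
        assert v.inconsistent

    def test_z_score_matches_gaussian_propagation(self, paper_readouts):
        v = occ.test_exclusivity(paper_readouts, n_draws=1000)
        expected = (41.8 - 12.5 - 4.4) / np.sqrt(6.5**2 + 2.9**2 + 0.4**2)
        assert v.z_score == pytest.approx(expected)
        assert expected == pytest.approx(3.49, abs=0.01)

    def test_inside_feasible_band_is_consistent(self):
        ro = occ.ConstructReadouts.from_means(
            {"D3RE": (4.0, 0.01, 3), "LOOP": (12.0, 0.01, 3),
             "DOUBLE": (15.5, 0.01, 3)}
        )
        v = occ.test_exclusivity(ro, n_draws=10_000)
        assert v.point_consistent
        assert v.p_consistent > 0.99

    def test_reproducible_for_fixed_seed(self, paper_readouts):
        v1 = occ.test_exclusivity(paper_readouts, n_draws=20_000, seed=42)
        v2 = occ.test_exclusivity(paper_readouts, n_draws=20_000, seed=42)
        assert v1 == v2

    def test_p_consistent_nonincreasing_in_double_mean(self):
        ps = []
        for double_mean in (10.0, 14.0, 17.0, 22.0, 30.0):
            ro = occ.ConstructReadouts.from_means(
                {"D3RE": (4.4, 0.4, 6), "LOOP": (12.5, 2.9, 6),
                 "DOUBLE": (double_mean, 3.0, 6)}
            )
            ps.append(occ.test_exclusivity(ro, n_draws=50_000, seed=5).p_consistent)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_missing_construct_named_in_error(self):
        ro = occ.ConstructReadouts.from_means({"D3RE": (4.4, 0.4, 6)})
        with pytest.raises(occ.ConstraintError, match="LOOP"):
            occ.test_exclusivity(ro)

    def test_low_draw_count_warns_but_computes(self, paper_readouts, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ftlrep.occupancy"):
            v = occ.test_exclusivity(paper_readouts, n_draws=500)
        assert 0.0 <= v.p_consistent <= 1.0
        assert any("n_draws" in r.message for r in caplog.records)


class TestFitExclusive:
    def test_recovers_noise_free_synthetic_readouts(self, rng):
        """Predicted outputs (not parameters) are the identifiable contract."""
        p = draw_params(rng, with_x3=False)
        red = occ.predict_reduced(p)
        ro = occ.ConstructReadouts.from_means(
            {"D3RE": (red.d3re, 0.01, 3), "LOOP": (red.loop, 0.01, 3),
             "DOUBLE": (red.double, 0.01, 3)}
        )
        rep = occ.fit_exclusive(ro)
        assert rep.feasible
        assert rep.chi_square < 1e-6
        assert np.allclose(rep.predicted, red, atol=1e-6)

    def test_published_readouts_infeasible(self, paper_readouts):
        rep = occ.fit_exclusive(paper_readouts)
        assert not rep.feasible
        # the best feasible Double prediction stays below the measured 41.8
        assert rep.predicted.double < 41.8

    def test_unit_readouts_feasible_via_unrepressed_solution(self):
        ro = occ.ConstructReadouts.from_means(
            {"D3RE": (1.0, 0.01, 3), "LOOP": (1.0, 0.01, 3), "DOUBLE": (1.0, 0.01, 3)}
        )
        rep = occ.fit_exclusive(ro)
        assert rep.feasible
        assert rep.chi_square < 1e-6


class TestReadoutContainers:
    def test_canonical_names_accept_greek_and_case(self):
        assert occ.canonical_construct("Δ3RE") == "D3RE"
        assert occ.canonical_construct("∆PAR") == "DPAR"
        assert occ.canonical_construct("double") == "DOUBLE"
        assert occ.canonical_construct("wt") == "FTL"

    def test_unknown_construct_rejected(self):
        with pytest.raises(occ.ConstraintError, match="unknown construct"):
            occ.canonical_construct("FTH1")

    def test_invalid_readout_rejected(self):
        with pytest.raises(occ.ConstraintError):
            occ.Readout(mean=-1.0, sd=0.1)
        with pytest.raises(occ.ConstraintError):
            occ.Readout(mean=1.0, sd=-0.1)
        with pytest.raises(occ.ConstraintError):
            occ.Readout(mean=1.0, sd=0.1, n=0)

    def test_pooled_sd_reproduces_printed_combined_uncertainty(self):
        assert round(occ.pooled_sd(2.9, 0.4), 1) == 2.9
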