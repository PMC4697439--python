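"""Unit and property tests for the composite-bundle buckling model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanobridge import mechanics as mech
from nanobridge.exceptions import InvalidInputError, ZeroCapacityError
from nanobridge.mechanics import (
    ACTIN,
    TUBULIN,
    BundleSpec,
    FilamentClass,
    ModelConstants,
    ProjectionGeometry,
)


class TestBundleRigidity:
    def test_single_actin_filament_identity(self):
        # B = k_B T * L_p for one filament
        b = mech.bundle_rigidity(BundleSpec(1, 0))
        assert b == pytest.approx(4.28 * 17_700.0)

    def test_mixed_bundle_hand_sum(self):
        # 4.28 * (10*17,700 + 1*5,200,000) = 23,013,560 pN nm^2
        b = mech.bundle_rigidity(BundleSpec(10, 1))
        assert b == pytest.approx(2.301356e7, rel=1e-9)

    def test_doubling_counts_doubles_rigidity(self):
        b1 = mech.bundle_rigidity(BundleSpec(7, 3))
        b2 = mech.bundle_rigidity(BundleSpec(14, 6))
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    def test_empty_bundle_rejected(self):
        with pytest.raises(InvalidInputError):
            mech.bundle_rigidity(BundleSpec(0, 0))

    def test_crosslinked_coupling_exponent(self):
        # kappa = 2 scales a pure bundle by N^2 instead of N
        b = mech.bundle_rigidity(BundleSpec(10, 0), coupling_exponent=2.0)
        assert b == pytest.approx(100 * 4.28 * 17_700.0)


class TestBucklingForce:
    def test_single_actin_at_10um(self):
        f = mech.buckling_force(BundleSpec(1, 0), ProjectionGeometry(10_000.0, 290.0))
        assert f == pytest.approx((math.pi**2 / 4) * 75_756.0 / 1e8, rel=1e-12)
        assert f == pytest.approx(1.869e-3, rel=1e-3)

    def test_inverse_square_length_scaling(self):
        f1 = mech.buckling_force(BundleSpec(3, 1), ProjectionGeometry(5_000.0, 290.0))
        f2 = mech.buckling_force(BundleSpec(3, 1), ProjectionGeometry(10_000.0, 290.0))
        assert f1 == pytest.approx(4 * f2, rel=1e-12)

    def test_linearity_in_filament_count(self):
        f1 = mech.buckling_force(BundleSpec(1, 0), ProjectionGeometry(10_000.0, 290.0))
        f100 = mech.buckling_force(BundleSpec(100, 0), ProjectionGeometry(10_000.0, 290.0))
        assert f100 == pytest.approx(100 * f1, rel=1e-12)
        assert f100 == pytest.approx(0.1869, rel=1e-3)

    def test_zero_length_diverges(self):
        with pytest.raises(InvalidInputError):
            mech.buckling_force(BundleSpec(1, 0), ProjectionGeometry(0.0, 290.0))


class TestBucklingLength:
    def test_round_trip_with_force(self):
        geom = ProjectionGeometry(10_000.0, 290.0)
        f = mech.buckling_force(BundleSpec(1, 0), geom)
        c = ModelConstants(load_force=f)
        assert mech.buckling_length(BundleSpec(1, 0), constants=c) == pytest.approx(
            10_000.0, rel=1e-9
        )

    def test_sqrt_load_scaling(self):
        c1 = ModelConstants(load_force=10.0)
        c4 = ModelConstants(load_force=40.0)
        l1 = mech.buckling_length(BundleSpec(5, 1), constants=c1)
        l4 = mech.buckling_length(BundleSpec(5, 1), constants=c4)
        assert l1 == pytest.approx(2 * l4, rel=1e-12)

    def test_actin_bundle_filling_observed_width_falls_short(self):
        # 1,556 actin filaments fill a 290-nm sheath but buckle at ~5.4 um,
        # far below the observed 30.69-um mean bridge length
        bundle = mech.max_filaments_for_diameter(290.0, 0.0)
        lmax = mech.buckling_length(bundle)
        assert lmax == pytest.approx(5.39e3, rel=5e-3)
        assert lmax < 30_690.0

    def test_nonpositive_load_rejected(self):
        with pytest.raises(InvalidInputError):
            ModelConstants(load_force=0.0)


class TestMinDiameter:
    def test_nineteen_actin(self):
        d = mech.min_diameter(BundleSpec(19, 0))
        assert d == pytest.approx(2 * math.sqrt(19 * 12.25 / mech.HEX_PACKING), rel=1e-12)
        assert d == pytest.approx(32.0, abs=0.1)

    def test_observed_width_bundle(self):
        assert mech.min_diameter(BundleSpec(1556, 0)) == pytest.approx(290.0, rel=1e-3)

    def test_tubulin_substitution_area_penalty(self):
        # swapping one actin for one tubulin adds (q-1) * r_a^2 = 15 * r_a^2
        phi = mech.HEX_PACKING
        a0 = phi * (mech.min_diameter(BundleSpec(10, 0)) / 2) ** 2
        a1 = phi * (mech.min_diameter(BundleSpec(9, 1)) / 2) ** 2
        assert a1 - a0 == pytest.approx(15 * 3.5**2, rel=1e-9)


class TestMaxFilamentsForDiameter:
    def test_actin_capacity_at_observed_width(self):
        b = mech.max_filaments_for_diameter(290.0, 0.0)
        assert b == BundleSpec(1556, 0)

    def test_zero_capacity_below_single_filament(self):
        d_single = 2 * ACTIN.radius / math.sqrt(mech.HEX_PACKING)
        with pytest.raises(ZeroCapacityError):
            mech.max_filaments_for_diameter(d_single * 0.999, 0.0)

    def test_packing_round_trip_on_grid(self):
        for d in np.linspace(10.0, 600.0, 40):
            for f in (0.0, 0.066, 0.3, 1.0):
                try:
                    b = mech.max_filaments_for_diameter(d, f)
                except ZeroCapacityError:
                    continue
                assert mech.min_diameter(b) <= d * (1 + 1e-9)
                if f == 0.0:  # maximality: one more actin filament must overflow
                    assert mech.min_diameter(BundleSpec(b.n_actin + 1, 0)) > d

    def test_composition_tie_rounds_to_fewer_microtubules(self):
        # N=2 at f=0.25 -> n_t = round-half-down(0.5) = 0
        b = mech.max_filaments_for_diameter(9.0, 0.25)
        if b.total == 2:
            assert b.n_tubulin == 0


class TestFeasibilityCurve:
    def test_monotone_and_contains_observed_point(self):
        grid = np.concatenate([np.linspace(10, 280, 20), [290.0], np.linspace(300, 600, 10)])
        curve = mech.feasibility_curve(0.0, grid)
        lengths = curve.points["max_length_nm"].to_numpy()
        assert np.all(np.diff(lengths) >= -1e-9)
        at_290 = curve.points.loc[curve.points["min_diameter_nm"] == 290.0, "max_length_nm"]
        assert float(at_290.iloc[0]) == pytest.approx(5.39e3, rel=5e-3)

    def test_single_filament_diameter(self):
        d = mech.min_diameter(BundleSpec(1, 0)) * 1.001
        curve = mech.feasibility_curve(0.0, [d])
        expected = mech.buckling_length(BundleSpec(1, 0))
        assert curve.points["max_length_nm"].iloc[0] == pytest.approx(expected)

    def test_tubulin_lifts_curve_at_observed_width(self):
        actin_only = mech.feasibility_curve(0.0, [290.0]).points["max_length_nm"].iloc[0]
        composite = mech.feasibility_curve(0.066, [290.0]).points["max_length_nm"].iloc[0]
        assert composite > actin_only

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            mech.feasibility_curve(0.0, [])


class TestClassifyFeasibility:
    @pytest.mark.parametrize(
        "length,diameter,composition,expected",
        [
            (30_690.0, 290.0, 0.0, "infeasible"),  # observed mean geometry, actin-only
            (0.0, 290.0, 0.0, "feasible"),
            (5_000.0, 290.0, 0.0, "feasible"),  # below the ~5.39-um actin-only limit
        ],
    )
    def test_rule(self, length, diameter, composition, expected):
        geom = ProjectionGeometry(length, diameter)
        assert mech.classify_feasibility(geom, composition) == expected


class TestOptimalTubulinFraction:
    def test_stiff_microtubule_regime_matches_printed_optimum(self):
        res = mech.optimal_tubulin_fraction(3_000.0, 16.0)
        assert res.interior
        assert res.fraction == pytest.approx(0.0660, abs=5e-5)

    def test_default_persistence_length_ratio(self):
        # rho = 5.2 mm / 17.7 um ~ 294
        rho = TUBULIN.persistence_length / ACTIN.persistence_length
        res = mech.optimal_tubulin_fraction(rho, 16.0)
        assert res.fraction == pytest.approx(1 / 15 - 2 / (rho - 1), rel=1e-12)
        assert res.fraction == pytest.approx(0.0598, abs=2e-4)

    def test_infinitely_stiff_limit(self):
        res = mech.optimal_tubulin_fraction(1e12, 16.0)
        assert res.fraction == pytest.approx(1 / 15, rel=1e-6)

    def test_numeric_maximization_agrees_with_closed_form(self):
        for rho, q in [(3_000.0, 16.0), (294.0, 16.0), (50.0, 9.0)]:
            closed = mech.optimal_tubulin_fraction(rho, q)
            numeric = mech.optimal_tubulin_fraction(rho, q, numeric=True)
            assert numeric.fraction == pytest.approx(closed.fraction, abs=1e-6)

    def test_no_interior_optimum_flag(self):
        res = mech.optimal_tubulin_fraction(25.0, 16.0)  # rho <= 2q - 1
        assert res.fraction == 0.0
        assert not res.interior

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            mech.optimal_tubulin_fraction(3_000.0, 1.5)  # q - 1 < 1
        with pytest.raises(InvalidInputError):
            mech.optimal_tubulin_fraction(10.0, 16.0)  # rho <= q - 1


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

bundles = st.tuples(st.integers(0, 500), st.integers(0, 50)).filter(lambda t: sum(t) >= 1)


@given(bundle=bundles, length=st.floats(10.0, 1e6))
@settings(max_examples=100, deadline=None)
def test_force_length_rigidity_identity(bundle, length):
    """F_b * L^2 / B equals the boundary prefactor for every bundle and length."""
    b = BundleSpec(*bundle)
    B = mech.bundle_rigidity(b)
    f = mech.buckling_force(b, ProjectionGeometry(length, 290.0))
    assert f * length**2 / B == pytest.approx(mech.CLAMPED_FREE, rel=1e-12)


@given(bundle=bundles, length=st.floats(10.0, 1e6))
@settings(max_examples=100, deadline=None)
def test_buckling_round_trip(bundle, length):
    """buckling_length inverts buckling_force to 1e-9 relative."""
    b = BundleSpec(*bundle)
    f = mech.buckling_force(b, ProjectionGeometry(length, 290.0))
    c = ModelConstants(load_force=f)
    assert mech.buckling_length(b, constants=c) == pytest.approx(length, rel=1e-9)


@given(b1=bundles, b2=bundles)
@settings(max_examples=100, deadline=None)
def test_rigidity_additivity(b1, b2):
    """Rigidity of a merged bundle is the sum of the parts."""
    merged = BundleSpec(b1[0] + b2[0], b1[1] + b2[1])
    total = mech.bundle_rigidity(BundleSpec(*b1)) + mech.bundle_rigidity(BundleSpec(*b2))
    assert mech.bundle_rigidity(merged) == pytest.approx(total, rel=1e-12)


@given(
    rho=st.floats(35.0, 1e5),
    q=st.floats(4.0, 17.0),
)
@settings(max_examples=20, deadline=None)
def test_closed_form_optimum_matches_grid_search(rho, q):
    """Closed-form f* agrees with brute-force maximization of P(f)."""
    if rho <= 2 * q - 1:
        return
    grid = np.arange(0.0, 0.5, 1e-5)
    best = grid[np.argmax(mech.performance_metric(grid, rho, q))]
    res = mech.optimal_tubulin_fraction(rho, q)
    assert res.fraction == pytest.approx(best, abs=2e-5)


def test_unit_homogeneity_nm_vs_um():
    """Dimensionless outputs are unchanged when all lengths are in um."""
    factor = 1e-3  # nm -> um
    actin_um = FilamentClass("actin", ACTIN.radius * factor, ACTIN.persistence_length * factor)
    tub_um = FilamentClass("tubulin", TUBULIN.radius * factor, TUBULIN.persistence_length * factor)
    const_um = mech.rescale_constants(mech.DEFAULT_CONSTANTS, factor)
    for length, diameter in [(30_690.0, 290.0), (5_000.0, 290.0), (2_000.0, 100.0)]:
        nm = mech.classify_feasibility(ProjectionGeometry(length, diameter), 0.066)
        um = mech.classify_feasibility(
            ProjectionGeometry(length * factor, diameter * factor),
            0.066,
            actin_um,
            tub_um,
            const_um,
        )
        assert nm == um
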