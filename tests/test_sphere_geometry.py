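"""Square-root-transform geometry: closed forms, sphere maps, Karcher mean."""

import numpy as np
import pytest

from retdens import (
    DensityFunction,
    SRTFunction,
    TangentVector,
    exp_map,
    geodesic_distance,
    inverse_srt,
    karcher_mean,
    karcher_variance,
    l2_inner,
    l2_norm,
    log_map,
    srt,
    trapezoid_weights,
    unit_grid,
)
from conftest import make_random_density, make_random_srt

M = 512


def uniform_srt(m: int = M) -> SRTFunction:
    g = unit_grid(m)
    return srt(DensityFunction(g, np.ones(m)))


def linear_srt(m: int = M, increasing: bool = True) -> SRTFunction:
    g = unit_grid(m)
    f = 2 * g if increasing else 2 * (1 - g)
    return srt(DensityFunction(g, f))


class TestSRT:
    def test_uniform_density_maps_to_constant_one(self):
        h = uniform_srt()
        assert np.allclose(h.values, 1.0)
        assert abs(l2_norm(h) - 1.0) < 1e-12

    def test_linear_density_maps_to_sqrt(self, grid512):
        h = linear_srt()
        assert np.allclose(h.values, np.sqrt(2 * grid512))

    def test_round_trip_identity_on_random_densities(self, rng):
        for _ in range(5):
            f = make_random_density(rng)
            back = inverse_srt(srt(f))
            np.testing.assert_allclose(back.values, f.values, atol=1e-14)

    def test_negative_density_rejected(self, grid512):
        f = DensityFunction(grid512, np.ones(M))
        f.values[3] = -0.5  # corrupt after validation
        with pytest.raises(ValueError):
            srt(f)


class TestInnerProduct:
    def test_constant_functions(self):
        assert abs(l2_inner(np.ones(M), np.ones(M)) - 1.0) < 1e-12

    def test_sqrt_linear_against_closed_form(self):
        # integral of sqrt(2x) over [0,1] = 2*sqrt(2)/3
        h = linear_srt()
        got = l2_inner(h, uniform_srt())
        assert abs(got - 2 * np.sqrt(2) / 3) < 1e-4

    def test_nonnegativity_and_symmetry(self, rng):
        g1 = rng.normal(size=M)
        g2 = rng.normal(size=M)
        assert l2_inner(g1, g1) >= 0
        assert l2_inner(g1, g2) == pytest.approx(l2_inner(g2, g1), abs=0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_inner(np.ones(M), np.ones(M + 1))


class TestGeodesicDistance:
    def test_zero_for_identical(self, rng):
        h = make_random_srt(rng)
        assert geodesic_distance(h, h) == 0.0

    def test_uniform_vs_linear_closed_form(self):
        d = geodesic_distance(uniform_srt(), linear_srt())
        assert abs(d - np.arccos(2 * np.sqrt(2) / 3)) < 1e-4

    def test_opposed_linear_closed_form(self):
        # integral of sqrt(4x(1-x)) = pi/4; both SRTs vanish at a boundary so
        # the integrand has sqrt singularities and the trapezoid rule is
        # O(m^-3/2): endpoint error 2 * dx^{3/2}/3 through d(theta)/d(ip) =
        # 1.62 bounds the distance error by ~2e-4 at m = 512.
        d = geodesic_distance(linear_srt(increasing=True), linear_srt(increasing=False))
        assert abs(d - np.arccos(np.pi / 4)) < 2e-4

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(100):
            h1, h2, h3 = (make_random_srt(rng, m=128) for _ in range(3))
            d12 = geodesic_distance(h1, h2)
            d21 = geodesic_distance(h2, h1)
            assert d12 == pytest.approx(d21, abs=0)
            assert 0 <= d12 <= np.pi
            d13 = geodesic_distance(h1, h3)
            d23 = geodesic_distance(h2, h3)
            assert d13 <= d12 + d23 + 1e-8

    def test_non_unit_input_rejected(self, grid512):
        bad = SRTFunction(grid512, np.ones(M))
        bad.values = bad.values * 1.01  # corrupt after validation
        with pytest.raises(ValueError):
            geodesic_distance(bad, uniform_srt())


class TestExpLogMaps:
    def test_exp_of_zero_vector_is_identity(self, rng):
        h = make_random_srt(rng)
        v = TangentVector(h, np.zeros(M))
        assert np.array_equal(exp_map(h, v).values, h.values)

    def test_exp_moves_by_tangent_norm(self, rng):
        for _ in range(10):
            h = make_random_srt(rng)
            raw = make_random_srt(rng).values - h.values
            wq = trapezoid_weights(M)
            raw -= h.values * np.sum(wq * h.values * raw)  # project to tangent
            raw *= 0.3 / np.sqrt(np.sum(wq * raw**2))
            v = TangentVector(h, raw)
            assert geodesic_distance(h, exp_map(h, v)) == pytest.approx(0.3, abs=1e-6)

    def test_exp_closed_form_on_hand_vector(self, grid512):
        h = uniform_srt()
        vals = np.sqrt(12) * 0.1 * (grid512 - 0.5)
        v = TangentVector(h, vals)
        assert v.norm == pytest.approx(0.1, abs=1e-6)
        out = exp_map(h, v)
        expected = np.cos(v.norm) + np.sin(v.norm) * vals / v.norm
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_log_of_self_is_zero(self, rng):
        h = make_random_srt(rng)
        assert log_map(h, h).norm == 0.0

    def test_exp_log_mutual_inverse(self, rng):
        for _ in range(20):
            h1 = make_random_srt(rng)
            h2 = make_random_srt(rng)
            v = log_map(h1, h2)
            assert v.norm == pytest.approx(geodesic_distance(h1, h2), abs=1e-8)
            back = exp_map(h1, v)
            assert np.max(np.abs(back.values - h2.values)) < 1e-6

    def test_log_orthogonal_to_base(self, rng):
        h1, h2 = make_random_srt(rng), make_random_srt(rng)
        v = log_map(h1, h2)
        assert abs(l2_inner(h1, v.values)) < 1e-8

    def test_base_mismatch_rejected(self, rng):
        h1, h2 = make_random_srt(rng), make_random_srt(rng)
        v = log_map(h1, h2)
        with pytest.raises(ValueError):
            exp_map(h2, v)


class TestKarcherMean:
    def test_identical_inputs_converge_immediately(self, rng):
        h = make_random_srt(rng)
        res = karcher_mean([h] * 5)
        assert res.converged and res.iterations == 1
        np.testing.assert_allclose(res.mean.values, h.values, atol=1e-12)
        assert res.variance == pytest.approx(0.0, abs=1e-12)

    def test_two_point_mean_is_geodesic_midpoint(self, rng):
        for _ in range(5):
            h1, h2 = make_random_srt(rng), make_random_srt(rng)
            theta = geodesic_distance(h1, h2)
            res = karcher_mean([h1, h2])
            assert geodesic_distance(res.mean, h1) == pytest.approx(theta / 2, abs=1e-6)
            assert geodesic_distance(res.mean, h2) == pytest.approx(theta / 2, abs=1e-6)

    def test_mean_is_fixed_point(self, rng):
        hs = [make_random_srt(rng) for _ in range(6)]
        res = karcher_mean(hs)
        assert res.converged
        rerun = karcher_mean([res.mean] + hs)  # noqa: F841 sanity only
        again = karcher_mean(hs)
        assert again.iterations >= 1
        # restarting from the converged mean: first gradient already < tol
        from retdens.sphere_geometry import _karcher_stack, _stack_srts

        grid, H = _stack_srts(hs)
        wq = trapezoid_weights(grid.size)
        mu = res.mean.values[None, :]
        dots = np.clip((mu * wq) @ H.T, -1, 1)
        theta = np.arccos(dots)
        coef = np.where(theta < 1e-9, 1.0, theta / np.sin(np.maximum(theta, 1e-9)))
        W = np.full((1, len(hs)), 1 / len(hs))
        WC = W * coef
        vbar = WC @ H - (WC * dots).sum(1, keepdims=True) * mu
        assert np.sqrt(((vbar**2) * wq).sum()) < 1e-6

    def test_variance_definition_and_minimizer_property(self, rng):
        hs = [make_random_srt(rng, m=128) for _ in range(8)]
        res = karcher_mean(hs)
        assert res.variance == pytest.approx(
            sum(geodesic_distance(res.mean, h) ** 2 for h in hs), abs=1e-12
        )
        # no sample point beats the Karcher mean as a center
        for h in hs:
            assert res.variance <= karcher_variance(h, hs) + 1e-10
        # and the extrinsic (normalized average) candidate does not either
        wq = trapezoid_weights(128)
        avg = np.mean([h.values for h in hs], axis=0)
        avg /= np.sqrt(np.sum(wq * avg**2))
        extrinsic = SRTFunction(hs[0].grid, avg)
        assert res.variance <= karcher_variance(extrinsic, hs) + 1e-10

    def test_two_point_variance_at_midpoint(self, rng):
        h1, h2 = make_random_srt(rng), make_random_srt(rng)
        theta = geodesic_distance(h1, h2)
        mid = karcher_mean([h1, h2]).mean
        assert karcher_variance(mid, [h1, h2]) == pytest.approx(theta**2 / 2, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            karcher_mean([])


class TestGridRefinement:
    def test_distance_stable_under_grid_doubling(self, rng):
        # quantities should agree to O(1/m^2) between m and 2m for smooth SRTs
        fine = np.random.default_rng(7)
        for _ in range(3):
            seed = int(fine.integers(2**31))
            h_a_c = make_random_srt(np.random.default_rng(seed), m=257)
            h_b_c = make_random_srt(np.random.default_rng(seed + 1), m=257)
            h_a_f = make_random_srt(np.random.default_rng(seed), m=513)
            h_b_f = make_random_srt(np.random.default_rng(seed + 1), m=513)
            d_c = geodesic_distance(h_a_c, h_b_c)
            d_f = geodesic_distance(h_a_f, h_b_f)
            assert abs(d_c - d_f) < 5e-4
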