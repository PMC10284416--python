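import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from levelseg import (
    EdgeMap,
    EvolveParams,
    LevelSet,
    ValidationError,
    area_energy,
    dirac_reg,
    evolve,
    evolve_step,
    extract_zero_contour,
    hausdorff,
    heaviside_reg,
    init_binary_step,
    length_energy,
    penalty_energy,
    reinitialize,
    signed_distance_disk,
    total_energy,
)

from .conftest import run_fixture_evolution


class TestEvolveParams:
    def test_defaults_valid(self):
        p = EvolveParams()
        assert p.mu * p.tau <= 0.25

    def test_stability_bound(self):
        with pytest.raises(ValidationError):
            EvolveParams(mu=0.1, tau=5.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu": 0.0},
            {"lambda_": -1.0},
            {"eps": 0.0},
            {"tau": -1.0},
            {"n_iter": -1},
            {"c0": 0.0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValidationError):
            EvolveParams(**kwargs)


class TestInitBinaryStep:
    def test_counts(self):
        mask = np.zeros((10, 10), bool)
        mask[3:7, 3:7] = True
        ls = init_binary_step((10, 10), mask, 2.0)
        assert (ls.phi == -2.0).sum() == 16
        assert (ls.phi == 2.0).sum() == 84

    def test_empty_and_full_rejected(self):
        with pytest.raises(ValidationError):
            init_binary_step((8, 8), np.zeros((8, 8), bool), 2.0)
        with pytest.raises(ValidationError):
            init_binary_step((8, 8), np.ones((8, 8), bool), 2.0)

    def test_contour_traces_mask_boundary(self):
        mask = np.zeros((32, 32), bool)
        mask[10:22, 8:26] = True
        ls = init_binary_step((32, 32), mask, 2.0)
        contours = extract_zero_contour(ls)
        assert len(contours) == 1
        edge = mask ^ ndi.binary_erosion(mask)
        edge_pts = np.argwhere(edge).astype(float)
        assert hausdorff(contours[0].points, edge_pts) <= 1.0


class TestSignedDistanceDisk:
    def test_plug_in_values(self):
        ls = signed_distance_disk((64, 64), (32, 32), 10.0)
        assert ls.phi[32, 32] == -10.0
        assert abs(ls.phi[32, 52] - 10.0) < 1e-12  # distance 2R from centre

    def test_penalty_small_away_from_centre(self):
        ls = signed_distance_disk((64, 64), (32, 32), 10.0)
        phi = ls.phi.copy()
        gy, gx = np.gradient(phi)
        dev = 0.5 * (np.hypot(gy, gx) - 1.0) ** 2
        rows = np.arange(64)[:, None]
        cols = np.arange(64)[None, :]
        keep = np.hypot(rows - 32, cols - 32) > 2.0
        keep[0, :] = keep[-1, :] = keep[:, 0] = keep[:, -1] = False
        assert dev[keep].max() < 1e-3

    def test_invalid_radius(self):
        with pytest.raises(ValidationError):
            signed_distance_disk((16, 16), (8, 8), 0.0)


class TestDiracHeaviside:
    def test_dirac_at_zero(self):
        assert abs(dirac_reg(np.array([[0.0]]), 1.5)[0, 0] - 2.0 / 3.0) < 1e-12

    def test_dirac_support_edge(self):
        vals = dirac_reg(np.array([[1.5, -1.5, 2.0]]), 1.5)
        np.testing.assert_allclose(vals, 0.0, atol=1e-15)

    def test_dirac_integrates_to_one(self):
        eps = 1.5
        x = np.arange(-2 * eps, 2 * eps + 0.005, 0.01)
        y = dirac_reg(x[None, :], eps)[0]
        assert abs(np.trapezoid(y, x) - 1.0) < 1e-6

    def test_dirac_nonnegative(self):
        x = np.linspace(-5, 5, 401)[None, :]
        assert dirac_reg(x, 1.5).min() >= 0.0

    def test_heaviside_half_at_zero(self):
        assert heaviside_reg(np.array([[0.0]]), 1.5)[0, 0] == 0.5

    def test_heaviside_saturation(self):
        vals = heaviside_reg(np.array([[-15.0, 15.0]]), 1.5)[0]
        assert vals[0] == 0.0
        assert vals[1] == 1.0

    def test_heaviside_derivative_matches_dirac(self):
        eps, x0, h = 1.5, 0.45, 1e-6  # x0 = 0.3 * eps
        d = (
            heaviside_reg(np.array([[x0 + h]]), eps)[0, 0]
            - heaviside_reg(np.array([[x0 - h]]), eps)[0, 0]
        ) / (2 * h)
        assert abs(d - dirac_reg(np.array([[x0]]), eps)[0, 0]) < 1e-6

    def test_eps_validation(self):
        with pytest.raises(ValidationError):
            dirac_reg(np.zeros((2, 2)), 0.0)
        with pytest.raises(ValidationError):
            heaviside_reg(np.zeros((2, 2)), -1.0)


class TestEnergies:
    def test_penalty_unit_plane_zero(self):
        rows = np.arange(20)[:, None] + np.zeros((20, 20))
        assert penalty_energy(rows - 5.0) < 1e-12

    def test_penalty_constant_closed_form(self):
        phi = np.full((16, 16), 3.0)
        assert abs(penalty_energy(phi) - 0.5 * phi.size) < 1e-12

    def test_penalty_sdf_small(self):
        ls = signed_distance_disk((128, 128), (64, 64), 20.0)
        assert penalty_energy(ls) / ls.phi.size < 1e-2

    def test_length_circle(self):
        ls = signed_distance_disk((128, 128), (64, 64), 20.0)
        ones = np.ones((128, 128))
        val = length_energy(ls, ones, eps=1.5)
        assert abs(val - 2 * math.pi * 20) / (2 * math.pi * 20) < 0.05

    def test_length_zero_gate(self):
        ls = signed_distance_disk((64, 64), (32, 32), 10.0)
        assert length_energy(ls, np.zeros((64, 64)), eps=1.5) == 0.0

    def test_length_empty_dirac_support(self):
        ls = signed_distance_disk((64, 64), (32, 32), 10.0)
        shifted = ls.phi + 15.0  # no zero set within the band
        assert length_energy(shifted, np.ones((64, 64)), eps=1.5) == 0.0

    def test_area_circle(self):
        ls = signed_distance_disk((128, 128), (64, 64), 20.0)
        val = area_energy(ls, np.ones((128, 128)), eps=1.5)
        expected = math.pi * 400
        assert abs(val - expected) / expected < 0.03

    def test_area_all_outside(self):
        phi = np.full((64, 64), 15.0)
        assert area_energy(phi, np.ones((64, 64)), eps=1.5) == 0.0

    def test_area_all_inside(self):
        phi = np.full((64, 64), -15.0)
        assert area_energy(phi, np.ones((64, 64)), eps=1.5) == 4096.0

    def test_shape_mismatch(self):
        ls = signed_distance_disk((16, 16), (8, 8), 4.0)
        with pytest.raises(ValidationError):
            length_energy(ls, np.ones((8, 8)), eps=1.5)
        with pytest.raises(ValidationError):
            area_energy(ls, np.ones((8, 8)), eps=1.5)

    def test_total_additivity_and_homogeneity(self):
        ls = signed_distance_disk((64, 64), (32, 32), 12.0)
        g = np.full((64, 64), 0.7)
        p = EvolveParams(mu=0.04, lambda_=5.0, nu=1.5, eps=1.5)
        total = total_energy(ls, g, p)
        parts = (
            p.mu * penalty_energy(ls)
            + p.lambda_ * length_energy(ls, g, p.eps)
            + p.nu * area_energy(ls, g, p.eps)
        )
        assert abs(total - parts) < 1e-12
        doubled = EvolveParams(mu=0.08, lambda_=10.0, nu=3.0, eps=1.5, tau=3.0)
        assert abs(total_energy(ls, g, doubled) - 2 * total) < 1e-9


def _oracle_evolve_step(phi, g, params):
    """Naive per-pixel stencil implementation of one evolution step."""
    h, w = phi.shape

    def at(f, i, j):  # replicate boundary
        return f[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]

    def grad(f, i, j):
        if 0 < i < h - 1:
            gy = (f[i + 1, j] - f[i - 1, j]) / 2.0
        elif i == 0:
            gy = f[1, j] - f[0, j]
        else:
            gy = f[h - 1, j] - f[h - 2, j]
        if 0 < j < w - 1:
            gx = (f[i, j + 1] - f[i, j - 1]) / 2.0
        elif j == 0:
            gx = f[i, 1] - f[i, 0]
        else:
            gx = f[i, w - 1] - f[i, w - 2]
        return gy, gx

    nx = np.zeros_like(phi)
    ny = np.zeros_like(phi)
    for i in range(h):
        for j in range(w):
            gy, gx = grad(phi, i, j)
            mag = math.sqrt(gx * gx + gy * gy + 1e-10)
            nx[i, j] = gx / mag
            ny[i, j] = gy / mag

    gnx = g * nx
    gny = g * ny
    out = np.zeros_like(phi)
    for i in range(h):
        for j in range(w):
            lap = (
                at(phi, i - 1, j)
                + at(phi, i + 1, j)
                + at(phi, i, j - 1)
                + at(phi, i, j + 1)
                - 4.0 * phi[i, j]
            )
            _, dnx = grad(nx, i, j)
            dny, _ = grad(ny, i, j)
            _, dgnx = grad(gnx, i, j)
            dgny, _ = grad(gny, i, j)
            x = phi[i, j]
            if abs(x) <= params.eps:
                dirac = (1.0 + math.cos(math.pi * x / params.eps)) / (
                    2.0 * params.eps
                )
            else:
                dirac = 0.0
            dphi = (
                params.mu * (lap - (dnx + dny))
                + params.lambda_ * dirac * (dgnx + dgny)
                + params.nu * g[i, j] * dirac
            )
            out[i, j] = x + params.tau * dphi
    return out


class TestEvolveStep:
    def test_flat_field_unchanged(self):
        phi = np.full((16, 16), 2.0)
        p = EvolveParams(lambda_=0.0, nu=0.0)
        out = evolve_step(phi, np.ones((16, 16)), p)
        assert np.abs(out.phi - phi).max() < 1e-12

    def test_plane_sdf_fixed_point(self):
        # exact unit-slope SDF: the penalty flow leaves it untouched
        rows = np.arange(24)[:, None] + np.zeros((24, 24))
        phi = rows - 11.5
        p = EvolveParams(lambda_=0.0, nu=0.0)
        out = evolve_step(phi, np.ones((24, 24)), p)
        interior = np.abs(out.phi - phi)[1:-1, 1:-1]
        assert interior.max() < 1e-3 * p.tau

    def test_disk_sdf_near_fixed_point(self):
        ls = signed_distance_disk((64, 64), (32, 32), 16.0)
        p = EvolveParams(lambda_=0.0, nu=0.0)
        out = evolve_step(ls, np.ones((64, 64)), p)
        delta = np.abs(out.phi - ls.phi)
        rows = np.arange(64)[:, None]
        cols = np.arange(64)[None, :]
        away = np.hypot(rows - 32, cols - 32) > 3.0
        away[0, :] = away[-1, :] = away[:, 0] = away[:, -1] = False
        assert delta[away].max() < 1e-3 * p.tau

    def test_matches_stencil_oracle(self, rng):
        phi = rng.normal(scale=2.0, size=(16, 16))
        g = rng.uniform(0.1, 1.0, size=(16, 16))
        p = EvolveParams(eps=1.5)
        fast = evolve_step(phi, g, p)
        slow = _oracle_evolve_step(phi, g, p)
        assert np.abs(fast.phi - slow).max() < 1e-10

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            evolve_step(np.zeros((8, 8)), np.ones((4, 4)), EvolveParams())


class TestEvolve:
    def test_zero_iterations(self):
        phi = np.where(np.zeros((16, 16), bool), -2.0, 2.0)
        phi[5:10, 5:10] = -2.0
        final, trace = evolve(phi, np.ones((16, 16)), EvolveParams(n_iter=0))
        np.testing.assert_array_equal(final.phi, phi)
        assert len(trace) == 0

    def test_trace_one_record_per_iteration(self, noisy_disk):
        noisy, _ = noisy_disk
        _, trace = run_fixture_evolution(
            noisy, "gaussian", EvolveParams(n_iter=10)
        )
        assert len(trace) == 10
        assert trace.iterations == list(range(1, 11))

    def test_snapshot_hook_fires(self, noisy_disk):
        noisy, _ = noisy_disk
        from levelseg import GaussianSpec, edge_indicator_gaussian

        g = edge_indicator_gaussian(noisy, GaussianSpec(1.5))
        mask = np.zeros(noisy.shape, bool)
        mask[14:-14, 14:-14] = True
        phi0 = init_binary_step(noisy.shape, mask, 2.0)
        seen = []
        evolve(
            phi0,
            g,
            EvolveParams(n_iter=12),
            snapshot_iters=(4, 8, 12),
            snapshot_hook=lambda it, ls: seen.append(it),
        )
        assert seen == [4, 8, 12]

    def test_energy_descent_on_fixture(self, evolved_gaussian):
        _, trace = evolved_gaussian
        total = np.asarray(trace.total)
        diffs = np.diff(total)
        tol = 1e-3 * np.abs(total[:-1])  # tiny regularization upticks
        assert np.mean(diffs <= tol) >= 0.95

    def test_band_stays_near_sdf_without_reinit(self, evolved_gaussian):
        final, trace = evolved_gaussian
        assert trace.sdf_deviation[-1] < 0.3

    def test_trace_csv_roundtrip(self, tmp_path, noisy_disk):
        noisy, _ = noisy_disk
        _, trace = run_fixture_evolution(
            noisy, "gaussian", EvolveParams(n_iter=5)
        )
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (5, 6)
        np.testing.assert_allclose(data[:, 4], trace.total)


class TestShrinkExpandSymmetry:
    def test_nu_sign_flips_area_motion(self):
        ones = np.ones((64, 64))
        base = signed_distance_disk((64, 64), (32, 32), 15.0)

        def signed_area_change(nu):
            p = EvolveParams(nu=nu, n_iter=20)
            final, _ = evolve(base, ones, p)
            return (final.phi < 0).sum() - (base.phi < 0).sum()

        shrink = signed_area_change(+1.5)
        expand = signed_area_change(-1.5)
        assert shrink < 0 < expand


class TestReinitialize:
    def test_plane_sdf_fixed_point(self):
        plane = np.arange(40)[None, :] - 10.5 + np.zeros((40, 40))
        out = reinitialize(plane, 10, 0.5)
        assert np.abs(out.phi - plane).max() < 1e-6

    def test_binary_step_converges_and_interface_static(self):
        mask = np.zeros((64, 64), bool)
        mask[20:44, 18:46] = True
        ls0 = init_binary_step((64, 64), mask, 2.0)
        out = reinitialize(ls0, 50, 0.5)
        gy, gx = np.gradient(out.phi)
        mag = np.hypot(gy, gx)
        edge = mask ^ ndi.binary_erosion(mask)
        band = ndi.binary_dilation(edge, iterations=2)
        frac = (np.abs(mag[~band] - 1.0) <= 0.1).mean()
        assert frac >= 0.9
        before = np.vstack([c.points for c in extract_zero_contour(ls0)])
        after = np.vstack([c.points for c in extract_zero_contour(out)])
        assert hausdorff(after, before) < 0.5

    def test_sign_zero_rows_stationary(self):
        phi = np.zeros((8, 8))
        phi[:, :4] = -1.0
        phi[:, 5:] = 1.0  # column 4 exactly zero
        out = reinitialize(phi, 5, 0.5)
        assert np.all(out.phi[:, 4] == 0.0)

    def test_dt_validation(self):
        with pytest.raises(ValidationError):
            reinitialize(np.ones((8, 8)), 5, dt=0.6)


class TestExtractZeroContour:
    def test_disk_radial_accuracy(self):
        ls = signed_distance_disk((128, 128), (64, 64), 20.0)
        contours = extract_zero_contour(ls)
        assert len(contours) == 1
        assert contours[0].closed
        radii = np.hypot(
            contours[0].points[:, 0] - 64, contours[0].points[:, 1] - 64
        )
        assert np.abs(radii - 20.0).max() < 0.2

    def test_single_signed_empty(self):
        assert extract_zero_contour(np.ones((16, 16))) == []

    def test_plane_exact_interpolation(self):
        cols = np.arange(32)[None, :] + np.zeros((16, 32))
        contours = extract_zero_contour(cols - 10.5)
        assert len(contours) == 1
        assert not contours[0].closed
        np.testing.assert_allclose(contours[0].points[:, 1], 10.5, atol=1e-9)

    def test_deterministic(self, rng):
        phi = rng.normal(size=(24, 24))
        a = extract_zero_contour(phi)
        b = extract_zero_contour(phi)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.points, cb.points)
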