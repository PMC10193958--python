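"""Hierarchical Hamiltonian dynamics, shooting, adjoints and matching."""

import numpy as np
import pytest

from varimap.geodesics import (
    HierMomenta,
    HierState,
    _dynamics,
    _dynamics_vjp,
    _pack,
    control_from_momenta,
    hamiltonian_energy,
    match,
    rkhs_energy,
    shoot,
    verify_momentum_integral,
)
from varimap.kernels import CumulativeKernel, VarifoldKernelSpec
from varimap.measures import Features, MultiscaleMeasure, ParticleMeasure, image_to_measure


@pytest.fixture
def rng():
    return np.random.default_rng(33)


def random_instance(rng, ns=(5, 5), d=2, pscale=0.25, wscale=0.15):
    q = HierState(
        [rng.uniform(0, 4, size=(n, d)) for n in ns],
        [rng.uniform(0.5, 2.0, n) for n in ns],
    )
    p = HierMomenta(
        [pscale * rng.standard_normal((n, d)) for n in ns],
        [wscale * rng.standard_normal(n) for n in ns],
    )
    return q, p


KERN2 = CumulativeKernel.from_fwhm([5.0, 2.0])


class TestControlField:
    def test_zero_momenta_give_zero_field(self, rng):
        q, _ = random_instance(rng)
        p = HierMomenta.zeros(q)
        u = control_from_momenta(q, p, KERN2, 0)
        np.testing.assert_array_equal(u(rng.normal(size=(7, 2))), 0.0)

    def test_single_particle_field_value_and_jacobian(self):
        q = HierState([np.array([[1.0, -0.5]])], [np.array([1.0])])
        p = HierMomenta([np.array([[0.4, 0.2]])], [np.array([0.0])])
        kern = CumulativeKernel.from_fwhm([3.0])
        u = control_from_momenta(q, p, kern, 0)
        np.testing.assert_allclose(u(q.positions[0])[0], [0.4, 0.2], atol=1e-14)
        np.testing.assert_allclose(u.jacobian(q.positions[0])[0], 0.0, atol=1e-14)

    def test_derivatives_match_finite_differences(self, rng):
        q, p = random_instance(rng)
        h = 1e-5
        eye = np.eye(2)
        for ell in range(2):
            u = control_from_momenta(q, p, KERN2, ell)
            X = rng.uniform(0, 4, size=(30, 2))
            J = u.jacobian(X)
            fdJ = np.stack([(u(X + h * e) - u(X - h * e)) / (2 * h) for e in eye], axis=-1)
            assert np.max(np.abs(J - fdJ)) <= 1e-5 * max(np.max(np.abs(fdJ)), 1e-3)
            div = u.divergence(X)
            np.testing.assert_allclose(div, np.trace(fdJ, axis1=1, axis2=2),
                                       rtol=1e-5, atol=1e-8)
            gd = u.grad_divergence(X)
            fdg = np.stack([(u.divergence(X + h * e) - u.divergence(X - h * e)) / (2 * h)
                            for e in eye], axis=-1)
            assert np.max(np.abs(gd - fdg)) <= 1e-5 * max(np.max(np.abs(fdg)), 1e-3)

    def test_momenta_only_at_coarse_scale_degenerate_hierarchy(self, rng):
        """With momenta only at scale 0, gbar_{min(l,0)} = g_0 for all l,
        so every scale sees the identical control field."""
        q, p = random_instance(rng)
        p.px[1][:] = 0.0
        p.pw[1][:] = 0.0
        X = rng.uniform(0, 4, size=(20, 2))
        u0 = control_from_momenta(q, p, KERN2, 0)
        u1 = control_from_momenta(q, p, KERN2, 1)
        np.testing.assert_allclose(u0(X), u1(X), atol=1e-12)


class TestEnergy:
    def test_zero_momenta(self, rng):
        q, _ = random_instance(rng)
        total, per = hamiltonian_energy(q, HierMomenta.zeros(q), KERN2)
        assert total == 0.0 and per == [0.0, 0.0]

    def test_single_particle_closed_form(self):
        q = HierState([np.array([[0.0, 0.0]])], [np.array([1.0])])
        p = HierMomenta([np.array([[0.3, -0.4]])], [np.array([0.0])])
        kern = CumulativeKernel.from_fwhm([2.0])
        total, _ = hamiltonian_energy(q, p, kern)
        assert total == pytest.approx(0.5 * (0.3**2 + 0.4**2), rel=1e-14)

    def test_pairing_equals_rkhs_double_sum(self, rng):
        """Stationarity identity: the costate pairing energy equals the
        direct RKHS norm of the refinements, on random 3-scale instances."""
        kern3 = CumulativeKernel.from_fwhm([6.0, 3.0, 1.5])
        for _ in range(5):
            q, p = random_instance(rng, ns=(8, 8, 8))
            e1, _ = hamiltonian_energy(q, p, kern3)
            e2 = rkhs_energy(q, p, kern3)
            assert e1 == pytest.approx(e2, rel=1e-8)


class TestShoot:
    def test_zero_momenta_is_identity(self, rng):
        q, _ = random_instance(rng)
        flow = shoot(q, HierMomenta.zeros(q), KERN2, 10)
        np.testing.assert_array_equal(flow.states[-1].positions[0], q.positions[0])
        assert flow.energy == 0.0

    def test_single_particle_straight_line(self):
        q = HierState([np.array([[0.5, 0.2]])], [np.array([1.0])])
        p = HierMomenta([np.array([[0.3, -0.1]])], [np.array([0.0])])
        kern = CumulativeKernel.from_fwhm([2.0])
        flow = shoot(q, p, kern, 50)
        expect = np.array([0.5, 0.2]) + np.array([0.3, -0.1])
        assert np.max(np.abs(flow.states[-1].positions[0][0] - expect)) < 1e-10
        assert np.max(np.abs(flow.states[-1].weights[0] - 1.0)) < 1e-12

    def test_rk4_self_convergence_order(self, rng):
        """Halving the step size shrinks endpoint error by >= 8x."""
        q, p = random_instance(rng, ns=(5,), pscale=0.4)
        kern = CumulativeKernel.from_fwhm([3.0])
        ref = shoot(q, p, kern, 320).states[-1].positions[0]
        e1 = np.max(np.abs(shoot(q, p, kern, 10).states[-1].positions[0] - ref))
        e2 = np.max(np.abs(shoot(q, p, kern, 20).states[-1].positions[0] - ref))
        assert e1 / e2 >= 8.0

    def test_weights_stay_positive(self, rng):
        q, p = random_instance(rng, pscale=0.5, wscale=0.3)
        flow = shoot(q, p, KERN2, 30)
        for st in flow.states:
            for w in st.weights:
                assert np.all(w > 0)

    def test_hamiltonian_conserved(self, rng):
        q, p = random_instance(rng, ns=(5, 5), pscale=0.3)
        flow = shoot(q, p, KERN2, 50)
        assert flow.hamiltonian_drift() < 1e-4

    def test_energy_identity_along_flow(self, rng):
        q, p = random_instance(rng, ns=(4, 4))
        flow = shoot(q, p, KERN2, 20)
        for st, mo in zip(flow.states[::5], flow.momenta[::5]):
            e1, _ = hamiltonian_energy(st, mo, KERN2)
            assert e1 == pytest.approx(rkhs_energy(st, mo, KERN2), rel=1e-8)

    def test_mirror_symmetry_two_particle_head_on(self):
        """A symmetric head-on configuration keeps its mirror symmetry."""
        q = HierState([np.array([[-1.0, 0.0], [1.0, 0.0]])], [np.ones(2)])
        p = HierMomenta([np.array([[0.5, 0.0], [-0.5, 0.0]])], [np.zeros(2)])
        kern = CumulativeKernel.from_fwhm([2.5])
        flow = shoot(q, p, kern, 50)
        for st in flow.states:
            x = st.positions[0]
            assert abs(x[0, 0] + x[1, 0]) < 1e-10
            assert abs(x[0, 1]) < 1e-12 and abs(x[1, 1]) < 1e-12

    def test_blow_up_reports_step(self):
        q = HierState([np.array([[0.0, 0.0], [0.1, 0.0]])], [np.ones(2)])
        p = HierMomenta([np.zeros((2, 2))], [np.array([50.0, 50.0])])
        kern = CumulativeKernel.from_fwhm([0.5])
        with pytest.raises(FloatingPointError, match="step"):
            shoot(q, p, kern, 5)


class TestPixelParticleFlow:
    def test_weights_track_jacobian_determinant(self, rng):
        """Pixel particles with zero momenta flowed through a smooth field
        gain weight |dphi|; against the determinant of a finite-difference
        flow-map Jacobian the error shrinks when the raster is refined."""
        kern = CumulativeKernel.from_fwhm([2.0, 1.0])
        ctrl_x = np.array([[1.2, 1.0], [2.8, 2.6]])
        ctrl_p = np.array([[0.5, -0.2], [-0.3, 0.4]])

        def run(n_pix):
            img = image_to_measure(np.ones((n_pix, n_pix)), spacing=4.0 / n_pix)
            q = HierState([ctrl_x.copy(), img.positions], [np.ones(2), img.weights])
            p = HierMomenta([ctrl_p.copy(), np.zeros_like(img.positions)],
                            [np.zeros(2), np.zeros(img.n)])
            flow = shoot(q, p, kern, 20)
            X0 = img.positions.reshape(n_pix, n_pix, 2)
            X1 = flow.states[-1].positions[1].reshape(n_pix, n_pix, 2)
            h = 4.0 / n_pix
            J = np.empty((n_pix - 2, n_pix - 2, 2, 2))
            J[..., 0] = (X1[2:, 1:-1] - X1[:-2, 1:-1]) / (2 * h)
            J[..., 1] = (X1[1:-1, 2:] - X1[1:-1, :-2]) / (2 * h)
            det = np.abs(np.linalg.det(J))
            w_ratio = (flow.states[-1].weights[1] / img.weights).reshape(n_pix, n_pix)
            return np.max(np.abs(w_ratio[1:-1, 1:-1] - det))

        err_coarse = run(10)
        err_fine = run(20)
        assert err_fine <= err_coarse / 2.0


class TestMomentumIntegral:
    def test_zero_momenta_zero_residual(self, rng):
        q, _ = random_instance(rng)
        flow = shoot(q, HierMomenta.zeros(q), KERN2, 10)
        assert verify_momentum_integral(flow) == 0.0

    def test_pure_jacobian_transport_when_pw_zero(self, rng):
        q, p = random_instance(rng, ns=(6,), pscale=0.3, wscale=0.0)
        kern = CumulativeKernel.from_fwhm([3.0])
        flow = shoot(q, p, kern, 100)
        assert verify_momentum_integral(flow) < 1e-4

    def test_residual_decreases_under_refinement(self, rng):
        q, p = random_instance(rng, ns=(6,), pscale=0.3, wscale=0.2)
        kern = CumulativeKernel.from_fwhm([3.0])
        r1 = verify_momentum_integral(shoot(q, p, kern, 50))
        r2 = verify_momentum_integral(shoot(q, p, kern, 100))
        assert r2 < r1


class TestAdjoint:
    def test_vjp_matches_finite_differences(self, rng):
        kern = KERN2
        shapes = [(3, 2), (4, 2)]
        x = [rng.uniform(0, 3, size=s) for s in shapes]
        w = [rng.uniform(0.5, 2, s[0]) for s in shapes]
        px = [0.3 * rng.standard_normal(s) for s in shapes]
        pw = [0.2 * rng.standard_normal(s[0]) for s in shapes]
        z = _pack(x, w, px, pw)
        lam = rng.standard_normal(z.shape)
        got = _dynamics_vjp(kern, shapes, z, lam)
        h = 1e-6
        fd = np.array([
            (lam @ _dynamics(kern, shapes, z + h * e)
             - lam @ _dynamics(kern, shapes, z - h * e)) / (2 * h)
            for e in np.eye(len(z))
        ])
        assert np.max(np.abs(got - fd)) <= 1e-6 * max(np.max(np.abs(fd)), 1.0)


def small_pair(rng, n=5):
    base = ParticleMeasure(rng.uniform(0, 4, size=(n, 2)), np.ones(n),
                           Features("scalar", rng.uniform(1, 2, n)))
    return MultiscaleMeasure([base])


class TestMatch:
    def test_identical_target_stays_at_zero(self, rng):
        tpl = small_pair(rng)
        kern = CumulativeKernel.from_fwhm([3.0])
        res = match(tpl, tpl, kern, [VarifoldKernelSpec(1.0, 1.0)],
                    alpha=1.0, steps=5, max_iter=10)
        assert res.objective_trace[-1] == pytest.approx(0.0, abs=1e-12)
        assert res.p0.norm_inf() == 0.0

    def test_gradient_modes_agree(self, rng):
        """Discrete-adjoint and finite-difference gradients of the full
        matching objective agree on a 5-particle instance."""
        from varimap.geodesics import match_objective_gradient
        from varimap.synthetic import gen_deformed_pair

        base = small_pair(rng).scales[0]
        kern = CumulativeKernel.from_fwhm([3.0])
        tpl, tgt, _ = gen_deformed_pair(base, kern, 0.2, seed=4, steps=8)
        specs = [VarifoldKernelSpec(1.0, 1.5)]
        p0 = HierMomenta([0.1 * rng.standard_normal((5, 2))],
                         [0.05 * rng.standard_normal(5)])
        J_a, g_a = match_objective_gradient(tpl, tgt, kern, specs, 5.0, p0,
                                            steps=8, grad_mode="adjoint")
        J_f, g_f = match_objective_gradient(tpl, tgt, kern, specs, 5.0, p0,
                                            steps=8, grad_mode="fd")
        assert J_a == J_f
        scale = max(np.max(np.abs(g_f.px[0])), np.max(np.abs(g_f.pw[0])))
        assert np.max(np.abs(g_a.px[0] - g_f.px[0])) <= 1e-4 * scale
        assert np.max(np.abs(g_a.pw[0] - g_f.pw[0])) <= 1e-4 * scale

    def test_objective_trace_non_increasing(self, rng):
        from varimap.synthetic import gen_deformed_pair

        base = small_pair(rng, n=8).scales[0]
        kern = CumulativeKernel.from_fwhm([3.0])
        tpl, tgt, _ = gen_deformed_pair(base, kern, 0.25, seed=6, steps=10)
        res = match(tpl, tgt, kern, [VarifoldKernelSpec(1.0, 1.5)],
                    alpha=5.0, steps=10, max_iter=25)
        assert all(b <= a + 1e-10 for a, b in zip(res.objective_trace,
                                                  res.objective_trace[1:]))
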