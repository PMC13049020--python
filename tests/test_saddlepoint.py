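"""CGF construction, saddle solver, density, tail engine, LR formula."""

import numpy as np
import pytest
from scipy import stats

from saddleperm import (
    BoundaryError,
    DesignSpec,
    GaussianCGF,
    build_cgf,
    conditional_density,
    enumerate_null,
    exact_midp,
    lugannani_rice,
    mid_p,
    saddlepoint_tail,
    solve_saddlepoint,
    tail_probability_Q,
)
from saddleperm.design import sigma_matrix


@pytest.fixture(scope="module")
def medium_case():
    rng = np.random.default_rng(7)
    c = rng.normal(size=12)
    c -= c.mean()
    spec = DesignSpec((4, 4, 4))
    return c, spec, build_cgf(c, spec)


class TestCGF:
    def test_value_and_gradient_at_zero(self, medium_case):
        c, spec, cgf = medium_case
        x0 = np.zeros((1, 2 * cgf.d))
        k, grad, _ = cgf.value_grad(x0)
        assert k[0] == pytest.approx(0.0, abs=1e-12)
        # statistic block: centered scores; count block: multinomial means
        assert grad[0, : cgf.d] == pytest.approx([0.0] * cgf.d, abs=1e-12)
        assert grad[0, cgf.d :] == pytest.approx(list(cgf.counts))

    def test_conditional_hessian_is_finite_population_sigma(self, medium_case):
        """Count-conditioned curvature at 0 equals ((N-1)/N) * Sigma."""
        c, spec, cgf = medium_case
        n = spec.n_clusters
        sigma = sigma_matrix(spec, float(np.mean(c**2)))
        cond = cgf.conditional_hessian_at_zero()
        assert cond == pytest.approx(sigma * (n - 1) / n, rel=1e-8)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            build_cgf(np.zeros(6), DesignSpec((3, 3)))

    def test_kernel_solver_matches_numpy_reference(self, medium_case, rng):
        c, spec, cgf = medium_case
        w = rng.normal(size=(6, cgf.d)) * 1.2
        fast = cgf.solve(w)
        slow = cgf._solve_numpy(w)
        assert fast["converged"].tolist() == slow["converged"].tolist()
        ok = fast["converged"]
        assert fast["ell"][ok] == pytest.approx(slow["ell"][ok], abs=1e-10)
        assert fast["logdet"][ok] == pytest.approx(slow["logdet"][ok], abs=1e-8)


class TestSolveSaddlepoint:
    def test_zero_target_zero_tilt(self, medium_case):
        _, _, cgf = medium_case
        s_hat, sol = solve_saddlepoint(cgf, np.zeros(cgf.d))
        assert s_hat == pytest.approx([0.0] * cgf.d, abs=1e-9)
        assert sol["converged"][0]

    def test_gaussian_cgf_closed_form(self, rng):
        v = np.array([[2.0, 0.3], [0.3, 1.0]])
        g = GaussianCGF(v)
        w = np.array([0.7, -0.4])
        s_hat, _ = solve_saddlepoint(g, w)
        assert s_hat == pytest.approx(np.linalg.solve(v, w))

    def test_brute_force_tilt_search(self, rng):
        """Newton optimum matches a dense grid search of the dual."""
        c = rng.normal(size=8)
        c -= c.mean()
        cgf = build_cgf(c, DesignSpec((4, 4)))
        w0 = 0.8 * float(np.std(c)) * 2
        s_hat, sol = solve_saddlepoint(cgf, np.array([w0]))
        best = (np.inf, None)
        for s in np.linspace(s_hat[0] - 0.4, s_hat[0] + 0.4, 161):
            for phi in np.linspace(sol["phi_hat"][0, 0] - 0.4,
                                   sol["phi_hat"][0, 0] + 0.4, 161):
                k, _, _ = cgf.value_grad(np.array([[s, phi]]))
                h = k[0] - s * w0 - phi * cgf.counts[0]
                if h < best[0]:
                    best = (h, s)
        assert best[1] == pytest.approx(s_hat[0], abs=0.01)
        assert best[0] == pytest.approx(sol["ell"][0], abs=1e-4)

    def test_outside_hull_raises(self, medium_case):
        c, _, cgf = medium_case
        far = np.full(cgf.d, 100.0 * np.abs(c).sum())
        with pytest.raises(BoundaryError):
            solve_saddlepoint(cgf, far)


class TestConditionalDensity:
    def test_symmetry_for_sign_symmetric_scores(self):
        c = np.array([2.0, 1.0, -1.0, -2.0, 0.5, -0.5])
        cgf = build_cgf(c, DesignSpec((3, 3)))
        f1 = conditional_density(cgf, np.array([1.3]))
        f2 = conditional_density(cgf, np.array([-1.3]))
        assert f1 == pytest.approx(f2, rel=1e-6)

    def test_zero_tilt_formula(self, medium_case):
        """At w = 0 the density reduces to the explicit Laplace constant."""
        _, _, cgf = medium_case
        d = cgf.d
        x0 = np.zeros((1, 2 * d))
        _, _, pd = cgf.value_grad(x0)
        h = cgf.hessian(pd)[0]
        _, ld_full = np.linalg.slogdet(h)
        _, ld_pp = np.linalg.slogdet(h[d:, d:])
        expected = np.exp(
            -0.5 * d * np.log(2 * np.pi) - 0.5 * ld_full + 0.5 * ld_pp
        )
        assert conditional_density(cgf, np.zeros(d)) == pytest.approx(expected)

    def test_bulk_mass_matches_enumeration(self, rng):
        """Density mass over the bulk region tracks the exact probability.

        Integrated over the central region (|W| within ~2 sd) the
        saddlepoint density and the enumerated law agree to ~10%;
        near the support hull the Laplace prefactor degrades, which is
        why the tail engine carries a monotone-envelope guard.
        """
        c = rng.normal(size=12)
        c -= c.mean()
        spec = DesignSpec((6, 6))
        cgf = build_cgf(c, spec)
        sd = float(np.sqrt(sigma_matrix(spec, np.mean(c**2))[0, 0]))
        from saddleperm.reference import _iter_group_sums

        ws = np.sort([w[0] for w in _iter_group_sums(c, spec.group_sizes)])
        exact_bulk = np.mean(np.abs(ws) <= 1.5 * sd)
        grid = np.linspace(-3.5 * sd, 3.5 * sd, 501)
        dens = []
        for w in grid:
            try:
                dens.append(conditional_density(cgf, np.array([w])))
            except BoundaryError:
                dens.append(0.0)
        dens = np.asarray(dens)
        total = np.trapezoid(dens, grid)
        bulk = np.trapezoid(np.where(np.abs(grid) <= 1.5 * sd, dens, 0.0), grid)
        assert bulk / total == pytest.approx(exact_bulk, rel=0.10)


class TestTailEngine:
    def test_gaussian_reduces_to_chisq(self):
        for d in (1, 2, 4):
            g = GaussianCGF(np.eye(d) * 1.7)
            for q in (0.5, 3.0, 9.0):
                assert tail_probability_Q(g, g.v, q).tail == pytest.approx(
                    stats.chi2.sf(q, d), rel=1e-6
                )

    def test_q_zero_gives_one(self, medium_case):
        c, spec, cgf = medium_case
        assert tail_probability_Q(cgf, cgf.sigma, 0.0).tail == 1.0

    def test_monotone_decreasing_in_q(self, medium_case):
        c, spec, cgf = medium_case
        qs = [0.5, 1.5, 3.0, 5.0, 8.0, 12.0]
        tails = [tail_probability_Q(cgf, cgf.sigma, q).tail for q in qs]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_scale_invariance(self, rng):
        c = rng.normal(size=10)
        c -= c.mean()
        spec = DesignSpec((5, 5))
        t1 = saddlepoint_tail(c, spec, 2.8).tail
        t2 = saddlepoint_tail(3.7 * c, spec, 2.8).tail
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_tracks_enumeration_on_moderate_design(self, rng):
        """Analytic tail vs exact mid-p at enumerated support points."""
        c = rng.normal(size=14)
        c -= c.mean()
        spec = DesignSpec((7, 7))
        null = enumerate_null(c, spec)
        mids = 1.0 - np.cumsum(null.pmf) + 0.5 * null.pmf
        eligible = np.flatnonzero((mids >= 0.02) & (mids <= 0.2))
        cgf = build_cgf(c, spec)
        for i in eligible[:: max(1, eligible.size // 8)]:
            sp = tail_probability_Q(cgf, cgf.sigma, float(null.support[i])).tail
            assert sp == pytest.approx(float(mids[i]), rel=0.25)

    def test_diagnostics_signs(self, medium_case):
        c, spec, cgf = medium_case
        res = tail_probability_Q(cgf, cgf.sigma, 7.0)
        assert 0.0 <= res.tail <= 1.0
        assert res.mid_p == res.tail  # continuous law: no atom
        if res.t_hat is not None and res.r is not None:
            assert np.sign(res.r) == np.sign(res.t_hat)


class TestLugannaniRice:
    def test_reduces_to_normal_tail_when_r_equals_u(self):
        assert lugannani_rice(1.645, 1.645) == pytest.approx(0.05, abs=1e-3)
        for r in (-2.0, -0.5, 0.5, 2.5):
            assert lugannani_rice(r, r) == pytest.approx(stats.norm.sf(r))

    def test_exponential_tail_benchmark(self):
        """Three-digit accuracy on the exact exponential upper tail."""
        x = 4.0
        t_hat = 1.0 - 1.0 / x
        r = np.sqrt(2 * (t_hat * x - np.log(x)))
        u = t_hat * x
        assert lugannani_rice(r, u) == pytest.approx(np.exp(-x), rel=0.02)

    def test_singularity_limit(self):
        assert lugannani_rice(1e-6, 1e-6) == 0.5

    def test_clamped_to_unit_interval(self):
        assert 0.0 <= lugannani_rice(-8.0, -0.01) <= 1.0

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            lugannani_rice(np.nan, 1.0)


class TestMidP:
    def test_arithmetic(self):
        assert mid_p(0.04, 0.02) == pytest.approx(0.05)
        assert mid_p(0.123, 0.0) == pytest.approx(0.123)
        assert mid_p(0.0, 1.0) == 0.5

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            mid_p(0.9, 0.3)
        with pytest.raises(ValueError):
            mid_p(-0.1, 0.0)


class TestDegenerateAndBoundary:
    def test_exact_midp_consistency_on_support(self, rng):
        c = rng.integers(-4, 5, size=8).astype(float)
        c -= c.mean()
        if np.allclose(c, 0):
            c = np.array([1.0, -1, 2, -2, 0, 0, 1, -1])
        spec = DesignSpec((4, 4))
        null = enumerate_null(c, spec)
        q = float(null.support[len(null.support) // 2])
        strict, atom = (
            float(null.pmf[null.support > q + 1e-9].sum()),
            float(null.pmf[np.abs(null.support - q) <= 1e-9].sum()),
        )
        assert exact_midp(null, q) == pytest.approx(strict + atom / 2)
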