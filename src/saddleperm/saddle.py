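"""Analytic p-value engine for the permutation distribution of Q.

The urn law of the group-total vector W is recovered from an
independent-multinomial-label surrogate by double-saddlepoint
conditioning on the group counts: per cluster, the label is j with
probability ``p_j = N_j / N``; tilting jointly in the statistic
coordinates (s) and the count coordinates (phi) and solving

    grad K(s_hat, phi_hat) = (w, n),   n = (N_1, ..., N_{k-1}),

gives the conditional log-density exponent ``l(w) = K - s'w - phi'n``
and the Laplace prefactor ``det K''(s_hat, phi_hat)^{-1/2}``.
Conditioning independent labels on their counts reproduces sampling
without replacement exactly, so the targeted conditional law IS the
urn permutation law; the double saddlepoint approximates it with
relative error O(1/N).

The scalar reduction for ``Q = W' Sigma^{-1} W`` integrates this
density over the ellipsoid shells: in Sigma-standardized coordinates
the constraint is a sphere of radius ``sqrt(q)``, so

    P(Q >= q)  =  int_{sqrt(q)}^inf rho^{d-1} J(rho) drho
               /  int_0^inf       rho^{d-1} J(rho) drho,

with ``J(rho)`` the spherical average of the saddlepoint density over
a fixed antithetic direction set (orthonormal-frame design) and the
radial integrals evaluated on Gauss-Legendre panels.  Normalizing by
the full integral removes the constant-order error of the raw
saddlepoint density.  For a Gaussian cumulant generating function the
density is exact and the pipeline reproduces the chi-squared tail to
quadrature accuracy.  The Lugannani-Rice tail formula and the scalar
saddle diagnostics (t_hat, r, u) are computed from the radial profile
and reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .design import DesignSpec, sigma_matrix
from .scoring import ClusterScoreVector

__all__ = [
    "SaddleConfig",
    "PermutationCGF",
    "GaussianCGF",
    "SaddlepointResult",
    "BoundaryError",
    "build_cgf",
    "solve_saddlepoint",
    "conditional_density",
    "tail_probability_Q",
    "lugannani_rice",
    "mid_p",
]

_DIRECTION_SEED = 91042  # fixed: the direction set is part of the algorithm


class BoundaryError(RuntimeError):
    """Target outside the attainable support; fall back to enumeration/MC."""


@dataclass(frozen=True)
class SaddleConfig:
    """Numerical knobs of the analytic engine.

    ``newton_tol`` is the relative infinity-norm tolerance on the
    gradient equation; ``n_direction_pairs`` of None picks a default
    that grows with the dimension k-1.  ``logf_floor`` truncates
    density evaluations more than ~20 orders of magnitude below the
    mode (they cannot move the tail ratio).
    """

    newton_tol: float = 1e-10
    newton_maxiter: int = 50
    max_halvings: int = 25
    n_direction_pairs: int | None = None
    gl_order: int = 5
    tail_panel_edges: tuple[float, ...] = (0.0, 0.7, 1.5, 2.4, 3.5, 5.0, 7.0)
    norm_panel_width: float = 1.5
    logf_floor: float = -46.0
    r_singular_tol: float = 1e-4
    use_correction: bool = False
    use_envelope: bool = True
    correction_clip: tuple[float, float] = (0.1, 4.0)

    def direction_pairs(self, d: int) -> int:
        if self.n_direction_pairs is not None:
            return self.n_direction_pairs
        return {1: 1, 2: 12, 3: 16, 4: 24, 5: 32}.get(d, 8 * d)


def _direction_set(d: int, n_pairs: int) -> np.ndarray:
    """Fixed antithetic direction set on the unit sphere in R^d.

    d = 1 uses {+1, -1}; d = 2 equally spaced half-circle angles; for
    d >= 3 columns of Haar-random orthogonal frames drawn from a fixed
    internal seed (orthonormal frames reduce the angular-average
    variance for smooth integrands).  Antithetic pairs cancel the odd
    (skewness) part of the log-density exactly.
    """
    if d == 1:
        return np.array([[1.0], [-1.0]])
    if d == 2:
        theta = np.pi * (np.arange(n_pairs) + 0.5) / n_pairs
        half = np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        rng = np.random.default_rng(_DIRECTION_SEED)
        cols = []
        while len(cols) < n_pairs:
            a = rng.standard_normal((d, d))
            q_mat, r_mat = np.linalg.qr(a)
            q_mat *= np.sign(np.diag(r_mat))
            cols.extend(q_mat.T)
        half = np.array(cols[:n_pairs])
    return np.concatenate([half, -half], axis=0)


@dataclass
class SaddlepointResult:
    """Tail probability of Q with solver and reduction diagnostics."""

    q_obs: float
    tail: float
    mid_p: float
    s_hat: np.ndarray | None = None
    t_hat: float | None = None
    r: float | None = None
    u: float | None = None
    p_lugannani_rice: float | None = None
    iterations: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


class PermutationCGF:
    """Joint CGF of (W, group counts) under independent multinomial labels.

    Exposes exact value/gradient/Hessian in closed form (per-cluster
    softmax moments, summed over clusters) and a batched damped-Newton
    solver for the joint saddle equation.
    """

    def __init__(self, scores: np.ndarray, spec: DesignSpec, config: SaddleConfig | None = None):
        scores = np.asarray(scores, dtype=float)
        n = spec.n_clusters
        if scores.size != n:
            raise ValueError("scores length does not match the design")
        s2 = float(np.mean(scores**2))
        if s2 == 0.0:
            raise ValueError("degenerate scores (s2 = 0)")
        if not n > spec.k:
            raise ValueError("need more clusters than groups (N > k)")
        self.spec = spec
        self.config = config or SaddleConfig()
        self.d = spec.k - 1
        self.scores = scores
        self.logp = np.log(spec.label_probs)
        self.counts = np.asarray(spec.group_sizes[:-1], dtype=float)
        self.sigma = sigma_matrix(spec, s2)

    # -- CGF evaluation -------------------------------------------------
    def value_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """K, gradient and label probabilities at tilt ``x = (s, phi)``."""
        d = self.d
        s, phi = x[:, :d], x[:, d:]
        logits = self.scores[None, :, None] * s[:, None, :] + phi[:, None, :]
        logits = np.concatenate(
            [logits, np.zeros(logits.shape[:2] + (1,))], axis=2
        )
        logits += self.logp[None, None, :]
        mx = logits.max(axis=2, keepdims=True)
        ex = np.exp(logits - mx)
        tot = ex.sum(axis=2, keepdims=True)
        kval = (mx[..., 0] + np.log(tot[..., 0])).sum(axis=1)
        prob = ex / tot
        pd = prob[:, :, :d]
        grad_s = np.einsum("c,mcj->mj", self.scores, pd)
        grad_phi = pd.sum(axis=1)
        return kval, np.concatenate([grad_s, grad_phi], axis=1), pd

    def hessian(self, pd: np.ndarray) -> np.ndarray:
        c = self.scores
        d = self.d
        cp = c[None, :, None] * pd
        c2p = (c**2)[None, :, None] * pd
        h_ss = -np.einsum("mcj,mcl->mjl", cp, cp)
        h_sp = -np.einsum("mcj,mcl->mjl", cp, pd)
        h_pp = -np.einsum("mcj,mcl->mjl", pd, pd)
        idx = np.arange(d)
        h_ss[:, idx, idx] += c2p.sum(axis=1)
        h_sp[:, idx, idx] += cp.sum(axis=1)
        h_pp[:, idx, idx] += pd.sum(axis=1)
        top = np.concatenate([h_ss, h_sp], axis=2)
        bot = np.concatenate([np.transpose(h_sp, (0, 2, 1)), h_pp], axis=2)
        return np.concatenate([top, bot], axis=1)

    def conditional_hessian_at_zero(self) -> np.ndarray:
        """Count-conditioned curvature at zero tilt: ``(N-1)/N * Sigma``.

        The conditional law targeted by the double saddlepoint is
        exactly the urn law (conditioning independent labels on their
        counts yields sampling without replacement), whose covariance
        is Sigma; the Laplace curvature at the origin carries the
        finite-population factor ``(N-1)/N``.  This is a property of
        the approximation geometry, not a distortion of the target:
        rescaling the scores to force the curvature onto Sigma would
        change the conditional law itself and systematically inflate
        tails (verified against exact enumeration).
        """
        x0 = np.zeros((1, 2 * self.d))
        _, _, pd = self.value_grad(x0)
        h = self.hessian(pd)[0]
        d = self.d
        h_ss, h_sp, h_pp = h[:d, :d], h[:d, d:], h[d:, d:]
        return h_ss - h_sp @ np.linalg.solve(h_pp, h_sp.T)

    # -- joint saddle solve ---------------------------------------------
    def solve(self, w_targets: np.ndarray) -> dict:
        """Damped-Newton solve of ``grad K(s, phi) = (w, n)`` per row of w.

        Returns the saddle coordinates, the conditional exponent
        ``l = K - s'w - phi'n``, log-determinant of the joint Hessian,
        a convergence flag per point and the iteration count.
        """
        from . import _kernels as kern

        cfg = self.config
        w_targets = np.atleast_2d(np.ascontiguousarray(w_targets, dtype=float))
        x, ell, logdet, status, iters = kern.solve_points(
            self.scores,
            self.logp,
            self.counts,
            w_targets,
            cfg.newton_tol,
            cfg.newton_maxiter,
            cfg.max_halvings,
            cfg.logf_floor - 25.0,
        )
        d = self.d
        return {
            "x": x,
            "s_hat": x[:, :d],
            "phi_hat": x[:, d:],
            "ell": ell,
            "logdet": logdet,
            "converged": status == kern.STATUS_CONVERGED,
            "negligible": status == kern.STATUS_NEGLIGIBLE,
            "iterations": int(iters.max()) if iters.size else 0,
        }

    def profile(self, ray_dirs: np.ndarray, rhos: np.ndarray) -> dict:
        """Warm-started solves along rays ``w = rho * ray_dirs[i]``."""
        from . import _kernels as kern

        cfg = self.config
        x, ell, logdet, status, iters = kern.solve_rays(
            self.scores,
            self.logp,
            self.counts,
            np.ascontiguousarray(ray_dirs, dtype=float),
            np.ascontiguousarray(rhos, dtype=float),
            cfg.newton_tol,
            cfg.newton_maxiter,
            cfg.max_halvings,
            cfg.logf_floor - 25.0,
        )
        return {
            "x": x,
            "ell": ell,
            "logdet": logdet,
            "converged": status == kern.STATUS_CONVERGED,
            "negligible": status == kern.STATUS_NEGLIGIBLE,
            "iterations": int(iters),
        }

    supports_correction = True

    def logdensity_at_zero(self) -> float:
        """Unnormalized log-density at w = 0 (the mode reference value)."""
        x0 = np.zeros((1, 2 * self.d))
        _, _, pd = self.value_grad(x0)
        _, ld = np.linalg.slogdet(self.hessian(pd)[0])
        return -0.5 * float(ld)

    def correction(self, x_points: np.ndarray) -> np.ndarray:
        """Second-order density factors ``c`` (density multiplier 1 + c)."""
        from . import _kernels as kern

        return kern.correction_points(
            self.scores,
            self.logp,
            self.counts,
            np.ascontiguousarray(np.atleast_2d(x_points), dtype=float),
        )

    def _solve_numpy(self, w_targets: np.ndarray) -> dict:
        """Pure-numpy reference solver (parity oracle for the kernels)."""
        cfg = self.config
        w_targets = np.atleast_2d(np.asarray(w_targets, dtype=float))
        m, d = w_targets.shape
        target = np.concatenate(
            [w_targets, np.tile(self.counts, (m, 1))], axis=1
        )
        tol = cfg.newton_tol * (1.0 + np.abs(target).max(axis=1))
        # a descent value this far below the mode is negligible mass;
        # stop chasing the (possibly nonexistent) saddle there
        negligible_floor = cfg.logf_floor - 25.0
        x = np.zeros((m, 2 * d))
        kval, grad, pd = self.value_grad(x)
        hval = kval - np.einsum("mi,mi->m", x, target)
        converged = np.zeros(m, dtype=bool)
        failed = np.zeros(m, dtype=bool)
        negligible = np.zeros(m, dtype=bool)
        iterations = 0
        for iterations in range(1, cfg.newton_maxiter + 1):
            resid = target - grad
            newly = np.abs(resid).max(axis=1) < tol
            converged |= newly & ~failed & ~negligible
            negligible |= (hval < negligible_floor) & ~converged
            active = ~converged & ~failed & ~negligible
            if not active.any():
                break
            idx = np.flatnonzero(active)
            hess = self.hessian(pd[idx])
            # tiny Levenberg ridge guards near-singular far-tail points
            ridge = 1e-12 * np.trace(hess, axis1=1, axis2=2) / (2 * d)
            hess[:, np.arange(2 * d), np.arange(2 * d)] += ridge[:, None]
            try:
                step = np.linalg.solve(hess, resid[idx][..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.stack(
                    [
                        np.linalg.lstsq(h_i, r_i, rcond=None)[0]
                        for h_i, r_i in zip(hess, resid[idx])
                    ]
                )
            alpha = np.ones(len(idx))
            pending = np.arange(len(idx))
            for _ in range(cfg.max_halvings):
                rows = idx[pending]
                trial = x[rows] + alpha[pending, None] * step[pending]
                sane = np.abs(trial).max(axis=1) < 1e6
                h_t = np.full(len(pending), np.inf)
                if sane.any():
                    k_t, g_t, p_t = self.value_grad(trial[sane])
                    h_try = k_t - np.einsum("mi,mi->m", trial[sane], target[rows[sane]])
                    h_t[sane] = np.where(np.isfinite(h_try), h_try, np.inf)
                good = h_t <= hval[rows] + 1e-12 * (1.0 + np.abs(hval[rows]))
                if good.any():  # good implies sane (insane points got inf)
                    acc = rows[good]
                    x[acc] = trial[good]
                    hval[acc] = h_t[good]
                    src = (np.cumsum(sane) - 1)[good]
                    kval[acc] = k_t[src]
                    grad[acc] = g_t[src]
                    pd[acc] = p_t[src]
                pending = pending[~good]
                if pending.size == 0:
                    break
                alpha[pending] *= 0.5
            failed[idx[pending]] = True
        converged &= ~failed & ~negligible
        # log-determinant of the joint Hessian at the solution
        logdet = np.full(m, np.nan)
        ok_idx = np.flatnonzero(converged)
        if ok_idx.size:
            hess = self.hessian(pd[ok_idx])
            sign, ld = np.linalg.slogdet(hess)
            good = sign > 0
            logdet[ok_idx[good]] = ld[good]
            converged[ok_idx[~good]] = False
        return {
            "x": x,
            "s_hat": x[:, :d],
            "phi_hat": x[:, d:],
            "ell": hval,
            "logdet": logdet,
            "converged": converged,
            "negligible": negligible,
            "iterations": iterations,
        }

    def logdensity(self, w_targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Normalizable log-density of W given the counts (up to a constant).

        ``log f = l(w) - 0.5 logdet K''(s_hat, phi_hat)``; the constant
        (2 pi powers and the count-margin determinant) cancels in the
        radial tail ratio.
        """
        sol = self.solve(w_targets)
        ok = sol["converged"]
        logf = np.where(ok, sol["ell"] - 0.5 * sol["logdet"], -np.inf)
        # negligible-mass points are valid zeros, not boundary failures
        return logf, ok | sol["negligible"]

    def density_constant(self) -> float:
        """log of the double-saddlepoint normalization constant.

        ``-(d/2) log 2pi + 0.5 logdet H_phiphi(0, 0)``: the zero-tilt
        count-margin solve has ``phi_hat = 0`` because the targeted
        counts are the multinomial means.
        """
        x0 = np.zeros((1, 2 * self.d))
        _, _, pd = self.value_grad(x0)
        h = self.hessian(pd)[0]
        hpp = h[self.d :, self.d :]
        _, ld = np.linalg.slogdet(hpp)
        return -0.5 * self.d * np.log(2 * np.pi) + 0.5 * ld


class GaussianCGF:
    """Quadratic CGF ``K(s) = s' V s / 2`` (exact-Gaussian substitute).

    Serves as the closed-form check of the scalar reduction: with this
    CGF the density is exactly N(0, V) and the tail of Q is exactly
    chi-squared.
    """

    def __init__(self, v: np.ndarray):
        self.v = np.atleast_2d(np.asarray(v, dtype=float))
        self.d = self.v.shape[0]
        self._cho = linalg.cho_factor(self.v)

    def solve(self, w_targets: np.ndarray) -> dict:
        w = np.atleast_2d(np.asarray(w_targets, dtype=float))
        s_hat = linalg.cho_solve(self._cho, w.T).T
        ell = -0.5 * np.einsum("mi,mi->m", w, s_hat)
        _, ld = np.linalg.slogdet(self.v)
        return {
            "s_hat": s_hat,
            "ell": ell,
            "logdet": np.full(w.shape[0], ld),
            "converged": np.ones(w.shape[0], dtype=bool),
            "iterations": 1,
        }

    def logdensity(self, w_targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sol = self.solve(w_targets)
        return sol["ell"] - 0.5 * sol["logdet"], sol["converged"]

    def logdensity_at_zero(self) -> float:
        _, ld = np.linalg.slogdet(self.v)
        return -0.5 * float(ld)

    def profile(self, ray_dirs: np.ndarray, rhos: np.ndarray) -> dict:
        n_dir = ray_dirs.shape[0]
        quad = np.einsum(
            "id,id->i", ray_dirs, linalg.cho_solve(self._cho, ray_dirs.T).T
        )
        ell = -0.5 * quad[:, None] * (rhos**2)[None, :]
        _, ld = np.linalg.slogdet(self.v)
        return {
            "ell": ell,
            "logdet": np.full_like(ell, ld),
            "converged": np.ones_like(ell, dtype=bool),
            "negligible": np.zeros_like(ell, dtype=bool),
            "iterations": 1,
        }

    supports_correction = False

    def density_constant(self) -> float:
        return -0.5 * self.d * np.log(2 * np.pi)


def build_cgf(
    c: ClusterScoreVector | np.ndarray,
    spec: DesignSpec,
    config: SaddleConfig | None = None,
) -> PermutationCGF:
    scores = c.scores if isinstance(c, ClusterScoreVector) else np.asarray(c, dtype=float)
    return PermutationCGF(scores, spec, config)


def solve_saddlepoint(cgf, w: np.ndarray) -> tuple[np.ndarray, dict]:
    """Saddle ``s_hat`` for one target w (count-conditioned for the urn CGF).

    Raises :class:`BoundaryError` if the Newton iteration cannot reach
    the target (w on or outside the attainable hull).
    """
    sol = cgf.solve(np.atleast_2d(w))
    if not sol["converged"][0]:
        raise BoundaryError(
            "saddle equation did not converge: target on or outside the "
            "support hull; fall back to enumeration or Monte Carlo"
        )
    return sol["s_hat"][0], sol


def conditional_density(cgf, w: np.ndarray) -> float:
    """Count-conditioned saddlepoint density f_SP(w) (fully normalized)."""
    logf, ok = cgf.logdensity(np.atleast_2d(w))
    if not ok[0]:
        raise BoundaryError("no saddlepoint at the requested w")
    return float(np.exp(logf[0] + cgf.density_constant()))


def lugannani_rice(r: float, u: float) -> float:
    """Upper-tail formula ``1 - Phi(r) + phi(r) (1/u - 1/r)``, clamped to [0, 1].

    With the signed root ``r = sign(t) sqrt(2 (t q - K(t)))`` and
    ``u = t sqrt(K''(t))`` the correction term is ``1/u - 1/r`` (the
    formula then reproduces, e.g., the exact exponential tail to three
    digits; the opposite sign moves it away from the exact value).
    For ``|r|`` below the singularity threshold the removable
    singularity at r = 0 is handled by returning the limiting value
    1/2 (r and u vanish together at the mean).
    """
    if not (np.isfinite(r) and np.isfinite(u)):
        raise ValueError("r and u must be finite")
    if abs(r) < 1e-4 or abs(u) < 1e-12:
        return 0.5
    val = stats.norm.sf(r) + stats.norm.pdf(r) * (1.0 / u - 1.0 / r)
    return float(min(1.0, max(0.0, val)))


def mid_p(tail_strict: float, atom: float) -> float:
    """``P(Q > q) + atom / 2`` with basic sanity checks."""
    if tail_strict < -1e-12 or atom < -1e-12:
        raise ValueError("probabilities must be nonnegative")
    if tail_strict + atom > 1.0 + 1e-12:
        raise ValueError("tail_strict + atom exceeds 1")
    return float(tail_strict + 0.5 * atom)


def _gl_panels(edges: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights over consecutive panels."""
    xg, wg = np.polynomial.legendre.leggauss(order)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        half = 0.5 * (b - a)
        nodes.append(0.5 * (a + b) + half * xg)
        weights.append(half * wg)
    return np.concatenate(nodes), np.concatenate(weights)


def _monotone_envelope(rel: np.ndarray) -> None:
    """In-place per-ray clamp: non-increasing after the first descent.

    The true conditional density along a ray is unimodal in the radius;
    the raw Laplace prefactor ``det^{-1/2}`` diverges as the tilt
    approaches the support hull, which would otherwise re-inflate the
    profile.  Everything past the first local maximum is forced onto a
    non-increasing envelope.
    """
    n_rho, n_dir = rel.shape
    for j in range(n_dir):
        col = rel[:, j]
        drops = np.flatnonzero(np.diff(col) < 0)
        start = int(drops[0]) + 1 if drops.size else n_rho
        if start < n_rho:
            col[start:] = np.minimum.accumulate(
                np.minimum(col[start:], col[start - 1])
            )


def _correction_factors(
    cgf, ray_dirs: np.ndarray, rho_all: np.ndarray, q_obs: float,
    config: SaddleConfig,
) -> np.ndarray:
    """Second-order density factors interpolated from radial anchors.

    The correction ``1 + c(w)`` varies smoothly along a ray; it is
    evaluated exactly at ``q in {0, q_obs/2, q_obs, q_obs+4}`` per
    direction and linearly interpolated in ``q = rho^2`` between the
    anchors (held constant beyond the last one).  Factors are clipped
    to a positive window: the asymptotic series is not trusted where
    it would swing harder than that.
    """
    d = ray_dirs.shape[1]
    c0 = float(cgf.correction(np.zeros((1, 2 * d)))[0])
    anchor_q = np.array([0.5 * q_obs, q_obs, q_obs + 4.0])
    prof = cgf.profile(ray_dirs, np.sqrt(anchor_q))
    n_dir = ray_dirs.shape[0]
    x_pts = prof["x"].reshape(-1, 2 * d)
    conv = prof["converged"].reshape(-1)
    c_anchor = np.zeros(n_dir * anchor_q.size)
    if conv.any():
        c_anchor[conv] = cgf.correction(x_pts[conv])
    c_anchor = c_anchor.reshape(n_dir, anchor_q.size)
    # a non-converged anchor inherits its inner neighbour's value
    for a in range(anchor_q.size):
        fallback = np.full(n_dir, c0) if a == 0 else c_anchor[:, a - 1]
        bad = ~prof["converged"][:, a]
        c_anchor[bad, a] = fallback[bad]
    q_nodes = rho_all**2
    xp = np.concatenate(([0.0], anchor_q))
    lo, hi = config.correction_clip
    factors = np.empty((rho_all.size, n_dir))
    for j in range(n_dir):
        fp = np.concatenate(([c0], c_anchor[j]))
        factors[:, j] = np.clip(1.0 + np.interp(q_nodes, xp, fp), lo, hi)
    return factors


def tail_probability_Q(
    cgf,
    sigma: np.ndarray,
    q_obs: float,
    config: SaddleConfig | None = None,
) -> SaddlepointResult:
    """P(Q >= q_obs) by spherical-radial integration of the saddle density.

    Directions live on the Sigma-standardized sphere; the radial
    integrand ``rho^{d-1} J(rho)`` is integrated on Gauss-Legendre
    panels split at ``rho = sqrt(q_obs)``.  Points beyond the
    attainable support (no saddle solution) contribute zero mass; if
    the whole observed shell is outside the support the tail is 0 with
    a boundary flag.
    """
    config = config or getattr(cgf, "config", None) or SaddleConfig()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    d = sigma.shape[0]
    if q_obs < 0:
        raise ValueError("Q_obs must be nonnegative")
    if q_obs == 0.0:
        return SaddlepointResult(q_obs=0.0, tail=1.0, mid_p=1.0)
    lmat = np.linalg.cholesky(sigma)
    dirs = _direction_set(d, config.direction_pairs(d))
    ray_dirs = dirs @ lmat.T  # unit Sigma-norm rays in w-space
    n_dir = dirs.shape[0]
    rho_q = float(np.sqrt(q_obs))

    n_norm_panels = max(2, int(np.ceil(rho_q / config.norm_panel_width)))
    norm_edges = np.linspace(0.0, rho_q, n_norm_panels + 1)
    tail_edges = rho_q + np.asarray(config.tail_panel_edges)
    rho_norm, w_norm = _gl_panels(norm_edges, config.gl_order)
    rho_tail, w_tail = _gl_panels(tail_edges, config.gl_order)
    rho_all = np.concatenate([rho_norm, rho_tail])

    prof = cgf.profile(ray_dirs, rho_all)
    conv = prof["converged"]
    logf = np.where(conv, prof["ell"] - 0.5 * prof["logdet"], -np.inf).T
    ok = (conv | prof["negligible"]).T  # (n_rho, n_dir)
    if not np.isfinite(logf).any():
        raise BoundaryError("no density point could be evaluated")
    # reference = mode value (w = 0), so spurious near-hull spikes cannot
    # shift the floor that prunes negligible mass
    ref = float(cgf.logdensity_at_zero())
    rel = np.where(
        np.isfinite(logf) & (logf - ref > config.logf_floor),
        np.exp(np.clip(logf - ref, config.logf_floor, 80.0)),
        0.0,
    )

    if config.use_correction and getattr(cgf, "supports_correction", False):
        rel *= _correction_factors(cgf, ray_dirs, rho_all, q_obs, config)

    if config.use_envelope:
        # density along a ray decays beyond its mode; clamp the spurious
        # Laplace-prefactor divergence near the support hull
        _monotone_envelope(rel)

    j_rho = rel.mean(axis=1)
    integrand = j_rho * rho_all ** (d - 1)
    n_n = rho_norm.size
    norm_int = float(w_norm @ integrand[:n_n])
    tail_int = float(w_tail @ integrand[n_n:])
    total = norm_int + tail_int
    boundary = bool((~ok[n_n:, :]).all())
    if total <= 0.0:
        raise BoundaryError("zero total mass in the radial integration")
    tail = min(1.0, max(0.0, tail_int / total))

    diag = {
        "n_points": int(rho_all.size * n_dir),
        "n_failed": int((~ok).sum()),
        "n_directions": n_dir,
        "boundary": boundary,
        "norm_mass": norm_int,
        "tail_mass": tail_int,
        "solver_iterations": prof["iterations"],
    }
    result = SaddlepointResult(
        q_obs=q_obs,
        tail=tail,
        mid_p=tail,  # continuous analytic law: no atom at q_obs
        converged=not boundary,
        diagnostics=diag,
    )
    _attach_scalar_diagnostics(result, cgf, lmat, dirs, q_obs, config)
    return result


def _attach_scalar_diagnostics(result, cgf, lmat, dirs, q_obs, config) -> None:
    """Scalar-saddle diagnostics t_hat, r, u from the radial exponent.

    The constrained max of the exponent over the shell defines
    ``l*(q)``; ``t_hat = -dl*/dq`` (Lagrange multiplier of the
    ellipsoid constraint), ``r = sign(t_hat) sqrt(-2 l*)`` and
    ``K_Q'' = -1 / (d^2 l*/dq^2)`` by implicit differentiation, giving
    the Lugannani-Rice cross-check reported in the result record.
    """
    try:
        eps = 0.02
        qs = np.array([q_obs * (1 - eps), q_obs, q_obs * (1 + eps)])
        rhos = np.sqrt(qs)
        targets = rhos[:, None, None] * (dirs @ lmat.T)[None, :, :]
        sol = cgf.solve(targets.reshape(-1, dirs.shape[1]))
        ell = np.where(sol["converged"], sol["ell"], -np.inf).reshape(3, -1)
        lstar = ell.max(axis=1)
        if not np.isfinite(lstar).all():
            return
        dq = qs[2] - qs[0]
        t_hat = -(lstar[2] - lstar[0]) / dq
        d2 = (lstar[2] - 2 * lstar[1] + lstar[0]) / (0.5 * dq) ** 2
        result.t_hat = float(t_hat)
        result.r = float(np.sign(t_hat) * np.sqrt(max(0.0, -2.0 * lstar[1])))
        result.iterations = int(sol["iterations"])
        if d2 < 0:
            kq2 = -1.0 / d2
            result.u = float(t_hat * np.sqrt(kq2))
            result.p_lugannani_rice = lugannani_rice(result.r, result.u)
    except Exception:  # diagnostics must never break the tail computation
        return


def saddlepoint_tail(
    c: ClusterScoreVector | np.ndarray,
    spec: DesignSpec,
    q_obs: float,
    config: SaddleConfig | None = None,
) -> SaddlepointResult:
    """Convenience wrapper: build the urn CGF and compute P(Q >= q_obs)."""
    cgf = build_cgf(c, spec, config)
    result = tail_probability_Q(cgf, cgf.sigma, q_obs, config or cgf.config)
    return result
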