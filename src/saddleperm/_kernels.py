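"""Numba kernels for the joint saddle equation and density corrections.

One point = one target ``(w, n)`` for the joint CGF of (statistic
coordinates, count coordinates) under independent multinomial labels:

    K(s, phi) = sum_c log( sum_j p_j exp(s_j C_c [j<k] + phi_j [j<k]) ).

Each point runs a damped Newton iteration on the strictly convex dual
``h(x) = K(x) - x' target``; the minimum value is the conditional
log-density exponent.  Status codes: 0 converged, 1 negligible mass
(dual descended below the floor; the point cannot influence the tail
ratio), 2 failed (target on/outside the attainable hull).

``correction_points`` evaluates the standard second-order saddlepoint
density factor ``1 + kappa4/8 - (2 kappa13 + 3 kappa23)/24`` from the
third/fourth cumulant tensors of the tilted label distribution,
contracted through the inverse Hessian (computed in standardized
coordinates via triangular solves).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_CONVERGED = 0
STATUS_NEGLIGIBLE = 1
STATUS_FAILED = 2


@njit(cache=False)
def _eval_k(scores, logp, s, phi, k_only, grad, probs):
    """K(s, phi); fills grad and per-cluster label probs when k_only is False."""
    n = scores.size
    k = logp.size
    d = k - 1
    kval = 0.0
    if not k_only:
        for j in range(2 * d):
            grad[j] = 0.0
    logits = np.empty(k)
    for c in range(n):
        mx = -1e308
        for j in range(d):
            logits[j] = s[j] * scores[c] + phi[j] + logp[j]
            if logits[j] > mx:
                mx = logits[j]
        logits[d] = logp[d]
        if logits[d] > mx:
            mx = logits[d]
        tot = 0.0
        for j in range(k):
            logits[j] = np.exp(logits[j] - mx)
            tot += logits[j]
        kval += mx + np.log(tot)
        if not k_only:
            for j in range(k):
                probs[c, j] = logits[j] / tot
            for j in range(d):
                grad[j] += scores[c] * probs[c, j]
                grad[d + j] += probs[c, j]
    return kval


@njit(cache=False)
def _build_hess(scores, probs, hess):
    n, k = probs.shape
    d = k - 1
    for a in range(2 * d):
        for b in range(2 * d):
            hess[a, b] = 0.0
    for c in range(n):
        cc = scores[c]
        for j in range(d):
            pj = probs[c, j]
            hess[j, j] += cc * cc * pj
            hess[j, d + j] += cc * pj
            hess[d + j, d + j] += pj
            for l in range(d):
                pl = probs[c, l]
                hess[j, l] -= cc * cc * pj * pl
                hess[j, d + l] -= cc * pj * pl
                hess[d + j, d + l] -= pj * pl
    for j in range(d):
        for l in range(d):
            hess[d + j, l] = hess[l, d + j]


@njit(cache=False)
def _chol(a, lmat):
    """Cholesky of a (small) SPD matrix; returns False on failure."""
    nn = a.shape[0]
    for i in range(nn):
        for j in range(i + 1):
            acc = a[i, j]
            for p in range(j):
                acc -= lmat[i, p] * lmat[j, p]
            if i == j:
                if acc <= 0.0:
                    return False
                lmat[i, i] = np.sqrt(acc)
            else:
                lmat[i, j] = acc / lmat[j, j]
    return True


@njit(cache=False)
def _chol_solve(lmat, b, out):
    nn = lmat.shape[0]
    for i in range(nn):
        acc = b[i]
        for p in range(i):
            acc -= lmat[i, p] * out[p]
        out[i] = acc / lmat[i, i]
    for i in range(nn - 1, -1, -1):
        acc = out[i]
        for p in range(i + 1, nn):
            acc -= lmat[p, i] * out[p]
        out[i] = acc / lmat[i, i]


@njit(cache=False)
def solve_points(
    scores,
    logp,
    counts,
    targets_w,
    tol_rel,
    maxiter,
    max_halvings,
    negligible_floor,
):
    """Damped Newton for every target; see module docstring for statuses."""
    m = targets_w.shape[0]
    k = logp.size
    d = k - 1
    n = scores.size
    dim = 2 * d
    x_out = np.zeros((m, dim))
    ell = np.full(m, -np.inf)
    logdet = np.full(m, np.nan)
    status = np.full(m, STATUS_FAILED, dtype=np.int8)
    iters = np.zeros(m, dtype=np.int32)

    target = np.empty(dim)
    x = np.empty(dim)
    x_t = np.empty(dim)
    grad = np.empty(dim)
    dummy_grad = np.empty(dim)
    probs = np.empty((n, k))
    dummy_probs = np.empty((1, 1))
    hess = np.empty((dim, dim))
    lmat = np.empty((dim, dim))
    step = np.empty(dim)
    resid = np.empty(dim)

    for b in range(m):
        tmax = 0.0
        for j in range(d):
            target[j] = targets_w[b, j]
            target[d + j] = counts[j]
        for j in range(dim):
            if abs(target[j]) > tmax:
                tmax = abs(target[j])
        tol = tol_rel * (1.0 + tmax)
        for j in range(dim):
            x[j] = 0.0
        kval = _eval_k(scores, logp, x[:d], x[d:], False, grad, probs)
        hval = kval
        for j in range(dim):
            hval -= x[j] * target[j]
        done = False
        for it in range(maxiter):
            iters[b] = it + 1
            rmax = 0.0
            for j in range(dim):
                resid[j] = target[j] - grad[j]
                if abs(resid[j]) > rmax:
                    rmax = abs(resid[j])
            if rmax < tol:
                status[b] = STATUS_CONVERGED
                done = True
                break
            if hval < negligible_floor:
                status[b] = STATUS_NEGLIGIBLE
                done = True
                break
            _build_hess(scores, probs, hess)
            tr = 0.0
            for j in range(dim):
                tr += hess[j, j]
            for j in range(dim):
                hess[j, j] += 1e-12 * tr / dim
            if not _chol(hess, lmat):
                for j in range(dim):
                    hess[j, j] += 1e-8 * tr / dim
                if not _chol(hess, lmat):
                    break  # failed
            _chol_solve(lmat, resid, step)
            alpha = 1.0
            accepted = False
            for _ in range(max_halvings):
                sane = True
                for j in range(dim):
                    x_t[j] = x[j] + alpha * step[j]
                    if abs(x_t[j]) > 1e6:
                        sane = False
                if sane:
                    k_t = _eval_k(
                        scores, logp, x_t[:d], x_t[d:], True, dummy_grad, dummy_probs
                    )
                    h_t = k_t
                    for j in range(dim):
                        h_t -= x_t[j] * target[j]
                    if np.isfinite(h_t) and h_t <= hval + 1e-12 * (1.0 + abs(hval)):
                        accepted = True
                        break
                alpha *= 0.5
            if not accepted:
                break  # failed (hull boundary)
            for j in range(dim):
                x[j] = x_t[j]
            kval = _eval_k(scores, logp, x[:d], x[d:], False, grad, probs)
            hval = kval
            for j in range(dim):
                hval -= x[j] * target[j]
        for j in range(dim):
            x_out[b, j] = x[j]
        ell[b] = hval
        if status[b] == STATUS_CONVERGED:
            _build_hess(scores, probs, hess)
            if _chol(hess, lmat):
                ld = 0.0
                for j in range(dim):
                    ld += 2.0 * np.log(lmat[j, j])
                logdet[b] = ld
            else:
                status[b] = STATUS_FAILED
    return x_out, ell, logdet, status, iters


@njit(cache=False)
def solve_rays(
    scores,
    logp,
    counts,
    ray_dirs,
    rhos,
    tol_rel,
    maxiter,
    max_halvings,
    negligible_floor,
):
    """Saddle solves along rays ``w = rho * ray_dirs[i]`` with continuation.

    Radial nodes are processed in ascending order per direction, warm
    starting each Newton run from the previous node's solution; this
    cuts the iteration count several-fold.  Once a node on a ray is
    negligible or fails, the remaining (larger-radius) nodes inherit
    that status: the dual minimum is nonincreasing along the ray.
    """
    n_dir = ray_dirs.shape[0]
    n_rho = rhos.size
    k = logp.size
    d = k - 1
    n = scores.size
    dim = 2 * d
    x_out = np.zeros((n_dir, n_rho, dim))
    ell = np.full((n_dir, n_rho), -np.inf)
    logdet = np.full((n_dir, n_rho), np.nan)
    status = np.full((n_dir, n_rho), STATUS_FAILED, dtype=np.int8)
    total_iters = 0

    target = np.empty(dim)
    x = np.empty(dim)
    x_t = np.empty(dim)
    grad = np.empty(dim)
    dummy_grad = np.empty(dim)
    probs = np.empty((n, k))
    dummy_probs = np.empty((1, 1))
    hess = np.empty((dim, dim))
    lmat = np.empty((dim, dim))
    step = np.empty(dim)
    resid = np.empty(dim)

    for idir in range(n_dir):
        for j in range(dim):
            x[j] = 0.0
        ray_dead = False
        dead_status = STATUS_FAILED
        for irho in range(n_rho):
            if ray_dead:
                status[idir, irho] = dead_status
                continue
            for j in range(d):
                target[j] = rhos[irho] * ray_dirs[idir, j]
                target[d + j] = counts[j]
            tmax = 0.0
            for j in range(dim):
                if abs(target[j]) > tmax:
                    tmax = abs(target[j])
            tol = tol_rel * (1.0 + tmax)
            kval = _eval_k(scores, logp, x[:d], x[d:], False, grad, probs)
            hval = kval
            for j in range(dim):
                hval -= x[j] * target[j]
            solved = False
            for _ in range(maxiter):
                total_iters += 1
                rmax = 0.0
                for j in range(dim):
                    resid[j] = target[j] - grad[j]
                    if abs(resid[j]) > rmax:
                        rmax = abs(resid[j])
                if rmax < tol:
                    status[idir, irho] = STATUS_CONVERGED
                    solved = True
                    break
                if hval < negligible_floor:
                    status[idir, irho] = STATUS_NEGLIGIBLE
                    ray_dead = True
                    dead_status = STATUS_NEGLIGIBLE
                    break
                _build_hess(scores, probs, hess)
                tr = 0.0
                for j in range(dim):
                    tr += hess[j, j]
                for j in range(dim):
                    hess[j, j] += 1e-12 * tr / dim
                if not _chol(hess, lmat):
                    for j in range(dim):
                        hess[j, j] += 1e-8 * tr / dim
                    if not _chol(hess, lmat):
                        break
                _chol_solve(lmat, resid, step)
                alpha = 1.0
                accepted = False
                for _ in range(max_halvings):
                    sane = True
                    for j in range(dim):
                        x_t[j] = x[j] + alpha * step[j]
                        if abs(x_t[j]) > 1e6:
                            sane = False
                    if sane:
                        k_t = _eval_k(
                            scores, logp, x_t[:d], x_t[d:], True,
                            dummy_grad, dummy_probs,
                        )
                        h_t = k_t
                        for j in range(dim):
                            h_t -= x_t[j] * target[j]
                        if np.isfinite(h_t) and h_t <= hval + 1e-12 * (1.0 + abs(hval)):
                            accepted = True
                            break
                    alpha *= 0.5
                if not accepted:
                    break
                for j in range(dim):
                    x[j] = x_t[j]
                kval = _eval_k(scores, logp, x[:d], x[d:], False, grad, probs)
                hval = kval
                for j in range(dim):
                    hval -= x[j] * target[j]
            if solved:
                for j in range(dim):
                    x_out[idir, irho, j] = x[j]
                ell[idir, irho] = hval
                _build_hess(scores, probs, hess)
                if _chol(hess, lmat):
                    ld = 0.0
                    for j in range(dim):
                        ld += 2.0 * np.log(lmat[j, j])
                    logdet[idir, irho] = ld
                else:
                    status[idir, irho] = STATUS_FAILED
            elif status[idir, irho] == STATUS_NEGLIGIBLE:
                ell[idir, irho] = hval
            else:
                ray_dead = True
                dead_status = STATUS_FAILED
                # reset warm start for safety (ray is done anyway)
                for j in range(dim):
                    x[j] = 0.0
    return x_out, ell, logdet, status, total_iters


@njit(cache=False)
def correction_points(scores, logp, counts, x_points):
    """Second-order density factor ``1 + k4/8 - (2 k13 + 3 k23)/24``.

    ``x_points`` holds converged saddle coordinates.  Cumulant tensors
    of the tilted per-cluster label law are contracted through the
    inverse joint Hessian by moving to standardized coordinates
    (triangular solves against the Cholesky factor).
    """
    m = x_points.shape[0]
    k = logp.size
    d = k - 1
    n = scores.size
    dim = 2 * d
    out = np.zeros(m)

    probs = np.empty((n, k))
    grad = np.empty(dim)
    hess = np.empty((dim, dim))
    lmat = np.empty((dim, dim))
    feat = np.empty((k, dim))
    y = np.empty((k, dim))
    mu = np.empty(dim)
    tvec = np.empty((dim, dim, dim))
    uvec = np.empty(dim)

    for b in range(m):
        s = x_points[b, :d]
        phi = x_points[b, d:]
        _eval_k(scores, logp, s, phi, False, grad, probs)
        _build_hess(scores, probs, hess)
        tr = 0.0
        for j in range(dim):
            tr += hess[j, j]
        for j in range(dim):
            hess[j, j] += 1e-12 * tr / dim
        if not _chol(hess, lmat):
            out[b] = 0.0
            continue
        k4 = 0.0
        for a in range(dim):
            for bb in range(dim):
                for cc in range(dim):
                    tvec[a, bb, cc] = 0.0
        for c in range(n):
            # features per label in joint coordinates
            for j in range(k):
                for a in range(dim):
                    feat[j, a] = 0.0
            for j in range(d):
                feat[j, j] = scores[c]
                feat[j, d + j] = 1.0
            for a in range(dim):
                mu[a] = 0.0
                for j in range(k):
                    mu[a] += probs[c, j] * feat[j, a]
            # standardized centered features: y = L^{-1} (f - mu)
            for j in range(k):
                for a in range(dim):
                    acc = feat[j, a] - mu[a]
                    for p in range(a):
                        acc -= lmat[a, p] * y[j, p]
                    y[j, a] = acc / lmat[a, a]
            # fourth-cumulant contraction per cluster
            t_c = 0.0
            s4 = 0.0
            for j in range(k):
                nrm = 0.0
                for a in range(dim):
                    nrm += y[j, a] * y[j, a]
                t_c += probs[c, j] * nrm
                s4 += probs[c, j] * nrm * nrm
            frob = 0.0
            for j in range(k):
                for l in range(k):
                    dot = 0.0
                    for a in range(dim):
                        dot += y[j, a] * y[l, a]
                    frob += probs[c, j] * probs[c, l] * dot * dot
            k4 += s4 - t_c * t_c - 2.0 * frob
            # third-cumulant tensor accumulation (central => exact cumulant)
            for j in range(k):
                pj = probs[c, j]
                for a in range(dim):
                    ya = pj * y[j, a]
                    for bb in range(dim):
                        yab = ya * y[j, bb]
                        for cc in range(dim):
                            tvec[a, bb, cc] += yab * y[j, cc]
        k13 = 0.0
        for a in range(dim):
            for bb in range(dim):
                for cc in range(dim):
                    k13 += tvec[a, bb, cc] * tvec[a, bb, cc]
        k23 = 0.0
        for cc in range(dim):
            acc = 0.0
            for a in range(dim):
                acc += tvec[a, a, cc]
            uvec[cc] = acc
        for cc in range(dim):
            k23 += uvec[cc] * uvec[cc]
        out[b] = k4 / 8.0 - (2.0 * k13 + 3.0 * k23) / 24.0
    return out
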