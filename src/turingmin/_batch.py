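"""Vectorized steady-state and Jacobian kernel for the catalogue search.

The feasibility search evaluates very large batches of candidate kinetics
(one candidate = one integer stoichiometry tuple combined with one sampled
rate vector).  This module solves ``{F = 0, G = 0}`` for whole batches at
once: the variable v is eliminated through the appropriate resultant for the
class's fixed monomial support, the univariate polynomial is solved by
batched companion-matrix eigenvalues, and candidate roots are polished by a
vectorized 2-D Newton iteration.  Accuracy on any individual candidate is
secondary -- every witness the search reports is re-verified afterwards by
the scalar path in :mod:`turingmin.kinetics` / :mod:`turingmin.stability`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["batched_candidates", "batched_jacobians"]

_EPS = 1e-12


def _conv(p, q):
    """Batched polynomial product along the last axis (ascending coeffs)."""
    B = p.shape[0]
    out = np.zeros((B, p.shape[1] + q.shape[1] - 1))
    for i in range(p.shape[1]):
        for j in range(q.shape[1]):
            out[:, i + j] += p[:, i] * q[:, j]
    return out


def _batched_real_roots(C):
    """Real roots of batched ascending-coefficient polynomials.

    ``C`` has shape (B, D+1).  Returns (B, D) array padded with NaN.  Rows
    whose leading coefficient is negligible relative to the row scale are
    deflated to the lower degree.
    """
    B, D1 = C.shape
    D = D1 - 1
    out = np.full((B, max(D, 1)), np.nan)
    if D == 0 or B == 0:
        return out
    scale = np.abs(C).max(axis=1)
    ok = scale > 0
    # group rows by effective degree
    eff = np.zeros(B, dtype=int)
    for d in range(D, 0, -1):
        mask = ok & (eff == 0) & (np.abs(C[:, d]) > _EPS * scale)
        eff[mask] = d
    for d in range(1, D + 1):
        rows = np.nonzero(eff == d)[0]
        if rows.size == 0:
            continue
        c = C[rows, : d + 1] / C[rows, d][:, None]
        if d == 1:
            out[rows, 0] = -c[:, 0]
            continue
        if d == 2:
            disc = c[:, 1] ** 2 - 4 * c[:, 0]
            sq = np.sqrt(np.maximum(disc, 0.0))
            r1 = (-c[:, 1] + sq) / 2
            r2 = (-c[:, 1] - sq) / 2
            bad = disc < 0
            r1[bad] = np.nan
            r2[bad] = np.nan
            out[rows, 0] = r1
            out[rows, 1] = r2
            continue
        comp = np.zeros((rows.size, d, d))
        idx = np.arange(d - 1)
        comp[:, idx + 1, idx] = 1.0
        comp[:, :, d - 1] = -c[:, :d]
        ev = np.linalg.eigvals(comp)
        real = np.where(np.abs(ev.imag) < 1e-7 * (1 + np.abs(ev.real)),
                        ev.real, np.nan)
        out[rows, :d] = real
    return out


def _polyval_b(C, u):
    """Evaluate batched ascending polynomials C (B, D+1) at u (B,)."""
    res = np.zeros_like(u)
    for d in range(C.shape[1] - 1, -1, -1):
        res = res * u + C[:, d]
    return res


def _support_degree(support_a, support_v2, support_v1):
    if support_v2:
        return 2
    if support_v1:
        return 1
    return 0


def batched_candidates(a, b, support_a, support_b):
    """Candidate steady-state roots for batched kinetics.

    Parameters
    ----------
    a, b
        Arrays (B, 6) of kinetic coefficients in the monomial order
        ``1, u, v, u^2, uv, v^2``.
    support_a, support_b
        Boolean 6-vectors marking which monomials can be non-zero for this
        class (fixed by the qualitative types).

    Returns
    -------
    idx, u, v
        Flat candidate arrays: ``idx`` maps each (possibly polished-away)
        candidate back to its batch row.
    """
    A0 = a[:, [0, 1, 3]]
    A1 = a[:, [2, 4]]
    A2 = a[:, 5]
    B0 = b[:, [0, 1, 3]]
    B1 = b[:, [2, 4]]
    B2 = b[:, 5]
    dF = _support_degree(support_a, support_a[5], support_a[2] or support_a[4])
    dG = _support_degree(support_b, support_b[5], support_b[2] or support_b[4])
    if dF < dG:
        A0, A1, A2, B0, B1, B2 = B0, B1, B2, A0, A1, A2
        dF, dG = dG, dF

    Bn = a.shape[0]
    if dG == 0 and dF == 0:
        # neither polynomial involves v: no isolated roots to report
        return (np.zeros(0, dtype=int), np.zeros(0), np.zeros(0))

    if dG == 0:
        roots = _batched_real_roots(B0)
        idx = np.repeat(np.arange(Bn), roots.shape[1])
        u = roots.ravel()
        keep = np.isfinite(u) & (u > 0)
        idx, u = idx[keep], u[keep]
        # v from the (at most quadratic) polynomial F(u, .)
        c0 = _polyval_b(A0[idx], u)
        c1 = _polyval_b(A1[idx], u)
        c2 = A2[idx]
        us, idxs, vs = [], [], []
        quad = np.abs(c2) > _EPS
        disc = c1**2 - 4 * c2 * c0
        sq = np.sqrt(np.maximum(disc, 0.0))
        for sign in (1.0, -1.0):
            vq = np.where(quad & (disc >= 0), (-c1 + sign * sq) / np.where(quad, 2 * c2, 1.0), np.nan)
            vl = np.where(~quad & (np.abs(c1) > _EPS), -c0 / np.where(np.abs(c1) > _EPS, c1, 1.0), np.nan)
            v = np.where(quad, vq, vl)
            keep2 = np.isfinite(v)
            idxs.append(idx[keep2])
            us.append(u[keep2])
            vs.append(v[keep2])
            if not quad.any():
                break
        return np.concatenate(idxs), np.concatenate(us), np.concatenate(vs)

    if dF == 1:  # (1, 1)
        R = _conv(A1, B0) - _conv(A0, B1)  # degree <= 3
        roots = _batched_real_roots(R)
        idx = np.repeat(np.arange(Bn), roots.shape[1])
        u = roots.ravel()
        keep = np.isfinite(u) & (u > 0)
        idx, u = idx[keep], u[keep]
        a1 = _polyval_b(A1[idx], u)
        b1 = _polyval_b(B1[idx], u)
        use_a = np.abs(a1) >= np.abs(b1)
        den = np.where(use_a, a1, b1)
        num = np.where(use_a, _polyval_b(A0[idx], u), _polyval_b(B0[idx], u))
        good = np.abs(den) > _EPS
        v = np.where(good, -num / np.where(good, den, 1.0), np.nan)
        keep2 = np.isfinite(v)
        return idx[keep2], u[keep2], v[keep2]

    if dG == 1:  # (2, 1)
        R = (_conv(A2[:, None] * B0, B0)
             - _conv(A1, _conv(B0, B1))
             + _conv(A0, _conv(B1, B1)))  # degree <= 4
        roots = _batched_real_roots(R)
        idx = np.repeat(np.arange(Bn), roots.shape[1])
        u = roots.ravel()
        keep = np.isfinite(u) & (u > 0)
        idx, u = idx[keep], u[keep]
        b1 = _polyval_b(B1[idx], u)
        good = np.abs(b1) > _EPS
        v = np.where(good, -_polyval_b(B0[idx], u) / np.where(good, b1, 1.0), np.nan)
        keep2 = np.isfinite(v)
        return idx[keep2], u[keep2], v[keep2]

    # (2, 2): Sylvester resultant of two quadratics in v
    P = A2[:, None] * B0 - B2[:, None] * A0          # degree 2
    Q = A2[:, None] * B1 - B2[:, None] * A1          # degree 1
    S = _conv(A1, B0) - _conv(A0, B1)                # degree 3
    R = _conv(P, P) - _conv(Q, S)  # both (B, 5): degree 4
    roots = _batched_real_roots(R)
    idx = np.repeat(np.arange(Bn), roots.shape[1])
    u = roots.ravel()
    keep = np.isfinite(u) & (u > 0)
    idx, u = idx[keep], u[keep]
    qv = _polyval_b(Q[idx], u)
    good = np.abs(qv) > _EPS
    v = np.where(good, -_polyval_b(P[idx], u) / np.where(good, qv, 1.0), np.nan)
    keep2 = np.isfinite(v)
    return idx[keep2], u[keep2], v[keep2]


def newton_polish_batch(a, b, idx, u, v, iters=6):
    """Vectorized 2-D Newton refinement of candidate roots."""
    ai = a[idx]
    bi = b[idx]
    for _ in range(iters):
        f = (ai[:, 0] + ai[:, 1] * u + ai[:, 2] * v + ai[:, 3] * u * u
             + ai[:, 4] * u * v + ai[:, 5] * v * v)
        g = (bi[:, 0] + bi[:, 1] * u + bi[:, 2] * v + bi[:, 3] * u * u
             + bi[:, 4] * u * v + bi[:, 5] * v * v)
        fu = ai[:, 1] + 2 * ai[:, 3] * u + ai[:, 4] * v
        fv = ai[:, 2] + ai[:, 4] * u + 2 * ai[:, 5] * v
        gu = bi[:, 1] + 2 * bi[:, 3] * u + bi[:, 4] * v
        gv = bi[:, 2] + bi[:, 4] * u + 2 * bi[:, 5] * v
        det = fu * gv - fv * gu
        ok = np.abs(det) > 1e-300
        det = np.where(ok, det, 1.0)
        du = np.where(ok, (f * gv - g * fv) / det, 0.0)
        dv = np.where(ok, (g * fu - f * gu) / det, 0.0)
        u = u - du
        v = v - dv
    f = (ai[:, 0] + ai[:, 1] * u + ai[:, 2] * v + ai[:, 3] * u * u
         + ai[:, 4] * u * v + ai[:, 5] * v * v)
    g = (bi[:, 0] + bi[:, 1] * u + bi[:, 2] * v + bi[:, 3] * u * u
         + bi[:, 4] * u * v + bi[:, 5] * v * v)
    res = np.maximum(np.abs(f), np.abs(g))
    return u, v, res


def batched_jacobians(a, b, idx, u, v):
    """Jacobian entries for flat candidate arrays."""
    ai = a[idx]
    bi = b[idx]
    j11 = ai[:, 1] + 2 * ai[:, 3] * u + ai[:, 4] * v
    j12 = ai[:, 2] + ai[:, 4] * u + 2 * ai[:, 5] * v
    j21 = bi[:, 1] + 2 * bi[:, 3] * u + bi[:, 4] * v
    j22 = bi[:, 2] + bi[:, 4] * u + 2 * bi[:, 5] * v
    return j11, j12, j21, j22
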