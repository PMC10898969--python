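"""Mass-action kinetics: reaction polynomials F, G and positive steady states.

A scheme of elementary reactions compiles to a pair of bivariate quadratics

    F(u, v) = a1 + a2 u + a3 v + a4 u^2 + a5 u v + a6 v^2
    G(u, v) = b1 + b2 u + b3 v + b4 u^2 + b5 u v + b6 v^2

where each reaction contributes ``r * s1`` (resp. ``r * s2``) to the
coefficient of its reactant monomial ``u^p v^q`` in F (resp. G).  Because a
reaction can only remove particles it consumes, the coefficients
``a1, a3, a6`` and ``b1, b2, b4`` are always non-negative.

Positive homogeneous steady states are the isolated roots of
``{F = 0, G = 0}`` with ``u, v > 0``.  They are found by eliminating one
variable through a polynomial resultant, solving the resulting univariate
polynomial by companion matrix, back-substituting, and polishing with a full
2-D Newton iteration; every accepted root is verified by its residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reactions import ReactionScheme

__all__ = [
    "KineticCoefficients",
    "SteadyState",
    "DegenerateSystemError",
    "compile_scheme",
    "positive_steady_states",
]

#: monomial exponent order (p, q) for coefficients 1..6
MONOMIALS = ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2))

_ROOT_TOL = 1e-12       # relative acceptance tolerance for polished roots
_RESIDUAL_TOL = 1e-9    # absolute residual bound on the unit coefficient scale


class DegenerateSystemError(ValueError):
    """F and G share a curve of zeros: the steady-state set is not isolated."""


@dataclass(frozen=True)
class KineticCoefficients:
    """The twelve polynomial coefficients of the reaction terms F and G."""

    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(float(x) for x in self.a))
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if len(self.a) != 6 or len(self.b) != 6:
            raise ValueError("need six coefficients for each of F and G")

    def f(self, u: float, v: float) -> float:
        a = self.a
        return a[0] + a[1] * u + a[2] * v + a[3] * u * u + a[4] * u * v + a[5] * v * v

    def g(self, u: float, v: float) -> float:
        b = self.b
        return b[0] + b[1] * u + b[2] * v + b[3] * u * u + b[4] * u * v + b[5] * v * v

    def f_u(self, u: float, v: float) -> float:
        a = self.a
        return a[1] + 2 * a[3] * u + a[4] * v

    def f_v(self, u: float, v: float) -> float:
        a = self.a
        return a[2] + a[4] * u + 2 * a[5] * v

    def g_u(self, u: float, v: float) -> float:
        b = self.b
        return b[1] + 2 * b[3] * u + b[4] * v

    def g_v(self, u: float, v: float) -> float:
        b = self.b
        return b[2] + b[4] * u + 2 * b[5] * v

    @property
    def scale(self) -> float:
        """Largest coefficient magnitude (used to scale tolerances)."""
        return max(1e-300, max(abs(x) for x in self.a + self.b))


@dataclass(frozen=True)
class SteadyState:
    """A positive homogeneous steady state with its verified residual."""

    u_star: float
    v_star: float
    residual: float


def compile_scheme(scheme: ReactionScheme) -> KineticCoefficients:
    """Compile a scheme to its mass-action coefficients (additive in reactions)."""
    a = [0.0] * 6
    b = [0.0] * 6
    index = {pq: j for j, pq in enumerate(MONOMIALS)}
    for rxn in scheme.reactions:
        j = index[(rxn.p, rxn.q)]
        a[j] += rxn.rate * rxn.s1
        b[j] += rxn.rate * rxn.s2
    return KineticCoefficients(tuple(a), tuple(b))


# ---------------------------------------------------------------------------
# polynomial helpers (ascending coefficient arrays, trimmed)
# ---------------------------------------------------------------------------

def _trim(c: np.ndarray, tol: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    nz = np.nonzero(np.abs(c) > tol)[0]
    if nz.size == 0:
        return np.zeros(0)
    return c[: nz[-1] + 1]


def _polyroots(c: np.ndarray) -> np.ndarray:
    """Real roots of an ascending-coefficient polynomial via companion matrix."""
    if c.size <= 1:
        return np.zeros(0)
    roots = np.polynomial.polynomial.polyroots(c)
    real = roots[np.abs(roots.imag) < 1e-7 * (1 + np.abs(roots.real))].real
    return np.asarray(real, dtype=float)


def _v_slices(k: KineticCoefficients, which: str):
    """Coefficients of F (or G) viewed as a polynomial in v: (A0(u), A1(u), A2)."""
    c = k.a if which == "f" else k.b
    A0 = np.array([c[0], c[1], c[3]])  # 1, u, u^2
    A1 = np.array([c[2], c[4]])        # v, uv
    A2 = np.array([c[5]])              # v^2
    return A0, A1, A2


def _deg_v(A0, A1, A2, tol) -> int:
    if np.abs(A2).max() > tol:
        return 2
    if np.abs(A1).max() > tol:
        return 1
    return 0


def _newton_polish(k: KineticCoefficients, u: float, v: float, iters: int = 12):
    for _ in range(iters):
        f, g = k.f(u, v), k.g(u, v)
        fu, fv, gu, gv = k.f_u(u, v), k.f_v(u, v), k.g_u(u, v), k.g_v(u, v)
        det = fu * gv - fv * gu
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        du = (f * gv - g * fv) / det
        dv = (g * fu - f * gu) / det
        u, v = u - du, v - dv
        if abs(du) <= _ROOT_TOL * (1 + abs(u)) and abs(dv) <= _ROOT_TOL * (1 + abs(v)):
            break
    return u, v


def _resultant_u(k: KineticCoefficients, tol: float):
    """Eliminate v: return the resultant polynomial in u and a back-substitution.

    Returns ``(R, subst)`` where ``R`` is an ascending coefficient array and
    ``subst(u)`` yields candidate v values for a given root u.  Raises
    :class:`DegenerateSystemError` when the resultant vanishes identically.
    """
    pm = np.polynomial.polynomial
    A0, A1, A2 = _v_slices(k, "f")
    B0, B1, B2 = _v_slices(k, "g")
    dF = _deg_v(A0, A1, A2, tol)
    dG = _deg_v(B0, B1, B2, tol)
    if dF < dG:  # ensure deg_v F >= deg_v G
        (A0, A1, A2, dF), (B0, B1, B2, dG) = (B0, B1, B2, dG), (A0, A1, A2, dF)

    def _v_from_quadratic(u, C0, C1, C2):
        c0 = pm.polyval(u, C0)
        c1 = pm.polyval(u, C1)
        c2 = C2[0]
        if abs(c2) > tol:
            disc = c1 * c1 - 4 * c2 * c0
            if disc < 0:
                return []
            sq = np.sqrt(disc)
            return [(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)]
        if abs(c1) > tol:
            return [-c0 / c1]
        return []

    if dG == 0:
        # One polynomial involves u only; its roots give u, back-substitute.
        R = _trim(B0, 0.0)
        if R.size == 0:
            raise DegenerateSystemError("one of F, G vanishes identically")
        if dF == 0:
            # Neither polynomial involves v: any common positive u-root
            # leaves v free, a positive-dimensional solution set.
            RF = _trim(A0, 0.0)
            if RF.size == 0:
                raise DegenerateSystemError("one of F, G vanishes identically")
            ru, rf = _polyroots(R), _polyroots(RF)
            for u in ru:
                if u > 0 and rf.size and np.min(np.abs(rf - u)) < 1e-8 * (1 + abs(u)):
                    raise DegenerateSystemError(
                        "F and G share a u-root and neither involves v: "
                        "steady states form a line"
                    )
            return R, (lambda u: []), 1.0

        def subst(u):
            return _v_from_quadratic(u, A0, A1, A2)

        return R, subst, 1.0

    sF = max(np.abs(A0).max(), np.abs(A1).max(), np.abs(A2).max(), 1e-300)
    sG = max(np.abs(B0).max(), np.abs(B1).max(), np.abs(B2).max(), 1e-300)

    if dF == 1:  # (1, 1)
        ref = sF * sG
        R = pm.polysub(pm.polymul(A1, B0), pm.polymul(A0, B1))

        def subst(u):
            a1 = pm.polyval(u, A1)
            if abs(a1) > tol:
                return [-pm.polyval(u, A0) / a1]
            b1 = pm.polyval(u, B1)
            if abs(b1) > tol:
                return [-pm.polyval(u, B0) / b1]
            return []

    elif dG == 1:  # (2, 1)
        ref = sF * sG * sG
        R = pm.polyadd(
            pm.polysub(
                pm.polymul(A2, pm.polymul(B0, B0)),
                pm.polymul(A1, pm.polymul(B0, B1)),
            ),
            pm.polymul(A0, pm.polymul(B1, B1)),
        )

        def subst(u):
            b1 = pm.polyval(u, B1)
            if abs(b1) > tol:
                return [-pm.polyval(u, B0) / b1]
            return _v_from_quadratic(u, A0, A1, A2)

    else:  # (2, 2): Sylvester resultant of two quadratics in v
        ref = sF * sF * sG * sG
        P = pm.polysub(pm.polymul(A2, B0), pm.polymul(A0, B2))
        Q = pm.polysub(pm.polymul(A2, B1), pm.polymul(A1, B2))
        S = pm.polysub(pm.polymul(A1, B0), pm.polymul(A0, B1))
        R = pm.polysub(pm.polymul(P, P), pm.polymul(Q, S))

        def subst(u):
            qv = pm.polyval(u, Q)
            if abs(qv) > tol:
                return [-pm.polyval(u, P) / qv]  # B2*F - A2*G = -P - Q v = 0
            return _v_from_quadratic(u, A0, A1, A2)

    R = _trim(R, 1e-13 * np.abs(R).max(initial=0.0))
    return R, subst, ref


def positive_steady_states(
    k: KineticCoefficients, tol: float = 1e-9
) -> list[SteadyState]:
    """All isolated positive roots of {F=0, G=0}, sorted by u ascending.

    Parameters
    ----------
    k
        Compiled kinetic coefficients; must not all be zero.
    tol
        Positivity threshold: roots with ``u`` or ``v`` below ``tol`` are
        discarded as boundary states.

    Raises
    ------
    DegenerateSystemError
        When F and G share a common curve of zeros (positive-dimensional
        solution set), which cannot be reported as isolated roots.
    """
    scale = k.scale
    if scale <= 1e-300 or all(x == 0 for x in k.a + k.b):
        raise ValueError("all kinetic coefficients are zero")
    eps = 1e-13 * scale

    R, subst, ref = _resultant_u(k, eps)
    if R.size == 0 or np.abs(R).max(initial=0.0) <= 1e-10 * ref:
        raise DegenerateSystemError(
            "the resultant of F and G vanishes identically: "
            "the steady-state set is positive-dimensional"
        )

    candidates: list[tuple[float, float]] = []
    for u in _polyroots(R):
        if u <= 0:
            continue
        for v in subst(float(u)):
            if np.isfinite(v):
                candidates.append((float(u), float(v)))

    accepted: list[SteadyState] = []
    for u0, v0 in candidates:
        u, v = _newton_polish(k, u0, v0)
        if not (np.isfinite(u) and np.isfinite(v)):
            continue
        if u <= tol or v <= tol:
            continue
        local = scale * max(1.0, u, v) ** 2
        res = max(abs(k.f(u, v)), abs(k.g(u, v)))
        if res > _RESIDUAL_TOL * local:
            continue
        if any(
            abs(u - s.u_star) <= 1e-7 * (1 + abs(u))
            and abs(v - s.v_star) <= 1e-7 * (1 + abs(v))
            for s in accepted
        ):
            continue
        accepted.append(SteadyState(u, v, res))

    accepted.sort(key=lambda s: s.u_star)
    return accepted
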