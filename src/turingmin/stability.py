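"""Linear stability analysis: Turing-instability decision and dispersion relation.

About a positive homogeneous steady state ``(u*, v*)`` the linearized
dynamics are governed by the Jacobian ``J*`` of ``(F, G)``.  A scheme is
*Turing-unstable* when, for some rates, ``J*`` satisfies the Routh-Hurwitz
conditions ``tr(J*) < 0``, ``det(J*) > 0`` together with the stricter sign
requirement ``J12* J21* < J11* J22* < 0``; adding unequal diffusion then
destabilizes a band of wavenumbers once the diffusivity ratio
``delta = Dv/Du`` exceeds the critical value

    delta_c = (sqrt(det J*) + sqrt(-J12* J21*))^2 / J11*^2

(with labels chosen so the auto-activator is U, i.e. ``J11* > 0``).  The
admissible Jacobian sign patterns split Turing patterns into type I
(in-phase peaks, pattern ``(+,-;+,-)``) and type II (anti-phase,
``(+,+;-,-)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kinetics import KineticCoefficients, SteadyState, positive_steady_states

__all__ = [
    "JacobianSummary",
    "Diffusivities",
    "TuringReport",
    "NotTuringCapableError",
    "jacobian_at",
    "classify_pattern_type",
    "delta_critical",
    "dispersion",
    "wavenumber_band",
    "growth_rate_max",
    "turing_report",
    "default_k_grid",
]

#: default margin for testing strict inequalities
MARGIN = 1e-9


class NotTuringCapableError(ValueError):
    """The Jacobian cannot produce a diffusion-driven instability."""


@dataclass(frozen=True)
class JacobianSummary:
    """Entries of the non-spatial Jacobian at a steady state."""

    j11: float
    j12: float
    j21: float
    j22: float

    @property
    def trace(self) -> float:
        return self.j11 + self.j22

    @property
    def det(self) -> float:
        return self.j11 * self.j22 - self.j12 * self.j21

    @property
    def scale(self) -> float:
        return max(abs(self.j11), abs(self.j12), abs(self.j21), abs(self.j22), 1e-300)

    def sign_pattern(self, margin: float = 0.0) -> tuple[tuple[int, int], tuple[int, int]]:
        """2x2 grid of entry signs; entries within ``margin * scale`` of zero are 0."""
        thr = margin * self.scale
        s = lambda x: 0 if abs(x) <= thr else (1 if x > 0 else -1)
        return ((s(self.j11), s(self.j12)), (s(self.j21), s(self.j22)))

    def swapped(self) -> "JacobianSummary":
        """Jacobian after relabelling the species U <-> V."""
        return JacobianSummary(self.j22, self.j21, self.j12, self.j11)

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.j11, self.j12], [self.j21, self.j22]])


@dataclass(frozen=True)
class Diffusivities:
    """Diffusion coefficients of U and V and their ratio delta = Dv/Du."""

    du: float
    dv: float

    def __post_init__(self) -> None:
        if not (self.du > 0 and self.dv > 0):
            raise ValueError("diffusivities must be positive")

    @property
    def delta(self) -> float:
        return self.dv / self.du

    def swapped(self) -> "Diffusivities":
        return Diffusivities(self.dv, self.du)


def jacobian_at(k: KineticCoefficients, ss: SteadyState) -> JacobianSummary:
    """Jacobian of (F, G) evaluated at a steady state."""
    u, v = ss.u_star, ss.v_star
    return JacobianSummary(
        k.f_u(u, v), k.f_v(u, v), k.g_u(u, v), k.g_v(u, v)
    )


def classify_pattern_type(j: JacobianSummary, margin: float = 0.0) -> str:
    """Pattern type implied by the Jacobian sign pattern: 'I', 'II' or 'none'.

    Type I is the in-phase pattern ``(+,-;+,-)``; type II the anti-phase
    pattern ``(+,+;-,-)``.  The mirrored patterns ``(-,+;-,+)`` and
    ``(-,-;+,+)`` arise from the same schemes with the species labels
    exchanged and are classified identically.  Zero entries never match.
    """
    pat = j.sign_pattern(margin)
    if pat in (((1, -1), (1, -1)), ((-1, 1), (-1, 1))):
        return "I"
    if pat in (((1, 1), (-1, -1)), ((-1, -1), (1, 1))):
        return "II"
    return "none"


def _canonical(j: JacobianSummary) -> JacobianSummary:
    """Swap species labels if needed so that the auto-activator is U."""
    if j.j11 < 0 < j.j22:
        return j.swapped()
    return j


def delta_critical(j: JacobianSummary, margin: float = MARGIN) -> float:
    """Smallest diffusivity ratio Dv/Du at which some wavenumber destabilizes.

    Requires a kinetically stable Jacobian (negative trace, positive
    determinant) with an activator-inhibitor structure
    (``J12 J21 < J11 J22 < 0``); the species are relabelled internally so
    that ``J11 > 0``.
    """
    thr = margin * j.scale
    if j.trace >= -thr:
        raise NotTuringCapableError(f"tr(J*) = {j.trace} is not negative")
    if j.det <= thr:
        raise NotTuringCapableError(f"det(J*) = {j.det} is not positive")
    j = _canonical(j)
    if not (j.j11 > thr and j.j22 < -thr):
        raise NotTuringCapableError(
            "diagonal entries must have opposite signs (one auto-activator, "
            "one auto-inhibitor)"
        )
    cross = -j.j12 * j.j21
    if cross <= thr * j.scale:
        raise NotTuringCapableError("J12* and J21* must have opposite signs")
    return (np.sqrt(j.det) + np.sqrt(cross)) ** 2 / j.j11**2


def dispersion(
    j: JacobianSummary, d: Diffusivities, k_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Growth rate lambda(k^2) and det(J~(k)) on a grid of wavenumbers.

    ``J~(k) = J* - k^2 diag(Du, Dv)``; lambda is the largest real part of
    its eigenvalues, via the closed form
    ``lambda = (tr +/- sqrt(tr^2 - 4 det))/2`` of the 2x2 eigenproblem.
    """
    k2 = np.asarray(k_grid, dtype=float) ** 2
    jt11 = j.j11 - d.du * k2
    jt22 = j.j22 - d.dv * k2
    tr = jt11 + jt22
    det = jt11 * jt22 - j.j12 * j.j21
    disc = (jt11 - jt22) ** 2 + 4 * j.j12 * j.j21
    lam = np.where(disc >= 0, (tr + np.sqrt(np.maximum(disc, 0.0))) / 2, tr / 2)
    return lam, det


def wavenumber_band(
    j: JacobianSummary, d: Diffusivities
) -> Optional[tuple[float, float]]:
    """Interval (k-, k+) of unstable wavenumbers, or None when it is empty."""
    b = d.dv * j.j11 + d.du * j.j22
    disc = b * b - 4 * d.du * d.dv * j.det
    if b <= 0 or disc <= 0:
        return None
    sq = np.sqrt(disc)
    k2m = (b - sq) / (2 * d.du * d.dv)
    k2p = (b + sq) / (2 * d.du * d.dv)
    if k2p <= 0:
        return None
    return (np.sqrt(max(k2m, 0.0)), np.sqrt(k2p))


def growth_rate_max(
    j: JacobianSummary, d: Diffusivities
) -> tuple[Optional[float], Optional[float]]:
    """(lambda_max, k_max) over the unstable band, or (None, None) if stable."""
    from scipy.optimize import minimize_scalar

    band = wavenumber_band(j, d)
    if band is None:
        return None, None
    km, kp = band

    def neg(k):
        lam, _ = dispersion(j, d, np.array([k]))
        return -lam[0]

    res = minimize_scalar(neg, bounds=(km, kp), method="bounded",
                          options={"xatol": 1e-10 * max(kp, 1.0)})
    return -res.fun, float(res.x)


def default_k_grid(j: JacobianSummary, d: Diffusivities, n: int = 512) -> np.ndarray:
    """Log-spaced wavenumber grid spanning the dynamically relevant scales."""
    k0 = np.sqrt(max(abs(j.j11), j.scale * 1e-3) / d.du)
    return k0 * np.logspace(-3, 2, n)


@dataclass(frozen=True)
class TuringReport:
    """Full linear-stability verdict for one positive steady state."""

    steady_state: SteadyState
    jacobian: JacobianSummary
    kinetically_stable: bool
    pattern_type: str                      # 'I', 'II' or 'none'
    delta_c: Optional[float] = None
    relabelled: bool = False               # species swapped so that J11 > 0
    k_minus: Optional[float] = None
    k_plus: Optional[float] = None
    lambda_max: Optional[float] = None
    k_max: Optional[float] = None

    @property
    def turing_capable(self) -> bool:
        """Unstable band exists for delta = Dv/Du in an open set."""
        return self.pattern_type != "none" and self.delta_c is not None

    @property
    def pattern_predicted(self) -> bool:
        """Unstable band exists at the diffusivities actually supplied."""
        return self.lambda_max is not None and self.lambda_max > 0


def turing_report(
    k: KineticCoefficients,
    d: Optional[Diffusivities] = None,
    margin: float = MARGIN,
    tol: float = 1e-9,
) -> list[TuringReport]:
    """Run the full pipeline and report on every positive steady state.

    For each steady state: Jacobian, Routh-Hurwitz stability, pattern-type
    classification, and (when Turing-capable) the critical ratio ``delta_c``.
    When diffusivities are supplied the unstable wavenumber band and the
    fastest-growing mode are included.
    """
    reports = []
    for ss in positive_steady_states(k, tol=tol):
        j = jacobian_at(k, ss)
        thr = margin * j.scale
        stable = j.trace < -thr and j.det > thr
        ptype = classify_pattern_type(j, margin)
        delta_c = None
        if stable and ptype != "none":
            try:
                delta_c = delta_critical(j, margin)
            except NotTuringCapableError:
                ptype = "none"
        else:
            ptype = "none" if not stable else ptype
        relabelled = j.j11 < 0 < j.j22
        km = kp = lmax = kmax = None
        if d is not None and delta_c is not None:
            jc = _canonical(j)
            dc = d if not relabelled else d.swapped()
            band = wavenumber_band(jc, dc)
            if band is not None:
                km, kp = band
                lmax, kmax = growth_rate_max(jc, dc)
        reports.append(
            TuringReport(
                steady_state=ss,
                jacobian=j,
                kinetically_stable=stable,
                pattern_type=ptype if stable else "none",
                delta_c=delta_c,
                relabelled=relabelled,
                k_minus=km,
                k_plus=kp,
                lambda_max=lmax,
                k_max=kmax,
            )
        )
    return reports
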