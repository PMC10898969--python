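"""The 25 minimal Turing-unstable scheme classes and their regime analysis.

Type-I (in-phase) patterns need three elementary reactions; there are
exactly 11 qualitatively distinct minimal classes, each of the form

    2U   --r1-->  n1 U + m1 V      (auto-amplification, n1 > 2, m1 > 0)
    U+V  --r2-->  ...              (interspecific consumption of U)
    .    --r3-->  ...              (a zeroth- or first-order closure)

and each carries a closed-form *iff* condition on the integer product
coefficients for Turing instability (for rates in an open set).  Type-II
(anti-phase) patterns need four reactions; there are exactly 14 minimal
classes, stored here as qualitative templates whose instability is
certified numerically by :mod:`turingmin.search`.

With the third-reaction rate normalized to one, the linear-instability
behaviour of every type-I class collapses onto a single regime diagram in
the rate ratio ``rho = r2/r1`` and diffusivity ratio ``delta = Dv/Du``:
the uniform state is stable to uniform perturbations only for
``rho > rho_c``, and Turing-unstable for ``delta > delta_c(rho)`` where
``delta_c`` is linear through the origin with slope ``H`` depending only on
the stoichiometric coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp

from .reactions import QualitativeType, Reaction, ReactionScheme, SchemeClass

__all__ = [
    "MinimalClass",
    "RegimeLine",
    "list_minimal_classes",
    "get_class",
    "build_scheme",
    "is_turing_unstable_typeI",
    "regime_line",
    "inf_delta_c",
    "inf_delta_c_report",
    "typeII_structural_ok",
]

_T = QualitativeType


@dataclass(frozen=True)
class MinimalClass:
    """One qualitative class of minimal Turing-unstable reaction schemes."""

    pattern_type: str                   # 'I' or 'II'
    class_id: str                       # 'I.a' ... 'II.n'
    template: SchemeClass
    description: str
    coeff_names: tuple[str, ...] = ()
    # structural bounds (name -> (lo, hi or None)); hi None means unbounded
    coeff_bounds: dict | None = None
    # closed-form iff condition over the integer coefficients (type I only)
    turing_condition: Optional[Callable[..., bool]] = None
    # scheme builder: coefficients + rates -> ReactionScheme (type I only)
    builder: Optional[Callable[..., ReactionScheme]] = None


@dataclass(frozen=True)
class RegimeLine:
    """Linear Turing boundary of a type-I class instance in the (rho, delta) plane."""

    rho_c: float                 # uniform-stability threshold of rho = r2/r1
    slope: float                 # H = d delta_c / d rho (zero intercept)
    delta_c_at_rho_c: float      # smallest delta on the instability boundary
    intercept: float             # fitted intercept of delta_c(rho); ~0 in all classes


# ---------------------------------------------------------------------------
# type-I catalogue (closed forms from the per-class steady-state analysis)
# ---------------------------------------------------------------------------

def _r(p, q, n, m, rate):
    return Reaction(p, q, int(n), int(m), float(rate))


def _rxn_template(spec, coeffs, rate):
    """Instantiate one (p, q, n, m) template; n/m may be coefficient names."""
    p, q, n, m = spec
    n = coeffs[n] if isinstance(n, str) else n
    m = coeffs[m] if isinstance(m, str) else m
    return p, q, n, m, rate


def _make_builder(rxn_specs):
    def build(c, rates):
        out = []
        for spec, rate in zip(rxn_specs, rates):
            p, q, n, m, r_ = _rxn_template(spec, c, rate)
            out.append(_r(p, q, n, m, r_))
        return ReactionScheme(tuple(out))

    return build


# Declarative templates: reactions are (p, q, n, m) with coefficient names as
# strings; rates are (r1, r2, r3) with r2 the interspecific U+V reaction.
_TYPE_I_DEFS = [
    (
        "a", "2U -> n1 U + m1 V;  U+V -> 0;  0 -> n3 U",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (0, 0, "n3", 0)),
        {"n1": (3, None), "m1": (1, None), "n3": (1, None)},
        lambda n1, m1, n3: 2 * (n1 - 2) > m1 > n1 - 2,
        {"n1": 4, "m1": 3, "n3": 1},
    ),
    (
        "b", "2U -> n1 U + m1 V;  U+V -> 0;  0 -> n3 U + m3 V",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (0, 0, "n3", "m3")),
        {"n1": (3, None), "m1": (1, None), "n3": (1, None), "m3": (1, None)},
        lambda n1, m1, n3, m3: (
            m1 > n1 - 2 and n3 > m3
            and 2 * (n1 - 2) * n3 > m1 * n3 + (n1 - 2) * m3
        ),
        {"n1": 4, "m1": 3, "n3": 3, "m3": 1},
    ),
    (
        "c", "2U -> n1 U + m1 V;  U+V -> 0;  U -> n3 U",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (1, 0, "n3", 0)),
        {"n1": (3, None), "m1": (1, None), "n3": (2, None)},
        lambda n1, m1, n3: m1 > n1 - 2,
        {"n1": 4, "m1": 3, "n3": 2},
    ),
    (
        "d", "2U -> n1 U + m1 V;  U+V -> 0;  U -> n3 U + m3 V",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (1, 0, "n3", "m3")),
        {"n1": (3, None), "m1": (1, None), "n3": (2, None), "m3": (1, None)},
        lambda n1, m1, n3, m3: m1 > n1 - 2 and n3 - 1 > m3,
        {"n1": 4, "m1": 3, "n3": 3, "m3": 1},
    ),
    (
        "e", "2U -> n1 U + m1 V;  U+V -> 0;  V -> 0",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (0, 1, 0, 0)),
        {"n1": (3, None), "m1": (1, None)},
        lambda n1, m1: m1 > n1 - 2,
        {"n1": 4, "m1": 3},
    ),
    (
        "f", "2U -> n1 U + m1 V;  U+V -> 0;  V -> n3 U",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (0, 1, "n3", 0)),
        {"n1": (3, None), "m1": (1, None), "n3": (1, None)},
        lambda n1, m1, n3: (
            m1 > n1 - 2 and (n1 - 2) * (2 * n3 + 1) > m1 * n3
        ),
        {"n1": 4, "m1": 3, "n3": 1},
    ),
    (
        "g", "2U -> n1 U + m1 V;  U+V -> 0;  V -> n3 U + V",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (0, 1, "n3", 1)),
        {"n1": (3, None), "m1": (1, None), "n3": (1, None)},
        lambda n1, m1, n3: m1 > n1 - 2 and 2 * (n1 - 2) > m1,
        {"n1": 4, "m1": 3, "n3": 1},
    ),
    (
        "h", "2U -> n1 U + m1 V;  U+V -> 0;  V -> n3 U + m3 V",
        ((2, 0, "n1", "m1"), (1, 1, 0, 0), (0, 1, "n3", "m3")),
        {"n1": (3, None), "m1": (1, None), "n3": (1, None), "m3": (2, None)},
        lambda n1, m1, n3, m3: (
            m1 > n1 - 2 and n3 > m3 - 1
            and 2 * (n1 - 2) * n3 > m1 * n3 + (n1 - 2) * (m3 - 1)
        ),
        {"n1": 5, "m1": 4, "n3": 3, "m3": 2},
    ),
    (
        "i", "2U -> n1 U + m1 V;  U+V -> V;  V -> 0",
        ((2, 0, "n1", "m1"), (1, 1, 0, 1), (0, 1, 0, 0)),
        {"n1": (3, None), "m1": (1, None)},
        lambda n1, m1: True,
        {"n1": 4, "m1": 1},
    ),
    (
        "j", "2U -> n1 U + m1 V;  U+V -> V;  V -> n3 U",
        ((2, 0, "n1", "m1"), (1, 1, 0, 1), (0, 1, "n3", 0)),
        {"n1": (3, None), "m1": (1, None), "n3": (1, None)},
        lambda n1, m1, n3: n1 - 2 > m1 * n3,
        {"n1": 4, "m1": 1, "n3": 1},
    ),
    (
        "k", "2U -> n1 U + m1 V;  U+V -> m2 V;  V -> 0",
        ((2, 0, "n1", "m1"), (1, 1, 0, "m2"), (0, 1, 0, 0)),
        {"n1": (3, None), "m1": (1, None), "m2": (2, None)},
        lambda n1, m1, m2: True,
        {"n1": 4, "m1": 4, "m2": 2},
    ),
]

_TYPE_I_TEMPLATES = {f"I.{d[0]}": d[2] for d in _TYPE_I_DEFS}

#: admissible sample coefficients used for symbolic branch selection
_TYPE_I_SAMPLES = {f"I.{d[0]}": d[5] for d in _TYPE_I_DEFS}


def _typeI_classes() -> list[MinimalClass]:
    out = []
    for letter, desc, rxns, bounds, cond, sample in _TYPE_I_DEFS:
        builder = _make_builder(rxns)
        scheme = builder(sample, (1.0, 1.0, 1.0))
        from .reactions import scheme_class

        out.append(
            MinimalClass(
                pattern_type="I",
                class_id=f"I.{letter}",
                template=scheme_class(scheme),
                description=desc,
                coeff_names=tuple(bounds),
                coeff_bounds=bounds,
                turing_condition=cond,
                builder=builder,
            )
        )
    return out


# ---------------------------------------------------------------------------
# type-II catalogue (templates rediscovered by the feasibility search)
# ---------------------------------------------------------------------------
# Canonical orientation: U is the auto-activator (J11>0); the class contains
#   2U   -> ... increasing U,
#   U+V  -> ... decreasing V,
#   U    -> ... decreasing U,
# plus a fourth reaction that increases V and does not decrease U.

_TYPE_II_DEFS = [
    # (letter, (2U sgn2, U+V sgn1, U sgn2, fourth type), description)
    ("a", (_T(2, 0, 1, 0), _T(1, 1, 1, -1), _T(1, 0, -1, 0), _T(0, 0, 0, 1)),
     "2U -> n1 U;  U+V -> n2 U;  U -> 0;  0 -> m4 V"),
    ("b", (_T(2, 0, 1, 1), _T(1, 1, 1, -1), _T(1, 0, -1, 0), _T(0, 0, 0, 1)),
     "2U -> n1 U + m1 V;  U+V -> n2 U;  U -> 0;  0 -> m4 V"),
    ("c", (_T(2, 0, 1, 0), _T(1, 1, 1, -1), _T(1, 0, -1, 0), _T(0, 0, 1, 1)),
     "2U -> n1 U;  U+V -> n2 U;  U -> 0;  0 -> n4 U + m4 V"),
    ("d", (_T(2, 0, 1, 1), _T(1, 1, 1, -1), _T(1, 0, -1, 0), _T(0, 0, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> n2 U;  U -> 0;  0 -> n4 U + m4 V"),
    ("e", (_T(2, 0, 1, 1), _T(1, 1, 1, -1), _T(1, 0, -1, 0), _T(0, 1, 0, 1)),
     "2U -> n1 U + m1 V;  U+V -> n2 U;  U -> 0;  V -> m4 V"),
    ("f", (_T(2, 0, 1, 1), _T(1, 1, -1, -1), _T(1, 0, -1, 0), _T(0, 1, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> 0;  U -> 0;  V -> n4 U + m4 V"),
    ("g", (_T(2, 0, 1, 1), _T(1, 1, 0, -1), _T(1, 0, -1, 0), _T(0, 1, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> U;  U -> 0;  V -> n4 U + m4 V"),
    ("h", (_T(2, 0, 1, 1), _T(1, 1, 1, -1), _T(1, 0, -1, 0), _T(0, 1, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> n2 U;  U -> 0;  V -> n4 U + m4 V"),
    ("i", (_T(2, 0, 1, 0), _T(1, 1, 0, -1), _T(1, 0, -1, 1), _T(0, 1, 1, 1)),
     "2U -> n1 U;  U+V -> U;  U -> m3 V;  V -> n4 U + m4 V"),
    ("j", (_T(2, 0, 1, 1), _T(1, 1, 0, -1), _T(1, 0, -1, 1), _T(0, 1, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> U;  U -> m3 V;  V -> n4 U + m4 V"),
    ("k", (_T(2, 0, 1, 0), _T(1, 1, -1, -1), _T(1, 0, -1, 1), _T(0, 2, 1, 1)),
     "2U -> n1 U;  U+V -> 0;  U -> m3 V;  2V -> n4 U + m4 V"),
    ("l", (_T(2, 0, 1, 1), _T(1, 1, -1, -1), _T(1, 0, -1, 1), _T(0, 2, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> 0;  U -> m3 V;  2V -> n4 U + m4 V"),
    ("m", (_T(2, 0, 1, 0), _T(1, 1, 0, -1), _T(1, 0, -1, 1), _T(0, 2, 1, 1)),
     "2U -> n1 U;  U+V -> U;  U -> m3 V;  2V -> n4 U + m4 V"),
    ("n", (_T(2, 0, 1, 1), _T(1, 1, 0, -1), _T(1, 0, -1, 1), _T(0, 2, 1, 1)),
     "2U -> n1 U + m1 V;  U+V -> U;  U -> m3 V;  2V -> n4 U + m4 V"),
]


def typeII_structural_ok(template: SchemeClass) -> bool:
    """Check the four structural constraints every type-II template satisfies.

    In the canonical orientation: the 2U reaction increases U; the U+V
    reaction decreases V; the first-order U reaction decreases U; the fourth
    reaction increases V and does not decrease U.
    """
    ts = list(template)

    def pop(pred):
        for i, t in enumerate(ts):
            if pred(t):
                return ts.pop(i)
        return None

    if pop(lambda t: (t.p, t.q) == (2, 0) and t.sgn1 == 1) is None:
        return False
    if pop(lambda t: (t.p, t.q) == (1, 1) and t.sgn2 == -1) is None:
        return False
    if pop(lambda t: (t.p, t.q) == (1, 0) and t.sgn1 == -1) is None:
        return False
    if len(ts) != 1:
        return False
    fourth = ts[0]
    return fourth.sgn2 == 1 and fourth.sgn1 >= 0


def _typeII_classes() -> list[MinimalClass]:
    return [
        MinimalClass(
            pattern_type="II",
            class_id=f"II.{letter}",
            template=SchemeClass(types),
            description=desc,
        )
        for letter, types, desc in _TYPE_II_DEFS
    ]


@lru_cache(maxsize=None)
def _catalogue() -> dict[str, MinimalClass]:
    out = {}
    for mc in _typeI_classes() + _typeII_classes():
        out[mc.class_id] = mc
    return out


def list_minimal_classes(pattern_type: str = "both") -> list[MinimalClass]:
    """The full catalogue: 11 type-I classes, 14 type-II classes, 25 total."""
    cat = _catalogue().values()
    if pattern_type == "both":
        return list(cat)
    if pattern_type in ("I", "II"):
        return [mc for mc in cat if mc.pattern_type == pattern_type]
    raise ValueError("pattern_type must be 'I', 'II' or 'both'")


def get_class(class_id: str) -> MinimalClass:
    try:
        return _catalogue()[class_id]
    except KeyError:
        raise KeyError(f"unknown class id {class_id!r}") from None


def _check_bounds(mc: MinimalClass, coeffs: dict) -> None:
    for name in mc.coeff_names:
        if name not in coeffs:
            raise ValueError(f"{mc.class_id} needs coefficient {name!r}")
        lo, hi = mc.coeff_bounds[name]
        val = coeffs[name]
        if val < lo or (hi is not None and val > hi):
            raise ValueError(
                f"{mc.class_id}: coefficient {name}={val} violates the "
                f"structural bound {name} >= {lo}"
            )


def build_scheme(
    class_id: str, coeffs: dict, rates: Sequence[float] = (1.0, 1.0, 1.0)
) -> ReactionScheme:
    """Concrete scheme of a type-I class with given coefficients and rates."""
    mc = get_class(class_id)
    if mc.builder is None:
        raise ValueError(f"{class_id} is a type-II template without a builder")
    _check_bounds(mc, coeffs)
    return mc.builder(coeffs, tuple(rates))


def is_turing_unstable_typeI(class_id: str, coeffs: dict) -> bool:
    """Evaluate the class's closed-form iff Turing-instability condition."""
    mc = get_class(class_id)
    if mc.turing_condition is None:
        raise ValueError(
            f"{class_id} has no closed-form condition (type-II instability "
            "is decided numerically by turingmin.search)"
        )
    _check_bounds(mc, coeffs)
    return bool(mc.turing_condition(*(coeffs[n] for n in mc.coeff_names)))


# ---------------------------------------------------------------------------
# regime diagram (rho, delta) for type-I classes
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _symbolic_instance(class_id: str):
    """Symbolic steady state and Jacobian of a type-I class.

    Rates are normalized to (1, rho, 1).  The steady state is derived by
    guided elimination: one of {F - G, F, G} is linear in v (or free of v),
    giving v(u) and a low-degree univariate equation for u.  The positive
    branch is selected numerically at an admissible sample.  Returns
    lambdified functions of ``(rho, *coeffs)`` for u*, v* and the four
    Jacobian entries, plus the coefficient symbols.
    """
    mc = get_class(class_id)
    sample = dict(_TYPE_I_SAMPLES[class_id])
    u, v, rho = sp.symbols("u v rho", positive=True)
    csyms = {name: sp.Symbol(name, positive=True) for name in mc.coeff_names}
    # symbolic F, G from the declarative template, rates (1, rho, 1)
    F = sp.Integer(0)
    G = sp.Integer(0)
    sym_rates = (sp.Integer(1), rho, sp.Integer(1))
    for spec, rate in zip(_TYPE_I_TEMPLATES[class_id], sym_rates):
        p, q, n, m, r_ = _rxn_template(spec, csyms, rate)
        mono = u**p * v**q
        F += r_ * (n - p) * mono
        G += r_ * (m - q) * mono

    # guided elimination
    FmG = sp.expand(F - G)
    subs_num = {csyms[k]: sample[k] for k in mc.coeff_names}

    def positive_root(expr_in_u):
        roots = sp.solve(sp.Eq(expr_in_u, 0), u)
        best = None
        for r_ in roots:
            val = complex(sp.simplify(r_).subs(subs_num).subs(rho, 57.3))
            if abs(val.imag) < 1e-9 and val.real > 1e-12:
                best = r_
        if best is None:
            raise RuntimeError(f"no positive u branch for {class_id}")
        return best

    if v not in FmG.free_symbols:
        u_star = positive_root(FmG)
        v_star = sp.solve(sp.Eq(F.subs(u, u_star), 0), v)[0]
    else:
        # find an equation linear in v
        for eq in (G, F, FmG):
            if sp.degree(sp.expand(eq), v) == 1:
                v_of_u = sp.solve(sp.Eq(eq, 0), v)[0]
                other = F if eq is G else G
                red = sp.cancel(sp.together(other.subs(v, v_of_u)))
                red = sp.numer(red)
                # strip trivial u factors (boundary steady states)
                red = sp.factor(red)
                if isinstance(red, sp.Mul):
                    red = sp.Mul(*[f for f in red.args
                                   if not (f == u or (f.is_Pow and f.base == u))])
                u_star = positive_root(red)
                v_star = sp.simplify(v_of_u.subs(u, u_star))
                break
        else:  # pragma: no cover - all catalogued classes hit the loop above
            raise RuntimeError(f"no linear elimination found for {class_id}")

    J = {}
    for name, expr in (("j11", sp.diff(F, u)), ("j12", sp.diff(F, v)),
                       ("j21", sp.diff(G, u)), ("j22", sp.diff(G, v))):
        J[name] = expr.subs({u: u_star, v: v_star})

    args = (rho,) + tuple(csyms[k] for k in mc.coeff_names)
    funcs = {
        "u": sp.lambdify(args, u_star, "numpy"),
        "v": sp.lambdify(args, v_star, "numpy"),
        **{k: sp.lambdify(args, sp.simplify(e), "numpy") for k, e in J.items()},
    }
    return funcs, mc.coeff_names


def _jac_arrays(class_id: str, rho, coeff_arrays):
    funcs, names = _symbolic_instance(class_id)
    vals = [np.asarray(coeff_arrays[n], dtype=float) for n in names]
    out = {k: np.asarray(funcs[k](rho, *vals), dtype=float)
           for k in ("u", "v", "j11", "j12", "j21", "j22")}
    return out


def _rho_c_bisect(class_id: str, coeff_arrays, lo=1e-8, hi=1e12, iters=200):
    """Vectorized root of tr(J*)(rho) = 0 (the uniform-stability threshold)."""
    def trace(rho):
        J = _jac_arrays(class_id, rho, coeff_arrays)
        return J["j11"] + J["j22"]

    lo = np.full_like(trace(1.0), lo, dtype=float)
    hi = np.full_like(lo, hi)
    # trace is positive below rho_c and negative above in every class
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        pos = trace(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return np.sqrt(lo * hi)


def _delta_c_arrays(class_id: str, rho, coeff_arrays):
    J = _jac_arrays(class_id, rho, coeff_arrays)
    det = J["j11"] * J["j22"] - J["j12"] * J["j21"]
    cross = -J["j12"] * J["j21"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return (np.sqrt(det) + np.sqrt(cross)) ** 2 / J["j11"] ** 2


def regime_line(class_id: str, coeffs: dict) -> RegimeLine:
    """Turing boundary of one type-I class instance (rates (1, rho, 1)).

    ``rho_c`` is the root of ``tr(J*) = 0``; the slope is ``delta_c(rho)/rho``,
    verified constant (relative spread below 1e-6) over rho in
    {2, 5, 10} rho_c, consistent with a linear boundary through the origin.
    """
    mc = get_class(class_id)
    if mc.pattern_type != "I":
        raise ValueError(
            "regime_line supports type-I classes only; type-II involves an "
            "additional dimensionless rate group and is analysed numerically"
        )
    if not is_turing_unstable_typeI(class_id, coeffs):
        raise ValueError(f"{class_id} with {coeffs} is not Turing-unstable")
    arrays = {k: np.array([float(val)]) for k, val in coeffs.items()}
    rho_c = float(_rho_c_bisect(class_id, arrays)[0])
    rhos = np.array([2.0, 5.0, 10.0]) * rho_c
    slopes = np.array(
        [float(_delta_c_arrays(class_id, r, arrays)[0]) / r for r in rhos]
    )
    slope = float(np.mean(slopes))
    spread = float(np.ptp(slopes) / slope)
    if spread > 1e-6:
        raise RuntimeError(
            f"{class_id}: delta_c(rho)/rho varies by {spread:.2e}; "
            "boundary is not linear through the origin"
        )
    # affine fit to expose any intercept (expected ~0)
    d1 = float(_delta_c_arrays(class_id, rhos[0], arrays)[0])
    d2 = float(_delta_c_arrays(class_id, rhos[2], arrays)[0])
    a = (d2 - d1) / (rhos[2] - rhos[0])
    intercept = d1 - a * rhos[0]
    delta_at_rc = float(_delta_c_arrays(class_id, rho_c, arrays)[0])
    return RegimeLine(rho_c, slope, delta_at_rc, intercept)


# ---------------------------------------------------------------------------
# infimum of delta_c(rho_c) over stoichiometric coefficients
# ---------------------------------------------------------------------------

def _coeff_grid(lo: int, bound: int) -> np.ndarray:
    """Nested integer grid: dense up to 12, then log-spaced (always incl. bound)."""
    vals = set(range(lo, min(bound, 12) + 1))
    x = lo
    while x <= bound:
        vals.update((int(x) - 1, int(x), int(x) + 1))
        x = max(x + 1, int(round(x * 1.35)))
    vals.update((bound - 2, bound - 1, bound))
    return np.array(sorted(v for v in vals if lo <= v <= bound))


def inf_delta_c(class_id: str, coeff_bound: int) -> float:
    """Minimum of delta_c(rho_c) over admissible coefficients up to a bound.

    The minimum is monotonically non-increasing in ``coeff_bound``; for most
    classes it keeps decreasing toward the infimum 1 as coefficients grow,
    while for the three classes whose interspecific reaction preserves or
    produces V (I.i, I.j, I.k) it is bounded below by (1+sqrt(2))^2.
    """
    mc = get_class(class_id)
    if mc.pattern_type != "I" or mc.turing_condition is None:
        raise ValueError("inf_delta_c applies to type-I classes")
    names = mc.coeff_names
    axes = [_coeff_grid(mc.coeff_bounds[n][0], coeff_bound) for n in names]
    grids = np.meshgrid(*axes, indexing="ij")
    flat = {n: g.ravel() for n, g in zip(names, grids)}
    mask = np.array(
        [bool(mc.turing_condition(*vals)) for vals in zip(*(flat[n] for n in names))]
    )
    if not mask.any():
        return np.inf
    sel = {n: flat[n][mask] for n in names}
    rho_c = _rho_c_bisect(class_id, sel)
    dc = _delta_c_arrays(class_id, rho_c, sel)
    dc = dc[np.isfinite(dc)]
    return float(dc.min())


def inf_delta_c_report(
    class_ids: Optional[Sequence[str]] = None,
    bounds: Sequence[int] = (10, 25, 50, 100, 200),
) -> dict:
    """Sweep the minimum of delta_c(rho_c) over growing coefficient bounds.

    For each class, returns the sequence of minima and an extrapolated limit
    from a quadratic fit in ``bound**-0.5`` over the three largest bounds
    (the leading correction decays as the inverse square root of the largest
    admissible coefficient, so the tail is the asymptotic regime).
    """
    if class_ids is None:
        class_ids = [mc.class_id for mc in list_minimal_classes("I")]
    out = {}
    for cid in class_ids:
        mins = np.array([inf_delta_c(cid, b) for b in bounds])
        x = np.asarray(bounds, dtype=float) ** -0.5
        coeffs = np.polynomial.polynomial.polyfit(x[-3:], mins[-3:], deg=2)
        out[cid] = {
            "bounds": list(bounds),
            "minima": mins.tolist(),
            "limit": float(coeffs[0]),
            "decreasing": bool(np.all(np.diff(mins) <= 1e-12)),
        }
    return out
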