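"""Rediscovery of the minimal Turing-unstable scheme classes by feasibility search.

The search enumerates qualitative scheme classes (multisets of reaction
types, taken up to the U <-> V relabelling), discards those that cannot
support a Turing instability on structural grounds, and decides each
survivor by searching for a concrete *witness*: integer product
coefficients and sampled rate constants whose compiled kinetics admit a
positive steady state satisfying the Routh-Hurwitz and sign-pattern
conditions.  A witness certifies the class as Turing-unstable (it is
re-verified independently by the scalar stability pipeline); "no witness
found" is a budget-limited statement, not a proof of stability.

Two analytic exclusion rules, both consequences of evaluating the Jacobian
with the steady-state relations, are applied before any numerics:

* if every reaction is bimolecular, F and G are homogeneous quadratics and
  Euler's identity forces ``det(J*) = 0``;
* if every reactant combination lies in {2U, U+V, U}, then
  ``J21* = b4 u* >= 0``, ruling out the anti-phase (type II) sign pattern.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _batch
from .kinetics import compile_scheme
from .reactions import (
    QualitativeType,
    Reaction,
    ReactionScheme,
    SchemeClass,
    canonical_class,
    enumerate_scheme_classes,
)
from .stability import Diffusivities, TuringReport, turing_report

__all__ = [
    "SearchConfig",
    "Witness",
    "SearchResult",
    "prune_necessary",
    "analytic_exclusion",
    "decide_class",
    "find_minimal_schemes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Budget and reproducibility knobs for the catalogue search."""

    n_reactions: int = 3
    pattern_type: str = "I"             # 'I', 'II' or 'both'
    coeff_bound: int = 6
    rate_samples: int = 500
    rate_range: tuple[float, float] = (1e-2, 1e2)
    seed: int = 0
    margin: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_reactions < 1 or self.coeff_bound < 1 or self.rate_samples < 1:
            raise ValueError("search bounds must be positive")
        if not self.rate_range[0] < self.rate_range[1]:
            raise ValueError("rate_range must be increasing")
        if self.pattern_type not in ("I", "II", "both"):
            raise ValueError("pattern_type must be 'I', 'II' or 'both'")


@dataclass(frozen=True)
class Witness:
    """A concrete Turing-unstable scheme certifying its qualitative class."""

    scheme: ReactionScheme
    scheme_class: SchemeClass          # canonical representative
    pattern_type: str
    delta: float                       # diffusivity ratio just above delta_c
    report: TuringReport
    mirrored: bool                     # witness found in the relabelled orientation


@dataclass
class SearchResult:
    unstable_classes: dict[SchemeClass, Witness]
    pruned_count: int
    examined_count: int

    @property
    def n_unstable(self) -> int:
        return len(self.unstable_classes)


# ---------------------------------------------------------------------------
# structural pruning
# ---------------------------------------------------------------------------

def prune_necessary(cls: SchemeClass, pattern_type: str) -> bool:
    """Necessary reactant combinations, checked in the given orientation.

    Type I needs an auto-amplifying ``2U`` reaction (a4 > 0) and a ``U+V``
    reaction consuming U (a5 < 0).  Type II needs the ``2U`` reaction, a
    ``U+V`` reaction consuming V (b5 < 0) and a first-order ``U`` reaction
    consuming U (a2 < 0).
    """
    has = lambda p, q, cond: any(
        t.p == p and t.q == q and cond(t) for t in cls
    )
    if not has(2, 0, lambda t: t.sgn1 == 1):
        return False
    if pattern_type == "I":
        return has(1, 1, lambda t: t.sgn1 == -1)
    if pattern_type == "II":
        return has(1, 1, lambda t: t.sgn2 == -1) and has(
            1, 0, lambda t: t.sgn1 == -1
        )
    raise ValueError("pattern_type must be 'I' or 'II'")


def analytic_exclusion(cls: SchemeClass, pattern_type: str) -> Optional[str]:
    """Reason the class provably has no Turing-unstable member, else None."""
    if all(t.p + t.q == 2 for t in cls):
        return (
            "all reactions bimolecular: F, G homogeneous quadratics, "
            "so det(J*) = 0 at any positive steady state"
        )
    if pattern_type == "II" and all(
        (t.p, t.q) in ((2, 0), (1, 1), (1, 0)) for t in cls
    ):
        return (
            "reactant combinations within {2U, U+V, U}: J21* = b4 u* >= 0, "
            "incompatible with the anti-phase sign pattern"
        )
    return None


# ---------------------------------------------------------------------------
# witness search over coefficients and rates
# ---------------------------------------------------------------------------

def _coeff_options(t: QualitativeType, bound: int) -> list[tuple[int, int]]:
    """Admissible (n, m) product coefficients for a qualitative type."""
    def axis(p, sgn):
        if sgn == 0:
            return [p]
        if sgn == 1:
            return list(range(p + 1, max(bound, p + 1) + 1))
        return list(range(0, p))

    return [(n, m) for n in axis(t.p, t.sgn1) for m in axis(t.q, t.sgn2)]


def _coeff_tuples(types, bound):
    opts = [_coeff_options(t, bound) for t in types]
    tuples = list(itertools.product(*opts))
    tuples.sort(key=lambda tup: (sum(n + m for n, m in tup), tup))
    return tuples


_MONO_INDEX = {(0, 0): 0, (1, 0): 1, (0, 1): 2, (2, 0): 3, (1, 1): 4, (0, 2): 5}


def _kernel_search(types, cfg: SearchConfig, target: str, rng):
    """Scan (coefficient tuple, rate sample) candidates; return first witness.

    Returns ``(coeffs, rates, u, v)`` or None.  Candidates are ordered by
    total stoichiometric coefficient so the simplest witness is found first.
    """
    N = len(types)
    tuples = _coeff_tuples(types, cfg.coeff_bound)
    mono = np.array([_MONO_INDEX[(t.p, t.q)] for t in types])
    support_a = [False] * 6
    support_b = [False] * 6
    for t in types:
        if t.sgn1 != 0:
            support_a[_MONO_INDEX[(t.p, t.q)]] = True
        if t.sgn2 != 0:
            support_b[_MONO_INDEX[(t.p, t.q)]] = True

    lo, hi = np.log(cfg.rate_range)
    rates = np.exp(rng.uniform(lo, hi, size=(cfg.rate_samples, N)))
    margin = cfg.margin

    chunk = max(1, 200_000 // max(cfg.rate_samples, 1))
    S = cfg.rate_samples
    for start in range(0, len(tuples), chunk):
        batch_tuples = tuples[start:start + chunk]
        T = len(batch_tuples)
        s1 = np.array([[n - t.p for (n, m), t in zip(tup, types)]
                       for tup in batch_tuples], dtype=float)  # (T, N)
        s2 = np.array([[m - t.q for (n, m), t in zip(tup, types)]
                       for tup in batch_tuples], dtype=float)
        B = T * S
        a = np.zeros((B, 6))
        b = np.zeros((B, 6))
        # candidate (ti, si) -> row ti*S + si
        r_full = np.broadcast_to(rates, (T, S, N)).reshape(B, N)
        s1_full = np.repeat(s1, S, axis=0)
        s2_full = np.repeat(s2, S, axis=0)
        for i in range(N):
            a[:, mono[i]] += r_full[:, i] * s1_full[:, i]
            b[:, mono[i]] += r_full[:, i] * s2_full[:, i]

        idx, u, v = _batch.batched_candidates(a, b, support_a, support_b)
        if idx.size == 0:
            continue
        u, v, res = _batch.newton_polish_batch(a, b, idx, u, v)
        scale = np.maximum(np.abs(a[idx]).max(axis=1), np.abs(b[idx]).max(axis=1))
        local = scale * np.maximum(1.0, np.maximum(u, v)) ** 2
        ok = (
            np.isfinite(u) & np.isfinite(v)
            & (u > 1e-9) & (v > 1e-9)
            & (res <= 1e-9 * local)
        )
        if not ok.any():
            continue
        idx, u, v = idx[ok], u[ok], v[ok]
        j11, j12, j21, j22 = _batch.batched_jacobians(a, b, idx, u, v)
        js = np.max(np.abs(np.stack([j11, j12, j21, j22])), axis=0)
        thr = np.maximum(margin * js, 1e-300)
        tr = j11 + j22
        det = j11 * j22 - j12 * j21
        good = (tr < -thr) & (det > thr * js)
        if target == "I":
            good &= (j11 > thr) & (j12 < -thr) & (j21 > thr) & (j22 < -thr)
        else:
            good &= (j11 > thr) & (j12 > thr) & (j21 < -thr) & (j22 < -thr)
        if not good.any():
            continue
        # earliest candidate in (tuple, sample) order
        rows = idx[good]
        first = np.argmin(rows)
        row = int(rows[first])
        ti, si = divmod(row, S)
        return batch_tuples[ti], rates[si], float(u[good][first]), float(v[good][first])
    return None


def _anchored_search(types, cfg: SearchConfig, target: str, rng):
    """Second-stage scan with the steady state pinned at (1, v*).

    By the concentration-scaling symmetry the steady state can be fixed at
    ``u* = 1`` without loss of generality.  The steady-state equations are
    then linear in the rates: sampling ``v*`` and the rates of all
    reactions except the ``2U`` and ``U+V`` ones, the latter two are solved
    from ``F = G = 0`` and kept when positive.  Every candidate therefore
    sits exactly on the steady-state manifold, which reaches witnesses in
    regions of rate space that plain forward sampling misses.
    """
    N = len(types)
    i1 = next(i for i, t in enumerate(types) if (t.p, t.q) == (2, 0))
    i2 = next(i for i, t in enumerate(types) if (t.p, t.q) == (1, 1))
    others = [i for i in range(N) if i not in (i1, i2)]
    tuples = _coeff_tuples(types, cfg.coeff_bound)
    lo, hi = np.log(cfg.rate_range)
    S = cfg.rate_samples
    v = np.exp(rng.uniform(np.log(1e-3), np.log(1e3), S))
    r_other = np.exp(rng.uniform(lo, hi, size=(S, len(others))))
    margin = cfg.margin

    def mono_val(t, vv):
        return vv**t.q  # at u = 1

    for tup in tuples:
        s1 = np.array([n - t.p for (n, m), t in zip(tup, types)], dtype=float)
        s2 = np.array([m - t.q for (n, m), t in zip(tup, types)], dtype=float)
        # F = A11 r1 + A12 r2 + cF = 0 ; G = A21 r1 + A22 r2 + cG = 0
        A11 = np.full(S, s1[i1])
        A12 = s1[i2] * v
        A21 = np.full(S, s2[i1])
        A22 = s2[i2] * v
        cF = np.zeros(S)
        cG = np.zeros(S)
        for jo, i in enumerate(others):
            mv = mono_val(types[i], v)
            cF += r_other[:, jo] * s1[i] * mv
            cG += r_other[:, jo] * s2[i] * mv
        det = A11 * A22 - A12 * A21
        ok = np.abs(det) > 1e-12
        dets = np.where(ok, det, 1.0)
        r1 = np.where(ok, (-cF * A22 + cG * A12) / dets, np.nan)
        r2 = np.where(ok, (-cG * A11 + cF * A21) / dets, np.nan)
        ok &= np.isfinite(r1) & np.isfinite(r2) & (r1 > 1e-12) & (r2 > 1e-12)
        if not ok.any():
            continue
        rates = np.zeros((S, N))
        rates[:, i1] = r1
        rates[:, i2] = r2
        for jo, i in enumerate(others):
            rates[:, i] = r_other[:, jo]
        # Jacobian entries at (1, v)
        a = np.zeros((S, 6))
        b = np.zeros((S, 6))
        mono = [_MONO_INDEX[(t.p, t.q)] for t in types]
        for i in range(N):
            a[:, mono[i]] += rates[:, i] * s1[i]
            b[:, mono[i]] += rates[:, i] * s2[i]
        u1 = np.ones(S)
        idx = np.arange(S)
        j11, j12, j21, j22 = _batch.batched_jacobians(a, b, idx, u1, v)
        js = np.max(np.abs(np.stack([j11, j12, j21, j22])), axis=0)
        thr = np.maximum(margin * js, 1e-300)
        tr = j11 + j22
        det_j = j11 * j22 - j12 * j21
        good = ok & (tr < -thr) & (det_j > thr * js)
        if target == "I":
            good &= (j11 > thr) & (j12 < -thr) & (j21 > thr) & (j22 < -thr)
        else:
            good &= (j11 > thr) & (j12 > thr) & (j21 < -thr) & (j22 < -thr)
        if good.any():
            si = int(np.nonzero(good)[0][0])
            return tup, rates[si], 1.0, float(v[si])
    return None


def _build_scheme(types, coeffs, rates, label=""):
    reactions = tuple(
        Reaction(t.p, t.q, n, m, float(r))
        for t, (n, m), r in zip(types, coeffs, rates)
    )
    return ReactionScheme(reactions, label=label)


def decide_class(
    cls: SchemeClass, cfg: SearchConfig, _class_index: int = 0
) -> Optional[Witness]:
    """Search one qualitative class for a verified Turing-unstable witness.

    The class and its mirror image are both examined (a scheme and its
    relabelled twin are the same physical system).  Returns the first
    witness whose full :func:`turing_report` confirms the predicted pattern
    at ``delta = 1.01 * delta_c``, or None if the budget is exhausted.
    """
    targets = ("I", "II") if cfg.pattern_type == "both" else (cfg.pattern_type,)
    orientations = [(cls, False)]
    m = cls.mirrored()
    if tuple(m) != tuple(cls):
        orientations.append((m, True))

    for target in targets:
        for oriented, mirrored in orientations:
            if not prune_necessary(oriented, target):
                continue
            if analytic_exclusion(oriented, target) is not None:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, _class_index, len(target)])
            )
            hit = _kernel_search(tuple(oriented), cfg, target, rng)
            if hit is None:
                hit = _anchored_search(tuple(oriented), cfg, target, rng)
            if hit is None:
                continue
            coeffs, rates, u, v = hit
            scheme = _build_scheme(tuple(oriented), coeffs, rates)
            witness = _verify_witness(scheme, cls, target, mirrored, cfg)
            if witness is not None:
                return witness
            logger.debug("kernel hit for %s failed verification", cls)
    return None


def _verify_witness(scheme, cls, target, mirrored, cfg) -> Optional[Witness]:
    """Independent scalar re-check of a kernel hit; returns a Witness or None."""
    k = compile_scheme(scheme)
    for rep in turing_report(k, margin=cfg.margin):
        if rep.pattern_type != target or rep.delta_c is None:
            continue
        delta = 1.01 * rep.delta_c
        d = Diffusivities(1.0, delta)
        full = turing_report(k, d, margin=cfg.margin)
        for fr in full:
            if fr.pattern_type == target and fr.pattern_predicted:
                return Witness(
                    scheme=scheme,
                    scheme_class=cls,
                    pattern_type=target,
                    delta=delta,
                    report=fr,
                    mirrored=mirrored,
                )
    return None


def find_minimal_schemes(cfg: SearchConfig) -> SearchResult:
    """Search every qualitative class of ``cfg.n_reactions`` reactions.

    Classes are enumerated as multisets over the 31 reaction types and
    deduplicated under the U <-> V relabelling; the result maps each
    Turing-unstable canonical class to one verified witness.
    """
    seen: set[tuple] = set()
    unstable: dict[SchemeClass, Witness] = {}
    pruned = 0
    examined = 0
    for cls in enumerate_scheme_classes(cfg.n_reactions):
        canon = canonical_class(cls)
        key = tuple(canon)
        if key in seen:
            continue
        seen.add(key)
        examined += 1
        targets = ("I", "II") if cfg.pattern_type == "both" else (cfg.pattern_type,)
        viable = any(
            prune_necessary(orient, t) and analytic_exclusion(orient, t) is None
            for orient in (canon, canon.mirrored())
            for t in targets
        )
        if not viable:
            pruned += 1
            continue
        witness = decide_class(canon, cfg, _class_index=examined)
        if witness is not None:
            unstable[canon] = witness
            logger.info("Turing-unstable class: %s (type %s)",
                        canon, witness.pattern_type)
        else:
            logger.debug("no witness: %s", canon)
    return SearchResult(unstable, pruned, examined)
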