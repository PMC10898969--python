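"""Elementary two-species reactions, schemes and their qualitative classification.

A reaction ``pU + qV -> nU + mV`` with rate constant ``r`` is *elementary*
when its order ``p + q`` is at most two (zeroth-, first- or second-order,
i.e. at most bimolecular).  Its net stoichiometric effects are
``s1 = n - p`` on species U and ``s2 = m - q`` on species V.  Two reactions
are *qualitatively equivalent* when they share ``(p, q, sign(s1), sign(s2))``;
there are exactly 31 such qualitative types.  A reaction scheme is a finite
set of reactions, and its qualitative class is the multiset of its reactions'
types, invariant to reaction order and to the values of the rate constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Reaction",
    "QualitativeType",
    "ReactionScheme",
    "SchemeClass",
    "ReactionValidationError",
    "qualitative_type",
    "enumerate_reaction_types",
    "scheme_class",
    "mirror_type",
    "mirror_class",
    "canonical_class",
    "count_scheme_classes",
    "enumerate_scheme_classes",
    "random_scheme",
    "load_scheme",
    "save_scheme",
    "scheme_to_dict",
    "scheme_from_dict",
]

#: Rate constants drawn by :func:`random_scheme` are log-uniform on this range.
FIXTURE_RATE_RANGE = (1e-2, 1e2)


class ReactionValidationError(ValueError):
    """A reaction violates the elementary mass-action constraints."""


class QualitativeType(NamedTuple):
    """Qualitative type ``(p, q, sign(s1), sign(s2))`` of an elementary reaction."""

    p: int
    q: int
    sgn1: int
    sgn2: int

    def __str__(self) -> str:  # e.g. "2U+0V(+,-)"
        sym = {-1: "-", 0: "0", 1: "+"}
        lhs = _reactant_str(self.p, self.q)
        return f"{lhs}({sym[self.sgn1]},{sym[self.sgn2]})"


def _reactant_str(p: int, q: int) -> str:
    if p == 0 and q == 0:
        return "0"
    parts = []
    if p:
        parts.append("U" if p == 1 else f"{p}U")
    if q:
        parts.append("V" if q == 1 else f"{q}V")
    return "+".join(parts)


@dataclass(frozen=True)
class Reaction:
    """One stoichiometric equation ``pU + qV -> nU + mV`` with rate ``r``.

    Parameters
    ----------
    p, q
        Non-negative integer reactant coefficients with ``p + q <= 2``.
    n, m
        Non-negative integer product coefficients.
    rate
        Positive mass-action rate constant (units consistent with order ``p+q``).
    """

    p: int
    q: int
    n: int
    m: int
    rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p", "q", "n", "m"):
            val = getattr(self, name)
            if not isinstance(val, (int, np.integer)) or isinstance(val, bool):
                raise ReactionValidationError(
                    f"coefficient {name}={val!r} must be an integer"
                )
            if val < 0:
                raise ReactionValidationError(
                    f"coefficient {name}={val} must be non-negative"
                )
        if self.p + self.q > 2:
            raise ReactionValidationError(
                f"reaction order p+q={self.p + self.q} exceeds 2 "
                "(only elementary, at most bimolecular, reactions are allowed)"
            )
        if self.s1 == 0 and self.s2 == 0:
            raise ReactionValidationError(
                "reaction changes neither species (s1=s2=0); "
                "a no-op interaction is not a meaningful reaction"
            )
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise ReactionValidationError(f"rate={self.rate} must be positive")

    @property
    def s1(self) -> int:
        """Net stoichiometric effect on U: ``n - p``."""
        return self.n - self.p

    @property
    def s2(self) -> int:
        """Net stoichiometric effect on V: ``m - q``."""
        return self.m - self.q

    @property
    def order(self) -> int:
        return self.p + self.q

    def mirrored(self) -> "Reaction":
        """The same reaction with the species labels U and V swapped."""
        return Reaction(self.q, self.p, self.m, self.n, self.rate)

    def __str__(self) -> str:
        return f"{_reactant_str(self.p, self.q)} -> {_reactant_str(self.n, self.m)}"


def qualitative_type(rxn: Reaction) -> QualitativeType:
    """Qualitative type ``(p, q, sign(n-p), sign(m-q))`` of a valid reaction."""
    return QualitativeType(rxn.p, rxn.q, int(np.sign(rxn.s1)), int(np.sign(rxn.s2)))


def enumerate_reaction_types() -> list[QualitativeType]:
    """All 31 qualitative types of elementary two-species reactions.

    The signs are constrained by stoichiometry: a reaction can only decrease
    a species it consumes (``sign(s1) = -1`` requires ``p > 0`` and likewise
    for V), and a reaction must change at least one species.  The list is
    ordered lexicographically on ``(p, q, sgn1, sgn2)``.
    """
    types = []
    for p in range(3):
        for q in range(3 - p):
            for sgn1 in (-1, 0, 1):
                if sgn1 == -1 and p == 0:
                    continue
                for sgn2 in (-1, 0, 1):
                    if sgn2 == -1 and q == 0:
                        continue
                    if sgn1 == 0 and sgn2 == 0:
                        continue
                    types.append(QualitativeType(p, q, sgn1, sgn2))
    return sorted(types)


@dataclass(frozen=True)
class ReactionScheme:
    """An ordered collection of elementary reactions."""

    reactions: tuple[Reaction, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if len(self.reactions) < 1:
            raise ReactionValidationError("a reaction scheme needs at least one reaction")

    @property
    def size(self) -> int:
        return len(self.reactions)

    def mirrored(self) -> "ReactionScheme":
        return ReactionScheme(
            tuple(r.mirrored() for r in self.reactions), label=self.label
        )

    def __str__(self) -> str:
        return "; ".join(str(r) for r in self.reactions)


class SchemeClass(tuple):
    """Canonically ordered multiset of qualitative reaction types.

    Two schemes are qualitatively equivalent iff their ``SchemeClass`` values
    compare equal, regardless of the order the reactions were listed in and
    of the rate constants.
    """

    def __new__(cls, types: Iterable[QualitativeType]) -> "SchemeClass":
        return super().__new__(cls, sorted(QualitativeType(*t) for t in types))

    def mirrored(self) -> "SchemeClass":
        return SchemeClass(mirror_type(t) for t in self)

    def __str__(self) -> str:
        return "{" + ", ".join(str(t) for t in self) + "}"


def scheme_class(scheme: ReactionScheme) -> SchemeClass:
    """Multiset of the qualitative types of a scheme's reactions."""
    return SchemeClass(qualitative_type(r) for r in scheme.reactions)


def mirror_type(t: QualitativeType) -> QualitativeType:
    """Image of a qualitative type under relabelling U <-> V."""
    return QualitativeType(t.q, t.p, t.sgn2, t.sgn1)


def mirror_class(cls: SchemeClass) -> SchemeClass:
    return cls.mirrored()


def canonical_class(cls: SchemeClass) -> SchemeClass:
    """Representative of ``{cls, mirror(cls)}`` chosen by tuple ordering."""
    m = cls.mirrored()
    return cls if tuple(cls) <= tuple(m) else m


def count_scheme_classes(n: int) -> int:
    """Number of qualitative scheme classes of ``n`` reactions.

    A class is a multiset of size ``n`` over the 31 qualitative reaction
    types, so the count is the multiset coefficient ``C(31+n-1, n)``
    (5456 for n=3, 46376 for n=4).
    """
    if n < 1:
        raise ValueError(f"scheme size n={n} must be at least 1")
    return math.comb(31 + n - 1, n)


def enumerate_scheme_classes(n: int) -> Iterable[SchemeClass]:
    """Generate every qualitative scheme class of ``n`` reactions."""
    if n < 1:
        raise ValueError(f"scheme size n={n} must be at least 1")
    for combo in combinations_with_replacement(enumerate_reaction_types(), n):
        yield SchemeClass(combo)


def random_scheme(
    n: int, seed: int, coeff_bound: int = 4, label: str = ""
) -> ReactionScheme:
    """Seeded random scheme of ``n`` valid elementary reactions.

    Reactant pairs are drawn uniformly from the six elementary combinations,
    product coefficients uniformly on ``0..coeff_bound`` (redrawn when the
    reaction would be a no-op), and rates log-uniformly on
    :data:`FIXTURE_RATE_RANGE`.  The same seed always returns the same scheme.
    """
    if coeff_bound < 1:
        raise ValueError("coeff_bound must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]
    lo, hi = FIXTURE_RATE_RANGE
    reactions = []
    for _ in range(n):
        while True:
            p, q = pairs[rng.integers(len(pairs))]
            nn = int(rng.integers(0, coeff_bound + 1))
            mm = int(rng.integers(0, coeff_bound + 1))
            if nn - p == 0 and mm - q == 0:
                continue
            rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            reactions.append(Reaction(p, q, nn, mm, rate))
            break
    return ReactionScheme(tuple(reactions), label=label or f"random(seed={seed})")


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: ReactionScheme) -> dict:
    return {
        "label": scheme.label,
        "reactions": [
            {"p": r.p, "q": r.q, "n": r.n, "m": r.m, "rate": r.rate}
            for r in scheme.reactions
        ],
    }


def scheme_from_dict(data: dict) -> ReactionScheme:
    if not isinstance(data, dict) or "reactions" not in data:
        raise ReactionValidationError(
            "scheme JSON must be an object with a 'reactions' list"
        )
    reactions = []
    for i, rd in enumerate(data["reactions"]):
        try:
            reactions.append(
                Reaction(
                    int(rd["p"]), int(rd["q"]), int(rd["n"]), int(rd["m"]),
                    float(rd.get("rate", 1.0)),
                )
            )
        except (KeyError, TypeError, ReactionValidationError) as exc:
            raise ReactionValidationError(f"reaction {i}: {exc}") from exc
    return ReactionScheme(tuple(reactions), label=str(data.get("label", "")))


def load_scheme(path: str | Path) -> ReactionScheme:
    """Read a scheme from a JSON file, reporting the offending reaction on failure."""
    with open(path) as fh:
        return scheme_from_dict(json.load(fh))


def save_scheme(scheme: ReactionScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(scheme_to_dict(scheme), fh, indent=2)
        fh.write("\n")
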