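"""MaxEnt phonotactic grammars.

A grammar is a weighted set of markedness constraints over phoneme strings.
The harmony score of a string ``x`` is ``h(x) = sum_i w_i * C_i(x)`` where
``C_i(x)`` counts the violations of constraint ``i`` in ``x``.  The MaxEnt
value is ``P*(x) = exp(-h(x))`` and the probability is ``P*`` normalised
over a candidate set Omega, here all strings of the same length over the
grammar's inventory.

Constraints are phoneme n-grams (unigrams or bigrams); ``C_i`` counts
(possibly overlapping) occurrences of the n-gram.  For unigram/bigram
constraints the normaliser over all length-L strings is computed exactly
with a transfer-matrix recursion, so no enumeration of Omega is needed;
an explicit Omega may still be supplied (e.g. for toy oracles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

PhonemeString = tuple[str, ...]


@dataclass(frozen=True)
class Constraint:
    """A weighted n-gram constraint; ``pattern`` is the offending n-gram."""

    pattern: PhonemeString
    weight: float

    def violations(self, x: Sequence[str]) -> int:
        n = len(self.pattern)
        if n == 0 or n > len(x):
            return 0
        pat = tuple(self.pattern)
        return sum(1 for i in range(len(x) - n + 1) if tuple(x[i:i + n]) == pat)


@dataclass
class PhonotacticGrammar:
    constraints: list[Constraint]
    inventory: list[str]
    omega: list[PhonemeString] | None = None  # optional explicit candidate set
    _transfer: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValueError("a grammar needs at least one constraint")
        if any(not np.isfinite(c.weight) or c.weight < 0 for c in self.constraints):
            raise ValueError("constraint weights must be finite and nonnegative")

    # -- scoring -----------------------------------------------------------
    def _check(self, x: Sequence[str]) -> PhonemeString:
        x = tuple(x)
        unknown = [p for p in x if p not in self.inventory]
        if unknown:
            raise ValueError(f"symbols {unknown} outside the grammar inventory")
        return x

    def score(self, x: Sequence[str]) -> float:
        """Harmony h(x): weighted violation count."""
        x = self._check(x)
        return float(sum(c.weight * c.violations(x) for c in self.constraints))

    def maxent_value(self, x: Sequence[str]) -> float:
        return float(np.exp(-self.score(x)))

    def partition(self, length: int) -> float:
        """Z(L) = sum over all length-L inventory strings of exp(-h)."""
        if length < 1:
            raise ValueError("length must be >= 1")
        if self.omega is not None:
            return float(sum(np.exp(-self.score(y)) for y in self.omega
                             if len(y) == length))
        if length not in self._transfer:
            self._transfer[length] = self._transfer_partition(length)
        return self._transfer[length]

    def _transfer_partition(self, length: int) -> float:
        syms = self.inventory
        idx = {s: i for i, s in enumerate(syms)}
        uni = np.zeros(len(syms))
        big = np.zeros((len(syms), len(syms)))
        for c in self.constraints:
            if len(c.pattern) == 1:
                uni[idx[c.pattern[0]]] += c.weight
            elif len(c.pattern) == 2:
                big[idx[c.pattern[0]], idx[c.pattern[1]]] += c.weight
            else:
                raise ValueError(
                    "transfer-matrix normalisation handles n-grams of order "
                    "<= 2; supply an explicit omega for longer constraints")
        v = np.exp(-uni)
        if length == 1:
            return float(v.sum())
        T = np.exp(-(big + uni[None, :]))
        for _ in range(length - 1):
            v = v @ T
        return float(v.sum())

    def prob(self, x: Sequence[str]) -> float:
        """Normalised MaxEnt probability of x within same-length candidates."""
        x = self._check(x)
        return float(np.exp(-self.score(x)) / self.partition(len(x)))


def maxent_probability(x: Sequence[str], grammar: PhonotacticGrammar
                       ) -> tuple[float, float, float]:
    """Return (h, P*, P) of a phoneme string under a grammar."""
    h = grammar.score(x)
    pstar = float(np.exp(-h))
    p = pstar / grammar.partition(len(tuple(x)))
    return h, pstar, float(p)


def enumerate_omega(inventory: Iterable[str], length: int) -> list[PhonemeString]:
    """Explicit candidate set of all length-L strings (toy-scale oracle)."""
    return [tuple(t) for t in product(tuple(inventory), repeat=length)]


def random_grammar(inventory: Sequence[str], m_constraints: int,
                   rng: np.random.Generator) -> PhonotacticGrammar:
    """Draw m bigram constraints with Uniform(0.5, 3) weights."""
    if m_constraints < 1:
        raise ValueError("m_constraints must be >= 1")
    inv = list(inventory)
    pairs = [(a, b) for a in inv for b in inv]
    take = rng.choice(len(pairs), size=min(m_constraints, len(pairs)),
                      replace=False)
    cons = [Constraint(pairs[i], float(rng.uniform(0.5, 3.0))) for i in take]
    return PhonotacticGrammar(cons, inv)
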