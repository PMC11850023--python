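"""Exact rational oracles for the observer engine.

Everything here recomputes testimony likelihoods and posteriors by direct
enumeration with :class:`fractions.Fraction`, independently of the package's
floating-point implementation, so tests can compare the two routes.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

from urnlearn.space import (
    COPY_AFTER_FIRST,
    INDEPENDENT,
    MAXIMIZE,
    HypothesisSpace,
    TestimonySet,
)


def jar_likelihood(space: HypothesisSpace, colour: str, label: str) -> Fraction:
    jar = space.jar(label)
    return Fraction(jar.composition.get(colour, 0), jar.total)


def endorsement(space: HypothesisSpace, colour: str, strategy: str) -> dict[str, Fraction]:
    weights = {
        lab: jar_likelihood(space, colour, lab) * Fraction(space.prior[lab])
        for lab in space.labels
    }
    total = sum(weights.values())
    if total == 0:
        raise ValueError("impossible colour")
    if strategy == MAXIMIZE:
        best = max(weights.values())
        ties = [lab for lab, w in weights.items() if w == best]
        return {lab: (Fraction(1, len(ties)) if lab in ties else Fraction(0))
                for lab in space.labels}
    return {lab: w / total for lab, w in weights.items()}


def single_likelihood(space, t: str, h: str, strategy: str) -> Fraction:
    return sum(
        jar_likelihood(space, c, h) * endorsement(space, c, strategy)[t]
        for c in space.colours
        if jar_likelihood(space, c, h) > 0
    )


def brute_force_set_likelihood(
    space: HypothesisSpace, tset: TestimonySet, h: str, strategy: str
) -> Fraction:
    """Likelihood by enumerating every colour assignment to informants."""
    colours = [c for c in space.colours if jar_likelihood(space, c, h) > 0]
    n = len(tset)
    if tset.structure == INDEPENDENT:
        total = Fraction(0)
        for draws in product(colours, repeat=n):
            term = Fraction(1)
            for d, t in zip(draws, tset.endorsements):
                term *= jar_likelihood(space, d, h) * endorsement(space, d, strategy)[t]
            total += term
        return total
    total = Fraction(0)
    for d in colours:  # one shared draw
        p_d = jar_likelihood(space, d, h)
        dist = endorsement(space, d, strategy)
        if tset.shared_variant == COPY_AFTER_FIRST:
            first = tset.endorsements[0]
            copies_ok = all(t == first for t in tset.endorsements[1:])
            total += p_d * dist[first] * (1 if copies_ok else 0)
        else:
            term = Fraction(1)
            for t in tset.endorsements:
                term *= dist[t]
            total += p_d * term
    return total


def brute_force_posterior(
    space: HypothesisSpace,
    testimony_groups,
    observations,
    strategy: str,
) -> dict[str, Fraction]:
    scores = {}
    for lab in space.labels:
        lik = Fraction(space.prior[lab])
        for tset in testimony_groups:
            lik *= brute_force_set_likelihood(space, tset, lab, strategy)
        for colour in observations:
            lik *= jar_likelihood(space, colour, lab)
        scores[lab] = lik
    total = sum(scores.values())
    return {lab: s / total for lab, s in scores.items()}
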