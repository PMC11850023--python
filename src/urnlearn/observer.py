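"""Ideal-observer inference for the ball-and-urn testimony task.

A learner receives endorsements t_1..t_n from informants and possibly some
directly observed draws e, and must infer which jar h the balls came from:

    p(h | e, t_1..t_n)  proportional to  p(t_1..t_n | h) p(e | h) p(h)

The testimony likelihood depends on the evidence structure.  When each
informant drew a private ball, endorsements are conditionally independent
given the jar and the set likelihood is a product of single-testimony
likelihoods, each obtained by marginalizing over the informant's unseen
draw.  When the informants all inspected one shared ball d', the set
likelihood marginalizes over that single draw, so additional concurring
endorsements add little or no evidence — the statistical-dependency effect
this package exists to quantify.

Two readings of the shared case are provided, both first-class:

``literal_product``
    Every informant reacts (noisily, under probability matching) to the
    shared ball:  sum_d' p(d'|h) prod_i p(t_i|d').
``copy_after_first``
    Only the first informant reacts to the ball; the rest deterministically
    voice agreement with the first endorsement, as scripted stimuli often
    have them do:  sum_d' p(d'|h) p(t_1|d') for a unanimous set, zero
    otherwise.

For maximizing informants with no tie colours the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .space import (
    COPY_AFTER_FIRST,
    INDEPENDENT,
    LITERAL_PRODUCT,
    MAXIMIZE,
    POSTERIOR_MATCH,
    POSTERIOR_MAXIMIZE,
    HypothesisSpace,
    InformantModel,
    Jar,
    LearnerData,
    TestimonySet,
)

__all__ = [
    "colour_likelihood",
    "endorsement_distribution",
    "single_testimony_likelihood",
    "testimony_set_likelihood",
    "posterior",
    "posterior_from_samples",
    "predicted_choice_probability",
    "IdealObserver",
]


def colour_likelihood(colour: str, jar: Jar) -> float:
    """p(draw = colour | jar): the colour's share of the jar's balls.

    Returns 0 for a colour absent from this jar (distractor balls unique to
    the other jar, for instance).
    """
    return jar.likelihood(colour)


def endorsement_distribution(
    model: InformantModel, colour: str, space: HypothesisSpace
) -> dict[str, float]:
    """Distribution over endorsed jar labels for an informant who saw ``colour``.

    Maximizing informants put all mass on the argmax of p(d|h)p(h), split
    uniformly over exact ties; probability-matching informants return the
    normalized single-datum posterior.

    Raises
    ------
    ValueError
        If the colour is impossible under every jar.
    """
    weights = {
        jar.label: jar.likelihood(colour) * space.prior[jar.label]
        for jar in space.jars
    }
    total = sum(weights.values())
    if total == 0.0:
        raise ValueError(
            f"colour {colour!r} has zero likelihood under every jar in the space"
        )
    if model.strategy == MAXIMIZE:
        best = max(weights.values())
        ties = [lab for lab, w in weights.items() if w == best]
        return {lab: (1.0 / len(ties) if lab in ties else 0.0) for lab in weights}
    return {lab: w / total for lab, w in weights.items()}


def single_testimony_likelihood(
    t: str, h: str, model: InformantModel, space: HypothesisSpace
) -> float:
    """p(t | h): likelihood of one endorsement, marginalizing the private draw.

    sum_d p(d|h) p(t|d), where p(t|d) is the informant's endorsement
    distribution.  Colours the hypothesis jar cannot produce contribute
    nothing.
    """
    space.jar(t)  # label validation
    jar = space.jar(h)
    out = 0.0
    for colour in space.colours:
        p_d = jar.likelihood(colour)
        if p_d == 0.0:
            continue
        out += p_d * endorsement_distribution(model, colour, space)[t]
    return out


def testimony_set_likelihood(
    tset: TestimonySet, h: str, model: InformantModel, space: HypothesisSpace
) -> float:
    """p(t_1..t_n | h) under the set's evidence structure.

    independent
        prod_i p(t_i | h).
    shared, literal_product
        sum_d' p(d'|h) prod_i p(t_i | d').
    shared, copy_after_first
        sum_d' p(d'|h) p(t_1 | d') if the set is unanimous; informants after
        the first are deterministic copies of the first endorsement, so a
        non-unanimous shared set has likelihood zero.

    An empty independent set has likelihood 1 (no evidence).
    """
    for t in tset.endorsements:
        space.jar(t)
    jar = space.jar(h)

    if tset.structure == INDEPENDENT:
        out = 1.0
        for t in tset.endorsements:
            out *= single_testimony_likelihood(t, h, model, space)
        return out

    # shared structure, n >= 1 enforced by TestimonySet
    if tset.shared_variant == COPY_AFTER_FIRST:
        first = tset.endorsements[0]
        if any(t != first for t in tset.endorsements[1:]):
            return 0.0
        return single_testimony_likelihood(first, h, model, space)

    # literal product over the shared draw
    out = 0.0
    for colour in space.colours:
        p_d = jar.likelihood(colour)
        if p_d == 0.0:
            continue
        dist = endorsement_distribution(model, colour, space)
        prod = 1.0
        for t in tset.endorsements:
            prod *= dist[t]
        out += p_d * prod
    return out


def _as_testimony_groups(
    testimony: TestimonySet | Iterable[TestimonySet] | None,
) -> tuple[TestimonySet, ...]:
    if testimony is None:
        return ()
    if isinstance(testimony, TestimonySet):
        return (testimony,)
    return tuple(testimony)


def posterior(
    space: HypothesisSpace,
    testimony: TestimonySet | Iterable[TestimonySet] | None,
    learner: LearnerData | None = None,
    model: InformantModel | None = None,
) -> dict[str, float]:
    """Posterior over jars given testimony and the learner's own draws.

    ``testimony`` may be a single :class:`TestimonySet` or a sequence of
    mutually independent sets (e.g. a shared-evidence majority plus an
    independently sampled dissenter).  With no testimony and no observations
    the prior is returned.

    Raises
    ------
    ValueError
        If every hypothesis has zero joint likelihood (impossible evidence).
    """
    groups = _as_testimony_groups(testimony)
    if groups and model is None:
        raise ValueError("an InformantModel is required when testimony is present")
    observations = learner.observations if learner is not None else ()

    scores: dict[str, float] = {}
    for jar in space.jars:
        lik = 1.0
        for tset in groups:
            lik *= testimony_set_likelihood(tset, jar.label, model, space)
        for colour in observations:
            lik *= jar.likelihood(colour)
        scores[jar.label] = lik * space.prior[jar.label]
    total = sum(scores.values())
    if total == 0.0:
        raise ValueError("impossible evidence: zero joint likelihood for every jar")
    return {lab: s / total for lab, s in scores.items()}


def posterior_from_samples(
    space: HypothesisSpace, learner: LearnerData
) -> dict[str, float]:
    """Posterior from directly observed draws only (no testimony).

    Identical for every informant model, since no endorsements enter the
    computation.
    """
    if len(learner) == 0:
        raise ValueError("posterior_from_samples requires at least one observation")
    return posterior(space, None, learner, None)


def predicted_choice_probability(posterior_value: float, rule: str) -> float:
    """Map a posterior probability to a predicted choice proportion.

    ``posterior_match`` is the identity (a population of probability-matching
    responders endorses in proportion to the posterior); ``posterior_maximize``
    thresholds at 1/2, returning 1/2 at an exact tie.
    """
    if not 0.0 <= posterior_value <= 1.0:
        raise ValueError(f"posterior_value must lie in [0, 1], got {posterior_value}")
    if rule == POSTERIOR_MATCH:
        return posterior_value
    if rule == POSTERIOR_MAXIMIZE:
        if posterior_value > 0.5:
            return 1.0
        if posterior_value < 0.5:
            return 0.0
        return 0.5
    raise ValueError(
        f"rule must be {POSTERIOR_MATCH!r} or {POSTERIOR_MAXIMIZE!r}, got {rule!r}"
    )


@dataclass(frozen=True)
class IdealObserver:
    """A configured ideal observer: hypothesis space + informant strategy
    + shared-datum treatment + response rule.

    Convenience object bundling the functional API for a fixed setting, so a
    prediction for one experimental cell is a single call.
    """

    space: HypothesisSpace
    strategy: str = "probability_match"
    shared_variant: str = LITERAL_PRODUCT
    response_rule: str = POSTERIOR_MATCH

    @property
    def informant_model(self) -> InformantModel:
        return InformantModel(self.strategy)

    def posterior(
        self,
        testimony: TestimonySet | Iterable[TestimonySet] | None = None,
        observations: Sequence[str] = (),
    ) -> dict[str, float]:
        return posterior(
            self.space, testimony, LearnerData(observations), self.informant_model
        )

    def majority_testimony(self, jar_label: str, n: int, structure: str) -> TestimonySet:
        """A unanimous n-strong endorsement of ``jar_label``."""
        return TestimonySet([jar_label] * n, structure, self.shared_variant)

    def predict_choice(self, posterior_value: float) -> float:
        return predicted_choice_probability(posterior_value, self.response_rule)
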