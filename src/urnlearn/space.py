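"""Domain types for the ball-and-urn testimony task.

The task: an experimenter fills a bag from one of two (or more) jars with
known colour compositions, draws balls from it, and shows them to informants
and/or to the learner.  The learner must infer which jar was chosen from the
informants' endorsements and any directly observed draws.

These types carry no behaviour beyond validation and elementary likelihoods;
the inference machinery lives in :mod:`urnlearn.observer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Jar",
    "HypothesisSpace",
    "InformantModel",
    "TestimonySet",
    "LearnerData",
    "MAXIMIZE",
    "PROBABILITY_MATCH",
    "INDEPENDENT",
    "SHARED",
    "LITERAL_PRODUCT",
    "COPY_AFTER_FIRST",
    "POSTERIOR_MATCH",
    "POSTERIOR_MAXIMIZE",
]

# Informant decision strategies.
MAXIMIZE = "maximize"
PROBABILITY_MATCH = "probability_match"

# Evidence structures for a set of testimony.
INDEPENDENT = "independent"
SHARED = "shared"

# Treatments of a shared datum's likelihood (see observer.testimony_set_likelihood).
LITERAL_PRODUCT = "literal_product"
COPY_AFTER_FIRST = "copy_after_first"

# Mappings from a posterior to a predicted choice probability.
POSTERIOR_MATCH = "posterior_match"
POSTERIOR_MAXIMIZE = "posterior_maximize"


@dataclass(frozen=True)
class Jar:
    """One candidate urn: a label and an integer colour composition.

    Parameters
    ----------
    label :
        Identifier for the hypothesis this jar represents.
    composition :
        Mapping colour -> ball count.  Counts must be positive integers and
        at least one colour must be present.
    """

    label: str
    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError(f"jar {self.label!r} must contain at least one colour")
        for colour, count in self.composition.items():
            if not isinstance(count, int) or count < 1:
                raise ValueError(
                    f"jar {self.label!r}: count for colour {colour!r} must be a "
                    f"positive integer, got {count!r}"
                )
        object.__setattr__(self, "composition", dict(self.composition))

    @property
    def total(self) -> int:
        return sum(self.composition.values())

    def likelihood(self, colour: str) -> float:
        """p(draw = colour | this jar); zero for colours absent from the jar."""
        return self.composition.get(colour, 0) / self.total


@dataclass(frozen=True)
class HypothesisSpace:
    """An ordered collection of candidate jars with a prior over them.

    The prior defaults to uniform.  Jar labels must be unique and prior
    weights must be non-negative and sum to one (tolerance 1e-12).
    """

    jars: Sequence[Jar]
    prior: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        jars = tuple(self.jars)
        if len(jars) < 2:
            raise ValueError("a hypothesis space needs at least two jars")
        labels = [j.label for j in jars]
        if len(set(labels)) != len(labels):
            raise ValueError(f"jar labels must be unique, got {labels}")
        if self.prior is None:
            prior = {lab: 1.0 / len(jars) for lab in labels}
        else:
            prior = dict(self.prior)
            if set(prior) != set(labels):
                raise ValueError("prior must assign a weight to every jar label")
            if any(w < 0 for w in prior.values()):
                raise ValueError("prior weights must be non-negative")
            if abs(sum(prior.values()) - 1.0) > 1e-12:
                raise ValueError("prior weights must sum to 1 (tolerance 1e-12)")
        object.__setattr__(self, "jars", jars)
        object.__setattr__(self, "prior", prior)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(j.label for j in self.jars)

    @property
    def colours(self) -> tuple[str, ...]:
        """All colours appearing in any jar, in first-appearance order."""
        seen: dict[str, None] = {}
        for jar in self.jars:
            for colour in jar.composition:
                seen.setdefault(colour, None)
        return tuple(seen)

    def jar(self, label: str) -> Jar:
        for j in self.jars:
            if j.label == label:
                return j
        raise KeyError(f"unknown jar label {label!r}; valid labels: {self.labels}")


@dataclass(frozen=True)
class InformantModel:
    """How an informant turns their private draw into an endorsement.

    ``maximize``: deterministically endorse the jar with the highest
    posterior given the draw, splitting uniformly over exact ties.
    ``probability_match``: endorse each jar with probability equal to its
    single-datum posterior.
    """

    strategy: str = PROBABILITY_MATCH

    def __post_init__(self) -> None:
        if self.strategy not in (MAXIMIZE, PROBABILITY_MATCH):
            raise ValueError(
                f"strategy must be {MAXIMIZE!r} or {PROBABILITY_MATCH!r}, "
                f"got {self.strategy!r}"
            )


@dataclass(frozen=True)
class TestimonySet:
    """An ordered list of endorsements plus their evidence structure.

    ``independent`` informants each drew a private ball; ``shared``
    informants all inspected one common ball.  ``shared_variant`` selects the
    treatment of the shared datum (see
    :func:`urnlearn.observer.testimony_set_likelihood`).
    """

    endorsements: Sequence[str]
    structure: str = INDEPENDENT
    shared_variant: str = LITERAL_PRODUCT

    def __post_init__(self) -> None:
        endorsements = tuple(self.endorsements)
        if self.structure not in (INDEPENDENT, SHARED):
            raise ValueError(
                f"structure must be {INDEPENDENT!r} or {SHARED!r}, got {self.structure!r}"
            )
        if self.shared_variant not in (LITERAL_PRODUCT, COPY_AFTER_FIRST):
            raise ValueError(
                f"shared_variant must be {LITERAL_PRODUCT!r} or {COPY_AFTER_FIRST!r}, "
                f"got {self.shared_variant!r}"
            )
        if self.structure == SHARED and len(endorsements) < 1:
            raise ValueError("a shared testimony set needs at least one endorsement")
        object.__setattr__(self, "endorsements", endorsements)

    def __len__(self) -> int:
        return len(self.endorsements)


@dataclass(frozen=True)
class LearnerData:
    """Colours of the balls the learner directly observed (possibly none)."""

    observations: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))

    def __len__(self) -> int:
        return len(self.observations)
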