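"""Condition definitions for the three child experiments and model tables.

Each experiment is a 2x2 between-subjects design crossing

* majority evidence: ``independent`` (each majority member drew a private
  ball) vs ``shared`` (all inspected one common ball), and
* dissenting information: a dissenting ``informant``, the learner's
  ``own_observation`` (an opposite-colour ball given to the child), or — in
  the testimony-free design — a final sample presented apart (``none``).

Experiment 1 uses ball jars in a 5:1 ratio plus one distractor ball unique
to each jar, with 2-person majorities in the dissenting-informant cells and
3-person majorities in the own-ball cells.  Experiment 2 uses toy jars
(5:1, no distractors) with 3-person majorities everywhere.  Experiment 3
removes informants: the draws themselves are visible, three majority-colour
cups plus one dissenting cup (independent) or one cup of each colour
(shared).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .observer import IdealObserver, posterior_from_samples
from .space import (
    INDEPENDENT,
    LITERAL_PRODUCT,
    POSTERIOR_MATCH,
    SHARED,
    HypothesisSpace,
    Jar,
    LearnerData,
)

__all__ = [
    "ConditionSpec",
    "exp1_space",
    "plain_space",
    "builtin_space",
    "builtin_conditions",
    "equal_majority_conditions",
    "prediction_table",
    "independence_effect",
    "independence_effect_breakdown",
]

DISSENT_SOURCES = ("informant", "own_observation", "none")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental cell.

    For testimony cells (Experiments 1-2), ``majority_size`` concurring
    endorsements of ``majority_jar`` are delivered under
    ``evidence_structure``, and the dissent is either one independent
    dissenting endorsement of the other jar (``dissent_source='informant'``)
    or an opposite-colour ball observed by the learner
    (``dissent_source='own_observation'``).

    Testimony-free cells (Experiment 3) set ``observed_sample`` to the full
    multiset of visible draws; ``majority_size`` then counts the
    majority-colour draws.
    """

    experiment: int
    cell_id: str
    majority_size: int
    evidence_structure: str
    dissent_source: str
    majority_jar: str
    dissent_colour: str
    majority_colour: str
    observed_sample: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.evidence_structure not in (INDEPENDENT, SHARED):
            raise ValueError(f"bad evidence_structure {self.evidence_structure!r}")
        if self.dissent_source not in DISSENT_SOURCES:
            raise ValueError(f"bad dissent_source {self.dissent_source!r}")
        if self.majority_size < 1:
            raise ValueError("majority_size must be >= 1")
        if self.observed_sample is not None:
            object.__setattr__(self, "observed_sample", tuple(self.observed_sample))

    @property
    def has_testimony(self) -> bool:
        return self.observed_sample is None


def exp1_space() -> HypothesisSpace:
    """Ball jars: 5:1 ratio plus one distractor ball unique to each jar.

    The distractor balls were visible and enter the model's likelihoods even
    though they were never sampled.
    """
    return HypothesisSpace(
        [
            Jar("mostly_red", {"red": 5, "yellow": 1, "white": 1}),
            Jar("mostly_yellow", {"yellow": 5, "red": 1, "green": 1}),
        ]
    )


def plain_space(
    majority_colour: str = "frog", minority_colour: str = "fish", ratio: tuple[int, int] = (5, 1)
) -> HypothesisSpace:
    """Two-colour 5:1 jars (toy jars of the later experiments)."""
    hi, lo = ratio
    return HypothesisSpace(
        [
            Jar(f"mostly_{majority_colour}", {majority_colour: hi, minority_colour: lo}),
            Jar(f"mostly_{minority_colour}", {minority_colour: hi, majority_colour: lo}),
        ]
    )


def builtin_space(experiment: int) -> HypothesisSpace:
    if experiment == 1:
        return exp1_space()
    if experiment in (2, 3):
        return plain_space()
    raise ValueError(f"unknown experiment {experiment!r}; valid ids: 1, 2, 3")


def _testimony_cells(
    experiment: int,
    majority_jar: str,
    majority_colour: str,
    dissent_colour: str,
    n_informant: int,
    n_own: int,
) -> list[ConditionSpec]:
    cells = []
    for structure in (INDEPENDENT, SHARED):
        cells.append(
            ConditionSpec(
                experiment=experiment,
                cell_id=f"exp{experiment}_{structure}_informant",
                majority_size=n_informant,
                evidence_structure=structure,
                dissent_source="informant",
                majority_jar=majority_jar,
                dissent_colour=dissent_colour,
                majority_colour=majority_colour,
            )
        )
    for structure in (INDEPENDENT, SHARED):
        cells.append(
            ConditionSpec(
                experiment=experiment,
                cell_id=f"exp{experiment}_{structure}_own",
                majority_size=n_own,
                evidence_structure=structure,
                dissent_source="own_observation",
                majority_jar=majority_jar,
                dissent_colour=dissent_colour,
                majority_colour=majority_colour,
            )
        )
    return cells


def builtin_conditions(experiment: int) -> list[ConditionSpec]:
    """The four cells of one experiment, with design-faithful majority sizes.

    Experiment 1: 2-person majorities in the dissenting-informant cells,
    3-person in the own-ball cells (total informant count was equated
    instead of majority size).  Experiment 2: 3-person majorities in every
    cell.  Experiment 3: visible sample multisets, no testimony.
    """
    if experiment == 1:
        return _testimony_cells(1, "mostly_red", "red", "yellow", n_informant=2, n_own=3)
    if experiment == 2:
        return _testimony_cells(2, "mostly_frog", "frog", "fish", n_informant=3, n_own=3)
    if experiment == 3:
        cells = []
        for dissent_source, tag in (("none", "last"), ("own_observation", "own")):
            for structure, n_maj in ((INDEPENDENT, 3), (SHARED, 1)):
                cells.append(
                    ConditionSpec(
                        experiment=3,
                        cell_id=f"exp3_{structure}_{tag}",
                        majority_size=n_maj,
                        evidence_structure=structure,
                        dissent_source=dissent_source,
                        majority_jar="mostly_frog",
                        dissent_colour="fish",
                        majority_colour="frog",
                        observed_sample=("frog",) * n_maj + ("fish",),
                    )
                )
        return cells
    raise ValueError(f"unknown experiment {experiment!r}; valid ids: 1, 2, 3")


def equal_majority_conditions(experiment: int = 1) -> list[ConditionSpec]:
    """The experiment's cells with every majority set to three informants.

    The canonical task narrative describes three concurring informants in
    every condition; Experiment 2 implements exactly that.  For Experiment 1
    this variant differs from the design as run, whose dissenting-informant
    cells used two-person majorities.
    """
    return [
        c if not c.has_testimony else replace(c, majority_size=3, cell_id=c.cell_id + "_eq3")
        for c in builtin_conditions(experiment)
    ]


def predict_condition(cond: ConditionSpec, observer: IdealObserver) -> float:
    """Model probability of choosing the majority-consistent jar in one cell."""
    space = observer.space
    if not cond.has_testimony:
        post = posterior_from_samples(space, LearnerData(cond.observed_sample))
        return observer.predict_choice(post[cond.majority_jar])

    groups = [
        observer.majority_testimony(
            cond.majority_jar, cond.majority_size, cond.evidence_structure
        )
    ]
    observations: list[str] = []
    other = [lab for lab in space.labels if lab != cond.majority_jar]
    if len(other) != 1:
        raise ValueError("testimony cells require a two-jar hypothesis space")
    if cond.dissent_source == "informant":
        groups.append(observer.majority_testimony(other[0], 1, INDEPENDENT))
    elif cond.dissent_source == "own_observation":
        observations.append(cond.dissent_colour)
    post = observer.posterior(groups, observations)
    return observer.predict_choice(post[cond.majority_jar])


def prediction_table(
    experiment: int,
    strategy: str = "probability_match",
    shared_variant: str = LITERAL_PRODUCT,
    response_rule: str = POSTERIOR_MATCH,
    conditions: Sequence[ConditionSpec] | None = None,
    space: HypothesisSpace | None = None,
) -> pd.DataFrame:
    """One prediction row per cell of the experiment.

    Columns: cell_id, experiment, evidence_structure, dissent_source,
    majority_size, informant_strategy, shared_variant, response_rule,
    p_majority.
    """
    if conditions is None:
        conditions = builtin_conditions(experiment)
    if space is None:
        space = builtin_space(experiment)
    observer = IdealObserver(space, strategy, shared_variant, response_rule)
    rows = []
    for cond in conditions:
        rows.append(
            {
                "cell_id": cond.cell_id,
                "experiment": cond.experiment,
                "evidence_structure": cond.evidence_structure,
                "dissent_source": cond.dissent_source,
                "majority_size": cond.majority_size,
                "informant_strategy": strategy,
                "shared_variant": shared_variant,
                "response_rule": response_rule,
                "p_majority": predict_condition(cond, observer),
            }
        )
    return pd.DataFrame(rows)


def _paired_differences(table: pd.DataFrame) -> pd.Series:
    """independent-minus-shared p_majority per dissenting-information condition."""
    required = {"evidence_structure", "dissent_source", "p_majority"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"prediction table lacks columns {sorted(missing)}")
    pivot = table.pivot_table(
        index="dissent_source", columns="evidence_structure", values="p_majority"
    )
    if not {INDEPENDENT, SHARED} <= set(pivot.columns) or pivot.isna().any().any():
        raise ValueError(
            "table must contain an independent and a shared cell for every "
            "dissenting-information condition"
        )
    return pivot[INDEPENDENT] - pivot[SHARED]


def independence_effect(table: pd.DataFrame) -> float:
    """Predicted advantage (percentage points) of independent over shared
    majority evidence, averaged with equal weight over the dissenting
    conditions.

    100 x mean over dissent conditions of
    (p_majority[independent] - p_majority[shared]).
    """
    return 100.0 * float(_paired_differences(table).mean())


def independence_effect_breakdown(table: pd.DataFrame) -> pd.DataFrame:
    """Per-dissent-condition independent-minus-shared differences (in %)."""
    diffs = _paired_differences(table) * 100.0
    return diffs.rename("independence_effect_pct").reset_index()
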