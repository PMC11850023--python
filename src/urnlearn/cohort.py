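"""Synthetic child cohorts for the between-subjects testimony designs.

The generator mirrors the experiments' structure — a 2x2 between-subjects
layout, binary jar choices, uniform ages, deterministic majority-jar
counterbalancing — under parameterized candidate decision strategies:

``bayesian``
    Choices drawn from the ideal observer's predicted probability for the
    cell (configurable informant strategy / shared variant / response rule).
``conform``
    Always choose the majority jar.
``own_data``
    In own-observation cells, follow one's own sample with probability
    ``theta`` (so the majority is chosen with probability 1 - theta); in
    all other cells choose the majority with probability ``phi``.
``uniform``
    Choose at random.

The displayed evidence is scripted exactly as in the experiments (the
majority always endorses the pre-assigned jar, the dissenting sample is
always opposite); ``generative=True`` instead samples evidence at random
from the pre-assigned jar, for model exploration only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .experiments import ConditionSpec, builtin_space, predict_condition
from .observer import IdealObserver
from .space import LITERAL_PRODUCT, POSTERIOR_MATCH, HypothesisSpace

__all__ = [
    "StrategySpec",
    "CohortConfig",
    "CHOICE_COLUMNS",
    "cell_choice_probability",
    "simulate_cohort",
    "estimate_strategy",
    "StrategyEstimate",
    "StrategyFit",
]

STRATEGY_KINDS = ("bayesian", "conform", "own_data", "uniform")

#: Fixed column schema of a choice table (one row per participant).
CHOICE_COLUMNS = (
    "participant_id",
    "experiment",
    "cell_id",
    "evidence_structure",
    "dissent_source",
    "majority_jar",
    "age_months",
    "chose_majority",
)


@dataclass(frozen=True)
class StrategySpec:
    """A candidate decision strategy for simulated children."""

    kind: str = "bayesian"
    informant_strategy: str = "probability_match"
    shared_variant: str = LITERAL_PRODUCT
    response_rule: str = POSTERIOR_MATCH
    theta: float = 0.5
    phi: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"kind must be one of {STRATEGY_KINDS}, got {self.kind!r}")
        for name in ("theta", "phi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CohortConfig:
    """Size, strategy, seed and age range of one simulated cohort."""

    n_per_cell: int
    strategy: StrategySpec = field(default_factory=StrategySpec)
    seed: int = 0
    age_range_months: tuple[int, int] = (45, 71)
    age_slope: float = 0.0  # optional logistic slope per month, 0 = no age effect

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        lo, hi = self.age_range_months
        if lo > hi:
            raise ValueError("age_range_months must satisfy low <= high")


def cell_choice_probability(
    strategy: StrategySpec,
    condition: ConditionSpec,
    space: HypothesisSpace | None = None,
) -> float:
    """Probability that a participant following ``strategy`` chooses the
    majority-consistent jar in ``condition``."""
    if strategy.kind == "conform":
        return 1.0
    if strategy.kind == "uniform":
        return 0.5
    if strategy.kind == "own_data":
        if condition.dissent_source == "own_observation":
            return 1.0 - strategy.theta
        return strategy.phi
    if space is None:
        space = builtin_space(condition.experiment)
    observer = IdealObserver(
        space,
        strategy.informant_strategy,
        strategy.shared_variant,
        strategy.response_rule,
    )
    return predict_condition(condition, observer)


def simulate_cohort(
    config: CohortConfig,
    conditions: Sequence[ConditionSpec],
    space: HypothesisSpace | None = None,
    generative: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_per_cell`` participants in every cell.

    Returns a choice table with the :data:`CHOICE_COLUMNS` schema.  The
    majority jar alternates deterministically within each cell
    (counterbalancing, split differing by at most one); ages are uniform
    integers over the configured range; the same (config, conditions) pair
    always yields a bit-identical table.

    With ``generative=True`` the evidence shown in each trial is drawn at
    random from the counterbalanced majority jar instead of being scripted,
    and the Bayesian strategies respond to the realised evidence.  This mode
    is for model exploration; the experiments themselves were scripted.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions must be non-empty")
    experiments = {c.experiment for c in conditions}
    if len(experiments) != 1:
        raise ValueError("all conditions must come from a single experiment")
    if space is None:
        space = builtin_space(conditions[0].experiment)

    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range_months
    mid_age = (lo + hi) / 2.0
    rows = []
    pid = 0
    for cond in conditions:
        n = config.n_per_cell
        other = [lab for lab in space.labels if lab != cond.majority_jar]
        jar_cycle = [cond.majority_jar, other[0]] if other else [cond.majority_jar]
        ages = rng.integers(lo, hi + 1, size=n)
        if generative:
            p = np.array(
                [
                    _generative_choice_probability(config.strategy, cond, space, rng)
                    for _ in range(n)
                ]
            )
        else:
            p = np.full(n, cell_choice_probability(config.strategy, cond, space))
        if config.age_slope != 0.0:
            logit = np.log(np.clip(p, 1e-12, 1.0) / np.clip(1.0 - p, 1e-12, 1.0))
            p = 1.0 / (1.0 + np.exp(-(logit + config.age_slope * (ages - mid_age))))
        chose = (rng.random(n) < p).astype(int)
        for i in range(n):
            rows.append(
                (
                    f"p{pid:05d}",
                    cond.experiment,
                    cond.cell_id,
                    cond.evidence_structure,
                    cond.dissent_source,
                    jar_cycle[i % len(jar_cycle)],
                    int(ages[i]),
                    int(chose[i]),
                )
            )
            pid += 1
    return pd.DataFrame(rows, columns=list(CHOICE_COLUMNS))


def _generative_choice_probability(
    strategy: StrategySpec,
    cond: ConditionSpec,
    space: HypothesisSpace,
    rng: np.random.Generator,
) -> float:
    """Choice probability with evidence re-sampled from the majority jar."""
    if strategy.kind != "bayesian":
        return cell_choice_probability(strategy, cond, space)
    jar = space.jar(cond.majority_jar)
    colours = list(jar.composition)
    weights = np.array([jar.composition[c] for c in colours], dtype=float)
    weights /= weights.sum()
    observer = IdealObserver(
        space, strategy.informant_strategy, strategy.shared_variant, strategy.response_rule
    )
    if not cond.has_testimony:
        n_draws = len(cond.observed_sample)
        draws = list(rng.choice(colours, size=n_draws, p=weights))
        post = observer.posterior(None, draws)
        return observer.predict_choice(post[cond.majority_jar])
    # informants respond to sampled draws; the learner sees only endorsements
    n_draws = 1 if cond.evidence_structure == "shared" else cond.majority_size
    draws = rng.choice(colours, size=n_draws, p=weights)
    model = observer.informant_model
    from .observer import endorsement_distribution  # local to avoid cycle at import

    endorsements = []
    for d in (list(draws) * cond.majority_size)[: cond.majority_size] if n_draws == 1 else draws:
        dist = endorsement_distribution(model, d, space)
        labs = list(dist)
        endorsements.append(rng.choice(labs, p=[dist[l] for l in labs]))
    from .space import TestimonySet

    groups = [TestimonySet(endorsements, cond.evidence_structure, strategy.shared_variant)]
    observations = []
    if cond.dissent_source == "informant":
        dissent_draw = rng.choice(colours, p=weights)
        dist = endorsement_distribution(model, dissent_draw, space)
        labs = list(dist)
        groups.append(TestimonySet([rng.choice(labs, p=[dist[l] for l in labs])]))
    elif cond.dissent_source == "own_observation":
        observations.append(rng.choice(colours, p=weights))
    post = observer.posterior(groups, observations)
    return observer.predict_choice(post[cond.majority_jar])


@dataclass(frozen=True)
class StrategyEstimate:
    """One recovered parameter with its exact 95% interval."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    boundary: bool  # pinned at 0 or 1 (degenerate cell), flagged not fatal


@dataclass(frozen=True)
class StrategyFit:
    """Maximum-likelihood recovery of a strategy family's parameters."""

    family: str
    estimates: tuple[StrategyEstimate, ...]

    def __getitem__(self, name: str) -> StrategyEstimate:
        for est in self.estimates:
            if est.name == name:
                return est
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.name,
                    "estimate": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "k": e.k,
                    "n": e.n,
                    "boundary": e.boundary,
                }
                for e in self.estimates
            ]
        )


def _binomial_estimate(name: str, k: int, n: int, invert: bool = False) -> StrategyEstimate:
    from scipy.stats import beta

    p_hat = k / n
    lo = 0.0 if k == 0 else float(beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.isf(0.025, k + 1, n - k))
    if invert:  # parameter is 1 - choice probability
        p_hat, lo, hi = 1.0 - p_hat, 1.0 - hi, 1.0 - lo
    return StrategyEstimate(name, p_hat, lo, hi, k, n, boundary=k in (0, n))


def estimate_strategy(records: pd.DataFrame, strategy_family: str) -> StrategyFit:
    """Recover a strategy family's parameters from a choice table.

    ``own_data``: theta = 1 - P(choose majority | own-observation cells),
    phi = P(choose majority | remaining cells); exact Clopper-Pearson 95%
    intervals.  Degenerate cells (all 0 or all 1) are flagged via the
    ``boundary`` field, not fatal.

    ``saturated``: the best-fitting response probability per cell.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    if strategy_family == "own_data":
        estimates = []
        own = records[records["dissent_source"] == "own_observation"]
        rest = records[records["dissent_source"] != "own_observation"]
        if len(own):
            estimates.append(
                _binomial_estimate(
                    "theta", int(own["chose_majority"].sum()), len(own), invert=True
                )
            )
        if len(rest):
            estimates.append(
                _binomial_estimate("phi", int(rest["chose_majority"].sum()), len(rest))
            )
        if not estimates:
            raise ValueError("records contain no usable cells for the own_data family")
        return StrategyFit("own_data", tuple(estimates))
    if strategy_family == "saturated":
        estimates = [
            _binomial_estimate(str(cell), int(grp["chose_majority"].sum()), len(grp))
            for cell, grp in records.groupby("cell_id", sort=True)
        ]
        return StrategyFit("saturated", tuple(estimates))
    raise ValueError(
        f"strategy_family must be 'own_data' or 'saturated', got {strategy_family!r}"
    )
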