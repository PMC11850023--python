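"""Statistical pipeline for binary jar-choice tables.

Per-cell endorsement rates with exact intervals, factorial logistic
regressions with likelihood-ratio tests, per-condition chance tests,
observed-vs-model comparisons, contingency analysis of justification codes,
and inter-rater agreement.

Logistic fits are maximum-likelihood via iteratively reweighted least
squares (statsmodels GLM with a binomial family); identical covariate rows
are aggregated into binomial counts before the solver call, which changes
nothing about the estimates.  Reported deviances are on the Bernoulli scale
(-2 x the maximized log-likelihood, whose saturated reference is zero), so
deviance differences between nested fits are likelihood-ratio statistics
regardless of how each fit grouped its rows.  Factor coding is sum-to-zero
(+1/-1) by default, matching the factorial tests; per-condition chance
tests are separate intercept-only fits on the relevant subset, for which
B = logit(k/n) and SE = sqrt(1/k + 1/(n-k)) in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "SeparationError",
    "GlmFit",
    "LrtResult",
    "ContingencyFit",
    "KappaResult",
    "endorsement_table",
    "ChoiceLogit",
    "fit_logistic",
    "lrt",
    "chance_test",
    "compare_to_model",
    "contingency_chisq",
    "cohens_kappa",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Raised when a logistic MLE does not exist (complete separation)."""


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.isf(alpha / 2, k + 1, n - k))
    return lo, hi


def endorsement_table(
    records: pd.DataFrame, by: Sequence[str] = ("cell_id",)
) -> pd.DataFrame:
    """Per-cell successes, n, proportion and exact (Clopper-Pearson) 95% CI."""
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    rows = []
    for key, grp in records.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        k, n = int(grp["chose_majority"].sum()), len(grp)
        lo, hi = _clopper_pearson(k, n)
        rows.append(dict(zip(by, key)) | {
            "k": k, "n": n, "proportion": k / n, "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test between two nested logistic fits."""

    chi_square: float
    df: int
    p: float


@dataclass
class GlmFit:
    """A fitted logistic model: per-coefficient Wald table plus deviance.

    ``params`` is indexed by term and has columns estimate, se, z, p,
    odds_ratio, ci_low, ci_high (the interval is Wald on the log-odds scale,
    exponentiated).
    """

    params: pd.DataFrame
    deviance: float
    df_model: int
    nobs: int
    converged: bool
    coding: str
    terms: tuple[str, ...]

    def summary(self) -> str:
        lines = [
            f"Logistic fit ({self.coding} coding), n = {self.nobs}, "
            f"deviance = {self.deviance:.4f}, converged = {self.converged}",
            self.params.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def _aggregate(design: pd.DataFrame, outcome: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Collapse identical covariate rows into binomial (successes, failures)."""
    df = design.copy()
    df["_y"] = outcome
    cols = [c for c in design.columns]
    grouped = df.groupby(cols, sort=True)["_y"].agg(["sum", "count"]).reset_index()
    endog = np.column_stack(
        [grouped["sum"].to_numpy(float), (grouped["count"] - grouped["sum"]).to_numpy(float)]
    )
    return grouped[cols], endog


def _build_design(
    records: pd.DataFrame,
    factors: Sequence[str],
    interaction: bool,
    include_age: bool,
    coding: str,
) -> tuple[pd.DataFrame, tuple[str, ...], dict[str, tuple[str, str]]]:
    if coding != "sum":
        raise ValueError("only sum-to-zero ('sum') coding is implemented")
    design = pd.DataFrame({"intercept": np.ones(len(records))}, index=records.index)
    levels_used: dict[str, tuple[str, str]] = {}
    for f in factors:
        levels = sorted(records[f].astype(str).unique())
        if len(levels) == 1:
            raise ValueError(f"factor {f!r} has a single level in these records")
        if len(levels) > 2:
            raise ValueError(f"factor {f!r} has more than two levels; not supported")
        # +1 for the first sorted level, -1 for the second
        design[f] = np.where(records[f].astype(str) == levels[0], 1.0, -1.0)
        levels_used[f] = (levels[0], levels[1])
    if interaction:
        if len(factors) != 2:
            raise ValueError("interaction requires exactly two factors")
        design[f"{factors[0]}:{factors[1]}"] = design[factors[0]] * design[factors[1]]
    if include_age:
        age = records["age_months"].to_numpy(float)
        design["age_months"] = age - age.mean()
    return design, tuple(design.columns), levels_used


def _separating_factors(records: pd.DataFrame, factors: Sequence[str]) -> list[str]:
    out = []
    for f in factors:
        for _, grp in records.groupby(f):
            if grp["chose_majority"].nunique() == 1:
                out.append(f)
                break
    return out


class ChoiceLogit:
    """Logistic model of majority choice, statsmodels-style.

    Build from a choice table, then ``fit()`` for a :class:`GlmFit` results
    object.  ``factors`` name two-level columns entered with sum-to-zero
    (+1/-1) contrasts; ``interaction`` adds their product; ``include_age``
    adds centred age in months as a linear term.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        factors: Sequence[str] = (),
        interaction: bool = False,
        include_age: bool = False,
        coding: str = "sum",
    ) -> None:
        if len(records) == 0:
            raise ValueError("records must be non-empty")
        if not records["chose_majority"].isin((0, 1)).all():
            raise ValueError("chose_majority must be binary 0/1")
        self.records = records
        self.factors = tuple(factors)
        self.interaction = interaction
        self.include_age = include_age
        self.coding = coding

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> GlmFit:
        records = self.records
        design, terms, _ = _build_design(
            records, self.factors, self.interaction, self.include_age, self.coding
        )
        outcome = records["chose_majority"].to_numpy(int)
        if outcome.min() == outcome.max():
            raise SeparationError(
                "all outcomes identical: the intercept-only MLE is infinite "
                "(complete separation)"
            )
        exog, endog = _aggregate(design, outcome)
        model = sm.GLM(endog, exog.to_numpy(float), family=sm.families.Binomial())
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import (
            PerfectSeparationError,
            PerfectSeparationWarning,
        )

        try:
            with _warnings.catch_warnings():
                # saturated aggregations leave 0 residual df, which trips a
                # harmless scale computation inside the IRLS helper
                _warnings.simplefilter("ignore", RuntimeWarning)
                _warnings.simplefilter("ignore", PerfectSeparationWarning)
                res = model.fit(maxiter=maxiter, tol=tol)
        except PerfectSeparationError as exc:
            culprits = _separating_factors(records, self.factors) or ["intercept"]
            raise SeparationError(
                f"complete separation detected; separating factor(s): {culprits}"
            ) from exc
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 15.0:
            culprits = _separating_factors(records, self.factors) or ["intercept"]
            raise SeparationError(
                f"complete separation detected; separating factor(s): {culprits}"
            )
        est = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        z = est / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        # Bernoulli-scale deviance: -2 * maximized log-likelihood, computed
        # from the fitted group probabilities (saturated reference = 0)
        mu = np.clip(np.asarray(res.fittedvalues, float), 1e-12, 1.0 - 1e-12)
        k, m = endog[:, 0], endog[:, 0] + endog[:, 1]
        deviance = -2.0 * float(np.sum(k * np.log(mu) + (m - k) * np.log1p(-mu)))
        with np.errstate(over="ignore"):  # near-boundary cells: inf upper bound
            table = pd.DataFrame(
                {
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": p,
                    "odds_ratio": np.exp(est),
                    "ci_low": np.exp(est - Z_95 * se),
                    "ci_high": np.exp(est + Z_95 * se),
                },
                index=list(terms),
            )
        return GlmFit(
            params=table,
            deviance=deviance,
            df_model=len(terms),
            nobs=len(records),
            converged=bool(res.converged),
            coding=self.coding,
            terms=tuple(terms),
        )


def fit_logistic(
    records: pd.DataFrame,
    factors: Sequence[str] = (),
    interaction: bool = False,
    include_age: bool = False,
    coding: str = "sum",
) -> GlmFit:
    """Functional front-end to :class:`ChoiceLogit`."""
    return ChoiceLogit(records, factors, interaction, include_age, coding).fit()


def lrt(fit_reduced: GlmFit, fit_full: GlmFit) -> LrtResult:
    """Likelihood-ratio test between nested fits on identical records.

    chi_square = deviance(reduced) - deviance(full); df is the
    parameter-count difference; p from the upper chi-square tail.
    """
    if fit_reduced.nobs != fit_full.nobs:
        raise ValueError("fits are not on identical records (different n)")
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ValueError(
            "models are not nested: reduced terms must be a subset of "
            f"full terms ({fit_reduced.terms} vs {fit_full.terms})"
        )
    df = fit_full.df_model - fit_reduced.df_model
    chi2 = fit_reduced.deviance - fit_full.deviance
    chi2 = max(chi2, 0.0)  # guard tiny negative from convergence tolerance
    if df == 0:
        return LrtResult(chi_square=chi2, df=0, p=1.0)
    return LrtResult(chi_square=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def chance_test(records_subset: pd.DataFrame) -> GlmFit:
    """Intercept-only fit on a subset; chance responding corresponds to B = 0."""
    return fit_logistic(records_subset, factors=())


def compare_to_model(
    endorsements: pd.DataFrame, predictions: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell observed-minus-predicted deviations with exact binomial tests.

    ``endorsements`` is the output of :func:`endorsement_table`;
    ``predictions`` must carry cell_id and p_majority.  Every endorsement
    cell must have a matching prediction.
    """
    preds = predictions.set_index("cell_id")["p_majority"]
    rows = []
    for _, row in endorsements.iterrows():
        cell = row["cell_id"]
        if cell not in preds.index:
            raise ValueError(f"no model prediction for cell {cell!r}")
        p0 = float(preds.loc[cell])
        k, n = int(row["k"]), int(row["n"])
        p_exact = float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
        rows.append(
            {
                "cell_id": cell,
                "observed": k / n,
                "predicted": p0,
                "deviation": k / n - p0,
                "k": k,
                "n": n,
                "p_exact": p_exact,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyFit:
    """Pearson chi-square for an r x c table with adjusted residuals."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi_square: float
    df: int
    p: float
    residuals: pd.DataFrame  # adjusted standardized residuals e_ij


def contingency_chisq(observed: pd.DataFrame | np.ndarray) -> ContingencyFit:
    """Pearson chi-square with adjusted standardized residuals.

    e_ij = (O - E) / sqrt(E (1 - row/total) (1 - col/total)); each e_ij is
    approximately standard normal under independence, so a single cell's
    contribution can be tested directly.
    """
    obs = pd.DataFrame(observed).astype(float)
    if (obs.to_numpy() < 0).any():
        raise ValueError("observed counts must be non-negative")
    row = obs.sum(axis=1).to_numpy()
    col = obs.sum(axis=0).to_numpy()
    total = obs.to_numpy().sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("every row and column margin must be positive")
    chi2, p, df, expected = stats.chi2_contingency(obs.to_numpy(), correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    denom = np.sqrt(
        expected
        * (1.0 - row[:, None] / total)
        * (1.0 - col[None, :] / total)
    )
    resid = pd.DataFrame(
        (obs.to_numpy() - expected) / denom, index=obs.index, columns=obs.columns
    )
    return ContingencyFit(obs, exp, float(chi2), int(df), float(p), resid)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa: chance-corrected agreement between two coders."""

    kappa: float
    observed_agreement: float
    chance_agreement: float


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """kappa = (po - pe) / (1 - pe), pe from the coders' marginal products.

    Raises
    ------
    ValueError
        If the sequences differ in length, or chance agreement is 1 (both
        coders constant on the same category), making kappa undefined.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    if len(a) == 0:
        raise ValueError("label sequences must be non-empty")
    cats = sorted(set(a) | set(b))
    if len(cats) < 2:
        raise ValueError(
            "kappa undefined: fewer than 2 categories used jointly "
            "(chance agreement is 1)"
        )
    po = float((a.to_numpy() == b.to_numpy()).mean())
    pa = a.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    pb = b.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    pe = float((pa * pb).sum())
    if pe == 1.0:
        raise ValueError("kappa undefined: chance agreement equals 1")
    return KappaResult((po - pe) / (1.0 - pe), po, pe)
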