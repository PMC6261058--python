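"""Wald tests, effect translation, change-in-deviance tests and backward
model selection for the study's logistic models.

Two nested logistic fits are compared through the change in deviance

    Delta D = D_reduced - D_current = 2 * (l_current - l_reduced),

referred to an upper-tail chi-square with df equal to the difference in
residual degrees of freedom.  A significant change means the dropped term(s)
worsened the fit.  ``signed_delta`` additionally reports the display
convention used in the sequential table (current minus reduced, negative when
the reduced model fits worse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .data import CellTable, ObservationSet
from .glm import LogitGlm, LogitGlmResults, ModelFormula

__all__ = [
    "WaldResult",
    "DevianceComparison",
    "SelectionStep",
    "SelectionTrace",
    "NonNestedModelError",
    "wald_test",
    "effect_translation",
    "change_in_deviance",
    "sequential_deviance_table",
    "backward_select",
    "MODEL_LABELS",
]

#: Candidate final models of the backward-elimination procedure.
MODEL_LABELS = ("full", "main_effects", "motivation_only", "relationship_only", "null")

_LABEL_BY_TERMS = {
    frozenset({"Relationship", "Motivation", "Relationship:Motivation"}): "full",
    frozenset({"Relationship", "Motivation"}): "main_effects",
    frozenset({"Motivation"}): "motivation_only",
    frozenset({"Relationship"}): "relationship_only",
    frozenset(): "null",
}


class NonNestedModelError(ValueError):
    """The reduced model's terms are not a subset of the current model's."""


def _as_model(data, formula: ModelFormula) -> LogitGlm:
    if isinstance(data, CellTable):
        return LogitGlm.from_cells(data, formula)
    if isinstance(data, ObservationSet):
        return LogitGlm.from_observations(data, formula)
    raise TypeError(f"cannot build a model from {type(data).__name__}")


@dataclass(frozen=True)
class WaldResult:
    """Per-coefficient Wald z statistics against H0: beta_j = 0."""

    table: pd.DataFrame

    def __getitem__(self, label: str) -> pd.Series:
        return self.table.loc[label]


def wald_test(fit: LogitGlmResults) -> WaldResult:
    """Wald test of each coefficient: z = estimate/SE, two-sided N(0,1) p."""
    return WaldResult(fit.wald_table())


@dataclass(frozen=True)
class EffectTranslation:
    """A linear-predictor contrast moved to the natural scale."""

    odds_ratio: float
    probability: float


def effect_translation(
    fit: LogitGlmResults, terms: tuple[str, ...] = ()
) -> EffectTranslation:
    """Translate a sum of coefficients to an odds ratio and a probability.

    ``odds_ratio`` is exp of the summed non-intercept coefficients (the
    relative effect against the reference cell); ``probability`` is the
    inverse logit of the intercept plus that sum (the absolute effect).
    An empty subset returns odds ratio 1 and the baseline probability.
    """
    params = fit.params
    total = 0.0
    for t in terms:
        if t not in params.index:
            raise KeyError(f"term {t!r} not in fitted model")
        total += float(params[t])
    eta = float(params.iloc[0]) + total
    return EffectTranslation(odds_ratio=float(np.exp(total)), probability=float(expit(eta)))


@dataclass(frozen=True)
class DevianceComparison:
    """Change-in-deviance comparison of two nested fits."""

    current_label: str
    reduced_label: str
    delta: float          # D_reduced - D_current  (the chi-square statistic, >= 0)
    signed_delta: float   # D_current - D_reduced  (display convention)
    df_diff: int
    pvalue: float

    def is_significant(self, alpha: float = 0.05) -> bool:
        return self.pvalue < alpha


def change_in_deviance(
    fit_current: LogitGlmResults, fit_reduced: LogitGlmResults
) -> DevianceComparison:
    """Likelihood-ratio (change in deviance) test of nested logistic fits."""
    cur_terms = fit_current.formula.effective_terms
    red_terms = fit_reduced.formula.effective_terms
    if not red_terms < cur_terms and red_terms != cur_terms:
        raise NonNestedModelError(
            f"{fit_reduced.formula.label()!r} is not nested in "
            f"{fit_current.formula.label()!r}"
        )
    if fit_current.nobs != fit_reduced.nobs:
        raise NonNestedModelError("fits are not on the same data")
    delta = fit_reduced.deviance - fit_current.deviance
    df_diff = fit_reduced.df_resid - fit_current.df_resid
    if delta < -1e-8:
        raise NonNestedModelError(
            "reduced model has smaller deviance; models are not nested as fitted"
        )
    delta = max(delta, 0.0)
    p = 1.0 if df_diff == 0 else float(chi2.sf(delta, df_diff))
    return DevianceComparison(
        current_label=fit_current.formula.label(),
        reduced_label=fit_reduced.formula.label(),
        delta=float(delta),
        signed_delta=float(-delta),
        df_diff=int(df_diff),
        pvalue=p,
    )


def sequential_deviance_table(data, alpha: float = 0.05) -> pd.DataFrame:
    """Deviance summary of the sequential term-removal exercise.

    Rows: the full interaction model; the main-effects model (interaction
    removed); motivation removed from the main-effects model; relationship
    removed (motivation reintroduced).  The delta column uses the display
    convention (parent deviance minus row deviance, negative when dropping a
    term worsens fit); the test p-value is the upper chi-square tail of |delta|.
    """
    fits = {
        name: _as_model(data, f).fit()
        for name, f in {
            "full": ModelFormula.full(),
            "main": ModelFormula.main_effects(),
            "rel_only": ModelFormula.of("Relationship"),
            "mot_only": ModelFormula.of("Motivation"),
        }.items()
    }
    rows = [
        ("Full model", fits["full"], None),
        ("Interaction removed (main effects only)", fits["main"], fits["full"]),
        ("Motivation removed", fits["rel_only"], fits["main"]),
        ("Relationship removed", fits["mot_only"], fits["main"]),
    ]
    records = []
    for name, fit, parent in rows:
        if parent is None:
            delta, p = np.nan, np.nan
        else:
            cmp_ = change_in_deviance(parent, fit)
            delta, p = cmp_.signed_delta, cmp_.pvalue
        records.append(
            {
                "model": name,
                "deviance": fit.deviance,
                "df": fit.df_resid,
                "delta_deviance": delta,
                "pvalue": p,
                "significant": (p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class SelectionStep:
    """One tested deletion during backward elimination."""

    dropped_term: str
    from_model: str
    deviance_before: float
    deviance_after: float
    delta: float
    pvalue: float
    dropped: bool


@dataclass
class SelectionTrace:
    """Record of a backward-elimination run and its final model."""

    alpha: float
    steps: list[SelectionStep] = field(default_factory=list)
    final: str = "full"
    final_fit: LogitGlmResults | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def backward_select(data, alpha: float = 0.05, check_rank: bool = True) -> SelectionTrace:
    """Backward elimination by chi-square(1) change-in-deviance tests.

    The interaction is tested first (marginality is respected during
    deletion); if retained the full model is final.  Otherwise main effects
    are dropped one at a time, always removing the term with the largest
    non-significant p, refitting after each drop.

    ``check_rank=False`` lets degenerate designs (an empty predictor cell)
    proceed through pseudo-inverse fits, flagged on the results.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    trace = SelectionTrace(alpha=alpha)
    full = _as_model(data, ModelFormula.full()).fit(check_rank=check_rank)
    main = _as_model(data, ModelFormula.main_effects()).fit(check_rank=check_rank)
    cmp_int = change_in_deviance(full, main)
    dropped = cmp_int.pvalue >= alpha
    trace.steps.append(
        SelectionStep(
            dropped_term="Relationship:Motivation",
            from_model=full.formula.label(),
            deviance_before=full.deviance,
            deviance_after=main.deviance,
            delta=cmp_int.delta,
            pvalue=cmp_int.pvalue,
            dropped=dropped,
        )
    )
    if not dropped:
        trace.final, trace.final_fit = "full", full
        return trace

    current_terms = ["Relationship", "Motivation"]
    current_fit = main
    while current_terms:
        candidates = []
        for term in current_terms:
            reduced_terms = tuple(t for t in current_terms if t != term)
            reduced = _as_model(data, ModelFormula.of(*reduced_terms)).fit(
                check_rank=check_rank
            )
            candidates.append((term, reduced, change_in_deviance(current_fit, reduced)))
        term, reduced, cmp_ = max(candidates, key=lambda c: c[2].pvalue)
        dropped = cmp_.pvalue >= alpha
        trace.steps.append(
            SelectionStep(
                dropped_term=term,
                from_model=current_fit.formula.label(),
                deviance_before=current_fit.deviance,
                deviance_after=reduced.deviance,
                delta=cmp_.delta,
                pvalue=cmp_.pvalue,
                dropped=dropped,
            )
        )
        if not dropped:
            break
        current_terms.remove(term)
        current_fit = reduced
    trace.final = _LABEL_BY_TERMS[frozenset(current_terms)]
    trace.final_fit = current_fit
    return trace
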