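"""BIC-based Bayesian Model Averaging for the study's logistic models.

All subsets of the candidate terms are enumerated (the intercept is always
included and no marginality constraint is imposed, so the interaction may
appear without its main effects).  Each model k is scored with

    BIC_k = D_k - df_k * ln(n),

where D_k is the binary-convention deviance and df_k the residual degrees of
freedom n - p_k.  This differs from the textbook p*ln(n) - 2*loglik form only
by the additive constant n*ln(n), so model rankings and the posterior model
probabilities

    p(M_k | X) = exp(-BIC_k / 2) / sum_i exp(-BIC_i / 2)

(uniform model prior) are identical under either convention.  An Occam's
window keeps only models whose posterior probability is within a fixed odds
ratio (default 20) of the best model's, then renormalizes.

Per-term inclusion probabilities are sums of retained-model probabilities;
model-averaged coefficient moments use the mixture over the retained window,
with models that exclude a term contributing a point mass at zero (the
default "unconditional" average; the conditional-on-inclusion variant is also
available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CellTable, ObservationSet
from .glm import LogitGlm, LogitGlmResults, ModelFormula, TERMS

__all__ = [
    "CandidateModel",
    "BmaLogit",
    "BmaResults",
    "ModelSpaceCapError",
    "enumerate_models",
    "bic_of",
    "model_posteriors",
    "occams_window",
    "inclusion_probabilities",
    "averaged_moments",
    "comparison_table",
]


class ModelSpaceCapError(ValueError):
    """The candidate-term count exceeds the enumeration cap."""


def bic_of(fit: LogitGlmResults, n: int | None = None) -> float:
    """BIC in the deviance-minus-df*ln(n) convention."""
    if n is None:
        n = fit.nobs
    return float(fit.deviance - fit.df_resid * np.log(n))


def model_posteriors(bics) -> np.ndarray:
    """Posterior model probabilities: softmax of -BIC/2 (max-shifted)."""
    b = np.asarray(bics, dtype=float)
    w = np.exp(-(b - b.min()) / 2.0)
    return w / w.sum()


def occams_window(probs, odds_ratio: float = 20.0) -> np.ndarray:
    """Boolean retention mask: probability within ``odds_ratio`` of the best."""
    if not odds_ratio > 1.0:
        raise ValueError("Occam's window odds ratio must exceed 1")
    p = np.asarray(probs, dtype=float)
    return p >= p.max() / odds_ratio


@dataclass(eq=False)
class CandidateModel:
    """One enumerated model with its fit, BIC and posterior probability."""

    terms: tuple[str, ...]
    fit: LogitGlmResults
    bic: float
    posterior_prob: float = np.nan   # over the full enumeration
    retained: bool = False
    weight: float = np.nan           # renormalized within the Occam window

    @property
    def label(self) -> str:
        return self.fit.formula.label()

    def coefficient(self, term: str) -> float:
        params = self.fit.params
        return float(params[term]) if term in params.index else 0.0

    def std_error(self, term: str) -> float:
        bse = self.fit.bse
        return float(bse[term]) if term in bse.index else 0.0


def enumerate_models(
    data,
    candidate_terms: tuple[str, ...] = TERMS,
    cap: int = 15,
    check_rank: bool = True,
) -> list[CandidateModel]:
    """Fit every subset of ``candidate_terms`` (intercept always included)."""
    k = len(candidate_terms)
    if k > cap:
        raise ModelSpaceCapError(
            f"{k} candidate terms exceed the enumeration cap of {cap} "
            f"(2^{k} models); raise the cap explicitly if intended"
        )
    models = []
    for r in range(k + 1):
        for subset in combinations(candidate_terms, r):
            formula = ModelFormula.of(*subset)
            if isinstance(data, CellTable):
                fit = LogitGlm.from_cells(data, formula).fit(check_rank=check_rank)
            else:
                fit = LogitGlm.from_observations(data, formula).fit(
                    check_rank=check_rank
                )
            models.append(CandidateModel(terms=formula.terms, fit=fit, bic=bic_of(fit)))
    probs = model_posteriors([m.bic for m in models])
    for m, p in zip(models, probs):
        m.posterior_prob = float(p)
    return models


class BmaLogit:
    """Model object for BIC-based Bayesian Model Averaging."""

    def __init__(
        self,
        data,
        candidate_terms: tuple[str, ...] = TERMS,
        cap: int = 15,
    ):
        if not isinstance(data, (CellTable, ObservationSet)):
            raise TypeError(f"cannot build a model space from {type(data).__name__}")
        self.data = data
        self.candidate_terms = tuple(candidate_terms)
        self.cap = cap

    def fit(self, occam_odds: float = 20.0, check_rank: bool = True) -> "BmaResults":
        models = enumerate_models(
            self.data, self.candidate_terms, self.cap, check_rank=check_rank
        )
        mask = occams_window([m.posterior_prob for m in models], occam_odds)
        retained = [m for m, keep in zip(models, mask) if keep]
        weights = np.array([m.posterior_prob for m in retained])
        weights = weights / weights.sum()
        for m, w in zip(retained, weights):
            m.retained = True
            m.weight = float(w)
        return BmaResults(
            models=sorted(models, key=lambda m: m.bic),
            terms=self.candidate_terms,
            occam_odds=occam_odds,
        )


class BmaResults:
    """Enumerated model space with windowed posterior weights and averages."""

    def __init__(
        self, models: list[CandidateModel], terms: tuple[str, ...], occam_odds: float
    ):
        self.models = models
        self.terms = terms
        self.occam_odds = occam_odds
        self.retained = [m for m in models if m.retained]
        if not self.retained:
            raise ValueError("no models retained")
        self.nobs = models[0].fit.nobs

    @property
    def best_model(self) -> CandidateModel:
        return min(self.models, key=lambda m: m.bic)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def inclusion_probabilities(self) -> pd.Series:
        """Pr(beta != 0) per term: summed retained-model weights containing it."""
        out = {"Intercept": 1.0}
        for t in self.terms:
            out[t] = float(sum(m.weight for m in self.retained if t in m.terms))
        return pd.Series(out, name="Pr(beta != 0)")

    def averaged_mean(self, conditional: bool = False) -> pd.Series:
        """Model-averaged posterior mean per coefficient.

        Unconditional (default): models excluding the term contribute zero.
        Conditional: averaged over the models that contain the term only.
        """
        incl = self.inclusion_probabilities()
        out = {}
        for t in ("Intercept",) + self.terms:
            m1 = sum(m.weight * m.coefficient(t) for m in self.retained)
            if conditional:
                out[t] = m1 / incl[t] if incl[t] > 0 else np.nan
            else:
                out[t] = m1
        return pd.Series(out, name="posterior mean")

    def averaged_sd(self, conditional: bool = False) -> pd.Series:
        """Model-averaged posterior SD per coefficient (mixture moments)."""
        incl = self.inclusion_probabilities()
        means = self.averaged_mean(conditional=conditional)
        out = {}
        for t in ("Intercept",) + self.terms:
            e2 = sum(
                m.weight * (m.std_error(t) ** 2 + m.coefficient(t) ** 2)
                for m in self.retained
            )
            if conditional:
                e2 = e2 / incl[t] if incl[t] > 0 else np.nan
            var = e2 - means[t] ** 2
            out[t] = float(np.sqrt(max(var, 0.0)))
        return pd.Series(out, name="posterior sd")

    def cell_predictions(self) -> np.ndarray:
        """Model-averaged fitted probability per predictor profile."""
        pred = np.zeros(4)
        for m in self.retained:
            pred += m.weight * expit(m.fit.cell_linear_predictor())
        return pred

    def summary(self, n_models: int | None = None) -> pd.DataFrame:
        """Averaging summary plus per-model coefficient columns.

        Rows: intercept and candidate terms (coefficients; blank = excluded),
        then the posterior probability and BIC of each retained model, ordered
        by posterior probability.
        """
        if n_models is None:
            n_models = self.n_retained
        shown = sorted(self.retained, key=lambda m: -m.weight)[:n_models]
        rows = ("Intercept",) + self.terms
        table = pd.DataFrame(
            {
                "Pr(beta != 0)": self.inclusion_probabilities(),
                "mean": self.averaged_mean(),
                "sd": self.averaged_sd(),
            },
            index=list(rows),
        )
        for i, m in enumerate(shown, start=1):
            col = []
            for t in rows:
                if t == "Intercept" or t in m.terms:
                    col.append(m.coefficient(t))
                else:
                    col.append(np.nan)
            table[f"Model {i}"] = col
        prob_row = {"Pr(beta != 0)": np.nan, "mean": np.nan, "sd": np.nan}
        bic_row = dict(prob_row)
        for i, m in enumerate(shown, start=1):
            prob_row[f"Model {i}"] = m.weight
            bic_row[f"Model {i}"] = m.bic
        table.loc["Posterior probability"] = prob_row
        table.loc["BIC"] = bic_row
        return table

    def image_text(self, width: int = 60) -> str:
        """Aligned-text stand-in for the usual BMA image plot.

        One column block per retained model, width proportional to its
        posterior probability; '+'/'-' code the coefficient sign, '.' means
        the term is excluded from that model.
        """
        shown = sorted(self.retained, key=lambda m: -m.weight)
        widths = [max(1, round(m.weight * width)) for m in shown]
        name_w = max(len(t) for t in self.terms)
        lines = [
            " " * name_w
            + " |"
            + "|".join(f"{m.weight:^{w}.2f}" if w >= 4 else "?" * w for m, w in zip(shown, widths))
            + "|"
        ]
        for t in self.terms:
            cells = []
            for m, w in zip(shown, widths):
                if t in m.terms:
                    ch = "+" if m.coefficient(t) >= 0 else "-"
                else:
                    ch = "."
                cells.append(ch * w)
            lines.append(f"{t:<{name_w}} |" + "|".join(cells) + "|")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "n_retained": self.n_retained,
            "occam_odds": self.occam_odds,
            "inclusion_probabilities": self.inclusion_probabilities().to_dict(),
            "averaged_mean": self.averaged_mean().to_dict(),
            "averaged_sd": self.averaged_sd().to_dict(),
            "models": [
                {
                    "terms": list(m.terms),
                    "bic": m.bic,
                    "posterior_prob": m.posterior_prob,
                    "retained": m.retained,
                    "weight": None if np.isnan(m.weight) else m.weight,
                    "coefficients": m.fit.params.to_dict(),
                }
                for m in self.models
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# -- spec-level convenience wrappers -----------------------------------------


def inclusion_probabilities(space: BmaResults) -> pd.Series:
    return space.inclusion_probabilities()


def averaged_moments(space: BmaResults, conditional: bool = False) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mean": space.averaged_mean(conditional=conditional),
            "sd": space.averaged_sd(conditional=conditional),
        }
    )


def comparison_table(
    glm_fit: LogitGlmResults,
    bayes_summary: pd.DataFrame,
    bma: BmaResults,
) -> pd.DataFrame:
    """Side-by-side coefficients and SDs from the three analyses.

    ``bayes_summary`` is a posterior summary frame with ``mean``/``sd``
    columns indexed like the GLM coefficients.
    """
    glm_labels = list(glm_fit.labels)
    bma_labels = ["Intercept"] + list(bma.terms)
    if glm_labels != bma_labels or len(bayes_summary) != len(glm_labels):
        raise ValueError("the three analyses do not share a term set")
    bayes = bayes_summary.copy()
    bayes.index = glm_labels
    return pd.DataFrame(
        {
            "GLM": glm_fit.params,
            "GLM sd": glm_fit.bse,
            "Bayesian": bayes["mean"],
            "Bayesian sd": bayes["sd"],
            "BMA": bma.averaged_mean().reindex(glm_labels),
            "BMA sd": bma.averaged_sd().reindex(glm_labels),
        }
    )
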