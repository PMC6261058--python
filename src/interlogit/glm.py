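"""Binomial GLM with logit link, fitted by iteratively reweighted least squares.

The model is the standard logistic regression

    Y_i ~ Bernoulli(pi_i),   logit(pi_i) = eta_i = x_i' beta,

with 0/1 treatment-coded predictors.  Two parameterizations of the worked
example's 2x2 design are supported and span the same column space:

* the conventional one — intercept, Relationship, Motivation and their
  product (the explicit interaction), and
* a single four-level factor with the (Rel=0, Mot=0) cell as baseline.

Fitting maximizes the ungrouped (binary) likelihood; internally, rows are
collapsed to their distinct covariate patterns, which leaves the MLE,
covariance and binary-convention deviance unchanged but makes repeated fits
(e.g. inside the simulation study) cheap.  Reported residual degrees of
freedom are always n_rows - p.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import PROFILE_ORDER, CellTable, ObservationSet

__all__ = [
    "ModelFormula",
    "DesignMatrix",
    "LogitGlm",
    "LogitGlmResults",
    "RankDeficientDesignError",
    "NotConvergedError",
    "SeparationWarning",
    "build_design",
    "fit_irls",
    "deviance_of",
    "inverse_logit",
    "inverse_logit_gradient",
    "linear_predictor_comparison",
]

#: Canonical non-intercept terms of the conventional parameterization.
TERMS = ("Relationship", "Motivation", "Relationship:Motivation")

_ALIASES = {
    "R": "Relationship",
    "M": "Motivation",
    "R:M": "Relationship:Motivation",
    "RM": "Relationship:Motivation",
    "M:R": "Relationship:Motivation",
    "MOTIVATION:RELATIONSHIP": "Relationship:Motivation",
    "RELATIONSHIP": "Relationship",
    "MOTIVATION": "Motivation",
    "RELATIONSHIP:MOTIVATION": "Relationship:Motivation",
}

#: Coefficient labels of the single-factor parameterization (levels 2-4,
#: with level 1 = (Rel 0, Mot 0) as baseline).
SINGLE_FACTOR_LABELS = ("Rel(1)-Mot(0)", "Rel(0)-Mot(1)", "Rel(1)-Mot(1)")

#: Probability clamp used in likelihood evaluation; keeps the deviance finite
#: under (quasi-)separation while leaving regular fits untouched.
_PROB_CLAMP = 1e-12

#: |eta| beyond which a fit is flagged as quasi-separated.
_SEPARATION_ETA = 30.0


class RankDeficientDesignError(np.linalg.LinAlgError):
    """The design matrix does not have full column rank."""


class NotConvergedError(RuntimeError):
    """IRLS hit the iteration cap before meeting the step tolerance."""


class SeparationWarning(UserWarning):
    """Some fitted linear predictor is extreme enough to suggest separation."""


class UndefinedWaldWarning(UserWarning):
    """A coefficient has zero standard error; its Wald statistic is undefined."""


@dataclass(frozen=True)
class ModelFormula:
    """Term set of a logistic model on the study's binary predictors.

    ``terms`` is an ordered subset of :data:`TERMS`; the intercept is always
    present.  ``single_factor=True`` selects the four-level single-factor
    parameterization instead (it spans the same space as the full term set).
    """

    terms: tuple[str, ...] = TERMS
    single_factor: bool = False

    def __post_init__(self) -> None:
        canon = tuple(_canonical_term(t) for t in self.terms)
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate terms in formula")
        # keep canonical ordering
        ordered = tuple(t for t in TERMS if t in canon)
        object.__setattr__(self, "terms", ordered)
        if self.single_factor and ordered not in ((), TERMS):
            raise ValueError("single-factor mode does not take a term subset")

    # -- constructors --------------------------------------------------------

    @classmethod
    def full(cls) -> "ModelFormula":
        return cls(TERMS)

    @classmethod
    def main_effects(cls) -> "ModelFormula":
        return cls(("Relationship", "Motivation"))

    @classmethod
    def intercept_only(cls) -> "ModelFormula":
        return cls(())

    @classmethod
    def single_factor_mode(cls) -> "ModelFormula":
        return cls(TERMS, single_factor=True)

    @classmethod
    def of(cls, *terms: str) -> "ModelFormula":
        return cls(tuple(terms))

    @classmethod
    def from_string(cls, spec: str) -> "ModelFormula":
        """Parse e.g. ``"Method ~ Relationship * Motivation"`` or ``"R + M"``."""
        rhs = spec.split("~")[-1].strip()
        if rhs in ("1", ""):
            return cls.intercept_only()
        tokens: list[str] = []
        for part in rhs.split("+"):
            part = part.strip()
            if not part or part == "1":
                continue
            if "*" in part:
                a, b = (p.strip() for p in part.split("*", 1))
                tokens.extend([a, b, f"{a}:{b}"])
            else:
                tokens.append(part)
        seen: list[str] = []
        for t in tokens:
            c = _canonical_term(t)
            if c not in seen:
                seen.append(c)
        return cls(tuple(seen))

    # -- properties ----------------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        if self.single_factor:
            return ("Intercept",) + SINGLE_FACTOR_LABELS
        return ("Intercept",) + self.terms

    @property
    def n_params(self) -> int:
        return len(self.labels)

    @property
    def effective_terms(self) -> frozenset[str]:
        """Term content for nesting checks (single-factor spans all terms)."""
        return frozenset(TERMS if self.single_factor else self.terms)

    def label(self) -> str:
        if self.single_factor:
            return "1 + factor(Rel-Mot)"
        return "1" + "".join(f" + {t}" for t in self.terms)


def _canonical_term(term: str) -> str:
    key = term.strip().upper()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(f"unknown model term {term!r}")


@dataclass(frozen=True, eq=False)
class DesignMatrix:
    """Row-level design: 0/1 predictor matrix (first column all ones) and response."""

    X: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...]
    formula: ModelFormula

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("design shape mismatch")
        if not np.all((X == 0) | (X == 1)):
            raise ValueError("design entries must be 0/1")
        if not np.all(X[:, 0] == 1):
            raise ValueError("first design column must be the intercept")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def nobs(self) -> int:
        return self.X.shape[0]


def _design_columns(rel: np.ndarray, mot: np.ndarray, formula: ModelFormula) -> np.ndarray:
    ones = np.ones_like(rel, dtype=float)
    if formula.single_factor:
        cols = [ones]
        for r, m in PROFILE_ORDER[1:]:
            cols.append(((rel == r) & (mot == m)).astype(float))
        return np.column_stack(cols)
    cols = [ones]
    for term in formula.terms:
        if term == "Relationship":
            cols.append(rel.astype(float))
        elif term == "Motivation":
            cols.append(mot.astype(float))
        else:
            cols.append((rel * mot).astype(float))
    return np.column_stack(cols)


def build_design(obs: ObservationSet, formula: ModelFormula | str) -> DesignMatrix:
    """Row-level treatment-coded design matrix for ``formula`` on ``obs``."""
    if isinstance(formula, str):
        formula = ModelFormula.from_string(formula)
    rel = obs.column("Relationship")
    mot = obs.column("Motivation")
    X = _design_columns(rel, mot, formula)
    return DesignMatrix(X, obs.column("Method").astype(float), formula.labels, formula)


def cell_design(formula: ModelFormula) -> np.ndarray:
    """Design rows of the four predictor profiles, in profile order."""
    rel = np.array([r for r, _ in PROFILE_ORDER], dtype=float)
    mot = np.array([m for _, m in PROFILE_ORDER], dtype=float)
    return _design_columns(rel, mot, formula)


# -- likelihood machinery on grouped counts ---------------------------------


def _loglik(eta: np.ndarray, s: np.ndarray, n: np.ndarray) -> float:
    mu = np.clip(expit(eta), _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    return float(s @ np.log(mu) + (n - s) @ np.log1p(-mu))


def _fit_grouped(
    Xg: np.ndarray,
    s: np.ndarray,
    n: np.ndarray,
    tol: float = 1e-10,
    maxiter: int = 50,
    check_rank: bool = True,
):
    """Grouped-binomial IRLS (Fisher scoring with step-halving).

    Returns (beta, cov, n_iter, converged, flagged) where ``flagged`` marks
    fits that needed a pseudo-inverse (rank-deficient information).
    """
    active = n > 0
    p = Xg.shape[1]
    deficient = np.linalg.matrix_rank(Xg[active]) < p
    if deficient and check_rank:
        raise RankDeficientDesignError(
            "design matrix is rank deficient on the observed covariate patterns"
        )
    beta = np.zeros(p)
    dev = -2.0 * _loglik(Xg @ beta, s, n)
    flagged = deficient
    converged = False
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        eta = Xg @ beta
        mu = expit(eta)
        w = n * mu * (1.0 - mu)
        score = Xg.T @ (s - n * mu)
        info = (Xg * w[:, None]).T @ Xg
        if deficient:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        else:
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
                flagged = True
        # step-halving: never accept a deviance increase
        for _ in range(30):
            cand = beta + step
            cand_dev = -2.0 * _loglik(Xg @ cand, s, n)
            if cand_dev <= dev + 1e-10:
                break
            step = step / 2.0
        beta, dev = beta + step, cand_dev
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xg @ beta
    mu = expit(eta)
    w = n * mu * (1.0 - mu)
    info = (Xg * w[:, None]).T @ Xg
    if deficient:
        cov = np.linalg.pinv(info)
    else:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
            flagged = True
    return beta, cov, n_iter, converged, flagged


class LogitGlm:
    """Logistic-regression model object.

    Construct from an :class:`~interlogit.data.ObservationSet`, a
    :class:`~interlogit.data.CellTable`, or a raw :class:`DesignMatrix`, then
    call :meth:`fit`.
    """

    def __init__(self, design: DesignMatrix):
        self.formula = design.formula
        self.labels = design.labels
        self._row_X: np.ndarray | None = design.X
        # collapse to distinct covariate patterns
        patterns, inverse = np.unique(design.X, axis=0, return_inverse=True)
        self._Xg = patterns
        self._n = np.bincount(inverse, minlength=len(patterns)).astype(float)
        self._s = np.bincount(
            inverse, weights=design.y, minlength=len(patterns)
        ).astype(float)
        self._row_pattern = inverse
        self.nobs = design.nobs

    @classmethod
    def from_observations(
        cls, obs: ObservationSet, formula: ModelFormula | str = ModelFormula.full()
    ) -> "LogitGlm":
        return cls(build_design(obs, formula))

    @classmethod
    def from_cells(
        cls, cells: CellTable, formula: ModelFormula | str = ModelFormula.full()
    ) -> "LogitGlm":
        if isinstance(formula, str):
            formula = ModelFormula.from_string(formula)
        model = cls.__new__(cls)
        model.formula = formula
        model.labels = formula.labels
        model._row_X = None
        model._Xg = cell_design(formula)
        model._n = np.asarray(cells.totals, dtype=float)
        model._s = np.asarray(cells.successes, dtype=float)
        model._row_pattern = None
        model.nobs = cells.grand_total
        return model

    def loglike(self, beta: np.ndarray) -> float:
        """Binary-convention log-likelihood at ``beta``."""
        beta = np.asarray(beta, dtype=float)
        return _loglik(self._Xg @ beta, self._s, self._n)

    def fit(
        self,
        tol: float = 1e-10,
        maxiter: int = 50,
        check_rank: bool = True,
        raise_on_nonconvergence: bool = False,
    ) -> "LogitGlmResults":
        beta, cov, n_iter, converged, flagged = _fit_grouped(
            self._Xg, self._s, self._n, tol=tol, maxiter=maxiter, check_rank=check_rank
        )
        if not converged and raise_on_nonconvergence:
            raise NotConvergedError(
                f"IRLS did not converge in {maxiter} iterations "
                f"(last max step unavailable; deviance {-2 * self.loglike(beta):.4f})"
            )
        res = LogitGlmResults(self, beta, cov, n_iter, converged, flagged)
        if np.max(np.abs(res.eta_patterns)) > _SEPARATION_ETA:
            warnings.warn(
                "fitted linear predictors exceed +/-30; data may be (quasi-)separated",
                SeparationWarning,
                stacklevel=2,
            )
            res.separation = True
        return res


class LogitGlmResults:
    """MLE fit of a logistic GLM: estimates, covariance, deviance, diagnostics."""

    def __init__(
        self,
        model: LogitGlm,
        beta: np.ndarray,
        cov: np.ndarray,
        n_iter: int,
        converged: bool,
        flagged: bool,
    ):
        self.model = model
        self.formula = model.formula
        self.labels = model.labels
        self._beta = np.asarray(beta, dtype=float)
        self._cov = np.asarray(cov, dtype=float)
        self.n_iter = n_iter
        self.converged = converged
        self.flagged = flagged
        self.separation = False
        self.nobs = model.nobs
        self.df_resid = model.nobs - len(beta)
        self.llf = model.loglike(beta)
        self.deviance = -2.0 * self.llf

    # -- parameter summaries -------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._beta, index=list(self.labels), name="estimate")

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=list(self.labels), columns=list(self.labels))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self._cov)), index=list(self.labels), name="std error"
        )

    @property
    def zvalues(self) -> pd.Series:
        se = self.bse.to_numpy()
        est = self._beta
        z = np.full_like(est, np.nan)
        if np.any(se == 0):
            warnings.warn(
                "zero standard error: Wald statistic undefined for some coefficients",
                UndefinedWaldWarning,
                stacklevel=2,
            )
        nz = se > 0
        z[nz] = est[nz] / se[nz]
        z[(se > 0) & (est == 0)] = 0.0
        return pd.Series(z, index=list(self.labels), name="z value")

    @property
    def pvalues(self) -> pd.Series:
        z = self.zvalues.to_numpy()
        p = 2.0 * norm.sf(np.abs(z))
        return pd.Series(p, index=list(self.labels), name="Pr(>|z|)")

    # -- fitted quantities ---------------------------------------------------

    @property
    def eta_patterns(self) -> np.ndarray:
        """Linear predictor at each distinct covariate pattern."""
        return self.model._Xg @ self._beta

    @property
    def linear_predictor(self) -> np.ndarray:
        """eta_i per input row (per pattern if built from a CellTable)."""
        eta = self.eta_patterns
        if self.model._row_pattern is None:
            return eta
        return eta[self.model._row_pattern]

    @property
    def fittedvalues(self) -> np.ndarray:
        return expit(self.linear_predictor)

    def cell_linear_predictor(self) -> np.ndarray:
        """eta at the four predictor profiles, in profile order."""
        return cell_design(self.formula) @ self._beta

    def cell_probabilities(self) -> np.ndarray:
        return expit(self.cell_linear_predictor())

    # -- output --------------------------------------------------------------

    def wald_table(self) -> pd.DataFrame:
        """Per-coefficient estimate, SE, z and two-sided normal p."""
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "Std. Error": self.bse,
                "z value": self.zvalues,
                "Pr(>|z|)": self.pvalues,
            }
        )

    def summary(self) -> str:
        table = self.wald_table().round(4).to_string()
        lines = [
            f"Logistic GLM (logit link), model: {self.formula.label()}",
            f"n = {self.nobs}, residual df = {self.df_resid}",
            f"deviance = {self.deviance:.4f}, log-likelihood = {self.llf:.4f}",
            f"converged = {self.converged} in {self.n_iter} IRLS iterations",
            "",
            table,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.formula.label(),
            "labels": list(self.labels),
            "coefficients": [float(b) for b in self._beta],
            "standard_errors": [float(v) for v in self.bse],
            "deviance": float(self.deviance),
            "df_resid": int(self.df_resid),
            "log_likelihood": float(self.llf),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# -- spec-level convenience operations ---------------------------------------


def fit_irls(design: DesignMatrix, **kwargs) -> LogitGlmResults:
    """Fit a logistic GLM on a row-level design matrix by IRLS."""
    return LogitGlm(design).fit(**kwargs)


def deviance_of(fit: LogitGlmResults) -> float:
    """Residual deviance, binary convention: -2 * log-likelihood at the MLE."""
    return fit.deviance


def inverse_logit(eta):
    """Numerically stable logistic function e^eta / (1 + e^eta)."""
    return expit(eta)


def inverse_logit_gradient(eta):
    """Derivative of the inverse logit: p(1-p) with p = expit(eta)."""
    p = expit(eta)
    return p * (1.0 - p)


def linear_predictor_comparison(
    fit_a: LogitGlmResults, fit_b: LogitGlmResults, cells: CellTable
) -> pd.DataFrame:
    """Per-profile linear predictors under two fits, with fitted probability,
    inverse-logit gradient, cell size and the change in linear predictor.

    ``change = lp_a - lp_b`` (the displacement of the reduced model's linear
    predictor relative to the richer model when ``fit_b`` is the reduced fit).
    """
    if fit_a.nobs != fit_b.nobs:
        raise ValueError("fits must be on the same data")
    lp_a = fit_a.cell_linear_predictor()
    lp_b = fit_b.cell_linear_predictor()
    prob = expit(lp_a)
    return pd.DataFrame(
        {
            "profile": [1, 2, 3, 4],
            "lp": lp_a,
            "probability": prob,
            "gradient": prob * (1.0 - prob),
            "n": cells.totals,
            "lp_reduced": lp_b,
            "change": lp_a - lp_b,
        }
    )
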