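"""Bayesian logistic regression by random-walk Metropolis-Hastings.

The posterior is

    p(beta | y, X)  proportional to  p(y | X, beta) * p(beta),

with a multivariate-normal prior beta ~ MVN(mu, Sigma).  For the worked
example the vaguely-informative prior encodes the pilot-study hypotheses:

    mu    = (-1.0, 0.1, 0.1, 1.1)
    Sigma = diag(2, 0.5, 0.5, 2)        (variances, not SDs)

so e.g. the intercept prior N(-1, 2) leaves 24% of its mass positive, and the
interaction prior N(1.1, 2) leaves 22% negative — directional but weak.

Sampling uses a symmetric Gaussian random-walk proposal whose covariance is
tune^2 times the inverse observed Fisher information at the MLE (falling back
to the prior covariance if the MLE is unavailable).  With the default
tune = 1.1 the example data yield an acceptance rate near 0.34.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import CellTable, ObservationSet
from .glm import DesignMatrix, LogitGlm, ModelFormula, cell_design

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "CellPosterior",
    "BayesLogitGlm",
    "TuningWarning",
    "log_posterior",
    "rw_metropolis",
    "posterior_summary",
    "posterior_functionals",
    "prior_tail_mass",
    "mc_standard_error",
]


class TuningWarning(UserWarning):
    """Post-burn-in acceptance rate is far from the useful range."""


@dataclass(frozen=True, eq=False)
class PriorSpec:
    """Multivariate-normal prior hyper-parameters (mean vector, covariance)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if cov.shape != (len(mean), len(mean)):
            raise ValueError("prior covariance shape does not match mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("prior covariance must be positive definite") from exc
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "_chol", chol)

    @classmethod
    def example_default(cls) -> "PriorSpec":
        """The worked example's vaguely-informative prior."""
        return cls(np.array([-1.0, 0.1, 0.1, 1.1]), np.diag([2.0, 0.5, 0.5, 2.0]))

    @classmethod
    def from_precision(cls, mean, precision) -> "PriorSpec":
        """Build from per-coordinate precisions (1 / variance)."""
        prec = np.atleast_1d(np.asarray(precision, dtype=float))
        if np.any(prec <= 0):
            raise ValueError("precisions must be positive")
        return cls(np.asarray(mean, dtype=float), np.diag(1.0 / prec))

    @classmethod
    def vague(cls, k: int, variance: float = 1e6) -> "PriorSpec":
        return cls(np.zeros(k), np.eye(k) * variance)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def logpdf(self, beta: np.ndarray) -> float:
        """MVN log-density at ``beta`` (normalizing constant included)."""
        d = np.asarray(beta, dtype=float) - self.mean
        u = np.linalg.solve(self._chol, d)
        logdet = 2.0 * np.sum(np.log(np.diag(self._chol)))
        k = len(self.mean)
        return float(-0.5 * (u @ u + logdet + k * np.log(2.0 * np.pi)))


@dataclass(frozen=True)
class McmcConfig:
    """Random-walk sampler settings (defaults follow the worked example)."""

    burnin: int = 10_000
    iterations: int = 100_000
    thin: int = 1
    tune: float = 1.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.iterations < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.thin < 1:
            raise ValueError("thinning stride must be >= 1")
        if self.tune <= 0:
            raise ValueError("tuning scalar must be positive")


def prior_tail_mass(prior: PriorSpec, index: int, side: str = "positive") -> float:
    """Mass of one (diagonal) prior coordinate on one side of zero."""
    sd = float(np.sqrt(prior.cov[index, index]))
    mean = float(prior.mean[index])
    if side == "positive":
        return float(norm.sf(0.0, loc=mean, scale=sd))
    if side == "negative":
        return float(norm.cdf(0.0, loc=mean, scale=sd))
    raise ValueError("side must be 'positive' or 'negative'")


class BayesLogitGlm:
    """Bayesian logistic-regression model: binomial likelihood, MVN prior."""

    def __init__(
        self,
        data,
        formula: ModelFormula | str = ModelFormula.full(),
        prior: PriorSpec | None = None,
    ):
        if isinstance(formula, str):
            formula = ModelFormula.from_string(formula)
        if isinstance(data, DesignMatrix):
            self._glm = LogitGlm(data)
        elif isinstance(data, CellTable):
            self._glm = LogitGlm.from_cells(data, formula)
        elif isinstance(data, ObservationSet):
            self._glm = LogitGlm.from_observations(data, formula)
        else:
            raise TypeError(f"cannot build a model from {type(data).__name__}")
        self.formula = self._glm.formula
        self.labels = self._glm.labels
        p = len(self.labels)
        if prior is None:
            prior = PriorSpec.example_default() if p == 4 else PriorSpec.vague(p)
        if len(prior.mean) != p:
            raise ValueError("prior dimension does not match design")
        self.prior = prior

    def log_posterior(self, beta) -> float:
        """Log binomial likelihood plus log MVN prior density at ``beta``."""
        beta = np.asarray(beta, dtype=float)
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta must be finite")
        return self._glm.loglike(beta) + self.prior.logpdf(beta)

    def _proposal_root(self, tune: float) -> tuple[np.ndarray, np.ndarray]:
        """Proposal covariance Cholesky factor and the chain start point."""
        try:
            mle = self._glm.fit()
            V = mle.cov_params.to_numpy()
            start = mle.params.to_numpy()
        except np.linalg.LinAlgError:
            V = self.prior.cov
            start = self.prior.mean.copy()
        if self._glm.nobs == 0:
            V = self.prior.cov
            start = self.prior.mean.copy()
        return tune * np.linalg.cholesky(V), start

    def fit(self, config: McmcConfig = McmcConfig()) -> "PosteriorDraws":
        """Run the random-walk Metropolis-Hastings sampler."""
        L, beta = self._proposal_root(config.tune)
        p = len(beta)
        total = config.burnin + config.iterations
        rng = np.random.default_rng(config.seed)
        steps = rng.standard_normal((total, p)) @ L.T
        logu = np.log(rng.random(total))

        n_keep = config.iterations // config.thin
        draws = np.empty((n_keep, p))
        lp = self.log_posterior(beta)
        accepted_post = 0
        kept = 0
        for t in range(total):
            cand = beta + steps[t]
            cand_lp = self.log_posterior(cand)
            if cand_lp - lp > logu[t]:
                beta, lp = cand, cand_lp
                if t >= config.burnin:
                    accepted_post += 1
            if t >= config.burnin and (t - config.burnin) % config.thin == config.thin - 1:
                if kept < n_keep:
                    draws[kept] = beta
                    kept += 1
        rate = accepted_post / config.iterations if config.iterations else float("nan")
        if config.iterations and not 0.05 < rate < 0.95:
            suggested = config.tune * (max(rate, 0.01) / 0.35) ** 0.5
            warnings.warn(
                f"acceptance rate {rate:.3f} outside (0.05, 0.95); "
                f"consider tune ~ {suggested:.2f}",
                TuningWarning,
                stacklevel=2,
            )
        return PosteriorDraws(
            draws=draws[:kept],
            labels=self.labels,
            acceptance_rate=float(rate),
            config=config,
            model=self,
        )


class PosteriorDraws:
    """Retained MCMC output with acceptance diagnostics and summaries."""

    def __init__(
        self,
        draws: np.ndarray,
        labels: tuple[str, ...],
        acceptance_rate: float,
        config: McmcConfig,
        model: BayesLogitGlm | None = None,
    ):
        draws = np.atleast_2d(np.asarray(draws, dtype=float))
        if draws.shape[1] != len(labels):
            raise ValueError("draw matrix width does not match labels")
        self.draws = draws
        self.labels = tuple(labels)
        self.acceptance_rate = acceptance_rate
        self.config = config
        self.model = model

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def summary(
        self, quantiles: tuple[float, ...] = (2.5, 25.0, 50.0, 75.0, 97.5)
    ) -> pd.DataFrame:
        """Posterior mean, SD and quantiles per parameter."""
        if self.n_draws == 0:
            raise ValueError("no retained draws to summarize")
        data = {
            "mean": self.draws.mean(axis=0),
            "sd": self.draws.std(axis=0, ddof=1) if self.n_draws > 1 else np.zeros(
                self.draws.shape[1]
            ),
        }
        for q in quantiles:
            data[f"{q:g}%"] = np.percentile(self.draws, q, axis=0)
        return pd.DataFrame(data, index=list(self.labels))

    def mc_se(self, index: int = 0, n_batches: int = 50) -> float:
        """Batch-means Monte-Carlo standard error of a posterior mean."""
        return mc_standard_error(self.draws[:, index], n_batches=n_batches)

    def functionals(self, cells: CellTable | None = None) -> "CellPosterior":
        """Posterior draws of the per-profile linear predictor and probability."""
        if self.model is None:
            raise ValueError("draws are not attached to a model")
        Xc = cell_design(self.model.formula)
        eta = self.draws @ Xc.T
        return CellPosterior(eta_draws=eta, cells=cells)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.draws, columns=list(self.labels)).to_csv(
            Path(path), index=False
        )


@dataclass(frozen=True, eq=False)
class CellPosterior:
    """Posterior draws of eta and pi for the four predictor profiles."""

    eta_draws: np.ndarray
    cells: CellTable | None = None

    @property
    def pi_draws(self) -> np.ndarray:
        return expit(self.eta_draws)

    def table(self, level: float = 0.80) -> pd.DataFrame:
        """Posterior means and equal-tail credible intervals per profile.

        The default 80% interval excludes the highest and lowest 10% of draws.
        """
        lo = 100.0 * (1.0 - level) / 2.0
        hi = 100.0 - lo
        pi = self.pi_draws
        out = pd.DataFrame(
            {
                "profile": [1, 2, 3, 4],
                "eta_mean": self.eta_draws.mean(axis=0),
                "pi_mean": pi.mean(axis=0),
                "pi_lower": np.percentile(pi, lo, axis=0),
                "pi_upper": np.percentile(pi, hi, axis=0),
            }
        )
        if self.cells is not None:
            out["n"] = self.cells.totals
        return out


def mc_standard_error(x: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means MC standard error of the mean of a (correlated) chain."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    if m < 2:
        raise ValueError("chain too short for the requested batch count")
    batches = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


# -- spec-level convenience operations ---------------------------------------


def log_posterior(beta, design, prior: PriorSpec) -> float:
    """Log posterior (up to a constant) of a logistic model on ``design``."""
    model = BayesLogitGlm(design, prior=prior) if isinstance(design, DesignMatrix) else None
    if model is None:
        raise TypeError("design must be a DesignMatrix; use BayesLogitGlm otherwise")
    return model.log_posterior(beta)


def rw_metropolis(design, prior: PriorSpec, config: McmcConfig) -> PosteriorDraws:
    """Sample the posterior of a logistic model by random-walk Metropolis."""
    return BayesLogitGlm(design, prior=prior).fit(config)


def posterior_summary(
    draws: PosteriorDraws, quantiles: tuple[float, ...] = (2.5, 25.0, 50.0, 75.0, 97.5)
) -> pd.DataFrame:
    return draws.summary(quantiles)


def posterior_functionals(draws: PosteriorDraws, cells: CellTable) -> CellPosterior:
    return draws.functionals(cells)
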