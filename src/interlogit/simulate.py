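"""Monte-Carlo simulation study of model selection and BMA behaviour.

The generator mirrors the worked example's population structure: each subject
is allocated to one of the four (Relationship, Motivation) profiles by a
multinomial draw with probabilities (0.16, 0.10, 0.26, 0.48), and the
indirect-method outcome is Bernoulli with per-profile probabilities
(0.25, 0.25, 0.40, 0.70).  On the logit scale this design implies true
coefficients

    beta_0 = logit(0.25) = -1.0986      (intercept)
    beta_R = 0                          (no relationship main effect)
    beta_M = logit(0.40) - logit(0.25) = 0.6931   (moderate effect)
    beta_RM = 1.2528                    (large interaction effect)

For each replicate and sample size the study applies backward
change-in-deviance selection and BMA to the same simulated dataset, recording
the selected model, the coefficient estimates (selected-model MLEs and
model-averaged means), the per-term inclusion probabilities, subgroup sizes,
and fitted per-profile probabilities.  Replicates with an empty cell or a
separable/rank-deficient fit are retained and flagged.

Reproducibility: the root seed spawns one independent substream per
(sample size, replicate) through ``numpy.random.SeedSequence``, so studies
are byte-reproducible and replicates are independent by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit as _logit

from .bma import BmaLogit
from .data import CellTable, ObservationSet, expand_to_observations
from .glm import SeparationWarning
from .inference import MODEL_LABELS, backward_select

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SizeResult",
    "INCLUSION_QUANTILES",
    "simulate_cells",
    "simulate_dataset",
    "run_simulation_study",
    "run_deviance_selection_study",
    "run_bma_study",
    "coefficient_recovery_summary",
    "prediction_summary",
]

#: Quantile levels (percent) reported for inclusion probabilities.
INCLUSION_QUANTILES = (5, 10, 15, 25, 50, 75, 90, 98)

#: Coefficient labels in design order.
_COEF_LABELS = ("Intercept", "Relationship", "Motivation", "Relationship:Motivation")

#: Profile index (0-based) whose subgroup size accompanies each term's
#: inclusion-probability row: R -> profile 2, M -> profile 3, R:M -> profile 4.
_TERM_PROFILE = {"Relationship": 1, "Motivation": 2, "Relationship:Motivation": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters and study settings."""

    allocation: tuple[float, float, float, float] = (0.16, 0.10, 0.26, 0.48)
    outcome_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.40, 0.70)
    sample_sizes: tuple[int, ...] = (110, 500, 1000)
    replicates: int = 1000
    alpha: float = 0.05
    occam_odds: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        alloc = np.asarray(self.allocation, dtype=float)
        probs = np.asarray(self.outcome_probs, dtype=float)
        if len(alloc) != 4 or len(probs) != 4:
            raise ValueError("allocation and outcome probabilities have 4 cells")
        if not np.isclose(alloc.sum(), 1.0):
            raise ValueError("allocation probabilities must sum to 1")
        if np.any(alloc < 0) or np.any((probs <= 0) | (probs >= 1)):
            raise ValueError("probabilities out of range")
        if self.replicates < 0:
            raise ValueError("replicates must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def true_coefficients(self) -> pd.Series:
        """Implied logit-scale coefficients of the generating design."""
        p = np.asarray(self.outcome_probs, dtype=float)
        b0 = _logit(p[0])
        bR = _logit(p[1]) - b0
        bM = _logit(p[2]) - b0
        bRM = _logit(p[3]) - b0 - bR - bM
        return pd.Series([b0, bR, bM, bRM], index=list(_COEF_LABELS))


def simulate_cells(config: SimulationConfig, n: int, rng: np.random.Generator) -> CellTable:
    """Draw one replicate's cell counts: multinomial allocation, binomial outcomes."""
    totals = rng.multinomial(n, config.allocation)
    successes = rng.binomial(totals, config.outcome_probs)
    return CellTable(tuple(int(t) for t in totals), tuple(int(s) for s in successes))


def simulate_dataset(
    config: SimulationConfig, n: int, seed: int | np.random.Generator | None = None
) -> ObservationSet:
    """Simulate one individual-level dataset of size ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = simulate_cells(config, n, rng)
    recorded = seed if isinstance(seed, int) else None
    return expand_to_observations(cells, provenance="simulated", seed=recorded)


@dataclass
class SizeResult:
    """Per-replicate records for one sample size."""

    n: int
    selection: np.ndarray          # (reps,) index into MODEL_LABELS
    glm_coefs: np.ndarray          # (reps, 4) selected-model MLEs, 0 when excluded
    glm_pred: np.ndarray           # (reps, 4) selected-model fitted cell probs
    bma_means: np.ndarray          # (reps, 4) model-averaged coefficient means
    bma_pred: np.ndarray           # (reps, 4) model-averaged fitted cell probs
    inclusion: np.ndarray          # (reps, 3) per-term inclusion probabilities
    subgroup_n: np.ndarray         # (reps, 4) simulated cell sizes
    flagged: np.ndarray            # (reps,) degenerate-replicate flag


@dataclass
class SimulationResult:
    """Study output: per-size records plus the generating configuration."""

    config: SimulationConfig
    sizes: dict[int, SizeResult] = field(default_factory=dict)

    @property
    def replicates(self) -> int:
        return self.config.replicates


def _embed_coefs(fit, labels=_COEF_LABELS) -> np.ndarray:
    out = np.zeros(len(labels))
    params = fit.params
    for j, lab in enumerate(labels):
        if lab in params.index:
            out[j] = float(params[lab])
    return out


def run_simulation_study(
    config: SimulationConfig,
    do_selection: bool = True,
    do_bma: bool = True,
) -> SimulationResult:
    """Run the full study; deviance selection and BMA share each dataset."""
    result = SimulationResult(config=config)
    root = np.random.SeedSequence(config.seed)
    size_streams = root.spawn(len(config.sample_sizes))
    terms = ("Relationship", "Motivation", "Relationship:Motivation")
    for n, stream in zip(config.sample_sizes, size_streams):
        reps = config.replicates
        rec = SizeResult(
            n=n,
            selection=np.full(reps, -1, dtype=int),
            glm_coefs=np.zeros((reps, 4)),
            glm_pred=np.full((reps, 4), np.nan),
            bma_means=np.zeros((reps, 4)),
            bma_pred=np.full((reps, 4), np.nan),
            inclusion=np.full((reps, 3), np.nan),
            subgroup_n=np.zeros((reps, 4), dtype=int),
            flagged=np.zeros(reps, dtype=bool),
        )
        for j, child in enumerate(stream.spawn(reps)):
            rng = np.random.default_rng(child)
            cells = simulate_cells(config, n, rng)
            rec.subgroup_n[j] = cells.totals
            degenerate = any(t == 0 for t in cells.totals)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                if do_selection:
                    trace = backward_select(cells, alpha=config.alpha, check_rank=False)
                    rec.selection[j] = MODEL_LABELS.index(trace.final)
                    rec.glm_coefs[j] = _embed_coefs(trace.final_fit)
                    rec.glm_pred[j] = trace.final_fit.cell_probabilities()
                    if trace.final_fit.flagged or trace.final_fit.separation:
                        degenerate = True
                if do_bma:
                    bma = BmaLogit(cells).fit(
                        occam_odds=config.occam_odds, check_rank=False
                    )
                    incl = bma.inclusion_probabilities()
                    rec.inclusion[j] = [incl[t] for t in terms]
                    means = bma.averaged_mean()
                    rec.bma_means[j] = [means[lab] for lab in _COEF_LABELS]
                    rec.bma_pred[j] = bma.cell_predictions()
                    if any(m.fit.flagged for m in bma.models):
                        degenerate = True
            if any(issubclass(w.category, SeparationWarning) for w in caught):
                degenerate = True
            rec.flagged[j] = degenerate
        result.sizes[n] = rec
    return result


def _ensure_result(x, **kwargs) -> SimulationResult:
    if isinstance(x, SimulationResult):
        return x
    if isinstance(x, SimulationConfig):
        return run_simulation_study(x, **kwargs)
    raise TypeError("expected a SimulationConfig or SimulationResult")


def run_deviance_selection_study(config_or_result) -> pd.DataFrame:
    """Selection counts per sample size (one column per final model)."""
    result = _ensure_result(config_or_result, do_bma=False)
    rows = []
    for n, rec in result.sizes.items():
        if result.replicates == 0:
            continue
        counts = {
            label: int((rec.selection == i).sum()) for i, label in enumerate(MODEL_LABELS)
        }
        rows.append({"N": n, **counts, "flagged": int(rec.flagged.sum())})
    return pd.DataFrame(rows)


def run_bma_study(config_or_result) -> pd.DataFrame:
    """Inclusion-probability quantiles per (term, sample size).

    Also reports the median and middle-80% range of the subgroup size tied to
    each term's effect (quantiles use linear interpolation).
    """
    result = _ensure_result(config_or_result, do_selection=False)
    terms = ("Relationship", "Motivation", "Relationship:Motivation")
    rows = []
    for t_idx, term in enumerate(terms):
        for n, rec in result.sizes.items():
            if result.replicates == 0:
                continue
            sizes = rec.subgroup_n[:, _TERM_PROFILE[term]]
            row = {
                "coefficient": term,
                "N": n,
                "median_n": float(np.median(sizes)),
                "n_lower": float(np.quantile(sizes, 0.10)),
                "n_upper": float(np.quantile(sizes, 0.90)),
            }
            for q in INCLUSION_QUANTILES:
                row[f"q{q}"] = float(np.quantile(rec.inclusion[:, t_idx], q / 100.0))
            rows.append(row)
    return pd.DataFrame(rows)


_RECOVERY_QUANTILES = (2.5, 10, 40, 60, 90, 97.5)


def coefficient_recovery_summary(config_or_result) -> pd.DataFrame:
    """Distribution of coefficient estimates per term, size and method.

    Methods: BMA model-averaged means and the deviance-selected model's MLEs
    (zero when the term is excluded from the selected model).
    """
    result = _ensure_result(config_or_result)
    rows = []
    for n, rec in result.sizes.items():
        if result.replicates == 0:
            continue
        for method, est in (("bma", rec.bma_means), ("deviance_selected", rec.glm_coefs)):
            for j, lab in enumerate(_COEF_LABELS):
                row = {
                    "coefficient": lab,
                    "N": n,
                    "method": method,
                    "mean": float(est[:, j].mean()),
                }
                for q in _RECOVERY_QUANTILES:
                    row[f"q{q:g}"] = float(np.quantile(est[:, j], q / 100.0))
                rows.append(row)
    return pd.DataFrame(rows)


_PREDICTION_QUANTILES = (10, 25, 50, 75, 90)


def prediction_summary(config_or_result) -> pd.DataFrame:
    """Distribution of fitted per-profile probabilities, by size and method.

    Profiles with zero allocation probability are excluded; their indices are
    listed in ``DataFrame.attrs['excluded_profiles']``.
    """
    result = _ensure_result(config_or_result)
    excluded = [
        i + 1 for i, a in enumerate(result.config.allocation) if a == 0
    ]
    rows = []
    for n, rec in result.sizes.items():
        if result.replicates == 0:
            continue
        for method, pred in (("bma", rec.bma_pred), ("deviance_selected", rec.glm_pred)):
            for i in range(4):
                if (i + 1) in excluded:
                    continue
                row = {
                    "profile": i + 1,
                    "N": n,
                    "method": method,
                    "true_probability": result.config.outcome_probs[i],
                    "mean": float(np.nanmean(pred[:, i])),
                }
                for q in _PREDICTION_QUANTILES:
                    row[f"q{q}"] = float(np.nanquantile(pred[:, i], q / 100.0))
                rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["excluded_profiles"] = excluded
    return out
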