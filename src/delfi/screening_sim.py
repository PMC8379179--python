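"""Monte Carlo model of screening performance in a high-risk population.

A hypothetical cohort of 100,000 high-risk individuals is screened with one
of four strategies: LDCT alone (with operating characteristics anchored to
either the LUCAS or the NLST cohort), a cfDNA-fragmentation prescreen
followed by LDCT, or a multimodal prescreen followed by LDCT. Uncertainty in
sensitivity (theta1), specificity (theta2), adherence (eta), and prevalence
(psi) is propagated with priors:

  theta1: LDCT_LUCAS  -> 0.5/0.5 mixture of N(0.96, 0.005) and N(0.94, 0.02)
          LDCT_NLST   -> Beta(93.8, 6.2)
          DELFI+LDCT  -> Beta(85, 15)
          DELFI_multi+LDCT -> Beta(91, 9)
  theta2: Beta(58, 42) / Beta(93.8, 6.2) / Beta(86, 14) / Beta(94, 6)
  eta:    Beta(12, 188) for LDCT-alone arms; Beta(15, 11) for blood-first arms
  psi:    Beta(9.1, 990.9)  (mean prevalence 0.91%)

Each repetition draws the parameters, then n ~ Binomial(pop, eta),
cancers ~ Binomial(n, psi), TP ~ Binomial(cancers, theta1),
FP ~ Binomial(n - cancers, 1 - theta2) -- count-level sampling,
distributionally identical to per-individual Bernoulli draws. 10,000
repetitions yield predictive distributions for detections, accuracy,
unnecessary procedures, and PPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES",
    "SENSITIVITY_PRIORS",
    "SPECIFICITY_PRIORS",
    "ADHERENCE_PRIORS",
    "PREVALENCE_PRIOR",
    "ScreeningScenario",
    "PredictiveSummary",
    "draw_parameters",
    "simulate_once",
    "run_simulation",
    "compare_arms",
]

MODALITIES = ("LDCT_LUCAS", "LDCT_NLST", "DELFI+LDCT", "DELFI_multi+LDCT")

# Sensitivity: LDCT_LUCAS is a two-component normal mixture (spreads are SDs,
# draws clipped to [0, 1]); the rest are Beta shapes.
SENSITIVITY_PRIORS: dict[str, dict] = {
    "LDCT_LUCAS": {
        "kind": "normal_mixture",
        "means": (0.96, 0.94),
        "sds": (0.005, 0.02),
        "mix": 0.5,
    },
    "LDCT_NLST": {"kind": "beta", "a": 93.8, "b": 6.2},
    "DELFI+LDCT": {"kind": "beta", "a": 85.0, "b": 15.0},
    "DELFI_multi+LDCT": {"kind": "beta", "a": 91.0, "b": 9.0},
}

SPECIFICITY_PRIORS: dict[str, dict] = {
    "LDCT_LUCAS": {"kind": "beta", "a": 58.0, "b": 42.0},
    "LDCT_NLST": {"kind": "beta", "a": 93.8, "b": 6.2},
    "DELFI+LDCT": {"kind": "beta", "a": 86.0, "b": 14.0},
    "DELFI_multi+LDCT": {"kind": "beta", "a": 94.0, "b": 6.0},
}

# Image-only screening has ~6% US adherence; a blood-first pathway assumes
# the ~60% adherence reported for blood-based biomarkers.
ADHERENCE_PRIORS: dict[str, dict] = {
    "LDCT_LUCAS": {"kind": "beta", "a": 12.0, "b": 188.0},
    "LDCT_NLST": {"kind": "beta", "a": 12.0, "b": 188.0},
    "DELFI+LDCT": {"kind": "beta", "a": 15.0, "b": 11.0},
    "DELFI_multi+LDCT": {"kind": "beta", "a": 15.0, "b": 11.0},
}

PREVALENCE_PRIOR: dict = {"kind": "beta", "a": 9.1, "b": 990.9}


def _draw(prior: dict, rng: np.random.Generator, size: int) -> np.ndarray:
    kind = prior["kind"]
    if kind == "beta":
        return rng.beta(prior["a"], prior["b"], size=size)
    if kind == "point":
        return np.full(size, float(prior["value"]))
    if kind == "normal_mixture":
        pick = rng.random(size) < prior["mix"]
        means = np.where(pick, prior["means"][0], prior["means"][1])
        sds = np.where(pick, prior["sds"][0], prior["sds"][1])
        return np.clip(rng.normal(means, sds), 0.0, 1.0)
    raise ValueError(f"unknown prior kind {kind!r}")


@dataclass
class ScreeningScenario:
    """One arm of the screening model: modality, priors, and Monte Carlo
    settings. Priors default to the modality's published shapes; any can be
    overridden (including with {'kind': 'point', 'value': v} point masses)."""

    modality: str = "LDCT_LUCAS"
    population: int = 100_000
    repetitions: int = 10_000
    seed: int = 0
    sensitivity_prior: dict | None = None
    specificity_prior: dict | None = None
    adherence_prior: dict | None = None
    prevalence_prior: dict = field(default_factory=lambda: dict(PREVALENCE_PRIOR))

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.population < 1 or self.repetitions < 1:
            raise ValueError("population and repetitions must be >= 1")
        if self.sensitivity_prior is None:
            self.sensitivity_prior = dict(SENSITIVITY_PRIORS[self.modality])
        if self.specificity_prior is None:
            self.specificity_prior = dict(SPECIFICITY_PRIORS[self.modality])
        if self.adherence_prior is None:
            self.adherence_prior = dict(ADHERENCE_PRIORS[self.modality])


def draw_parameters(
    scenario: ScreeningScenario, rng: np.random.Generator, size: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Joint draws of (theta1, theta2, eta, psi) from the scenario's priors."""
    theta1 = _draw(scenario.sensitivity_prior, rng, size)
    theta2 = _draw(scenario.specificity_prior, rng, size)
    eta = _draw(scenario.adherence_prior, rng, size)
    psi = _draw(scenario.prevalence_prior, rng, size)
    return theta1, theta2, eta, psi


def simulate_once(
    params: tuple[float, float, float, float],
    population: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """One realization of the screening cohort given fixed parameters."""
    theta1, theta2, eta, psi = params
    n = int(rng.binomial(population, eta))
    cancers = int(rng.binomial(n, psi))
    tp = int(rng.binomial(cancers, theta1))
    fp = int(rng.binomial(n - cancers, 1.0 - theta2))
    return {
        "n": n,
        "cancers": cancers,
        "TP": tp,
        "FP": fp,
        "FN": cancers - tp,
        "TN": (n - cancers) - fp,
    }


@dataclass
class PredictiveSummary:
    """Summary (mean + equal-tailed 95% interval) per statistic, with raw
    per-repetition draws retained for paired arm comparisons."""

    scenario: ScreeningScenario
    draws: pd.DataFrame
    n_undefined_ppv: int

    def summary_table(self) -> pd.DataFrame:
        rows = {}
        for col in self.draws.columns:
            v = self.draws[col].dropna().to_numpy()
            rows[col] = {
                "mean": v.mean(),
                "lower_95": np.percentile(v, 2.5),
                "upper_95": np.percentile(v, 97.5),
            }
        return pd.DataFrame(rows).T

    def stat(self, name: str) -> tuple[float, float, float]:
        v = self.draws[name].dropna().to_numpy()
        return float(v.mean()), float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))


def run_simulation(
    scenario: ScreeningScenario, psi_draws: np.ndarray | None = None
) -> PredictiveSummary:
    """Predictive distributions over ``repetitions`` Monte Carlo draws.

    ``psi_draws`` lets two arms share prevalence draws (common population).
    Per repetition: detected = TP; accuracy = (TP + TN)/n; unnecessary
    procedures = FP (rate FP/n); PPV = TP/(TP + FP). Draws with an undefined
    ratio (n = 0 or TP + FP = 0) are excluded from that statistic and
    counted.
    """
    rng = np.random.default_rng(scenario.seed)
    reps = scenario.repetitions
    theta1, theta2, eta, psi = draw_parameters(scenario, rng, size=reps)
    if psi_draws is not None:
        if len(psi_draws) != reps:
            raise ValueError("shared prevalence draws must match repetitions")
        psi = np.asarray(psi_draws, dtype=float)
    n = rng.binomial(scenario.population, eta)
    cancers = rng.binomial(n, psi)
    tp = rng.binomial(cancers, theta1)
    fp = rng.binomial(n - cancers, 1.0 - theta2)
    tn = (n - cancers) - fp
    # cancer burden over the whole population, independent of adherence
    population_cancers = rng.binomial(scenario.population, psi)

    with np.errstate(divide="ignore", invalid="ignore"):
        accuracy = np.where(n > 0, (tp + tn) / np.maximum(n, 1), np.nan)
        fp_rate = np.where(n > 0, fp / np.maximum(n, 1), np.nan)
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
    draws = pd.DataFrame(
        {
            "detected": tp,
            "tested": n,
            "cancers_tested": cancers,
            "population_cancers": population_cancers,
            "unnecessary_procedures": fp,
            "unnecessary_rate": fp_rate,
            "accuracy": accuracy,
            "ppv": ppv,
            "psi": psi,
        }
    )
    return PredictiveSummary(
        scenario=scenario,
        draws=draws,
        n_undefined_ppv=int(np.isnan(ppv).sum()),
    )


def compare_arms(
    arm_a: PredictiveSummary, arm_b: PredictiveSummary
) -> dict[str, float | tuple[float, float]]:
    """Additional detections and fold change of arm A over arm B.

    The fold distribution uses per-draw ratios (paired when the arms shared
    prevalence draws); draws with zero detections in arm B are excluded and
    counted.
    """
    da = arm_a.draws["detected"].to_numpy(dtype=float)
    db = arm_b.draws["detected"].to_numpy(dtype=float)
    if len(da) != len(db):
        raise ValueError("arms must use the same number of repetitions")
    valid = db > 0
    fold = da[valid] / db[valid]
    return {
        "additional_detected": float(da.mean() - db.mean()),
        "fold_mean": float(fold.mean()),
        "fold_95": (float(np.percentile(fold, 2.5)), float(np.percentile(fold, 97.5))),
        "n_excluded_zero_denominator": int((~valid).sum()),
    }


def paired_arms(
    scenario_a: ScreeningScenario, scenario_b: ScreeningScenario, seed: int | None = None
) -> tuple[PredictiveSummary, PredictiveSummary]:
    """Run two arms over a common population: prevalence draws are shared so
    per-draw comparisons are paired."""
    if seed is not None:
        scenario_a = replace(scenario_a, seed=seed)
        scenario_b = replace(scenario_b, seed=seed + 1)
    rng = np.random.default_rng((scenario_a.seed, scenario_b.seed, 9173))
    psi = _draw(scenario_a.prevalence_prior, rng, scenario_a.repetitions)
    return run_simulation(scenario_a, psi_draws=psi), run_simulation(scenario_b, psi_draws=psi)
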