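"""Cancer scoring from fragmentation features.

The score is a cross-validated probability of cancer: within each training
split, the per-bin standardized short/long ratios are compressed by PCA to
the minimum number of components explaining >= 90% of the variance, the
component scores are joined with the 39 arm z-scores, and an L1-penalized
(LASSO) logistic regression is fit. Each sample's score is the mean of its
held-out probabilities over 10 repeats of stratified 5-fold CV. A final
model fit on the full training cohort is frozen (centering means, loadings,
coefficients, cutoff) and applied to external cohorts by projecting their
profiles onto the stored loadings.

Also here: specificity-anchored cutoffs, Jeffreys (Beta(k+1/2, n-k+1/2))
credible intervals for binomial proportions, and bootstrap AUC confidence
intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureMatrix",
    "PCALoadings",
    "CVConfig",
    "DelfiModel",
    "fit_pca",
    "project",
    "fit_penalized_logistic",
    "cross_validated_scores",
    "choose_cutoff",
    "classify",
    "augment_multimodal",
    "jeffreys_interval",
    "roc_auc",
]


@dataclass
class FeatureMatrix:
    """Cohort features: X (samples x bins standardized ratios), Z (samples x
    arm z-scores), binary labels (1 = cancer), sample ids."""

    X: np.ndarray
    Z: np.ndarray
    labels: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.sample_ids)
        if not (self.X.shape[0] == self.Z.shape[0] == len(self.labels) == n):
            raise ValueError("feature blocks, labels, and ids disagree on sample count")
        if np.isnan(self.X).any() or np.isnan(self.Z).any():
            raise ValueError("features contain missing values")


@dataclass
class PCALoadings:
    """Centering means plus the loading matrix of the leading components."""

    loadings: np.ndarray  # p x K, orthonormal columns
    means: np.ndarray  # p
    explained_variance_ratio: np.ndarray  # K
    variance_target: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(X: np.ndarray, variance_target: float = 0.90) -> PCALoadings:
    """Center columns by training means; keep the minimum number of principal
    components whose cumulative explained variance reaches the target."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    means = X.mean(axis=0)
    Xc = X - means
    if not np.any(Xc):
        raise ValueError("feature matrix is constant; PCA undefined")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    evr = var / var.sum()
    K = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    return PCALoadings(
        loadings=Vt[:K].T.copy(),
        means=means,
        explained_variance_ratio=evr[:K].copy(),
        variance_target=variance_target,
    )


def project(x: np.ndarray, L: PCALoadings) -> np.ndarray:
    """Project profile vector(s) onto stored loadings after applying the
    training centering means: PC_k = sum_i L[i, k] * (x[i] - mean[i])."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != L.loadings.shape[0]:
        raise ValueError(
            f"profile length {x2.shape[1]} != loading rows {L.loadings.shape[0]}"
        )
    scores = (x2 - L.means) @ L.loadings
    return scores[0] if single else scores


def _lasso_logistic(features: np.ndarray, labels: np.ndarray, lam: float,
                    seed: int | None = None) -> LogisticRegression:
    # glmnet-style objective (1/n) sum logloss + lam * ||w||_1  <=>  C = 1/(n*lam)
    n = len(labels)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="saga",
        max_iter=5000, tol=1e-4, random_state=seed,
    )
    model.fit(features, labels)
    return model


def fit_penalized_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float | None = None,
    lam_grid: np.ndarray | None = None,
    seed: int = 0,
    n_resample_folds: int = 5,
) -> tuple[LogisticRegression, float]:
    """L1-penalized logistic fit; when a penalty grid is given, the penalty is
    chosen by resampled (stratified K-fold) log-loss."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if lam is None and lam_grid is None:
        lam = 0.0017  # default operating penalty
    if lam_grid is not None:
        losses = []
        skf = StratifiedKFold(n_splits=n_resample_folds, shuffle=True, random_state=seed)
        for cand in lam_grid:
            fold_losses = []
            for tr, te in skf.split(features, labels):
                m = _lasso_logistic(features[tr], labels[tr], cand, seed)
                p = m.predict_proba(features[te])[:, 1]
                fold_losses.append(log_loss(labels[te], p, labels=[0, 1]))
            losses.append(np.mean(fold_losses))
        lam = float(lam_grid[int(np.argmin(losses))])
    model = _lasso_logistic(features, labels, float(lam), seed)
    return model, float(lam)


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0
    lam: float = 0.0017
    lam_grid: np.ndarray | None = None
    variance_target: float = 0.90

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


def cross_validated_scores(
    cohort: FeatureMatrix, cfg: CVConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Repeated stratified K-fold out-of-fold probabilities, averaged.

    PCA and the logistic fit see only the training folds of each split; each
    sample's score is the mean of its held-out probabilities across repeats.
    Returns (scores, per-fold coefficient table for stability reporting).
    """
    y = cohort.labels
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")
    n = len(y)
    prob_sum = np.zeros(n)
    coef_rows = []
    for rep in range(cfg.repeats):
        fold_seed = cfg.seed * 1000 + rep
        for attempt in range(10):
            skf = StratifiedKFold(cfg.folds, shuffle=True, random_state=fold_seed + attempt)
            splits = list(skf.split(cohort.X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                if attempt:
                    warnings.warn(f"repeat {rep}: re-drew folds {attempt} time(s)")
                break
        else:  # pragma: no cover - needs pathological label balance
            raise ValueError("could not draw folds containing both classes")
        rep_prob = np.empty(n)
        for fold, (tr, te) in enumerate(splits):
            L = fit_pca(cohort.X[tr], cfg.variance_target)
            feats_tr = np.hstack([project(cohort.X[tr], L), cohort.Z[tr]])
            feats_te = np.hstack([project(cohort.X[te], L), cohort.Z[te]])
            model, lam = fit_penalized_logistic(
                feats_tr, y[tr], lam=cfg.lam, lam_grid=cfg.lam_grid, seed=fold_seed
            )
            rep_prob[te] = model.predict_proba(feats_te)[:, 1]
            coef_rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "lambda": lam,
                    "n_components": L.n_components,
                    "intercept": float(model.intercept_[0]),
                    "n_nonzero": int(np.count_nonzero(model.coef_)),
                }
            )
        prob_sum += rep_prob
    return prob_sum / cfg.repeats, pd.DataFrame(coef_rows)


def choose_cutoff(scores: np.ndarray, labels: np.ndarray, target_specificity: float) -> float:
    """Smallest score threshold achieving the target specificity among
    non-cancer samples (ties broken toward higher sensitivity)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    neg = np.sort(scores[labels == 0])
    if len(neg) == 0:
        raise ValueError("no non-cancer samples; specificity undefined")
    candidates = np.concatenate([[np.nextafter(neg[0], -np.inf)], np.unique(neg)])
    for theta in candidates:
        if np.mean(neg <= theta) >= target_specificity:
            return float(theta)
    raise ValueError(f"specificity {target_specificity} unattainable")


def classify(scores: np.ndarray | float, theta: float) -> np.ndarray | bool:
    """Positive iff score strictly exceeds the cutoff."""
    arr = np.asarray(scores, dtype=float)
    out = arr > theta
    return bool(out) if np.isscalar(scores) or arr.ndim == 0 else out


def augment_multimodal(features: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Append clinical covariates (age, pack-years, COPD, log1p CEA) to a
    feature block for the multimodal model."""
    required = ["age", "pack_years", "copd", "cea"]
    missing_cols = [c for c in required if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"covariates missing columns: {missing_cols}")
    bad = covariates[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"missing covariates for sample(s): {list(covariates.index[bad])}")
    if (covariates["age"] <= 0).any() or (covariates["pack_years"] < 0).any() or (
        covariates["cea"] < 0
    ).any():
        raise ValueError("covariates out of range (age > 0, pack_years >= 0, CEA >= 0)")
    extra = np.column_stack(
        [
            covariates["age"].to_numpy(float),
            covariates["pack_years"].to_numpy(float),
            covariates["copd"].to_numpy(float),
            np.log1p(covariates["cea"].to_numpy(float)),
        ]
    )
    return np.hstack([np.asarray(features, dtype=float), extra])


def jeffreys_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval for a binomial proportion under the
    Jeffreys Beta(1/2, 1/2) prior, i.e. quantiles of Beta(k+1/2, n-k+1/2)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid (k, n) = ({k}, {n})")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    alpha = (1 - level) / 2
    post = stats.beta(k + 0.5, n - k + 0.5)
    return float(post.ppf(alpha)), float(post.ppf(1 - alpha))


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC (ties count 1/2) with a percentile-bootstrap confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    n = len(labels)
    boots = []
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(boots, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return auc, (float(lo), float(hi))


@dataclass
class DelfiModel:
    """Frozen final model: loadings + centering means, logistic coefficients,
    penalty, and the operating cutoff, for fixed-model external projection."""

    pca: PCALoadings
    coef: np.ndarray  # K + n_arms (+ covariates) logistic coefficients
    intercept: float
    lam: float
    theta: float | None = None
    feature_names: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        cohort: FeatureMatrix,
        lam: float = 0.0017,
        variance_target: float = 0.90,
        target_specificity: float | None = None,
        cv: CVConfig | None = None,
        seed: int = 0,
    ) -> "DelfiModel":
        """Fit the final full-cohort model; if a target specificity is given,
        anchor the cutoff on cross-validated scores (cv config required)."""
        L = fit_pca(cohort.X, variance_target)
        feats = np.hstack([project(cohort.X, L), cohort.Z])
        model, lam = fit_penalized_logistic(feats, cohort.labels, lam=lam, seed=seed)
        theta = None
        if target_specificity is not None:
            cv = cv or CVConfig(seed=seed, lam=lam, variance_target=variance_target)
            cv_scores, _ = cross_validated_scores(cohort, cv)
            theta = choose_cutoff(cv_scores, cohort.labels, target_specificity)
        names = tuple(f"PC{k+1}" for k in range(L.n_components)) + tuple(
            f"z{j+1}" for j in range(cohort.Z.shape[1])
        )
        return cls(
            pca=L,
            coef=model.coef_[0].copy(),
            intercept=float(model.intercept_[0]),
            lam=lam,
            theta=theta,
            feature_names=names,
            provenance={"n_train": len(cohort.labels), "seed": seed},
        )

    def score(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Probability-scale score for external samples via the frozen
        loadings and coefficients."""
        feats = np.hstack([project(np.atleast_2d(X), self.pca), np.atleast_2d(Z)])
        logit = feats @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    # -- serialization (plain-text archive directory) ----------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "loadings.tsv", self.pca.loadings, delimiter="\t")
        np.savetxt(d / "bin_means.tsv", self.pca.means, delimiter="\t")
        np.savetxt(d / "coefficients.tsv", self.coef, delimiter="\t")
        meta = {
            "intercept": self.intercept,
            "lambda": self.lam,
            "theta": self.theta,
            "variance_target": self.pca.variance_target,
            "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            "feature_names": list(self.feature_names),
            "provenance": self.provenance,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "DelfiModel":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        loadings = np.loadtxt(d / "loadings.tsv", delimiter="\t", ndmin=2)
        pca = PCALoadings(
            loadings=loadings,
            means=np.loadtxt(d / "bin_means.tsv", delimiter="\t"),
            explained_variance_ratio=np.asarray(meta["explained_variance_ratio"]),
            variance_target=meta["variance_target"],
        )
        return cls(
            pca=pca,
            coef=np.atleast_1d(np.loadtxt(d / "coefficients.tsv", delimiter="\t")),
            intercept=meta["intercept"],
            lam=meta["lambda"],
            theta=meta["theta"],
            feature_names=tuple(meta["feature_names"]),
            provenance=meta["provenance"],
        )
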