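"""Hierarchical two-stage binary RBF-SVM with GA-searched hyperparameters.

Stage 1 separates the seriously fatigued state (level 3) from levels 1-2;
stage 2 separates level 1 from level 2 among the stage-1 negatives. Each
stage is a soft-margin SVM with kernel exp(-g * ||x - xi||^2); its penalty C
and kernel width g are found by a real-coded genetic algorithm whose fitness
is stratified K-fold cross-validation accuracy.

GA operators: roulette selection proportional to fitness, arithmetic
crossover (convex gene blend with a uniform weight), and boundary-decaying
non-uniform mutation with decay factor r2*(1 - gen/Gmax)^2, plus elitism of
one so the best-fitness trace is monotone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SVMSpec",
    "GAConfig",
    "GAResult",
    "BinarySVM",
    "HierarchicalModel",
    "train_binary_svm",
    "kfold_cv_accuracy",
    "ga_optimize",
    "train_hierarchical",
    "predict",
    "DEFAULT_FEATURE_COLS",
]

#: Default classifier inputs: reaction time plus the top-ranked EEG index.
DEFAULT_FEATURE_COLS = ("reaction_time_s", "alpha_over_beta")


@dataclass(frozen=True)
class SVMSpec:
    """RBF-SVM hyperparameters: penalty C and kernel width g (= 1/sigma^2)."""

    C: float
    g: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g <= 0:
            raise ValueError("C and g must be positive")


@dataclass(frozen=True)
class GAConfig:
    population: int = 20
    generations: int = 200
    cv_folds: int = 10
    c_bounds: tuple[float, float] = (0.01, 100.0)
    g_bounds: tuple[float, float] = (0.01, 100.0)
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for lo, hi in (self.c_bounds, self.g_bounds):
            if not 0 < lo < hi:
                raise ValueError("bounds must be positive with min < max")


@dataclass
class GAResult:
    best: SVMSpec
    best_fitness: float
    trace: list[float]


class BinarySVM:
    """Soft-margin RBF-SVM over standardized features with labels in {-1, +1}.

    Fitting delegates the dual quadratic program to scikit-learn's SVC; the
    decision function is then evaluated from the stored support vectors so a
    JSON-restored model predicts identically to a freshly fitted one.
    """

    def __init__(self, spec: SVMSpec):
        self.spec = spec
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinarySVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if not np.all(np.isin(y, (-1, 1))):
            raise ValueError("labels must be in {-1, +1}")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least one sample per class")

        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        Xs = (X - self.mean_) / self.scale_

        svc = SVC(C=self.spec.C, kernel="rbf", gamma=self.spec.g)
        svc.fit(Xs, y)
        self._svc = svc
        self.support_vectors_ = svc.support_vectors_.copy()
        # dual_coef_ rows follow sklearn's class order; sign encodes y_i*alpha_i
        self.dual_coef_ = svc.dual_coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self._fitted = True
        return self

    @property
    def alphas(self) -> np.ndarray:
        """Lagrange multipliers of the support vectors (|y_i * alpha_i|)."""
        self._check_fitted()
        return np.abs(self.dual_coef_)

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("model is not fitted")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.mean_) / self.scale_
        d2 = ((Xs[:, None, :] - self.support_vectors_[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.spec.g * d2)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "C": self.spec.C,
            "g": self.spec.g,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinarySVM":
        model = cls(SVMSpec(C=d["C"], g=d["g"]))
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        model._svc = None
        model._fitted = True
        return model


def train_binary_svm(X: np.ndarray, y: np.ndarray, spec: SVMSpec) -> BinarySVM:
    """Fit one standardized RBF-SVM; labels must be in {-1, +1}."""
    return BinarySVM(spec).fit(X, y)


def kfold_cv_accuracy(
    X: np.ndarray, y: np.ndarray, spec: SVMSpec, k: int = 10, seed: int = 0
) -> float:
    """Mean per-fold accuracy of a stratified K-fold; deterministic per seed.

    Falls back to unstratified folds (with a warning) when some class has
    fewer members than K.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn("class smaller than K: falling back to unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)

    accs = []
    for train_idx, test_idx in folds:
        if len(np.unique(y[train_idx])) < 2:
            accs.append(0.0)
            continue
        model = train_binary_svm(X[train_idx], y[train_idx], spec)
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def _mutate_gene(
    a: float, lo: float, hi: float, gen: int, gmax: int, rng: np.random.Generator
) -> float:
    """Non-uniform mutation: pull toward a bound by r2*(1 - gen/Gmax)^2.

    Both branches are convex combinations with a bound, so a mutated gene
    never leaves [lo, hi].
    """
    r, r2 = rng.random(), rng.random()
    f = r2 * (1.0 - gen / gmax) ** 2
    if r > 0.5:
        return a + (hi - a) * f
    return a - (a - lo) * f


def ga_optimize(X: np.ndarray, y: np.ndarray, cfg: GAConfig) -> GAResult:
    """Search (C, g) maximizing K-fold CV accuracy with a real-coded GA.

    Roulette weights are the CV accuracies themselves (the quantity being
    maximized); elitism of one guarantees a non-decreasing best-fitness
    trace.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lo = np.array([cfg.c_bounds[0], cfg.g_bounds[0]])
    hi = np.array([cfg.c_bounds[1], cfg.g_bounds[1]])
    n_pop = cfg.population

    cache: dict[tuple[float, float], float] = {}

    def fitness_of(ind: np.ndarray) -> float:
        key = (round(float(ind[0]), 12), round(float(ind[1]), 12))
        if key not in cache:
            cache[key] = kfold_cv_accuracy(
                X, y, SVMSpec(C=key[0], g=key[1]), k=cfg.cv_folds, seed=cfg.rng_seed
            )
        return cache[key]

    pop = lo + rng.random((n_pop, 2)) * (hi - lo)
    fitness = np.array([fitness_of(ind) for ind in pop])

    best_idx = int(np.argmax(fitness))
    elite, elite_fit = pop[best_idx].copy(), float(fitness[best_idx])
    trace = [elite_fit]

    for gen in range(1, cfg.generations + 1):
        total = fitness.sum()
        probs = fitness / total if total > 0 else np.full(n_pop, 1.0 / n_pop)
        pop = pop[rng.choice(n_pop, size=n_pop, p=probs)].copy()

        for i in range(0, n_pop - 1, 2):
            if rng.random() < cfg.crossover_rate:
                b = rng.random()
                a_k, a_l = pop[i].copy(), pop[i + 1].copy()
                pop[i] = a_k * (1 - b) + a_l * b
                pop[i + 1] = a_l * (1 - b) + a_k * b

        for i in range(n_pop):
            for j in range(2):
                if rng.random() < cfg.mutation_rate:
                    pop[i, j] = _mutate_gene(
                        pop[i, j], lo[j], hi[j], gen, cfg.generations, rng
                    )

        pop[0] = elite  # elitism of 1
        fitness = np.array([fitness_of(ind) for ind in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > elite_fit:
            elite, elite_fit = pop[gen_best].copy(), float(fitness[gen_best])
        trace.append(elite_fit)

    return GAResult(
        best=SVMSpec(C=float(elite[0]), g=float(elite[1])),
        best_fitness=elite_fit,
        trace=trace,
    )


@dataclass
class HierarchicalModel:
    """Two cascaded binary SVMs predicting levels {1, 2, 3}."""

    stage1: BinarySVM
    stage2: BinarySVM
    feature_cols: tuple[str, ...] = DEFAULT_FEATURE_COLS

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_cols": list(self.feature_cols),
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HierarchicalModel":
        d = json.loads(Path(path).read_text())
        return cls(
            stage1=BinarySVM.from_dict(d["stage1"]),
            stage2=BinarySVM.from_dict(d["stage2"]),
            feature_cols=tuple(d["feature_cols"]),
        )


def _as_matrix(rows, feature_cols: Sequence[str]) -> np.ndarray:
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in feature_cols if c not in rows.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        return rows[list(feature_cols)].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != len(feature_cols):
        raise ValueError("row width does not match the model's feature columns")
    return X


def train_hierarchical(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = DEFAULT_FEATURE_COLS,
    ga_cfg: GAConfig | None = None,
    specs: tuple[SVMSpec, SVMSpec] | None = None,
    share_params: bool = False,
) -> tuple[HierarchicalModel, dict]:
    """Train the two-stage classifier on a feature table with a level column.

    Each stage's (C, g) is GA-optimized independently unless
    ``share_params`` reuses stage 1's result, or explicit ``specs`` are
    given (which skips the GA entirely). Returns the model plus a details
    dict with per-stage specs, CV fitness and traces.
    """
    levels = features["level"].to_numpy(dtype=int)
    present = set(np.unique(levels))
    if present != {1, 2, 3}:
        raise ValueError(f"training data must contain all three levels, got {sorted(present)}")
    X = _as_matrix(features, feature_cols)

    y1 = np.where(levels == 3, 1, -1)
    mask_cat1 = levels != 3
    X2 = X[mask_cat1]
    y2 = np.where(levels[mask_cat1] == 2, 1, -1)

    details: dict = {"feature_cols": list(feature_cols)}
    if specs is not None:
        spec1, spec2 = specs
    else:
        cfg = ga_cfg or GAConfig()
        res1 = ga_optimize(X, y1, cfg)
        spec1 = res1.best
        details["stage1_ga"] = {"fitness": res1.best_fitness, "trace": res1.trace}
        if share_params:
            spec2 = spec1
        else:
            cfg2 = dataclasses.replace(cfg, rng_seed=cfg.rng_seed + 1)
            res2 = ga_optimize(X2, y2, cfg2)
            spec2 = res2.best
            details["stage2_ga"] = {"fitness": res2.best_fitness, "trace": res2.trace}

    stage1 = train_binary_svm(X, y1, spec1)
    stage2 = train_binary_svm(X2, y2, spec2)
    details["stage1_spec"] = {"C": spec1.C, "g": spec1.g}
    details["stage2_spec"] = {"C": spec2.C, "g": spec2.g}
    model = HierarchicalModel(stage1=stage1, stage2=stage2, feature_cols=tuple(feature_cols))
    return model, details


def predict(model: HierarchicalModel, rows) -> np.ndarray:
    """Predict levels in {1, 2, 3}; stage-1 negatives route to stage 2."""
    X = _as_matrix(rows, model.feature_cols)
    out = np.empty(len(X), dtype=int)
    is3 = model.stage1.predict(X) == 1
    out[is3] = 3
    if np.any(~is3):
        is2 = model.stage2.predict(X[~is3]) == 1
        out[~is3] = np.where(is2, 2, 1)
    return out
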