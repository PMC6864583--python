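"""Classifier fitting: GA-driven LDA with discriminant statistics, random forest,
and the Y-randomisation robustness check.

The linear model is a two-class Fisher discriminant expressed as an intercept
plus one coefficient per deviation descriptor, oriented so that the decision
boundary sits at score 0 with actives positive:

    IA_i(c_j) = b0 + Σ_k b_k · Δ(D_k)   →   active iff score > 0

Goodness-of-fit statistics are the classical discriminant battery:

* Wilks λ = |W| / |T|, the within/total scatter determinant ratio (smaller is
  better separation; λ ∈ (0, 1]);
* canonical R = √(1 − λ);
* χ² = −(n − 1 − (p + g)/2) · ln λ  (Bartlett's correction, g = 2 groups);
* Mahalanobis D² between the class centroids under the pooled covariance;
* F = ((n − p − 1)/p) · (1 − λ)/λ, the exact two-group transformation of λ,
  on (p, n − p − 1) degrees of freedom.

Feature selection is a genetic algorithm over fixed-length descriptor
subsets with Wilks λ as the (minimised) fitness, elitist selection, uniform
crossover and per-gene mutation.  A published fixed equation length can be
longer than the equation finally reported; a post-search backward-elimination
pass therefore drops terms whose removal worsens λ by less than a relative
tolerance (default 1%).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .boxjenkins import ACTIVE, INACTIVE

_RIDGE = 1e-8


class ModelError(ValueError):
    pass


@dataclass
class LDAStats:
    wilks_lambda: float
    canonical_R: float
    chi_square: float
    mahalanobis_D2: float
    fisher_F: float
    p_value: float
    n: int
    p: int


@dataclass
class LinearDiscriminantModel:
    """Intercept + coefficients over named deviation descriptors."""

    intercept: float
    coefficients: dict[str, float]
    stats: LDAStats | None = None
    fingerprint: str = ""

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def score(self, X: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Linear score(s); raises on any missing descriptor."""
        names = self.descriptor_names
        if isinstance(X, pd.DataFrame):
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise ModelError(f"missing descriptors: {missing}")
            vals = X[names].values
        else:
            missing = [n for n in names if n not in X]
            if missing:
                raise ModelError(f"missing descriptors: {missing}")
            vals = np.array([[X[n] for n in names]])
        return self.intercept + vals @ np.array([self.coefficients[n] for n in names])

    def classify(self, X) -> np.ndarray:
        s = self.score(X)
        return np.where(s > 0, ACTIVE, INACTIVE)

    # sklearn-ish aliases so LDA and RF models are interchangeable downstream
    def predict(self, X) -> np.ndarray:
        return self.classify(X)

    def decision_scores(self, X) -> np.ndarray:
        return self.score(X)

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "kind": "lda",
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "stats": self.stats.__dict__ if self.stats else None,
            "fingerprint": self.fingerprint,
        }
        payload.update(extra or {})
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearDiscriminantModel":
        payload = json.loads(Path(path).read_text())
        stats_ = LDAStats(**payload["stats"]) if payload.get("stats") else None
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            stats=stats_,
            fingerprint=payload.get("fingerprint", ""),
        )


def reference_erk_model() -> LinearDiscriminantModel:
    """The bundled seven-descriptor ERK-1/2 inhibition discriminant.

    A literature linear mt-QSAR discriminant over Box–Jenkins deviation
    descriptors, shipped as a worked example and as the scoring model for the
    fragment-contribution analysis demos.
    """
    with resources.files("mtqsar").joinpath("data/erk_lda_reference.json").open() as fh:
        payload = json.load(fh)
    return LinearDiscriminantModel(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        stats=LDAStats(**payload["stats"]) if payload.get("stats") else None,
        fingerprint="reference-erk-lda",
    )


# -- LDA fitting ---------------------------------------------------------------


def _scatter(X: np.ndarray, mu: np.ndarray) -> np.ndarray:
    d = X - mu
    return d.T @ d


def fit_lda(X: pd.DataFrame, y: Sequence[int]) -> LinearDiscriminantModel:
    """Two-class Fisher discriminant with the full statistic battery.

    Classification is equivalent to assigning each point to the nearer class
    centroid under pooled-covariance Mahalanobis distance (equal priors).
    """
    y = np.asarray(y)
    Xv = np.asarray(X.values, dtype=float)
    n, p = Xv.shape
    classes = np.unique(y)
    if set(classes) != {ACTIVE, INACTIVE}:
        raise ModelError(f"need both classes +1/-1, got {classes}")
    Xa, Xi = Xv[y == ACTIVE], Xv[y == INACTIVE]
    mu_a, mu_i, mu = Xa.mean(0), Xi.mean(0), Xv.mean(0)
    W = _scatter(Xa, mu_a) + _scatter(Xi, mu_i)
    T = _scatter(Xv, mu)

    ridge = _RIDGE * np.eye(p)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        sign_w, logdet_w = np.linalg.slogdet(W + ridge)
        sign_t, logdet_t = np.linalg.slogdet(T + ridge)
        if sign_w <= 0 or sign_t <= 0:
            raise ModelError("singular scatter matrices (after ridge)")
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)

    Sp = W / (n - 2)
    try:
        Sp_inv = np.linalg.inv(Sp)
    except np.linalg.LinAlgError:
        Sp_inv = np.linalg.inv(Sp + ridge)
    dmu = mu_a - mu_i
    w = Sp_inv @ dmu
    intercept = -float(w @ (mu_a + mu_i) / 2)
    D2 = float(dmu @ Sp_inv @ dmu)

    g = 2
    chi2 = max(0.0, -(n - 1 - (p + g) / 2) * math.log(max(lam, 1e-300)))
    df2 = n - p - 1
    if lam < 1.0 and df2 > 0:
        F = (df2 / p) * (1 - lam) / lam
        p_value = float(stats.f.sf(F, p, df2))
    else:
        F, p_value = 0.0, 1.0

    names = list(X.columns)
    fp = hashlib.sha256(("|".join(names) + f"|n={n}").encode()).hexdigest()[:12]
    return LinearDiscriminantModel(
        intercept=intercept,
        coefficients=dict(zip(names, map(float, w))),
        stats=LDAStats(lam, math.sqrt(1 - lam), chi2, D2, F, p_value, n, p),
        fingerprint=fp,
    )


def score_linear(model: LinearDiscriminantModel, x: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
    return model.score(x)


# -- genetic algorithm feature selection ---------------------------------------


@dataclass
class GAConfig:
    generations: int = 100
    equation_length: int = 10
    mutation_prob: float = 0.3
    initial_population: int = 100
    selected_per_generation: int = 30
    seed: int | None = None

    def __post_init__(self):
        for name in ("generations", "equation_length", "initial_population", "selected_per_generation"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if not 0 <= self.mutation_prob <= 1:
            raise ModelError("mutation_prob must be in [0, 1]")


@dataclass
class GAResult:
    columns: list[str]
    model: LinearDiscriminantModel
    history: list[float]
    n_evaluations: int
    eliminated: list[str] = field(default_factory=list)


def _subset_lambda(X: pd.DataFrame, y, cols: tuple[int, ...], colnames, memo: dict) -> float:
    if cols in memo:
        return memo[cols]
    try:
        lam = fit_lda(X.iloc[:, list(cols)], y).stats.wilks_lambda
    except (ModelError, np.linalg.LinAlgError):
        lam = 2.0  # worse than any valid Wilks lambda
    memo[cols] = lam
    return lam


def backward_eliminate(
    X: pd.DataFrame,
    y,
    columns: Sequence[str],
    rel_tol: float = 0.01,
) -> tuple[list[str], list[str]]:
    """Drop terms whose removal worsens Wilks λ by at most ``rel_tol`` (relative)."""
    cols = list(columns)
    dropped = []
    current = fit_lda(X[cols], y).stats.wilks_lambda
    while len(cols) > 1:
        candidates = []
        for c in cols:
            rest = [k for k in cols if k != c]
            try:
                lam = fit_lda(X[rest], y).stats.wilks_lambda
            except (ModelError, np.linalg.LinAlgError):
                continue
            candidates.append((lam, c))
        if not candidates:
            break
        lam_best, col_best = min(candidates)
        if lam_best <= current * (1 + rel_tol):
            cols.remove(col_best)
            dropped.append(col_best)
            current = lam_best
        else:
            break
    return cols, dropped


def ga_select(
    X: pd.DataFrame,
    y: Sequence[int],
    cfg: GAConfig | None = None,
    eliminate: bool = True,
) -> GAResult:
    """Evolve fixed-length descriptor subsets, minimising Wilks λ.

    Elitist: the top ``selected_per_generation`` chromosomes survive each
    generation unchanged, so the best fitness is non-increasing.  Offspring
    are built by uniform crossover on the union of two parents' genes, then
    per-gene mutation at ``mutation_prob``.  Deterministic under ``seed``.
    """
    cfg = cfg or GAConfig()
    y = np.asarray(y)
    p = X.shape[1]
    L = cfg.equation_length
    if L > p:
        raise ModelError(f"equation_length {L} exceeds {p} available descriptors")
    rng = np.random.default_rng(cfg.seed)
    colnames = list(X.columns)
    memo: dict[tuple[int, ...], float] = {}

    def new_chromosome() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=L, replace=False)))

    population = {new_chromosome() for _ in range(cfg.initial_population)}
    while len(population) < min(cfg.initial_population, math.comb(p, L)):
        population.add(new_chromosome())
    population = list(population)

    history: list[float] = []
    best_chrom, best_lam = None, np.inf
    for _ in range(cfg.generations):
        scored = sorted((_subset_lambda(X, y, c, colnames, memo), c) for c in population)
        if scored[0][0] < best_lam:
            best_lam, best_chrom = scored[0]
        history.append(best_lam)
        parents = [c for _, c in scored[: cfg.selected_per_generation]]
        next_pop = set(parents)
        guard = 0
        while len(next_pop) < cfg.initial_population and guard < 20 * cfg.initial_population:
            guard += 1
            pa, pb = (parents[i] for i in rng.integers(len(parents), size=2))
            union = np.array(sorted(set(pa) | set(pb)))
            child = set(rng.choice(union, size=L, replace=False))
            # per-gene mutation: swap a gene for a random unused column
            for gene in list(child):
                if rng.random() < cfg.mutation_prob:
                    pool = np.setdiff1d(np.arange(p), np.fromiter(child, int))
                    if pool.size:
                        child.discard(gene)
                        child.add(int(rng.choice(pool)))
            next_pop.add(tuple(sorted(child)))
        population = list(next_pop)

    assert best_chrom is not None
    cols = [colnames[i] for i in best_chrom]
    dropped: list[str] = []
    if eliminate and len(cols) > 1:
        cols, dropped = backward_eliminate(X, y, cols)
    model = fit_lda(X[cols], y)
    return GAResult(cols, model, history, len(memo), dropped)


# -- random forest -------------------------------------------------------------


@dataclass
class RFConfig:
    n_trees: int = 100
    bag_fraction: float = 1.0
    max_depth: int | None = None
    seed: int | None = None

    def features_per_split(self, p: int) -> int:
        return max(1, min(p, int(math.log2(p) + 1)))


@dataclass
class RandomForestModel:
    estimator: RandomForestClassifier
    feature_names: list[str]

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.feature_names if n not in X.columns]
        if missing:
            raise ModelError(f"missing descriptors: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return X[self.feature_names].values

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._matrix(X)).astype(int)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting active."""
        proba = self.estimator.predict_proba(self._matrix(X))
        active_col = list(self.estimator.classes_).index(ACTIVE)
        return proba[:, active_col]

    @property
    def oob_score(self) -> float | None:
        return getattr(self.estimator, "oob_score_", None)


def fit_rf(X: pd.DataFrame, y: Sequence[int], cfg: RFConfig | None = None, oob: bool = False) -> RandomForestModel:
    """Bagged decision-tree ensemble: bootstrap bags of size n·bag_fraction,
    unlimited depth, int(log2(p)+1) candidate features per split, Gini
    criterion, majority vote."""
    cfg = cfg or RFConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ModelError("both classes required")
    p = X.shape[1]
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features=cfg.features_per_split(p),
        max_samples=None if cfg.bag_fraction >= 1.0 else cfg.bag_fraction,
        bootstrap=True,
        criterion="gini",
        oob_score=oob,
        random_state=None if cfg.seed is None else int(cfg.seed) % (2**32),
        n_jobs=1,
    )
    clf.fit(X.values, y)
    return RandomForestModel(clf, list(X.columns))


# -- Y-randomisation -----------------------------------------------------------


@dataclass
class YRandomizationResult:
    lambda_original: float
    lambda_rand_mean: float
    lambdas: list[float]


def y_randomization(
    X: pd.DataFrame,
    y: Sequence[int],
    n_rand: int = 100,
    seed: int | None = None,
) -> YRandomizationResult:
    """Refit the same descriptor subset on scrambled labels ``n_rand`` times.

    A real structure–activity relationship collapses under scrambling: the
    mean randomised Wilks λ should sit near 1, far above the original λ.
    """
    y = np.asarray(y)
    lam0 = fit_lda(X, y).stats.wilks_lambda
    rng = np.random.default_rng(seed)
    lams = []
    for _ in range(n_rand):
        lams.append(fit_lda(X, rng.permutation(y)).stats.wilks_lambda)
    return YRandomizationResult(lam0, float(np.mean(lams)), lams)
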