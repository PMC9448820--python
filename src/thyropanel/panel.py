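"""Feature screening and genetic-algorithm panel selection.

The screening ladder keeps proteins that are differentially expressed
between benign and malignant samples (union an optional whitelist) and
have a missing rate below a cutoff.  The genetic algorithm then searches
fixed-size feature subsets, scoring each candidate by mean 3-fold
cross-validated accuracy of a compact neural classifier on dataset A;
dataset B is touched exactly once per finalist for the final ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from . import dep
from .matrix import AbundanceMatrix

__all__ = [
    "ScreenConfig",
    "GAConfig",
    "PanelCandidate",
    "PanelSelection",
    "ScreenError",
    "screen_features",
    "FitnessEvaluator",
    "evaluate_fitness",
    "ga_select",
]


class ScreenError(RuntimeError):
    pass


@dataclass
class ScreenConfig:
    """Thresholds of the initial screening ladder."""

    fc_threshold: float = 2.0  # linear-scale fold change for the DE screen
    alpha: float = 0.01
    whitelist: tuple[str, ...] = ()
    missing_rate_cutoff: float = 0.35
    min_obs: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.missing_rate_cutoff <= 1.0):
            raise ValueError("missing_rate_cutoff must lie in (0, 1]")


@dataclass
class GAConfig:
    panel_size: int = 19
    population_size: int = 60
    generations: int = 40
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    elitism_count: int = 2
    cv_folds: int = 3
    tournament_size: int = 3
    top_candidates: int = 10  # finalists ranked on dataset B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must lie in [0, population_size)")

    @classmethod
    def from_json(cls, path) -> "GAConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class PanelCandidate:
    """A fixed-size feature combination with its cross-validated fitness."""

    features: frozenset[str]
    fitness: float  # mean of the per-fold accuracies
    fold_accuracies: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.fitness - float(np.mean(self.fold_accuracies))) > 1e-12:
            raise ValueError("fitness must equal the mean fold accuracy")
        if not (0.0 <= self.fitness <= 1.0):
            raise ValueError("fitness must lie in [0, 1]")


@dataclass
class PanelSelection:
    """GA outcome: winning panel, search trajectory, and holdout accuracy."""

    best: PanelCandidate
    holdout_accuracy: float
    trajectory: list[float]  # best-so-far fitness per generation
    finalists: list[tuple[PanelCandidate, float]] = field(default_factory=list)
    holdout_eval_counts: dict[frozenset, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "panel": sorted(self.best.features),
            "fitness": self.best.fitness,
            "fold_accuracies": list(self.best.fold_accuracies),
            "holdout_accuracy": self.holdout_accuracy,
            "trajectory": self.trajectory,
            "finalists": [
                {"panel": sorted(c.features), "fitness": c.fitness, "holdout_accuracy": acc}
                for c, acc in self.finalists
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def screen_features(
    matrix: AbundanceMatrix,
    labels,
    config: ScreenConfig,
) -> list[str]:
    """Screening ladder: (DE proteins union whitelist), then missing-rate filter.

    ``labels`` are per-sample benign/malignant values aligned with the
    matrix rows.  Returns feature ids sorted lexicographically.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_samples:
        raise ValueError("labels must align with matrix samples")
    classes = set(labels.tolist())
    if classes != {"benign", "malignant"}:
        raise ValueError("both classes must be present")
    sample_ids = np.asarray(matrix.sample_ids)
    hits = dep.pairwise_dep(
        matrix,
        group_a=sample_ids[labels == "malignant"].tolist(),
        group_b=sample_ids[labels == "benign"].tolist(),
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
        min_obs=config.min_obs,
    )
    known = set(matrix.protein_ids)
    selected = {r.protein_id for r in hits} | (set(config.whitelist) & known)
    rates = matrix.missing_rate_per_protein()
    survivors = sorted(p for p in selected if rates[p] < config.missing_rate_cutoff)
    if not survivors:
        raise ScreenError(
            "screening removed every feature; relax fc_threshold/alpha or the "
            "missing-rate cutoff"
        )
    return survivors


class FitnessEvaluator:
    """Cross-validated accuracy of candidate panels on dataset A, with caching.

    The per-fold classifier is a compact two-hidden-layer perceptron
    trained with plain cross-entropy (LBFGS), deliberately cheaper than the
    final classifier.
    """

    def __init__(
        self,
        X: np.ndarray,
        y,
        feature_ids: Sequence[str],
        folds: int = 3,
        seed: int = 0,
        hidden: tuple[int, int] = (16, 8),
        max_iter: int = 150,
    ):
        self.X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("dataset A must be complete (normalize first)")
        self.y = np.asarray(y)
        self.feature_ids = list(feature_ids)
        self.index = {f: j for j, f in enumerate(self.feature_ids)}
        self.folds = folds
        self.seed = seed
        self.hidden = hidden
        self.max_iter = max_iter
        self.cache: dict[frozenset, PanelCandidate] = {}
        self.n_evaluations = 0

    def _classifier(self) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=self.hidden,
            solver="lbfgs",
            alpha=1e-3,
            max_iter=self.max_iter,
            random_state=self.seed,
        )

    def columns(self, features: Sequence[str]) -> np.ndarray:
        try:
            cols = [self.index[f] for f in sorted(features)]
        except KeyError as exc:
            raise KeyError(f"candidate feature {exc.args[0]!r} not in dataset A") from None
        return self.X[:, cols]

    def evaluate(self, features) -> PanelCandidate:
        key = frozenset(features)
        if key in self.cache:
            return self.cache[key]
        Xc = self.columns(key)
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=self.seed)
        accs = []
        for tr, va in skf.split(Xc, self.y):
            if len(set(self.y[tr])) < 2 or len(set(self.y[va])) < 2:
                raise ValueError("a CV fold lacks one of the classes")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = self._classifier().fit(Xc[tr], self.y[tr])
            accs.append(float(np.mean(clf.predict(Xc[va]) == self.y[va])))
        candidate = PanelCandidate(key, float(np.mean(accs)), tuple(accs))
        self.cache[key] = candidate
        self.n_evaluations += 1
        return candidate

    def fit_full(self, features) -> MLPClassifier:
        """Train on all of dataset A (for the single holdout evaluation)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self._classifier().fit(self.columns(features), self.y)


def evaluate_fitness(
    features,
    X: np.ndarray,
    y,
    feature_ids: Sequence[str],
    folds: int = 3,
    seed: int = 0,
) -> PanelCandidate:
    """One-off fitness of a candidate (mean held-out accuracy over folds)."""
    return FitnessEvaluator(X, y, feature_ids, folds=folds, seed=seed).evaluate(features)


def _crossover(a: frozenset, b: frozenset, k: int, rng: np.random.Generator) -> frozenset:
    """Uniform set recombination preserving |child| = k.

    The intersection is always inherited; the remainder is drawn without
    replacement from the symmetric difference.
    """
    common = a & b
    pool = sorted(a ^ b)
    need = k - len(common)
    picked = rng.choice(len(pool), size=need, replace=False) if need else []
    return frozenset(common | {pool[i] for i in picked})


def _mutate(c: frozenset, universe: Sequence[str], rng: np.random.Generator) -> frozenset:
    """Swap one random member for one random non-member."""
    members = sorted(c)
    outside = sorted(set(universe) - c)
    if not outside:
        return c
    out = members[rng.integers(len(members))]
    new = outside[rng.integers(len(outside))]
    return frozenset(set(members) - {out} | {new})


def ga_select(
    dataset_a: tuple[np.ndarray, np.ndarray],
    dataset_b: tuple[np.ndarray, np.ndarray],
    screened_features: Sequence[str],
    config: GAConfig,
    evaluator: Optional[FitnessEvaluator] = None,
) -> PanelSelection:
    """Evolve fixed-size feature subsets; rank finalists on dataset B.

    ``dataset_a`` and ``dataset_b`` are (matrix, labels) pairs whose
    columns follow ``screened_features``.  Fitness is only ever computed on
    dataset A; each distinct finalist is evaluated exactly once on dataset
    B and the candidate with the best holdout accuracy wins.
    """
    features = list(screened_features)
    k = config.panel_size
    if len(features) < k:
        raise ValueError(f"{len(features)} screened features for panel size {k}")
    Xa, ya = dataset_a
    Xb, yb = dataset_b
    ya = np.asarray(ya)
    yb = np.asarray(yb)
    if evaluator is None:
        evaluator = FitnessEvaluator(Xa, ya, features, folds=config.cv_folds, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    b_index = {f: j for j, f in enumerate(features)}

    def holdout_accuracy(candidate: PanelCandidate) -> float:
        clf = evaluator.fit_full(candidate.features)
        cols = [b_index[f] for f in sorted(candidate.features)]
        return float(np.mean(clf.predict(np.asarray(Xb)[:, cols]) == yb))

    if len(features) == k:
        best = evaluator.evaluate(frozenset(features))
        acc = holdout_accuracy(best)
        return PanelSelection(best, acc, [best.fitness], [(best, acc)], {best.features: 1})

    def random_individual() -> frozenset:
        idx = rng.choice(len(features), size=k, replace=False)
        return frozenset(features[i] for i in idx)

    population = [random_individual() for _ in range(config.population_size)]
    scored = [evaluator.evaluate(ind) for ind in population]
    trajectory = [max(c.fitness for c in scored)]

    def tournament() -> PanelCandidate:
        idx = rng.integers(len(scored), size=config.tournament_size)
        return max((scored[i] for i in idx), key=lambda c: c.fitness)

    for _gen in range(config.generations):
        if len(set(population)) == 1 and config.mutation_rate == 0.0:
            warnings.warn("population degenerate with zero mutation; stopping early", stacklevel=2)
            break
        elites = sorted(scored, key=lambda c: c.fitness, reverse=True)[: config.elitism_count]
        offspring: list[frozenset] = [c.features for c in elites]
        while len(offspring) < config.population_size:
            p1, p2 = tournament().features, tournament().features
            child = _crossover(p1, p2, k, rng) if rng.random() < config.crossover_rate else p1
            if rng.random() < config.mutation_rate:
                child = _mutate(child, features, rng)
            assert len(child) == k
            offspring.append(child)
        population = offspring
        scored = [evaluator.evaluate(ind) for ind in population]
        trajectory.append(max(max(c.fitness for c in scored), trajectory[-1] if elites else -np.inf))

    # final ranking of the distinct best-fitness candidates on dataset B
    distinct: dict[frozenset, PanelCandidate] = {c.features: c for c in scored}
    finalists = sorted(distinct.values(), key=lambda c: (-c.fitness, tuple(sorted(c.features))))
    finalists = finalists[: config.top_candidates]
    b_counts: dict[frozenset, int] = {}
    ranked: list[tuple[PanelCandidate, float]] = []
    for cand in finalists:
        b_counts[cand.features] = b_counts.get(cand.features, 0) + 1
        ranked.append((cand, holdout_accuracy(cand)))
    best, best_acc = max(ranked, key=lambda t: (t[1], t[0].fitness, tuple(sorted(t[0].features))))
    return PanelSelection(best, best_acc, trajectory, ranked, b_counts)
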