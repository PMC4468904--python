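"""SiderFinder: side-effect signature selection over MetChange scores.

Given a drugs/samples x metabolites score matrix and clinical
side-effect occurrence frequencies, SiderFinder searches for a small
ternary signature (one value in {-1, 0, +1} per metabolite, at most 20
nonzero) whose inner product with each sample's scores ranks samples of
drugs bearing the side effect above the rest.

The ranking objective is a frequency-weighted pseudo-ROC: each positive
sample contributes its adjusted log10 frequency as true-positive mass
(lowest nonzero frequency = 1, one unit per decade, zeros stay zero),
and the total true mass is the sum of the adjusted frequencies so the
area still spans 0 to 1. A genetic algorithm with elitism maximizes the
AUC; tenfold cross-validation plus summing of fold signatures yields a
consensus signature robust to overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GAConfig",
    "GAResult",
    "CVResult",
    "process_frequencies",
    "filter_side_effects",
    "adjust_frequencies",
    "score_samples",
    "pseudo_roc_auc",
    "run_ga",
    "cross_validate",
    "consensus_from_folds",
]


# ---------------------------------------------------------------------------
# frequency processing


def process_frequencies(
    table: pd.DataFrame, side_effect: str
) -> pd.Series:
    """Differential occurrence frequency per drug for one side effect.

    Per study: mean of (min, max) frequency. Per arm: median across
    studies. Result: treated minus placebo, clamped at 0; when no
    placebo studies exist, the treated frequency alone. Table columns:
    ``drug, side_effect, study_id, arm, freq_min, freq_max``.
    """
    sub = table[table["side_effect"] == side_effect]
    out: dict[str, float] = {}
    for drug, grp in sub.groupby("drug"):
        study_means = (grp["freq_min"] + grp["freq_max"]) / 2.0
        treated = study_means[grp["arm"] == "treated"]
        placebo = study_means[grp["arm"] == "placebo"]
        if treated.empty:
            continue
        f = float(treated.median())
        if not placebo.empty:
            f -= float(placebo.median())
        out[drug] = max(f, 0.0)
    return pd.Series(out, name=side_effect, dtype=float)


def filter_side_effects(
    sample_frequencies: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    min_samples: int = 30,
) -> list[str]:
    """Side effects with at least ``min_samples`` mapped expression sets
    (boundary inclusive)."""
    if isinstance(sample_frequencies, pd.DataFrame):
        counts = sample_frequencies.notna().sum(axis=0)
        return [se for se, n in counts.items() if n >= min_samples]
    return [
        se for se, m in sample_frequencies.items() if len(m) >= min_samples
    ]


def adjust_frequencies(frequencies: pd.Series | Mapping[str, float]) -> pd.Series:
    """log10 adjustment of side-effect frequencies into ROC weights.

    w = log10(f) - log10(min positive f) + 1 for f > 0, and w = 0 for
    f = 0: the lowest nonzero frequency weighs 1 and each decade adds a
    unit, so high-frequency samples dominate the true-positive mass.
    """
    f = pd.Series(dict(frequencies), dtype=float) if not isinstance(
        frequencies, pd.Series
    ) else frequencies.astype(float)
    if (f < 0).any():
        raise ValueError("frequencies must be nonnegative")
    pos = f[f > 0]
    if pos.empty:
        raise ValueError("no positive frequencies; weights undefined")
    fmin = pos.min()
    w = pd.Series(0.0, index=f.index)
    w[f > 0] = np.log10(f[f > 0]) - np.log10(fmin) + 1.0
    return w


# ---------------------------------------------------------------------------
# scoring and the weighted ROC


def score_samples(
    signature: Mapping[str, int] | pd.Series, scores: pd.DataFrame
) -> pd.Series:
    """Inner product of a ternary signature with each sample's score
    vector; missing score entries contribute 0."""
    sig = pd.Series(dict(signature), dtype=float) if not isinstance(
        signature, pd.Series
    ) else signature.astype(float)
    missing = sig.index.difference(scores.columns)
    if len(missing) > 0:
        raise KeyError(f"signature metabolites not in score matrix: {list(missing)[:5]}")
    X = scores[sig.index].fillna(0.0).to_numpy(dtype=float)
    return pd.Series(X @ sig.to_numpy(), index=scores.index)


def pseudo_roc_auc(scores: np.ndarray, weights: np.ndarray) -> float:
    """Frequency-weighted ROC area.

    Sweeping a threshold over descending scores, samples at or above the
    threshold are called positive. TPR accumulates the adjusted-frequency
    weight of called samples over the total weight; FPR accumulates the
    count of called zero-weight samples over their total. Tied scores
    move both rates in one step (trapezoid over the tie group). With all
    positive weights equal the area reduces to the classical
    tie-corrected AUC.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape or s.ndim != 1:
        raise ValueError("scores and weights must be 1-d and aligned")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total_w = w.sum()
    n_neg = int((w == 0).sum())
    if total_w <= 0 or n_neg == 0:
        raise ValueError("need at least one positive-weight and one zero-weight sample")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    w_sorted = w[order]
    # group boundaries where the sorted score changes
    boundary = np.nonzero(np.diff(s_sorted))[0]
    ends = np.append(boundary, s_sorted.size - 1)
    cum_w = np.cumsum(w_sorted)
    cum_neg = np.cumsum(w_sorted == 0)
    tpr = np.concatenate([[0.0], cum_w[ends] / total_w])
    fpr = np.concatenate([[0.0], cum_neg[ends] / n_neg])
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# the genetic algorithm


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults: 125 candidate signatures, at most 20 nonzero entries,
    uniform crossover, per-locus mutation probability 1/m, 5 elites,
    tournament selection of size 3, termination after 300 generations or
    50 generations without improvement. Deterministic for a fixed seed.
    """

    population_size: int = 125
    max_predictors: int = 20
    mutation_prob: float | None = None  # default 1/m
    crossover_prob: float = 0.9
    elite: int = 5
    tournament: int = 3
    max_generations: int = 300
    stall_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population must be at least 2")
        if self.max_predictors < 1:
            raise ValueError("max_predictors must be positive")


@dataclass
class GAResult:
    signature: pd.Series  # ternary, indexed by metabolite
    auc: float
    generations: int
    history: list[float] = field(default_factory=list)
    config: GAConfig | None = None

    def support(self) -> list[str]:
        return list(self.signature.index[self.signature != 0])


def _repair(pop: np.ndarray, cap: int, rng: np.random.Generator) -> None:
    """Zero randomly chosen excess nonzero loci so |support| <= cap."""
    for row in pop:
        nz = np.nonzero(row)[0]
        if nz.size > cap:
            drop = rng.choice(nz, size=nz.size - cap, replace=False)
            row[drop] = 0


def _init_population(
    n_pop: int, m: int, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Sparse random ternary individuals with support size 1..cap."""
    pop = np.zeros((n_pop, m), dtype=np.int8)
    for row in pop:
        k = int(rng.integers(1, min(cap, m) + 1))
        loci = rng.choice(m, size=k, replace=False)
        row[loci] = rng.choice([-1, 1], size=k)
    return pop


def _evaluate(
    pop: np.ndarray, X: np.ndarray, w: np.ndarray
) -> np.ndarray:
    sample_scores = X @ pop.T  # n_samples x n_pop
    return np.array(
        [pseudo_roc_auc(sample_scores[:, j], w) for j in range(pop.shape[0])]
    )


def run_ga(
    scores: pd.DataFrame,
    weights: pd.Series | Mapping[str, float],
    config: GAConfig | None = None,
) -> GAResult:
    """Maximize the pseudo-ROC AUC over cardinality-capped ternary
    signatures. Elitism makes the best AUC monotone non-decreasing in
    generation; identical (data, config, seed) give identical output.
    """
    config = config or GAConfig()
    w = pd.Series(dict(weights), dtype=float) if not isinstance(
        weights, pd.Series
    ) else weights.astype(float)
    w = w.loc[scores.index]
    wv = w.to_numpy()
    if (wv > 0).sum() == 0 or (wv == 0).sum() == 0:
        raise ValueError("need both positive-weight and zero-weight samples")
    X = scores.fillna(0.0).to_numpy(dtype=float)
    m = X.shape[1]
    cap = min(config.max_predictors, m)
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / m
    rng = np.random.default_rng(config.seed)

    pop = _init_population(config.population_size, m, cap, rng)
    fitness = _evaluate(pop, X, wv)
    best_auc = -np.inf
    best: np.ndarray | None = None
    history: list[float] = []
    stall = 0
    gen = 0
    for gen in range(config.max_generations + 1):
        top = int(np.argmax(fitness))
        if fitness[top] > best_auc + 1e-12:
            best_auc = float(fitness[top])
            best = pop[top].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_auc)
        if gen == config.max_generations or stall >= config.stall_generations:
            break
        # next generation: elites + tournament/crossover/mutation offspring
        elite_idx = np.argsort(-fitness)[: config.elite]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.population_size:
            pa = _tournament(fitness, config.tournament, rng)
            pb = _tournament(fitness, config.tournament, rng)
            if rng.random() < config.crossover_prob:
                mask = rng.random(m) < 0.5
                child = np.where(mask, pop[pa], pop[pb]).astype(np.int8)
            else:
                child = pop[pa].copy()
            mut = rng.random(m) < p_mut
            if mut.any():
                child[mut] = rng.choice([-1, 0, 1], size=int(mut.sum()))
            children.append(child)
        pop = np.array(children, dtype=np.int8)
        _repair(pop, cap, rng)
        fitness = _evaluate(pop, X, wv)

    assert best is not None
    signature = pd.Series(best, index=scores.columns, dtype=int)
    return GAResult(signature, best_auc, gen, history, config)


def _tournament(fitness: np.ndarray, k: int, rng: np.random.Generator) -> int:
    idx = rng.integers(0, fitness.size, size=k)
    return int(idx[np.argmax(fitness[idx])])


# ---------------------------------------------------------------------------
# cross-validation consensus


@dataclass
class CVResult:
    fold_signatures: pd.DataFrame  # folds x metabolites, ternary
    summed: pd.Series  # integer sum per metabolite
    consensus: pd.Series  # ternary consensus signature
    train_auc: list[float]
    test_auc: list[float]

    def support(self) -> list[str]:
        return list(self.consensus.index[self.consensus != 0])


def _stratified_folds(
    positive: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Indices per fold, preserving the positive/negative ratio."""
    pos = np.nonzero(positive)[0]
    neg = np.nonzero(~positive)[0]
    if pos.size < folds or neg.size < folds:
        raise ValueError(
            f"need at least {folds} samples of each class for {folds}-fold CV"
        )
    rng.shuffle(pos)
    rng.shuffle(neg)
    out: list[np.ndarray] = []
    for i in range(folds):
        out.append(np.concatenate([pos[i::folds], neg[i::folds]]))
    return out


def cross_validate(
    scores: pd.DataFrame,
    weights: pd.Series | Mapping[str, float],
    config: GAConfig | None = None,
    folds: int = 10,
    consensus_threshold: int = 4,
    consensus_mode: str = "sum",
) -> CVResult:
    """Tenfold cross-validated consensus signature.

    A signature is trained per fold on 90% of the samples and evaluated
    on the held-out 10%. Fold signatures are summed per metabolite; the
    consensus keeps metabolites appearing cumulatively in at least
    ``consensus_threshold`` folds, signed by the sum. ``consensus_mode``
    selects the cumulative reading: ``"sum"`` (|sum of ternary values|
    >= threshold) or ``"count"`` (number of folds with a nonzero entry
    >= threshold, excluded when the sum is 0).
    """
    if consensus_mode not in ("sum", "count"):
        raise ValueError("consensus_mode must be 'sum' or 'count'")
    config = config or GAConfig()
    w = pd.Series(dict(weights), dtype=float) if not isinstance(
        weights, pd.Series
    ) else weights.astype(float)
    w = w.loc[scores.index]
    rng = np.random.default_rng(config.seed)
    fold_idx = _stratified_folds((w > 0).to_numpy(), folds, rng)

    sigs: list[pd.Series] = []
    train_auc: list[float] = []
    test_auc: list[float] = []
    for i, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(len(scores)), test)
        fold_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        res = run_ga(scores.iloc[train], w.iloc[train], fold_cfg)
        sigs.append(res.signature.rename(f"fold{i}"))
        train_auc.append(res.auc)
        held = score_samples(res.signature, scores.iloc[test])
        test_auc.append(
            pseudo_roc_auc(held.to_numpy(), w.iloc[test].to_numpy())
        )
    fold_signatures = pd.DataFrame(sigs)
    summed, consensus = consensus_from_folds(
        fold_signatures, consensus_threshold, consensus_mode
    )
    return CVResult(fold_signatures, summed, consensus, train_auc, test_auc)


def consensus_from_folds(
    fold_signatures: pd.DataFrame,
    threshold: int = 4,
    mode: str = "sum",
) -> tuple[pd.Series, pd.Series]:
    """Sum fold signatures and keep metabolites appearing cumulatively in
    at least ``threshold`` folds, signed by the sum. Returns (sum,
    consensus). ``mode='count'`` counts nonzero appearances instead of
    the absolute sum (a metabolite cancelling to 0 is always dropped)."""
    if mode not in ("sum", "count"):
        raise ValueError("mode must be 'sum' or 'count'")
    summed = fold_signatures.sum(axis=0).astype(int)
    if mode == "sum":
        keep = summed.abs() >= threshold
    else:
        counts = (fold_signatures != 0).sum(axis=0)
        keep = (counts >= threshold) & (summed != 0)
    consensus = pd.Series(0, index=summed.index, dtype=int)
    consensus[keep] = np.sign(summed[keep]).astype(int)
    return summed, consensus
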