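"""Validation statistics: network distance to drug targets, score-bin
comparisons, permutation tests and enrichment tests.

These support the downstream claims about scored metabolites: that drug
targets sit close (in reaction hops) to highly perturbed metabolites,
that an observed signature AUC beats a permuted background, and that
pathway/nutrient hit rates exceed chance (hypergeometric and binomial
tails, Benjamini-Hochberg across families).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import MetabolicNetwork

__all__ = [
    "DistanceProfile",
    "EnrichmentResult",
    "network_distance",
    "bin_and_compare",
    "permutation_auc_test",
    "hypergeom_enrichment",
    "binomial_enrichment",
    "adjust_bh",
    "dual_permutation_test",
]

#: metabolites in more than this many distinct reactions (cofactors,
#: protons, water...) are dropped from the distance graph
CONNECTIVITY_CAP = 30


@dataclass
class DistanceProfile:
    """Minimal reaction-hop distance per metabolite to a target reaction
    set; unreachable metabolites are missing from ``distances``."""

    distances: dict[str, int]
    excluded: set[str]  # metabolites over the connectivity cap

    def __getitem__(self, met: str) -> int:
        return self.distances[met]

    def series(self) -> pd.Series:
        return pd.Series(self.distances, dtype=float)


def metabolite_graph(
    net: MetabolicNetwork, connectivity_cap: int = CONNECTIVITY_CAP
) -> tuple[nx.Graph, set[str]]:
    """Undirected metabolite graph: metabolites adjacent when they share
    a reaction; metabolites in more than ``connectivity_cap`` distinct
    (parent) reactions are removed as nodes. Build on the pre-split
    network so `_f`/`_b` halves don't double-count connectivity."""
    excluded = {
        m for m in net.metabolites if net.connectivity(m) > connectivity_cap
    }
    g = nx.Graph()
    g.add_nodes_from(m for m in net.metabolites if m not in excluded)
    for r in net.reactions.values():
        mets = [m for m in r.stoichiometry if m not in excluded]
        for i, a in enumerate(mets):
            for b in mets[i + 1 :]:
                g.add_edge(a, b)
    return g, excluded


def network_distance(
    net: MetabolicNetwork,
    target_reactions: Iterable[str],
    connectivity_cap: int = CONNECTIVITY_CAP,
) -> DistanceProfile:
    """Breadth-first reaction-hop distance of every metabolite to a set
    of target reactions. Participants of a target reaction are at
    distance 0; each further shared reaction adds one hop. High-
    connectivity metabolites neither appear nor propagate distance."""
    targets = list(target_reactions)
    if not targets:
        raise ValueError("empty target reaction set")
    missing = [t for t in targets if t not in net.reactions]
    if missing:
        raise KeyError(f"unknown target reactions: {missing}")
    g, excluded = metabolite_graph(net, connectivity_cap)
    sources = set()
    for t in targets:
        sources |= set(net.reactions[t].stoichiometry)
    dist: dict[str, int] = {m: 0 for m in sources}
    reachable_sources = [m for m in sources if m in g]
    if reachable_sources:
        bfs = nx.multi_source_dijkstra_path_length(g, reachable_sources, weight=None)
        for m, d in bfs.items():
            dist[m] = min(int(d), dist.get(m, int(d)))
    return DistanceProfile(dist, excluded)


def bin_and_compare(
    scores: Mapping[str, float] | pd.Series,
    distances: DistanceProfile | Mapping[str, float],
    bin_width: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Pool metabolites into standardized-score bins and compare network
    distances of the highest-score bin against all others.

    Returns a per-bin summary (count, mean distance) and the two-sided
    rank-sum p-value for the highest nonempty bin vs the rest.
    """
    s = pd.Series(dict(scores), dtype=float) if not isinstance(
        scores, pd.Series
    ) else scores.astype(float)
    d = distances.series() if isinstance(distances, DistanceProfile) else pd.Series(
        dict(distances), dtype=float
    )
    joint = pd.concat([s.rename("score"), d.rename("distance")], axis=1).dropna()
    if joint.empty:
        raise ValueError("no metabolites with both a score and a distance")
    bins = np.floor(joint["score"] / bin_width).astype(int)
    summary = (
        joint.assign(bin=bins)
        .groupby("bin")["distance"]
        .agg(n="count", mean_distance="mean")
        .sort_index()
    )
    if len(summary) < 2:
        raise ValueError("need at least two nonempty score bins")
    top = summary.index.max()
    top_d = joint.loc[bins == top, "distance"]
    rest_d = joint.loc[bins != top, "distance"]
    if len(top_d) < 2 or len(rest_d) < 2:
        raise ValueError("too few metabolites in the extreme bin for a rank test")
    p = float(sps.ranksums(top_d, rest_d).pvalue)
    return summary, p


def permutation_auc_test(
    observed_auc: float,
    scores: pd.DataFrame,
    auc_of: Callable[[pd.DataFrame], float],
    permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Non-parametric rank test of an observed AUC against AUCs of
    row-permuted score matrices.

    ``auc_of`` recomputes the AUC from a (permuted) score matrix; rows
    are shuffled relative to their labels. p = (1 + #{permuted AUC >=
    observed}) / (permutations + 1), never exactly 0.
    """
    if permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(len(scores))
    for _ in range(permutations):
        perm = rng.permutation(idx)
        shuffled = pd.DataFrame(
            scores.to_numpy()[perm], index=scores.index, columns=scores.columns
        )
        if auc_of(shuffled) >= observed_auc:
            hits += 1
    return (1 + hits) / (permutations + 1)


@dataclass
class EnrichmentResult:
    k: int  # hits inside the category
    n: int  # total hits (or trials)
    K: int  # category size (or expected successes context)
    N: int  # universe size (or trials)
    direction: str  # "enriched" | "depleted"
    p: float
    p_adjusted: float | None = None
    test: str = "hypergeometric"


def hypergeom_enrichment(
    k: int, n: int, K: int, N: int, tail: str = "upper"
) -> EnrichmentResult:
    """Exact hypergeometric tail: k hits in a pathway of size K, among n
    total hits drawn from a universe of N."""
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError("inconsistent contingency margins")
    rv = sps.hypergeom(N, K, n)
    if tail == "upper":
        p = float(rv.sf(k - 1))
        direction = "enriched"
    elif tail == "lower":
        p = float(rv.cdf(k))
        direction = "depleted"
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return EnrichmentResult(k, n, K, N, direction, min(p, 1.0), test="hypergeometric")


def binomial_enrichment(
    successes: int, trials: int, p0: float, tail: str = "upper"
) -> EnrichmentResult:
    """Exact one-tailed binomial tail sum against null probability p0."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 < p0 < 1:
        raise ValueError("null probability must lie in (0, 1)")
    if not 0 <= successes <= trials:
        raise ValueError("successes outside [0, trials]")
    rv = sps.binom(trials, p0)
    if tail == "upper":
        p = float(rv.sf(successes - 1))
        direction = "enriched"
    elif tail == "lower":
        p = float(rv.cdf(successes))
        direction = "depleted"
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return EnrichmentResult(
        successes, trials, successes, trials, direction, min(p, 1.0), test="binomial"
    )


def adjust_bh(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg adjustment across a family of enrichment tests."""
    ps = np.array([r.p for r in results], dtype=float)
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, ps[i] * m / rank)
        adj[i] = prev
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return list(results)


def dual_permutation_test(
    outcomes: pd.DataFrame,
    predicted: Sequence[tuple[str, str]] | None = None,
    permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Dual permutation test for hit enrichment among predicted pairs.

    ``outcomes`` is a (side effect x nutrient) table of hit/miss results
    for every investigated pair (predicted and background alike); missing
    entries are uninvestigated. ``predicted`` names the pairs whose total
    hit count is under test (default: every investigated pair).

    Per replicate, each predicted pair (s, n) is replaced by the average
    of a random investigated outcome for the same side effect (a random
    nutrient in row s) and a random investigated outcome for the same
    nutrient (a random side effect in column n); the replicate total is
    compared with the observed total of predicted hits.
    p = (1 + #{replicate total >= observed}) / (permutations + 1), never
    exactly 0. A pair whose row or column has no alternative draws
    contributes its own value.

    Note the replicate totals average two draws per pair, which shrinks
    their spread relative to the sampling variation of the observed
    total: the p-value is conservative (concentrated away from the
    tails) rather than exactly uniform under a random-outcome null.
    """
    if permutations < 1:
        raise ValueError("need at least one permutation")
    vals = outcomes.to_numpy(dtype=float)
    obs_mask = np.isfinite(vals)
    if predicted is None:
        pairs = np.argwhere(obs_mask)
    else:
        ridx = {r: i for i, r in enumerate(outcomes.index)}
        cidx = {c: j for j, c in enumerate(outcomes.columns)}
        pairs = np.array([[ridx[s], cidx[n]] for s, n in predicted])
        if not all(obs_mask[i, j] for i, j in pairs):
            raise ValueError("predicted pairs must have investigated outcomes")
    if pairs.size == 0:
        raise ValueError("no observed pairs")
    observed_total = float(sum(vals[i, j] for i, j in pairs))
    rng = np.random.default_rng(seed)
    row_pool = [np.nonzero(obs_mask[i])[0] for i in range(vals.shape[0])]
    col_pool = [np.nonzero(obs_mask[:, j])[0] for j in range(vals.shape[1])]
    hits = 0
    for _ in range(permutations):
        total = 0.0
        for i, j in pairs:
            rp = row_pool[i]
            cp = col_pool[j]
            a = vals[i, rng.choice(rp)] if rp.size > 1 else vals[i, j]
            b = vals[rng.choice(cp), j] if cp.size > 1 else vals[i, j]
            total += 0.5 * (a + b)
        if total >= observed_total:
            hits += 1
    return (1 + hits) / (permutations + 1)
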