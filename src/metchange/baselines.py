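"""Baseline expression-to-metabolite scoring methods and a benchmark
harness comparing them (and MetChange) against measured metabolomics.

* E-Flux: reaction upper bounds scaled by relative expression
  (reaction expression / max over mapped reactions); metabolite sinks
  maximized like the MetChange LP 1.
* Reporter metabolites: per-gene change p-values are quantile-normal
  transformed and aggregated over each metabolite's neighbouring genes,
  then corrected against a permuted background per neighbourhood size.
* Expression baselines: reaction-mapped standardized expression changes
  summed over each metabolite's reactions, either by absolute value
  weighted by |stoichiometry| (magnitude prediction) or by the signed
  stoichiometric coefficient (directional prediction: products gain,
  reactants lose).
* Benchmark: Spearman rank correlations (robust to the methods' very
  different score distributions) of predicted vs measured log2
  concentration changes per condition, both in magnitude and direction,
  summarized by the median across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lp import NetworkLP
from .network import DEMAND, MetabolicNetwork, add_demand, demand_id

__all__ = [
    "BenchmarkReport",
    "map_expression_to_reactions",
    "eflux_production",
    "reporter_scores",
    "expression_magnitude_baseline",
    "expression_directional_baseline",
    "benchmark",
]


def map_expression_to_reactions(
    net: MetabolicNetwork, intensities: Mapping[str, float]
) -> dict[str, float | None]:
    """Abundance-style GPR mapping: AND -> min, OR -> sum; reactions
    without a GPR (or with no measured gene) map to None (unconstrained)."""
    out: dict[str, float | None] = {}
    for r in net.reactions.values():
        if r.gpr is None or not (r.gpr.genes() & set(intensities)):
            out[r.id] = None
        else:
            out[r.id] = float(
                r.gpr.evaluate_expression(lambda g: float(intensities.get(g, 0.0)))
            )
    return out


def eflux_production(
    net: MetabolicNetwork,
    expression: Mapping[str, float],
    metabolites: Sequence[str],
    by_reaction: bool = False,
    norm_max: float | None = None,
) -> pd.Series:
    """E-Flux maximal production per metabolite.

    Reaction upper bounds are scaled to expression / max(expression over
    mapped reactions) — so the result is invariant to rescaling all
    expression values — and each metabolite's demand flux is maximized.
    ``expression`` is per-gene unless ``by_reaction``. ``norm_max``
    overrides the normalization constant (e.g. a per-reaction max across
    conditions).
    """
    if by_reaction:
        rxn_expr: dict[str, float | None] = {
            r.id: (float(expression[r.id]) if r.id in expression else None)
            for r in net.reactions.values()
        }
    else:
        rxn_expr = map_expression_to_reactions(net, expression)
    mapped = [v for v in rxn_expr.values() if v is not None]
    if not mapped or max(mapped) <= 0:
        raise ValueError("no positive expression mapped to any reaction")
    scale = norm_max if norm_max is not None else max(mapped)
    for m in metabolites:
        net = add_demand(net, m)
    overrides = {}
    for rid, e in rxn_expr.items():
        if e is None:
            continue
        r = net.reactions[rid]
        if r.kind == DEMAND:
            continue
        overrides[rid] = (r.lower_bound, e / scale)
    lp = NetworkLP(net)
    out = {}
    for m in metabolites:
        out[m] = lp.solve(
            {demand_id(m): 1.0}, sense="max", bound_overrides=overrides
        ).objective
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# reporter metabolites


def gene_metabolite_adjacency(net: MetabolicNetwork) -> dict[str, set[str]]:
    """Metabolite -> set of neighbouring genes (genes of any reaction the
    metabolite takes part in, counted on parent reactions once)."""
    adj: dict[str, set[str]] = {m: set() for m in net.metabolites}
    for r in net.reactions.values():
        if r.gpr is None:
            continue
        genes = r.gpr.genes()
        for m in r.stoichiometry:
            adj[m] |= genes
    return adj


def reporter_scores(
    net: MetabolicNetwork,
    gene_pvalues: Mapping[str, float],
    permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reporter-metabolite Z-scores with a permuted background.

    Per gene, Z_g = Phi^-1(1 - p). Per metabolite with k neighbouring
    measured genes, raw Z = sum(Z_g) / sqrt(k). The background shuffles
    gene p-values over gene labels: for each occurring k, ``permutations``
    random draws of k gene Z-values give mean_k and sd_k, and the
    corrected Z is (raw - mean_k) / sd_k. Metabolites without measured
    neighbour genes are missing.
    """
    p = pd.Series(dict(gene_pvalues), dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("gene p-values must lie strictly inside (0, 1)")
    z_gene = pd.Series(stats.norm.ppf(1.0 - p.to_numpy()), index=p.index)
    adj = gene_metabolite_adjacency(net)
    rows = {}
    for m, genes in adj.items():
        measured = sorted(genes & set(p.index))
        k = len(measured)
        if k == 0:
            rows[m] = (np.nan, 0)
        else:
            rows[m] = (float(z_gene[measured].sum()) / np.sqrt(k), k)
    raw = pd.Series({m: v[0] for m, v in rows.items()})
    degree = pd.Series({m: v[1] for m, v in rows.items()})

    rng = np.random.default_rng(seed)
    zv = z_gene.to_numpy()
    bg: dict[int, tuple[float, float]] = {}
    for k in sorted(set(degree[degree > 0])):
        draws = rng.choice(zv, size=(permutations, k), replace=True).sum(axis=1)
        draws = draws / np.sqrt(k)
        bg[k] = (float(draws.mean()), float(draws.std(ddof=1)))
    corrected = pd.Series(np.nan, index=raw.index)
    for m in raw.index:
        k = int(degree[m])
        if k > 0 and bg[k][1] > 0:
            corrected[m] = (raw[m] - bg[k][0]) / bg[k][1]
    return pd.DataFrame(
        {"raw_z": raw, "corrected_z": corrected, "n_genes": degree}
    )


# ---------------------------------------------------------------------------
# expression-only baselines


def expression_magnitude_baseline(
    net: MetabolicNetwork, reaction_scores: Mapping[str, float]
) -> pd.Series:
    """Magnitude prediction: per metabolite, sum over incident reactions
    of |stoichiometric coefficient| x |standardized reaction score|."""
    out = {m: 0.0 for m in net.metabolites}
    for r in net.reactions.values():
        s = reaction_scores.get(r.id)
        if s is None:
            continue
        for m, coef in r.stoichiometry.items():
            out[m] += abs(coef) * abs(float(s))
    return pd.Series(out, dtype=float)


def expression_directional_baseline(
    net: MetabolicNetwork, reaction_scores: Mapping[str, float]
) -> pd.Series:
    """Directional prediction: per metabolite, sum of signed
    stoichiometric coefficient x reaction score (products gain score,
    reactants lose it)."""
    out = {m: 0.0 for m in net.metabolites}
    for r in net.reactions.values():
        s = reaction_scores.get(r.id)
        if s is None:
            continue
        for m, coef in r.stoichiometry.items():
            out[m] += coef * float(s)
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# benchmarking harness


@dataclass
class BenchmarkReport:
    """Median-across-conditions Spearman correlations per method."""

    absolute: pd.Series  # method -> median rho of |score| vs |log2 change|
    directional: pd.Series  # method -> median rho of signed values
    per_condition: pd.DataFrame  # (method, kind) x condition


def _spearman(a: pd.Series, b: pd.Series) -> float:
    joint = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joint) < 3:
        return np.nan
    rho = stats.spearmanr(joint.iloc[:, 0], joint.iloc[:, 1]).statistic
    return float(rho)


def benchmark(
    method_scores: Mapping[str, pd.DataFrame],
    metabolomics: pd.DataFrame,
) -> BenchmarkReport:
    """Compare per-method metabolite scores to measured log2 changes.

    ``method_scores``: method tag -> metabolites x conditions frame.
    ``metabolomics``: metabolites x conditions log2 concentration changes.
    Spearman rank correlations are used to avoid bias from the methods'
    different score distributions; conditions with fewer than 3 shared
    metabolites are missing.
    """
    records = {}
    for tag, scores in method_scores.items():
        conds = scores.columns.intersection(metabolomics.columns)
        for cond in conds:
            records[(tag, "absolute", cond)] = _spearman(
                scores[cond].abs(), metabolomics[cond].abs()
            )
            records[(tag, "directional", cond)] = _spearman(
                scores[cond], metabolomics[cond]
            )
    per = pd.Series(records).rename_axis(["method", "kind", "condition"])
    per_condition = per.unstack("condition")
    med = per.groupby(["method", "kind"]).median()
    return BenchmarkReport(
        absolute=med.xs("absolute", level="kind"),
        directional=med.xs("directional", level="kind"),
        per_condition=per_condition,
    )
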