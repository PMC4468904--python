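"""High-level drivers: expression profiles in, score matrices out.

``run_metchange`` performs the full per-sample scoring pass: media
constraints, irreversibilization, producibility screen, LP1/LP2 per
metabolite per sample, and standardization of treated samples against
batch controls.

``benchmark_methods`` runs MetChange alongside the baseline methods on a
longitudinal intensity table and correlates every method's output with
measured metabolomics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import baselines as bl
from .expression import GeneProfile, derive_pvals_from_intensities, map_gene_pvals
from .network import MediaSpec, MetabolicNetwork, apply_media, find_producible, make_irreversible
from .scoring import (
    MetChangeModel,
    ProductionCapability,
    longitudinal_log2_scores,
    standardized_scores,
)

__all__ = ["MetChangeResult", "run_metchange", "benchmark_methods"]


@dataclass
class MetChangeResult:
    consistency: pd.DataFrame  # all samples x metabolites (x scores)
    z: pd.DataFrame  # treated samples x metabolites (standard scores)
    vmax: ProductionCapability
    producible: set[str]
    skipped_media: list[str]


def profiles_metadata(profiles: Iterable[GeneProfile]) -> pd.DataFrame:
    rows = {
        p.sample: {
            "drug": p.drug,
            "cell_line": p.cell_line,
            "batch": p.batch,
            "is_control": p.is_control,
        }
        for p in profiles
    }
    meta = pd.DataFrame(rows).T
    meta["is_control"] = meta["is_control"].astype(bool)
    return meta


def run_metchange(
    net: MetabolicNetwork,
    media: MediaSpec,
    profiles: Sequence[GeneProfile],
    metabolites: Sequence[str] | None = None,
) -> MetChangeResult:
    """Score every profile on a media-constrained network.

    Metabolites that cannot be produced even with every exchange open
    are removed up front; metabolites non-producible only under the
    given media come out as missing values.
    """
    constrained, skipped = apply_media(net, media)
    irrev = make_irreversible(constrained)
    mets = list(metabolites) if metabolites is not None else net.metabolite_ids
    # producibility is screened on the unconstrained network (all
    # exchanges open), not under the medium
    producible = find_producible(net, mets)
    model = MetChangeModel(irrev, [m for m in mets if m in producible])
    rows = []
    for p in profiles:
        penalty = map_gene_pvals(model.net, p)
        rows.append(model.score_sample(penalty))
    consistency = pd.DataFrame(rows)
    meta = profiles_metadata(profiles)
    if meta["is_control"].any():
        z = standardized_scores(consistency, meta)
    else:
        z = pd.DataFrame(index=pd.Index([]), columns=consistency.columns)
    return MetChangeResult(consistency, z, model.production_capability(), producible, skipped)


# ---------------------------------------------------------------------------
# longitudinal benchmarking of MetChange vs the baseline methods


def _gene_change_scores(intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standard score of each condition against the gene's own
    distribution across conditions."""
    mu = intensities.mean(axis=1)
    sd = intensities.std(axis=1, ddof=1).replace(0.0, np.nan)
    return intensities.sub(mu, axis=0).div(sd, axis=0)


def _reaction_scores(net: MetabolicNetwork, gene_scores: pd.Series) -> dict[str, float]:
    """Signed gene scores averaged over each reaction's genes."""
    out = {}
    for r in net.reactions.values():
        if r.gpr is None:
            continue
        vals = [gene_scores[g] for g in r.gpr.genes() if g in gene_scores.index]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            out[r.id] = float(np.mean(vals))
    return out


def benchmark_methods(
    net: MetabolicNetwork,
    media: MediaSpec,
    intensities: pd.DataFrame,
    metabolomics: pd.DataFrame,
    methods: Sequence[str] = ("metchange", "eflux", "reporter", "expr_abs", "expr_dir"),
    reporter_permutations: int = 2000,
    seed: int = 0,
) -> bl.BenchmarkReport:
    """Run each method on a genes x conditions intensity table (columns
    ordered in time, first column the reference) and correlate with
    metabolites x conditions log2 concentration changes.

    MetChange and E-Flux report log2 scores against the first condition;
    the reporter and expression baselines score each condition from the
    per-gene change statistics.
    """
    constrained, _ = apply_media(net, media)
    irrev = make_irreversible(constrained)
    conditions = list(intensities.columns)
    mets = net.metabolite_ids
    scores: dict[str, pd.DataFrame] = {}

    if "metchange" in methods:
        producible = find_producible(net, mets)
        model = MetChangeModel(irrev, [m for m in mets if m in producible])
        rows = []
        for cond in conditions:
            profile = derive_pvals_from_intensities(intensities[cond], sample=cond)
            rows.append(model.score_sample(map_gene_pvals(model.net, profile)))
        x = pd.DataFrame(rows)
        # orient as a concentration-change prediction: rising production
        # inconsistency means falling production capability
        scores["metchange"] = -longitudinal_log2_scores(x).T

    if "eflux" in methods:
        cols = {}
        for cond in conditions:
            cols[cond] = bl.eflux_production(irrev, intensities[cond].to_dict(), mets)
        flux = pd.DataFrame(cols)
        scores["eflux"] = longitudinal_log2_scores(flux.T).T

    gene_z = _gene_change_scores(intensities)
    if "reporter" in methods:
        cols = {}
        for cond in conditions:
            p = sps.norm.sf(gene_z[cond].to_numpy())
            p = np.clip(p, 1e-12, 1 - 1e-12)
            rep = bl.reporter_scores(
                net, dict(zip(gene_z.index, p)), permutations=reporter_permutations, seed=seed
            )
            cols[cond] = rep["corrected_z"]
        scores["reporter"] = pd.DataFrame(cols)

    for tag, fn in (
        ("expr_abs", bl.expression_magnitude_baseline),
        ("expr_dir", bl.expression_directional_baseline),
    ):
        if tag not in methods:
            continue
        cols = {}
        for cond in conditions:
            rscores = _reaction_scores(net, gene_z[cond])
            cols[cond] = fn(net, rscores)
        scores[tag] = pd.DataFrame(cols)

    return bl.benchmark(scores, metabolomics)
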