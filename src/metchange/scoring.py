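"""The MetChange algorithm.

For each metabolite i a demand (sink) reaction is added and two LPs are
solved on the irreversible, media-constrained network:

LP 1 (maximal production)
    max  v_sink,i   s.t.  S v = 0,  alpha <= v <= beta
    giving the maximal production flux v_max,i.

LP 2 (production-consistency score)
    min  c_p . v    s.t.  S v = 0,  alpha <= v <= beta,
                          v_sink,i >= v_max,i (1 - eps)
    where c_p holds the per-reaction detection p-values. The optimum
    x_i >= 0 measures how inconsistent the expression state is with
    producing metabolite i at full capacity: x_i = 0 when some optimal
    production route uses only reactions whose genes are detected.

Raw x_i are not comparable across metabolites (each has a different flux
state at maximal production), so treated samples are compared to batch
controls with a standard score z = (x - mean_ctrl) / sd_ctrl. Higher z
means production-pathway expression is MORE inconsistent (pathway
down-regulated relative to controls).

Aggregation helpers collapse compartments (cytosol wins, else median),
take per-drug medians, re-standardize across drugs, and average across
cell lines; a log2-versus-baseline variant serves longitudinal designs
with no replicate controls.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ReactionPenalty
from .lp import LPError, NetworkLP
from .network import (
    DEFAULT_COMPARTMENT_RE,
    PRODUCIBILITY_TOL,
    MetabolicNetwork,
    add_demand,
    demand_id,
)

__all__ = [
    "ProductionCapability",
    "MetChangeModel",
    "max_production",
    "consistency_score",
    "consistency_scores",
    "standardized_scores",
    "standardize_columns",
    "collapse_compartments",
    "drug_response",
    "consensus_across_cell_lines",
    "longitudinal_log2_scores",
]

logger = logging.getLogger(__name__)

#: relative slack on the LP2 demand bound, guarding against round-off
#: infeasibility when the bound is pinned at the LP1 optimum
DEMAND_EPS = 1e-6

#: control standard deviations below this give undefined (missing) scores
SD_FLOOR = 1e-12


@dataclass
class ProductionCapability:
    """Maximal production fluxes v_max per metabolite; metabolites with
    v_max at or below tolerance are flagged non-producible."""

    vmax: dict[str, float]
    non_producible: set[str] = field(default_factory=set)

    def __getitem__(self, met: str) -> float:
        return self.vmax[met]


class MetChangeModel:
    """Reusable LP state for scoring many samples on one network.

    The network must already be irreversible with media applied; demand
    reactions are inserted here for every requested metabolite (all
    demands coexist, so LP1 and LP2 see identical constraints and
    byproducts can always drain through zero-penalty sinks).
    """

    def __init__(
        self,
        net: MetabolicNetwork,
        metabolites: Sequence[str] | None = None,
        eps: float = DEMAND_EPS,
    ) -> None:
        if not net.is_irreversible:
            raise ValueError("MetChange requires an irreversible network")
        self.metabolites = list(metabolites) if metabolites is not None else net.metabolite_ids
        self.eps = eps
        for m in self.metabolites:
            net = add_demand(net, m)
        self.net = net
        self._lp = NetworkLP(net)
        self._vmax: ProductionCapability | None = None

    # -- LP 1 -----------------------------------------------------------
    def max_production(self, met: str) -> float:
        v = self._lp.solve({demand_id(met): 1.0}, sense="max").objective
        return max(v, 0.0)

    def production_capability(self) -> ProductionCapability:
        if self._vmax is None:
            vmax: dict[str, float] = {}
            flagged: set[str] = set()
            for m in self.metabolites:
                v = self.max_production(m)
                vmax[m] = v
                if v <= PRODUCIBILITY_TOL:
                    flagged.add(m)
            self._vmax = ProductionCapability(vmax, flagged)
        return self._vmax

    # -- LP 2 -----------------------------------------------------------
    def consistency_score(
        self, met: str, penalty: ReactionPenalty, vmax: float | None = None
    ) -> float:
        if vmax is None:
            vmax = self.production_capability()[met]
        if vmax <= PRODUCIBILITY_TOL:
            raise LPError(
                f"metabolite {met!r} is non-producible under the current media"
            )
        did = demand_id(met)
        objective = {
            r: p for r, p in penalty.penalties.items() if p != 0.0 and r in self._lp.rxn_idx
        }
        dem = self.net.reactions[did]
        res = self._lp.solve(
            objective,
            sense="min",
            bound_overrides={did: (vmax * (1 - self.eps), dem.upper_bound)},
        )
        return max(res.objective, 0.0)

    def score_sample(self, penalty: ReactionPenalty) -> pd.Series:
        """Consistency scores x for one sample; NaN for metabolites
        non-producible under the applied media."""
        cap = self.production_capability()
        out = {}
        for m in self.metabolites:
            if m in cap.non_producible:
                out[m] = np.nan
            else:
                out[m] = self.consistency_score(m, penalty, cap[m])
        return pd.Series(out, name=penalty.sample)


def max_production(net: MetabolicNetwork, met: str) -> float:
    """Maximal demand flux for one metabolite (LP 1) on an irreversible
    network with media applied."""
    return MetChangeModel(net, [met]).max_production(met)


def consistency_score(
    net: MetabolicNetwork,
    met: str,
    penalty: ReactionPenalty,
    vmax: float | None = None,
    eps: float = DEMAND_EPS,
) -> float:
    """Minimal expression inconsistency at maximal production (LP 2)."""
    return MetChangeModel(net, [met], eps=eps).consistency_score(met, penalty, vmax)


def consistency_scores(
    net: MetabolicNetwork,
    penalties: Iterable[ReactionPenalty],
    metabolites: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x metabolites matrix of consistency scores x."""
    model = MetChangeModel(net, metabolites)
    rows = [model.score_sample(p) for p in penalties]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standardization and aggregation


def standardized_scores(
    scores: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Standard scores of treated samples against batch controls.

    ``scores``: samples x metabolites consistency scores.
    ``meta``: indexed by sample id, columns ``batch`` and ``is_control``.
    z = (x_treated - mean(batch controls)) / sd(batch controls); a batch
    with fewer than two controls falls back to the mean and sd of ALL
    control samples. Control sd below ``SD_FLOOR`` yields missing values.
    """
    meta = meta.loc[scores.index].copy()
    meta["is_control"] = meta["is_control"].astype(bool)
    ctrl = scores.loc[meta["is_control"]]
    if ctrl.empty:
        raise ValueError("no control samples")
    g_mean = ctrl.mean(axis=0)
    g_sd = ctrl.std(axis=0, ddof=1)
    out = {}
    for batch, idx in meta.groupby("batch").groups.items():
        sub = meta.loc[idx]
        treated = sub.index[~sub["is_control"]]
        if len(treated) == 0:
            continue
        bctrl = scores.loc[sub.index[sub["is_control"]]]
        if len(bctrl) >= 2:
            mean, sd = bctrl.mean(axis=0), bctrl.std(axis=0, ddof=1)
        else:
            if len(bctrl) == 0:
                warnings.warn(
                    f"batch {batch!r} has no control; using the global control pool",
                    stacklevel=2,
                )
            mean, sd = g_mean, g_sd
        sd = sd.where(sd > SD_FLOOR)
        for s in treated:
            out[s] = (scores.loc[s] - mean) / sd
    z = pd.DataFrame(out).T
    return z.loc[[s for s in scores.index if s in z.index]]


def standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standard score (sample sd, n-1); columns with sd at or
    below the floor become missing."""
    sd = df.std(axis=0, ddof=1)
    sd = sd.where(sd > SD_FLOOR)
    return (df - df.mean(axis=0)) / sd


def split_compartment(
    met_id: str, pattern: re.Pattern = DEFAULT_COMPARTMENT_RE
) -> tuple[str, str]:
    """Return (base id, compartment tag) for a metabolite id."""
    m = pattern.search(met_id)
    if m is None:
        return met_id, ""
    tag = next(g for g in m.groups() if g is not None)
    return met_id[: m.start()], tag


def collapse_compartments(
    scores: pd.DataFrame,
    cytosol: str = "c",
    pattern: re.Pattern = DEFAULT_COMPARTMENT_RE,
) -> pd.DataFrame:
    """Collapse compartmentalized species columns to one per metabolite:
    the cytosolic score when available, otherwise the median across
    compartments."""
    groups: dict[str, dict[str, str]] = {}
    for col in scores.columns:
        base, tag = split_compartment(col, pattern)
        groups.setdefault(base, {})[tag] = col
    out = {}
    for base, by_tag in groups.items():
        if cytosol in by_tag:
            out[base] = scores[by_tag[cytosol]]
        else:
            out[base] = scores[list(by_tag.values())].median(axis=1)
    return pd.DataFrame(out)


def drug_response(z: pd.DataFrame, drugs: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Per-drug median score per metabolite across samples, then each
    metabolite column standardized across drugs."""
    drugs = pd.Series(dict(drugs)) if not isinstance(drugs, pd.Series) else drugs
    med = z.groupby(drugs.loc[z.index]).median()
    return standardize_columns(med)


def consensus_across_cell_lines(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Entrywise mean of per-cell-line drug x metabolite matrices (inner
    join on both axes), re-standardized across drugs."""
    if not matrices:
        raise ValueError("no matrices given")
    rows = matrices[0].index
    cols = matrices[0].columns
    for m in matrices[1:]:
        rows = rows.intersection(m.index)
        cols = cols.intersection(m.columns)
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("cell-line matrices share no drug x metabolite entries")
    stack = np.stack([m.loc[rows, cols].to_numpy(dtype=float) for m in matrices])
    mean = pd.DataFrame(np.nanmean(stack, axis=0), index=rows, columns=cols)
    return standardize_columns(mean)


def longitudinal_log2_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """log2 of each time point's consistency score against the first row.

    For longitudinal designs without replicate controls. Zero scores are
    stabilized with a pseudocount of half the smallest positive score in
    the table (flagged via a warning).
    """
    if scores.shape[0] < 2:
        raise ValueError("need at least two time points")
    vals = scores.to_numpy(dtype=float)
    positive = vals[np.isfinite(vals) & (vals > 0)]
    if positive.size == 0:
        raise ValueError("all scores are zero; log ratios undefined")
    pc = positive.min() / 2.0
    if (vals[np.isfinite(vals)] <= 0).any():
        warnings.warn(
            f"zero consistency scores stabilized with pseudocount {pc:g}",
            stacklevel=2,
        )
    stab = np.where(vals > 0, vals, pc)
    ref = stab[0]
    out = np.log2(stab / ref)
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)
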