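"""Mapping gene-level expression evidence onto reactions.

The scoring LP weights each reaction by a detection p-value: the
probability that the gene product is *absent* (low p = present, the
MAS5.0 detection-call convention). Gene p-values are pushed through the
GPR rules — OR (isozymes) takes the minimum, AND (complexes) the
maximum — to give one penalty per reaction. Reactions without a gene
association get penalty 0 (never penalized).

For data sets that report raw intensities instead of detection calls, a
noise model is fit: the bottom 2% of intensities define the noise level,
the sub-threshold values are mirrored across the threshold to form a
symmetric noise distribution, and each intensity is converted to a
one-tailed upper-tail Z-test p-value against that distribution (values
below the threshold are declared absent, p = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network import MetabolicNetwork

__all__ = [
    "GeneProfile",
    "ReactionPenalty",
    "map_gene_pvals",
    "collapse_probes",
    "derive_pvals_from_intensities",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneProfile:
    """Per-gene detection p-values for one sample, plus metadata."""

    sample: str
    pvalues: Mapping[str, float]
    drug: str | None = None
    cell_line: str | None = None
    batch: str | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        bad = [g for g, p in self.pvalues.items() if not (0.0 <= p <= 1.0)]
        if bad:
            raise ValueError(f"p-values outside [0, 1] for genes {bad[:5]}")


@dataclass
class ReactionPenalty:
    """Per-reaction penalties (the LP weighting vector c_p)."""

    sample: str
    penalties: dict[str, float]
    missing_genes: set[str] = field(default_factory=set)

    def __getitem__(self, rxn: str) -> float:
        return self.penalties[rxn]


def collapse_probes(values: Iterable[float]) -> float:
    """Combine multiple probe p-values for one gene/reaction: minimum
    (the strongest evidence of presence wins)."""
    vals = list(values)
    if not vals:
        raise ValueError("cannot collapse an empty probe group")
    return min(vals)


def map_gene_pvals(
    net: MetabolicNetwork,
    profile: GeneProfile,
    missing: str = "zero",
) -> ReactionPenalty:
    """Map gene detection p-values onto reactions via GPR rules.

    OR -> min, AND -> max; reactions without a GPR get penalty 0. Genes
    present in a GPR but absent from the profile are treated as p = 0
    (non-penalizing) and recorded, or raise when ``missing='error'``.
    Split halves of a reversible reaction share the parent's GPR and so
    inherit the same penalty.
    """
    if missing not in ("zero", "error"):
        raise ValueError("missing must be 'zero' or 'error'")
    missing_genes: set[str] = set()

    def leaf(gene: str) -> float:
        try:
            return float(profile.pvalues[gene])
        except KeyError:
            if missing == "error":
                raise KeyError(f"gene {gene!r} absent from profile {profile.sample!r}")
            missing_genes.add(gene)
            return 0.0

    penalties: dict[str, float] = {}
    for r in net.reactions.values():
        penalties[r.id] = 0.0 if r.gpr is None else float(r.gpr.evaluate(leaf))
    if missing_genes:
        logger.info(
            "%d GPR genes missing from profile %s; treated as present (p=0)",
            len(missing_genes),
            profile.sample,
        )
    return ReactionPenalty(profile.sample, penalties, missing_genes)


def derive_pvals_from_intensities(
    intensities: Mapping[str, float] | pd.Series,
    noise_percentile: float = 2.0,
    p_floor: float = 1e-6,
    sample: str = "sample",
    **metadata,
) -> GeneProfile:
    """Convert raw nonnegative intensities to detection p-values.

    The value at ``noise_percentile`` of the intensity distribution is
    the noise threshold t. Intensities below t are called absent
    (p = 1). The sub-threshold values are mirrored across t
    ({x} ∪ {2t - x}) to build a symmetric noise distribution whose mean
    and sd parameterize a normal noise model; every intensity at or
    above t gets the one-tailed upper-tail p-value under that model, so
    p is monotone non-increasing in intensity.

    ``p_floor`` keeps highly expressed genes at a small positive penalty
    instead of an underflowed exact 0: consistency scores are sums of
    penalty x flux, and exact zeros make between-condition ratios
    degenerate while differences below solver tolerance carry no
    information anyway.
    """
    s = pd.Series(dict(intensities), dtype=float) if not isinstance(
        intensities, pd.Series
    ) else intensities.astype(float)
    if len(s) < 50:
        raise ValueError("need at least 50 genes for a stable noise percentile")
    if s.min() < 0:
        raise ValueError("intensities must be nonnegative")
    values = s.to_numpy()
    if np.allclose(values, values[0]):
        raise ValueError("all intensities identical; noise model degenerate")
    threshold = float(np.percentile(values, noise_percentile))
    below = values[values < threshold]
    if below.size == 0:
        # percentile fell on the minimum; use the minimum itself as noise
        below = values[values <= threshold][:1]
    mirrored = np.concatenate([below, 2 * threshold - below])
    mu = float(mirrored.mean())
    sd = float(mirrored.std(ddof=0))
    if sd <= 0:
        raise ValueError("noise distribution has zero spread")
    p = np.maximum(stats.norm.sf(values, loc=mu, scale=sd), p_floor)
    p = np.where(values < threshold, 1.0, p)
    return GeneProfile(sample=sample, pvalues=dict(zip(s.index, p)), **metadata)
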