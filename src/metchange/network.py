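"""Metabolic network container and structural transforms.

The network is a stoichiometric model: metabolites, reactions with
flux bounds and GPR rules, from which the stoichiometric matrix S is
derived. Transforms here cover irreversibilization (every reaction
forward-only), demand-reaction insertion (metabolite -> Ø sinks used to
probe production capability), growth-media exchange constraints, and a
producibility screen that removes metabolites the network can never
make even with all exchanges open.

Sign convention: an exchange reaction is written ``A_e <->`` (stoich
{A_e: -1}); negative flux is uptake, positive flux secretion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GprRule

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "MediaSpec",
    "NetworkError",
    "LARGE_BOUND",
    "PRODUCIBILITY_TOL",
    "make_irreversible",
    "add_demand",
    "apply_media",
    "find_producible",
]

#: "Large" bound used for unconstrained reactions and demand sinks.
LARGE_BOUND = 1000.0

#: Demand flux above this counts as producible.
PRODUCIBILITY_TOL = 1e-9

#: Compartment parsed from an id suffix ``[c]`` or ``_c``.
DEFAULT_COMPARTMENT_RE = re.compile(r"\[([A-Za-z0-9]+)\]$|_([A-Za-z0-9])$")

INTERNAL = "internal"
EXCHANGE = "exchange"
DEMAND = "demand"


class NetworkError(ValueError):
    """Structural problem in a metabolic network definition."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GprRule | None = None
    kind: str = INTERNAL
    #: original reaction id when this reaction is a half of a split
    #: reversible reaction (or a flipped backward-only reaction)
    parent: str | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass(frozen=True)
class MediaSpec:
    """Metabolites available for uptake, and the uptake magnitude."""

    metabolites: frozenset[str]
    uptake: float = 1.0

    def __post_init__(self) -> None:
        if self.uptake <= 0:
            raise ValueError("uptake magnitude must be positive")

    @classmethod
    def of(cls, ids: Iterable[str], uptake: float = 1.0) -> "MediaSpec":
        return cls(frozenset(ids), uptake)


class MetabolicNetwork:
    """An ordered collection of metabolites and reactions.

    Immutable-style: transforms return new networks. The stoichiometric
    matrix S (metabolites x reactions) is built on demand.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        compartment_re: re.Pattern | None = None,
    ) -> None:
        self.compartment_re = compartment_re or DEFAULT_COMPARTMENT_RE
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if not m.compartment:
                m = replace(m, compartment=self._parse_compartment(m.id))
            self.metabolites[m.id] = m
        self.reactions: dict[str, Reaction] = {}
        for r in reactions:
            self.reactions[r.id] = r
        self.validate()

    # -- construction helpers ------------------------------------------
    def _parse_compartment(self, met_id: str) -> str:
        m = self.compartment_re.search(met_id)
        if m is None:
            return ""
        return next(g for g in m.groups() if g is not None)

    def validate(self) -> None:
        for r in self.reactions.values():
            if not r.stoichiometry:
                raise NetworkError(f"reaction {r.id!r} has empty stoichiometry")
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    raise NetworkError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise NetworkError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            if r.kind == DEMAND:
                if list(r.stoichiometry.values()) != [-1]:
                    raise NetworkError(
                        f"demand reaction {r.id!r} must consume exactly one "
                        "metabolite with coefficient -1"
                    )

    # -- views ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def is_irreversible(self) -> bool:
        return all(r.lower_bound >= 0 for r in self.reactions.values())

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == EXCHANGE]

    def demands(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == DEMAND]

    def connectivity(self, met_id: str) -> int:
        """Number of distinct reactions the metabolite takes part in.

        Split halves of one reversible reaction count once (via parent).
        """
        seen: set[str] = set()
        for r in self.reactions.values():
            if met_id in r.stoichiometry:
                seen.add(r.parent or r.id)
        return len(seen)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, dict[str, int], dict[str, int]]:
        """Return (S, metabolite index, reaction index)."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        rxn_idx = {r: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for r in self.reactions.values():
            j = rxn_idx[r.id]
            for met, coef in r.stoichiometry.items():
                rows.append(met_idx[met])
                cols.append(j)
                vals.append(float(coef))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_idx), len(rxn_idx))
        )
        return S, met_idx, rxn_idx

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()])
        ub = np.array([r.upper_bound for r in self.reactions.values()])
        return lb, ub

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.metabolites.values(), self.reactions.values(), self.compartment_re
        )

    def with_reactions(self, reactions: Iterable[Reaction]) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.metabolites.values(), reactions, self.compartment_re
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# transforms


def make_irreversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Split reversible reactions into forward-only pairs.

    A reaction with lb < 0 < ub becomes ``<id>_f`` ([0, ub]) and
    ``<id>_b`` ([0, -lb], negated stoichiometry); a backward-only
    reaction (ub <= 0) is flipped in place keeping its id. Both carry
    ``parent`` so penalties map onto both halves. The feasible net-flux
    polytope is preserved.
    """
    out: list[Reaction] = []
    for r in net.reactions.values():
        if r.lower_bound >= 0:
            out.append(r)
        elif r.upper_bound <= 0:
            out.append(
                replace(
                    r,
                    stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                    lower_bound=-r.upper_bound,
                    upper_bound=-r.lower_bound,
                    parent=r.parent or r.id,
                )
            )
        else:
            out.append(
                replace(
                    r,
                    id=f"{r.id}_f",
                    lower_bound=0.0,
                    parent=r.parent or r.id,
                )
            )
            out.append(
                replace(
                    r,
                    id=f"{r.id}_b",
                    stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                    lower_bound=0.0,
                    upper_bound=-r.lower_bound,
                    parent=r.parent or r.id,
                )
            )
    return net.with_reactions(out)


def demand_id(met_id: str) -> str:
    return f"DM_{met_id}"


def add_demand(net: MetabolicNetwork, met_id: str) -> MetabolicNetwork:
    """Insert an irreversible sink ``DM_<met>``: metabolite -> Ø.

    Idempotent: if the demand already exists the network is returned
    unchanged.
    """
    if met_id not in net.metabolites:
        raise NetworkError(f"unknown metabolite {met_id!r}")
    did = demand_id(met_id)
    if did in net.reactions:
        return net
    dem = Reaction(
        id=did,
        stoichiometry={met_id: -1.0},
        lower_bound=0.0,
        upper_bound=LARGE_BOUND,
        kind=DEMAND,
    )
    return net.with_reactions(list(net.reactions.values()) + [dem])


def _exchange_uptake_bounds(
    rxn: Reaction, open_: bool, magnitude: float
) -> Reaction:
    """Return the exchange reaction with its uptake direction set.

    Uptake is the direction that *adds* the metabolite to the system:
    with coefficient s on the exchanged metabolite, mass enters when
    s * flux > 0. Secretion is left open at LARGE_BOUND.
    """
    (met, coef), = rxn.stoichiometry.items()
    if coef < 0:
        # uptake is negative flux: lower bound controls it. A forward-only
        # exchange (e.g. the secretion half of a split pair) cannot take up
        # and is left alone.
        if rxn.lower_bound >= 0 and rxn.parent is not None:
            return rxn
        lb = -magnitude if open_ else 0.0
        ub = rxn.upper_bound if rxn.upper_bound > 0 else LARGE_BOUND
        return replace(rxn, lower_bound=lb, upper_bound=ub)
    # uptake is positive flux: upper bound controls it
    if rxn.upper_bound <= 0 and rxn.parent is not None:
        return rxn
    ub = magnitude if open_ else 0.0
    return replace(rxn, upper_bound=ub)


def apply_media(
    net: MetabolicNetwork, media: MediaSpec
) -> tuple[MetabolicNetwork, list[str]]:
    """Constrain exchange reactions to a growth medium.

    Uptake of media metabolites is bounded at the uptake magnitude
    (lb = -1 in the reversible convention); uptake of everything else is
    closed; secretion stays open. Returns the constrained network and a
    skip list of media ids with no exchange reaction.

    Works on reversible networks and on irreversible (split) ones, where
    the uptake half of each exchange carries a positive coefficient.
    """
    exchanged: set[str] = set()
    out: list[Reaction] = []
    for r in net.reactions.values():
        if r.kind != EXCHANGE:
            out.append(r)
            continue
        (met,) = r.stoichiometry.keys()
        exchanged.add(met)
        out.append(_exchange_uptake_bounds(r, met in media.metabolites, media.uptake))
    skipped = sorted(media.metabolites - exchanged)
    if skipped:
        warnings.warn(
            f"media metabolites without exchange reactions skipped: {skipped}",
            stacklevel=2,
        )
    return net.with_reactions(out), skipped


def open_all_exchanges(
    net: MetabolicNetwork, magnitude: float = LARGE_BOUND
) -> MetabolicNetwork:
    """Open uptake and secretion of every exchange reaction."""
    out = []
    for r in net.reactions.values():
        if r.kind == EXCHANGE:
            r = _exchange_uptake_bounds(r, True, magnitude)
        out.append(r)
    return net.with_reactions(out)


def find_producible(
    net: MetabolicNetwork,
    metabolites: Iterable[str] | None = None,
    tol: float = PRODUCIBILITY_TOL,
) -> set[str]:
    """Metabolites whose maximal demand flux, with every exchange fully
    open, exceeds ``tol``. The complement is removed from scoring.
    """
    from .lp import maximize_flux  # local import to avoid a cycle

    mets = list(metabolites) if metabolites is not None else net.metabolite_ids
    opened = open_all_exchanges(net)
    for m in mets:
        opened = add_demand(opened, m)
    producible: set[str] = set()
    for m in mets:
        v = maximize_flux(opened, demand_id(m))
        if v > tol:
            producible.add(m)
    return producible
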