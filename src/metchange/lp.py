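"""Thin LP layer over scipy's HiGHS solver.

All flux-balance problems here share the same shape: optimize a linear
objective over fluxes v subject to steady-state mass balance S v = 0 and
box bounds alpha <= v <= beta. ``NetworkLP`` builds the constraint
structure once per network so repeated solves (one or two LPs per
metabolite per sample) only swap the objective and bound overrides.

Only the optimal objective *value* is part of any contract: flux vectors
may be degenerate (alternate optima), objective values are unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = ["NetworkLP", "LPResult", "LPError", "maximize_flux"]


class LPError(RuntimeError):
    """LP solver failure (infeasible/unbounded/numerical)."""


@dataclass(frozen=True)
class LPResult:
    objective: float
    fluxes: np.ndarray
    status: int


class NetworkLP:
    """Reusable LP structure for one network."""

    def __init__(self, net: MetabolicNetwork) -> None:
        self.net = net
        self.S, self.met_idx, self.rxn_idx = net.stoichiometric_matrix()
        self.lb, self.ub = net.bounds()
        self._n = len(self.rxn_idx)

    def _vector(self, coefs: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(self._n)
        for rxn, w in coefs.items():
            try:
                c[self.rxn_idx[rxn]] = w
            except KeyError:
                raise LPError(f"unknown reaction in objective: {rxn!r}") from None
        return c

    def solve(
        self,
        objective: Mapping[str, float],
        sense: str = "max",
        bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    ) -> LPResult:
        """Optimize ``sum objective[r] * v_r`` subject to S v = 0, bounds.

        ``bound_overrides`` maps reaction id -> (lb, ub) replacing the
        network bounds for that reaction in this solve only.
        """
        c = self._vector(objective)
        if sense == "max":
            c = -c
        elif sense != "min":
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        lb = self.lb
        ub = self.ub
        if bound_overrides:
            lb = lb.copy()
            ub = ub.copy()
            for rxn, (lo, hi) in bound_overrides.items():
                j = self.rxn_idx.get(rxn)
                if j is None:
                    raise LPError(f"unknown reaction in bounds: {rxn!r}")
                lb[j], ub[j] = lo, hi
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status != 0:
            raise LPError(
                f"LP failed (status {res.status}: {res.message}) for objective "
                f"over {list(objective)[:3]}..."
            )
        value = -res.fun if sense == "max" else res.fun
        # clamp tiny negative round-off on intrinsically nonnegative optima
        return LPResult(float(value), res.x, res.status)


def maximize_flux(net: MetabolicNetwork, reaction_id: str) -> float:
    """Maximal steady-state flux through one reaction (FBA objective)."""
    return NetworkLP(net).solve({reaction_id: 1.0}, sense="max").objective
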