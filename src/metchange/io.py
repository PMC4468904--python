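"""File formats.

* Reaction table: one reaction per line,
  ``id <TAB> equation <TAB> lb <TAB> ub <TAB> gpr`` with equations like
  ``2 A_c + B_c -> C_c`` (``<=>`` for reversible; one side may be empty
  for boundary reactions).
* SBML (read/write) through cobrapy.
* Media: JSON list of metabolite ids, or ``{"metabolites": [...],
  "uptake": 1.0}``.
* Expression tables: TSV, first column gene id, one column per sample;
  companion metadata TSV with columns
  ``sample, drug, cell_line, batch, is_control``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import TextIO

import pandas as pd

from .gpr import parse_gpr
from .network import (
    DEMAND,
    EXCHANGE,
    INTERNAL,
    MediaSpec,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
)

__all__ = [
    "load_network",
    "read_reaction_table",
    "write_reaction_table",
    "read_sbml",
    "write_sbml",
    "to_cobra",
    "read_media",
    "write_media",
    "read_expression",
    "read_metadata",
]

_ARROWS = ("<=>", "<->", "-->", "->")
_COEF_RE = re.compile(r"^(\d+(?:\.\d+)?)\s+(\S.*)$")


def _parse_side(side: str, rxn_id: str, sign: float, stoich: dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise NetworkError(f"reaction {rxn_id!r}: malformed equation term")
        m = _COEF_RE.match(term)
        if m:
            coef, met = float(m.group(1)), m.group(2).strip()
        else:
            coef, met = 1.0, term
        if coef <= 0:
            raise NetworkError(f"reaction {rxn_id!r}: non-positive coefficient")
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def parse_equation(equation: str, rxn_id: str) -> tuple[dict[str, float], bool]:
    """Return (stoichiometry, reversible)."""
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            reversible = arrow in ("<=>", "<->")
            break
    else:
        raise NetworkError(f"reaction {rxn_id!r}: no arrow in equation {equation!r}")
    stoich: dict[str, float] = {}
    _parse_side(left, rxn_id, -1.0, stoich)
    _parse_side(right, rxn_id, +1.0, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise NetworkError(f"reaction {rxn_id!r}: empty stoichiometry")
    return stoich, reversible


def _classify(rxn_id: str, stoich: dict[str, float]) -> str:
    if len(stoich) == 1:
        if rxn_id.startswith("DM_") and next(iter(stoich.values())) == -1:
            return DEMAND
        return EXCHANGE
    return INTERNAL


def read_reaction_table(source: str | Path | TextIO) -> MetabolicNetwork:
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    reactions: list[Reaction] = []
    mets: dict[str, Metabolite] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 4:
            raise NetworkError(f"line {lineno}: expected at least 4 tab-separated fields")
        rxn_id = parts[0].strip()
        stoich, reversible = parse_equation(parts[1], rxn_id)
        try:
            lb, ub = float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise NetworkError(f"reaction {rxn_id!r}: bad bounds") from exc
        gpr_text = parts[4].strip() if len(parts) > 4 else ""
        gpr = parse_gpr(gpr_text)
        if not reversible and lb < 0:
            lb = max(lb, 0.0)
        for m in stoich:
            mets.setdefault(m, Metabolite(m))
        reactions.append(
            Reaction(rxn_id, stoich, lb, ub, gpr, kind=_classify(rxn_id, stoich))
        )
    if not reactions:
        raise NetworkError("no reactions in table")
    return MetabolicNetwork(mets.values(), reactions)


def write_reaction_table(net: MetabolicNetwork, path: str | Path) -> None:
    lines = []
    for r in net.reactions.values():
        subs = " + ".join(
            (f"{-c:g} {m}" if c != -1 else m)
            for m, c in r.stoichiometry.items()
            if c < 0
        )
        prods = " + ".join(
            (f"{c:g} {m}" if c != 1 else m)
            for m, c in r.stoichiometry.items()
            if c > 0
        )
        arrow = "<=>" if r.reversible else "->"
        gpr = r.gpr.to_string() if r.gpr is not None else ""
        lines.append(
            f"{r.id}\t{subs} {arrow} {prods}\t{r.lower_bound:g}\t{r.upper_bound:g}\t{gpr}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML via cobrapy


def to_cobra(net: MetabolicNetwork, name: str = "model"):
    """Convert to a cobrapy Model (used for SBML export and as a bridge
    to independent solvers in tests)."""
    import cobra

    model = cobra.Model(name)
    cmets = {}
    for m in net.metabolites.values():
        cm = cobra.Metabolite(m.id, compartment=m.compartment or "c")
        cmets[m.id] = cm
    model.add_metabolites(list(cmets.values()))
    rxns = []
    for r in net.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in net.reactions.values():
        cr = model.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    return model


def from_cobra(model) -> MetabolicNetwork:
    mets = [Metabolite(m.id, m.compartment or "") for m in model.metabolites]
    reactions = []
    boundary_ids = {r.id for r in model.boundary}
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        kind = _classify(r.id, stoich)
        if r.id in boundary_ids and kind == INTERNAL:
            kind = EXCHANGE
        gpr = parse_gpr(r.gene_reaction_rule or "")
        reactions.append(
            Reaction(r.id, stoich, float(r.lower_bound), float(r.upper_bound), gpr, kind)
        )
    return MetabolicNetwork(mets, reactions)


def read_sbml(path: str | Path) -> MetabolicNetwork:
    import cobra.io

    return from_cobra(cobra.io.read_sbml_model(str(path)))


def write_sbml(net: MetabolicNetwork, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(net), str(path))


def load_network(path: str | Path) -> MetabolicNetwork:
    """Load SBML (``.xml``/``.sbml``) or the reaction-table dialect."""
    p = Path(path)
    if p.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(p)
    return read_reaction_table(p)


# ---------------------------------------------------------------------------
# media / expression tables


def read_media(path: str | Path) -> MediaSpec:
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        return MediaSpec.of(data)
    return MediaSpec.of(data["metabolites"], float(data.get("uptake", 1.0)))


def write_media(media: MediaSpec, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"metabolites": sorted(media.metabolites), "uptake": media.uptake},
            indent=1,
        )
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples table; first column gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "is_control" in meta.columns:
        meta["is_control"] = meta["is_control"].astype(bool)
    return meta
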