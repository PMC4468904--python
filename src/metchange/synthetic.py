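"""Deterministic synthetic fixtures with planted ground truth.

Three generators emulate the inputs of the full workflow so every stage
is testable without external data:

* ``make_toy_network`` — a compartmentalized toy metabolic network of
  linear/branched production pathways fed from media precursors, with
  GPR rules over a generated gene set (including an isozyme OR, a
  complex AND, a reversible reaction and a gene-free reaction).
* ``make_expression_profiles`` — control samples with detection
  p-values drawn from Beta(0.5, 5) (most genes look present, the
  detection-call convention) organized into batches (one single-control
  batch to exercise the global-pool fallback), plus treated samples in
  which the genes of chosen pathways have their p-values shifted by a
  planted magnitude.
* ``make_side_effect_dataset`` — a samples x metabolites score matrix
  of standard-normal noise in which positive samples carry a planted
  ternary signature times an effect size, together with a SIDER-style
  min/max frequency study table on a three-decade grid.

``make_end_to_end_dataset`` wires the first two into a complete
expression -> penalty -> scoring -> signature-selection exercise.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GeneProfile
from .network import (
    EXCHANGE,
    INTERNAL,
    LARGE_BOUND,
    MediaSpec,
    MetabolicNetwork,
    Metabolite,
    Reaction,
)
from .gpr import parse_gpr

__all__ = [
    "FixtureSpec",
    "Perturbation",
    "ToyNetwork",
    "ExpressionFixture",
    "SideEffectDataset",
    "EndToEndDataset",
    "make_toy_network",
    "make_expression_profiles",
    "make_side_effect_dataset",
    "make_end_to_end_dataset",
]


@dataclass(frozen=True)
class Perturbation:
    """A planted expression shift: add ``magnitude`` (signed) to the
    detection p-values of genes in the pathway, each gene hit
    independently with probability ``gene_prob`` (1.0 = whole pathway)."""

    pathway: int
    magnitude: float
    gene_prob: float = 1.0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    # network shape
    n_pathways: int = 4
    pathway_length: int = 3
    branch_probability: float = 0.25
    # expression profiles
    n_control_batches: int = 3
    controls_per_batch: int = 2
    treated_per_drug: int = 1
    # side-effect score matrix
    n_samples: int = 200
    n_metabolites: int = 50
    signature: Mapping[str, int] = field(
        default_factory=lambda: {"m00": 1, "m01": 1, "m02": -1}
    )
    effect_size: float = 2.0
    noise_sd: float = 1.0
    positive_fraction: float = 0.5
    frequency_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    side_effect: str = "se1"
    # end-to-end wiring
    n_positive_drugs: int = 20
    n_negative_drugs: int = 20
    signature_pathways: tuple[int, ...] = (0, 1, 2)
    perturbation_magnitude: float = 0.5
    # identifiability of the end-to-end planting: each positive drug hits
    # a random subset of the signature pathways, and within a perturbed
    # pathway each gene is shifted with this probability, so no single
    # intermediate metabolite separates the classes on its own
    pathway_hit_probability: float = 0.7
    gene_hit_probability: float = 0.6

    def __post_init__(self) -> None:
        if sum(1 for v in self.signature.values() if v != 0) > 20:
            raise ValueError("planted signature support exceeds the cap of 20")


# ---------------------------------------------------------------------------
# toy network


@dataclass
class ToyNetwork:
    net: MetabolicNetwork
    media: MediaSpec
    pathway_genes: dict[int, list[str]]
    pathway_metabolites: dict[int, list[str]]
    terminal_metabolites: dict[int, str]


def make_toy_network(spec: FixtureSpec) -> ToyNetwork:
    """Connected production pathways from media precursors.

    Pathway j: ``P{j}_e`` (exchange, in media) -> transport ->
    ``P{j}M0_c`` -> ... -> ``P{j}M{L}_c``. Pathway 0 carries an isozyme
    (OR) on its first chain step, a complex (AND) on its transport, and
    a reversible second step; pathway 1's transport has no GPR.
    """
    if spec.n_pathways < 1 or spec.pathway_length < 1:
        raise ValueError("need at least one pathway of length one")
    rng = np.random.default_rng(spec.seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    pathway_genes: dict[int, list[str]] = {}
    pathway_metabolites: dict[int, list[str]] = {}
    terminal: dict[int, str] = {}
    gene_counter = 0

    def new_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:03d}"

    for j in range(spec.n_pathways):
        genes: list[str] = []
        pmets: list[str] = []
        pre = f"P{j}_e"
        mets.append(Metabolite(pre))
        rxns.append(
            Reaction(f"EX_P{j}", {pre: -1.0}, -LARGE_BOUND, LARGE_BOUND, kind=EXCHANGE)
        )
        prev = f"P{j}M0_c"
        mets.append(Metabolite(prev))
        pmets.append(prev)
        if j == 0:
            ga, gb = new_gene(), new_gene()
            gpr = parse_gpr(f"{ga} and {gb}")  # complex on the transport
            genes += [ga, gb]
        elif j == 1:
            gpr = None  # gene-free reaction
        else:
            g = new_gene()
            gpr = parse_gpr(g)
            genes.append(g)
        rxns.append(
            Reaction(f"T_P{j}", {pre: -1.0, prev: 1.0}, 0.0, LARGE_BOUND, gpr, INTERNAL)
        )
        for k in range(1, spec.pathway_length + 1):
            cur = f"P{j}M{k}_c"
            mets.append(Metabolite(cur))
            pmets.append(cur)
            if j == 0 and k == 1:
                ga, gb = new_gene(), new_gene()
                gpr = parse_gpr(f"{ga} or {gb}")  # isozymes
                genes += [ga, gb]
            else:
                g = new_gene()
                gpr = parse_gpr(g)
                genes.append(g)
            lb = -LARGE_BOUND if (j == 0 and k == 2) else 0.0  # one reversible step
            rxns.append(
                Reaction(f"R{j}_{k}", {prev: -1.0, cur: 1.0}, lb, LARGE_BOUND, gpr, INTERNAL)
            )
            if k < spec.pathway_length and rng.random() < spec.branch_probability:
                bmet = f"P{j}B{k}_c"
                mets.append(Metabolite(bmet))
                pmets.append(bmet)
                g = new_gene()
                genes.append(g)
                rxns.append(
                    Reaction(
                        f"B{j}_{k}",
                        {cur: -1.0, bmet: 1.0},
                        0.0,
                        LARGE_BOUND,
                        parse_gpr(g),
                        INTERNAL,
                    )
                )
            prev = cur
        terminal[j] = prev
        pathway_genes[j] = genes
        pathway_metabolites[j] = pmets

    net = MetabolicNetwork(mets, rxns)
    media = MediaSpec.of([f"P{j}_e" for j in range(spec.n_pathways)], uptake=1.0)
    return ToyNetwork(net, media, pathway_genes, pathway_metabolites, terminal)


# ---------------------------------------------------------------------------
# expression profiles


@dataclass
class ExpressionFixture:
    profiles: list[GeneProfile]
    metadata: pd.DataFrame  # indexed by sample: drug, cell_line, batch, is_control
    expression: pd.DataFrame  # genes x samples p-value table

    def controls(self) -> list[GeneProfile]:
        return [p for p in self.profiles if p.is_control]


#: baseline detection p-value distribution: most genes present (low p)
_BASELINE_ALPHA, _BASELINE_BETA = 0.5, 5.0


def _baseline_pvals(genes: Sequence[str], rng: np.random.Generator) -> dict[str, float]:
    return dict(zip(genes, rng.beta(_BASELINE_ALPHA, _BASELINE_BETA, size=len(genes))))


def make_expression_profiles(
    toy: ToyNetwork,
    spec: FixtureSpec,
    drug_perturbations: Mapping[str, Sequence[Perturbation]] | None = None,
) -> ExpressionFixture:
    """Control batches plus one treated profile set per drug.

    ``drug_perturbations`` maps drug name -> planted perturbations; by
    default one drug per spec'd signature pathway at the spec magnitude.
    The last control batch holds a single control so the global-pool
    standardization fallback is exercised.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(toy.net.genes())
    if drug_perturbations is None:
        drug_perturbations = {
            f"drug{p}": [Perturbation(p, spec.perturbation_magnitude)]
            for p in spec.signature_pathways
            if p in toy.pathway_genes
        }
    profiles: list[GeneProfile] = []
    meta_rows = []
    batches = [f"batch{i}" for i in range(spec.n_control_batches)]
    for i, batch in enumerate(batches):
        n_ctrl = 1 if i == len(batches) - 1 else spec.controls_per_batch
        for c in range(n_ctrl):
            sid = f"ctrl_{batch}_{c}"
            profiles.append(
                GeneProfile(sid, _baseline_pvals(genes, rng), drug="control",
                            batch=batch, is_control=True)
            )
            meta_rows.append((sid, "control", "toy", batch, True))
    for d, (drug, perts) in enumerate(drug_perturbations.items()):
        for rep in range(spec.treated_per_drug):
            sid = f"{drug}_s{rep}"
            p = _baseline_pvals(genes, rng)
            for pert in perts:
                for g in toy.pathway_genes[pert.pathway]:
                    if pert.gene_prob >= 1.0 or rng.random() < pert.gene_prob:
                        p[g] = float(np.clip(p[g] + pert.magnitude, 0.0, 1.0))
            batch = batches[(d + rep) % len(batches)]
            profiles.append(
                GeneProfile(sid, p, drug=drug, batch=batch, is_control=False)
            )
            meta_rows.append((sid, drug, "toy", batch, False))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "drug", "cell_line", "batch", "is_control"]
    ).set_index("sample")
    expr = pd.DataFrame({p.sample: pd.Series(p.pvalues) for p in profiles})
    expr.index.name = "gene"
    return ExpressionFixture(profiles, meta, expr)


# ---------------------------------------------------------------------------
# side-effect dataset (score level)


@dataclass
class SideEffectDataset:
    scores: pd.DataFrame  # samples x metabolites
    frequency_table: pd.DataFrame  # SIDER-style study records
    frequencies: pd.Series  # per-sample differential frequency
    signature: pd.Series  # planted ternary signature
    side_effect: str
    sample_drug: pd.Series


def _frequency_records(
    drug: str, side_effect: str, f: float, rng: np.random.Generator
) -> list[tuple]:
    recs = [(drug, side_effect, f"{drug}_st0", "treated", f, f)]
    if f > 0 and rng.random() < 0.5:
        recs.append((drug, side_effect, f"{drug}_st1", "placebo", 0.0, 0.0))
    return recs


def make_side_effect_dataset(spec: FixtureSpec) -> SideEffectDataset:
    """Standard-normal score matrix with a planted additive signature on
    positive samples, and the matching frequency study table."""
    rng = np.random.default_rng(spec.seed + 2)
    n, m = spec.n_samples, spec.n_metabolites
    mets = [f"m{i:02d}" for i in range(m)]
    sig = pd.Series(0, index=mets, dtype=int)
    for k, v in spec.signature.items():
        if k not in sig.index:
            raise ValueError(f"signature metabolite {k!r} outside the matrix")
        sig[k] = int(np.sign(v))
    samples = [f"s{i:03d}" for i in range(n)]
    drugs = pd.Series([f"drug{i:03d}" for i in range(n)], index=samples)
    X = rng.normal(0.0, spec.noise_sd, size=(n, m))
    n_pos = int(round(spec.positive_fraction * n))
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    X[pos_idx] += sig.to_numpy() * spec.effect_size
    scores = pd.DataFrame(X, index=samples, columns=mets)

    freqs = pd.Series(0.0, index=samples)
    records: list[tuple] = []
    grid = np.asarray(spec.frequency_grid, dtype=float)
    for i, s in enumerate(samples):
        f = float(rng.choice(grid)) if i in set(pos_idx) else 0.0
        freqs[s] = f
        records.extend(_frequency_records(drugs[s], spec.side_effect, f, rng))
    table = pd.DataFrame(
        records,
        columns=["drug", "side_effect", "study_id", "arm", "freq_min", "freq_max"],
    )
    return SideEffectDataset(scores, table, freqs, sig, spec.side_effect, drugs)


# ---------------------------------------------------------------------------
# end-to-end: expression -> scores -> side-effect signature


@dataclass
class EndToEndDataset:
    toy: ToyNetwork
    expression: ExpressionFixture
    frequency_table: pd.DataFrame
    frequencies: pd.Series  # per treated sample
    signature: pd.Series  # planted signature over metabolite ids
    side_effect: str


def make_end_to_end_dataset(spec: FixtureSpec) -> EndToEndDataset:
    """Full planted exercise: positive drugs shift p-values of the
    signature pathways upward (production down-regulated -> positive z
    expected at the pathway terminals), negative drugs perturb one
    non-signature pathway each; the frequency table marks positive
    drugs with grid frequencies.
    """
    rng = np.random.default_rng(spec.seed + 3)
    toy = make_toy_network(spec)
    sig_paths = [p for p in spec.signature_pathways if p in toy.pathway_genes]
    other = [p for p in toy.pathway_genes if p not in sig_paths]
    perts: dict[str, list[Perturbation]] = {}
    pos_drugs = [f"pos{i:02d}" for i in range(spec.n_positive_drugs)]
    neg_drugs = [f"neg{i:02d}" for i in range(spec.n_negative_drugs)]
    for d in pos_drugs:
        hit = [p for p in sig_paths if rng.random() < spec.pathway_hit_probability]
        if not hit:
            hit = [sig_paths[int(rng.integers(len(sig_paths)))]]
        perts[d] = [
            Perturbation(p, spec.perturbation_magnitude, spec.gene_hit_probability)
            for p in hit
        ]
    for d in neg_drugs:
        if other:
            perts[d] = [
                Perturbation(
                    int(rng.choice(other)),
                    spec.perturbation_magnitude,
                    spec.gene_hit_probability,
                )
            ]
        else:
            perts[d] = []
    expression = make_expression_profiles(toy, spec, perts)

    records: list[tuple] = []
    grid = np.asarray(spec.frequency_grid, dtype=float)
    drug_freq: dict[str, float] = {}
    for d in pos_drugs:
        drug_freq[d] = float(rng.choice(grid))
    for d in neg_drugs:
        drug_freq[d] = 0.0
    for d, f in drug_freq.items():
        records.extend(_frequency_records(d, spec.side_effect, f, rng))
    table = pd.DataFrame(
        records,
        columns=["drug", "side_effect", "study_id", "arm", "freq_min", "freq_max"],
    )
    treated = expression.metadata[~expression.metadata["is_control"]]
    freqs = treated["drug"].map(drug_freq).astype(float)
    signature = pd.Series(
        {toy.terminal_metabolites[p]: 1 for p in sig_paths}, dtype=int
    )
    return EndToEndDataset(toy, expression, table, freqs, signature, spec.side_effect)
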