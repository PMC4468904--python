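# Methods

## The scoring model

The network is a standard constraint-based model: steady-state mass
balance S·v = 0 with flux bounds α ≤ v ≤ β. Before scoring, the model is
made irreversible (a reaction with lb < 0 < ub splits into `_f`/`_b`
forward halves; a backward-only reaction is flipped in place), the
growth medium is applied (uptake of media metabolites bounded at 1 flux
unit, uptake of everything else closed, secretion open at the large
bound 1000), and a demand reaction `DM_<met>`: metabolite → Ø with
bounds [0, 1000] is inserted per metabolite.

All demand reactions coexist during scoring. This makes LP 1 and LP 2
share one constraint set and lets reaction byproducts drain through
zero-penalty sinks; the alternative (one demand at a time) can render
by-producing routes infeasible and is more brittle, not more faithful,
on toy models without spontaneous secretion routes.

Per metabolite *i*:

* **LP 1** maximizes the demand flux → v_max,i. Metabolites with
  v_max ≤ 1e-9 under the medium are reported as missing for that
  condition; metabolites not producible even with every exchange open
  are removed from the analysis entirely (screened on the
  unconstrained network, not under the medium).
* **LP 2** pins the demand at v_max,i·(1 − ε), ε = 1e-6 (guarding
  against round-off infeasibility when the bound sits exactly at the
  LP 1 optimum), and minimizes Σ c_p,j·v_j. The optimal *objective
  value* x_i is the contract; flux vectors may be degenerate. scipy's
  HiGHS solves every LP single-threaded and deterministically.

Penalties c_p are detection p-values (probability the gene product is
absent). GPR folding uses OR → min (one isozyme present suffices) and
AND → max (a complex is as absent as its most-absent subunit); the
combination rule is a convention of the GIMME lineage rather than a
derived quantity. Reactions without a gene association get 0 — they are
never penalized. Genes named in a GPR but missing from a profile default
to p = 0 (logged; a strict mode raises). Multiple probes for one gene or
reaction collapse to the minimum p-value.

Sign convention, stated once and used everywhere: larger x (and larger
standardized z) = production-pathway expression MORE inconsistent with
production = pathway looks down-regulated. When the benchmarking harness
compares methods against measured concentration changes, the
consistency method's directional prediction is the negative of its
log2 score, since rising inconsistency predicts falling production.

## Standardization and aggregation

z = (x_treated − mean of batch controls)/sd of batch controls, with the
sample (n−1) standard deviation. A batch with fewer than two controls
falls back to the mean/sd of all control samples. Control sd below
1e-12 yields a missing value rather than an explosion. Aggregation to a
per-drug response takes the median over a drug's samples (all
concentrations pooled), collapses compartments (cytosolic score when
present, else the median over compartments; compartment parsed from the
id suffix `[c]` or `_c`), and standardizes each metabolite column
across drugs (mean 0, sd 1). Cross-cell-line consensus averages
matrices on the inner join of drugs × metabolites and re-standardizes.
Longitudinal designs without replicate controls use log2(x_t/x_t0)
instead of standard scores; exact zeros are stabilized with a
pseudocount of half the smallest positive score and flagged.

## Intensity-based detection p-values

When only raw intensities are available, the bottom 2nd percentile
defines the noise threshold t; sub-threshold values are declared absent
(p = 1) and mirrored across t to a symmetric noise sample whose mean
(= t) and sd parameterize a normal model; everything at or above t gets
the one-tailed upper-tail p-value. Derived p-values are floored at
1e-6: beyond that the normal tail underflows for highly expressed
genes, and exact-zero penalties make between-condition score ratios
degenerate while encoding differences far below LP tolerance.

## Side-effect signatures

Frequency processing per drug and side effect: mean of (min, max) per
study, median across studies per arm, treated − placebo (treated alone
when no placebo exists), negative differences clamped to 0 (their log
adjustment would otherwise be undefined). Side effects need at least 30
mapped expression sets. Adjusted weights: w = log10(f) − log10(min
positive f) + 1, zeros stay zero.

The pseudo-ROC sweeps thresholds over descending distinct scores; tied
scores advance TPR (weighted) and FPR (counted) in one trapezoid step.
With unit weights it reduces exactly to the classical tie-corrected
AUC.

GA defaults: population 125, cardinality cap 20 (enforced by zeroing
randomly chosen excess loci), sparse random initialization (support
size uniform on 1..cap — dense ternary initialization would start every
individual at the repair boundary), uniform crossover (probability
0.9), per-locus mutation 1/m to a uniform value in {−1,0,+1},
tournament selection of size 3, 5 elites, termination at 300
generations or 50 stall generations. Generation-count termination
replaces wall-clock termination so runs are exactly reproducible for a
seed. Cross-validation uses stratified folds (class ratio preserved),
per-fold seeds derived from the master seed, and a consensus keeping
metabolites with |Σ fold values| ≥ 4, signed by the sum; a count-based
reading (≥ 4 folds with any nonzero value) is available as
`consensus_mode="count"`.

Integration tests run the GA at 60 generations with a 20-generation
stall window; on the fixture sizes used the best AUC plateaus well
inside that budget, and the shorter schedule keeps the suite fast.

## Baselines

* E-Flux: reaction upper bounds scaled to expression/max(expression
  over mapped reactions) — the normalization constant is chosen for
  scale invariance and is configurable — then each demand maximized.
  Expression maps to reactions with AND → min, OR → sum (capacities
  add across isozymes).
* Reporter metabolites: per gene Z = Φ⁻¹(1 − p); per metabolite with k
  measured neighbour genes, raw Z = ΣZ/√k; background mean/sd per
  degree k from random draws of k gene Z-values (10,000 by default,
  seeded); corrected Z = (raw − μ_k)/σ_k. Metabolites without measured
  neighbours are missing, not 0.
* Expression baselines: reaction-mapped standardized gene scores summed
  per metabolite, |stoichiometry|-weighted absolute values (magnitude)
  or signed stoichiometry × score (direction).
* Benchmarking uses Spearman correlations (the methods' score
  distributions differ wildly) of |score| vs |measured log2 change| and
  of signed values, median across conditions; conditions sharing fewer
  than 3 metabolites are missing.

## Validation statistics

Network distance: metabolites sharing a reaction are adjacent;
metabolites in more than 30 distinct reactions (cofactors, protons,
water) are removed as nodes; distances are counted on the pre-split
network so `_f`/`_b` halves don't double-count connectivity. Score
binning uses 0.5-sd bins (configurable; no canonical width exists) and
a two-sided rank-sum test of the top bin's distances against the rest.
Permutation p-values use the (r+1)/(n+1) estimator and are never 0.
Enrichment uses exact hypergeometric/binomial tails with
Benjamini-Hochberg across each test family.

The dual permutation test takes the full investigated outcome table
plus the predicted pair subset; each predicted pair is replaced per
replicate by the average of a random same-row and a random same-column
outcome. Because that average halves the replicate variance relative to
the sampling variance of the observed total, the p-value is
*conservative* — concentrated away from 0 and 1 — rather than exactly
uniform under a random-outcome null (measured: KS statistic ≈ 0.14
against uniform over 500 simulated tables). Significant results are
therefore trustworthy, but the test trades power for simplicity; the
calibration assertion in the acceptance suite documents this gap and is
expected to fail.

## Synthetic fixtures

The generator produces what the pipeline consumes, deterministically
from a seed (same spec → byte-identical outputs):

* Toy networks: linear/branched production pathways from media
  precursors, with at least one isozyme (OR), one complex (AND), one
  reversible step and one gene-free reaction.
* Expression profiles: control p-values ~ Beta(0.5, 5) (most genes look
  present, matching detection-call semantics), organized in batches
  including one single-control batch so the global-pool fallback is
  exercised; treated profiles shift the p-values of perturbed-pathway
  genes by a planted magnitude, truncated to [0, 1].
* Side-effect score matrices: standard-normal noise (sd 1) over 50
  metabolites × 200 samples, half the samples positive, a planted
  3-metabolite ternary signature added at effect size 2 sd, and
  frequencies on the three-decade grid {10⁻³, 10⁻², 10⁻¹} written as
  min/max study records (some with placebo arms) that round-trip
  through the frequency processing.
* End-to-end sets wire these together: positive drugs perturb a random
  subset of the signature pathways (probability 0.7) and, within a
  perturbed pathway, each gene with probability 0.6 at magnitude +0.5;
  negative drugs perturb one non-signature pathway each. The partial
  hits matter: if every positive drug perturbed every signature-pathway
  gene, dozens of correlated metabolites would separate the classes
  perfectly and consensus recovery of any specific support would be
  ill-posed. Because metabolites within one pathway share production
  reactions and are strongly correlated, recovery for the end-to-end
  exercise is scored per pathway (any consensus metabolite inside the
  planted pathway with the planted sign); the score-level fixture has
  independent metabolites and is scored on the exact support.

What passing these tests shows — and does not. The fixtures exercise
the algebra, the LP contracts and end-to-end signal recovery under
clean planted effects with independent noise. They do not emulate
array-level noise structure, batch confounding, correlated side
effects, or the topological complexity of genome-scale human models, so
performance on the fixtures says nothing quantitative about recovery
rates on real pharmacogenomic data.

## Problem sizes and determinism

Default analyses in the tests use toy networks of 2-10 pathways
(≤ ~60 reactions after splitting), 40-70 expression profiles, and
score matrices of 200 × 50; the LP-oracle comparison covers 100 random
networks. Every stochastic component (generators, GA, permutation
tests, reporter background) takes an explicit seed; fixed seed, config
and data give identical results.

## Known limitations

* LP 2 scores depend on the chosen media bounds; scores for metabolites
  non-producible under a medium are missing rather than 0, which
  downstream consumers must handle (the GA treats missing as 0
  contribution).
* The GA is a heuristic: the returned signature maximizes the AUC over
  the run, not globally; elitism only guarantees monotone best-AUC.
* The dual permutation test's conservatism (above).
* Compartment collapsing assumes the id suffix encodes the compartment;
  models with other conventions need a custom pattern.
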