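"""Validation statistics for scored metabolites.

Shows the downstream association tests: reaction-hop distance of each
metabolite to a drug-target reaction (cofactor-like hubs excluded),
binning of standardized scores against those distances with a rank-sum
test, a permutation test for an observed AUC, and exact enrichment
tests with Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd

from metchange.stats import (
    adjust_bh,
    bin_and_compare,
    binomial_enrichment,
    dual_permutation_test,
    hypergeom_enrichment,
    network_distance,
)
from metchange.synthetic import FixtureSpec, make_toy_network

toy = make_toy_network(FixtureSpec(seed=0, n_pathways=8, pathway_length=6))

# distance of every metabolite to putative drug-target reactions (one
# mid-pathway target per pathway, so every metabolite is reachable)
targets = [f"R{j}_3" for j in range(8)]
profile = network_distance(toy.net, targets, connectivity_cap=30)
print(f"reaction-hop distances to the {len(targets)} target reactions:")
for met, d in sorted(profile.distances.items())[:8]:
    print(f"  {met:10s} {d}")

# do high-scoring metabolites sit closer to the target? (planted here)
rng = np.random.default_rng(1)
dists = profile.series()
scores = pd.Series(rng.uniform(-1, 1, len(dists)), index=dists.index)
scores[dists <= 1] += 1.5  # plant the association
summary, p = bin_and_compare(scores, profile, bin_width=0.5)
print("\nscore-bin summary (mean distance per 0.5-sd bin):")
print(summary.to_string())
print(f"rank-sum p, top bin vs rest: {p:.3g} (planted -> small)")

# enrichment utilities
res = [hypergeom_enrichment(k=4, n=8, K=5, N=20), binomial_enrichment(8, 10, 0.5)]
adjust_bh(res)
for r in res:
    print(f"\n{r.test}: k={r.k}, n={r.n} -> p = {r.p:.4f}, BH-adjusted {r.p_adjusted:.4f}")

# dual permutation test: predicted (side effect, nutrient) pairs that are
# all hits inside a mostly-miss outcome table
full = pd.DataFrame(
    (np.random.default_rng(2).random((10, 10)) < 0.2).astype(float),
    index=[f"se{i}" for i in range(10)],
    columns=[f"nu{j}" for j in range(10)],
)
predicted = [(f"se{i}", f"nu{i}") for i in range(8)]
for s, n in predicted:
    full.loc[s, n] = 1.0
p = dual_permutation_test(full, predicted, permutations=999, seed=0)
print(f"\ndual permutation test on enriched predicted pairs: p = {p:.3g}")
print("(each predicted pair is replaced by the average of a same-side-effect")
print(" and a same-nutrient random outcome; small p = predictions enriched in hits)")
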