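"""Bayesian admixture clustering with Evanno delta-K model selection.

Simulates three moderately drifted populations, runs the Gibbs sampler for
K = 1..5 with replicate chains, and shows that delta-K peaks at the true K
while the mean ancestry matrix recovers the planted memberships.
"""

import itertools

import numpy as np

from ssrpop import SimConfig, generate_dataset
from ssrpop.structure import analyse_structure_level

config = SimConfig(
    n_accessions=150, n_loci=30, K_true=3, subgroups=None,
    admixture_alpha=0.0, drift_F=0.3, seed=8,
    missing_rate_per_locus=(0.0, 0.1), sister_fraction=0.0,
)
matrix, _, truth = generate_dataset(config)

res = analyse_structure_level(matrix, (2, 5), reps=3, burnin=500, iters=2000, seed=1)
print(res.delta_k[["K", "mean_L", "sd_L", "delta_K"]].to_string(index=False))
print(f"\nselected K* = {res.best_k} "
      f"({'clear' if res.clear_structure else 'no clear'} structure)")

true_k = truth.group_labels["subgroup"].to_numpy()
est = res.assignment["group"].to_numpy()
agree = max(
    np.mean(est == np.array(perm)[true_k])
    for perm in itertools.permutations(range(1, res.best_k + 1))
)
print(f"accessions assigned to their true population: {100 * agree:.1f}%")
# L(K) rises sharply up to the true K and flattens after; delta-K divides
# that second difference by the between-replicate spread, giving one
# pronounced peak at the planted number of ancestral populations.
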