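"""Simulated 3-round campaigns: the full workflow against its baselines.

Runs paired bootstrap replicates (fresh 50% holdout per replicate) of four
strategies on one synthetic landscape and compares cumulative top-10% hits
and the probability of finding a top-1% mutant, with a one-sided Wilcoxon
signed-rank test on log-transformed hit counts.
"""

import numpy as np

from folde import (CampaignConfig, SyntheticOracleConfig, TrainConfig,
                   bootstrap_benchmark, make_oracle, wilcoxon_log_ratio)

config = SyntheticOracleConfig(L=32, dim=32, naturalness_rho=0.5,
                               signal_fraction=0.5, noise_sd=0.1, seed=3)
landscape, oracle = make_oracle(config)
train_cfg = TrainConfig(input_dim=config.dim)

strategies = ("folde", "random", "zero_shot", "random_forest")
configs = {s: CampaignConfig(strategy=s, train=train_cfg)
           for s in strategies}
print("running 8 paired replicates x 4 strategies (3 rounds x 16) ...")
results = bootstrap_benchmark(landscape, oracle, configs, n_replicates=8,
                              seed=4)

hits = {s: [m.cumulative_top10_hits for m in results[s]] for s in strategies}
for s in strategies:
    p_top1 = np.mean([m.found_top1 for m in results[s]])
    print(f"  {s:14s} mean top-10% hits {np.mean(hits[s]):5.1f}   "
          f"P(top-1% found) {p_top1:.2f}")

for other in ("random", "random_forest"):
    w = wilcoxon_log_ratio(hits["folde"], hits[other])
    print(f"folde > {other}: one-sided Wilcoxon p = {w.p_value:.4f} "
          f"(n = {w.n_effective})")
# Of 48 mutants measured, the count at or above the accessible set's 90th
# activity percentile is the hit count; the Wilcoxon p-value tests whether
# the full workflow reliably beats the baseline across replicates.
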