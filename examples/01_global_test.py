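"""Global k-sample test on a simulated cluster randomized trial.

Simulates a 6-arm trial of 30 clusters with a ratio endpoint, strong
intra-cluster correlation (theta = 0.75) and ~40% censoring under the
global null, then evaluates every p-value engine on the same
quadratic statistic.
"""

from saddleperm import get_scenario, simulate_dataset
from saddleperm.io import RunConfig, run_test

ds = simulate_dataset(get_scenario(8), seed=12)
records = ds.records()
config = RunConfig(weight="gehan", engines=("chisq", "saddlepoint", "midp"),
                   seed=12)
result = run_test(records, config)

print(f"subjects: {len(records)}, clusters: {ds.spec.n_clusters}, "
      f"arms: {ds.spec.k}")
print(f"Q = {result.q_obs:.3f} on {result.df} df")
print(f"conventional chi-squared p : {result.p_chisq:.4f}")
print(f"saddlepoint p              : {result.p_saddle:.4f}")
print(f"Monte Carlo mid-p (B=2000) : {result.p_midp:.4f}")
print()
print("The data were generated with no treatment effect, so a well-"
      "calibrated p-value should look uniform; the saddlepoint and mid-p "
      "values agree closely, while the conventional chi-squared analysis "
      "can differ noticeably at this cluster count.")
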