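"""Mini Type I error study: conventional chi-squared vs saddlepoint.

Replays a slice of the small-cluster / high-correlation stress
scenario (6 arms, 30 clusters, theta = 0.75, ~40% censoring,
Gehan-Wilcoxon scores) at 400 replicates.  The conventional
estimated-variance chi-squared analysis inflates above the nominal
0.05, while the saddlepoint engine tracks the Monte Carlo mid-p.
"""

from saddleperm import get_scenario, type1_error_experiment

run = type1_error_experiment(
    get_scenario(8), reps=500,
    engines=("chisq", "saddlepoint", "midp"), seed=3,
)
print(run.summary().to_string(index=False))
print()
print("Coverage of the true (null) effect by inverted 95% intervals is "
      "the complement of each rejection rate:",
      {e: round(run.coverage(e), 3) for e in run.engines})
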