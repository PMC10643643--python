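"""Leave-one-out prediction of fetal RRI on a synthetic cohort.

Simulates 150 subjects whose fetal RRI depends linearly on maternal RRI,
age, SDHR and HF power (plus 10 ms noise), then compares the linear
epsilon-insensitive SVR with the random forest under leave-one-out
cross-validation.
"""

from fetalrri import (
    ModelConfig,
    SyntheticCohortSpec,
    acceptability,
    generate_cohort,
    run_loo_evaluation,
)

cohort = generate_cohort(SyntheticCohortSpec(n_subjects=150, noise_sd=10.0, seed=5))

for kind in ("svr", "rf"):
    result = run_loo_evaluation(cohort, ModelConfig(kind=kind, seed=0))
    accepted, _ = acceptability(result.error_pct)
    print(f"[{kind.upper()}]")
    print(f"  RMSE                : {result.rmse_ms:.1f} ms")
    print(f"  Spearman r (p)      : {result.spearman_r:.2f} ({result.spearman_p:.2g})")
    print(f"  BA mean diff        : {result.ba_mean_diff_ms:+.2f} ms")
    print(f"  BA limits           : [{result.ba_lower_ms:+.1f}, {result.ba_upper_ms:+.1f}] ms")
    print(f"  within limits       : {result.pct_within_limits:.1f} %")
    print(f"  error <= 5 %        : {accepted}/{result.n} subjects")
# The SVR RMSE sits just above the injected 10 ms noise floor (the best any
# model can do); the forest is close but less exact on a purely linear map.
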