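"""Which maternal features drive the fetal-RRI prediction?

Fits the linear SVR on a synthetic cohort with known generative weights and
computes interventional Shapley attributions (permutation-sampled, background
= the training cohort). The absolute-mean summary with 95 % CI should rank
maternal RRI first — it has by far the largest |weight x feature SD| in the
generative map.
"""

from fetalrri import (
    ModelConfig,
    SyntheticCohortSpec,
    fit,
    generate_cohort,
    shapley_values,
    summarize,
)

cohort = generate_cohort(SyntheticCohortSpec(n_subjects=150, noise_sd=10.0, seed=5))
model = fit(ModelConfig(kind="svr"), cohort)
report = summarize(shapley_values(model, cohort, seed=0, n_coalitions=1024))

print(f"{'feature':>10s}  mean|Shapley| (ms)   95% CI")
for _, row in report.to_frame().sort_values("mean_abs_shapley_ms", ascending=False).iterrows():
    print(
        f"{row['feature']:>10s}  {row['mean_abs_shapley_ms']:14.2f}   "
        f"[{row['ci_low_ms']:.2f}, {row['ci_high_ms']:.2f}]"
    )
# maternal rri_ms dominates (generative |w*sd| = 0.15*114 ~ 17 ms); hf, age
# and sdhr follow; features with zero generative weight sit near zero.
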