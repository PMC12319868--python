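"""Monte-Carlo parameter recovery with MAR missingness.

Simulates replicates at the canonical truth, deletes wave-2 brain values
at 20% (more likely for adolescents with lower observed baseline social
scores — missing at random) and wave-2 indicators at 10%, refits by FIML,
and reports per-parameter bias and coverage.  Under MAR, FIML point
estimates should stay unbiased and 95% intervals should cover.
"""

from latentchange import recovery_study

table = recovery_study(n=2000, reps=6, seed=10, missingness=True, se="sandwich")
cols = ["parameter", "truth", "mean_estimate", "bias", "mc_se",
        "empirical_sd", "mean_model_se", "coverage_95"]
print(table[cols].round(4).to_string(index=False))
print(
    "\n|bias| within ~2 Monte-Carlo SEs indicates unbiased recovery; the"
    "\nmodel SE column should track the empirical SD across replicates."
)
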