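"""Preprocessing a native-scale table: exclusions, QC, and 0-100 scaling.

Reverse-scales a synthetic cohort to native instrument metrics (prosocial
0-2, school scales 1-4, friend counts, cortical thickness in mm), plants a
few rule violations, then runs the hygiene pipeline: friend counts
truncate at 100, MRI quality-control failures blank the thickness value,
cells beyond +/-5 SD go missing, and everything is rescaled to percent of
maximum possible (0-100).

Note the generator is Gaussian, so a reverse-scaled synthetic column can
spill slightly past its theoretical scale bounds; real instrument data are
bounded by construction.
"""

from latentchange import apply_exclusions, canonical_params, scale_0_100, simulate_dataset, to_native_scale

scaled = simulate_dataset(canonical_params(), n=500, seed=4, include_demographics=True)
native = to_native_scale(scaled)
print("native-scale snapshot:")
print(native[["friends_t1", "school_env_t1", "ct_t1"]].describe().loc[["mean", "min", "max"]].round(2))

# plant violations: an implausible friend count and a flagged MRI
native.loc[0, "friends_t1"] = 400
native.loc[1, "qc_clinical_score_t2"] = 3

clean, log = apply_exclusions(native)
print(f"\nexclusion log ({log.count()} entries):")
print(log.to_frame().to_string(index=False))

modeled = scale_0_100(clean)
print("\nafter POMP scaling (0-100):")
print(modeled[["friends_t1", "school_env_t1", "ct_t1"]].describe().loc[["mean", "min", "max"]].round(2))
print(
    "\nThe truncated friend count enters the model as 100; the flagged MRI"
    "\nvalue is missing and will be handled by FIML, not dropped listwise."
)
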