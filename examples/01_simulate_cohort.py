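"""Simulate a three-generation study: cohort, worklist, and all omic
layers with ground truth."""

from triomics import synth

study = synth.simulate_study(seed=1)

print("Study samples:", len(study.study_meta))
print(study.study_meta.groupby(["batch", "generation"]).size())
print("\nInjections per role:")
print(study.meta["role"].value_counts())
print("\nRaw metabolite matrix:", study.matrix.shape,
      f"({study.matrix.isna().mean().mean():.1%} missing)")
print("Taxa table:", study.taxa.shape, "| KO table:", study.ko.shape)
print("Features with true generation effects:",
      int(study.truth.informative.sum()), "of", len(study.truth.features))

# Each batch holds one generation (as in the original worklists), opens
# with 3 equilibrium QCs and carries 8 interspersed QCs; the truth object
# records every drift curve and effect size for recovery testing.
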