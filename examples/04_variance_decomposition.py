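"""Where does the variance of a Ct measurement come from?

A nested ANOVA per gene charges sequential sums of squares to the replicate
hierarchy -- treatment group, biological replicate, cDNA conversion -- with
the residual left to the qPCR step. The sd-vs-mean regression diagnoses
heteroscedasticity: weakly expressed genes (high Ct) are noisier.
"""

import lemnorm as ln

table, design, _ = ln.simulate(
    ln.SimConfig(seed=5, global_shift=(0.0, 0.4)))

vd = ln.variance_decomposition(table, design,
                               ["group", "bio_rep", "cdna_batch"])
med = vd.proportions.median(axis=0)
print("median proportion of per-gene variance (sequential SS):")
for name, label in [("group", "treatment"), ("bio_rep", "biological"),
                    ("cdna_batch", "cDNA conversion"), ("residual", "qPCR")]:
    print(f"  {label:16s} {100 * med[name]:5.1f} %")
print("(the reverse-transcription step dominates the technical error)")

reg = ln.sd_vs_mean_regression(table, design, level="technical")
print(f"\ntechnical sd vs mean Ct: slope {reg.slope:+.4f} sd-cycles per "
      f"cycle (positive: {reg.positive_slope}), intercept {reg.intercept:.3f}")
print("higher Ct (less template) -> noisier measurement")
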