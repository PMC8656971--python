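"""Enrichment factors: how far above crustal composition is household dust?

EF = (C_i/C_Al) / (B_i/B_Al) compares each element, normalized to Al, with
the same ratio in Texas background soil.  EF near 1 is natural; > 20 flags
heavy anthropogenic input (electronics, paint, rubber, plumbing).
"""

import dustrisk as dr

panel = dr.load_reference_panel()
means = dr.load_study_means()

print("Study-mean enrichment factors (Al reference, Texas background):")
efs = dr.study_mean_ef(means, panel, ["Zn", "Cu", "Pb", "Ni", "Cr", "As", "Fe", "Mn"])
for element, ef in sorted(efs.items(), key=lambda kv: -kv[1]):
    print(f"  {element:>2}: EF = {ef:7.2f}  ({dr.categorize_ef(ef).value})")

print("\nPer-sample EF distribution on a synthetic survey (Fig-style boxplot):")
study = dr.simulate_study(dr.default_config(seed=1))
results = dr.ef_table(study, panel, ["Zn"])
box = dr.boxplot_summary([(r.scope, r.ef_value) for r in results], "Zn")
print(f"  Zn: q1={box.q1:.1f} median={box.median:.1f} q3={box.q3:.1f} "
      f"outliers={[sid for sid, _ in box.outliers]}")
print("\nZn and Cu exceed EF 20 at the study means: household sources, not "
      "soil, dominate those metals in floor dust.")
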