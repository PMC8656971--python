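"""Correlation screening between elements and bacterial loads.

Pairwise Pearson correlations with two-tailed significance stars and the
conventional strength bands; plus a group-mean comparison with compact
significance letters (levels sharing a letter are indistinguishable).
"""

import dustrisk as dr

study = dr.simulate_study(dr.default_config(seed=1))

matrix = dr.correlation_matrix(
    study, ["Cu", "Fe", "Zn", "Pb", "TB", "EB"]
)
print("Annotated correlation matrix (* p<0.05, ** p<0.01):")
print(matrix.annotated())
r = matrix.r.loc["TB", "EB"]
print(f"\nTotal vs enteric bacteria: r={r:.2f} "
      f"({dr.classify_correlation(r)}) — enteric load tracks total load.")

comparison = dr.compare_groups(study, "home_age_class", "Pb")
print("\nPb by home age (letters: shared = not significantly different):")
for level in comparison.levels:
    print(f"  {level:>7}: mean {comparison.means[level]:6.1f} mg/kg "
          f"(n={comparison.n[level]})  {comparison.letters[level]}")
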