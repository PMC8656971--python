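"""Draw a synthetic 31-residence household dust survey and inspect it.

The default configuration emulates a four-county metropolitan survey:
log-normal element concentrations whose arithmetic means match the
published study-wide means, a Gaussian copula reproducing the published
inter-element correlations, and habitat attributes with multiplicative
effects (older homes carry more Pb and Cd).
"""

import dustrisk as dr

config = dr.default_config(seed=1)
study = dr.simulate_study(config)

frame = study.to_dataframe()
print(f"{len(study)} samples across counties:",
      frame["county"].value_counts().to_dict())
print("\nMean concentrations (mg/kg) vs configured targets:")
for element in ("Al", "As", "Cd", "Cu", "Pb", "Zn"):
    print(f"  {element:>2}: simulated {frame[element].mean():8.1f}"
          f"   target {config.means[element]:8.1f}")
print("\nA small survey (n=31) scatters around its targets; at n=10,000 the "
      "generator recovers means within 3% and log-correlations within 0.03.")
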