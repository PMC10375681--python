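"""Genome-wide REA scan for low-level heteroplasmy differences.

Builds two groups of subjects where the 'maternal' group carries extra
low-level variants (fractions below the 20% calling threshold) at a fixed
set of positions, then scans all 16,544 callable positions for group
differences in the REA index.
"""

import numpy as np

from mitorea import SimConfig, load_reference, rea_profile, rea_scan, simulate_cohort
from mitorea.rea import direction_summary

genome = load_reference()

profiles = {"CTRL": [], "maternal": []}
for group, lowlevel_rate, seed in (("CTRL", 0.0, 100), ("maternal", 0.002, 200)):
    config = SimConfig(groups={group: 10}, structure_seed=seed,
                       noise_seed=seed + 1, hom_rate_per_kb=0.0,
                       het_rate_per_kb=0.0, lowlevel_rate=lowlevel_rate,
                       haplogroup_probs={"rCRS": 1.0})
    cohort = simulate_cohort(config, genome)
    for sub in cohort.intensities.values():
        profiles[group].append(rea_profile(sub, genome))

result = rea_scan(profiles, alpha=0.001)
print(f"significant positions at p <= 0.001: {result.n_significant} "
      f"of {len(result.table)}")
frac = direction_summary(result, "CTRL")
print(f"fraction with higher REA in CTRL: {100 * frac:.1f}%")
print(f"tests used: {result.table['test'].value_counts().to_dict()}")

print()
print("Low-level variants shift fluorescence away from the reference")
print("channel, lowering REA.  Positions flagged by the scan are where the")
print("maternal group's REA differs; CTRL having the higher mean REA at")
print("most flagged positions means the maternal group carries the extra")
print("low-level heteroplasmy (the planted truth here).")
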