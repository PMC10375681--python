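"""Simulate a small cohort and call every subject against the reference.

Plants haplogroup backbones, homoplasmic and heteroplasmic variants per
subject, then runs the diploid-model caller and compares the per-subject
counts with the ground-truth ledger.
"""

from mitorea import SimConfig, call_subject, load_reference, simulate_cohort

genome = load_reference()
config = SimConfig(groups={"CTRL": 3, "maternal": 3},
                   structure_seed=7, noise_seed=8)
cohort = simulate_cohort(config, genome)

print("subject   group         truth hom/het   called hom/het  no-calls")
for truth in cohort.truth.subjects:
    cs = call_subject(cohort.intensities[truth.subject_id], genome)
    print(f"{truth.subject_id:<9} {truth.group:<13} "
          f"{truth.count('homoplasmic'):>5} /{truth.count('heteroplasmic'):>3}"
          f"     {cs.n_homoplasmic:>8} /{cs.n_heteroplasmic:>3}"
          f"     {int((cs.states == 3).sum()):>6}")

print()
print("Each row is one simulated subject: 'truth' counts are the planted")
print("homoplasmic/heteroplasmic variants, 'called' what the caller")
print("recovered from the noisy eight-channel intensities. At the default")
print("noise level the caller recovers the planted truth exactly; the")
print("low-level plantings (<20% fraction) are deliberately not called.")
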