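"""Per-gene mutation burden with a planted ND5 enrichment.

Simulates maternal vs non-maternal subjects with a 3x homoplasmic burden
multiplier on ND5 in the maternal group, tabulates per-gene counts and
runs the two-group Mann-Whitney test per gene, then contrasts bulbar vs
spinal onset on the ND5 counts.
"""

from mitorea import (
    SimConfig,
    burden_table,
    call_subject,
    compare_burden_groups,
    load_reference,
    simulate_cohort,
)
from mitorea.cohortstats import onset_contrast

genome = load_reference()
config = SimConfig(
    groups={"non-maternal": 12, "maternal": 12},
    structure_seed=21, noise_seed=22,
    hom_gene_multipliers={"maternal": {"ND5": 3.0}},
)
cohort = simulate_cohort(config, genome)
callsets = [call_subject(s, genome) for s in cohort.intensities.values()]

table = burden_table(callsets, genome, "homoplasmic")
reports = compare_burden_groups(table.drop(columns="total"), cohort.grouping())
ranked = sorted(reports.items(), key=lambda kv: kv[1].p)

print("gene    test          p       (5 smallest of", len(ranked), "genes)")
for gene, rep in ranked[:5]:
    print(f"{gene:<7} {rep.test:<12} {rep.p:.4f}")

mat = [m.subject_id for m in cohort.meta if m.group == "maternal"]
print(f"\nmean ND5 homoplasmic count, maternal:     "
      f"{table.loc[mat, 'ND5'].mean():.2f}")
other = [m.subject_id for m in cohort.meta if m.group == "non-maternal"]
print(f"mean ND5 homoplasmic count, non-maternal: "
      f"{table.loc[other, 'ND5'].mean():.2f}")

try:
    rep = onset_contrast(table, cohort.meta, "ND5")
    print(f"\nbulbar vs spinal onset, ND5 counts: Mann-Whitney p = {rep.p:.3f} "
          f"(n = {rep.n})")
except ValueError as exc:
    print(f"\nonset contrast skipped: {exc}")

print()
print("The planted 3x ND5 enrichment surfaces as the smallest per-gene p;")
print("the onset contrast is null here because the simulator assigned onset")
print("sites independently of the burden.")
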