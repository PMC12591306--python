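"""Clone dynamics across paired pre/post-treatment samples.

Simulates 24 patients sampled before and after treatment with drifting
clone sizes, joins each patient's mutations across timepoints and prints
the per-patient vanished/emerged counts with cohort means.
"""

from chclone import pair_variants, summarize_dynamics
from chclone.simulate import simulate_paired_cohort

rows, variants = simulate_paired_cohort(n_pairs=24, drift_sd=0.35, seed=1)

paired = []
for r in rows:
    if r.paired_pre_sample:
        paired += pair_variants(
            variants[r.paired_pre_sample], variants[r.sample_id],
            patient_id=r.paired_pre_sample,
            months_between=r.elapsed_months,
        )

table, means = summarize_dynamics(paired)
print(table.head(8).to_string(index=False))
print("...")
print(f"\ncohort means per patient: "
      f"vanished/decreased {means['mean_vanished_decreased']:.1f}, "
      f"emerged/increased {means['mean_emerged_increased']:.1f}, "
      f"unchanged {means['mean_unchanged']:.1f}")
# A mutation is vanished/decreased if undetectable after treatment or its
# VAF fell; emerged/increased if new or its VAF rose.
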