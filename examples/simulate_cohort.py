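"""Simulate a TMA scoring cohort and recover its generating parameters.

Generates a 177-patient cohort (575 spots) with rater discordance
concentrated in the 2+ category and FISH counts whose log-scale
correlation with the patient's maximum connectivity is 0.67, then runs
the same concordance analysis a real study would: spot-level weighted
kappa, patient-level aggregation, and the log-log Pearson correlation.
"""

from memconnect import (
    CohortSimParams,
    aggregate_patients,
    build_contingency,
    generate_cohort,
    log_pearson,
    weighted_kappa,
)

spots, fish = generate_cohort(CohortSimParams(seed=11))
print(f"simulated {len(spots)} spots from {spots['patient_id'].nunique()} patients")

table = build_contingency(spots, "ve1", "ve2")
res = weighted_kappa(table)
print(f"spot-level kappa (ve1 vs ve2): {res.kappa:.3f} "
      f"[{res.ci_low:.3f}, {res.ci_high:.3f}]")

patients = aggregate_patients(spots, min_spots=2)
print(f"{len(patients)} patients with 2-4 adequate spots kept")

merged = patients.merge(fish, on="patient_id")
r, p = log_pearson(merged["connect_max"], merged["her2_mean"])
print(f"Pearson r of log(ConnectMax) vs log(mean HER2): {r:.3f} (p = {p:.2g})")
print()
print("The recovered kappa sits near the generating 0.91 and the recovered")
print("correlation near the generating 0.67, up to cohort-sized sampling noise.")
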