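"""Generate a synthetic multi-cohort stroke study and inspect its structure.

Builds the default nine-cohort study (2,343 patients, 38% women) and
prints the marginal structure the generator is calibrated to: cohort
sizes, per-domain assessment rates, and per-domain impairment rates by
sex.
"""

from pscikit import GeneratorConfig, generate_study

study = generate_study(GeneratorConfig(seed=1))
patients = study.participants
scores = study.test_scores

print(f"patients: {len(patients)}, "
      f"women: {100 * (patients['sex'] == 'woman').mean():.0f}%")
print("\ncohort sizes:")
print(patients["cohort"].value_counts().sort_index().to_string())

assessed = scores.drop_duplicates(["id", "domain"])
print("\nper-domain assessment rate (fraction of patients with >=1 test):")
print((assessed.groupby("domain").size() / len(patients))
      .round(2).to_string())

# the latent ground truth exists only in synthetic data
print(f"\ntrue PSCI prevalence: {100 * patients['true_psci'].mean():.1f}%")
# Cohort sizes, the 34-98% assessment-rate spread and the 11-29% domain
# impairment rates mirror the pooled structure the generator emulates.
# The latent PSCI prevalence lands near 79%, higher than the ~51% seen
# in real cohorts, because the generator draws the six domains
# independently: in patients, impairments cluster.
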