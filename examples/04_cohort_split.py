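"""Exclusion filtering and leakage-free patient-wise splitting.

Generates a two-hospital cohort with implants and mis-scans, applies the
exclusion rules, splits each hospital 70/20/10 on patients, and assembles
the federation layout with a test-only site.
"""

from fedmammo import (
    HospitalProfile,
    SplitSpec,
    assemble_federation,
    filter_cohort,
    generate_cohort,
    patientwise_split,
)

profiles = [
    HospitalProfile("H1", intensity_range=(50, 1050), implant_prob=0.05, mis_scan_prob=0.05),
    HospitalProfile("H2", intensity_range=(3000, 4095)),
    HospitalProfile("H3", intensity_range=(0, 2000)),
]
cohort = generate_cohort(90, 2, profiles, seed=3, image_size=(32, 32))

kept, report = filter_cohort(cohort.manifest)
print("exclusion report:", report)

splits = {
    h: patientwise_split(grp, SplitSpec(seed=0)) for h, grp in kept.groupby("hospital_id")
}
for h, (tr, va, te) in splits.items():
    print(f"{h}: {tr.patient_id.nunique()}/{va.patient_id.nunique()}/"
          f"{te.patient_id.nunique()} patients in train/val/test")

fed = assemble_federation(splits, test_only={"H3"})
print(f"federation: clients {sorted(fed.clients)}, "
      f"test sets {sorted(fed.test_sets)} (H3 contributes testing only)")

# No patient appears in a training set and any test set:
train_patients = set()
for parts in fed.clients.values():
    train_patients |= set(parts["train"].patient_id) | set(parts["val"].patient_id)
leaks = sum(len(set(t.patient_id) & train_patients) for t in fed.test_sets.values())
print(f"patients leaking between train and test: {leaks}")
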