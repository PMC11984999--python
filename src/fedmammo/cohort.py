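"""Cohort assembly: exclusions, patient-wise splitting, federation layout.

Images with noisy assessments (BIRADS 0 or 6) are dropped, as are all images
of patients flagged for implants or incorrect scans. Splitting into
train/validation/test is done on patients, never images, so no patient can
contribute to more than one set; the default proportions are 70/20/10.
Hospitals' train and validation sets become federated clients while every
hospital keeps its own named test set — including hospitals too small to
train on, which participate as test-only sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SplitSpec:
    """Patient-wise split proportions."""

    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")


def filter_cohort(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion rules; returns the kept rows and a report.

    Drops every image labelled BIRADS 0 or 6, and every image of any patient
    with an implant or mis-scan flag anywhere in their record. The report
    counts dropped images per reason and dropped patients.
    """
    required = {"patient_id", "birads", "implant_flag", "mis_scan_flag"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")

    bad_birads = manifest.birads.isin([0, 6])
    implant_patients = set(manifest.loc[manifest.implant_flag.astype(bool), "patient_id"])
    mis_scan_patients = set(manifest.loc[manifest.mis_scan_flag.astype(bool), "patient_id"])
    flagged = manifest.patient_id.isin(implant_patients | mis_scan_patients)

    kept = manifest[~bad_birads & ~flagged].copy()
    report = {
        "birads_0_or_6": int(bad_birads.sum()),
        "implant_images": int((manifest.patient_id.isin(implant_patients) & ~bad_birads).sum()),
        "mis_scan_images": int(
            (manifest.patient_id.isin(mis_scan_patients - implant_patients) & ~bad_birads).sum()
        ),
        "implant_patients": len(implant_patients),
        "mis_scan_patients": len(mis_scan_patients),
        "kept_images": int(len(kept)),
    }
    if kept.empty:
        raise ValueError(f"cohort is empty after exclusions ({report})")
    return kept, report


def _largest_remainder(total: int, fractions) -> list[int]:
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = total - sum(counts)
    order = np.argsort([-(q - c) for q, c in zip(quotas, counts)], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def patientwise_split(
    manifest: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition patients into train/val/test with stratification by BIRADS.

    Patient counts per set follow largest-remainder rounding of the requested
    fractions (so 10 patients at 70/20/10 gives exactly 7/2/1); within each
    BIRADS stratum patients are shuffled deterministically under the seed and
    dealt out so per-stratum allocations respect the global totals. All
    images of one patient land in the same set.
    """
    spec = spec or SplitSpec()
    patients = manifest.drop_duplicates("patient_id")[["patient_id", "birads"]]
    n = len(patients)
    if n < 3:
        raise ValueError(f"need at least 3 patients to split, got {n}")
    targets = _largest_remainder(n, spec.fractions)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 29]))
    deficits = list(targets)
    assignment: dict[str, int] = {}
    # per-stratum floor allocations, then controlled rounding against the
    # global targets (ties broken by patient-id sort for determinism)
    pending = []  # (remainder_key, stratum_patients, set_index)
    strata = []
    for birads, grp in sorted(patients.groupby("birads"), key=lambda kv: kv[0]):
        ids = sorted(grp.patient_id)
        rng.shuffle(ids)
        quotas = [len(ids) * f for f in spec.fractions]
        floors = [int(np.floor(q)) for q in quotas]
        strata.append({"ids": ids, "floors": floors, "quotas": quotas, "cursor": 0})
    # assign floors first
    for st in strata:
        for si, cnt in enumerate(st["floors"]):
            for _ in range(cnt):
                assignment[st["ids"][st["cursor"]]] = si
                st["cursor"] += 1
                deficits[si] -= 1
    # distribute leftover patients by largest fractional remainder where a
    # global deficit remains
    leftovers = []
    for st in strata:
        rema = [(st["quotas"][si] - st["floors"][si], si) for si in range(3)]
        n_left = len(st["ids"]) - st["cursor"]
        rema.sort(key=lambda t: (-t[0], t[1]))
        leftovers.append({"st": st, "prefs": [si for _, si in rema], "n_left": n_left})
    for item in sorted(leftovers, key=lambda d: -d["n_left"]):
        st = item["st"]
        while st["cursor"] < len(st["ids"]):
            for si in item["prefs"]:
                if deficits[si] > 0:
                    assignment[st["ids"][st["cursor"]]] = si
                    st["cursor"] += 1
                    deficits[si] -= 1
                    break
            else:  # pragma: no cover - targets always absorb all patients
                raise RuntimeError("split bookkeeping failed")

    sets = [manifest[manifest.patient_id.map(assignment).eq(i)] for i in range(3)]
    return sets[0], sets[1], sets[2]


@dataclass
class FederationDataset:
    """Clients (train+val manifests per training hospital) and named test sets."""

    clients: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    test_sets: dict[str, pd.DataFrame] = field(default_factory=dict)


def assemble_federation(
    per_hospital_splits: dict[str, tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]],
    test_only: set[str] | None = None,
) -> FederationDataset:
    """Lay out hospital splits as a federation.

    Training hospitals contribute their train and validation sets as one
    client each; every hospital — including ``test_only`` ones, whose entire
    data becomes their test set — contributes a separately-named test set.
    """
    test_only = test_only or set()
    fed = FederationDataset()
    for hospital, (train, val, test) in per_hospital_splits.items():
        if hospital in test_only:
            fed.test_sets[hospital] = pd.concat([train, val, test], ignore_index=True)
            continue
        fed.clients[hospital] = {"train": train, "val": val}
        fed.test_sets[hospital] = test
    if not fed.clients:
        raise ValueError("federation needs at least one training hospital")
    return fed
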