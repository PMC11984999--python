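"""Federated training and the rounds-vs-local-epochs trade-off.

Builds a small two-client federation from phantom cohorts and compares
(rounds, local_epochs) combinations with the same total local epochs, all
starting from one seeded initial model. Runs in a couple of minutes.
"""

import numpy as np

import fedmammo as fm
from fedmammo.classifier import TrainConfig, build_model, compute_norm_stats, normalize
from fedmammo.federated import ClientData, FLConfig, rounds_epochs_sweep

profile = fm.HospitalProfile("H", intensity_range=(0, 4095))
cohort = fm.generate_cohort(220, 1, [profile], seed=2, image_size=(64, 64))
manifest = cohort.manifest.assign(record_index=np.arange(len(cohort.records)))
tr, va, te = fm.patientwise_split(manifest, fm.SplitSpec(seed=0))

def arrays(rows):
    X = np.stack([fm.preprocess(cohort.records[i], target_size=(64, 64)).pixels
                  for i in rows.record_index])
    return X, rows.birads.to_numpy() - 1

(Xtr, ytr), (Xva, yva), (Xte, yte) = arrays(tr), arrays(va), arrays(te)
stats = compute_norm_stats([Xtr])
Xtr, Xva, Xte = (normalize(X, stats).astype(np.float32) for X in (Xtr, Xva, Xte))

# two IID clients from one pool (heterogeneous clients: see example 06)
half = len(Xtr) // 2
clients = {
    "H1": ClientData(train=(Xtr[:half], ytr[:half]), val=(Xva, yva)),
    "H2": ClientData(train=(Xtr[half:], ytr[half:]), val=(Xva, yva)),
}
tests = {"held_out": (Xte, yte)}

base = FLConfig(rounds=1, local_epochs=1, seed=0,
                client_config=TrainConfig(learning_rate=3e-3, batch_size=10,
                                          epochs=1, seed=0))
builder = lambda s: build_model(input_size=(64, 64), seed=s)
table, traces = rounds_epochs_sweep(
    clients, tests, [(100, 1), (50, 2), (20, 5)], base, builder
)
print(table.to_string(index=False))
print("\nEach combination trains 100 total local epochs per client; more rounds "
      "means more frequent synchronization for the same compute.")
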