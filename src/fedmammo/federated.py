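"""In-process federated averaging over the classification model.

Clients are simulated in one process: each round the server broadcasts the
global parameters, every client trains its local epochs, and the server
replaces the global model with the (sample-size-weighted or uniform) average
of the client parameters, evaluating the merged model on every named
per-hospital test set. Client optimizer state persists across rounds and each
client draws its epoch shuffles from a global-epoch-indexed stream, which
makes single-client federation bit-identical to centralized training.

Also here: the rounds-vs-local-epochs sweep and the harmonization ablation
that contrasts minimal pre-processing against the full pipeline (metadata
harmonization, shared normalization statistics, breast-area cleaning) on a
deliberately heterogeneous two-hospital cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .bootstrap import AugmentationConfig, build_auld
from .classifier import (
    NormStats,
    TrainConfig,
    build_model,
    compute_norm_stats,
    evaluate_f1,
    normalize,
)
from .cohort import SplitSpec, assemble_federation, filter_cohort, patientwise_split
from .nn import Adam, Module, run_epochs, softmax_cross_entropy
from .preprocess import _resize, preprocess
from .segmenter import SegTrainConfig, clean_and_crop, predict_mask, train_unet
from .synthetic import Cohort, HospitalProfile, generate_cohort


@dataclass
class FLConfig:
    """Federated-run configuration: R rounds of E local epochs per client."""

    rounds: int = 50
    local_epochs: int = 2
    weighting: str = "sample_size"  # or "uniform"
    client_config: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.local_epochs < 1:
            raise ValueError("rounds and local_epochs must be >= 1")
        if self.weighting not in ("sample_size", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class RoundRecord:
    round_index: int
    client_losses: dict[str, float]
    test_f1: dict[str, float]


def fedavg_merge(
    states: list[dict[str, np.ndarray]],
    sample_counts: list[int] | None = None,
    weighting: str = "sample_size",
) -> dict[str, np.ndarray]:
    """Parameter-wise weighted average of client state dicts.

    Weights are proportional to client sample counts (canonical federated
    averaging) or uniform. Computed as ``p_1 + sum_i w_i (p_i - p_1)``, which
    is algebraically the weighted mean and returns identical inputs exactly.
    """
    if not states:
        raise ValueError("need at least one state dict to merge")
    keys = set(states[0])
    for s in states[1:]:
        if set(s) != keys or any(states[0][k].shape != s[k].shape for k in keys):
            raise ValueError("client architectures do not match")
    if weighting == "uniform":
        w = np.full(len(states), 1.0 / len(states))
    elif weighting == "sample_size":
        if sample_counts is None or len(sample_counts) != len(states):
            raise ValueError("sample_size weighting needs one count per client")
        counts = np.asarray(sample_counts, dtype=np.float64)
        if (counts <= 0).any():
            raise ValueError("sample counts must be positive")
        w = counts / counts.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    merged = {}
    for k in keys:
        base = states[0][k]
        acc = base.astype(np.float64).copy()
        for wi, s in zip(w, states):
            acc += wi * (s[k].astype(np.float64) - base)
        merged[k] = acc.astype(base.dtype)
    return merged


@dataclass
class ClientData:
    """One client's arrays: train and validation (images, labels)."""

    train: tuple[np.ndarray, np.ndarray]
    val: tuple[np.ndarray, np.ndarray]


@dataclass
class FLResult:
    model: Module
    rounds: list[RoundRecord]
    client_epochs: dict[str, int]


def run_federated(
    clients: dict[str, ClientData],
    test_sets: dict[str, tuple[np.ndarray, np.ndarray]],
    fl_cfg: FLConfig,
    model_builder: Callable[[int], Module],
) -> FLResult:
    """Simulate R broadcast-train-merge rounds.

    Every client trains ``local_epochs`` per round with a persistent local
    optimizer; the merged model is evaluated on every named test set after
    each round. Total local epochs per client equal ``rounds * local_epochs``
    and are tallied in the result for bookkeeping checks.
    """
    if not clients:
        raise ValueError("need at least one client")
    for name, data in clients.items():
        if data.train[0].shape[0] == 0:
            raise ValueError(f"client {name!r} has an empty training set")

    cfg = fl_cfg.client_config
    global_model = model_builder(fl_cfg.seed)
    local = {
        name: {
            "model": model_builder(fl_cfg.seed),
            "opt": Adam(cfg.learning_rate),
            "epochs": 0,
        }
        for name in clients
    }
    counts = [clients[name].train[0].shape[0] for name in clients]
    records: list[RoundRecord] = []
    for r in range(fl_cfg.rounds):
        broadcast = global_model.state_dict()
        states = []
        losses = {}
        for name in clients:
            st = local[name]
            st["model"].load_state_dict(broadcast)
            epoch_losses = run_epochs(
                st["model"], st["opt"], softmax_cross_entropy,
                clients[name].train[0], clients[name].train[1],
                epochs=fl_cfg.local_epochs, batch_size=cfg.batch_size,
                base_seed=cfg.seed, epoch_offset=r * fl_cfg.local_epochs,
            )
            st["epochs"] += fl_cfg.local_epochs
            losses[name] = float(np.mean(epoch_losses))
            states.append(st["model"].state_dict())
        merged = fedavg_merge(states, counts, fl_cfg.weighting)
        global_model.load_state_dict(merged)
        f1s = {
            name: res["f1"] for name, res in evaluate_f1(global_model, test_sets).items()
        }
        records.append(RoundRecord(round_index=r, client_losses=losses, test_f1=f1s))
    return FLResult(
        model=global_model,
        rounds=records,
        client_epochs={name: local[name]["epochs"] for name in clients},
    )


def rounds_epochs_sweep(
    clients: dict[str, ClientData],
    test_sets: dict[str, tuple[np.ndarray, np.ndarray]],
    combos: list[tuple[int, int]],
    base_cfg: FLConfig,
    model_builder: Callable[[int], Module],
) -> tuple[pd.DataFrame, dict[tuple[int, int], list[RoundRecord]]]:
    """Run the federation once per (rounds, local_epochs) combination.

    All combinations start from the same seeded initial model. Emits a table
    of final per-test-set F1 per combination plus the full per-round traces.
    Combinations with differing total local epochs trigger a warning since
    they are not comparable on equal compute.
    """
    totals = {r * e for r, e in combos}
    if len(totals) > 1:
        warnings.warn(f"combos differ in total local epochs: {sorted(totals)}")
    rows = []
    traces = {}
    for rounds, epochs in combos:
        cfg = replace(base_cfg, rounds=rounds, local_epochs=epochs)
        result = run_federated(clients, test_sets, cfg, model_builder)
        traces[(rounds, epochs)] = result.rounds
        row = {"rounds": rounds, "local_epochs": epochs, "total_epochs": rounds * epochs}
        row.update({f"f1_{name}": f1 for name, f1 in result.rounds[-1].test_f1.items()})
        rows.append(row)
    return pd.DataFrame(rows), traces


# ---------------------------------------------------------------------------
# Harmonization ablation
# ---------------------------------------------------------------------------

def default_heterogeneous_profiles() -> list[HospitalProfile]:
    """Two hospitals that stress the harmonization: disjoint raw intensity
    ranges, opposite photometric conventions, and artifact-heavy acquisition
    at the first hospital."""
    return [
        HospitalProfile(
            hospital_id="H1",
            intensity_range=(50.0, 1050.0),
            photometric="MONOCHROME2",
            label_prob=0.95,
            clip_prob=0.5,
            spacing_mm=(0.7, 0.7),
        ),
        HospitalProfile(
            hospital_id="H2",
            intensity_range=(3000.0, 4095.0),
            photometric="MONOCHROME1",
            label_prob=0.1,
            spacing_mm=(0.7, 0.7),
        ),
    ]


def harmonization_ablation(
    cohort: Cohort | None = None,
    seed: int = 0,
    n_patients: int = 150,
    image_size: int = 64,
    fl_rounds: int = 20,
    local_epochs: int = 5,
    learning_rate: float = 3e-3,
    unet_epochs: int = 3,
) -> dict:
    """Contrast minimal pre-processing against the full harmonization pipeline.

    Condition A runs only the metadata harmonization (rescale, inversion,
    laterality, resize) and normalizes per client — printed labels and clips
    stay in the images and no statistics are shared; condition B additionally
    trains a breast-area UNet on bootstrapped masks, cleans and crops every
    image, and shares global normalization statistics across clients. Both
    conditions train the same federated classifier from the same initial
    model and report per-hospital F1, the worst-hospital F1 and the
    inter-hospital spread.
    """
    if cohort is None:
        cohort = generate_cohort(
            n_patients=n_patients,
            images_per_patient=2,
            profiles=default_heterogeneous_profiles(),
            seed=seed,
            image_size=(image_size * 2, image_size * 2),
        )
    manifest = cohort.manifest.copy()
    manifest["record_index"] = np.arange(len(manifest))
    _warn_if_homogeneous(manifest, cohort.records)

    kept, _ = filter_cohort(manifest)
    splits = {
        hospital: patientwise_split(grp, SplitSpec(seed=seed))
        for hospital, grp in kept.groupby("hospital_id")
    }
    fed = assemble_federation(splits)
    # evaluate on each hospital's held-out patients (validation + test) to
    # keep per-hospital F1 estimates stable at this cohort size
    eval_rows = {
        name: pd.concat([fed.clients[name]["val"], fed.test_sets[name]], ignore_index=True)
        if name in fed.clients
        else fed.test_sets[name]
        for name in fed.test_sets
    }

    size = (image_size, image_size)
    records = cohort.records

    def arrays_minimal(rows):
        X = np.stack(
            [preprocess(records[i], target_size=size).pixels for i in rows.record_index]
        )
        y = rows.birads.to_numpy() - 1
        return X, y

    # Condition A: metadata harmonization only, per-client normalization
    cond_a = _train_condition(fed, eval_rows, arrays_minimal, per_client_norm=True,
                              seed=seed, fl_rounds=fl_rounds,
                              local_epochs=local_epochs, lr=learning_rate,
                              image_size=image_size)

    # Condition B: full pipeline — harmonize, BAD-clean, shared normalization
    pre = {}
    for i, rec in enumerate(records):
        pre[i] = preprocess(rec, target_size=(image_size * 2, image_size * 2))
    train_rows = pd.concat([c["train"] for c in fed.clients.values()])
    bad_inputs = [pre[i].pixels for i in train_rows.record_index[:40]]
    auld = build_auld(bad_inputs, k=2, cfg=AugmentationConfig(n_variants=5, seed=seed))
    n_samples = len(auld.samples)
    n_tr = max(5, int(0.8 * n_samples) // 5 * 5)
    seg_cfg = SegTrainConfig(
        n_train=n_tr, n_val=max(5, n_samples - n_tr), epochs=unet_epochs,
        seed=seed, base_channels=4, depth=3,
    )
    unet, _ = train_unet(auld.samples[:n_tr], auld.samples[n_tr:], seg_cfg)

    def arrays_full(rows):
        imgs = []
        for i in rows.record_index:
            img = pre[i].pixels
            mask = predict_mask(unet, img)
            if mask.any():
                imgs.append(clean_and_crop(img, mask, margin=2, out_size=size))
            else:
                imgs.append(_resize(img, size, order=1))
        return np.stack(imgs), rows.birads.to_numpy() - 1

    cond_b = _train_condition(fed, eval_rows, arrays_full, per_client_norm=False,
                              seed=seed, fl_rounds=fl_rounds,
                              local_epochs=local_epochs, lr=learning_rate,
                              image_size=image_size)
    return {"minimal": cond_a, "full_pipeline": cond_b}


def _warn_if_homogeneous(manifest, records) -> None:
    """Warn when the cohort's hospitals do not actually differ.

    The ablation is only meaningful on a heterogeneous federation; hospitals
    with near-identical empirical intensity ranges (or a single hospital)
    give statistically indistinguishable conditions.
    """
    hospitals = manifest.hospital_id.unique()
    if len(hospitals) < 2:
        warnings.warn("cohort is not heterogeneous (fewer than two hospitals)")
        return
    ranges = {}
    for h in hospitals:
        idx = manifest.loc[manifest.hospital_id == h, "record_index"]
        lo = min(float(records[i].pixels.min()) for i in idx)
        hi = max(float(records[i].pixels.max()) for i in idx)
        ranges[h] = (lo, hi)
    (lo_a, hi_a), (lo_b, hi_b) = (ranges[h] for h in list(hospitals)[:2])
    overlap = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    span = max(hi_a - lo_a, hi_b - lo_b)
    if span > 0 and overlap / span > 0.9:
        warnings.warn(
            "cohort is not heterogeneous (hospital intensity ranges nearly coincide); "
            "the two conditions will be statistically indistinguishable"
        )


def _train_condition(fed, eval_rows, make_arrays, per_client_norm, seed, fl_rounds,
                     local_epochs, lr, image_size):
    raw_clients = {}
    for name, parts in fed.clients.items():
        raw_clients[name] = {
            "train": make_arrays(parts["train"]),
            "val": make_arrays(parts["val"]),
        }
    raw_tests = {name: make_arrays(rows) for name, rows in eval_rows.items()}

    if per_client_norm:
        stats = {
            name: compute_norm_stats([d["train"][0]]) for name, d in raw_clients.items()
        }
        any_stats = next(iter(stats.values()))
        norm_for_test = {name: stats.get(name, any_stats) for name in raw_tests}
    else:
        # global min/max merged across clients before round 1
        per_client = [compute_norm_stats([d["train"][0]]) for d in raw_clients.values()]
        merged = NormStats(
            pixel_min=min(s.pixel_min for s in per_client),
            pixel_max=max(s.pixel_max for s in per_client),
        )
        stats = {name: merged for name in raw_clients}
        norm_for_test = {name: merged for name in raw_tests}

    clients = {
        name: ClientData(
            train=(normalize(d["train"][0], stats[name]).astype(np.float32), d["train"][1]),
            val=(normalize(d["val"][0], stats[name]).astype(np.float32), d["val"][1]),
        )
        for name, d in raw_clients.items()
    }
    tests = {
        name: (normalize(X, norm_for_test[name]).astype(np.float32), y)
        for name, (X, y) in raw_tests.items()
    }
    fl_cfg = FLConfig(
        rounds=fl_rounds,
        local_epochs=local_epochs,
        client_config=TrainConfig(learning_rate=lr, batch_size=10, epochs=1, seed=seed),
        seed=seed,
    )
    builder = lambda s: build_model(input_size=(image_size, image_size), seed=s)
    result = run_federated(clients, tests, fl_cfg, builder)
    # average the last rounds: round-to-round merge noise is large at this scale
    tail = result.rounds[-3:]
    f1s = {
        name: float(np.mean([r.test_f1[name] for r in tail]))
        for name in tail[-1].test_f1
    }
    return {
        "per_hospital_f1": f1s,
        "worst_f1": min(f1s.values()),
        "spread": max(f1s.values()) - min(f1s.values()),
    }
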