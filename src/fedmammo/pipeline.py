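"""The composed end-to-end workflow on a synthetic federation.

One call runs every stage in order — cohort synthesis, metadata
harmonization, breast-area bootstrap and UNet training, mask-guided
cleaning, patient-wise splitting, federated training, per-hospital
evaluation — writing each stage's outputs under one directory and recording
a run manifest with a content hash per file, so a rerun with the same
configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import AugmentationConfig, build_auld
from .classifier import NormStats, TrainConfig, build_model, compute_norm_stats, normalize
from .cohort import SplitSpec, assemble_federation, filter_cohort, patientwise_split
from .federated import ClientData, FLConfig, run_federated
from .io import save_model
from .preprocess import _resize, preprocess
from .segmenter import SegTrainConfig, clean_and_crop, predict_mask, train_unet
from .synthetic import HospitalProfile, generate_cohort


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end demo run."""

    out_dir: str = "fedmammo_run"
    n_patients: int = 60
    images_per_patient: int = 2
    image_size: int = 64          # classifier input side
    profiles: list[HospitalProfile] | None = None
    test_only_hospitals: set[str] = field(default_factory=set)
    use_bad: bool = True          # False switches to the minimal-preprocessing path
    unet_epochs: int = 3
    bootstrap_images: int = 30
    fl_rounds: int = 10
    local_epochs: int = 2
    learning_rate: float = 3e-3
    batch_size: int = 10
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[dict]
    files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_end_to_end(cfg: PipelineConfig) -> RunManifest:
    """Run every stage in order; any stage failure names the stage."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    files: dict[str, str] = {}
    state: dict = {}

    def record(path: Path) -> None:
        files[str(path.relative_to(out))] = _sha256(path)

    steps = [
        ("synth", _stage_synth),
        ("preprocess", _stage_preprocess),
        ("bad", _stage_bad),
        ("split", _stage_split),
        ("fed-train", _stage_fed_train),
        ("evaluate", _stage_evaluate),
    ]
    for name, fn in steps:
        try:
            info = fn(cfg, state, out, record)
        except Exception as exc:
            raise StageFailure(name, exc) from exc
        stages.append({"stage": name, **info})

    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        version=__version__,
        stages=stages,
        files=files,
    )
    (out / "run_manifest.json").write_text(manifest.to_json())
    return manifest


def _stage_synth(cfg, state, out, record):
    profiles = cfg.profiles or [
        HospitalProfile("H1", intensity_range=(50, 1050), label_prob=0.6, clip_prob=0.3),
        HospitalProfile("H2", intensity_range=(3000, 4095), photometric="MONOCHROME1"),
    ]
    cohort = generate_cohort(
        n_patients=cfg.n_patients,
        images_per_patient=cfg.images_per_patient,
        profiles=profiles,
        seed=cfg.seed,
        image_size=(cfg.image_size * 2, cfg.image_size * 2),
    )
    manifest = cohort.manifest.copy()
    manifest["record_index"] = np.arange(len(manifest))
    path = out / "cohort.csv"
    manifest.to_csv(path, index=False)
    record(path)
    state["cohort"] = cohort
    state["manifest"] = manifest
    return {"n_images": len(manifest), "n_patients": cfg.n_patients}


def _stage_preprocess(cfg, state, out, record):
    size = (cfg.image_size * 2, cfg.image_size * 2)
    state["pre"] = [preprocess(r, target_size=size) for r in state["cohort"].records]
    return {"target_size": list(size)}


def _stage_bad(cfg, state, out, record):
    size = (cfg.image_size, cfg.image_size)
    pre = state["pre"]
    if not cfg.use_bad:
        state["inputs"] = [_resize(p.pixels, size, order=1) for p in pre]
        return {"skipped": True}
    auld = build_auld(
        [p.pixels for p in pre[: cfg.bootstrap_images]],
        k=2,
        cfg=AugmentationConfig(n_variants=5, seed=cfg.seed),
    )
    n = len(auld.samples)
    n_tr = max(5, int(0.8 * n) // 5 * 5)
    seg_cfg = SegTrainConfig(
        n_train=n_tr, n_val=max(5, n - n_tr), epochs=cfg.unet_epochs,
        seed=cfg.seed, base_channels=4, depth=3,
    )
    unet, history = train_unet(auld.samples[:n_tr], auld.samples[n_tr:], seg_cfg)
    hist_path = out / "bad_history.csv"
    pd.DataFrame(history).to_csv(hist_path, index=False)
    record(hist_path)
    save_model(unet, out / "bad_model", {"kind": "unet", "base": 4, "depth": 3})
    record(out / "bad_model.npz")
    record(out / "bad_model.json")
    inputs = []
    for p in pre:
        mask = predict_mask(unet, p.pixels)
        if mask.any():
            inputs.append(clean_and_crop(p.pixels, mask, margin=2, out_size=size))
        else:
            inputs.append(_resize(p.pixels, size, order=1))
    state["inputs"] = inputs
    return {"auld_size": n, "final_val_dice": history[-1]["val_dice"]}


def _stage_split(cfg, state, out, record):
    kept, report = filter_cohort(state["manifest"])
    splits = {
        h: patientwise_split(grp, SplitSpec(seed=cfg.seed))
        for h, grp in kept.groupby("hospital_id")
    }
    fed = assemble_federation(splits, test_only=cfg.test_only_hospitals)
    assignment = {
        h: {
            part: sorted(rows.patient_id.unique())
            for part, rows in zip(("train", "val", "test"), splits[h])
        }
        for h in splits
    }
    path = out / "splits.json"
    path.write_text(json.dumps({"exclusions": report, "assignment": assignment}, indent=2))
    record(path)
    state["fed"] = fed
    return {"exclusions": report, "n_clients": len(fed.clients)}


def _stage_fed_train(cfg, state, out, record):
    fed = state["fed"]
    inputs = state["inputs"]

    def arrays(rows):
        X = np.stack([inputs[i] for i in rows.record_index])
        return X, rows.birads.to_numpy() - 1

    raw = {
        name: {"train": arrays(p["train"]), "val": arrays(p["val"])}
        for name, p in fed.clients.items()
    }
    per_client = [compute_norm_stats([d["train"][0]]) for d in raw.values()]
    stats = NormStats(
        pixel_min=min(s.pixel_min for s in per_client),
        pixel_max=max(s.pixel_max for s in per_client),
    )
    clients = {
        name: ClientData(
            train=(normalize(d["train"][0], stats).astype(np.float32), d["train"][1]),
            val=(normalize(d["val"][0], stats).astype(np.float32), d["val"][1]),
        )
        for name, d in raw.items()
    }
    # hospitals too small to receive test patients are evaluated on their
    # validation patients instead (still held out from training)
    tests = {}
    for name, rows in fed.test_sets.items():
        if rows.empty and name in fed.clients:
            rows = fed.clients[name]["val"]
        if rows.empty:
            continue
        X, y = arrays(rows)
        tests[name] = (normalize(X, stats).astype(np.float32), y)
    fl_cfg = FLConfig(
        rounds=cfg.fl_rounds,
        local_epochs=cfg.local_epochs,
        client_config=TrainConfig(
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
            epochs=1, seed=cfg.seed,
        ),
        seed=cfg.seed,
    )
    builder = lambda s: build_model(input_size=(cfg.image_size, cfg.image_size), seed=s)
    result = run_federated(clients, tests, fl_cfg, builder)
    hist = pd.DataFrame(
        [
            {"round": r.round_index, **{f"loss_{k}": v for k, v in r.client_losses.items()},
             **{f"f1_{k}": v for k, v in r.test_f1.items()}}
            for r in result.rounds
        ]
    )
    path = out / "fl_history.csv"
    hist.to_csv(path, index=False)
    record(path)
    save_model(
        result.model, out / "classifier",
        {"kind": "cnn", "n_classes": 5, "base": 8, "n_blocks": 3},
    )
    record(out / "classifier.npz")
    record(out / "classifier.json")
    state["result"] = result
    return {"rounds": cfg.fl_rounds, "client_epochs": result.client_epochs}


def _stage_evaluate(cfg, state, out, record):
    final = state["result"].rounds[-1].test_f1
    path = out / "evaluation.json"
    path.write_text(json.dumps({"per_hospital_f1": final}, indent=2))
    record(path)
    return {"per_hospital_f1": final}
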