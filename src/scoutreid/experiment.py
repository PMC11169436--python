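"""End-to-end experiment orchestration on the synthetic cohort.

Ties the pipeline together: generate a phantom cohort, preprocess onto
the common grid, train the embedding extractor (optionally with the
width-only scaling augmentation), enroll baselines, match follow-ups and
evaluate.  The paired with/without-augmentation comparison used to probe
the augmentation's cross-vendor benefit lives here too.

Default desk-scale study conditions: 96 phantom patients (36 training
patients with three exams each, one held out for validation; 60 test
patients with a baseline and a follow-up exam), two vendors assigned per
exam at random, 150 training epochs at a desk-scale learning rate of
0.02 -> 0.002, on a 4-mm working grid that feeds the same effective
8-mm backbone input as the full-resolution pipeline.  The epoch count is the model-selection knob: training
runs a fixed budget and the final weights are deployed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentConfig
from .embedder import ScoutEmbedder
from .evaluate import EvalReport, stratified_eval
from .io_preproc import PreprocessConfig, ScoutPreprocessor
from .matcher import GalleryMatcher
from .phantom import CohortSpec, generate_cohort

__all__ = [
    "ExperimentConfig",
    "default_cohort_spec",
    "build_dataset",
    "run_trial",
    "run_augmentation_comparison",
    "overtraining_drift",
    "run_overtraining_probe",
    "run_demo",
]


@dataclass
class ExperimentConfig:
    """One experiment = cohort design + preprocessing + augmentation + training.

    Round-trips through YAML bit-exactly (`to_yaml` / `from_yaml`); every
    demo run writes its resolved config next to its artifacts.
    """

    n_patients: int = 96
    exams_per_patient: int = 3
    vendor_policy: str = "random-exam"
    trainval_fraction: float = 0.375
    followup_fraction: float = 1.0
    master_seed: int = 0
    epochs: int = 150
    batch_size: int = 20
    lr_init: float = 0.02
    lr_final: float = 0.002
    similarity_diag_every: int = 25
    track_validation: bool = False
    feature_dim: int = 64
    width: int = 6
    embed_dim: int = 64
    # desk working resolution: 4 mm / 192 x 128 with a 2x stem reaches the
    # same 8-mm internal grid as the full 2 mm / 384 x 256 pipeline
    working_spacing: float = 4.0
    working_rows: int = 192
    working_cols: int = 128
    stem_pool: int = 2
    use_rts: bool = True  # RandomTransversalScaling on/off
    transversal_factor: float = 1.04
    transversal_prob: float = 0.25
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_cohort_spec(
    n_patients: int = 96,
    master_seed: int = 0,
    exams_per_patient: int = 3,
    trainval_fraction: float = 0.375,
    vendor_policy: str = "random-exam",
    followup_fraction: float = 1.0,
) -> CohortSpec:
    """Cohort design used by the desk-scale experiments."""
    train_frac = trainval_fraction * (exams_per_patient - 1) / exams_per_patient
    val_frac = trainval_fraction / exams_per_patient
    return CohortSpec(
        n_patients=n_patients,
        exams_per_patient=exams_per_patient,
        vendor_policy=vendor_policy,
        split=(train_frac, val_frac, 1.0 - trainval_fraction),
        followup_fraction=followup_fraction,
        master_seed=master_seed,
    )


def build_dataset(spec: CohortSpec, preprocess_config: PreprocessConfig | None = None) -> dict:
    """Generate a cohort and preprocess every image onto a common grid.

    Returns arrays keyed by pipeline role: training and validation images
    with patient labels, and the test baseline (gallery) / follow-up
    (query) images with ids and vendor tags.
    """
    manifest, images = generate_cohort(spec)
    cfg = preprocess_config or PreprocessConfig()
    pre = ScoutPreprocessor(
        target_spacing=cfg.target_spacing, crop_rows=cfg.crop_rows, crop_cols=cfg.crop_cols
    ).fit([])
    X = pre.transform(images)

    def sel(mask):
        idx = np.flatnonzero(mask.to_numpy())
        sub = manifest.iloc[idx]
        return {
            "images": X[idx],
            "labels": sub.patient_id.to_numpy(),
            "vendors": sub.vendor.to_numpy(),
        }

    return {
        "manifest": manifest,
        "train": sel(manifest.split == "train"),
        "val": sel(manifest.split == "val"),
        "baseline": sel(manifest.role == "baseline"),
        "followup": sel(manifest.role == "follow-up"),
    }


def _working_preprocess(config: ExperimentConfig) -> PreprocessConfig:
    return PreprocessConfig(
        target_spacing=(config.working_spacing, config.working_spacing),
        crop_rows=config.working_rows,
        crop_cols=config.working_cols,
    )


def run_trial(
    config: ExperimentConfig, seed: int | None = None, data: dict | None = None
) -> tuple[EvalReport, pd.DataFrame]:
    """One full generate -> train -> enroll -> match -> evaluate run.

    Returns the stratified evaluation report and the per-epoch training
    history (loss, AdaCos scale, validation ACC1, genuine/impostor
    similarity statistics).  A prebuilt ``data`` dict (from
    :func:`build_dataset`) can be passed to share one cohort between
    paired runs.
    """
    seed = config.master_seed if seed is None else seed
    if data is None:
        spec = default_cohort_spec(
            n_patients=config.n_patients,
            master_seed=seed,
            exams_per_patient=config.exams_per_patient,
            trainval_fraction=config.trainval_fraction,
            vendor_policy=config.vendor_policy,
            followup_fraction=config.followup_fraction,
        )
        data = build_dataset(spec, _working_preprocess(config))
    aug = AugmentConfig(
        transversal_factor=config.transversal_factor if config.use_rts else 1.0,
        transversal_prob=config.transversal_prob if config.use_rts else 0.0,
        crop_rows=config.working_rows,
        crop_cols=config.working_cols,
    )
    emb = ScoutEmbedder(
        feature_dim=config.feature_dim,
        width=config.width,
        stem_pool=config.stem_pool,
        embed_dim=config.embed_dim,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr_init=config.lr_init,
        lr_final=config.lr_final,
        augment=aug,
        similarity_diag_every=config.similarity_diag_every,
        random_state=seed,
    )
    emb.fit(
        data["train"]["images"],
        data["train"]["labels"],
        X_val=data["val"]["images"] if config.track_validation else None,
        y_val=data["val"]["labels"] if config.track_validation else None,
        probe=(
            data["followup"]["images"],
            data["followup"]["labels"],
            data["baseline"]["images"],
            data["baseline"]["labels"],
        ),
    )

    gal = data["baseline"]
    matcher = GalleryMatcher().fit(
        emb.transform(gal["images"]), gal["labels"], vendors=gal["vendors"]
    )
    q = data["followup"]
    sm = matcher.similarity(
        emb.transform(q["images"]), query_ids=q["labels"], query_vendors=q["vendors"]
    )
    return stratified_eval(sm), emb.history_


def run_augmentation_comparison(
    seeds: tuple[int, ...] = (0, 1, 2),
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Paired runs with and without the width-only scaling augmentation.

    For each seed, the cohort, initialization and batch order are shared
    between the two conditions (only the augmentation differs), so the
    comparison is paired in the McNemar sense.  Returns one row per
    (seed, condition) with overall/same-vendor/different-vendor ACC1 and
    the mid/late impostor-mean diagnostic.
    """
    base = config or ExperimentConfig()
    rows = []
    for seed in seeds:
        spec = default_cohort_spec(
            n_patients=base.n_patients,
            master_seed=seed,
            exams_per_patient=base.exams_per_patient,
            trainval_fraction=base.trainval_fraction,
            vendor_policy=base.vendor_policy,
            followup_fraction=base.followup_fraction,
        )
        data = build_dataset(spec, _working_preprocess(base))
        for use_rts in (False, True):
            cfg = dataclasses.replace(base, use_rts=use_rts)
            report, history = run_trial(cfg, seed=seed, data=data)
            sim = history.dropna(subset=["probe_impostor_mean"]) if "probe_impostor_mean" in history else history
            mid = sim.iloc[len(sim) // 2]
            late = sim.iloc[-1]
            rows.append(
                {
                    "seed": seed,
                    "rts": use_rts,
                    "acc1_entire": report.acc[1],
                    "acc10_entire": report.acc.get(10, float("nan")),
                    "acc1_same_vendor": report.same_vendor["acc1"],
                    "acc1_different_vendor": report.different_vendor["acc1"],
                    "n_same": report.same_vendor["n"],
                    "n_different": report.different_vendor["n"],
                    "impostor_mean_mid": mid.get("probe_impostor_mean", float("nan")),
                    "impostor_mean_late": late.get("probe_impostor_mean", float("nan")),
                    "genuine_mean_late": late.get("probe_genuine_mean", float("nan")),
                }
            )
    return pd.DataFrame(rows)


def overtraining_drift(history: pd.DataFrame) -> dict:
    """Drift of the probe impostor similarity over the second half of training.

    Compares the similarity checkpoint nearest the halfway epoch with the
    final one.  By halfway the training loss has long converged on the
    probe cohorts used here, so a positive drift means unseen identities'
    impostor pairs became *more* similar as training continued past
    convergence — the overtraining signature.
    """
    sim = history.dropna(subset=["probe_impostor_mean"])
    if len(sim) < 3:
        raise ValueError("history carries too few probe checkpoints")
    half = history.epoch.max() / 2.0
    mid = sim.iloc[int(np.argmin(np.abs(sim.epoch.to_numpy() - half)))]
    late = sim.iloc[-1]
    return {
        "mid_epoch": int(mid.epoch),
        "late_epoch": int(late.epoch),
        "impostor_mid": float(mid.probe_impostor_mean),
        "impostor_late": float(late.probe_impostor_mean),
        "drift": float(late.probe_impostor_mean - mid.probe_impostor_mean),
    }


def run_overtraining_probe(seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Train far past convergence on a reduced cohort and measure the drift.

    Uses 24 phantom patients for 400 epochs with augmentation disabled —
    at desk scale the augmentation noise masks the memorization effect,
    so the probe removes it to expose the signature.  The training loss
    plateaus before epoch 100 here; everything after is over-training.
    Probes the (disjoint) test identities every 20 epochs.
    """
    cfg = ExperimentConfig(
        n_patients=24,
        epochs=400,
        similarity_diag_every=20,
        master_seed=seed,
    )
    spec = default_cohort_spec(
        n_patients=cfg.n_patients, master_seed=seed, trainval_fraction=cfg.trainval_fraction
    )
    data = build_dataset(spec, _working_preprocess(cfg))
    emb = ScoutEmbedder(
        feature_dim=cfg.feature_dim,
        width=cfg.width,
        stem_pool=cfg.stem_pool,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr_init=cfg.lr_init,
        lr_final=cfg.lr_final,
        augment=None,
        similarity_diag_every=cfg.similarity_diag_every,
        random_state=seed,
    )
    emb.fit(
        data["train"]["images"],
        data["train"]["labels"],
        probe=(
            data["followup"]["images"],
            data["followup"]["labels"],
            data["baseline"]["images"],
            data["baseline"]["labels"],
        ),
    )
    return overtraining_drift(emb.history_), emb.history_


def run_demo(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Full demo run writing every artifact: dataset manifest, training
    history, gallery archive, evaluation report and resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report, history = run_trial(config)
    history.to_csv(out / "history.csv", index=False)
    report_dict = report.as_dict()
    (out / "report.json").write_text(json.dumps(report_dict, indent=1))
    pd.DataFrame(
        {"K": np.arange(1, len(report.cmc) + 1), "accuracy": report.cmc}
    ).to_csv(out / "cmc.csv", index=False)
    return report_dict
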