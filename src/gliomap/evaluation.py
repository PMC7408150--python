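"""Confusion-matrix metrics, multi-run experiments and ablations.

A "run" is one fresh patient-separated partition followed by the full
pipeline (optional CycleGAN mapping -> optional DCGAN augmentation +
CAE pre-training -> supervised refinement -> test evaluation); the
headline report averages slice-level test metrics over several runs
(mean ± sample standard deviation). The ablation harness evaluates the
arms {A only, B only, A∪B unmapped, Ã∪B mapped} x {with, without
pre-training} plus an augmentation-size sweep.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import augmentation as aug
from . import classifier as clf_mod
from . import domain_mapping as dm
from . import phantom as ph
from . import preprocess as pp


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive_class=1) -> ConfusionCounts:
    """TP/FP/TN/FN with "positive" = codeletion / IDH mutation."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricsError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(tp=int(np.sum(pos_t & pos_p)),
                           fp=int(np.sum(~pos_t & pos_p)),
                           tn=int(np.sum(~pos_t & ~pos_p)),
                           fn=int(np.sum(pos_t & ~pos_p)))


def metrics(counts: ConfusionCounts):
    """(accuracy, precision, recall, f1); undefined ratios return None.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2·P·R/(P+R).
    """
    if counts.total == 0:
        raise MetricsError("empty evaluation set")
    acc = (counts.tp + counts.tn) / counts.total
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if prec is None or rec is None or prec + rec == 0:
        f1 = None
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return acc, prec, rec, f1


@dataclass
class MetricsReport:
    """Per-run metric rows plus mean ± sample std (n-1 denominator)."""

    rows: list = field(default_factory=list)

    def add(self, run: int, seed: int, counts: ConfusionCounts, **extra):
        acc, prec, rec, f1 = metrics(counts)
        self.rows.append({"run": run, "seed": seed,
                          "tp": counts.tp, "fp": counts.fp,
                          "tn": counts.tn, "fn": counts.fn,
                          "accuracy": acc, "precision": prec,
                          "recall": rec, "f1": f1, **extra})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> dict:
        df = self.to_dataframe()
        out = {}
        for m in ("accuracy", "precision", "recall", "f1"):
            vals = df[m].dropna().astype(float)
            out[f"{m}_mean"] = float(vals.mean()) if len(vals) else None
            out[f"{m}_std"] = (float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return out


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Scaled-down full-pipeline experiment on phantom cohorts."""

    phantom: ph.PhantomConfig = None
    crop_size: int = 24
    slices_per_patient: int = 4
    minority_multiplier: int = 1
    minority_class: int | None = None
    label_attr: str = "label_1p19q"
    fractions: tuple = (0.6, 0.2, 0.2)
    use_mapping: bool = True
    use_pretraining: bool = True
    #: DCGAN-synthesized images per class for pre-training
    augment_per_class: int = 48
    cyclegan_epochs: int = 8
    dcgan_epochs: int = 4
    cae_epochs: int = 15
    refine: clf_mod.RefineConfig = None
    seed: int = 0

    def __post_init__(self):
        if self.phantom is None:
            self.phantom = ph.PhantomConfig(
                image_size=32, slices_per_patient=6,
                n_patients={(d, c): 16 for d in ph.DOMAINS for c in (0, 1)},
                seed=self.seed)
        if self.refine is None:
            self.refine = clf_mod.RefineConfig(epochs=20, patience=20,
                                               seed=self.seed)

    def config_hash(self) -> str:
        # repr-based: asdict payloads contain tuple-keyed dicts
        payload = repr(asdict(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _tiny_cyclegan_spec(cfg: ExperimentConfig, seed: int) -> dm.CycleGANSpec:
    # no-downsample generator: at small phantom sizes a stride-2 stage
    # would alias away the class texture the mapping must preserve;
    # stride-1 first discriminator layer keeps it sensitive to that
    # texture band, and a light cycle weight plus an identity term keep
    # the mapping content-preserving without steganographic cycles
    return dm.CycleGANSpec(image_size=cfg.phantom.image_size, channels=3,
                           gen_enc_filters=(8,), gen_res_blocks=1,
                           gen_dec_filters=(), disc_filters=(8, 16),
                           disc_strides=(1, 2),
                           lambda_cyc=1.0, lambda_identity=1.0,
                           epochs=cfg.cyclegan_epochs,
                           lr_decay_start=max(1, cfg.cyclegan_epochs // 2),
                           batch_size=4, seed=seed)


def _tiny_dcgan_spec(cfg: ExperimentConfig, seed: int) -> aug.DCGANSpec:
    return aug.DCGANSpec(image_size=cfg.crop_size, gen_base_filters=32,
                         gen_filters=(16, 8, 8), disc_filters=(8, 16, 16, 32),
                         batch_size=16, max_epochs=cfg.dcgan_epochs, seed=seed)


def _tiny_cae_spec(cfg: ExperimentConfig, seed: int) -> clf_mod.CAESpec:
    return clf_mod.CAESpec.tiny(input_size=cfg.crop_size, seed=seed,
                                epochs=cfg.cae_epochs)


# ---------------------------------------------------------------------------
# single pipeline run
# ---------------------------------------------------------------------------

def map_cohort(cfg: ExperimentConfig, cohort, seed: int | None = None):
    """Train per-modality CycleGANs on all slices and map domain A.

    Domain mapping is an unsupervised preprocessing stage applied once
    to the whole cohort (labels unused), before any partitioning; the
    per-run partitions downstream stay patient-separated regardless.
    Returns the combined cohort Ã ∪ B.
    """
    a = [p for p in cohort if p.domain == "A"]
    b = [p for p in cohort if p.domain == "B"]
    states = {}
    for m in ph.MODALITIES:
        sl_a = np.stack([s.pixels for p in a for s in p.slices[m]])
        sl_b = np.stack([s.pixels for p in b for s in p.slices[m]])
        spec = _tiny_cyclegan_spec(cfg, cfg.seed if seed is None else seed)
        states[m] = dm.train_cyclegan(sl_a, sl_b, spec)
    mapped = dm.map_patients(next(iter(states.values())), a,
                             modality_states=states)
    return dm.combine_domains(mapped, b)


def _arm_patients(cohort, arm, mapped_cohort=None):
    """Patient list for an ablation arm."""
    a = [p for p in cohort if p.domain == "A"]
    b = [p for p in cohort if p.domain == "B"]
    if arm == "A":
        return a
    if arm == "B":
        return b
    if arm == "pooled":
        return dm.combine_domains(a, b)
    if arm == "mapped":
        if mapped_cohort is None:
            raise ValueError("mapped arm needs a mapped cohort")
        return mapped_cohort
    raise ValueError(f"unknown arm {arm!r}")


def _single_run(cfg: ExperimentConfig, arm: str, use_pretraining: bool,
                run_seed: int, augment_per_class: int | None = None,
                cohort=None, mapped_cohort=None):
    """One partition -> (augment + pretrain) -> refine -> test."""
    if cohort is None:
        cohort = ph.generate_cohort(cfg.phantom)
    if arm == "mapped" and mapped_cohort is None:
        mapped_cohort = map_cohort(cfg, cohort, seed=run_seed)
    patients = _arm_patients(cohort, arm, mapped_cohort)
    assignment = pp.partition_patients(patients, cfg.fractions,
                                       seed=run_seed,
                                       label_attr=cfg.label_attr)
    splits = {s: [p for p in patients if assignment[p.patient_id] == s]
              for s in ("train", "val", "test")}
    ds = {s: pp.build_slice_dataset(
        splits[s], k=cfg.slices_per_patient, out_size=cfg.crop_size,
        minority_multiplier=cfg.minority_multiplier,
        minority_class=cfg.minority_class, seed=run_seed)
        for s in splits}

    cae1 = cae2 = None
    if use_pretraining:
        n_aug = cfg.augment_per_class if augment_per_class is None \
            else augment_per_class
        if n_aug > 0:
            pretrain_imgs = {m: [] for m in ph.MODALITIES}
            train = ds["train"]
            for ci, cls in enumerate(np.unique(train.y)):
                sel = train.y == cls
                for m, x in (("T1ce", train.x_t1ce), ("FLAIR", train.x_flair)):
                    spec = _tiny_dcgan_spec(cfg, run_seed + 17 * ci)
                    state = aug.train_dcgan(x[sel], spec)
                    pretrain_imgs[m].append(
                        aug.sample_augmented(state, n_aug, seed=run_seed))
            cae_spec = _tiny_cae_spec(cfg, run_seed)
            cae1 = clf_mod.pretrain_cae(
                np.concatenate(pretrain_imgs["T1ce"]), cae_spec)
            cae2 = clf_mod.pretrain_cae(
                np.concatenate(pretrain_imgs["FLAIR"]), cae_spec)

    refine_cfg = replace(cfg.refine, seed=run_seed)
    clf = clf_mod.refine_train(cae1, cae2, ds["train"], ds["val"],
                               config=refine_cfg,
                               spec=_tiny_cae_spec(cfg, run_seed))
    probs = clf_mod.predict(clf, ds["test"].x_t1ce, ds["test"].x_flair)
    y_pred = np.argmax(probs, axis=1)
    counts = confusion(ds["test"].y, y_pred, positive_class=0)
    return counts, clf, assignment


# ---------------------------------------------------------------------------
# public orchestration
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig, n_runs: int = 5) -> MetricsReport:
    """Multiple fresh-partition runs of the configured pipeline.

    Each run uses a new patient partition (and new downstream training
    seeds) derived from the master seed; the report carries per-run
    metrics and the mean ± σ summary.
    """
    arm = "mapped" if cfg.use_mapping else "pooled"
    cohort = ph.generate_cohort(cfg.phantom)
    mapped = map_cohort(cfg, cohort) if cfg.use_mapping else None
    report = MetricsReport()
    for run in range(1, n_runs + 1):
        run_seed = cfg.seed + 1000 * run
        counts, clf, _ = _single_run(cfg, arm, cfg.use_pretraining, run_seed,
                                     cohort=cohort, mapped_cohort=mapped)
        report.add(run, run_seed, counts, arm=arm,
                   pretrained=cfg.use_pretraining,
                   best_epoch=clf.best_epoch,
                   config_hash=cfg.config_hash())
    return report


def ablation(cfg: ExperimentConfig, seeds=(0, 1, 2),
             sweep_sizes=(0, 24, 48)) -> pd.DataFrame:
    """Arms {A, B, pooled, mapped} x {pretrain, scratch} + size sweep.

    Returns a tidy DataFrame with one row per (arm, pretraining, seed)
    and per sweep point; accuracies are reported, not asserted.
    """
    cohort = ph.generate_cohort(cfg.phantom)
    mapped = map_cohort(cfg, cohort)
    rows = []
    for seed in seeds:
        run_seed = cfg.seed + 1000 + seed
        for arm in ("A", "B", "pooled", "mapped"):
            for pre in (False, True):
                counts, _, _ = _single_run(cfg, arm, pre, run_seed,
                                           cohort=cohort, mapped_cohort=mapped)
                acc, prec, rec, f1 = metrics(counts)
                rows.append({"kind": "arm", "arm": arm, "pretrained": pre,
                             "seed": seed, "accuracy": acc,
                             "precision": prec, "recall": rec, "f1": f1})
        for n_aug in sweep_sizes:
            counts, _, _ = _single_run(cfg, "mapped", n_aug > 0, run_seed,
                                       augment_per_class=n_aug,
                                       cohort=cohort, mapped_cohort=mapped)
            acc, *_ = metrics(counts)
            rows.append({"kind": "sweep", "arm": "mapped",
                         "pretrained": n_aug > 0, "n_augmented": n_aug,
                         "seed": seed, "accuracy": acc})
    return pd.DataFrame(rows)
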