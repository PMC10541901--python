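"""End-to-end orchestration: simulate -> reconstruct -> featurize -> train
-> evaluate, driven by one nested configuration document.

A single global seed fans out to every stochastic stage through
``derive_seed(seed, stage_name)``, so each stage is independently
reproducible and rerunning the same config regenerates byte-identical
evaluation reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mmpol
from mmpol.classifier import TrainConfig, probability_map, save_model, train
from mmpol.evaluate import EvalConfig, EvalReport, cross_validate, derive_seed
from mmpol.features import build_feature_table, save_feature_table
from mmpol.instrument import InstrumentConfig, acquire, save_raw_stack
from mmpol.phantom import (
    CohortConfig,
    PhantomCohort,
    TissueClassSpec,
    abnormal_tissue_spec,
    generate_cohort,
    normal_tissue_spec,
    save_cohort,
)
from mmpol.reconstruct import reconstruct, save_mueller_image

__all__ = ["RunConfig", "run_pipeline", "compare_modes", "default_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Nested configuration of a full pipeline run.

    Every protocol constant of the study appears as a defaulted field of
    the nested configs: 5 wavelengths (450-625 nm), 75/5-dim features, 64
    hidden units, learning rate 1e-5, 10 epochs, k=4 patient-wise folds,
    decision threshold 0.43, specimen percentiles 50-99.
    """

    seed: int = 0
    modes: tuple[str, ...] = ("pol", "nopol")
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    normal_spec: TissueClassSpec = field(default_factory=normal_tissue_spec)
    abnormal_spec: TissueClassSpec = field(default_factory=abnormal_tissue_spec)
    save_intermediates: bool = True

    def __post_init__(self) -> None:
        for mode in self.modes:
            if mode not in ("pol", "nopol"):
                raise ValueError(f"unknown mode {mode!r} (expected 'pol' or 'nopol')")
        if self.eval.k > self.cohort.n_patients:
            raise ValueError(
                f"eval.k={self.eval.k} exceeds cohort.n_patients={self.cohort.n_patients}"
            )
        if self.cohort.wavelengths != self.instrument.wavelengths:
            raise ValueError("cohort.wavelengths must match instrument.wavelengths")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "modes": list(self.modes),
            "instrument": self.instrument.to_dict(),
            "cohort": self.cohort.to_dict(),
            "train": dataclasses.asdict(self.train),
            "eval": {
                **dataclasses.asdict(self.eval),
                "percentiles": list(self.eval.percentiles),
            },
            "normal_spec": self.normal_spec.to_dict(),
            "abnormal_spec": self.abnormal_spec.to_dict(),
            "save_intermediates": self.save_intermediates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs: dict = {
            "seed": int(d.get("seed", 0)),
            "modes": tuple(d.get("modes", ("pol", "nopol"))),
            "save_intermediates": bool(d.get("save_intermediates", True)),
        }
        if "instrument" in d:
            kwargs["instrument"] = InstrumentConfig.from_dict(d["instrument"])
        if "cohort" in d:
            kwargs["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "train" in d:
            kwargs["train"] = TrainConfig(**d["train"])
        if "eval" in d:
            ev = dict(d["eval"])
            if "percentiles" in ev:
                ev["percentiles"] = tuple(int(p) for p in ev["percentiles"])
            kwargs["eval"] = EvalConfig(**ev)
        if "normal_spec" in d:
            kwargs["normal_spec"] = TissueClassSpec.from_dict(d["normal_spec"])
        if "abnormal_spec" in d:
            kwargs["abnormal_spec"] = TissueClassSpec.from_dict(d["abnormal_spec"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config(**overrides) -> RunConfig:
    """A small demonstration configuration (4 patients, 6 samples, 32x32).

    All samples are mixed so that every patient-fold of the k=4 evaluation
    necessarily contains both pixel classes; the cohort is intensity-matched
    (the head-to-head condition where only polarimetric structure separates
    the classes) and a small hotspot fraction exercises the saturation
    bookkeeping.
    """
    base = dict(
        cohort=CohortConfig(
            n_patients=4,
            n_samples=6,
            frac_mixed=1.0,
            frac_normal=0.0,
            frac_abnormal=0.0,
            image_shape=(32, 32),
            intensity_matched=True,
            hotspot_fraction=0.01,
        ),
    )
    base.update(overrides)
    return RunConfig(**base)


def simulate_cohort(config: RunConfig) -> PhantomCohort:
    """Generate the phantom cohort stage of a run (seeded from the config)."""
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=derive_seed(config.seed, "cohort")
    )
    return generate_cohort(cohort_cfg, config.normal_spec, config.abnormal_spec)


def acquire_and_reconstruct(config: RunConfig, cohort: PhantomCohort, out_dir: Path | None):
    """Simulate acquisitions and reconstruct Mueller images for every sample."""
    images = []
    stacks = []
    for s in cohort.samples:
        stem = f"{s.layout.patient_id}_{s.layout.sample_id}"
        stack = acquire(
            s.mm_image, config.instrument, rng_seed=derive_seed(config.seed, f"acquire:{stem}")
        )
        image = reconstruct(stack, config.instrument)
        stacks.append(stack)
        images.append(image)
        if out_dir is not None:
            save_raw_stack(stack, config.instrument, out_dir / "raw" / stem)
            save_mueller_image(image, out_dir / "reconstructed" / stem)
    return stacks, images


def run_pipeline(config: RunConfig | str | Path, out_dir: str | Path) -> dict[str, EvalReport]:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Returns the evaluation reports keyed by feature mode.  Reruns with the
    same config produce byte-identical report JSON.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "raw").mkdir(exist_ok=True)
    (out_dir / "reconstructed").mkdir(exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    cohort = simulate_cohort(config)
    if config.save_intermediates:
        save_cohort(cohort, out_dir / "cohort")
    timings["simulate"] = time.perf_counter() - t0
    counts["samples"] = len(cohort.samples)
    counts["patients"] = len(cohort.patient_ids)

    t0 = time.perf_counter()
    stacks, images = acquire_and_reconstruct(
        config, cohort, out_dir if config.save_intermediates else None
    )
    timings["acquire_reconstruct"] = time.perf_counter() - t0
    counts["total_pixels"] = int(
        sum(np.prod(s.layout.label_mask.shape) for s in cohort.samples)
    )
    counts["saturated_pixels"] = int(sum((~im.valid_mask).sum() for im in images))

    layouts = [s.layout for s in cohort.samples]
    reports: dict[str, EvalReport] = {}
    for mode in config.modes:
        t0 = time.perf_counter()
        table = build_feature_table(images, layouts, mode=mode)
        counts[f"used_pixels_{mode}"] = len(table)
        if config.save_intermediates:
            save_feature_table(table, out_dir / f"features_{mode}.csv")
        train_cfg = dataclasses.replace(
            config.train, seed=derive_seed(config.seed, f"train:{mode}")
        )
        report = cross_validate(table, mode, train_cfg, config.eval)
        report.to_json(out_dir / f"report_{mode}.json")
        report.to_frame().to_csv(out_dir / f"report_{mode}.csv", index=False)

        # one model trained on everything, for probability maps
        full_model = train(table, train_cfg)
        save_model(full_model, out_dir / f"model_{mode}.json")
        if config.save_intermediates:
            maps_dir = out_dir / f"maps_{mode}"
            maps_dir.mkdir(exist_ok=True)
            for s, image in zip(cohort.samples, images):
                stem = f"{s.layout.patient_id}_{s.layout.sample_id}"
                pmap = probability_map(full_model, image, mode=mode)
                _save_probability_map(pmap, maps_dir / stem)
        timings[mode] = time.perf_counter() - t0
        reports[mode] = report
        logger.info(
            "mode=%s mean pixel AUC %.3f +/- %.3f over %d folds",
            mode, report.mean_auc, report.sd_auc, report.k,
        )

    manifest = {
        "package_version": mmpol.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "counts": counts,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return reports


def _save_probability_map(pmap: np.ndarray, prefix: Path) -> None:
    """16-bit PNG (0..65535 maps 0..1) plus a no-data mask."""
    import imageio.v3 as iio

    nodata = ~np.isfinite(pmap)
    scaled = np.where(nodata, 0.0, pmap)
    iio.imwrite(prefix.with_suffix(".png"), (scaled * 65535).round().astype(np.uint16))
    iio.imwrite(prefix.parent / (prefix.name + ".nodata.png"), nodata.astype(np.uint8) * 255)


def misregistration_sweep(
    images,
    layouts,
    shifts: tuple[int, ...] = (0, 3, 6),
    train_config: TrainConfig | None = None,
    test_patients: set[str] | None = None,
    mode: str = "pol",
) -> dict[int, float]:
    """Measured pixel AUC under growing annotation misregistration.

    One model is trained on the unshifted samples of the training patients;
    the held-out patients' label masks are then translated by each shift
    (the optical data stays put) and the pixel AUC re-measured against the
    corrupted annotations.  Larger shifts mislabel more pixels near region
    boundaries, so the measured AUC decays even though the classifier is
    unchanged -- the failure mode of manual histology-to-polarimetry
    registration.
    """
    from mmpol.evaluate import roc_auc
    from mmpol.phantom import corrupt_registration

    train_config = train_config or TrainConfig()
    patients = sorted({l.patient_id for l in layouts})
    if test_patients is None:
        test_patients = set(patients[len(patients) // 2 :])
    train_pairs = [
        (im, l) for im, l in zip(images, layouts) if l.patient_id not in test_patients
    ]
    test_pairs = [(im, l) for im, l in zip(images, layouts) if l.patient_id in test_patients]
    if not train_pairs or not test_pairs:
        raise ValueError("both train and test patients are required")
    table = build_feature_table([p[0] for p in train_pairs], [p[1] for p in train_pairs], mode)
    model = train(table, train_config)
    from mmpol.classifier import _split_table

    out: dict[int, float] = {}
    for shift in shifts:
        corrupted = [corrupt_registration(l, (shift, 0)) for _, l in test_pairs]
        test_table = build_feature_table([p[0] for p in test_pairs], corrupted, mode)
        X, y = _split_table(test_table)
        scores = model.predict_proba(X)[:, 1]
        _, auc = roc_auc(scores, y)
        out[int(shift)] = auc
    return out


def compare_modes(report_pol: EvalReport, report_nopol: EvalReport) -> pd.DataFrame:
    """Paired per-fold AUC comparison of the two feature modes.

    Requires reports from the same cohort and fold split (same test
    patients per fold).
    """
    if len(report_pol.folds) != len(report_nopol.folds):
        raise ValueError(
            f"fold-count mismatch: {len(report_pol.folds)} vs {len(report_nopol.folds)}"
        )
    rows = []
    for fp, fn in zip(report_pol.folds, report_nopol.folds):
        if fp.test_patients != fn.test_patients:
            raise ValueError(f"fold {fp.fold} holds different patients in the two reports")
        rows.append(
            {
                "fold": fp.fold,
                "auc_pol": fp.auc,
                "auc_nopol": fn.auc,
                "auc_difference": fp.auc - fn.auc,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["mean_difference"] = float(table["auc_difference"].mean())
    table.attrs["n_folds_pol_better"] = int((table["auc_difference"] > 0).sum())
    return table
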