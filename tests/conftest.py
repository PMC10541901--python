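"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mmpol.classifier import TrainConfig
from mmpol.evaluate import EvalConfig, cross_validate, derive_seed
from mmpol.features import build_feature_table
from mmpol.instrument import InstrumentConfig, acquire
from mmpol.phantom import CohortConfig, generate_cohort
from mmpol.reconstruct import reconstruct

MASTER_SEED = 20230929


def simulate_cohort_images(cohort_config, instrument_config=None, seed=MASTER_SEED):
    """Generate a cohort and push every sample through acquire + reconstruct."""
    instrument_config = instrument_config or InstrumentConfig()
    cohort = generate_cohort(cohort_config)
    images = []
    for i, s in enumerate(cohort.samples):
        stack = acquire(s.mm_image, instrument_config, rng_seed=derive_seed(seed, f"acq{i}"))
        images.append(reconstruct(stack, instrument_config))
    return cohort, images


@pytest.fixture(scope="session")
def matched_run():
    """Intensity-matched, all-mixed cohort with patient-wise 4-fold CV reports.

    This is the head-to-head comparison condition: both tissue classes share
    the same reflectance distribution, so only polarimetric structure can
    separate them.  8 patients x 12 mixed 32x32 samples, full instrument
    noise, reconstructed (not ground-truth) matrices.
    """
    config = CohortConfig(
        n_patients=8,
        n_samples=12,
        frac_mixed=1.0,
        frac_normal=0.0,
        frac_abnormal=0.0,
        image_shape=(32, 32),
        intensity_matched=True,
        seed=derive_seed(MASTER_SEED, "cohort"),
    )
    cohort, images = simulate_cohort_images(config)
    layouts = [s.layout for s in cohort.samples]
    tables = {m: build_feature_table(images, layouts, m) for m in ("pol", "nopol")}
    reports = {
        m: cross_validate(
            tables[m],
            m,
            TrainConfig(seed=derive_seed(MASTER_SEED, "train")),
            EvalConfig(seed=derive_seed(MASTER_SEED, "folds")),
        )
        for m in ("pol", "nopol")
    }
    return {
        "cohort": cohort,
        "images": images,
        "layouts": layouts,
        "tables": tables,
        "reports": reports,
    }


@pytest.fixture(scope="session")
def misreg_run():
    """Mixed-sample cohort with tight annotations (1 px border) for the
    misregistration experiment: labels trusted close to the region boundary
    are exactly the ones a registration shift corrupts."""
    config = CohortConfig(
        n_patients=6,
        n_samples=8,
        frac_mixed=1.0,
        frac_normal=0.0,
        frac_abnormal=0.0,
        image_shape=(32, 32),
        unlabeled_border_width=1,
        seed=derive_seed(MASTER_SEED, "mis-cohort"),
    )
    cohort, images = simulate_cohort_images(config, seed=MASTER_SEED + 1)
    return {"cohort": cohort, "images": images, "layouts": [s.layout for s in cohort.samples]}


@pytest.fixture(scope="session")
def tiny_cohort():
    """Tiny default-fraction cohort with ground-truth (noise-free) images."""
    config = CohortConfig(
        n_patients=3,
        n_samples=4,
        frac_mixed=0.5,
        frac_normal=0.25,
        frac_abnormal=0.25,
        image_shape=(16, 16),
        seed=7,
    )
    cohort = generate_cohort(config)
    images = [s.mm_image for s in cohort.samples]
    layouts = [s.layout for s in cohort.samples]
    return cohort, images, layouts
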