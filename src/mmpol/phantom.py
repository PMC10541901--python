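"""Synthetic multi-patient cohorts of labeled tissue phantoms.

Each phantom pixel is a physically realizable Mueller matrix built by
forward composition in Lu-Chipman order,

    M = M00 * M_depol(a, b, c) @ M_ret(delta, theta) @ M_diat(d, axis),

with the generative parameters (retardance, fast-axis orientation,
depolarization factors, diattenuation, base reflectance M00) drawn from a
per-tissue-class :class:`TissueClassSpec`.  This composition is a modeling
convention for producing realistic matrices, not a claim about pancreas
microstructure; the classifier downstream never sees these parameters,
only raw matrix values.

Cohort structure emulates a surgical-biopsy study: patients contribute one
or more samples; most samples are single-tissue, a few contain both normal
and abnormal regions separated by an unlabeled border band (annotation
uncertainty at region boundaries); per-patient random offsets on the class
parameters induce intra-patient correlation; a small fraction of specular
"hotspot" pixels saturate the simulated detector; and
:func:`corrupt_registration` emulates annotation misregistration by
translating the label mask while leaving the optical data untouched.

Wavelength dependence: retardance scales as ``lambda_ref / lambda`` and
depolarization increases mildly toward shorter wavelengths, so the five
spectral bands carry distinct but correlated information.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import ndimage

from mmpol import mueller
from mmpol.instrument import DEFAULT_WAVELENGTHS
from mmpol.reconstruct import MuellerImage, save_mueller_image, load_mueller_image

__all__ = [
    "TissueClassSpec",
    "PhantomLayout",
    "PhantomSample",
    "PhantomCohort",
    "CohortConfig",
    "normal_tissue_spec",
    "abnormal_tissue_spec",
    "sample_pixel_matrix",
    "generate_cohort",
    "corrupt_registration",
    "save_cohort",
    "load_cohort",
]

UNLABELED, NORMAL, ABNORMAL = 0, 1, 2

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class TissueClassSpec:
    """Generative polarimetric parameters of one tissue class.

    Retardance is specified at ``reference_wavelength`` and scaled by
    ``reference_wavelength / wavelength`` at other bands; depolarization
    factors are scaled by ``(wavelength / reference_wavelength) **
    depol_dispersion`` (shorter wavelengths depolarize more).  All angles
    in radians; M00 in relative reflectance units.
    """

    name: str
    retardance_mean: float
    retardance_sd: float
    fast_axis_mean: float
    fast_axis_spread: float
    depol_mean: tuple[float, float, float]
    depol_sd: float
    diattenuation_mean: float
    diattenuation_sd: float
    diattenuation_axis: float
    m00_mean: float
    m00_sd: float
    reference_wavelength: float = 625.0
    depol_dispersion: float = 0.3

    def __post_init__(self) -> None:
        for label, sd in (
            ("retardance_sd", self.retardance_sd),
            ("fast_axis_spread", self.fast_axis_spread),
            ("depol_sd", self.depol_sd),
            ("diattenuation_sd", self.diattenuation_sd),
            ("m00_sd", self.m00_sd),
        ):
            if sd < 0:
                raise ValueError(f"{label} must be >= 0")
        if not all(-1.0 <= v <= 1.0 for v in self.depol_mean):
            raise ValueError("depolarization means must lie in [-1, 1]")
        if self.m00_mean <= 0:
            raise ValueError("m00_mean must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depol_mean"] = list(self.depol_mean)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TissueClassSpec":
        d = dict(d)
        d["depol_mean"] = tuple(float(x) for x in d["depol_mean"])
        return cls(**d)


def normal_tissue_spec(**overrides) -> TissueClassSpec:
    """Default generative parameters for the normal class.

    Moderate birefringence, weak depolarization and near-zero
    diattenuation; reflectance around 0.55.
    """
    params = dict(
        name="normal",
        retardance_mean=0.6,
        retardance_sd=0.10,
        fast_axis_mean=0.0,
        fast_axis_spread=0.30,
        depol_mean=(0.85, 0.85, 0.75),
        depol_sd=0.04,
        diattenuation_mean=0.05,
        diattenuation_sd=0.02,
        diattenuation_axis=0.0,
        m00_mean=0.55,
        m00_sd=0.05,
    )
    params.update(overrides)
    return TissueClassSpec(**params)


def abnormal_tissue_spec(**overrides) -> TissueClassSpec:
    """Default generative parameters for the abnormal class.

    Higher retardance (fibrosis/desmoplasia-like collagen signal), stronger
    depolarization and diattenuation, slightly lower reflectance.
    """
    params = dict(
        name="abnormal",
        retardance_mean=1.2,
        retardance_sd=0.15,
        fast_axis_mean=np.pi / 6,
        fast_axis_spread=0.40,
        depol_mean=(0.60, 0.60, 0.48),
        depol_sd=0.05,
        diattenuation_mean=0.12,
        diattenuation_sd=0.03,
        diattenuation_axis=np.pi / 8,
        m00_mean=0.45,
        m00_sd=0.05,
    )
    params.update(overrides)
    return TissueClassSpec(**params)


@dataclass(frozen=True)
class PatientEffect:
    """Per-patient additive offsets on class-parameter means."""

    retardance: float = 0.0
    fast_axis: float = 0.0
    depol: float = 0.0
    m00: float = 0.0


def _draw_patient_effect(rng: np.random.Generator, sd: float) -> PatientEffect:
    return PatientEffect(
        retardance=float(rng.normal(0.0, sd)),
        fast_axis=float(rng.normal(0.0, sd)),
        depol=float(rng.normal(0.0, sd * 0.5)),
        m00=float(rng.normal(0.0, sd * 0.25)),
    )


@dataclass
class PhantomLayout:
    """Spatial layout and annotation of one phantom sample."""

    patient_id: str
    sample_id: str
    label_mask: NDArray[np.uint8]  # H x W in {0 unlabeled, 1 normal, 2 abnormal}
    category: str  # "normal" | "abnormal" | "mixed"
    unlabeled_border_width: int = 3

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask, dtype=np.uint8)
        if not np.isin(self.label_mask, [UNLABELED, NORMAL, ABNORMAL]).all():
            raise ValueError("label mask may contain only codes {0, 1, 2}")


@dataclass
class PhantomSample:
    layout: PhantomLayout
    mm_image: MuellerImage  # ground-truth matrices (pre-instrument)
    region_mask: NDArray[np.uint8]  # true tissue map (1/2, no unlabeled)


@dataclass
class PhantomCohort:
    samples: list[PhantomSample]
    config: "CohortConfig"
    normal_spec: TissueClassSpec
    abnormal_spec: TissueClassSpec
    patient_effects: dict[str, PatientEffect]

    @property
    def patient_ids(self) -> list[str]:
        return sorted({s.layout.patient_id for s in self.samples})


@dataclass(frozen=True)
class CohortConfig:
    """Shape and effect sizes of a synthetic cohort.

    Defaults mirror the study layout: 11 patients, 15 samples of which 2
    contain both tissue types, the rest split between all-normal and
    all-abnormal.  ``intensity_matched=True`` forces both classes to share
    the normal class's reflectance (M00) distribution, removing the
    intensity-only class signal by construction.
    """

    n_patients: int = 11
    n_samples: int = 15
    frac_mixed: float = 2.0 / 15.0
    frac_normal: float = 7.0 / 15.0
    frac_abnormal: float = 6.0 / 15.0
    image_shape: tuple[int, int] = (32, 32)
    patient_effect_sd: float = 0.08
    unlabeled_border_width: int = 3
    hotspot_fraction: float = 0.0
    hotspot_gain: float = 50.0
    intensity_matched: bool = False
    seed: int = 0
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_samples < 1:
            raise ValueError("n_patients and n_samples must be >= 1")
        if self.n_samples < self.n_patients:
            raise ValueError("need at least one sample per patient")
        total = self.frac_mixed + self.frac_normal + self.frac_abnormal
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions must sum to 1, got {total}")

    def category_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of samples to categories."""
        fracs = {
            "mixed": self.frac_mixed,
            "normal": self.frac_normal,
            "abnormal": self.frac_abnormal,
        }
        raw = {k: v * self.n_samples for k, v in fracs.items()}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        short = self.n_samples - sum(counts.values())
        for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
            counts[k] += 1
        return counts

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["wavelengths"] = list(self.wavelengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["image_shape"] = tuple(int(x) for x in d["image_shape"])
        d["wavelengths"] = tuple(float(x) for x in d.get("wavelengths", DEFAULT_WAVELENGTHS))
        return cls(**d)


# ---------------------------------------------------------------------------
# pixel-level sampling


def _retarder_batch(delta: NDArray, theta: NDArray) -> NDArray:
    """Vectorized linear retarder matrices, shape (..., 4, 4)."""
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    cd, sd = np.cos(delta), np.sin(delta)
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    out = np.zeros(delta.shape + (4, 4))
    out[..., 0, 0] = 1.0
    # R(th) @ ret(delta) @ R(-th), expanded in closed form
    out[..., 1, 1] = c * c + s * s * cd
    out[..., 1, 2] = c * s * (1 - cd)
    out[..., 1, 3] = -s * sd
    out[..., 2, 1] = c * s * (1 - cd)
    out[..., 2, 2] = s * s + c * c * cd
    out[..., 2, 3] = c * sd
    out[..., 3, 1] = s * sd
    out[..., 3, 2] = -c * sd
    out[..., 3, 3] = cd
    return out


def _diattenuator_batch(d: NDArray, theta: NDArray) -> NDArray:
    """Vectorized unit-transmittance linear diattenuators."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    cross = np.sqrt(np.clip(1.0 - d * d, 0.0, None))
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    out = np.zeros(d.shape + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 0, 1] = d * c
    out[..., 0, 2] = d * s
    out[..., 1, 0] = d * c
    out[..., 2, 0] = d * s
    out[..., 1, 1] = c * c + s * s * cross
    out[..., 1, 2] = c * s * (1 - cross)
    out[..., 2, 1] = c * s * (1 - cross)
    out[..., 2, 2] = s * s + c * c * cross
    out[..., 3, 3] = cross
    return out


def _draw_base_params(
    spec: TissueClassSpec,
    n: int,
    rng: np.random.Generator,
    offset: PatientEffect,
) -> dict[str, NDArray]:
    """Draw per-pixel generative parameters (wavelength-independent part).

    Out-of-bounds draws are replaced by redrawing, up to ``_MAX_REDRAWS``
    rounds; the defaults make redraws rare.
    """
    params = {
        "delta": rng.normal(spec.retardance_mean + offset.retardance, spec.retardance_sd, n),
        "theta": rng.normal(spec.fast_axis_mean + offset.fast_axis, spec.fast_axis_spread, n),
        "depol": np.stack(
            [rng.normal(m + offset.depol, spec.depol_sd, n) for m in spec.depol_mean], axis=1
        ),
        "d": rng.normal(spec.diattenuation_mean, spec.diattenuation_sd, n),
        "m00": rng.normal(spec.m00_mean + offset.m00, spec.m00_sd, n),
    }

    def bad(p):
        return (
            (p["delta"] < 0)
            | (np.abs(p["depol"]) > 1).any(axis=1)
            | (p["d"] < 0)
            | (p["d"] > 1)
            | (p["m00"] <= 0)
        )

    mask = bad(params)
    for _ in range(_MAX_REDRAWS):
        if not mask.any():
            break
        m = int(mask.sum())
        params["delta"][mask] = rng.normal(
            spec.retardance_mean + offset.retardance, spec.retardance_sd, m
        )
        params["depol"][mask] = np.stack(
            [rng.normal(mu + offset.depol, spec.depol_sd, m) for mu in spec.depol_mean], axis=1
        )
        params["d"][mask] = rng.normal(spec.diattenuation_mean, spec.diattenuation_sd, m)
        params["m00"][mask] = rng.normal(spec.m00_mean + offset.m00, spec.m00_sd, m)
        mask = bad(params)
    else:
        raise RuntimeError(
            f"could not draw physical parameters for class '{spec.name}' "
            f"after {_MAX_REDRAWS} redraw rounds"
        )
    return params


def _matrices_from_params(
    params: dict[str, NDArray], spec: TissueClassSpec, wavelengths: tuple[float, ...]
) -> NDArray:
    """Compose (n, L, 4, 4) matrices with the spec's wavelength dispersion."""
    n = params["delta"].shape[0]
    n_lambda = len(wavelengths)
    out = np.empty((n, n_lambda, 4, 4))
    for li, lam in enumerate(wavelengths):
        delta = params["delta"] * (spec.reference_wavelength / lam)
        scale = (lam / spec.reference_wavelength) ** spec.depol_dispersion
        depol = np.clip(params["depol"] * scale, -1.0, 1.0)
        ret = _retarder_batch(delta, params["theta"])
        diat = _diattenuator_batch(params["d"], np.full(n, spec.diattenuation_axis))
        dep = np.zeros((n, 4, 4))
        dep[:, 0, 0] = 1.0
        dep[:, 1, 1] = depol[:, 0]
        dep[:, 2, 2] = depol[:, 1]
        dep[:, 3, 3] = depol[:, 2]
        out[:, li] = params["m00"][:, None, None] * (dep @ ret @ diat)
    return out


def sample_pixel_matrix(
    spec: TissueClassSpec,
    wavelength: float,
    patient_offset: PatientEffect | None = None,
    rng: np.random.Generator | None = None,
) -> NDArray[np.float64]:
    """Draw one physically realizable pixel matrix at one wavelength."""
    rng = np.random.default_rng() if rng is None else rng
    offset = patient_offset or PatientEffect()
    for _ in range(_MAX_REDRAWS):
        params = _draw_base_params(spec, 1, rng, offset)
        m = _matrices_from_params(params, spec, (wavelength,))[0, 0]
        ok, _diag = mueller.is_physical(m)
        if ok:
            return m
    raise RuntimeError(f"no physical matrix drawn for class '{spec.name}' in {_MAX_REDRAWS} tries")


# ---------------------------------------------------------------------------
# sample geometry


def _mixed_region_mask(shape: tuple[int, int], rng: np.random.Generator) -> NDArray[np.uint8]:
    """Two-region tissue map from a smoothed random field split at its median."""
    h, w = shape
    noise = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=max(h, w) / 6.0)
    region = np.where(smooth > np.median(smooth), ABNORMAL, NORMAL).astype(np.uint8)
    return region


def _label_mask_from_regions(
    region: NDArray[np.uint8], border_width: int
) -> NDArray[np.uint8]:
    """Annotation mask: region labels with the inter-region band unlabeled.

    ``border_width`` is the unlabeled margin on each side of the boundary,
    mimicking annotators only trusting uniform regions.
    """
    labels = region.copy()
    a = region == NORMAL
    b = region == ABNORMAL
    if a.any() and b.any() and border_width > 0:
        near_a = ndimage.binary_dilation(a, iterations=border_width)
        near_b = ndimage.binary_dilation(b, iterations=border_width)
        labels[near_a & near_b] = UNLABELED
    return labels


def generate_cohort(
    config: CohortConfig,
    normal_spec: TissueClassSpec | None = None,
    abnormal_spec: TissueClassSpec | None = None,
) -> PhantomCohort:
    """Generate a deterministic labeled phantom cohort.

    Sample categories are apportioned by the config fractions, shuffled,
    and dealt to patients round-robin, so some patients carry both tissue
    classes.  Per-patient offsets are shared by every pixel of that
    patient.  With ``intensity_matched=True`` the abnormal spec inherits
    the normal class's M00 mean/sd and the M00 patient offsets are shared,
    removing any intensity class signal.
    """
    normal_spec = normal_spec or normal_tissue_spec()
    abnormal_spec = abnormal_spec or abnormal_tissue_spec()
    if config.intensity_matched:
        abnormal_spec = dataclasses.replace(
            abnormal_spec, m00_mean=normal_spec.m00_mean, m00_sd=normal_spec.m00_sd
        )
    rng = np.random.default_rng(config.seed)

    patients = [f"P{i:02d}" for i in range(config.n_patients)]
    effects = {p: _draw_patient_effect(rng, config.patient_effect_sd) for p in patients}

    counts = config.category_counts()
    categories = (
        ["mixed"] * counts["mixed"]
        + ["normal"] * counts["normal"]
        + ["abnormal"] * counts["abnormal"]
    )
    rng.shuffle(categories)
    h, w = config.image_shape
    n_lambda = len(config.wavelengths)

    samples: list[PhantomSample] = []
    for i, category in enumerate(categories):
        patient = patients[i % config.n_patients]
        effect = effects[patient]
        if category == "mixed":
            region = _mixed_region_mask((h, w), rng)
        elif category == "normal":
            region = np.full((h, w), NORMAL, dtype=np.uint8)
        else:
            region = np.full((h, w), ABNORMAL, dtype=np.uint8)
        labels = _label_mask_from_regions(region, config.unlabeled_border_width)

        matrices = np.empty((h, w, n_lambda, 4, 4))
        for code, spec in ((NORMAL, normal_spec), (ABNORMAL, abnormal_spec)):
            sel = region == code
            n_px = int(sel.sum())
            if n_px == 0:
                continue
            # patient offsets are shared across classes, so under
            # intensity matching the M00 offset cannot reintroduce a signal
            params = _draw_base_params(spec, n_px, rng, effect)
            matrices[sel] = _matrices_from_params(params, spec, config.wavelengths)

        if config.hotspot_fraction > 0:
            hot = rng.random((h, w)) < config.hotspot_fraction
            matrices[hot] *= config.hotspot_gain

        layout = PhantomLayout(
            patient_id=patient,
            sample_id=f"S{i:02d}",
            label_mask=labels,
            category=category,
            unlabeled_border_width=config.unlabeled_border_width,
        )
        mm_image = MuellerImage(
            matrices=matrices,
            valid_mask=np.ones((h, w), dtype=bool),
            wavelengths=config.wavelengths,
        )
        samples.append(PhantomSample(layout=layout, mm_image=mm_image, region_mask=region))

    return PhantomCohort(
        samples=samples,
        config=config,
        normal_spec=normal_spec,
        abnormal_spec=abnormal_spec,
        patient_effects=effects,
    )


def corrupt_registration(
    layout: PhantomLayout, shift: tuple[int, int], rng: np.random.Generator | None = None
) -> PhantomLayout:
    """Translate the annotation mask by ``(dx, dy)`` pixels.

    Emulates HE-to-polarimetry registration error: the optical data stays
    where it is, only the labels move.  Pixels shifted in from outside the
    field of view become unlabeled.  ``dx`` moves labels along columns
    (+right), ``dy`` along rows (+down).
    """
    dx, dy = int(shift[0]), int(shift[1])
    h, w = layout.label_mask.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift {shift} exceeds image size {(h, w)}")
    shifted = np.full_like(layout.label_mask, UNLABELED)
    src_rows = slice(max(0, -dy), min(h, h - dy))
    dst_rows = slice(max(0, dy), min(h, h + dy))
    src_cols = slice(max(0, -dx), min(w, w - dx))
    dst_cols = slice(max(0, dx), min(w, w + dx))
    shifted[dst_rows, dst_cols] = layout.label_mask[src_rows, src_cols]
    return PhantomLayout(
        patient_id=layout.patient_id,
        sample_id=layout.sample_id,
        label_mask=shifted,
        category=layout.category,
        unlabeled_border_width=layout.unlabeled_border_width,
    )


# ---------------------------------------------------------------------------
# persistence


def save_cohort(cohort: PhantomCohort, out_dir: str | Path) -> None:
    """Write a cohort: per-sample Mueller TIFF + label PNG + manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.samples:
        stem = f"{s.layout.patient_id}_{s.layout.sample_id}"
        save_mueller_image(s.mm_image, out_dir / stem)
        iio.imwrite(out_dir / f"{stem}.labels.png", s.layout.label_mask)
        iio.imwrite(out_dir / f"{stem}.region.png", s.region_mask)
        rows.append(
            {
                "patient_id": s.layout.patient_id,
                "sample_id": s.layout.sample_id,
                "category": s.layout.category,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    meta = {
        "config": cohort.config.to_dict(),
        "normal_spec": cohort.normal_spec.to_dict(),
        "abnormal_spec": cohort.abnormal_spec.to_dict(),
        "patient_effects": {
            p: dataclasses.asdict(e) for p, e in cohort.patient_effects.items()
        },
    }
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_cohort(out_dir: str | Path) -> PhantomCohort:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "cohort.json").read_text())
    config = CohortConfig.from_dict(meta["config"])
    manifest = pd.read_csv(out_dir / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        stem = f"{row.patient_id}_{row.sample_id}"
        mm_image = load_mueller_image(out_dir / stem)
        labels = np.asarray(iio.imread(out_dir / f"{stem}.labels.png"), dtype=np.uint8)
        region = np.asarray(iio.imread(out_dir / f"{stem}.region.png"), dtype=np.uint8)
        layout = PhantomLayout(
            patient_id=row.patient_id,
            sample_id=row.sample_id,
            label_mask=labels,
            category=row.category,
            unlabeled_border_width=config.unlabeled_border_width,
        )
        samples.append(PhantomSample(layout=layout, mm_image=mm_image, region_mask=region))
    return PhantomCohort(
        samples=samples,
        config=config,
        normal_spec=TissueClassSpec.from_dict(meta["normal_spec"]),
        abnormal_spec=TissueClassSpec.from_dict(meta["abnormal_spec"]),
        patient_effects={
            p: PatientEffect(**e) for p, e in meta["patient_effects"].items()
        },
    )
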