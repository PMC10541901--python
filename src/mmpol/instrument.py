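"""Forward model of a dual-rotating-retarder Mueller-matrix polarimeter.

The polarization state generator (PSG) is a fixed linear polarizer followed
by a quarter-wave plate that advances by ``step`` radians per measurement;
the polarization state analyzer (PSA) is a quarter-wave plate rotating
``q`` times faster followed by a fixed linear polarizer.  A scalar (CMOS)
detector records total intensity only.  ``N`` measurements per wavelength
filter make all 16 Mueller elements identifiable when the retarder angles
are chosen at the canonical 5:1 harmonic ratio.

The noise model is Gaussian shot noise (variance proportional to the
expected count) plus additive Gaussian read noise, followed by clipping at
the detector full scale; clipped frames are flagged in a saturation mask.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from numpy.typing import NDArray

from mmpol import mueller

__all__ = [
    "InstrumentConfig",
    "RawStack",
    "psg_state",
    "psa_row",
    "measure_pixel",
    "acquire",
    "save_raw_stack",
    "load_raw_stack",
]

DEFAULT_WAVELENGTHS = (450.0, 470.0, 500.0, 540.0, 625.0)


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry, rotation schedule, detector and noise parameters.

    Parameters
    ----------
    psg_polarizer_angle, psa_polarizer_angle : float
        Transmission-axis angles of the fixed polarizers (radians).
    delta1, delta2 : float
        Retardances of the PSG / PSA wave plates (radians); pi/2 models
        ideal quarter-wave plates at every wavelength.
    q : int
        PSA-to-PSG rotation ratio (integer harmonic).
    n_steps : int
        Number of measurements N per wavelength.
    step : float or None
        PSG retarder increment per measurement; ``None`` means ``pi / N``
        (a half revolution of the PSG plate over the sequence).
    source_intensity : float
        Source radiance in detector-count units at unit gain.
    gain : float
        Detector counts per unit intensity.
    read_noise_sd : float
        Additive Gaussian read noise, counts.
    shot_noise : bool
        Enable Gaussian shot noise with variance equal to the expected count.
    full_scale : float
        Saturation level of the detector, counts.
    wavelengths : tuple of float
        Central wavelengths of the color filters, nm.
    delta_overrides : mapping wavelength -> (delta1, delta2), optional
        Per-wavelength retardance overrides for dispersive wave plates.
    """

    psg_polarizer_angle: float = 0.0
    psa_polarizer_angle: float = 0.0
    delta1: float = np.pi / 2
    delta2: float = np.pi / 2
    q: int = 5
    n_steps: int = 36
    step: float | None = None
    source_intensity: float = 20000.0
    gain: float = 1.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    full_scale: float = 65535.0
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    delta_overrides: dict | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 16:
            raise ValueError(f"n_steps must be >= 16, got {self.n_steps}")
        if self.q < 1:
            raise ValueError(f"rotation ratio q must be >= 1, got {self.q}")
        if self.full_scale <= 0:
            raise ValueError("full_scale must be positive")
        if len(self.wavelengths) == 0:
            raise ValueError("at least one wavelength is required")

    @property
    def delta(self) -> float:
        """Effective angular step of the PSG retarder (radians)."""
        return np.pi / self.n_steps if self.step is None else self.step

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)

    def deltas_for(self, wavelength: float | None) -> tuple[float, float]:
        """PSG/PSA retardances effective at ``wavelength``."""
        if wavelength is not None and self.delta_overrides:
            if wavelength in self.delta_overrides:
                d1, d2 = self.delta_overrides[wavelength]
                return float(d1), float(d2)
        return self.delta1, self.delta2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavelengths"] = list(self.wavelengths)
        if d["delta_overrides"] is not None:
            d["delta_overrides"] = {str(k): list(v) for k, v in d["delta_overrides"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        d = dict(d)
        d["wavelengths"] = tuple(float(w) for w in d.get("wavelengths", DEFAULT_WAVELENGTHS))
        if d.get("delta_overrides"):
            d["delta_overrides"] = {
                float(k): tuple(float(x) for x in v) for k, v in d["delta_overrides"].items()
            }
        return cls(**d)


@dataclass
class RawStack:
    """Simulated detector frames.

    ``intensities`` has shape (H, W, N, L) -- one frame per rotation step
    per wavelength filter; ``saturated`` flags frames whose pre-clip count
    exceeded the detector full scale.
    """

    intensities: NDArray[np.float64]
    saturated: NDArray[np.bool_]
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def saturated_pixels(self) -> NDArray[np.bool_]:
        """H x W mask of pixels with at least one clipped frame."""
        return self.saturated.any(axis=(2, 3))


def _check_step(config: InstrumentConfig, k: int) -> None:
    if not 0 <= k < config.n_steps:
        raise IndexError(f"step index {k} outside [0, {config.n_steps})")


def psg_state(
    config: InstrumentConfig, k: int, wavelength: float | None = None
) -> NDArray[np.float64]:
    """Stokes vector produced by the PSG at rotation step ``k``."""
    _check_step(config, k)
    d1, _ = config.deltas_for(wavelength)
    chain = mueller.compose(
        [
            mueller.linear_polarizer(config.psg_polarizer_angle),
            mueller.retarder(d1, k * config.delta),
        ]
    )
    return chain @ mueller.unpolarized(config.source_intensity)


def psa_row(
    config: InstrumentConfig, k: int, wavelength: float | None = None
) -> NDArray[np.float64]:
    """Intensity-projection row of the PSA at rotation step ``k``.

    The detector reads only total intensity, so the PSA acts through the
    first row of ``polarizer @ retarder(delta2, q*k*step)``.
    """
    _check_step(config, k)
    _, d2 = config.deltas_for(wavelength)
    chain = mueller.compose(
        [
            mueller.retarder(d2, config.q * k * config.delta),
            mueller.linear_polarizer(config.psa_polarizer_angle),
        ]
    )
    return chain[0]


def measure_pixel(
    m_sample: NDArray[np.float64],
    config: InstrumentConfig,
    k: int,
    wavelength: float | None = None,
) -> float:
    """Noiseless detector count for one pixel at rotation step ``k``."""
    m_sample = np.asarray(m_sample, dtype=float)
    if not np.all(np.isfinite(m_sample)):
        raise ValueError("sample Mueller matrix contains non-finite entries")
    a = psa_row(config, k, wavelength)
    s = psg_state(config, k, wavelength)
    return float(config.gain * (a @ m_sample @ s))


def _psg_psa_arrays(
    config: InstrumentConfig, wavelength: float | None
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Stacked PSG states (N, 4) and PSA rows (N, 4) for one wavelength."""
    s = np.stack([psg_state(config, k, wavelength) for k in range(config.n_steps)])
    a = np.stack([psa_row(config, k, wavelength) for k in range(config.n_steps)])
    return s, a


def acquire(mm_image, config: InstrumentConfig, rng_seed: int | None = 0) -> RawStack:
    """Simulate a full acquisition of a Mueller-matrix image.

    Parameters
    ----------
    mm_image : MuellerImage or ndarray
        Ground-truth per-pixel matrices, shape (H, W, L, 4, 4) with L equal
        to the number of configured wavelengths.
    config : InstrumentConfig
    rng_seed : int or None
        Seed for the noise generator; identical seeds give bit-identical
        stacks.  ``None`` disables noise entirely (noiseless acquisition).

    Returns
    -------
    RawStack with intensities clipped to ``[0, full_scale]``.
    """
    matrices = np.asarray(getattr(mm_image, "matrices", mm_image), dtype=float)
    if matrices.ndim != 5 or matrices.shape[2:] != (config.n_wavelengths, 4, 4):
        raise ValueError(
            f"expected matrices of shape (H, W, {config.n_wavelengths}, 4, 4), "
            f"got {matrices.shape}"
        )
    h, w, n_lambda = matrices.shape[:3]
    n = config.n_steps
    counts = np.empty((h, w, n, n_lambda), dtype=float)
    for li, lam in enumerate(config.wavelengths):
        s, a = _psg_psa_arrays(config, lam)
        # I_k = a_k . M . s_k  for every pixel, vectorized over the image
        counts[:, :, :, li] = config.gain * np.einsum(
            "ki,hwij,kj->hwk", a, matrices[:, :, li], s, optimize=True
        )
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        if config.shot_noise:
            counts = counts + rng.standard_normal(counts.shape) * np.sqrt(
                np.clip(counts, 0.0, None)
            )
        if config.read_noise_sd > 0:
            counts = counts + rng.standard_normal(counts.shape) * config.read_noise_sd
    saturated = counts > config.full_scale
    counts = np.clip(counts, 0.0, config.full_scale)
    return RawStack(intensities=counts, saturated=saturated, wavelengths=config.wavelengths)


def save_raw_stack(stack: RawStack, config: InstrumentConfig, prefix: str | Path) -> None:
    """Write a raw stack as multi-page TIFF + JSON sidecar.

    Pages are ordered wavelength-major then step (``L*N`` pages of H x W);
    the saturation mask goes to ``<prefix>.saturated.tif`` collapsed per
    pixel, and the instrument configuration to ``<prefix>.json``.
    """
    prefix = Path(prefix)
    h, w, n, n_lambda = stack.intensities.shape
    pages = np.transpose(stack.intensities, (3, 2, 0, 1)).reshape(n_lambda * n, h, w)
    tifffile.imwrite(prefix.with_suffix(".tif"), pages.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(
        prefix.parent / (prefix.name + ".saturated.tif"),
        stack.saturated_pixels().astype(np.uint8),
    )
    sidecar = {"config": config.to_dict(), "shape": [h, w, n, n_lambda]}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_raw_stack(prefix: str | Path) -> tuple[RawStack, InstrumentConfig]:
    """Read a stack written by :func:`save_raw_stack`."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    config = InstrumentConfig.from_dict(sidecar["config"])
    h, w, n, n_lambda = sidecar["shape"]
    pages = tifffile.imread(prefix.with_suffix(".tif")).astype(float)
    intensities = np.transpose(pages.reshape(n_lambda, n, h, w), (2, 3, 1, 0))
    saturated = intensities >= config.full_scale
    return (
        RawStack(intensities=intensities, saturated=saturated, wavelengths=config.wavelengths),
        config,
    )
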