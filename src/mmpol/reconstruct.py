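"""Pixel-wise Mueller-matrix recovery from raw intensity stacks.

Each detector count is linear in the 16 elements of the sample matrix:

    I_k = gain * a_k^T M s_k = (a_k (x) s_k) . vec(M)

where ``s_k`` is the PSG Stokes state, ``a_k`` the PSA intensity row at
rotation step ``k``, and ``vec`` flattens row-major.  Stacking the N steps
gives an N x 16 design matrix; the per-pixel matrices are recovered by
linear least squares through a pseudo-inverse precomputed once per
configuration.  For noiseless data this round-trips machine-exactly; for
noisy data it is the maximum-likelihood estimate under homoscedastic
Gaussian noise.

Pixels with any saturated frame (at any step or wavelength) are marked
invalid and excluded downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from numpy.typing import NDArray

from mmpol.instrument import InstrumentConfig, RawStack, _psg_psa_arrays

__all__ = ["MuellerImage", "IdentifiabilityError", "design_matrix", "reconstruct",
           "save_mueller_image", "load_mueller_image"]

#: relative rank threshold for declaring a configuration non-identifiable
_RANK_RTOL = 1e-10


class IdentifiabilityError(ValueError):
    """The instrument configuration cannot identify all 16 Mueller elements."""


@dataclass
class MuellerImage:
    """Per-pixel 4x4 Mueller matrices on an H x W grid at L wavelengths.

    ``matrices`` has shape (H, W, L, 4, 4); ``valid_mask`` is H x W, False
    where the pixel was saturated or reconstruction failed.
    """

    matrices: NDArray[np.float64]
    valid_mask: NDArray[np.bool_]
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.matrices.ndim != 5 or self.matrices.shape[3:] != (4, 4):
            raise ValueError(f"matrices must be (H, W, L, 4, 4), got {self.matrices.shape}")
        if self.valid_mask.shape != self.matrices.shape[:2]:
            raise ValueError("valid_mask dimensions do not match the pixel grid")
        if self.matrices.shape[2] != len(self.wavelengths):
            raise ValueError("wavelength count does not match the matrix grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrices.shape[:2]


def design_matrix(config: InstrumentConfig, wavelength: float | None = None) -> NDArray[np.float64]:
    """N x 16 linear model mapping vec(M), row-major, to detector counts.

    Raises :class:`IdentifiabilityError` when the configuration probes
    fewer than 16 independent combinations of Mueller elements (e.g. with
    both retardances zero only unpolarized throughput is measured).
    """
    s, a = _psg_psa_arrays(config, wavelength)
    d = config.gain * np.einsum("ki,kj->kij", a, s).reshape(config.n_steps, 16)
    rank = np.linalg.matrix_rank(d, tol=_RANK_RTOL * np.abs(d).max() * max(d.shape))
    if rank < 16:
        raise IdentifiabilityError(
            f"design matrix rank {rank} < 16 for config with delta1={config.delta1}, "
            f"delta2={config.delta2}, q={config.q}, n_steps={config.n_steps}: "
            "not all Mueller elements are identifiable"
        )
    return d


def reconstruct(raw: RawStack, config: InstrumentConfig) -> MuellerImage:
    """Least-squares Mueller-matrix image from a raw stack.

    A pixel is valid only if none of its N x L frames saturated; invalid
    pixels still carry their (untrustworthy) least-squares solution so the
    grid stays dense, but every consumer must respect ``valid_mask``.
    """
    h, w, n, n_lambda = raw.intensities.shape
    if n != config.n_steps or n_lambda != config.n_wavelengths:
        raise ValueError(
            f"raw stack shape {raw.intensities.shape} inconsistent with config "
            f"(N={config.n_steps}, L={config.n_wavelengths})"
        )
    matrices = np.empty((h, w, n_lambda, 4, 4), dtype=float)
    for li, lam in enumerate(config.wavelengths):
        d = design_matrix(config, lam)
        pinv = np.linalg.pinv(d)  # (16, N), precomputed once per wavelength
        counts = raw.intensities[:, :, :, li].reshape(h * w, n)
        vecs = counts @ pinv.T
        matrices[:, :, li] = vecs.reshape(h, w, 4, 4)
    valid = ~raw.saturated.any(axis=(2, 3))
    valid &= np.isfinite(matrices).all(axis=(2, 3, 4))
    return MuellerImage(matrices=matrices, valid_mask=valid, wavelengths=tuple(raw.wavelengths))


def save_mueller_image(image: MuellerImage, prefix: str | Path) -> None:
    """Persist as a 16L-channel TIFF (wavelength-major, row-major elements)."""
    prefix = Path(prefix)
    h, w, n_lambda = image.matrices.shape[:3]
    channels = image.matrices.reshape(h, w, n_lambda * 16)
    tifffile.imwrite(prefix.with_suffix(".tif"), np.moveaxis(channels, 2, 0).astype(np.float32), photometric="minisblack")
    tifffile.imwrite(prefix.parent / (prefix.name + ".valid.tif"), image.valid_mask.astype(np.uint8))
    prefix.with_suffix(".json").write_text(
        json.dumps({"wavelengths": list(image.wavelengths)}, sort_keys=True)
    )


def load_mueller_image(prefix: str | Path) -> MuellerImage:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    wavelengths = tuple(float(x) for x in meta["wavelengths"])
    channels = np.moveaxis(tifffile.imread(prefix.with_suffix(".tif")).astype(float), 0, 2)
    h, w = channels.shape[:2]
    matrices = channels.reshape(h, w, len(wavelengths), 4, 4)
    valid = tifffile.imread(prefix.parent / (prefix.name + ".valid.tif")).astype(bool)
    return MuellerImage(matrices=matrices, valid_mask=valid, wavelengths=wavelengths)
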