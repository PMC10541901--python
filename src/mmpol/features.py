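"""Pixel feature construction from Mueller-matrix images.

Two representations are built per pixel:

* **pol** (75-dim): each of the five per-wavelength 4x4 matrices is scaled
  by the inverse of its first element M00, flattened row-major, and the
  (now constant) first element dropped, leaving 15 free parameters per
  matrix; the five 15-vectors are concatenated in ascending wavelength
  order.  The raw representation before normalization has 16 x 5 = 80
  elements per pixel.  By construction the pol vector is invariant to any
  positive per-pixel intensity gain.

* **nopol** (5-dim): the polarization-blind reading -- M00 at each
  wavelength in ascending order.  This scales with intensity gain, which
  is the structural reason the two representations can perform
  differently.

Feature tables are pandas DataFrames with one row per pixel that is both
annotated and valid (not saturated, M00 above threshold), carrying patient
and sample identifiers for grouped cross-validation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from mmpol.phantom import ABNORMAL, NORMAL, PhantomLayout
from mmpol.reconstruct import MuellerImage

__all__ = [
    "M00_EPSILON",
    "normalize_mm",
    "pol_features",
    "nopol_features",
    "build_feature_table",
    "feature_columns",
    "save_feature_table",
    "load_feature_table",
]

#: minimum M00 for a pixel to count as measurable (relative units)
M00_EPSILON = 1e-6


def normalize_mm(m: NDArray[np.float64], eps: float = M00_EPSILON) -> NDArray[np.float64]:
    """Scale a Mueller matrix by 1/M00 and drop the first element.

    Returns the 15 remaining elements flattened row-major.  Scale
    invariant: ``normalize_mm(c * M) == normalize_mm(M)`` for ``c > 0``.
    Raises ``ValueError`` when ``M00 <= eps``; image-level builders screen
    such pixels into the invalid mask instead of calling this.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got {m.shape}")
    m00 = m[0, 0]
    if not np.isfinite(m00) or m00 <= eps:
        raise ValueError(f"M00={m00} is below the measurable threshold {eps}")
    return (m / m00).ravel()[1:]


def pol_features(
    matrices: NDArray[np.float64],
    wavelengths: tuple[float, ...] | None = None,
    eps: float = M00_EPSILON,
) -> NDArray[np.float64]:
    """75-dim spectro-polarimetric vector for one pixel.

    ``matrices`` has shape (L, 4, 4); wavelengths (if given) determine the
    concatenation order (ascending nm), otherwise input order is kept.
    """
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1:] != (4, 4):
        raise ValueError(f"expected (L, 4, 4) matrices, got {matrices.shape}")
    order = range(matrices.shape[0]) if wavelengths is None else np.argsort(wavelengths)
    return np.concatenate([normalize_mm(matrices[i], eps) for i in order])


def nopol_features(
    matrices: NDArray[np.float64],
    wavelengths: tuple[float, ...] | None = None,
) -> NDArray[np.float64]:
    """Intensity-only vector for one pixel: M00 per wavelength, ascending."""
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1:] != (4, 4):
        raise ValueError(f"expected (L, 4, 4) matrices, got {matrices.shape}")
    order = range(matrices.shape[0]) if wavelengths is None else np.argsort(wavelengths)
    return np.array([matrices[i, 0, 0] for i in order], dtype=float)


def feature_columns(mode: str, n_wavelengths: int = 5) -> list[str]:
    if mode == "pol":
        return [f"f{i:03d}" for i in range(15 * n_wavelengths)]
    if mode == "nopol":
        return [f"f{i}" for i in range(n_wavelengths)]
    raise ValueError(f"mode must be 'pol' or 'nopol', got {mode!r}")


def build_feature_table(
    images: list[MuellerImage],
    layouts: list[PhantomLayout],
    mode: str = "pol",
    eps: float = M00_EPSILON,
) -> pd.DataFrame:
    """Labeled per-pixel feature table over a set of samples.

    One row per pixel that is annotated (normal/abnormal) AND valid
    (reconstruction mask true, M00 > eps at every wavelength).  Columns:
    ``patient_id, sample_id, row, col, label`` then the feature block;
    ``label`` is 1 for abnormal (the positive class) and 0 for normal.
    """
    if len(images) != len(layouts):
        raise ValueError("images and layouts must pair up one-to-one")
    cols = None
    frames = []
    for image, layout in zip(images, layouts):
        mats = image.matrices
        if mats.shape[:2] != layout.label_mask.shape:
            raise ValueError(
                f"image grid {mats.shape[:2]} does not match label mask "
                f"{layout.label_mask.shape} for {layout.sample_id}"
            )
        wl_order = np.argsort(image.wavelengths)
        labeled = np.isin(layout.label_mask, [NORMAL, ABNORMAL])
        m00 = mats[:, :, :, 0, 0]
        measurable = (m00 > eps).all(axis=2) & np.isfinite(mats).all(axis=(2, 3, 4))
        keep = labeled & image.valid_mask & measurable
        rows, colidx = np.nonzero(keep)
        if cols is None:
            cols = feature_columns(mode, mats.shape[2])
        sel = mats[rows, colidx][:, wl_order]  # (n, L, 4, 4) ascending wavelength
        if mode == "pol":
            normed = sel / sel[:, :, 0:1, 0:1]
            feats = normed.reshape(len(rows), -1, 16)[:, :, 1:].reshape(len(rows), -1)
        elif mode == "nopol":
            feats = sel[:, :, 0, 0]
        else:
            raise ValueError(f"mode must be 'pol' or 'nopol', got {mode!r}")
        frame = pd.DataFrame(feats, columns=cols)
        frame.insert(0, "label", (layout.label_mask[rows, colidx] == ABNORMAL).astype(int))
        frame.insert(0, "col", colidx)
        frame.insert(0, "row", rows)
        frame.insert(0, "sample_id", layout.sample_id)
        frame.insert(0, "patient_id", layout.patient_id)
        frames.append(frame)
    if not frames:
        raise ValueError("no samples provided")
    table = pd.concat(frames, ignore_index=True)
    return table


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str, "sample_id": str})
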