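"""Stokes-Mueller calculus.

Stokes vectors are length-4 float arrays ``(I, Q, U, V)``; Mueller matrices
are 4x4 float arrays.  All angles are in radians, measured counterclockwise
from the horizontal while looking toward the light source.  Rotating an
optical element by ``theta`` rotates the ``(Q, U)`` plane by ``2 * theta``.

Only forward composition of ideal elements is provided (polarizer, linear
retarder, diagonal depolarizer, linear diattenuator); no matrix
decomposition is performed anywhere in the package.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "stokes",
    "unpolarized",
    "identity",
    "linear_polarizer",
    "retarder",
    "linear_diattenuator",
    "depolarizer",
    "rotation_matrix",
    "rotate",
    "apply",
    "compose",
    "is_physical",
    "is_physical_stokes",
]

#: absolute tolerance for physical-realizability checks (double precision
#: closed forms keep violations far below this)
PHYSICALITY_ATOL = 1e-9


def stokes(s0: float, s1: float = 0.0, s2: float = 0.0, s3: float = 0.0) -> NDArray[np.float64]:
    """Build a Stokes vector ``(I, Q, U, V)``."""
    return np.array([s0, s1, s2, s3], dtype=float)


def unpolarized(intensity: float = 1.0) -> NDArray[np.float64]:
    """Unpolarized light of the given total intensity."""
    return stokes(intensity)


def identity() -> NDArray[np.float64]:
    """The identity Mueller matrix (perfect transparent element)."""
    return np.eye(4)


def rotation_matrix(theta: float) -> NDArray[np.float64]:
    """Mueller rotation matrix R(theta); acts on (Q, U) by angle 2*theta."""
    c, s = np.cos(2.0 * theta), np.sin(2.0 * theta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def linear_polarizer(theta: float = 0.0) -> NDArray[np.float64]:
    """Ideal linear polarizer with transmission axis at ``theta``.

    ``linear_polarizer(0)`` is the horizontal polarizer
    ``0.5 * [[1,1,0,0],[1,1,0,0],[0,0,0,0],[0,0,0,0]]``.
    """
    c, s = np.cos(2.0 * theta), np.sin(2.0 * theta)
    return 0.5 * np.array(
        [
            [1.0, c, s, 0.0],
            [c, c * c, c * s, 0.0],
            [s, c * s, s * s, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )


def retarder(delta: float, theta: float = 0.0) -> NDArray[np.float64]:
    """Ideal linear retarder with retardance ``delta`` and fast axis ``theta``.

    ``delta = pi/2`` is a quarter-wave plate; ``delta = 0`` is the identity.
    """
    cd, sd = np.cos(delta), np.sin(delta)
    m = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, cd, sd],
            [0.0, 0.0, -sd, cd],
        ]
    )
    if theta == 0.0:
        return m
    return rotate(m, theta)


def linear_diattenuator(d: float, theta: float = 0.0) -> NDArray[np.float64]:
    """Unit-transmittance linear diattenuator with diattenuation ``d``.

    ``d`` in [0, 1] is the normalized difference between the principal
    transmittances; the matrix is normalized so its (0, 0) element is 1.
    ``d = 1`` degenerates to a perfect polarizer (up to the factor 1/2).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"diattenuation must lie in [0, 1], got {d}")
    cross = np.sqrt(max(1.0 - d * d, 0.0))
    m = np.array(
        [
            [1.0, d, 0.0, 0.0],
            [d, 1.0, 0.0, 0.0],
            [0.0, 0.0, cross, 0.0],
            [0.0, 0.0, 0.0, cross],
        ]
    )
    if theta == 0.0:
        return m
    return rotate(m, theta)


def depolarizer(a: float, b: float, c: float) -> NDArray[np.float64]:
    """Diagonal depolarizer ``diag(1, a, b, c)`` with factors in [-1, 1]."""
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"depolarization factor {name}={v} outside [-1, 1]")
    return np.diag([1.0, a, b, c])


def rotate(m: ArrayLike, theta: float) -> NDArray[np.float64]:
    """Physically rotate an element by ``theta``: ``R(theta) M R(-theta)``."""
    m = np.asarray(m, dtype=float)
    r = rotation_matrix(theta)
    return r @ m @ rotation_matrix(-theta)


def apply(m: ArrayLike, s: ArrayLike) -> NDArray[np.float64]:
    """Apply a Mueller matrix to a Stokes vector: ``M @ S``."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if m.shape != (4, 4) or s.shape != (4,):
        raise ValueError(f"shape mismatch: M {m.shape}, S {s.shape}")
    return m @ s


def compose(elements: list[ArrayLike]) -> NDArray[np.float64]:
    """Compose optical elements listed in light-propagation order.

    The first list entry is the first element the light hits, so the
    resulting matrix is ``M_last @ ... @ M_first``.
    """
    if len(elements) == 0:
        raise ValueError("compose requires at least one element")
    out = np.asarray(elements[0], dtype=float)
    for m in elements[1:]:
        out = np.asarray(m, dtype=float) @ out
    return out


def is_physical_stokes(s: ArrayLike, atol: float = PHYSICALITY_ATOL) -> bool:
    """True iff ``s0 >= 0`` and the polarized part does not exceed ``s0``."""
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        return False
    return s[0] >= -atol and s[1] ** 2 + s[2] ** 2 + s[3] ** 2 <= s[0] ** 2 + atol


def is_physical(m: ArrayLike, atol: float = PHYSICALITY_ATOL) -> tuple[bool, dict]:
    """Quick physical-realizability screen for a Mueller matrix.

    Checks three necessary conditions: positive overall transmittance
    ``M00 > 0``, element dominance ``|m_ij| <= M00``, and the trace bound
    ``tr(M^T M) <= 4 M00^2``.  Returns ``(ok, diagnostics)`` where the
    diagnostics dict records each condition and its margin.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected 4x4 matrix, got {m.shape}")
    if not np.all(np.isfinite(m)):
        return False, {"finite": False}
    m00 = m[0, 0]
    max_abs = float(np.max(np.abs(m)))
    trace_mtm = float(np.trace(m.T @ m))
    diag = {
        "finite": True,
        "m00": float(m00),
        "m00_positive": m00 > 0.0,
        "element_dominance": max_abs <= m00 + atol,
        "max_abs_element": max_abs,
        "trace_bound": trace_mtm <= 4.0 * m00 * m00 + atol,
        "trace_mtm": trace_mtm,
    }
    ok = diag["m00_positive"] and diag["element_dominance"] and diag["trace_bound"]
    return bool(ok), diag
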