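"""Image levels: the transform domains on which features are extracted.

Starred feature groups are computed not only on the original image (IM)
but also on five transform domains: the one-level Haar wavelet transform
(W), the discrete Chebyshev transform (C), the Fourier modulus (F), and
the two compound transforms — Haar wavelet of the Fourier modulus (WF)
and Chebyshev transform of the Fourier modulus (CF).

Each level image is min-max rescaled to [0, 1] before feature
extraction so that histogram-type features have a defined range on
transform domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pywt
from numpy.polynomial import chebyshev as ncheb

from .io import RawImage

__all__ = [
    "Level",
    "LevelImage",
    "fourier_modulus",
    "haar_wavelet",
    "chebyshev_transform",
    "image_at_level",
    "compute_levels",
    "CHEBYSHEV_ORDER",
]

#: Order of the discrete Chebyshev expansion: 20 x 20 = 400 coefficients.
CHEBYSHEV_ORDER = 20


class Level(str, Enum):
    """The six image levels."""

    IM = "IM"  # original image
    W = "W"    # Haar wavelet transform
    C = "C"    # discrete Chebyshev transform
    F = "F"    # Fourier modulus
    WF = "WF"  # wavelet of the Fourier modulus
    CF = "CF"  # Chebyshev of the Fourier modulus


@dataclass(frozen=True)
class LevelImage:
    """A level's value matrix, rescaled to [0, 1] for feature extraction."""

    values: np.ndarray
    level: Level
    sample_id: str = ""
    channel_id: str = ""
    rescaled: bool = True


def fourier_modulus(M: np.ndarray) -> np.ndarray:
    """Modulus of the 2-D DFT (unnormalized forward transform, DC at corner)."""
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("fourier_modulus: input contains non-finite values")
    if M.shape[0] < 8 or M.shape[1] < 8:
        raise ValueError(f"fourier_modulus: input {M.shape} smaller than 8x8")
    return np.abs(np.fft.fft2(M))


def haar_wavelet(M: np.ndarray) -> np.ndarray:
    """One-level orthonormal 2-D Haar decomposition, subbands tiled.

    Odd dimensions are truncated by one row/column. The four subbands
    are tiled ``[[approx, horiz], [vert, diag]]`` into a matrix of the
    truncated input's size; orthonormality means the tiling conserves
    energy exactly.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError(f"haar_wavelet: input {M.shape} smaller than 2x2")
    h, w = M.shape[0] - M.shape[0] % 2, M.shape[1] - M.shape[1] % 2
    M = M[:h, :w]
    cA, (cH, cV, cD) = pywt.dwt2(M, "haar", mode="periodization")
    return np.block([[cA, cH], [cV, cD]])


def _cheb_vandermonde(n: int, order: int) -> np.ndarray:
    """Chebyshev Vandermonde matrix on n pixel centers mapped to [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n)
    return ncheb.chebvander(x, order - 1)


def chebyshev_transform(M: np.ndarray, order: int = CHEBYSHEV_ORDER) -> np.ndarray:
    """Coefficients of the 2-D Chebyshev (first kind) expansion of ``M``.

    Pixel coordinates are mapped affinely to [-1, 1]^2 and coefficients
    are obtained by least-squares projection on the sampled tensor basis
    T_i(x) T_j(y), i, j < order. Returns an ``order x order`` matrix
    ``C`` with ``C[i, j]`` multiplying T_i(x) T_j(y) (x along columns,
    y along rows).
    """
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("chebyshev_transform: non-finite input")
    if order < 2:
        raise ValueError("chebyshev_transform: order must be >= 2")
    if order * order > M.size:
        raise ValueError(
            f"chebyshev_transform: order^2 = {order * order} exceeds "
            f"pixel count {M.size}"
        )
    Vy = _cheb_vandermonde(M.shape[0], order)  # rows = y
    Vx = _cheb_vandermonde(M.shape[1], order)  # cols = x
    # Separable least squares: for a tensor-product basis the Kronecker
    # pseudo-inverse factorizes, so two small solves give the full LSQ fit.
    B = np.linalg.pinv(Vy) @ M @ np.linalg.pinv(Vx).T  # B[j, i] ~ T_j(y) T_i(x)
    return B.T


def chebyshev_reconstruct(C: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate a Chebyshev coefficient matrix back onto a pixel grid."""
    order = C.shape[0]
    Vy = _cheb_vandermonde(shape[0], order)
    Vx = _cheb_vandermonde(shape[1], order)
    return Vy @ C.T @ Vx.T


def rescale01(M: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1].

    A constant matrix maps to all zeros; "constant" includes ranges at
    floating round-off scale (relative 1e-12), so that e.g. the flat
    spectrum of a single-spike matrix is not blown up into noise.
    """
    M = np.asarray(M, dtype=np.float64)
    lo, hi = M.min(), M.max()
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return np.zeros_like(M)
    return (M - lo) / (hi - lo)


def _level_values(pixels: np.ndarray, level: Level) -> np.ndarray:
    if level == Level.IM:
        return pixels
    if level == Level.W:
        return haar_wavelet(pixels)
    if level == Level.C:
        return chebyshev_transform(pixels)
    if level == Level.F:
        return fourier_modulus(pixels)
    if level == Level.WF:
        return haar_wavelet(fourier_modulus(pixels))
    if level == Level.CF:
        return chebyshev_transform(fourier_modulus(pixels))
    raise ValueError(f"unknown level code {level!r}")


def image_at_level(img: RawImage, level: Level | str) -> LevelImage:
    """Compute one level image.

    Transform levels are min-max rescaled to [0, 1] so histogram-type
    features have a defined range; the IM level is the identity (the
    loader already guarantees [0, 1], and rescaling it would discard
    real global-brightness information).
    """
    level = Level(level)
    raw = _level_values(img.pixels, level)
    values = raw if level == Level.IM else rescale01(raw)
    return LevelImage(
        values=values,
        level=level,
        sample_id=img.sample_id,
        channel_id=img.channel_id,
        rescaled=level != Level.IM,
    )


def compute_levels(img: RawImage) -> dict[Level, LevelImage]:
    """All six levels of an image, sharing one Fourier-modulus computation."""
    F = fourier_modulus(img.pixels)
    raw = {
        Level.IM: img.pixels,
        Level.W: haar_wavelet(img.pixels),
        Level.C: chebyshev_transform(img.pixels),
        Level.F: F,
        Level.WF: haar_wavelet(F),
        Level.CF: chebyshev_transform(F),
    }
    return {
        lv: LevelImage(
            values=vals if lv == Level.IM else rescale01(vals),
            level=lv,
            sample_id=img.sample_id,
            channel_id=img.channel_id,
            rescaled=lv != Level.IM,
        )
        for lv, vals in raw.items()
    }
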