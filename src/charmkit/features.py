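"""The 953-element CHARM-style feature vector.

Nine feature groups are computed per channel. Five groups plus a subset
of the image statistics are "starred": they are extracted on all six
image levels (IM, W, C, F, WF, CF). The remainder is extracted on the
original image only.

    starred, per level (x6):
        pixel statistics (starred subset)   6
        moments                             4
        multiscale histograms              24
        Gabor features                      2
        Haralick textures                 104
        Tamura textures                     6
        -------------------------------------
                                          146
    original image only:
        pixel statistics (plain subset)     9
        edge statistics                     4
        Chebyshev statistics               32
        Chebyshev-Fourier statistics       32
        -------------------------------------
                                           77

    total: 146 x 6 + 77 = 953
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import gabor

from .io import RawImage
from .transforms import (
    Level,
    chebyshev_transform,
    compute_levels,
    rescale01,
)

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "pixel_statistics",
    "moments",
    "multiscale_histograms",
    "edge_statistics",
    "gabor_features",
    "haralick_features",
    "tamura_features",
    "chebyshev_statistics",
    "chebyshev_fourier_statistics",
    "assemble_feature_vector",
    "feature_matrix",
    "feature_names",
    "N_FEATURES",
    "HARALICK_GRAY_LEVELS",
    "GABOR_FREQUENCY",
]

N_FEATURES = 953
HARALICK_GRAY_LEVELS = 8
HARALICK_DISTANCES = (1, 2)
HARALICK_ANGLES_DEG = (0, 45, 90, 135)
GABOR_FREQUENCY = 0.25  # cycles/pixel
GABOR_ANGLES_DEG = (0, 45, 90, 135)

LEVEL_ORDER = (Level.IM, Level.W, Level.C, Level.F, Level.WF, Level.CF)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _otsu(values: np.ndarray) -> float:
    """Otsu threshold; a constant input returns its own value (nothing above)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.max() - values.min() <= 0:
        return float(values[0]) if values.size else 0.0
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values))


def _pop_var(values: np.ndarray) -> float:
    """Population variance with a round-off floor: values that are
    constant up to floating cancellation (e.g. np.var of a bitwise-
    constant array returning ~1e-33) count as zero variance, so the
    zero-variance conventions for skewness/kurtosis/contrast apply."""
    values = np.asarray(values)
    var = float(np.var(values))
    scale = max(1.0, float(np.max(np.abs(values), initial=0.0)))
    return 0.0 if var <= (1e-12 * scale) ** 2 else var


# ---------------------------------------------------------------------------
# feature groups
# ---------------------------------------------------------------------------

def pixel_statistics(M: np.ndarray) -> np.ndarray:
    """All 15 image statistics: 6 starred followed by 9 plain."""
    return np.concatenate([_pixel_statistics_starred(M), _pixel_statistics_plain(M)])


def _pixel_statistics_starred(M: np.ndarray) -> np.ndarray:
    """Starred subset (computed on every level): mean, max, variance,
    percent-minimal, percent-maximal, total intensity."""
    M = np.asarray(M, dtype=np.float64)
    if M.size == 0:
        raise ValueError("pixel_statistics: empty matrix")
    v = M.ravel()
    lo, hi = v.min(), v.max()
    return np.array(
        [
            v.mean(),
            hi,
            _pop_var(v),
            np.mean(v <= lo + 0.01),  # fraction within 0.01 of the minimum
            np.mean(v >= hi - 0.01),
            v.sum(),
        ]
    )


def _pixel_statistics_plain(M: np.ndarray) -> np.ndarray:
    """Plain subset (original image only): median, min, std, skewness,
    kurtosis, histogram mode, and three Otsu-threshold statistics."""
    v = np.asarray(M, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("pixel_statistics: empty matrix")
    var = _pop_var(v)
    skew = float(stats.skew(v)) if var > 0 else 0.0
    kurt = float(stats.kurtosis(v)) if var > 0 else 0.0
    counts, _ = np.histogram(v, bins=256, range=(0.0, 1.0))
    mode = (np.argmax(counts) + 0.5) / 256.0
    thr = _otsu(v)
    above = v[v > thr]
    return np.array(
        [
            np.median(v),
            v.min(),
            np.sqrt(var),
            skew,
            kurt,
            mode,
            above.mean() if above.size else 0.0,   # mean intensity after thresholding
            _pop_var(above) if above.size else 0.0,
            float(above.size),                      # pixels above threshold
        ]
    )


def moments(M: np.ndarray) -> np.ndarray:
    """First four moments of the pixel distribution.

    Population variance; skewness and excess kurtosis are defined as 0
    for zero-variance inputs.
    """
    v = np.asarray(M, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("moments: empty matrix")
    var = _pop_var(v)
    if var > 0:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))
    else:
        skew = kurt = 0.0
    return np.array([v.mean(), var, skew, kurt])


def multiscale_histograms(M: np.ndarray) -> np.ndarray:
    """Concatenated normalized histograms with 3, 5, 7 and 9 bins on [0, 1]."""
    v = np.asarray(M, dtype=np.float64).ravel()
    parts = []
    for nbins in (3, 5, 7, 9):
        counts, _ = np.histogram(v, bins=nbins, range=(0.0, 1.0))
        parts.append(counts / v.size)
    return np.concatenate(parts)


def edge_statistics(M: np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude statistics: mean, variance, max, edge-pixel count."""
    M = np.asarray(M, dtype=np.float64)
    gx = ndimage.sobel(M, axis=1, mode="reflect")
    gy = ndimage.sobel(M, axis=0, mode="reflect")
    G = np.hypot(gx, gy)
    thr = _otsu(G)
    n_edge = float(np.count_nonzero(G > thr))
    return np.array([G.mean(), _pop_var(G), G.max(), n_edge])


def gabor_features(M: np.ndarray) -> np.ndarray:
    """Pooled Gabor-bank responses at four orientations.

    A single center frequency (0.25 cycles/pixel, 1-octave bandwidth) is
    filtered at 0/45/90/135 degrees; with e_theta the mean response
    magnitude per orientation, the features are mean(e) (texture energy)
    and var(e) (orientation anisotropy).
    """
    M = np.asarray(M, dtype=np.float64)
    energies = []
    for deg in GABOR_ANGLES_DEG:
        real, imag = gabor(
            M, frequency=GABOR_FREQUENCY, theta=np.deg2rad(deg), bandwidth=1
        )
        energies.append(np.hypot(real, imag).mean())
    e = np.array(energies)
    return np.array([e.mean(), e.var()])


# -- Haralick ---------------------------------------------------------------

HARALICK_STAT_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def _haralick_stats(P: np.ndarray) -> np.ndarray:
    """The 13 standard co-occurrence statistics of one normalized GLCM."""
    G = P.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((np.arange(G) * px).sum())
    muy = float((np.arange(G) * py).sum())
    sx = np.sqrt(((np.arange(G) - mux) ** 2 * px).sum())
    sy = np.sqrt(((np.arange(G) - muy) ** 2 * py).sum())

    asm = float((P**2).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    if sx * sy > 0:
        correlation = float(((i * j * P).sum() - mux * muy) / (sx * sy))
    else:
        correlation = 0.0
    variance = float(((i - mux) ** 2 * P).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    k_sum = np.arange(2 * G - 1)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (i + j).ravel(), P.ravel())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlogx(p_sum).sum())

    entropy = float(-_xlogx(P).sum())

    k_diff = np.arange(G)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(i - j).ravel(), P.ravel())
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = float(-_xlogx(p_diff).sum())

    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    pxy = px[:, None] * py[None, :]
    log_pxy = np.zeros_like(pxy)
    nz = pxy > 0
    log_pxy[nz] = np.log(pxy[nz])
    hxy1 = float(-(P * log_pxy).sum())
    hxy2 = float(-_xlogx(pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def quantize_gray(M: np.ndarray, gray_levels: int = HARALICK_GRAY_LEVELS) -> np.ndarray:
    """Quantize [0, 1] intensities to ``gray_levels`` equal-width bins."""
    M = np.asarray(M, dtype=np.float64)
    q = np.floor(M * gray_levels).astype(np.int64)
    return np.clip(q, 0, gray_levels - 1).astype(np.uint8)


# unit pixel steps per direction; a distance-d matrix uses offset d*(dr, dc)
_HARALICK_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def _glcm(q: np.ndarray, dr: int, dc: int, levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one pixel offset."""
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel().astype(np.int64)
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel().astype(np.int64)
    P = np.zeros((levels, levels))
    np.add.at(P, (a, b), 1.0)
    P = P + P.T
    return P / P.sum()


def haralick_features(
    M: np.ndarray, gray_levels: int = HARALICK_GRAY_LEVELS
) -> np.ndarray:
    """13 Haralick statistics x 4 directions x 2 distances = 104 values.

    The image is quantized to ``gray_levels`` equal-width bins on [0, 1]
    and symmetric, normalized co-occurrence matrices are built for
    directions 0/45/90/135 degrees at pixel distances 1 and 2 (offset
    d pixels along each direction). Output order: distance-major, then
    angle, then the 13 statistics.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape[0] < 3 or M.shape[1] < 3:
        raise ValueError(f"haralick_features: input {M.shape} smaller than 3x3")
    q = quantize_gray(M, gray_levels)
    out = []
    for d in HARALICK_DISTANCES:
        for angle in HARALICK_ANGLES_DEG:
            dr, dc = _HARALICK_OFFSETS[angle]
            P = _glcm(q, d * dr, d * dc, gray_levels)
            out.append(_haralick_stats(P))
    return np.concatenate(out)


# -- Tamura -----------------------------------------------------------------

_TAMURA_MAX_K = 5  # largest averaging window is 2^5 = 32 pixels


def tamura_features(M: np.ndarray) -> np.ndarray:
    """Tamura perceptual texture descriptors: contrast, coarseness,
    directionality, and a 3-bin histogram of the coarseness map.

    Contrast is sigma / alpha4^(1/4) with alpha4 the kurtosis mu4/sigma^4
    (0 for flat images). Coarseness follows the classic 2^k averaging
    scheme (k <= 5, circular shifts at the borders): per pixel the window
    size with the largest neighborhood difference wins, and coarseness is
    the mean winning size. Directionality is the peakedness (sum of
    squared bin masses) of the 16-bin gradient-orientation histogram over
    pixels whose gradient magnitude exceeds its Otsu threshold.
    """
    M = np.asarray(M, dtype=np.float64)
    v = M.ravel()
    sigma2 = _pop_var(v)
    if sigma2 > 0:
        mu4 = float(np.mean((v - v.mean()) ** 4))
        alpha4 = mu4 / sigma2**2
        contrast = float(np.sqrt(sigma2) / alpha4**0.25) if alpha4 > 0 else 0.0
    else:
        contrast = 0.0

    # coarseness: best window size per pixel
    E = np.zeros((_TAMURA_MAX_K, *M.shape))
    for idx, k in enumerate(range(1, _TAMURA_MAX_K + 1)):
        size = 2**k
        A = ndimage.uniform_filter(M, size=size, mode="wrap")
        half = 2 ** (k - 1)
        eh = np.abs(np.roll(A, -half, axis=1) - np.roll(A, half, axis=1))
        ev = np.abs(np.roll(A, -half, axis=0) - np.roll(A, half, axis=0))
        E[idx] = np.maximum(eh, ev)
    best_k = np.argmax(E, axis=0) + 1  # ties -> smallest window
    S = (2.0**best_k).astype(np.float64)
    coarseness = float(S.mean())
    ch_counts, _ = np.histogram(S, bins=3, range=(2.0, 2.0**_TAMURA_MAX_K))
    ch = ch_counts / S.size

    # directionality
    gx = ndimage.sobel(M, axis=1, mode="reflect")
    gy = ndimage.sobel(M, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    thr = _otsu(mag)
    sel = mag > thr
    if np.any(sel):
        theta = np.mod(np.arctan2(gy[sel], gx[sel]), np.pi)
        h, _ = np.histogram(theta, bins=16, range=(0.0, np.pi))
        h = h / h.sum()
        directionality = float((h**2).sum())
    else:
        directionality = 0.0

    return np.concatenate([[contrast, coarseness, directionality], ch])


# -- polynomial decompositions ----------------------------------------------

def chebyshev_statistics(M: np.ndarray) -> np.ndarray:
    """32-bin normalized histogram of the 400 Chebyshev coefficients."""
    C = chebyshev_transform(M)
    r = rescale01(C)
    counts, _ = np.histogram(r.ravel(), bins=32, range=(0.0, 1.0))
    return counts / r.size


def chebyshev_fourier_statistics(M: np.ndarray) -> np.ndarray:
    """32-bin histogram of the Fourier modulus of the Chebyshev coefficients."""
    C = chebyshev_transform(M)
    FM = np.abs(np.fft.fft2(C))
    r = rescale01(FM)
    counts, _ = np.histogram(r.ravel(), bins=32, range=(0.0, 1.0))
    return counts / r.size


# ---------------------------------------------------------------------------
# vector assembly
# ---------------------------------------------------------------------------

_STARRED_BLOCKS = (
    ("pixstat", _pixel_statistics_starred,
     ("mean", "max", "variance", "pct_min", "pct_max", "total")),
    ("moments", moments, ("mean", "variance", "skewness", "kurtosis")),
    ("mshist", multiscale_histograms,
     tuple(f"h{n}_b{b}" for n in (3, 5, 7, 9) for b in range(n))),
    ("gabor", gabor_features, ("energy", "anisotropy")),
    ("haralick", haralick_features,
     tuple(
         f"d{d}_a{a}_{s}"
         for d in HARALICK_DISTANCES
         for a in HARALICK_ANGLES_DEG
         for s in HARALICK_STAT_NAMES
     )),
    ("tamura", tamura_features,
     ("contrast", "coarseness", "directionality", "coarse_b0", "coarse_b1",
      "coarse_b2")),
)

_BASE_BLOCKS = (
    ("pixstat", _pixel_statistics_plain,
     ("median", "min", "std", "skewness", "kurtosis", "mode",
      "thr_mean", "thr_variance", "thr_count")),
    ("edge", edge_statistics, ("mean", "variance", "max", "n_edge")),
    ("chebstat", chebyshev_statistics, tuple(f"b{b}" for b in range(32))),
    ("chebfourier", chebyshev_fourier_statistics,
     tuple(f"b{b}" for b in range(32))),
)


def feature_names(exclude_groups: tuple[str, ...] = ()) -> list[str]:
    """The 953 feature names, in extraction order: ``group.item@level``.

    ``exclude_groups`` drops whole feature groups (ablation studies): a
    starred group disappears from all six levels.
    """
    names = []
    for level in LEVEL_ORDER:
        for group, _, items in _STARRED_BLOCKS:
            if group in exclude_groups:
                continue
            names.extend(f"{group}.{item}@{level.value}" for item in items)
    for group, _, items in _BASE_BLOCKS:
        if group in exclude_groups:
            continue
        names.extend(f"{group}.{item}@IM" for item in items)
    return names


@dataclass(frozen=True)
class FeatureVector:
    """One channel's 953-element feature vector."""

    values: np.ndarray
    names: tuple[str, ...]
    channel_id: str = "ch0"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names differ in length")


def assemble_feature_vector(
    img: RawImage, exclude_groups: tuple[str, ...] = ()
) -> FeatureVector:
    """Compute the full 953-element vector for one channel of one sample.

    Starred blocks run on all six levels; base blocks on the original
    image only. Raises if any feature comes out non-finite, naming the
    offending group and level. ``exclude_groups`` supports group-ablation
    experiments (a starred group is removed from every level).
    """
    levels = compute_levels(img)
    values: list[np.ndarray] = []
    for level in LEVEL_ORDER:
        Mv = levels[level].values
        for group, fn, items in _STARRED_BLOCKS:
            if group in exclude_groups:
                continue
            block = np.asarray(fn(Mv), dtype=np.float64)
            if block.shape != (len(items),):
                raise RuntimeError(
                    f"{group}@{level.value}: expected {len(items)} values, "
                    f"got {block.shape}"
                )
            if not np.all(np.isfinite(block)):
                raise ArithmeticError(
                    f"non-finite feature in group {group} at level {level.value}"
                )
            values.append(block)
    M0 = levels[Level.IM].values
    for group, fn, items in _BASE_BLOCKS:
        if group in exclude_groups:
            continue
        block = np.asarray(fn(M0), dtype=np.float64)
        if not np.all(np.isfinite(block)):
            raise ArithmeticError(f"non-finite feature in group {group} at level IM")
        values.append(block)
    vec = np.concatenate(values)
    if not exclude_groups:
        assert vec.size == N_FEATURES
    return FeatureVector(
        values=vec,
        names=tuple(feature_names(exclude_groups)),
        channel_id=img.channel_id,
        sample_id=img.sample_id,
    )


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Stacked per-sample feature rows with labels and batch identifiers.

    ``X`` holds 953 x n_channels named columns per sample; ``labels`` is
    optional (prediction inputs have none); ``batches`` defaults to one
    batch per sample.
    """

    X: pd.DataFrame
    labels: pd.Series | None = None
    batches: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.batches is None:
            self.batches = pd.Series(self.X.index, index=self.X.index, dtype=str)
        if self.labels is not None and not self.labels.index.equals(self.X.index):
            raise ValueError("labels index does not match feature rows")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "batch", self.batches)
        out.insert(0, "class", self.labels if self.labels is not None else "")
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        if "class" not in df.columns or "batch" not in df.columns:
            raise ValueError("feature CSV must have 'class' and 'batch' columns")
        labels = df["class"].fillna("").astype(str)
        labels = None if (labels == "").all() else labels
        batches = df["batch"].fillna("").astype(str)
        empty = batches == ""
        batches[empty] = batches.index[empty]
        X = df.drop(columns=["class", "batch"]).astype(np.float64)
        return cls(X=X, labels=labels, batches=batches)


def feature_matrix(
    samples: dict[str, list[RawImage]],
    labels: dict[str, str] | None = None,
    batches: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Extract features for every sample (all channels) and stack them.

    ``samples`` maps sample_id to that sample's channel images; multi-
    channel samples get channel-qualified column names and a row of
    953 x n_channels values.
    """
    rows = {}
    for sid, imgs in samples.items():
        parts, names = [], []
        multi = len(imgs) > 1
        for img in imgs:
            fv = assemble_feature_vector(img)
            parts.append(fv.values)
            prefix = f"{img.channel_id}:" if multi else ""
            names.extend(prefix + n for n in fv.names)
        rows[sid] = pd.Series(np.concatenate(parts), index=names)
    X = pd.DataFrame(rows).T
    X.index.name = "sample_id"
    lab = (
        pd.Series({s: labels[s] for s in X.index}, dtype=str)
        if labels is not None
        else None
    )
    bat = (
        pd.Series({s: batches[s] for s in X.index}, dtype=str)
        if batches is not None
        else None
    )
    return FeatureMatrix(X=X, labels=lab, batches=bat)
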