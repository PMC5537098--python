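"""Counting lesions that resemble the primary lesion ("lesion load").

The pipeline, applied to a cropped region around/inside the organ:

1. Pick the weight ``lambda`` from the homogeneity of the primary lesion:
   0.75 when at least 68% of its pixels fall within one standard deviation
   of its mean (approximately Gaussian intensities), 0.15 otherwise.
2. Choose a global threshold ``T*`` minimising the objective

       J(lambda, T) = (1 - lambda) * sigma_w(T) - lambda * |m_l(T) - m_b(T)|

   over a grid of candidate thresholds, where ``m_l``/``m_b`` are the
   lesion- and background-class mean intensities at ``T`` and ``sigma_w``
   is the square root of the probability-weighted within-class variance

       sigma_w^2 = P_l(T) * var_l + P_b(T) * var_b.

   A low ``lambda`` reduces to (the square root of) Otsu's within-class
   variance criterion; a high ``lambda`` favours class separation.
3. Binarise at ``T*``, label 4-connected components, and drop tiny ones.
4. Summarise each candidate cluster by a first-order-statistics contrast
   ``alpha`` (difference in mean and standard deviation between the cluster
   and a two-pixel ring around it, collapsed into one magnitude) and a shape
   elongation ``beta`` (major/minor moment-axis ratio), and accept a cluster
   as a "similar lesion" when its Euclidean distance to the primary lesion
   in (alpha, beta) space is at most a similarity threshold.

The primary lesion itself is never counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import LesionImage, MaskError, mask_bbox

LAMBDA_HOMOGENEOUS = 0.75
LAMBDA_HETEROGENEOUS = 0.15
GAUSSIAN_FRACTION = 0.68


@dataclass
class LesionStats:
    """Class statistics of a two-class split of a region at a threshold."""

    m_l: float
    m_b: float
    sigma_l: float
    sigma_b: float
    P_l: float
    P_b: float


@dataclass
class ThresholdConfig:
    """Tunables of the similar-lesion counting pipeline.

    ``lambda_weight`` and ``t_grid`` default to ``None`` meaning
    "derive from the image" (homogeneity rule; integer grid between the
    1st and 99th intensity percentiles of the crop region).
    ``similarity_threshold`` is in (alpha, beta) units: alpha is an HU-like
    contrast magnitude and beta a dimensionless axis ratio.
    """

    lambda_weight: float | None = None
    t_grid: np.ndarray | None = None
    min_cluster_px: int = 9
    similarity_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.lambda_weight is not None and not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.t_grid is not None:
            self.t_grid = np.asarray(self.t_grid, float)
            if self.t_grid.size == 0:
                raise ValueError("t_grid must be nonempty")
            if np.any(np.diff(self.t_grid) <= 0):
                raise ValueError("t_grid must be strictly increasing")
        if self.min_cluster_px < 1:
            raise ValueError("min_cluster_px must be at least 1")


@dataclass
class ClusterSignature:
    """(alpha, beta) summary of one candidate cluster."""

    alpha: float
    beta: float
    pixel_count: int


@dataclass
class MultiplicityResult:
    count: int
    accepted_clusters: list[tuple[ClusterSignature, float]]
    rejected_clusters: list[tuple[ClusterSignature, float]]
    t_star: float
    lambda_used: float
    primary_signature: ClusterSignature | None = field(default=None)


# ---------------------------------------------------------------------------
# lambda selection
# ---------------------------------------------------------------------------


def fraction_within_sigma(values: np.ndarray) -> float:
    """Fraction of values within one (population) standard deviation of the mean."""
    values = np.asarray(values, float)
    m = values.mean()
    s = values.std()
    return float(np.mean(np.abs(values - m) <= s))


def lambda_for_fraction(frac: float) -> float:
    """Homogeneity rule: >= 68% within one sigma (boundary inclusive) -> 0.75."""
    return LAMBDA_HOMOGENEOUS if frac >= GAUSSIAN_FRACTION else LAMBDA_HETEROGENEOUS


def select_lambda(img: LesionImage) -> float:
    """Choose the objective weight from the primary lesion's homogeneity."""
    vals = img.lesion_values
    if vals.size == 0:
        raise MaskError("primary mask is empty")
    return lambda_for_fraction(fraction_within_sigma(vals))


# ---------------------------------------------------------------------------
# threshold objective and optimisation
# ---------------------------------------------------------------------------


def _lesion_side_high(pixels: np.ndarray, region: np.ndarray, primary: np.ndarray) -> bool:
    """Whether the lesion class is the high-intensity side of the threshold.

    Decided once from the user-drawn mask: lesion pixels brighter than the
    rest of the region mean "lesion = above T".
    """
    m_mask = pixels[primary & region].mean() if (primary & region).any() else pixels[primary].mean()
    rest = region & ~primary
    m_rest = pixels[rest].mean() if rest.any() else m_mask - 1.0
    return bool(m_mask >= m_rest)


def class_stats(values: np.ndarray, T: float, lesion_high: bool) -> LesionStats | None:
    """Split region values at ``T`` and return per-class statistics.

    Returns ``None`` when either class is empty.
    """
    hi = values > T
    lesion_vals = values[hi] if lesion_high else values[~hi]
    back_vals = values[~hi] if lesion_high else values[hi]
    if lesion_vals.size == 0 or back_vals.size == 0:
        return None
    n = values.size
    return LesionStats(
        m_l=float(lesion_vals.mean()),
        m_b=float(back_vals.mean()),
        sigma_l=float(lesion_vals.std()),
        sigma_b=float(back_vals.std()),
        P_l=lesion_vals.size / n,
        P_b=back_vals.size / n,
    )


def threshold_objective(
    img: LesionImage,
    region: np.ndarray,
    primary_mask: np.ndarray,
    lambda_weight: float,
    T: float,
) -> float:
    """Evaluate J(lambda, T) on the region; +inf when a class is emptied."""
    values = img.pixels[region].astype(float)
    lesion_high = _lesion_side_high(img.pixels.astype(float), region, primary_mask)
    stats = class_stats(values, T, lesion_high)
    if stats is None:
        return math.inf
    sigma_w = math.sqrt(stats.P_l * stats.sigma_l**2 + stats.P_b * stats.sigma_b**2)
    return (1.0 - lambda_weight) * sigma_w - lambda_weight * abs(stats.m_l - stats.m_b)


def optimize_threshold(
    img: LesionImage,
    region: np.ndarray,
    primary_mask: np.ndarray,
    lambda_weight: float,
    t_grid: np.ndarray,
) -> float:
    """Grid-minimise J(lambda, T); ties broken by the smallest threshold."""
    t_grid = np.asarray(t_grid, float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be nonempty")
    values = img.pixels[region].astype(float)

    # vectorised sweep: sort once, classes at each T follow from searchsorted
    order = np.sort(values)
    csum = np.concatenate(([0.0], np.cumsum(order)))
    csq = np.concatenate(([0.0], np.cumsum(order**2)))
    n = order.size
    k = np.searchsorted(order, t_grid, side="right")  # of values <= T

    J = np.full(t_grid.shape, np.inf)
    valid = (k > 0) & (k < n)
    kv = k[valid]
    lo_n, hi_n = kv.astype(float), (n - kv).astype(float)
    lo_mean = csum[kv] / lo_n
    hi_mean = (csum[n] - csum[kv]) / hi_n
    lo_var = csq[kv] / lo_n - lo_mean**2
    hi_var = (csq[n] - csq[kv]) / hi_n - hi_mean**2
    lo_var = np.maximum(lo_var, 0.0)
    hi_var = np.maximum(hi_var, 0.0)
    sigma_w = np.sqrt((lo_n * lo_var + hi_n * hi_var) / n)
    # J depends on the two classes only through |m_l - m_b| and sigma_w,
    # both symmetric, so the lesion/background role assignment cancels here
    sep = np.abs(hi_mean - lo_mean)
    J[valid] = (1.0 - lambda_weight) * sigma_w - lambda_weight * sep

    if not np.isfinite(J).any():
        raise ValueError("every candidate threshold empties one class")
    return float(t_grid[int(np.argmin(J))])


# ---------------------------------------------------------------------------
# components and signatures
# ---------------------------------------------------------------------------


def label_components(binary_grid: np.ndarray, min_cluster_px: int) -> list[np.ndarray]:
    """4-connected components of a binary grid, small ones dropped.

    Returns a list of ``(n_px, 2)`` integer pixel-coordinate arrays ordered
    by the scanline position of each cluster's topmost-leftmost pixel.
    """
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    labels, n = ndimage.label(np.asarray(binary_grid, bool), structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if coords.shape[0] >= min_cluster_px:
            clusters.append(coords)
    clusters.sort(key=lambda c: (int(c[0, 0]), int(c[0, 1])))
    return clusters


def _moment_axis_lengths(coords: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths of the moment ellipse of a pixel set."""
    pts = coords.astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / pts.shape[0]
    eig = np.linalg.eigvalsh(cov)  # ascending
    minor = 4.0 * math.sqrt(max(eig[0], 0.0))
    major = 4.0 * math.sqrt(max(eig[1], 0.0))
    return major, minor


def cluster_signature(img: LesionImage, cluster_pixels: np.ndarray) -> ClusterSignature:
    """(alpha, beta) signature of a cluster given as an ``(n, 2)`` coord array.

    alpha = sqrt(d_mean^2 + d_sd^2) where d_mean/d_sd compare the pixels
    inside the cluster with a two-pixel ring immediately outside it.
    beta = major/minor moment-axis ratio, minor floored at one pixel.
    """
    coords = np.asarray(cluster_pixels, int)
    mask = np.zeros(img.pixels.shape, bool)
    mask[coords[:, 0], coords[:, 1]] = True
    ring = ndimage.binary_dilation(mask, iterations=2) & ~mask
    inside = img.pixels[mask].astype(float)
    outside = img.pixels[ring].astype(float)
    d_mean = inside.mean() - (outside.mean() if outside.size else inside.mean())
    d_sd = inside.std() - (outside.std() if outside.size else inside.std())
    alpha = math.hypot(d_mean, d_sd)
    major, minor = _moment_axis_lengths(coords)
    beta = max(major, 1.0) / max(minor, 1.0)
    return ClusterSignature(alpha=alpha, beta=beta, pixel_count=coords.shape[0])


def similarity_distance(sig_p: ClusterSignature, sig_c: ClusterSignature) -> float:
    """Euclidean distance between two signatures in (alpha, beta) space."""
    return math.hypot(sig_p.alpha - sig_c.alpha, sig_p.beta - sig_c.beta)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def derive_crop_region(img: LesionImage) -> np.ndarray:
    """Crop region when no organ mask is given: the primary-lesion bounding
    box expanded on every side by four times its diagonal, clipped to the
    image."""
    r0, r1, c0, c1 = mask_bbox(img.primary_mask)
    diag = math.hypot(r1 - r0, c1 - c0)
    margin = int(round(4.0 * diag))
    region = np.zeros(img.pixels.shape, bool)
    region[
        max(r0 - margin, 0) : min(r1 + margin, img.pixels.shape[0]),
        max(c0 - margin, 0) : min(c1 + margin, img.pixels.shape[1]),
    ] = True
    return region


def default_t_grid(values: np.ndarray) -> np.ndarray:
    """All integer intensities between the 1st and 99th percentiles."""
    lo = math.floor(np.percentile(values, 1))
    hi = math.ceil(np.percentile(values, 99))
    if hi <= lo:
        hi = lo + 1
    return np.arange(lo, hi + 1, dtype=float)


def count_similar_lesions(
    img: LesionImage, cfg: ThresholdConfig | None = None
) -> MultiplicityResult:
    """Run the full similar-lesion counting pipeline on one image."""
    cfg = cfg or ThresholdConfig()
    img.validate_mask()
    region = img.crop_region if img.crop_region is not None else derive_crop_region(img)

    lam = cfg.lambda_weight if cfg.lambda_weight is not None else select_lambda(img)
    values = img.pixels[region].astype(float)
    t_grid = cfg.t_grid if cfg.t_grid is not None else default_t_grid(values)
    t_star = optimize_threshold(img, region, img.primary_mask, lam, t_grid)

    lesion_high = _lesion_side_high(img.pixels.astype(float), region, img.primary_mask)
    if lesion_high:
        binary = (img.pixels > t_star) & region
    else:
        binary = (img.pixels <= t_star) & region

    clusters = label_components(binary, cfg.min_cluster_px)
    primary_coords = np.argwhere(img.primary_mask)
    sig_p = cluster_signature(img, primary_coords)

    accepted: list[tuple[ClusterSignature, float]] = []
    rejected: list[tuple[ClusterSignature, float]] = []
    for coords in clusters:
        if img.primary_mask[coords[:, 0], coords[:, 1]].any():
            continue  # the primary lesion is never counted
        sig = cluster_signature(img, coords)
        d = similarity_distance(sig_p, sig)
        if d <= cfg.similarity_threshold:
            accepted.append((sig, d))
        else:
            rejected.append((sig, d))

    return MultiplicityResult(
        count=len(accepted),
        accepted_clusters=accepted,
        rejected_clusters=rejected,
        t_star=t_star,
        lambda_used=lam,
        primary_signature=sig_p,
    )
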