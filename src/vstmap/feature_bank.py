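"""A 495/496-dimensional radiomic feature bank for 2-D CT lesions.

Five feature blocks are computed from a :class:`~vstmap.image.LesionImage`:

====================  ====  =========================================================
block                 dims  families
====================  ====  =========================================================
intensity                6  IntensityM 1, Entropy 1, ProportionThres 1, IntensityDiff 3
texture                376  GLCM 12, Gabor 32, Daube 324, Haar 1, RLE 7
shape                   20  Compactness 1, Eccentricity 1, Roughness 1,
                            LocalIntegral 15, RadialSig 2
histogram               32  LBP 12, Histogram-bin 20
edge                    61  Edge sharpness 60, EdgeHist 1
====================  ====  =========================================================

for 495 traditional dimensions; appending the similar-lesion count (see
:mod:`vstmap.multiplicity`) gives the full 496-dimensional vector.

The cited feature families admit many internal variants; the exact
configuration used here (filter banks, quantisation levels, wavelet
layout) is fixed in :class:`FeatureConfig` and in the module constants so
that the bank is reproducible; see ``docs/methods.md`` for the rationale
of each choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve
from skimage import measure
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from skimage.filters import gabor, sobel
from skimage.transform import resize

from .image import LesionImage, MaskError, mask_bbox

# ---------------------------------------------------------------------------
# descriptors and the feature matrix container
# ---------------------------------------------------------------------------

BLOCK_ORDER = ("intensity", "texture", "shape", "histogram", "edge")
BLOCK_DIMS = {
    "intensity": 6,
    "texture": 376,
    "shape": 20,
    "histogram": 32,
    "edge": 61,
    "multiplicity": 1,
}
N_TRADITIONAL = 495
N_FULL = 496


@dataclass(frozen=True)
class FeatureDescriptor:
    """One named feature family within a block."""

    name: str
    block: str
    dim: int


FEATURE_FAMILIES: tuple[FeatureDescriptor, ...] = (
    FeatureDescriptor("IntensityM", "intensity", 1),
    FeatureDescriptor("Entropy", "intensity", 1),
    FeatureDescriptor("ProportionThres", "intensity", 1),
    FeatureDescriptor("IntensityDiff", "intensity", 3),
    FeatureDescriptor("GLCM", "texture", 12),
    FeatureDescriptor("Gabor", "texture", 32),
    FeatureDescriptor("Daube", "texture", 324),
    FeatureDescriptor("Haar", "texture", 1),
    FeatureDescriptor("RLE", "texture", 7),
    FeatureDescriptor("Compactness", "shape", 1),
    FeatureDescriptor("Eccentricity", "shape", 1),
    FeatureDescriptor("Roughness", "shape", 1),
    FeatureDescriptor("LocalIntegral", "shape", 15),
    FeatureDescriptor("RadialSig", "shape", 2),
    FeatureDescriptor("LBP", "histogram", 12),
    FeatureDescriptor("HistogramBin", "histogram", 20),
    FeatureDescriptor("EdgeSharpness", "edge", 60),
    FeatureDescriptor("EdgeHist", "edge", 1),
    FeatureDescriptor("NumSimilarLesions", "multiplicity", 1),
)

GLCM_PROPS = ("contrast", "correlation", "energy")
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GABOR_FREQUENCIES = (1 / 16, 1 / 8, 1 / 4, 1 / 2)
GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
RLE_STATS = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE")
LOCAL_INTEGRAL_RADII = tuple(range(2, 17))
WAVELET_PATCH = 64
DAUBE_GRID = 6  # 6x6 block energies per detail subband


def feature_names(include_multiplicity: bool = True) -> list[str]:
    """Fully expanded, ordered column names of the feature vector."""
    names: list[str] = [
        "IntensityM",
        "Entropy",
        "ProportionThres",
        "IntensityDiff_r2",
        "IntensityDiff_r4",
        "IntensityDiff_r8",
    ]
    for prop in GLCM_PROPS:
        for deg in (0, 45, 90, 135):
            names.append(f"GLCM_{prop}_{deg}")
    for i, _ in enumerate(GABOR_FREQUENCIES):
        for j, _ in enumerate(GABOR_THETAS):
            names.append(f"Gabor_f{i}_t{j}_mean")
            names.append(f"Gabor_f{i}_t{j}_sd")
    for level in (3, 2, 1):
        for orient in ("H", "V", "D"):
            for b in range(DAUBE_GRID * DAUBE_GRID):
                names.append(f"Daube_L{level}{orient}_b{b:02d}")
    names.append("Haar_detail_energy")
    names.extend(f"RLE_{s}" for s in RLE_STATS)
    names.extend(["Compactness", "Eccentricity", "Roughness"])
    names.extend(f"LocalIntegral_r{r}" for r in LOCAL_INTEGRAL_RADII)
    names.extend(["RadialSig_mean", "RadialSig_sd"])
    names.extend(f"LBP_u{c}" for c in range(10))
    names.extend(["LBP_energy", "LBP_entropy"])
    names.extend(f"HistBin_{b:02d}" for b in range(20))
    names.extend(f"EdgeSharp_{i:02d}" for i in range(60))
    names.append("EdgeHist")
    if include_multiplicity:
        names.append("NumSimilarLesions")
    return names


@dataclass
class FeatureMatrix:
    """Samples-by-features matrix with named columns and normalisation stats.

    ``norm_stats`` is ``None`` for raw matrices and ``(mean, sd)`` per
    column after :func:`zscore_normalize` (population sd convention).
    """

    values: np.ndarray
    column_names: list[str]
    sample_ids: list[str]
    norm_stats: tuple[np.ndarray, np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match matrix width")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix height")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_names)
        df.index.name = "sample_id"
        df.to_csv(path)
        if self.norm_stats is not None:
            side = Path(path).with_suffix(".norm.json")
            mean, sd = self.norm_stats
            side.write_text(
                json.dumps({"mean": mean.tolist(), "sd": sd.tolist()}, indent=1)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        stats = None
        side = Path(path).with_suffix(".norm.json")
        if side.exists():
            d = json.loads(side.read_text())
            stats = (np.asarray(d["mean"], float), np.asarray(d["sd"], float))
        return cls(
            values=df.to_numpy(float),
            column_names=list(df.columns),
            sample_ids=[str(s) for s in df.index],
            norm_stats=stats,
        )


class BlockError(ValueError):
    """A feature block could not be computed; the message names the block."""


@dataclass
class FeatureConfig:
    """Tunables of the feature bank.

    ``hu_window`` bounds the 20 equal-width histogram bins (HU-like units).
    ``proportion_threshold`` is the cut for ProportionThres; when ``None``
    it defaults to the optimum of the within-class-variance threshold
    objective on the image's crop region.
    """

    hu_window: tuple[float, float] = (-200.0, 400.0)
    proportion_threshold: float | None = None
    entropy_bins: int = 32
    glcm_levels: int = 32
    rle_levels: int = 16
    intensity_diff_radii: tuple[int, ...] = (2, 4, 8)
    edge_n_profiles: int = 60
    edge_profile_halflen: float = 4.0
    edge_profile_step: float = 0.5
    edge_hist_bins: int = 16


# ---------------------------------------------------------------------------
# small shared helpers
# ---------------------------------------------------------------------------


def _entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def _disk(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    return (rr**2 + cc**2) <= radius**2


def _masked_patch(img: LesionImage) -> tuple[np.ndarray, np.ndarray]:
    """Bounding-box crop of the pixels with outside-mask pixels replaced by
    the lesion median (keeps texture statistics mask-driven)."""
    r0, r1, c0, c1 = mask_bbox(img.primary_mask)
    patch = img.pixels[r0:r1, c0:c1].astype(float).copy()
    mpatch = img.primary_mask[r0:r1, c0:c1]
    patch[~mpatch] = float(np.median(img.lesion_values))
    return patch, mpatch


def _quantize(patch: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = patch[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(patch.shape, np.uint8)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(mask)
    return np.argwhere(mask & ~inner)


# ---------------------------------------------------------------------------
# intensity block (6)
# ---------------------------------------------------------------------------


def extract_intensity_block(
    img: LesionImage, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Median, binned entropy (bits), proportion above threshold, and the
    lesion-vs-ring intensity difference at three ring scales."""
    cfg = cfg or FeatureConfig()
    img.validate_mask()
    vals = img.lesion_values.astype(float)

    median = float(np.median(vals))
    counts, _ = np.histogram(vals, bins=cfg.entropy_bins)
    entropy = _entropy_bits(counts)

    thr = cfg.proportion_threshold
    if thr is None:
        thr = _default_proportion_threshold(img)
    proportion = float(np.mean(vals > thr))

    diffs = []
    for r in cfg.intensity_diff_radii:
        ring = ndimage.binary_dilation(img.primary_mask, structure=_disk(r))
        ring &= ~img.primary_mask
        ring_vals = img.pixels[ring].astype(float)
        diffs.append(vals.mean() - (ring_vals.mean() if ring_vals.size else vals.mean()))
    return np.array([median, entropy, proportion, *diffs], float)


def _default_proportion_threshold(img: LesionImage) -> float:
    # deferred import: multiplicity supplies the threshold optimiser
    from . import multiplicity as mp

    region = img.crop_region if img.crop_region is not None else mp.derive_crop_region(img)
    lam = mp.select_lambda(img)
    grid = mp.default_t_grid(img.pixels[region].astype(float))
    return mp.optimize_threshold(img, region, img.primary_mask, lam, grid)


# ---------------------------------------------------------------------------
# texture block (376)
# ---------------------------------------------------------------------------


def _glcm_features(patch: np.ndarray, mask: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    q = _quantize(patch, mask, cfg.glcm_levels)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=list(GLCM_ANGLES),
        levels=cfg.glcm_levels,
        symmetric=True,
        normed=True,
    )
    out = []
    for prop in GLCM_PROPS:
        out.extend(graycoprops(glcm, prop)[0])
    return np.asarray(out, float)


def _gabor_features(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = []
    for f in GABOR_FREQUENCIES:
        for t in GABOR_THETAS:
            real, imag = gabor(patch, frequency=f, theta=t)
            mag = np.hypot(real, imag)[mask]
            out.append(mag.mean())
            out.append(mag.std())
    return np.asarray(out, float)


def _wavelet_patch(patch: np.ndarray) -> np.ndarray:
    return resize(
        patch,
        (WAVELET_PATCH, WAVELET_PATCH),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )


def _daubechies_features(p64: np.ndarray) -> np.ndarray:
    """db4 3-level decomposition; per detail subband a 6x6 grid of block
    mean-square energies, ordered level 3 -> 1, orientation H, V, D."""
    coeffs = pywt.wavedec2(p64, "db4", level=3, mode="periodization")
    out = []
    for detail in coeffs[1:]:  # level 3, 2, 1
        for sub in detail:  # H, V, D
            for rows in np.array_split(sub, DAUBE_GRID, axis=0):
                for block in np.array_split(rows, DAUBE_GRID, axis=1):
                    out.append(float(np.mean(block * block)))
    return np.asarray(out, float)


def _haar_feature(p64: np.ndarray) -> float:
    _, (ch, cv, cd) = pywt.wavedec2(p64, "haar", level=1, mode="periodization")
    return float((ch**2).sum() + (cv**2).sum() + (cd**2).sum())


def _run_lengths(q: np.ndarray, levels: int) -> np.ndarray:
    """Gray-level run-length matrix over horizontal runs; shape (levels, max_len)."""
    max_len = q.shape[1]
    glrlm = np.zeros((levels, max_len), float)
    for row in q:
        start = 0
        for i in range(1, len(row) + 1):
            if i == len(row) or row[i] != row[start]:
                glrlm[row[start], i - start - 1] += 1
                start = i
    return glrlm


def _rle_features(patch: np.ndarray, mask: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    q = _quantize(patch, mask, cfg.rle_levels)
    glrlm = _run_lengths(q, cfg.rle_levels)
    n_runs = glrlm.sum()
    lengths = np.arange(1, glrlm.shape[1] + 1, dtype=float)
    grays = np.arange(1, cfg.rle_levels + 1, dtype=float)
    run_sum = glrlm.sum(axis=0)
    gray_sum = glrlm.sum(axis=1)
    sre = float((run_sum / lengths**2).sum() / n_runs)
    lre = float((run_sum * lengths**2).sum() / n_runs)
    gln = float((gray_sum**2).sum() / n_runs)
    rln = float((run_sum**2).sum() / n_runs)
    rp = float(n_runs / q.size)
    lgre = float((gray_sum / grays**2).sum() / n_runs)
    hgre = float((gray_sum * grays**2).sum() / n_runs)
    return np.array([sre, lre, gln, rln, rp, lgre, hgre], float)


def extract_texture_block(
    img: LesionImage, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """GLCM (12), Gabor (32), Daubechies (324), Haar (1) and run-length (7)
    texture features of the masked lesion patch."""
    cfg = cfg or FeatureConfig()
    img.validate_mask()
    r0, r1, c0, c1 = mask_bbox(img.primary_mask)
    if (r1 - r0) < 8 or (c1 - c0) < 8:
        raise BlockError(
            f"texture block: lesion bounding box {(r1 - r0)}x{(c1 - c0)} "
            "is smaller than 8x8 pixels"
        )
    patch, mpatch = _masked_patch(img)
    p64 = _wavelet_patch(patch)
    return np.concatenate(
        [
            _glcm_features(patch, mpatch, cfg),
            _gabor_features(patch, mpatch),
            _daubechies_features(p64),
            [_haar_feature(p64)],
            _rle_features(patch, mpatch, cfg),
        ]
    )


# ---------------------------------------------------------------------------
# shape block (20)
# ---------------------------------------------------------------------------


def extract_shape_block(img: LesionImage, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Compactness, eccentricity, roughness, local area integral invariant
    at 15 radii, and the (mean, sd) radial distance signature."""
    img.validate_mask()
    if img.mask_touches_border():
        raise BlockError("shape block: mask touches the image border")
    mask = img.primary_mask
    props = measure.regionprops(mask.astype(int))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    compactness = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0
    eccentricity = float(props.eccentricity)
    hull_perimeter = float(measure.perimeter(props.image_convex))
    roughness = perimeter / hull_perimeter if hull_perimeter > 0 else 1.0

    # local area integral invariant: mean over boundary pixels of the
    # fraction of a radius-r disk lying inside the mask
    r0, r1, c0, c1 = mask_bbox(mask)
    pad = max(LOCAL_INTEGRAL_RADII) + 1
    window = np.pad(mask[r0:r1, c0:c1].astype(float), pad)
    boundary = _boundary_pixels(mask)
    brel = boundary - np.array([r0 - pad, c0 - pad])
    lii = []
    for r in LOCAL_INTEGRAL_RADII:
        disk = _disk(r).astype(float)
        frac = fftconvolve(window, disk, mode="same") / disk.sum()
        lii.append(float(frac[brel[:, 0], brel[:, 1]].mean()))

    centroid = np.asarray(props.centroid)
    dists = np.linalg.norm(boundary - centroid, axis=1)
    return np.array(
        [compactness, eccentricity, roughness, *lii, dists.mean(), dists.std()], float
    )


# ---------------------------------------------------------------------------
# histogram block (32)
# ---------------------------------------------------------------------------


def extract_histogram_block(
    img: LesionImage, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Uniform LBP(P=8, R=1) summary (12) and 20 equal-width intensity-bin
    counts over the configured HU window.

    The LBP summary is the fraction of lesion pixels in each of the 10
    uniform codes plus the energy and entropy (bits) of that code
    distribution.  Out-of-window intensities are clipped into the edge
    bins, so the 20 counts always sum to the lesion pixel count.
    """
    cfg = cfg or FeatureConfig()
    img.validate_mask()
    pix = img.pixels
    if not np.issubdtype(pix.dtype, np.integer):
        pix = np.rint(pix).astype(np.int32)
    codes = local_binary_pattern(pix, P=8, R=1, method="uniform")
    lesion_codes = codes[img.primary_mask].astype(int)
    counts = np.bincount(lesion_codes, minlength=10).astype(float)
    p = counts / counts.sum()
    lbp = np.concatenate([p, [float((p**2).sum()), _entropy_bits(p)]])

    lo, hi = cfg.hu_window
    vals = np.clip(img.lesion_values.astype(float), lo, hi)
    hist, _ = np.histogram(vals, bins=20, range=(lo, hi))
    return np.concatenate([lbp, hist.astype(float)])


# ---------------------------------------------------------------------------
# edge block (61)
# ---------------------------------------------------------------------------


def _contour_samples(mask: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """``n`` equally spaced (by arc length) points on the lesion contour and
    their unit outward-normal directions."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise BlockError("edge block: no contour found")
    contour = max(contours, key=len)
    if len(contour) < n:
        raise BlockError(
            f"edge block: contour has {len(contour)} points, fewer than the "
            f"{n} requested profiles"
        )
    closed = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    seg = np.linalg.norm(np.diff(closed, axis=0, append=closed[:1]), axis=1)
    arclen = np.concatenate(([0.0], np.cumsum(seg)))[:-1]
    total = arclen[-1] + seg[-1]
    targets = np.arange(n) * total / n

    idx = np.searchsorted(arclen, targets, side="right") - 1
    nxt = (idx + 1) % len(closed)
    frac = (targets - arclen[idx]) / np.maximum(seg[idx], 1e-12)
    points = closed[idx] + frac[:, None] * (closed[nxt] - closed[idx])

    tangents = closed[nxt] - closed[(idx - 1) % len(closed)]
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    return points, normals


def extract_edge_block(img: LesionImage, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Max gradient magnitude along 60 profiles normal to the contour, plus
    the entropy of gradient magnitudes on the one-pixel contour band."""
    cfg = cfg or FeatureConfig()
    img.validate_mask()
    if img.mask_touches_border():
        raise BlockError("edge block: mask touches the image border")
    points, normals = _contour_samples(img.primary_mask, cfg.edge_n_profiles)
    ts = np.arange(
        -cfg.edge_profile_halflen,
        cfg.edge_profile_halflen + cfg.edge_profile_step / 2,
        cfg.edge_profile_step,
    )
    pix = img.pixels.astype(float)
    sharp = np.empty(cfg.edge_n_profiles)
    for i, (p, nvec) in enumerate(zip(points, normals)):
        coords = p[None, :] + ts[:, None] * nvec[None, :]
        profile = map_coordinates(pix, coords.T, order=1, mode="nearest")
        sharp[i] = np.max(np.abs(np.diff(profile))) / cfg.edge_profile_step

    band = ndimage.binary_dilation(img.primary_mask) & ~ndimage.binary_erosion(
        img.primary_mask
    )
    grad = sobel(pix)[band]
    hist, _ = np.histogram(grad, bins=cfg.edge_hist_bins)
    return np.concatenate([sharp, [_entropy_bits(hist)]])


# ---------------------------------------------------------------------------
# assembly and normalisation
# ---------------------------------------------------------------------------


def assemble_feature_vector(
    img: LesionImage,
    similar_count: int | None = None,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Concatenate all blocks in the fixed order; 495 values, or 496 when a
    similar-lesion count is appended."""
    cfg = cfg or FeatureConfig()
    blocks = [
        extract_intensity_block(img, cfg),
        extract_texture_block(img, cfg),
        extract_shape_block(img, cfg),
        extract_histogram_block(img, cfg),
        extract_edge_block(img, cfg),
    ]
    vec = np.concatenate(blocks)
    assert vec.size == N_TRADITIONAL
    if similar_count is not None:
        vec = np.concatenate([vec, [float(similar_count)]])
    return vec


def build_feature_matrix(
    images: list[LesionImage],
    sample_ids: list[str] | None = None,
    cfg: FeatureConfig | None = None,
    multiplicity_cfg=None,
    include_multiplicity: bool = True,
) -> FeatureMatrix:
    """Extract the feature matrix for a cohort of images.

    When ``include_multiplicity`` is set, the similar-lesion count is
    computed per image with :func:`vstmap.multiplicity.count_similar_lesions`
    and appended as the 496th column.
    """
    from . import multiplicity as mp

    cfg = cfg or FeatureConfig()
    if sample_ids is None:
        sample_ids = [f"sample_{i:03d}" for i in range(len(images))]
    rows = []
    for sid, img in zip(sample_ids, images):
        try:
            count = None
            if include_multiplicity:
                count = mp.count_similar_lesions(img, multiplicity_cfg).count
            rows.append(assemble_feature_vector(img, count, cfg))
        except Exception as exc:
            raise BlockError(f"feature extraction failed for sample {sid!r}: {exc}") from exc
    return FeatureMatrix(
        values=np.vstack(rows),
        column_names=feature_names(include_multiplicity),
        sample_ids=list(sample_ids),
    )


def zscore_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-column z-scoring to mean 0, sd 1 (population sd, divide by N).

    Constant columns map to all zeros.  The per-column (mean, sd) is stored
    in ``norm_stats`` so that prediction-time data can be normalised with
    the training statistics.
    """
    if fm.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0)
    values = np.where(sd > 0, (fm.values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return FeatureMatrix(
        values=values,
        column_names=list(fm.column_names),
        sample_ids=list(fm.sample_ids),
        norm_stats=(mean, sd),
    )


def apply_norm_stats(
    values: np.ndarray, norm_stats: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Normalise new data with stored training (mean, sd); constant training
    columns map to zero."""
    mean, sd = norm_stats
    return np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
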