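"""Synthetic CT-like lesion phantoms and feature/label matrices.

Real annotated liver-lesion CT cohorts are rarely shareable, so every
downstream stage of this package is exercised on two kinds of seeded
synthetic data:

* :func:`make_lesion_phantom` renders an elliptical "liver" region on a
  flat background and plants a primary lesion plus ``k`` satellite lesions
  with controlled intensity, shape and texture.  The ground truth (planted
  satellite count and footprints) is returned alongside the image, which
  makes lesion-multiplicity recovery directly checkable.
* :func:`make_feature_label_matrix` draws a feature matrix in which a known
  subset of columns carries the label signal, for testing the feature
  selector against a planted truth.

Both generators are fully determined by the seed carried in their spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .feature_bank import FeatureMatrix
from .image import LesionImage

TEXTURE_KINDS = ("flat", "speckle", "bimodal")


@dataclass
class LesionSpec:
    """Geometry and appearance of one rendered lesion (a rotated ellipse).

    ``axes`` are the (major, minor) semi-axis lengths in pixels; rotation is
    in radians.  ``texture_kind`` selects the fill: ``flat`` (constant),
    ``speckle`` (per-pixel Gaussian jitter of ``intensity_sigma``) or
    ``bimodal`` (two-level checker fill at ``mean_intensity +/-
    intensity_sigma``).
    """

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (major, minor) semi-axes, pixels
    rotation: float = 0.0
    mean_intensity: float = 100.0
    intensity_sigma: float = 0.0
    texture_kind: str = "flat"

    def __post_init__(self) -> None:
        major, minor = self.axes
        if not (major >= minor > 1):
            raise ValueError(
                f"lesion axes must satisfy major >= minor > 1, got {self.axes}"
            )
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(
                f"unknown texture_kind {self.texture_kind!r}; "
                f"choose one of {TEXTURE_KINDS}"
            )


@dataclass
class PhantomSpec:
    """Full description of a synthetic slice: liver, primary, satellites."""

    width: int = 128
    height: int = 128
    background_level: float = -50.0
    liver_level: float = 80.0
    primary: LesionSpec = field(
        default_factory=lambda: LesionSpec(center=(64, 64), axes=(12, 10))
    )
    satellites: list[LesionSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("phantom must be at least 64x64 pixels")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _liver_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), bool)
    rr, cc = draw_ellipse(
        spec.height / 2,
        spec.width / 2,
        spec.height * 0.44,
        spec.width * 0.46,
        shape=mask.shape,
    )
    mask[rr, cc] = True
    return mask


def _lesion_mask(les: LesionSpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    major, minor = les.axes
    # rotation=0 lays the major axis along columns
    rr, cc = draw_ellipse(
        les.center[0], les.center[1], minor, major, shape=shape, rotation=les.rotation
    )
    mask[rr, cc] = True
    return mask


def _fill_lesion(
    img: np.ndarray, mask: np.ndarray, les: LesionSpec, rng: np.random.Generator
) -> None:
    if les.texture_kind == "flat":
        img[mask] = les.mean_intensity
    elif les.texture_kind == "speckle":
        img[mask] = les.mean_intensity + rng.normal(
            0.0, les.intensity_sigma, size=int(mask.sum())
        )
    else:  # bimodal: 2-px checker of mean +/- sigma
        rr, cc = np.nonzero(mask)
        sign = (((rr // 2) + (cc // 2)) % 2) * 2 - 1
        img[rr, cc] = les.mean_intensity + sign * les.intensity_sigma


def make_lesion_phantom(spec: PhantomSpec) -> tuple[LesionImage, dict]:
    """Render a phantom slice and return it with its planted ground truth.

    Returns
    -------
    image : LesionImage
        Pixels as ``int16`` HU-like values; ``crop_region`` is set to the
        liver mask.
    ground_truth : dict
        ``satellite_count`` (int) and ``satellite_masks`` (list of boolean
        arrays, one per planted satellite, in spec order).

    Raises
    ------
    ValueError
        If any lesion centre lies outside the liver region or any pair of
        lesion footprints overlaps (the offending lesions are named).
    """
    rng = np.random.default_rng(spec.seed)
    liver = _liver_mask(spec)
    shape = liver.shape

    lesions = [("primary", spec.primary)] + [
        (f"satellite {i}", s) for i, s in enumerate(spec.satellites)
    ]
    masks: list[np.ndarray] = []
    for name, les in lesions:
        r, c = int(round(les.center[0])), int(round(les.center[1]))
        if not (0 <= r < spec.height and 0 <= c < spec.width) or not liver[r, c]:
            raise ValueError(f"{name} centre {les.center} lies outside the liver region")
        masks.append(_lesion_mask(les, shape))
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise ValueError(
                    f"lesion footprints overlap: {lesions[i][0]} and {lesions[j][0]}"
                )

    img = np.full(shape, spec.background_level, float)
    img[liver] = spec.liver_level
    for (_, les), mask in zip(lesions, masks):
        _fill_lesion(img, mask, les, rng)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)

    img16 = np.clip(np.rint(img), -32768, 32767).astype(np.int16)
    image = LesionImage(pixels=img16, primary_mask=masks[0], crop_region=liver)
    ground_truth = {
        "satellite_count": len(spec.satellites),
        "satellite_masks": masks[1:],
    }
    return image, ground_truth


# ---------------------------------------------------------------------------
# synthetic feature/label matrices
# ---------------------------------------------------------------------------

LabelRule = Callable[[np.ndarray], np.ndarray]


def _sign_sum(informative: np.ndarray) -> np.ndarray:
    s = informative.sum(axis=1)
    lab = np.where(s >= 0, 1, -1)
    return lab.astype(int)


_NAMED_RULES: dict[str, LabelRule] = {"sign_sum": _sign_sum}


@dataclass
class SyntheticLabelDesign:
    """Design of a feature matrix with a planted label signal.

    Features are i.i.d. standard normal.  Labels in ``{1, -1}`` are computed
    from the informative columns by ``label_rule`` (default ``"sign_sum"``:
    the sign of their row sum — an additive rule in which every informative
    column is individually predictive but the full set is needed for high
    accuracy), then a fraction ``label_noise_rate`` of labels is flipped.
    Non-informative columns are label-independent by construction.
    """

    n_samples: int
    n_features: int
    informative_columns: tuple[int, ...] = ()
    label_rule: str | LabelRule = "sign_sum"
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError(
                "n_samples must be at least 10 to support fivefold cross-validation"
            )
        self.informative_columns = tuple(self.informative_columns)
        for c in self.informative_columns:
            if not 0 <= c < self.n_features:
                raise ValueError(f"informative column {c} outside [0, {self.n_features})")
        if not 0.0 <= self.label_noise_rate < 0.5:
            raise ValueError("label_noise_rate must lie in [0, 0.5)")


def make_feature_label_matrix(
    design: SyntheticLabelDesign,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw a seeded (FeatureMatrix, labels) pair with a planted signal."""
    rng = np.random.default_rng(design.seed)
    X = rng.standard_normal((design.n_samples, design.n_features))
    rule = (
        _NAMED_RULES[design.label_rule]
        if isinstance(design.label_rule, str)
        else design.label_rule
    )
    if design.informative_columns:
        labels = rule(X[:, list(design.informative_columns)])
    else:
        labels = np.where(rng.random(design.n_samples) < 0.5, 1, -1)
    labels = np.asarray(labels, int).copy()
    if design.label_noise_rate > 0:
        flip = rng.random(design.n_samples) < design.label_noise_rate
        labels[flip] = -labels[flip]

    names = [f"syn_{j:03d}" for j in range(design.n_features)]
    fm = FeatureMatrix(
        values=X,
        column_names=names,
        sample_ids=[f"s{i:03d}" for i in range(design.n_samples)],
    )
    return fm, labels
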