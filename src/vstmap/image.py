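"""Core image container for lesion analysis.

A :class:`LesionImage` bundles a 2-D CT slice (HU-like intensities), the
radiologist-drawn binary mask of the primary lesion, and an optional crop
region delimiting the organ of interest (e.g. a liver mask).  All feature
extraction and lesion-counting operations take this container as input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class MaskError(ValueError):
    """Raised when a lesion mask violates the contract of an operation."""


@dataclass
class LesionImage:
    """A CT slice with a primary-lesion mask.

    Parameters
    ----------
    pixels
        2-D array of HU-like intensities (integer or float).
    primary_mask
        Boolean array of the same shape; the radiologist ROI of the
        primary lesion.  Must be a single connected component with at
        least 16 foreground pixels.
    crop_region
        Optional boolean array of the same shape restricting analysis to
        the organ and its surroundings (e.g. a liver mask).  When absent,
        operations that need it derive one from the primary-lesion
        bounding box.
    """

    pixels: np.ndarray
    primary_mask: np.ndarray
    crop_region: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.primary_mask = np.asarray(self.primary_mask).astype(bool)
        if self.pixels.ndim != 2:
            raise MaskError("pixels must be a 2-D array")
        if self.primary_mask.shape != self.pixels.shape:
            raise MaskError(
                f"mask shape {self.primary_mask.shape} does not match "
                f"pixel shape {self.pixels.shape}"
            )
        if self.crop_region is not None:
            self.crop_region = np.asarray(self.crop_region).astype(bool)
            if self.crop_region.shape != self.pixels.shape:
                raise MaskError("crop_region shape does not match pixel shape")

    # -- validation helpers -------------------------------------------------

    def validate_mask(self) -> None:
        """Check the primary-mask invariants (size and connectivity)."""
        n_fg = int(self.primary_mask.sum())
        if n_fg == 0:
            raise MaskError("primary mask is empty")
        if n_fg < 16:
            raise MaskError(f"primary mask has only {n_fg} pixels (minimum 16)")
        # 8-connectivity for the ROI itself; candidate-cluster labelling
        # elsewhere uses 4-connectivity.
        structure = np.ones((3, 3), bool)
        _, n_comp = ndimage.label(self.primary_mask, structure=structure)
        if n_comp != 1:
            raise MaskError(
                f"primary mask has {n_comp} connected components (expected 1)"
            )

    def mask_touches_border(self) -> bool:
        m = self.primary_mask
        return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())

    @property
    def lesion_values(self) -> np.ndarray:
        return self.pixels[self.primary_mask]


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Return the tight bounding box ``(r0, r1, c0, c1)`` (half-open) of a mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise MaskError("cannot take the bounding box of an empty mask")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1
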