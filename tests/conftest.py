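"""Shared fixtures: small analytic lesion images and phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from vstmap.image import LesionImage
from vstmap.phantoms import LesionSpec, PhantomSpec


def make_disk_image(
    radius: int = 12,
    level_in: float = 100.0,
    level_out: float = 50.0,
    shape: tuple[int, int] = (96, 96),
    center: tuple[int, int] | None = None,
) -> LesionImage:
    """Flat disk lesion on a flat background."""
    center = center or (shape[0] // 2, shape[1] // 2)
    mask = np.zeros(shape, bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    pixels = np.where(mask, level_in, level_out).astype(np.int16)
    return LesionImage(pixels=pixels, primary_mask=mask)


def ring_centers(k: int, radius: float = 38.0, offset: float = 0.0, center=(64.0, 64.0)):
    """k satellite centres evenly spaced on a circle inside the liver."""
    angles = offset + np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    return [
        (center[0] + radius * np.sin(a), center[1] + radius * np.cos(a)) for a in angles
    ]


def satellite_phantom_spec(
    k: int, seed: int, noise_sigma: float = 0.0, offset: float | None = None
) -> PhantomSpec:
    """A primary lesion plus k identical satellites on a ring."""
    offset = (0.3 * seed) if offset is None else offset
    sats = [
        LesionSpec(center=c, axes=(12, 10), mean_intensity=180.0)
        for c in ring_centers(max(k, 1), offset=offset)
    ][:k]
    return PhantomSpec(
        primary=LesionSpec(center=(64, 64), axes=(12, 10), mean_intensity=180.0),
        satellites=sats,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@pytest.fixture
def disk_img() -> LesionImage:
    return make_disk_image()


def annotation_cohort(n: int, seed: int):
    """Phantom cohort with three appearance-driven semantic terms.

    Each sample independently combines three balanced binary attributes:
    hyperdense (lesion mean 180 vs 120 HU), elongated (axes 16x6 vs 12x10)
    and multilesion (3 identical satellites vs none).  A fourth term
    "lesion" is present in every sample, so the 20-75% occurrence filter
    must drop it.  Returns (images, annotation_set, attributes).
    """
    from vstmap.annotator import VSTAnnotationSet
    from vstmap.phantoms import make_lesion_phantom

    rng = np.random.default_rng(seed)
    images, rows = [], []
    for i in range(n):
        hyper = bool((i % 2))
        elong = bool((i // 2) % 2)
        multi = bool((i // 4) % 2)
        level = (180.0 if hyper else 120.0) + rng.uniform(-5, 5)
        axes = (16.0, 6.0) if elong else (12.0, 10.0)
        axes = (axes[0] + rng.uniform(-1, 1), axes[1] + rng.uniform(-0.8, 0.8))
        primary = LesionSpec(
            center=(64, 64), axes=axes, rotation=rng.uniform(0, np.pi),
            mean_intensity=level,
        )
        sats = []
        if multi:
            # satellites stay round so they remain within the liver and
            # within the similarity threshold of any primary
            for c in ring_centers(3, offset=rng.uniform(0, 2 * np.pi)):
                sats.append(LesionSpec(center=c, axes=(12, 10), mean_intensity=level))
        spec = PhantomSpec(
            primary=primary, satellites=sats, noise_sigma=2.0,
            seed=int(rng.integers(2**31)),
        )
        img, _ = make_lesion_phantom(spec)
        images.append(img)
        rows.append([True, hyper, elong, multi])

    ann = VSTAnnotationSet(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        vocabulary=["lesion", "hyperdense", "elongated", "multilesion"],
        presence=np.array(rows, bool),
    )
    attrs = {
        "hyperdense": np.array([r[1] for r in rows]),
        "elongated": np.array([r[2] for r in rows]),
        "multilesion": np.array([r[3] for r in rows]),
    }
    return images, ann, attrs
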