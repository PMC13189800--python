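"""Circular particle detection, duplicate removal and fixed-size cropping.

Candidate particles are located with the circle Hough transform on a Canny
edge map, duplicate detections of the same grain are collapsed with DBSCAN
on the center coordinates, and a 512 x 512 region is cropped around each
surviving center.  Regions falling outside the source image are padded with
the image's median border intensity so no artificial step edges are
introduced for the edge-based descriptors downstream.

Coordinate convention: 0-based ``(x, y)`` with ``x`` the column; crops use
half-open pixel ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks
from sklearn.cluster import DBSCAN

__all__ = ["HoughParams", "Detection", "ParticleCrop", "detect_circles",
           "dedup_detections", "crop_particle"]

CROP_SIZE = 512


@dataclass(frozen=True)
class HoughParams:
    """Circle-transform settings.

    Defaults bracket the expected grain radii at the rendered scale
    (dust ~8-22 px up to swollen burst grains ~105 px); ``min_distance``
    is about the smallest intact radius so two true grains are never merged
    while near-coincident duplicate peaks still survive to the dedup stage.
    """

    min_radius: int = 20
    max_radius: int = 110
    radius_step: int = 2
    min_distance: int = 50
    canny_sigma: float = 2.0
    # edge thresholds as gradient-magnitude quantiles: keeping only the
    # strongest ~10% suppresses sensor-noise edges, which both cleans the
    # accumulator and dominates the transform's runtime
    canny_low_quantile: float = 0.90
    canny_high_quantile: float = 0.98
    accum_threshold: float = 0.35  # fraction of perimeter support, in [0, 1]
    max_detections: int = 200
    downscale: int = 1  # integer image downscale before the transform


@dataclass(frozen=True)
class Detection:
    """A candidate particle: Hough center, the Hough 'ideal circle' radius
    consumed by the inscribed-ratio descriptor, and the accumulator score."""

    image_id: str
    center: tuple[float, float]  # (x, y)
    radius: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class ParticleCrop:
    """A 512 x 512 grayscale crop centered on a detection.

    ``center_in_crop`` locates the Hough center in crop coordinates;
    ``pad_fill`` records the border-fill intensity used for out-of-image
    regions (the fill policy metadata)."""

    pixels: np.ndarray
    detection: Detection
    label: str | None = None
    center_in_crop: tuple[float, float] = (CROP_SIZE // 2, CROP_SIZE // 2)
    pad_fill: float | None = None


def as_gray(image: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit luminance; grayscale passes through."""
    if image.ndim == 3:
        return np.clip(np.rint(rgb2gray(image) * 255), 0, 255).astype(np.uint8)
    return image


def detect_circles(image: np.ndarray, params: HoughParams = HoughParams(),
                   image_id: str = "") -> list[Detection]:
    """Find circular candidates; deterministic ordering by descending
    accumulator score, ties broken by (y, x).

    Degenerate (empty or constant) images yield an empty list.
    """
    img = as_gray(image)
    if img.size == 0 or img.min() == img.max():
        return []
    ds = max(1, int(params.downscale))
    work = img.astype(float)
    if ds > 1:
        from skimage.transform import downscale_local_mean
        work = downscale_local_mean(work, (ds, ds))
    edges = canny(work, sigma=params.canny_sigma / ds if ds > 1 else params.canny_sigma,
                  use_quantiles=True,
                  low_threshold=params.canny_low_quantile,
                  high_threshold=params.canny_high_quantile)
    if not edges.any():
        return []
    radii = np.arange(max(2, params.min_radius // ds),
                      params.max_radius // ds + 1,
                      max(1, params.radius_step // ds))
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        accum, radii,
        min_xdistance=max(1, params.min_distance // ds),
        min_ydistance=max(1, params.min_distance // ds),
        threshold=params.accum_threshold,
        total_num_peaks=params.max_detections,
        normalize=True,
    )
    dets = [
        Detection(image_id=image_id,
                  center=(float(x) * ds + (ds - 1) / 2,
                          float(y) * ds + (ds - 1) / 2),
                  radius=float(r) * ds, score=float(a))
        for a, x, y, r in zip(accums, cx, cy, rad)
        if 0 <= x * ds < img.shape[1] and 0 <= y * ds < img.shape[0]
    ]
    dets.sort(key=lambda d: (-d.score, d.center[1], d.center[0]))
    return dets


def dedup_detections(dets: list[Detection], eps: float, min_pts: int = 1
                     ) -> list[Detection]:
    """Collapse overlapping detections by density-based clustering of their
    centers.

    Each cluster is represented by its largest-radius member (ties: smallest
    (y, x)); points in clusters below ``min_pts`` (possible only when
    ``min_pts`` > 1) are retained as singletons.  Idempotent for fixed eps
    when representatives stay further apart than eps.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    if not dets:
        return []
    centers = np.array([d.center for d in dets], dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(centers)
    out: list[Detection] = []
    for lab in sorted(set(labels)):
        members = [d for d, l in zip(dets, labels) if l == lab]
        if lab == -1:
            out.extend(members)
            continue
        members.sort(key=lambda d: (-d.radius, d.center[1], d.center[0]))
        out.append(members[0])
    out.sort(key=lambda d: (d.center[1], d.center[0]))
    return out


def crop_particle(image: np.ndarray, det: Detection, size: int = CROP_SIZE
                  ) -> ParticleCrop:
    """Crop a ``size`` x ``size`` region centered on the detection.

    Out-of-image regions are filled with the median intensity of the image's
    1-pixel border frame; the fill value is recorded on the crop.
    """
    img = as_gray(image)
    h, w = img.shape
    cx, cy = det.center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"detection center {det.center} outside image")
    border = np.concatenate([img[0, :], img[-1, :], img[:, 0], img[:, -1]])
    fill = float(np.median(border))
    x0 = int(round(cx)) - size // 2
    y0 = int(round(cy)) - size // 2
    out = np.full((size, size), fill, dtype=float)
    sx0, sx1 = max(0, x0), min(w, x0 + size)
    sy0, sy1 = max(0, y0), min(h, y0 + size)
    out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = img[sy0:sy1, sx0:sx1]
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return ParticleCrop(pixels=out, detection=det,
                        center_in_crop=(cx - x0, cy - y0), pad_fill=fill)
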