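"""The eleven interpretable particle descriptors and the core-9 subset.

Given a 512 x 512 grayscale crop and its circle detection, this module
computes a binary foreground mask and eleven morphological / textural
descriptors:

====================  =========================================================
radius                circle radius reported by the detector (px)
circularity           4*pi*Area / Perimeter^2 (1 for a disk)
inscribed_ratio       largest inscribed circle radius / detected radius
area_px               foreground pixel count after thresholding
centroid_shift        |detected center - mask centroid| (px)
fractal_dim           box-counting dimension of the outer contour
spike_cnt             number of radial line segments (furrow analogue)
radial_grad           mean(center disk) - mean(peripheral annulus) intensity
edge_density          Canny edge pixels in the mask bounding box / box area
texture_entropy       Shannon entropy (bits) of the uniform-LBP histogram
convex_def_ratio      1 - area / convex hull area (boundary concavity)
====================  =========================================================

The core-9 subset drops ``fractal_dim`` and ``edge_density``, which are
redundant with other descriptors (high multicollinearity) and less
biologically interpretable for pollen exines.

Numerical conventions (fixed for reproducibility):

* Thresholding is Otsu on the grayscale crop; foreground polarity is chosen
  so the crop-center neighborhood is foreground, which makes the mask
  invariant to intensity inversion. The largest connected component is
  retained and its holes filled.
* Perimeter is the arc length of the marching-squares outer contour at the
  0.5 level, simplified at 1-px tolerance to remove pixel-staircase bias.
* Canny thresholds are automatic: quantiles 0.90/0.97 of the smoothed
  gradient magnitude, adapting to each crop's contrast.
* LBP uses 8 neighbors at radius 1 with the rotation-invariant uniform
  binning (10 bins); entropy is in bits over mask-interior pixels.
* Box-counting uses grid sizes 2, 4, 8, 16, 32, 64 px anchored at the crop
  origin, slope fit by least squares on log(count) vs log(1/size).

Descriptors that are undefined (empty mask, degenerate contour, too-small
interior) are returned as NaN with a named flag on the feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import canny, local_binary_pattern
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image
from skimage.transform import probabilistic_hough_line

from .detect import Detection, ParticleCrop

__all__ = [
    "FEATURES_11", "CORE9", "FeatureVector",
    "binarize", "circularity", "inscribed_ratio", "area_px", "centroid_shift",
    "fractal_dim", "spike_cnt", "radial_grad", "edge_density",
    "texture_entropy", "convex_def_ratio", "extract_all", "to_core9",
]

#: Canonical 11-descriptor order (tables, CSV headers).
FEATURES_11 = (
    "radius", "circularity", "inscribed_ratio", "area_px", "centroid_shift",
    "fractal_dim", "spike_cnt", "radial_grad", "edge_density",
    "texture_entropy", "convex_def_ratio",
)

#: Core-9 order: the refined set after dropping fractal_dim and edge_density.
CORE9 = (
    "radius", "centroid_shift", "circularity", "spike_cnt", "texture_entropy",
    "area_px", "radial_grad", "inscribed_ratio", "convex_def_ratio",
)


@dataclass
class FeatureVector:
    radius: float
    circularity: float
    inscribed_ratio: float
    area_px: float
    centroid_shift: float
    fractal_dim: float
    spike_cnt: float
    radial_grad: float
    edge_density: float
    texture_entropy: float
    convex_def_ratio: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURES_11}


def to_core9(v: FeatureVector) -> dict[str, float]:
    """Project a full feature vector onto the core-9 subset (fixed order)."""
    d = v.to_dict() if isinstance(v, FeatureVector) else dict(v)
    return {name: d[name] for name in CORE9}


# --------------------------------------------------------------------------
# mask construction

def binarize(crop: ParticleCrop | np.ndarray) -> np.ndarray:
    """Foreground mask of the stained particle.

    Otsu threshold; polarity chosen so the crop-center 11x11 neighborhood
    mean falls on the foreground side (stained grains are centered in their
    crops and darker than background, but the rule also survives intensity
    inversion).  Largest connected component kept, holes filled.  A constant
    crop yields an empty mask.
    """
    img = np.asarray(crop.pixels if isinstance(crop, ParticleCrop) else crop,
                     dtype=float)
    if img.size == 0 or img.min() == img.max():
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    h, w = img.shape
    cy, cx = h // 2, w // 2
    if isinstance(crop, ParticleCrop):
        cx, cy = (int(round(c)) for c in crop.center_in_crop)
        cx, cy = min(max(cx, 5), w - 6), min(max(cy, 5), h - 6)
    center_mean = img[cy - 5:cy + 6, cx - 5:cx + 6].mean()
    mask = img <= t if center_mean <= t else img > t
    if not mask.any():
        return mask
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _perimeter(mask: np.ndarray) -> float:
    """Outer-contour arc length.

    The marching-squares contour at the 0.5 level is simplified with
    Douglas-Peucker at 1-px tolerance before measuring its polygon length;
    this removes the pixel-staircase bias that would otherwise overestimate
    smooth perimeters by ~5% (a digitized disk then measures within 1% of
    2*pi*r while corners of polygonal shapes are preserved)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return 0.0
    lengths = []
    for c in contours:
        poly = measure.approximate_polygon(c, tolerance=1.0)
        lengths.append(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
    return float(max(lengths))


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


# --------------------------------------------------------------------------
# shape descriptors

def circularity(mask: np.ndarray) -> float:
    """4*pi*A / P^2; 1 for a disk, lower for elongated/irregular shapes."""
    a = int(mask.sum())
    if a == 0:
        return float("nan")
    p = _perimeter(mask)
    if p == 0:  # single pixel or degenerate contour
        return 1.0
    return float(4 * np.pi * a / p**2)


def inscribed_ratio(mask: np.ndarray, hough_radius: float) -> float:
    """Largest-inscribed-circle radius over the detected circle radius."""
    if hough_radius <= 0:
        raise ValueError("hough_radius must be > 0")
    if not mask.any():
        return float("nan")
    dist = ndimage.distance_transform_edt(mask)
    return float(dist.max() / hough_radius)


def area_px(mask: np.ndarray) -> int:
    """Foreground pixel count."""
    return int(mask.sum())


def centroid_shift(mask: np.ndarray, hough_center: tuple[float, float]) -> float:
    """Euclidean distance (px) between the detected center and the mask
    centroid; large for asymmetric (e.g. ruptured) particles."""
    if not mask.any():
        return float("nan")
    cy, cx = ndimage.center_of_mass(mask)
    return float(np.hypot(cx - hough_center[0], cy - hough_center[1]))


_BOX_SIZES = (2, 4, 8, 16, 32, 64)


def fractal_dim(mask: np.ndarray) -> float:
    """Box-counting dimension of the outer contour.

    ~1 for smooth boundaries, larger for space-filling irregular contours.
    NaN if the contour has fewer than 8 pixels or fewer than 4 usable
    scales."""
    boundary = _boundary(mask)
    ys, xs = np.nonzero(boundary)
    if len(xs) < 8:
        return float("nan")
    sizes, counts = [], []
    for s in _BOX_SIZES:
        boxes = set(zip(xs // s, ys // s))
        if boxes:
            sizes.append(s)
            counts.append(len(boxes))
    if len(sizes) < 4:
        return float("nan")
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                       np.log(np.asarray(counts, float)), 1)[0]
    return float(slope)


def convex_def_ratio(mask: np.ndarray) -> float:
    """1 - A_obj / A_hull: 0 for convex shapes, toward 1 for concave /
    fragmented boundaries. Clamped to [0, 1]."""
    a = int(mask.sum())
    if a == 0:
        return float("nan")
    hull = convex_hull_image(mask)
    ah = int(hull.sum())
    if ah <= a:  # degenerate (collinear) hull
        return 0.0
    return float(np.clip(1.0 - a / ah, 0.0, 1.0))


# --------------------------------------------------------------------------
# intensity / texture descriptors

def _auto_canny(img: np.ndarray, sigma: float = 2.0,
                low_q: float = 0.90, high_q: float = 0.97) -> np.ndarray:
    """Canny with automatic thresholds at quantiles of the smoothed gradient
    magnitude.

    Quantile thresholds adapt to the crop's own contrast (a median-multiple
    rule is unstable when most of the crop is flat), keeping only the
    strongest ~10% of gradients as candidate edges."""
    img = np.asarray(img, dtype=float)
    if img.min() == img.max():
        return np.zeros(img.shape, dtype=bool)
    return canny(img, sigma=sigma, use_quantiles=True,
                 low_threshold=low_q, high_threshold=high_q)


def radial_grad(crop: np.ndarray, hough_center: tuple[float, float],
                hough_radius: float) -> float:
    """Mean intensity of the central disk (radius r/3) minus the peripheral
    annulus (2r/3, r]. Positive when the center is brighter."""
    if hough_radius <= 0:
        raise ValueError("hough_radius must be > 0")
    img = np.asarray(crop, dtype=float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - hough_center[0], yy - hough_center[1])
    inner = d <= hough_radius / 3.0
    annulus = (d > 2.0 * hough_radius / 3.0) & (d <= hough_radius)
    if not inner.any() or not annulus.any():
        return float("nan")
    return float(img[inner].mean() - img[annulus].mean())


def edge_density(crop: np.ndarray, mask: np.ndarray) -> float:
    """Canny edge pixels inside the mask's bounding box, normalized by the
    bounding-box area; in [0, 1]."""
    if not mask.any():
        return float("nan")
    ys, xs = np.nonzero(mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    edges = _auto_canny(np.asarray(crop, dtype=float))
    box = edges[y0:y1, x0:x1]
    return float(box.sum() / box.size)


_LBP_BINS = 10  # P=8 uniform method: 9 uniform classes + 1 non-uniform


def texture_entropy(crop: np.ndarray, mask: np.ndarray) -> float:
    """Shannon entropy (bits) of the uniform local-binary-pattern histogram
    (8 neighbors, radius 1) over mask-interior pixels.

    0 for constant texture; bounded above by log2(10). NaN when the interior
    has fewer than 16 pixels."""
    if not mask.any():
        return float("nan")
    interior = ndimage.binary_erosion(mask, iterations=2)
    if interior.sum() < 16:
        return float("nan")
    img = np.asarray(crop)
    if img.dtype.kind == "f":  # LBP comparisons are noisy on float dtypes
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    lbp = local_binary_pattern(img, P=8, R=1, method="uniform")
    hist = np.bincount(lbp[interior].astype(int), minlength=_LBP_BINS)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(max(0.0, -(p * np.log2(p)).sum()))


def spike_cnt(crop: np.ndarray, hough_center: tuple[float, float],
              hough_radius: float, angular_tol_deg: float = 20.0,
              merge_deg: float = 15.0) -> int:
    """Number of radial line segments (germinal-furrow analogue).

    Canny edges -> probabilistic Hough line segments; a segment counts when
    its midpoint lies within 1.5 x radius of the center and its direction is
    within ``angular_tol_deg`` of the radial direction at the midpoint.
    Segments belonging to the same furrow (the two Canny side-edges, or
    fragments) share the furrow's polar angle, so detections whose midpoint
    polar angles differ by less than ``merge_deg`` are merged into one.
    Deterministic: the line sampler runs on a fixed seed.
    """
    img = np.asarray(crop, dtype=float)
    # smoothing + a long minimum length keep granular cytoplasm texture
    # from chaining into spurious line segments
    edges = _auto_canny(img)
    if not edges.any():
        return 0
    min_len = max(20, int(0.6 * hough_radius))
    lines = probabilistic_hough_line(edges, threshold=30, line_length=min_len,
                                     line_gap=2, rng=np.random.default_rng(0))
    kept_angles: list[float] = []
    cx, cy = hough_center
    for (x0, y0), (x1, y1) in lines:
        p0 = np.array([x0, y0], float)
        p1 = np.array([x1, y1], float)
        mid = (p0 + p1) / 2
        if np.hypot(mid[0] - cx, mid[1] - cy) > 1.5 * hough_radius:
            continue
        seg = p1 - p0
        radial = mid - np.array([cx, cy])
        if np.linalg.norm(radial) < 1e-6 or np.linalg.norm(seg) < 1e-6:
            continue
        cosang = abs(np.dot(seg, radial)) / (np.linalg.norm(seg) * np.linalg.norm(radial))
        if np.degrees(np.arccos(np.clip(cosang, 0, 1))) > angular_tol_deg:
            continue
        ang = np.degrees(np.arctan2(mid[1] - cy, mid[0] - cx))
        if any(_circ_diff_deg(ang, a) < merge_deg for a in kept_angles):
            continue
        kept_angles.append(float(ang))
    return len(kept_angles)


def _circ_diff_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


# --------------------------------------------------------------------------
# batch extraction

def extract_all(crop: ParticleCrop, detection: Detection | None = None
                ) -> FeatureVector:
    """Compute all eleven descriptors for one crop.

    The ``radius`` field is taken directly from the detection. Mask-derived
    fields become NaN (with flags naming them) when the mask is empty or a
    descriptor-specific degeneracy applies; such records are excluded
    downstream with a logged count.
    """
    det = detection or crop.detection
    img = np.asarray(crop.pixels, dtype=float)
    center = crop.center_in_crop
    r = det.radius
    flags: list[str] = []
    mask = binarize(crop)
    if not mask.any():
        flags.append("empty_mask")
        nan = float("nan")
        return FeatureVector(radius=r, circularity=nan, inscribed_ratio=nan,
                             area_px=nan, centroid_shift=nan, fractal_dim=nan,
                             spike_cnt=nan, radial_grad=nan, edge_density=nan,
                             texture_entropy=nan, convex_def_ratio=nan,
                             flags=("empty_mask",))
    fd = fractal_dim(mask)
    if np.isnan(fd):
        flags.append("short_contour")
    te = texture_entropy(img, mask)
    if np.isnan(te):
        flags.append("small_interior")
    rg = radial_grad(img, center, r)
    if np.isnan(rg):
        flags.append("annulus_out_of_bounds")
    return FeatureVector(
        radius=float(r),
        circularity=circularity(mask),
        inscribed_ratio=inscribed_ratio(mask, r),
        area_px=float(area_px(mask)),
        centroid_shift=centroid_shift(mask, center),
        fractal_dim=fd,
        spike_cnt=float(spike_cnt(img, center, r)),
        radial_grad=rg,
        edge_density=edge_density(img, mask),
        texture_entropy=te,
        convex_def_ratio=convex_def_ratio(mask),
        flags=tuple(flags),
    )
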