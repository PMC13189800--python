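"""Ground-truthed synthetic brightfield slide generator.

Emulates gentian-violet-stained Durham-slide content at 400x magnification:
darkly stained near-circular pollen grains in two overlapping size classes
(cedar-like larger, cypress-like smaller), radial furrow lines on the
cedar-like class, burst particles with a ruptured sector and extruded blobs,
small irregular dust specks, a background intensity gradient, bubble-like
rings and additive sensor noise.

Intensity convention: particles are DARKER than the bright background
(stained material in brightfield). All downstream foreground logic relies on
this and auto-detects polarity defensively.

Coordinates are 0-based ``(x, y)`` with ``x`` the column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "INTACT_LABELS",
    "BURST_LABELS",
    "DEFAULT_CLASS_PARAMS",
    "ParticleSpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "render_crop",
    "render_class_palette",
    "sample_particle",
    "make_crop_dataset",
]

#: Canonical class order used everywhere downstream (tables, confusion matrix).
CLASS_LABELS = ("cedar", "cypre", "cedar_brst", "cypre_brst", "dust")
INTACT_LABELS = ("cedar", "cypre")
BURST_LABELS = ("cedar_brst", "cypre_brst")

#: Per-class sampling ranges for random particles. Radii in pixels at the
#: rendered scale; cedar-like grains are drawn larger than cypress-like ones
#: with a deliberate overlap, burst grains are swollen relative to their
#: intact parent, and dust is well below the smallest intact radius.
DEFAULT_CLASS_PARAMS: dict[str, dict] = {
    "cedar": dict(radius=(72.0, 96.0), intensity=(70, 110), n_spikes=(1, 3),
                  burst=(0.0, 0.0), texture_sd=(6.0, 12.0)),
    "cypre": dict(radius=(52.0, 76.0), intensity=(80, 120), n_spikes=(0, 0),
                  burst=(0.0, 0.0), texture_sd=(4.0, 9.0)),
    "cedar_brst": dict(radius=(78.0, 104.0), intensity=(70, 110), n_spikes=(0, 1),
                       burst=(0.18, 0.42), texture_sd=(8.0, 14.0)),
    "cypre_brst": dict(radius=(56.0, 82.0), intensity=(80, 120), n_spikes=(0, 0),
                       burst=(0.18, 0.42), texture_sd=(6.0, 12.0)),
    "dust": dict(radius=(8.0, 22.0), intensity=(60, 140), n_spikes=(0, 0),
                 burst=(0.0, 0.0), texture_sd=(2.0, 8.0)),
}


@dataclass(frozen=True)
class ParticleSpec:
    """One particle to render.

    ``burst_concavity`` is the fraction of the disk's angular extent removed
    (rupture sector); it must be 0 for intact classes.  ``n_spikes`` is the
    number of radial furrow lines (germinal-furrow analogue) and must be 0
    for dust.
    """

    class_label: str
    center: tuple[float, float]  # (x, y)
    radius: float
    mean_intensity: float = 90.0
    n_spikes: int = 0
    burst_concavity: float = 0.0
    texture_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if self.class_label == "dust" and self.n_spikes != 0:
            raise ValueError("dust particles carry no furrow lines")
        if self.class_label not in BURST_LABELS and self.burst_concavity != 0:
            raise ValueError("burst_concavity must be 0 for intact classes")
        if not 0 <= self.burst_concavity < 1:
            raise ValueError("burst_concavity must lie in [0, 1)")


@dataclass(frozen=True)
class SceneSpec:
    """Parameterized synthetic slide description."""

    width: int = 2048
    height: int = 2048
    particles: tuple[ParticleSpec, ...] = ()
    background_level: float = 200.0
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    bubble_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 512 or self.height < 512:
            raise ValueError("scene must be at least 512 x 512")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "particles", tuple(self.particles))
        for i, p in enumerate(self.particles):
            x, y = p.center
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"particle {i} center {p.center} outside image bounds")


@dataclass(frozen=True)
class GroundTruth:
    """Per-particle truth records: (particle_id, class_label, center, radius)."""

    records: tuple[tuple[int, str, tuple[float, float], float], ...]

    def __len__(self) -> int:
        return len(self.records)

    def centers(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=float).reshape(-1, 2)


def _disk_coverage(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
                   r: float) -> np.ndarray:
    """Anti-aliased disk coverage in [0, 1] (1-px linear edge ramp)."""
    d = np.hypot(xx - cx, yy - cy)
    return np.clip(r + 0.5 - d, 0.0, 1.0)


def _stamp_particle(img: np.ndarray, p: ParticleSpec, rng: np.random.Generator) -> None:
    h, w = img.shape
    cx, cy = p.center
    r = p.radius
    pad = int(np.ceil(r * 1.6)) + 4
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    lcx, lcy = cx, cy

    if p.class_label == "dust":
        cov = _dust_coverage(xx, yy, lcx, lcy, r, rng)
    else:
        cov = _disk_coverage(xx, yy, lcx, lcy, r)
        if p.burst_concavity > 0:
            theta0 = rng.uniform(0, 2 * np.pi)
            span = p.burst_concavity * 2 * np.pi
            ang = np.mod(np.arctan2(yy - lcy, xx - lcx) - theta0, 2 * np.pi)
            # rupture: delete an angular sector of the disk
            cov = np.where(ang < span, 0.0, cov)
            # extruded cytoplasm: 1-3 irregular blobs attached near the rupture
            for _ in range(rng.integers(1, 4)):
                bang = theta0 + rng.uniform(0, span)
                brad = r * rng.uniform(0.2, 0.45)
                bdist = r * rng.uniform(0.7, 1.1)
                bx = lcx + bdist * np.cos(bang)
                by = lcy + bdist * np.sin(bang)
                cov = np.maximum(cov, _disk_coverage(xx, yy, bx, by, brad))

    # stained-body intensity with internal texture
    body = p.mean_intensity + rng.normal(0.0, p.texture_sd, size=cov.shape)
    region = img[y0:y1, x0:x1]
    region[:] = region * (1 - cov) + body * cov

    # radial furrow lines: dark 3-px-wide segments from near-center to the rim
    if p.n_spikes > 0:
        furrow_val = max(5.0, p.mean_intensity - 55.0)
        # furrows keep >= 50 deg angular separation so they stay countable
        base = rng.uniform(0, 2 * np.pi)
        offsets = np.sort(rng.uniform(0, 2 * np.pi - p.n_spikes * 0.9, p.n_spikes))
        angles = base + offsets + 0.9 * np.arange(p.n_spikes)
        for ang in angles:
            t = np.linspace(0.12 * r, 0.95 * r, max(8, int(2 * r)))
            px = lcx + t * np.cos(ang)
            py = lcy + t * np.sin(ang)
            for sx, sy in zip(px, py):
                scov = np.clip(1.5 + 0.5 - np.hypot(xx - sx, yy - sy), 0, 1)
                region[:] = region * (1 - scov) + furrow_val * scov


def _dust_coverage(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
                   r: float, rng: np.random.Generator) -> np.ndarray:
    """Small irregular polygon: star-convex with jittered vertex radii."""
    n_vert = int(rng.integers(5, 9))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = rng.uniform(0.45 * r, r, n_vert)
    ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    # piecewise-linear star-convex boundary radius as a function of angle
    ang_ext = np.concatenate([angles, [angles[0] + 2 * np.pi]])
    rad_ext = np.concatenate([radii, [radii[0]]])
    idx = np.searchsorted(ang_ext, ang, side="right") - 1
    idx = np.clip(idx, 0, n_vert - 1)
    a0, a1 = ang_ext[idx], ang_ext[idx + 1]
    w = np.where(a1 > a0, (ang - a0) / np.maximum(a1 - a0, 1e-9), 0.0)
    bound = rad_ext[idx] * (1 - w) + rad_ext[idx + 1] * w
    d = np.hypot(xx - cx, yy - cy)
    return np.clip(bound + 0.5 - d, 0.0, 1.0)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit grayscale image plus its ground truth.

    Deterministic given ``spec`` (including ``rng_seed``): the same spec
    always yields bit-identical pixels.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), float(spec.background_level))
    if spec.background_gradient:
        img += spec.background_gradient * (np.arange(w) / max(w - 1, 1))[None, :]

    # bubble-like rings: annular darkening with a bright interior
    for _ in range(spec.bubble_count):
        bx = rng.uniform(0, w)
        by = rng.uniform(0, h)
        br = rng.uniform(20, 80)
        pad = int(br) + 6
        x0, x1 = max(0, int(bx) - pad), min(w, int(bx) + pad + 1)
        y0, y1 = max(0, int(by) - pad), min(h, int(by) + pad + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - bx, yy - by)
        ring = np.clip(1.0 - np.abs(d - br) / 3.0, 0, 1)
        img[y0:y1, x0:x1] -= 60.0 * ring

    records = []
    for i, p in enumerate(spec.particles):
        _stamp_particle(img, p, rng)
        records.append((i, p.class_label, p.center, p.radius))

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, GroundTruth(tuple(records))


def render_crop(p: ParticleSpec, size: int = 512, background_level: float = 200.0,
                noise_sd: float = 3.0, rng_seed: int = 0) -> np.ndarray:
    """Render a single particle into a ``size`` x ``size`` crop.

    The particle keeps the center given in ``p`` (crop coordinates)."""
    spec = SceneSpec(width=size, height=size, particles=(p,),
                     background_level=background_level, noise_sd=noise_sd,
                     rng_seed=rng_seed)
    img, _ = render_scene(spec)
    return img


def sample_particle(class_label: str, rng: np.random.Generator,
                    center: tuple[float, float] | None = None,
                    class_params: dict | None = None) -> ParticleSpec:
    """Draw a random ParticleSpec from the per-class sampling ranges."""
    params = (class_params or DEFAULT_CLASS_PARAMS)[class_label]
    r = rng.uniform(*params["radius"])
    if center is None:
        center = (256.0 + rng.uniform(-10, 10), 256.0 + rng.uniform(-10, 10))
    lo, hi = params["n_spikes"]
    n_spikes = int(rng.integers(lo, hi + 1))
    blo, bhi = params["burst"]
    burst = float(rng.uniform(blo, bhi)) if bhi > 0 else 0.0
    return ParticleSpec(
        class_label=class_label,
        center=center,
        radius=float(r),
        mean_intensity=float(rng.uniform(*params["intensity"])),
        n_spikes=n_spikes,
        burst_concavity=burst,
        texture_sd=float(rng.uniform(*params["texture_sd"])),
    )


def render_class_palette(seed: int = 0) -> list[tuple[np.ndarray, str]]:
    """One canonical 512x512 exemplar crop per class, in canonical order."""
    rng = np.random.default_rng(seed)
    out = []
    for label in CLASS_LABELS:
        p = sample_particle(label, rng, center=(256.0, 256.0))
        if label == "cedar" and p.n_spikes < 1:
            p = replace(p, n_spikes=1)
        out.append((render_crop(p, rng_seed=int(rng.integers(2**31))), label))
    return out


def sample_scene(class_counts: dict[str, int], seed: int,
                 width: int = 1024, height: int = 1024,
                 background_level: float = 200.0,
                 background_gradient: float = 0.0,
                 noise_sd: float = 3.0, bubble_count: int = 0,
                 min_gap: float = 30.0,
                 class_params: dict | None = None) -> SceneSpec:
    """Place the requested particles at random non-overlapping positions.

    Particle centers are rejection-sampled so neighboring particles keep at
    least ``min_gap`` px between their rims; raises if the scene cannot host
    the requested count."""
    rng = np.random.default_rng(seed)
    placed: list[ParticleSpec] = []
    labels = [l for l, c in class_counts.items() for _ in range(c)]
    rng.shuffle(labels)
    for label in labels:
        for _ in range(500):
            p = sample_particle(label, rng, center=(0.0, 0.0),
                                class_params=class_params)
            m = p.radius + 5
            c = (float(rng.uniform(m, width - m)), float(rng.uniform(m, height - m)))
            p = replace(p, center=c)
            if all(np.hypot(c[0] - q.center[0], c[1] - q.center[1])
                   >= p.radius + q.radius + min_gap for q in placed):
                placed.append(p)
                break
        else:
            raise ValueError(
                f"could not place a {label!r} particle; scene too crowded")
    return SceneSpec(width=width, height=height, particles=tuple(placed),
                     background_level=background_level,
                     background_gradient=background_gradient,
                     noise_sd=noise_sd, bubble_count=bubble_count,
                     rng_seed=seed)


def make_crop_dataset(n_per_class: int, seed: int,
                      classes: tuple[str, ...] = CLASS_LABELS,
                      class_params: dict | None = None,
                      noise_sd: float = 3.0,
                      ) -> list[tuple[np.ndarray, ParticleSpec]]:
    """Generate a labeled crop dataset: ``n_per_class`` random particles per
    class, each rendered in its own 512x512 crop. Returns (crop, spec) pairs
    in a fixed class-major order."""
    rng = np.random.default_rng(seed)
    out = []
    for label in classes:
        for _ in range(n_per_class):
            p = sample_particle(label, rng, class_params=class_params)
            out.append((render_crop(p, noise_sd=noise_sd,
                                    rng_seed=int(rng.integers(2**31))), p))
    return out
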