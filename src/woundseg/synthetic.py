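"""Synthetic wound scenes and calibration frames under a nadir pinhole camera.

Clinical wound photographs and physical height-platform captures are not
publicly available, so this module renders everything the pipeline needs: wound-like coloured blobs on skin-toned backgrounds with
exact masks, and prior-graphic frames across a ladder of shooting heights.

Geometry: a nadir pinhole camera with focal length ``f`` (mm) and pixel
pitch ``p`` (mm/px) images a plane at distance ``h`` (mm) at a scale of
``f / (h·p)`` pixels per millimetre, so a flat shape of physical area ``S``
(mm²) occupies ``λ = S · (f / (h·p))²`` pixels up to rasterisation — the
inverse-square law that the height calibration exploits.

Wound outlines are star-convex radial curves ``r(θ) = r0·(1 + Σ a_k cos(kθ+φ_k))``
(or ellipses), whose physical area has the closed form
``π r0² (1 + ½ Σ a_k²)``, so every rendered mask comes with an exact
ground-truth area.  Masks are rasterised with 4× supersampling (coverage
fraction > 0.5), bounding the staircase error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .area import CalibrationRecord

__all__ = [
    "CameraModel",
    "SceneSpec",
    "CalibrationSeriesSpec",
    "RenderedScene",
    "render_scene",
    "render_prior_frame",
    "render_calibration_series",
    "count_prior_pixels",
    "generate_scenes",
    "make_dataset",
]

SUPERSAMPLE = 4
# deterministic irrational sub-pixel offset: keeps straight shape edges from
# aligning exactly with pixel-centre rows/columns (which makes thresholded
# counts flip whole rows at once)
_CENTER_JITTER = (2.0**-0.5, 3.0**-0.5)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: focal length and pixel pitch in mm, sensor in px."""

    focal_mm: float = 4.0
    pixel_pitch_mm: float = 0.002
    resolution: tuple[int, int] = (2000, 1500)  # (width, height)

    def scale_px_per_mm(self, height_mm: float) -> float:
        if height_mm <= 0:
            raise ValueError("shooting height must be positive")
        return self.focal_mm / (height_mm * self.pixel_pitch_mm)

    def expected_pixels(self, area_cm2: float, height_mm: float) -> float:
        """Analytic pixel count of a flat shape of the given area."""
        return area_cm2 * 100.0 * self.scale_px_per_mm(height_mm) ** 2


#: Scaled-down camera with the same field of view as the default (pitch and
#: resolution scaled together); used by the examples and CPU-sized runs.
SCALED_CAMERA = CameraModel(focal_mm=4.0, pixel_pitch_mm=0.015625, resolution=(256, 192))


@dataclass(frozen=True)
class SceneSpec:
    """One synthetic wound capture."""

    true_area_cm2: float = 12.0
    height_mm: float = 250.0
    camera: CameraModel = field(default_factory=CameraModel)
    wound_shape: str = "blob"  # "blob" (smoothed random-radius curve) or "ellipse"
    wound_color_range: tuple = ((110, 160), (20, 55), (25, 60))
    skin_color_range: tuple = ((195, 235), (145, 185), (120, 160))
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.true_area_cm2 <= 0:
            raise ValueError("true area must be positive")
        if self.wound_shape not in ("blob", "ellipse"):
            raise ValueError("wound_shape must be 'blob' or 'ellipse'")
        for lo_hi in (*self.wound_color_range, *self.skin_color_range):
            lo, hi = lo_hi
            if not (0 <= lo <= hi <= 255):
                raise ValueError("color ranges must lie within [0, 255]")


@dataclass(frozen=True)
class CalibrationSeriesSpec:
    """A ladder of prior-graphic captures for height calibration."""

    prior_shape: str = "square"  # or "triangle"
    s_pi: float = 4.0            # prior-graphic area, cm²
    heights: tuple = tuple(range(100, 501, 10))
    camera: CameraModel = field(default_factory=CameraModel)
    seed: int = 0

    def __post_init__(self):
        if self.prior_shape not in ("square", "triangle"):
            raise ValueError("prior_shape must be 'square' or 'triangle'")
        if self.s_pi <= 0:
            raise ValueError("prior area must be positive")
        hs = tuple(float(h) for h in self.heights)
        if len(hs) < 5:
            raise ValueError("need at least 5 calibration heights")
        if any(a >= b for a, b in zip(hs, hs[1:])):
            raise ValueError("heights must be strictly increasing")
        object.__setattr__(self, "heights", hs)


@dataclass
class RenderedScene:
    image: np.ndarray       # (H, W, 3) uint8
    mask: np.ndarray        # (H, W) uint8 in {0, 1}
    true_area_cm2: float    # exact analytic physical area
    lambda_true: int        # rasterised wound pixel count (== mask.sum())
    height_mm: float
    coverage: np.ndarray = None  # per-pixel subsample coverage fraction


# -- rasterisation -------------------------------------------------------------


def _coverage(frame_hw, center_px, inside_fn, r_max_px):
    """Supersampled coverage fraction of a star-convex region.

    ``inside_fn(x_px, y_px) -> bool array`` tests camera-plane offsets from
    the region centre, in pixels.
    """
    H, W = frame_hw
    cx, cy = center_px
    pad = int(np.ceil(r_max_px)) + 2
    x0, x1 = max(0, int(cx) - pad), min(W, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(H, int(cy) + pad + 1)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("shape lies outside the frame")
    xs = np.arange(x0, x1, dtype=np.float64)
    ys = np.arange(y0, y1, dtype=np.float64)
    cover = np.zeros((y1 - y0, x1 - x0), dtype=np.float64)
    s = SUPERSAMPLE
    offsets = (np.arange(s) + 0.5) / s - 0.5
    for dy in offsets:
        yy = ys[:, None] + dy - cy
        for dx in offsets:
            xx = xs[None, :] + dx - cx
            cover += inside_fn(xx, yy)
    cover /= s * s
    full = np.zeros((H, W), dtype=np.float64)
    full[y0:y1, x0:x1] = cover
    return full


def _blob_profile(rng: np.random.Generator, n_harmonics: int = 4):
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(0.02, 0.12, size=n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    return ks, amps, phases


def _scene_geometry(spec: SceneSpec, rng: np.random.Generator):
    """Return (inside_fn in px units, r_max_px, exact area in mm²)."""
    scale = spec.camera.scale_px_per_mm(spec.height_mm)
    area_mm2 = spec.true_area_cm2 * 100.0
    if spec.wound_shape == "ellipse":
        aspect = rng.uniform(0.55, 0.95)
        phi = rng.uniform(0, np.pi)
        # π a b = area, b = aspect·a
        a = np.sqrt(area_mm2 / (np.pi * aspect))
        b = aspect * a
        c, s = np.cos(phi), np.sin(phi)

        def inside(x_px, y_px):
            x_mm, y_mm = x_px / scale, y_px / scale
            u = (x_mm * c + y_mm * s) / a
            v = (-x_mm * s + y_mm * c) / b
            return (u * u + v * v) <= 1.0

        r_max_px = a * scale
    else:
        ks, amps, phases = _blob_profile(rng)
        r0 = np.sqrt(area_mm2 / (np.pi * (1.0 + 0.5 * np.sum(amps**2))))

        def inside(x_px, y_px):
            x_mm, y_mm = x_px / scale, y_px / scale
            r = np.hypot(x_mm, y_mm)
            theta = np.arctan2(y_mm, x_mm)
            r_theta = r0 * (
                1.0 + sum(a_ * np.cos(k_ * theta + p_) for k_, a_, p_ in zip(ks, amps, phases))
            )
            return r <= r_theta

        r_max_px = r0 * (1.0 + np.sum(amps)) * scale
    return inside, r_max_px, area_mm2


def render_scene(spec: SceneSpec) -> RenderedScene:
    """Render a wound scene: textured wound on a skin-toned background, plus
    the exact rasterised mask and both physical and pixel areas."""
    rng = np.random.default_rng(spec.seed)
    W, H = spec.camera.resolution
    inside, r_max_px, _ = _scene_geometry(spec, rng)
    if 2 * r_max_px >= 0.92 * min(W, H):
        raise ValueError("wound does not fit inside the frame at this height")
    max_off_x = (W - 2 * r_max_px) * 0.35
    max_off_y = (H - 2 * r_max_px) * 0.35
    cx = W / 2 + rng.uniform(-max_off_x, max_off_x)
    cy = H / 2 + rng.uniform(-max_off_y, max_off_y)
    cover = _coverage((H, W), (cx, cy), inside, r_max_px)
    mask = (cover > 0.5).astype(np.uint8)

    skin = np.array([rng.uniform(lo, hi) for lo, hi in spec.skin_color_range])
    wound = np.array([rng.uniform(lo, hi) for lo, hi in spec.wound_color_range])
    yy, xx = np.mgrid[0:H, 0:W]
    grad = 1.0 + 0.08 * (yy / H - 0.5) + 0.05 * (xx / W - 0.5)  # gentle illumination
    img = skin[None, None, :] * grad[..., None]
    # radial darkening toward the wound centre + speckle
    r_pix = np.hypot(xx - cx, yy - cy) / max(r_max_px, 1.0)
    depth = np.clip(1.0 - r_pix, 0.0, 1.0)
    wound_tex = wound[None, None, :] * (0.65 + 0.35 * (1.0 - depth[..., None]))
    speckle = 1.0 + 0.06 * rng.standard_normal((H, W, 1))
    alpha = cover[..., None]  # soft edge from coverage fraction
    img = img * (1.0 - alpha) + wound_tex * speckle * alpha
    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return RenderedScene(
        image=img,
        mask=mask,
        true_area_cm2=spec.true_area_cm2,
        lambda_true=int(mask.sum()),
        height_mm=spec.height_mm,
        coverage=cover,
    )


# -- prior graphics / calibration ---------------------------------------------


def _prior_inside(shape: str, s_pi_cm2: float, scale: float):
    area_mm2 = s_pi_cm2 * 100.0
    if shape == "square":
        half = np.sqrt(area_mm2) / 2.0

        def inside(x_px, y_px):
            return (np.abs(x_px / scale) <= half) & (np.abs(y_px / scale) <= half)

        r_max_px = half * np.sqrt(2.0) * scale
    else:  # equilateral triangle, centroid at origin
        side = np.sqrt(4.0 * area_mm2 / np.sqrt(3.0))
        r_c = side / np.sqrt(3.0)  # circumradius
        verts = [
            (r_c * np.cos(a), r_c * np.sin(a))
            for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3)
        ]

        def inside(x_px, y_px):
            x_mm, y_mm = x_px / scale, y_px / scale
            ok = np.ones(np.broadcast(x_mm, y_mm).shape, dtype=bool)
            n = len(verts)
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                ok &= ((x2 - x1) * (y_mm - y1) - (y2 - y1) * (x_mm - x1)) >= 0
            return ok

        r_max_px = r_c * scale
    return inside, r_max_px


def render_prior_frame(
    shape: str, s_pi: float, camera: CameraModel, height_mm: float, seed: int = 0
):
    """Render one high-contrast calibration frame (dark shape on white) and
    return ``(image, pixel_count)``."""
    rng = np.random.default_rng(seed)
    W, H = camera.resolution
    scale = camera.scale_px_per_mm(height_mm)
    inside, r_max_px = _prior_inside(shape, s_pi, scale)
    if 2 * r_max_px >= 0.95 * min(W, H):
        raise ValueError("prior graphic does not fit the frame at the lowest height")
    cover = _coverage(
        (H, W), (W / 2 + _CENTER_JITTER[0], H / 2 + _CENTER_JITTER[1]), inside, r_max_px
    )
    mask = cover > 0.5
    img = np.full((H, W, 3), 242.0)
    img[mask] = 22.0
    img += rng.normal(0.0, 2.0, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, int(mask.sum())


def count_prior_pixels(image: np.ndarray, threshold: int = 128) -> int:
    """Segment a high-contrast prior graphic by intensity threshold and count
    its pixels (the synthetic/CLI calibration path)."""
    gray = np.asarray(image, dtype=np.float64).mean(axis=2)
    return int((gray < threshold).sum())


def render_calibration_series(
    spec: CalibrationSeriesSpec, render_images: bool = False
) -> list[CalibrationRecord]:
    """One calibration record per height, with rasterised pixel counts.

    The default path counts sub-pixel coverage (the sum of per-pixel coverage
    fractions): thresholded integer counts of an axis-aligned shape quantise
    each straight side to whole pixels, an error no supersampling removes,
    whereas the coverage sum tracks the projected area to ~0.05%.  With
    ``render_images=True`` the count instead comes from thresholding rendered
    frames via :func:`count_prior_pixels` (integer, the realistic path).
    Counts decrease strictly with height (projection geometry).
    """
    records = []
    for h in spec.heights:
        if render_images:
            img, _ = render_prior_frame(spec.prior_shape, spec.s_pi, spec.camera, h,
                                        seed=spec.seed)
            lam = float(count_prior_pixels(img))
        else:
            scale = spec.camera.scale_px_per_mm(h)
            inside, r_max_px = _prior_inside(spec.prior_shape, spec.s_pi, scale)
            W, H = spec.camera.resolution
            if 2 * r_max_px >= 0.95 * min(W, H):
                raise ValueError("prior graphic exceeds the frame at height "
                                 f"{h} mm")
            cover = _coverage(
                (H, W),
                (W / 2 + _CENTER_JITTER[0], H / 2 + _CENTER_JITTER[1]),
                inside,
                r_max_px,
            )
            lam = float(cover.sum())
        records.append(CalibrationRecord(h=h, lam=lam, s_pi=spec.s_pi))
    return records


# -- datasets ------------------------------------------------------------------


def generate_scenes(
    n: int,
    seed: int = 0,
    camera: CameraModel | None = None,
    area_range_cm2: tuple[float, float] = (4.0, 30.0),
    height_range_mm: tuple[float, float] = (100.0, 500.0),
    shapes: tuple[str, ...] = ("blob", "ellipse"),
) -> list[RenderedScene]:
    """Render ``n`` randomized wound scenes (in memory), reproducible under
    ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        # rejection loop: resample until the wound fits the frame
        for _ in range(50):
            spec = SceneSpec(
                true_area_cm2=float(rng.uniform(*area_range_cm2)),
                height_mm=float(rng.uniform(*height_range_mm)),
                camera=camera,
                wound_shape=shapes[int(rng.integers(len(shapes)))],
                seed=int(rng.integers(2**31 - 1)),
            )
            try:
                scenes.append(render_scene(spec))
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not fit a wound in the frame; check camera/height ranges")
    return scenes


def make_dataset(
    n: int,
    out_dir: str,
    seed: int = 0,
    camera: CameraModel | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Write ``n`` image/mask pairs plus a manifest CSV.

    Layout matches the training contract: ``images/`` and ``masks/`` with
    matching basenames, masks stored as 0/255 single-channel PNG.  The
    manifest records filename, height_mm, true_area_cm2 and lambda_true.
    """
    scenes = generate_scenes(n, seed=seed, camera=camera, **kwargs)
    img_dir = os.path.join(out_dir, "images")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    rows = []
    for i, sc in enumerate(scenes):
        name = f"scene_{i:04d}.png"
        Image.fromarray(sc.image).save(os.path.join(img_dir, name))
        Image.fromarray((sc.mask * 255).astype(np.uint8), mode="L").save(
            os.path.join(mask_dir, name)
        )
        rows.append(
            {
                "filename": name,
                "height_mm": sc.height_mm,
                "true_area_cm2": sc.true_area_cm2,
                "lambda_true": sc.lambda_true,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
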