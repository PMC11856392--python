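"""Synthetic indoor grape-scene generator.

Renders RGB images of grape-bunch clusters photographed against a white wall
or a blurred-green ("bokeh") backdrop, with artificial foliage drawn over the
bunches.  Every scene carries exact ground truth: a binary cluster mask,
per-berry visibility, visible / occluded / total berry counts and a bunch
weight in grams.  Occlusion arises from two controllable sources — berry
packing within a bunch and foliage cover — so the visible fraction can be
calibrated to a target (e.g. the heavily-occluded field regime where only
about a fifth of berries are visible).

Geometry is deliberately simple (disks and ellipses composited back-to-front
with a painter's algorithm over an object-id buffer), which keeps the ground
truth exact and the renderer fast enough to generate thousands of scenes on
one CPU core.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "BerrySpec",
    "SceneParams",
    "GrapeScene",
    "DatasetConfig",
    "PlacementError",
    "CalibrationError",
    "RESOLUTION_TIERS_DESK",
    "RESOLUTION_TIERS_PAPER",
    "GRAPE_COLORS",
    "MANIFEST_COLUMNS",
    "render_scene",
    "assign_weight",
    "generate_dataset",
    "calibrate_occlusion",
    "derive_seed",
    "save_manifest",
    "load_manifest",
]

# rows x cols, 3:4 aspect at every tier.  Desk tiers keep CPU runs fast;
# the full-size tiers used for the original imagery are available by name.
RESOLUTION_TIERS_DESK = {"low": (60, 80), "medium": (120, 160), "high": (240, 320)}
RESOLUTION_TIERS_PAPER = {"low": (120, 160), "medium": (480, 640), "high": (1080, 1440)}

# Base RGB of each berry variety, in [0, 1].
GRAPE_COLORS = {
    "blue": (0.16, 0.18, 0.45),
    "green": (0.45, 0.60, 0.28),
    "purple": (0.40, 0.20, 0.40),
}

# Foliage ellipses per cluster at density 1.0.
_FOLIAGE_BASE_COUNT = {"low": 2, "medium": 6, "high": 12}
# Fixed per-cluster pool so raising the drawn count never reshuffles the
# stream: element k is identical at every density (monotone occlusion).
_FOLIAGE_POOL = 64

_FOLIAGE_GREENS = np.array(
    [(0.18, 0.42, 0.14), (0.24, 0.52, 0.18), (0.30, 0.58, 0.24), (0.36, 0.64, 0.30)]
)

VIEW_ANGLES = (0, 90, 180, 270)

MANIFEST_COLUMNS = [
    "image_path", "mask_path", "group_id", "color_variety", "foliage_level",
    "background", "resolution_tier", "view_angle_deg", "visible_count",
    "total_count", "weight_g", "seed",
]


class PlacementError(ValueError):
    """Image too small to place the requested clusters."""


class CalibrationError(RuntimeError):
    """Occlusion calibration could not reach the requested visible fraction."""


def derive_seed(base_seed: int, counter: int) -> int:
    """Stable splitmix64-style per-item seed from a master seed (< 2**31)."""
    mask = (1 << 64) - 1
    z = (int(base_seed) * 0x9E3779B97F4A7C15 + int(counter)) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    return int(z & 0x7FFFFFFF)


@dataclass
class BerrySpec:
    """One rendered berry disk with its exact visibility ground truth."""

    center_row: float
    center_col: float
    radius: float
    depth_rank: int
    cluster_id: int
    base_color: tuple
    visible_pixel_count: int = 0
    is_visible: bool = False


@dataclass
class SceneParams:
    """Rendering conditions for one scene.

    ``rows``/``cols`` default from ``resolution_tier`` using the desk-scale
    tier table; pass explicit sizes (or ``tier_table="paper"``) for the
    full-size tiers.  ``min_visible_pixels=None`` means a berry counts as
    visible when at least 5% of its disk area is the top-most object
    (minimum one pixel).
    """

    resolution_tier: str = "medium"
    rows: int = 0
    cols: int = 0
    color_variety: str = "blue"
    foliage_level: str = "low"
    background: str = "white"
    n_clusters: int = 3
    berries_min: int = 12
    berries_max: int = 24
    packing_tightness: float = 0.5
    foliage_density: float = 1.0
    view_angle_deg: int = 0
    per_berry_mass_g: float = 1.5
    weight_noise_sd: float = 0.05
    min_visible_pixels: Optional[int] = None
    tier_table: str = "desk"
    seed: int = 0

    def __post_init__(self):
        table = RESOLUTION_TIERS_PAPER if self.tier_table == "paper" else RESOLUTION_TIERS_DESK
        if self.rows <= 0 or self.cols <= 0:
            if self.resolution_tier not in table:
                raise ValueError(f"unknown resolution tier {self.resolution_tier!r}")
            self.rows, self.cols = table[self.resolution_tier]
        if self.color_variety not in GRAPE_COLORS:
            raise ValueError(f"unknown color variety {self.color_variety!r}")
        if self.foliage_level not in _FOLIAGE_BASE_COUNT:
            raise ValueError(f"unknown foliage level {self.foliage_level!r}")
        if self.background not in ("white", "green_bokeh"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.view_angle_deg not in VIEW_ANGLES:
            raise ValueError(f"view angle must be one of {VIEW_ANGLES}")
        if not 0.0 <= self.packing_tightness <= 1.0:
            raise ValueError("packing_tightness must lie in [0, 1]")
        if self.berries_min < 0 or self.berries_max < self.berries_min:
            raise ValueError("invalid berries_per_cluster range")
        if self.per_berry_mass_g <= 0:
            raise ValueError("per_berry_mass_g must be positive")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be non-negative")


@dataclass
class GrapeScene:
    """A rendered scene plus exact ground truth (counts satisfy
    total == visible + occluded by construction)."""

    image: np.ndarray
    mask: np.ndarray
    berries: list
    visible_count: int
    occluded_count: int
    total_count: int
    weight_g: float
    params: SceneParams
    foliage: list = field(default_factory=list)


def assign_weight(total_count: int, per_berry_mass_g: float, noise_sd: float, seed: int) -> float:
    """Bunch weight: count x per-berry mass x (1 + eps), eps ~ N(0, sd), >= 0."""
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    if per_berry_mass_g <= 0:
        raise ValueError("per_berry_mass_g must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if total_count == 0:
        return 0.0
    base = total_count * per_berry_mass_g
    if noise_sd == 0:
        return float(base)
    rng = np.random.Generator(np.random.PCG64(seed))
    eps = rng.normal(0.0, noise_sd)
    return float(max(0.0, base * (1.0 + eps)))


# ---------------------------------------------------------------------------
# arrangement sampling (view-angle independent) and rasterisation


def _rotate(dr, dc, angle_deg):
    """Rotate offsets in the image plane by a multiple of 90 degrees."""
    if angle_deg == 0:
        return dr, dc
    if angle_deg == 90:
        return -dc, dr
    if angle_deg == 180:
        return -dr, -dc
    if angle_deg == 270:
        return dc, -dr
    raise ValueError(f"unsupported view angle {angle_deg}")


def _sample_arrangement(params: SceneParams, rng: np.random.Generator):
    """Sample cluster-local berry layouts, foliage pools and colours.

    Returns a structure independent of view angle so that the four angle
    renderings of one arrangement share identical bunch geometry.
    """
    rows, cols = params.rows, params.cols
    n_cl = params.n_clusters
    cluster_r = 0.22 * min(rows, cols)
    if cluster_r < 3.0:
        raise PlacementError(
            f"image {rows}x{cols} too small to place {n_cl} clusters: "
            f"cluster radius {cluster_r:.1f}px < 3px"
        )
    if n_cl * 2.0 * cluster_r > cols * 1.25:
        raise PlacementError(
            f"image width {cols}px cannot hold {n_cl} clusters of radius {cluster_r:.1f}px"
        )

    base_rgb = np.asarray(GRAPE_COLORS[params.color_variety])
    clusters = []
    placed_abs: list[tuple[float, float]] = []  # berry centres across clusters
    for ci in range(n_cl):
        center_row = rows * (0.5 + 0.08 * (rng.random() - 0.5))
        center_col = cols * (ci + 1.0) / (n_cl + 1.0) + cols * 0.02 * (rng.random() - 0.5)
        n_b = int(rng.integers(params.berries_min, params.berries_max + 1))
        # berry size is a property of the variety, not of the bunch count:
        # bigger bunches spread wider instead of shrinking their berries
        berry_r = max(2.0, 0.17 * cluster_r)
        t = params.packing_tightness
        # t=0: disjoint disks (gap of one pixel); t=1: centres may almost coincide
        min_gap = (2.0 * berry_r + 1.0) * (1.0 - t) + 0.8 * berry_r * t
        offsets = []
        # start from a reach that can actually hold n_b centres min_gap apart
        # (packing density ~0.5), else low-tightness small clusters thrash
        reach = max(cluster_r - berry_r, 0.5 * min_gap * np.sqrt(n_b / 0.5))
        reach_cap = max(4.0 * cluster_r, 1.5 * reach)
        tries = 0
        while len(offsets) < n_b:
            tries += 1
            if tries > 800:
                reach *= 1.12  # relax outward rather than fail
                tries = 0
                if reach > reach_cap:
                    raise PlacementError(
                        f"cannot place {n_b} berries of radius {berry_r:.1f}px in a "
                        f"cluster of radius {cluster_r:.1f}px without overlap"
                    )
            ang = rng.random() * 2 * np.pi
            rad = np.sqrt(rng.random()) * max(reach, 0.0)
            dr, dc = rad * np.sin(ang), rad * np.cos(ang)
            ar, ac = center_row + dr, center_col + dc
            # whole disk must lie in frame, and the packing gap holds across
            # clusters too (at the reference view angle), so tightness 0
            # means globally disjoint, fully visible disks
            if not (berry_r <= ar <= rows - 1 - berry_r
                    and berry_r <= ac <= cols - 1 - berry_r):
                continue
            if all((dr - o[0]) ** 2 + (dc - o[1]) ** 2 >= min_gap**2
                   for o in offsets) and all(
                (ar - pr) ** 2 + (ac - pc) ** 2 >= min_gap**2
                for pr, pc in placed_abs
            ):
                offsets.append((dr, dc))
                placed_abs.append((ar, ac))
        shades = 1.0 + 0.18 * (rng.random(n_b) - 0.5)
        foliage_pool = []
        for _ in range(_FOLIAGE_POOL):
            f_ang = rng.random() * 2 * np.pi
            f_rad = np.sqrt(rng.random()) * cluster_r * 1.1
            a = berry_r * (1.6 + 1.4 * rng.random())
            b = a * (0.35 + 0.3 * rng.random())
            theta = rng.random() * np.pi
            color = _FOLIAGE_GREENS[rng.integers(len(_FOLIAGE_GREENS))] * (
                1.0 + 0.2 * (rng.random() - 0.5)
            )
            foliage_pool.append(
                (f_rad * np.sin(f_ang), f_rad * np.cos(f_ang), a, b, theta, color)
            )
        clusters.append(
            dict(
                center=(center_row, center_col),
                offsets=offsets,
                berry_r=berry_r,
                shades=shades,
                base_rgb=base_rgb,
                foliage_pool=foliage_pool,
            )
        )
    n_total = sum(len(c["offsets"]) for c in clusters)
    depth_order = rng.permutation(n_total)  # depth_rank per berry, 0 = front
    bokeh_seed = int(rng.integers(0, 2**31))
    weight_seed = int(rng.integers(0, 2**31))
    return clusters, depth_order, bokeh_seed, weight_seed


def _disk_pixels(rows, cols, cr, cc, radius):
    r0 = max(0, int(np.floor(cr - radius)))
    r1 = min(rows - 1, int(np.ceil(cr + radius)))
    c0 = max(0, int(np.floor(cc - radius)))
    c1 = min(cols - 1, int(np.ceil(cc + radius)))
    if r1 < r0 or c1 < c0:
        return None
    rr, cc_grid = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    d2 = (rr - cr) ** 2 + (cc_grid - cc) ** 2
    inside = d2 <= radius**2
    return rr[inside], cc_grid[inside], np.sqrt(d2[inside])


def _ellipse_pixels(rows, cols, cr, cc, a, b, theta):
    ext = max(a, b)
    r0 = max(0, int(np.floor(cr - ext)))
    r1 = min(rows - 1, int(np.ceil(cr + ext)))
    c0 = max(0, int(np.floor(cc - ext)))
    c1 = min(cols - 1, int(np.ceil(cc + ext)))
    if r1 < r0 or c1 < c0:
        return None
    rr, cg = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    dr, dc = rr - cr, cg - cc
    u = (dc * np.cos(theta) + dr * np.sin(theta)) / a
    v = (-dc * np.sin(theta) + dr * np.cos(theta)) / b
    inside = u**2 + v**2 <= 1.0
    return rr[inside], cg[inside]


def _render_background(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    rows, cols = params.rows, params.cols
    if params.background == "white":
        img = np.full((rows, cols, 3), 0.93, dtype=np.float64)
        img += 0.04 * rng.random((rows, cols, 1))
        return img
    # green bokeh: blurred out-of-focus green disks on a dark-green base
    img = np.zeros((rows, cols, 3), dtype=np.float64)
    img[..., :] = (0.10, 0.22, 0.08)
    n_disks = max(12, (rows * cols) // 600)
    for _ in range(n_disks):
        cr, cc = rng.random() * rows, rng.random() * cols
        rad = (0.04 + 0.10 * rng.random()) * min(rows, cols)
        color = _FOLIAGE_GREENS[rng.integers(len(_FOLIAGE_GREENS))] * (
            0.8 + 0.6 * rng.random()
        )
        px = _disk_pixels(rows, cols, cr, cc, rad)
        if px is not None:
            img[px[0], px[1]] = color
    sigma = 0.02 * min(rows, cols)
    for ch in range(3):
        img[..., ch] = gaussian_filter(img[..., ch], sigma)
    return np.clip(img, 0.0, 1.0)


def render_scene(params: SceneParams, seed: Optional[int] = None) -> GrapeScene:
    """Render one scene deterministically from ``(params, seed)``.

    Berries are composited back-to-front (painter's algorithm over an
    object-id buffer), foliage is drawn on top of the bunches, and the mask
    marks pixels whose top-most object is a berry.  A berry is visible when
    its top-most pixel count reaches the configured threshold.
    """
    if seed is None:
        seed = params.seed
    rows, cols = params.rows, params.cols
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    clusters, depth_order, bokeh_seed, weight_seed = _sample_arrangement(params, rng)

    bg_rng = np.random.Generator(np.random.PCG64(bokeh_seed))
    image = _render_background(params, bg_rng)
    id_buf = np.full((rows, cols), -1, dtype=np.int64)

    # flatten berries with absolute centres under the view-angle rotation
    berries: list[BerrySpec] = []
    for ci, cl in enumerate(clusters):
        cr0, cc0 = cl["center"]
        for bi, (dr, dc) in enumerate(cl["offsets"]):
            rdr, rdc = _rotate(dr, dc, params.view_angle_deg)
            r_b = cl["berry_r"]
            berries.append(
                BerrySpec(
                    # keep whole disks in frame: bunches are photographed
                    # fully inside the image
                    center_row=float(np.clip(cr0 + rdr, r_b, rows - 1 - r_b)),
                    center_col=float(np.clip(cc0 + rdc, r_b, cols - 1 - r_b)),
                    radius=cl["berry_r"],
                    depth_rank=0,  # assigned below
                    cluster_id=ci,
                    base_color=tuple(cl["base_rgb"] * cl["shades"][bi]),
                )
            )
    for rank, idx in enumerate(depth_order):
        berries[idx].depth_rank = int(rank)

    # painter's algorithm: back-most first
    for idx in sorted(range(len(berries)), key=lambda i: -berries[i].depth_rank):
        b = berries[idx]
        px = _disk_pixels(rows, cols, b.center_row, b.center_col, b.radius)
        if px is None:
            continue
        rr, cc, dist = px
        shade = 0.72 + 0.42 * (1.0 - dist / max(b.radius, 1e-9))
        image[rr, cc] = np.clip(np.asarray(b.base_color) * shade[:, None], 0.0, 1.0)
        id_buf[rr, cc] = idx

    # foliage over the bunches; the fractional part of the effective count is
    # rendered as one partially-grown ellipse so occlusion varies
    # continuously (and monotonically) with foliage_density
    n_eff = _FOLIAGE_BASE_COUNT[params.foliage_level] * params.foliage_density
    n_eff = min(n_eff, float(_FOLIAGE_POOL))
    n_full = int(np.floor(n_eff))
    frac = n_eff - n_full
    foliage_drawn = []
    for ci, cl in enumerate(clusters):
        cr0, cc0 = cl["center"]
        for k in range(n_full + (1 if frac > 0 else 0)):
            fdr, fdc, a, bb, theta, color = cl["foliage_pool"][k]
            if k == n_full:  # partial ellipse: area scales with frac
                scale = np.sqrt(frac)
                a, bb = a * scale, bb * scale
            rdr, rdc = _rotate(fdr, fdc, params.view_angle_deg)
            theta_r = theta + np.deg2rad(params.view_angle_deg)
            px = _ellipse_pixels(rows, cols, cr0 + rdr, cc0 + rdc, a, bb, theta_r)
            if px is None:
                continue
            image[px[0], px[1]] = np.clip(color, 0.0, 1.0)
            id_buf[px[0], px[1]] = -2
            foliage_drawn.append((cr0 + rdr, cc0 + rdc, a, bb, theta_r))

    mask = (id_buf >= 0).astype(np.uint8)
    if len(berries):
        vis_counts = np.bincount(id_buf[id_buf >= 0], minlength=len(berries))
    else:
        vis_counts = np.zeros(0, dtype=int)

    visible = 0
    for i, b in enumerate(berries):
        b.visible_pixel_count = int(vis_counts[i])
        if params.min_visible_pixels is not None:
            thr = params.min_visible_pixels
        else:
            thr = max(1, int(round(0.05 * np.pi * b.radius**2)))
        b.is_visible = b.visible_pixel_count >= thr
        visible += int(b.is_visible)

    total = len(berries)
    weight = assign_weight(
        total, params.per_berry_mass_g, params.weight_noise_sd, weight_seed
    )
    return GrapeScene(
        image=np.clip(image, 0.0, 1.0).astype(np.float32),
        mask=mask,
        berries=berries,
        visible_count=visible,
        occluded_count=total - visible,
        total_count=total,
        weight_g=weight,
        params=params,
        foliage=foliage_drawn,
    )


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class DatasetConfig:
    """Factorial dataset-generation settings.

    Every combination of the requested condition levels is rendered for
    ``arrangements_per_condition`` bunch arrangements; each arrangement is
    rendered at all four view angles under a single ``group_id``.
    """

    out_dir: str = "dataset"
    colors: Sequence[str] = ("blue", "green", "purple")
    foliage_levels: Sequence[str] = ("low", "medium", "high")
    backgrounds: Sequence[str] = ("white", "green_bokeh")
    resolution_tiers: Sequence[str] = ("medium",)
    view_angles: Sequence[int] = VIEW_ANGLES
    arrangements_per_condition: int = 1
    base_seed: int = 0
    scene: SceneParams = field(default_factory=SceneParams)

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetConfig":
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = SceneParams(**d["scene"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def generate_dataset(config: DatasetConfig) -> pd.DataFrame:
    """Render the full factorial of conditions to PNG files plus a manifest.

    Re-running with identical config and base seed reproduces byte-identical
    image, mask and manifest files.
    """
    from . import io as gio  # local import: io depends only on PIL/numpy

    out = Path(config.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    records = []
    counter = 0
    for tier in config.resolution_tiers:
        for color in config.colors:
            for fol in config.foliage_levels:
                for bg in config.backgrounds:
                    for arr_i in range(config.arrangements_per_condition):
                        arr_seed = derive_seed(config.base_seed, counter)
                        group_id = f"g{counter:06d}"
                        counter += 1
                        for angle in config.view_angles:
                            params = dataclasses.replace(
                                config.scene,
                                resolution_tier=tier,
                                rows=0,
                                cols=0,
                                color_variety=color,
                                foliage_level=fol,
                                background=bg,
                                view_angle_deg=int(angle),
                            )
                            scene = render_scene(params, arr_seed)
                            stem = f"{group_id}_a{angle:03d}"
                            img_rel = f"images/{stem}.png"
                            msk_rel = f"masks/{stem}.png"
                            img_path = out / img_rel
                            msk_path = out / msk_rel
                            if img_path.exists():
                                raise FileExistsError(f"duplicate output path {img_path}")
                            gio.save_image(img_path, scene.image)
                            gio.save_mask(msk_path, scene.mask)
                            records.append(
                                dict(
                                    image_path=img_rel,
                                    mask_path=msk_rel,
                                    group_id=group_id,
                                    color_variety=color,
                                    foliage_level=fol,
                                    background=bg,
                                    resolution_tier=tier,
                                    view_angle_deg=int(angle),
                                    visible_count=scene.visible_count,
                                    total_count=scene.total_count,
                                    weight_g=scene.weight_g,
                                    seed=arr_seed,
                                )
                            )
    manifest = pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS)
    save_manifest(manifest, out / "manifest.csv")
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return manifest


def save_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# occlusion calibration


def _measure_visible_fraction(params: SceneParams, n_probe: int, seed: int) -> float:
    fracs = []
    for i in range(n_probe):
        sc = render_scene(params, derive_seed(seed, i))
        if sc.total_count > 0:
            fracs.append(sc.visible_count / sc.total_count)
    if not fracs:
        raise CalibrationError("all probe scenes were empty")
    return float(np.mean(fracs))


_MAX_FOLIAGE_DENSITY = 9.0


def _knob_params(base_params: SceneParams, t: float) -> SceneParams:
    # packing is quantized (layout resampling makes it a jumpy control);
    # the continuously-rendered foliage density provides fine resolution
    packing = np.floor(t * 6.0) / 6.0 if t < 1.0 else 1.0
    return dataclasses.replace(
        base_params,
        packing_tightness=float(packing),
        foliage_density=float(t * _MAX_FOLIAGE_DENSITY),
    )


def calibrate_occlusion(
    target_visible_fraction: float,
    base_params: SceneParams,
    n_probe: int = 20,
    seed: int = 0,
    tol: float = 0.05,
) -> SceneParams:
    """Bisect a single occlusion knob (packing + foliage density together)
    until the mean visible fraction over ``n_probe`` probe renders is within
    ``tol`` of the target.  Raises :class:`CalibrationError` with the
    achievable range when the target is out of reach.
    """
    if not 0.0 < target_visible_fraction <= 1.0:
        raise ValueError("target_visible_fraction must lie in (0, 1]")
    lo, hi = 0.0, 1.0
    f_lo = _measure_visible_fraction(_knob_params(base_params, lo), n_probe, seed)
    if abs(f_lo - target_visible_fraction) <= tol:
        return _knob_params(base_params, lo)
    f_hi = _measure_visible_fraction(_knob_params(base_params, hi), n_probe, seed)
    if target_visible_fraction > f_lo + tol or target_visible_fraction < f_hi - tol:
        raise CalibrationError(
            f"target visible fraction {target_visible_fraction:.3f} outside achievable "
            f"range [{f_hi:.3f}, {f_lo:.3f}]"
        )
    mid = 0.5
    for _ in range(16):
        mid = 0.5 * (lo + hi)
        f_mid = _measure_visible_fraction(_knob_params(base_params, mid), n_probe, seed)
        if abs(f_mid - target_visible_fraction) <= 0.2 * tol:
            break
        if f_mid > target_visible_fraction:
            lo = mid  # need more occlusion
        else:
            hi = mid
    # validate on an independent probe stream before accepting
    params = _knob_params(base_params, mid)
    f_val = _measure_visible_fraction(params, 2 * n_probe, seed ^ 0x5BD1E995)
    if abs(f_val - target_visible_fraction) > tol:
        raise CalibrationError(
            f"calibration did not converge: achieved {f_val:.3f}, "
            f"target {target_visible_fraction:.3f}"
        )
    return params
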