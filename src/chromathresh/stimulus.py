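"""Plate geometry and rendering.

A plate is a pseudoisochromatic mosaic: a dense packing of small circles in
which the circles under an arrow-shaped region carry one chromaticity and
all others carry a second chromaticity on the same confusion line.  Per-
circle luminance jitter masks any brightness cue, so the arrow is visible
only through the chromatic difference (Stilling principle).

Screen coordinates are visual-angle degrees from the screen center, x right
and y up, for a viewer at a fixed distance on the screen normal.  Pixel
coordinates follow image convention (origin top-left, y down).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as _MplPath
from PIL import Image, ImageDraw

from .colorimetry import (
    ColorPair,
    ConfusionAxis,
    AxisName,
    DisplayModel,
    LabColor,
    delta_e,
    rgb_to_lab,
    xy_to_xyz,
)

__all__ = [
    "ViewingGeometry",
    "Circle",
    "ArrowPlacement",
    "PlateStimulus",
    "deg_to_px",
    "pack_circles",
    "place_arrow",
    "render_plate",
    "is_hit",
    "make_catch_plate",
    "plate_metadata",
]

#: Circle diameter bounds, visual-angle degrees.
CIRCLE_DIAMETER_RANGE_DEG = (0.0466, 0.1244)

#: Per-circle multiplicative luminance jitter: up to ±60% of nominal.
LUMINANCE_JITTER_RANGE = (0.4, 1.6)

ARROW_LENGTH_DEG = 4.26
ARROW_SHAFT_WIDTH_DEG = 0.8
ARROW_HEAD_FRACTION = 0.35
ARROW_HEAD_WIDTH_DEG = 1.8
ARROW_CENTER_MAX_DEG = 2.0  # centerline must pass within this of screen center

HIT_RADIUS_CM = 0.774
DEFAULT_VIEWING_DISTANCE_CM = 50.0


@dataclass(frozen=True)
class ViewingGeometry:
    """Viewer-display geometry: converts visual angle ↔ physical ↔ pixels."""

    viewing_distance_cm: float = DEFAULT_VIEWING_DISTANCE_CM
    display: DisplayModel = field(default_factory=DisplayModel)

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing distance must be positive")

    @property
    def pixel_pitch_mm(self) -> float:
        diag_px = math.hypot(self.display.width_px, self.display.height_px)
        return self.display.diagonal_in * 25.4 / diag_px

    def deg_to_cm(self, angle_deg: float) -> float:
        """Extent subtending ``angle_deg`` at the viewing distance (exact
        tangent mapping, signed)."""
        return 2.0 * self.viewing_distance_cm * math.tan(math.radians(angle_deg) / 2.0)

    def cm_to_deg(self, size_cm: float) -> float:
        return math.degrees(2.0 * math.atan(size_cm / (2.0 * self.viewing_distance_cm)))

    def deg_to_px(self, angle_deg: float) -> float:
        return self.deg_to_cm(angle_deg) * 10.0 / self.pixel_pitch_mm

    def px_to_deg(self, px: float) -> float:
        return self.cm_to_deg(px * self.pixel_pitch_mm / 10.0)

    @property
    def screen_half_extent_deg(self) -> tuple[float, float]:
        w_cm = self.display.width_px * self.pixel_pitch_mm / 10.0
        h_cm = self.display.height_px * self.pixel_pitch_mm / 10.0
        return (self.cm_to_deg(w_cm) / 2.0, self.cm_to_deg(h_cm) / 2.0)

    def deg_xy_to_px(self, xy_deg: tuple[float, float]) -> tuple[float, float]:
        """Screen coords (deg from center, y up) -> pixel coords (y down)."""
        x = self.display.width_px / 2.0 + self.deg_to_px(xy_deg[0])
        y = self.display.height_px / 2.0 - self.deg_to_px(xy_deg[1])
        return (x, y)


def deg_to_px(angle_deg: float, geom: ViewingGeometry | None = None) -> float:
    """Visual-angle extent in pixels for the given viewing geometry."""
    geom = geom or ViewingGeometry()
    if abs(angle_deg) >= 90:
        raise ValueError("angle must satisfy |angle| < 90 degrees")
    return geom.deg_to_px(angle_deg)


@dataclass(frozen=True)
class Circle:
    """One mosaic element, in screen-degree coordinates."""

    center: tuple[float, float]
    radius_deg: float
    luminance_factor: float = 1.0
    role: str = "background"  # "arrow" | "background"


@dataclass(frozen=True)
class ArrowPlacement:
    direction_deg: float
    polygon_deg: tuple[tuple[float, float], ...]
    head_center_deg: tuple[float, float]
    center_deg: tuple[float, float]


@dataclass(frozen=True)
class PlateStimulus:
    """A rendered (or renderable) plate with its ground-truth metadata."""

    color_pair: ColorPair
    arrow: ArrowPlacement
    circles: tuple[Circle, ...] = ()
    hit_radius_cm: float = HIT_RADIUS_CM
    is_catch_trial: bool = False
    seed: int | None = None

    @property
    def arrow_direction_deg(self) -> float:
        return self.arrow.direction_deg

    @property
    def arrowhead_center_deg(self) -> tuple[float, float]:
        return self.arrow.head_center_deg


# ---------------------------------------------------------------------------
# circle packing
# ---------------------------------------------------------------------------


def pack_circles(
    region_px: tuple[float, float, float, float] | None = None,
    rng_seed: int | np.random.Generator = 0,
    size_range_deg: tuple[float, float] = CIRCLE_DIAMETER_RANGE_DEG,
    min_gap_px: float = 0.0,
    coverage_target: float = 0.55,
    max_attempts: int = 600_000,
    geom: ViewingGeometry | None = None,
) -> list[Circle]:
    """Pack non-overlapping circles into a pixel rectangle by dart throwing.

    Candidate radii are drawn uniformly from ``size_range_deg`` (diameters)
    and inserted largest-first, which lets the small circles fill the
    interstices left by the large ones and pushes the saturation coverage
    well above the equal-disk rejection-packing limit.  Placement stops at
    ``coverage_target`` (fraction of region area) or when the attempt budget
    is exhausted, whichever comes first; the result is best-effort and fully
    determined by the seed.

    Luminance jitter factors are drawn here, one per circle, uniform on
    ``LUMINANCE_JITTER_RANGE``.
    """
    geom = geom or ViewingGeometry()
    d = geom.display
    if region_px is None:
        region_px = (0.0, 0.0, float(d.width_px), float(d.height_px))
    x0, y0, x1, y1 = map(float, region_px)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty packing region")
    lo_d, hi_d = size_range_deg
    if not (CIRCLE_DIAMETER_RANGE_DEG[0] - 1e-9 <= lo_d <= hi_d <= CIRCLE_DIAMETER_RANGE_DEG[1] + 1e-9):
        raise ValueError("size range outside the allowed diameter bounds")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    r_lo = geom.deg_to_px(lo_d) / 2.0
    r_hi = geom.deg_to_px(hi_d) / 2.0
    area = (x1 - x0) * (y1 - y0)

    # All candidates drawn up front (sorted by radius, descending) so the
    # packing is a pure function of the seed.
    radii = np.sort(rng.uniform(r_lo, r_hi, size=max_attempts))[::-1]
    xs = rng.uniform(x0, x1, size=max_attempts)
    ys = rng.uniform(y0, y1, size=max_attempts)
    factors = rng.uniform(*LUMINANCE_JITTER_RANGE, size=max_attempts)

    cell = 2.0 * r_hi + min_gap_px
    grid: dict[tuple[int, int], list[int]] = {}
    acc_x: list[float] = []
    acc_y: list[float] = []
    acc_r: list[float] = []
    covered = 0.0
    target_area = coverage_target * area

    for i in range(max_attempts):
        x, y, r = xs[i], ys[i], radii[i]
        if x - r < x0 or x + r > x1 or y - r < y0 or y + r > y1:
            continue
        cx, cy = int(x // cell), int(y // cell)
        ok = True
        for gx in (cx - 1, cx, cx + 1):
            for gy in (cy - 1, cy, cy + 1):
                for j in grid.get((gx, gy), ()):
                    dx = x - acc_x[j]
                    dy = y - acc_y[j]
                    lim = r + acc_r[j] + min_gap_px
                    if dx * dx + dy * dy < lim * lim:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        j = len(acc_x)
        acc_x.append(x)
        acc_y.append(y)
        acc_r.append(r)
        grid.setdefault((cx, cy), []).append(j)
        covered += math.pi * r * r
        if covered >= target_area:
            break

    half_w = d.width_px / 2.0
    half_h = d.height_px / 2.0
    circles = []
    for k in range(len(acc_x)):
        cx_deg = geom.px_to_deg(acc_x[k] - half_w)
        cy_deg = geom.px_to_deg(half_h - acc_y[k])
        circles.append(
            Circle(
                center=(cx_deg, cy_deg),
                radius_deg=geom.px_to_deg(acc_r[k]),
                luminance_factor=float(factors[k]),
            )
        )
    return circles


def packing_coverage(circles: list[Circle], region_px, geom: ViewingGeometry) -> float:
    """Fraction of the region area covered by the packed circles."""
    x0, y0, x1, y1 = region_px
    total = sum(math.pi * geom.deg_to_px(c.radius_deg) ** 2 for c in circles)
    return total / ((x1 - x0) * (y1 - y0))


# ---------------------------------------------------------------------------
# arrow placement
# ---------------------------------------------------------------------------

_DIRECTIONS_DEG = tuple(45.0 * k for k in range(8))


def _arrow_polygon_local(
    length: float = ARROW_LENGTH_DEG,
    shaft_w: float = ARROW_SHAFT_WIDTH_DEG,
    head_frac: float = ARROW_HEAD_FRACTION,
    head_w: float = ARROW_HEAD_WIDTH_DEG,
) -> np.ndarray:
    hl = head_frac * length
    L2 = length / 2.0
    return np.array(
        [
            (-L2, shaft_w / 2),
            (L2 - hl, shaft_w / 2),
            (L2 - hl, head_w / 2),
            (L2, 0.0),
            (L2 - hl, -head_w / 2),
            (L2 - hl, -shaft_w / 2),
            (-L2, -shaft_w / 2),
        ]
    )


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def place_arrow(
    rng_seed: int | np.random.Generator = 0,
    geom: ViewingGeometry | None = None,
    max_radius_deg: float = 3.0,
) -> ArrowPlacement:
    """Choose a direction (8 presets) and a central position for the arrow.

    The position is drawn in polar coordinates about the screen center and
    redrawn until the arrow's centerline passes within
    ``ARROW_CENTER_MAX_DEG`` of the center and the polygon is fully
    on-screen, keeping the stimulus over the cone-dense central retina.
    """
    geom = geom or ViewingGeometry()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    half_w, half_h = geom.screen_half_extent_deg
    local = _arrow_polygon_local()
    origin = np.zeros(2)
    while True:
        direction = float(_DIRECTIONS_DEG[rng.integers(0, 8)])
        phi = rng.uniform(0.0, 2.0 * math.pi)
        rad = rng.uniform(0.0, max_radius_deg)
        center = np.array([rad * math.cos(phi), rad * math.sin(phi)])
        th = math.radians(direction)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        poly = local @ rot.T + center
        u = rot @ np.array([1.0, 0.0])
        a = center - (ARROW_LENGTH_DEG / 2.0) * u
        b = center + (ARROW_LENGTH_DEG / 2.0) * u
        if _point_segment_distance(origin, a, b) >= ARROW_CENTER_MAX_DEG:
            continue
        if np.any(np.abs(poly[:, 0]) > half_w) or np.any(np.abs(poly[:, 1]) > half_h):
            continue
        tip = poly[3]
        return ArrowPlacement(
            direction_deg=direction,
            polygon_deg=tuple((float(x), float(y)) for x, y in poly),
            head_center_deg=(float(tip[0]), float(tip[1])),
            center_deg=(float(center[0]), float(center[1])),
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _quantize8(rgb: np.ndarray) -> tuple[int, int, int]:
    # round half up, fixed across platforms
    return tuple(int(math.floor(v * 255.0 + 0.5)) for v in np.clip(rgb, 0.0, 1.0))


def _circle_rgb(
    xy: tuple[float, float],
    y_rel_nominal: float,
    factor: float,
    display: DisplayModel,
) -> tuple[np.ndarray, float]:
    """Encoded RGB of a mosaic circle at its jittered luminance.

    Chromaticity is preserved exactly: at fixed xy, linear RGB scales
    linearly with luminance, so jitter is a scalar multiply before encoding.
    Factors that would leave the gamut are clipped to the headroom.
    """
    lin1 = display.xyz_to_rgb_matrix @ xy_to_xyz(xy, y_rel_nominal)
    lin1 = np.clip(lin1, 0.0, None)
    peak = float(np.max(lin1))
    max_factor = 1.0 / peak if peak > 0 else np.inf
    used = min(factor, max_factor)
    return display.oetf(lin1 * used), used


def render_plate(
    pair: ColorPair,
    placement: ArrowPlacement | None = None,
    circles: list[Circle] | None = None,
    rng_seed: int = 0,
    geom: ViewingGeometry | None = None,
    is_catch_trial: bool = False,
) -> tuple[PlateStimulus, np.ndarray]:
    """Render a plate to an 8-bit RGB image (display resolution).

    Circles whose center falls inside the arrow polygon take the arrow
    chromaticity; all others take the background chromaticity.  Each circle
    is drawn at its nominal luminance times its jitter factor; the
    inter-circle field is a neutral gray at the nominal stimulus luminance,
    so no pixel outside the mosaic carries either stimulus chromaticity.
    """
    geom = geom or ViewingGeometry()
    d = geom.display
    if placement is None or circles is None:
        rng = np.random.default_rng(rng_seed)
        if placement is None:
            placement = place_arrow(rng, geom)
        if circles is None:
            circles = pack_circles(rng_seed=rng, geom=geom)

    y_rel = pair.luminance / d.peak_luminance
    path = _MplPath(np.asarray(placement.polygon_deg))
    centers = np.array([c.center for c in circles]) if circles else np.zeros((0, 2))
    inside = path.contains_points(centers) if len(circles) else np.array([], bool)

    gray = _quantize8(d.oetf(np.array([y_rel, y_rel, y_rel])))
    img = Image.new("RGB", (d.width_px, d.height_px), gray)
    draw = ImageDraw.Draw(img)

    final_circles = []
    for c, is_arrow in zip(circles, inside):
        role = "arrow" if is_arrow else "background"
        xy = pair.arrow_xy if is_arrow else pair.background_xy
        rgb, used = _circle_rgb(xy, y_rel, c.luminance_factor, d)
        px, py = geom.deg_xy_to_px(c.center)
        r = geom.deg_to_px(c.radius_deg)
        draw.ellipse([px - r, py - r, px + r, py + r], fill=_quantize8(rgb))
        final_circles.append(replace(c, role=role, luminance_factor=used))

    plate = PlateStimulus(
        color_pair=pair,
        arrow=placement,
        circles=tuple(final_circles),
        is_catch_trial=is_catch_trial,
        seed=rng_seed if isinstance(rng_seed, int) else None,
    )
    return plate, np.asarray(img, dtype=np.uint8)


def make_plate(
    pair: ColorPair,
    rng: int | np.random.Generator = 0,
    geom: ViewingGeometry | None = None,
    is_catch_trial: bool = False,
) -> PlateStimulus:
    """Lightweight plate (no mosaic raster) for driving the adaptive engine.

    Carries the full ground truth a responder needs — color pair, arrow
    placement, hit geometry — without paying for packing/rasterization on
    every trial.  ``render_plate`` produces the displayable version.
    """
    geom = geom or ViewingGeometry()
    placement = place_arrow(rng, geom)
    return PlateStimulus(color_pair=pair, arrow=placement, is_catch_trial=is_catch_trial)


def is_hit(
    touch_deg: tuple[float, float] | None,
    plate: PlateStimulus,
    geom: ViewingGeometry | None = None,
) -> bool:
    """True iff the touch lands within the hit radius of the arrowhead.

    ``touch_deg`` is in screen-degree coordinates; ``None`` means no touch
    (timeout) and is never a hit.  The boundary is inclusive.
    """
    if touch_deg is None:
        return False
    geom = geom or ViewingGeometry()
    tx = geom.deg_to_cm(touch_deg[0])
    ty = geom.deg_to_cm(touch_deg[1])
    hx = geom.deg_to_cm(plate.arrowhead_center_deg[0])
    hy = geom.deg_to_cm(plate.arrowhead_center_deg[1])
    return math.hypot(tx - hx, ty - hy) <= plate.hit_radius_cm + 1e-12


CATCH_TRIAL_MIN_DE = 60.0


def make_catch_plate(
    rng: int | np.random.Generator = 0,
    geom: ViewingGeometry | None = None,
    axis: str | AxisName = "deutan",
) -> PlateStimulus:
    """A control plate anyone with task comprehension can answer.

    The arrow is near-white and the background a dark neutral: the pair
    differs strongly in luminance as well as exceeding ``CATCH_TRIAL_MIN_DE``
    chromatically-combined ΔE, so detection does not depend on color vision.
    """
    geom = geom or ViewingGeometry()
    d = geom.display
    arrow_rgb = (1.0, 1.0, 1.0)
    background_rgb = tuple(float(v) for v in d.oetf(np.array([0.04, 0.04, 0.04])))
    de = delta_e(rgb_to_lab(arrow_rgb, d), rgb_to_lab(background_rgb, d))
    pair = ColorPair(
        axis=ConfusionAxis.standard(axis),
        base_xy=d.white_xy,
        luminance=d.peak_luminance * 0.52,
        requested_de=de,
        arrow_rgb=arrow_rgb,
        background_rgb=background_rgb,
        achieved_de=de,
        arrow_xy=d.white_xy,
        background_xy=d.white_xy,
    )
    placement = place_arrow(rng, geom)
    return PlateStimulus(color_pair=pair, arrow=placement, is_catch_trial=True)


def plate_metadata(plate: PlateStimulus, geom: ViewingGeometry | None = None) -> dict:
    """JSON-serializable ground truth sidecar for a plate."""
    geom = geom or ViewingGeometry()
    head_px = geom.deg_xy_to_px(plate.arrowhead_center_deg)
    return {
        "axis": plate.color_pair.axis.name.value,
        "requested_de": plate.color_pair.requested_de,
        "achieved_de": plate.color_pair.achieved_de,
        "arrow_rgb": list(plate.color_pair.arrow_rgb),
        "background_rgb": list(plate.color_pair.background_rgb),
        "arrow_direction_deg": plate.arrow_direction_deg,
        "arrowhead_center_deg": list(plate.arrowhead_center_deg),
        "arrowhead_center_px": [head_px[0], head_px[1]],
        "arrow_polygon_deg": [list(v) for v in plate.arrow.polygon_deg],
        "hit_radius_cm": plate.hit_radius_cm,
        "is_catch_trial": plate.is_catch_trial,
        "seed": plate.seed,
        "n_circles": len(plate.circles),
    }


def save_plate_png(image: np.ndarray, path: str) -> None:
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def save_plate_json(plate: PlateStimulus, path: str, geom: ViewingGeometry | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(plate_metadata(plate, geom), fh, indent=2, sort_keys=True)
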