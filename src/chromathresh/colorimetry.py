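"""Display model and color math for confusion-line stimuli.

The test presents pairs of colors that differ only along one of the three
dichromatic confusion axes (protan, deutan, tritan).  All color handling is
anchored to a calibrated-display model: a pure power-law transfer function
(gamma 2.2), sRGB primaries, a D65 white point and a stated peak luminance.
Perceptual separations are expressed as CIE76 ΔE distances in CIELAB computed
against the display white.

Chromaticities are CIE 1931 xy.  Display RGB triples live in [0, 1]^3.
"""

from __future__ import annotations

import enum
import math
from functools import lru_cache as _lru_cache
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "SRGB_PRIMARIES_XY",
    "D65_XY",
    "COPUNCTAL_XY",
    "AxisName",
    "ConfusionAxis",
    "DisplayModel",
    "LabColor",
    "ColorPair",
    "GamutExceededError",
    "rgb_to_lab",
    "lab_to_rgb",
    "delta_e",
    "confusion_pair",
    "max_achievable_de",
]

#: sRGB / Rec.709 primaries (CIE 1931 xy).
SRGB_PRIMARIES_XY = ((0.6400, 0.3300), (0.3000, 0.6000), (0.1500, 0.0600))

#: D65 white chromaticity.
D65_XY = (0.3127, 0.3290)

#: Standard copunctal points of the three confusion-line families (xy).
#: All confusion lines of a dichromat class converge on that class's point,
#: which lies outside any physical display gamut.
COPUNCTAL_XY = {
    "protan": (0.7465, 0.2535),
    "deutan": (1.4000, -0.4000),
    "tritan": (0.1748, 0.0000),
}


class AxisName(str, enum.Enum):
    PROTAN = "protan"
    DEUTAN = "deutan"
    TRITAN = "tritan"


@dataclass(frozen=True)
class ConfusionAxis:
    """A confusion-line family: its name and copunctal point."""

    name: AxisName
    copunctal_xy: tuple[float, float]

    @classmethod
    def standard(cls, name: AxisName | str) -> "ConfusionAxis":
        name = AxisName(name)
        return cls(name=name, copunctal_xy=COPUNCTAL_XY[name.value])


@dataclass(frozen=True)
class DisplayModel:
    """A calibrated display: geometry, transfer function and gamut.

    Defaults describe the tablet used by the test: a 12.3-inch 2736x1824
    touch screen calibrated to sRGB primaries, D65 white, gamma 2.2 and a
    peak white luminance of 120 cd/m^2.

    Parameters
    ----------
    gamma :
        Exponent of the pure power-law opto-electronic transfer function.
        Set ``transfer="srgb"`` to use the piecewise sRGB curve instead
        (gamma is then ignored).
    peak_luminance :
        Luminance of full white, cd/m^2.  Absolute luminances elsewhere in
        the package are expressed against this.
    """

    width_px: int = 2736
    height_px: int = 1824
    diagonal_in: float = 12.3
    gamma: float = 2.2
    white_xy: tuple[float, float] = D65_XY
    peak_luminance: float = 120.0
    rgb_primaries_xy: tuple[tuple[float, float], ...] = SRGB_PRIMARIES_XY
    transfer: str = "power"  # "power" | "srgb"

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("display resolution must be positive")
        if self.diagonal_in <= 0:
            raise ValueError("diagonal must be positive")
        if not (1.0 <= self.gamma <= 3.0):
            raise ValueError(f"gamma {self.gamma} outside [1, 3]")
        if self.peak_luminance <= 0:
            raise ValueError("peak_luminance must be positive")
        if self.transfer not in ("power", "srgb"):
            raise ValueError(f"unknown transfer {self.transfer!r}")
        # Non-degenerate gamut: the RGB->XYZ matrix must be invertible.
        m = self.rgb_to_xyz_matrix
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("primaries/white form a degenerate gamut")

    # -- derived, cached via object.__setattr__-free lazy properties ------

    @property
    def rgb_to_xyz_matrix(self) -> np.ndarray:
        """3x3 matrix taking linear RGB to XYZ relative to white Y = 1."""
        xy = np.asarray(self.rgb_primaries_xy, dtype=float)
        # XYZ of each primary at unit Y, columns of P.
        P = np.column_stack(
            [_xy_to_xyz_unit_y(x, y) for x, y in xy]
        )
        white = _xy_to_xyz_unit_y(*self.white_xy)
        s = np.linalg.solve(P, white)
        return P * s  # scale columns so R=G=B=1 yields the white point

    @property
    def xyz_to_rgb_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.rgb_to_xyz_matrix)

    @property
    def white_xyz(self) -> np.ndarray:
        """White-point XYZ with Y normalized to 1."""
        return _xy_to_xyz_unit_y(*self.white_xy)

    # -- transfer function -------------------------------------------------

    def eotf(self, v: np.ndarray) -> np.ndarray:
        """Encoded [0,1] value -> linear light."""
        v = np.asarray(v, dtype=float)
        if self.transfer == "power":
            return np.power(v, self.gamma)
        return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)

    def oetf(self, lin: np.ndarray) -> np.ndarray:
        """Linear light -> encoded [0,1] value (inverse of :meth:`eotf`)."""
        lin = np.asarray(lin, dtype=float)
        lin = np.clip(lin, 0.0, None)
        if self.transfer == "power":
            return np.power(lin, 1.0 / self.gamma)
        return np.where(
            lin <= 0.0031308, lin * 12.92, 1.055 * np.power(lin, 1 / 2.4) - 0.055
        )


def _xy_to_xyz_unit_y(x: float, y: float) -> np.ndarray:
    if y == 0:
        raise ValueError("chromaticity with y = 0 has undefined XYZ at unit Y")
    return np.array([x / y, 1.0, (1.0 - x - y) / y])


def xy_to_xyz(xy: tuple[float, float], Y: float) -> np.ndarray:
    """CIE xyY -> XYZ."""
    return _xy_to_xyz_unit_y(*xy) * Y


def xyz_to_xy(xyz: np.ndarray) -> tuple[float, float]:
    s = float(np.sum(xyz))
    return (float(xyz[0] / s), float(xyz[1] / s))


@dataclass(frozen=True)
class LabColor:
    """A CIELAB color (L* lightness, a* green-red, b* blue-yellow)."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


_LAB_EPS = (6.0 / 29.0) ** 3
_LAB_KAPPA = (29.0 / 6.0) ** 2 / 3.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_EPS, np.cbrt(t), _LAB_KAPPA * t + 4.0 / 29.0)


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > 6.0 / 29.0, ft**3, (ft - 4.0 / 29.0) / _LAB_KAPPA)


def xyz_to_lab(xyz: np.ndarray, display: DisplayModel) -> LabColor:
    """XYZ (white Y = 1) -> CIELAB against the display white."""
    f = _lab_f(np.asarray(xyz, float) / display.white_xyz)
    L = 116.0 * f[1] - 16.0
    return LabColor(L=float(L), a=float(500.0 * (f[0] - f[1])), b=float(200.0 * (f[1] - f[2])))


def lab_to_xyz(lab: LabColor, display: DisplayModel) -> np.ndarray:
    fy = (lab.L + 16.0) / 116.0
    f = np.array([fy + lab.a / 500.0, fy, fy - lab.b / 200.0])
    return _lab_f_inv(f) * display.white_xyz


def rgb_to_lab(rgb, display: DisplayModel | None = None) -> LabColor:
    """Convert a display RGB triple in [0,1]^3 to CIELAB.

    Applies the display transfer function, the primaries matrix and the
    CIELAB forward transform against the display white.
    """
    display = display or DisplayModel()
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("rgb must be a length-3 triple")
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError(f"rgb channels outside [0, 1]: {rgb}")
    xyz = display.rgb_to_xyz_matrix @ display.eotf(rgb)
    return xyz_to_lab(xyz, display)


class RgbResult(NamedTuple):
    rgb: np.ndarray
    in_gamut: bool


def lab_to_rgb(lab: LabColor, display: DisplayModel | None = None) -> RgbResult:
    """CIELAB -> display RGB.  Out-of-gamut results are flagged, not raised.

    The returned RGB is clipped to [0,1]; ``in_gamut`` is False when the
    unclipped value left the cube by more than 1e-9 in any channel.
    """
    display = display or DisplayModel()
    lin = display.xyz_to_rgb_matrix @ lab_to_xyz(lab, display)
    in_gamut = bool(np.all(lin >= -1e-9) and np.all(lin <= 1 + 1e-9))
    rgb = display.oetf(np.clip(lin, 0.0, 1.0))
    return RgbResult(rgb=np.clip(rgb, 0.0, 1.0), in_gamut=in_gamut)


def delta_e(x: LabColor, y: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in L*a*b*."""
    return float(np.linalg.norm(x.as_array() - y.as_array()))


def delta_e_2000(x: LabColor, y: LabColor) -> float:
    """CIEDE2000 color difference (available behind config; CIE76 is the
    package default and the reference everywhere else)."""
    L1, a1, b1 = x.L, x.a, x.b
    L2, a2, b2 = y.L, y.a, y.b
    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1 - math.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1 + G) * a1, (1 + G) * a2
    C1p, C2p = math.hypot(a1p, b1), math.hypot(a2p, b2)
    h1p = math.degrees(math.atan2(b1, a1p)) % 360 if (a1p or b1) else 0.0
    h2p = math.degrees(math.atan2(b2, a2p)) % 360 if (a2p or b2) else 0.0
    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0:
        dhp = 0.0
    else:
        dh = h2p - h1p
        dhp = dh - 360 if dh > 180 else dh + 360 if dh < -180 else dh
    dHp = 2 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2)
    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0:
        hbp = h1p + h2p
    elif abs(h1p - h2p) <= 180:
        hbp = 0.5 * (h1p + h2p)
    elif h1p + h2p < 360:
        hbp = 0.5 * (h1p + h2p + 360)
    else:
        hbp = 0.5 * (h1p + h2p - 360)
    T = (
        1
        - 0.17 * math.cos(math.radians(hbp - 30))
        + 0.24 * math.cos(math.radians(2 * hbp))
        + 0.32 * math.cos(math.radians(3 * hbp + 6))
        - 0.20 * math.cos(math.radians(4 * hbp - 63))
    )
    dtheta = 30 * math.exp(-(((hbp - 275) / 25) ** 2))
    Rc = 2 * math.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    Sl = 1 + 0.015 * (Lbp - 50) ** 2 / math.sqrt(20 + (Lbp - 50) ** 2)
    Sc = 1 + 0.045 * Cbp
    Sh = 1 + 0.015 * Cbp * T
    Rt = -math.sin(math.radians(2 * dtheta)) * Rc
    return math.sqrt(
        (dLp / Sl) ** 2
        + (dCp / Sc) ** 2
        + (dHp / Sh) ** 2
        + Rt * (dCp / Sc) * (dHp / Sh)
    )


class GamutExceededError(ValueError):
    """Requested ΔE cannot be realized along this confusion line.

    Carries ``max_achievable``, the largest ΔE the gamut admits for the
    same axis/base/luminance.
    """

    def __init__(self, requested: float, max_achievable: float):
        self.requested = requested
        self.max_achievable = max_achievable
        super().__init__(
            f"requested dE {requested:.2f} exceeds gamut headroom "
            f"(max achievable {max_achievable:.2f})"
        )


@dataclass(frozen=True)
class ColorPair:
    """An isoluminant arrow/background color pair on one confusion axis."""

    axis: ConfusionAxis
    base_xy: tuple[float, float]
    luminance: float  # cd/m^2
    requested_de: float
    arrow_rgb: tuple[float, float, float]
    background_rgb: tuple[float, float, float]
    achieved_de: float
    arrow_xy: tuple[float, float] = field(default=(0.0, 0.0))
    background_xy: tuple[float, float] = field(default=(0.0, 0.0))


#: Fraction of peak luminance at which stimuli are presented.  Chosen so the
#: red-green axes keep ≥ 80 ΔE of symmetric headroom around the neutral base
#: (observed deficient thresholds reach ~78 ΔE); see docs/methods.md.
DEFAULT_STIMULUS_LUMINANCE_FRACTION = 0.40


def default_stimulus_luminance(display: DisplayModel | None = None) -> float:
    display = display or DisplayModel()
    return DEFAULT_STIMULUS_LUMINANCE_FRACTION * display.peak_luminance


@_lru_cache(maxsize=64)
def default_base_xy(
    axis: ConfusionAxis,
    luminance: float,
    display: DisplayModel,
) -> tuple[float, float]:
    """Default pair center for an axis: the ΔE-midpoint of the gamut chord.

    The confusion line through the display white is intersected with the
    gamut at the stimulus luminance; the base is the point on that chord
    equidistant (in CIE76 ΔE) from both ends.  Centering there rather than
    exactly on white maximizes the symmetric ΔE range of the staircase while
    keeping the mean stimulus chromaticity near-neutral and constant.
    """
    y_rel = luminance / display.peak_luminance
    white = np.asarray(display.white_xy, float)
    cop = np.asarray(axis.copunctal_xy, float)
    u = (cop - white) / np.linalg.norm(cop - white)

    def edge(sign: float) -> float:
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _in_gamut_at(tuple(white + sign * mid * u), y_rel, display):
                lo = mid
            else:
                hi = mid
        return lo

    A = white + edge(1.0) * u
    B = white - edge(-1.0) * u

    def lab_at(p: np.ndarray) -> LabColor:
        return xyz_to_lab(xy_to_xyz(tuple(p), y_rel), display)

    la, lb = lab_at(A), lab_at(B)
    half = 0.5 * delta_e(la, lb)
    lo_t, hi_t = 0.0, 1.0  # parameter along B -> A; ΔE from B is monotone
    for _ in range(60):
        t = 0.5 * (lo_t + hi_t)
        if delta_e(lb, lab_at(B + t * (A - B))) < half:
            lo_t = t
        else:
            hi_t = t
    M = B + 0.5 * (lo_t + hi_t) * (A - B)
    return (float(M[0]), float(M[1]))


def _pair_points_lab(
    axis: ConfusionAxis,
    base_xy: tuple[float, float],
    y_rel: float,
    d: float,
    display: DisplayModel,
) -> tuple[LabColor, LabColor, tuple, tuple]:
    """Lab colors of the two pair members at xy displacement ±d along the axis."""
    base = np.asarray(base_xy, float)
    cop = np.asarray(axis.copunctal_xy, float)
    u = cop - base
    u = u / np.linalg.norm(u)
    xy_a = base + d * u
    xy_b = base - d * u
    lab_a = xyz_to_lab(xy_to_xyz(tuple(xy_a), y_rel), display)
    lab_b = xyz_to_lab(xy_to_xyz(tuple(xy_b), y_rel), display)
    return lab_a, lab_b, tuple(xy_a), tuple(xy_b)


def _in_gamut_at(xy: tuple[float, float], y_rel: float, display: DisplayModel) -> bool:
    lin = display.xyz_to_rgb_matrix @ xy_to_xyz(xy, y_rel)
    return bool(np.all(lin >= -1e-12) and np.all(lin <= 1 + 1e-12))


def _max_displacement(
    axis: ConfusionAxis,
    base_xy: tuple[float, float],
    y_rel: float,
    display: DisplayModel,
) -> float:
    """Largest symmetric xy displacement keeping both pair members in gamut."""
    base = np.asarray(base_xy, float)
    cop = np.asarray(axis.copunctal_xy, float)
    u = (cop - base) / np.linalg.norm(cop - base)

    def ok(d: float) -> bool:
        return _in_gamut_at(tuple(base + d * u), y_rel, display) and _in_gamut_at(
            tuple(base - d * u), y_rel, display
        )

    if not ok(0.0):
        return 0.0
    lo, hi = 0.0, 1.0
    # the whole xy diagram is < 1 unit across, so hi=1 is always out of gamut
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def max_achievable_de(
    axis: ConfusionAxis | AxisName | str,
    base_xy: tuple[float, float] | None = None,
    luminance: float | None = None,
    display: DisplayModel | None = None,
) -> float:
    """Largest CIE76 ΔE a symmetric confusion pair can reach in gamut."""
    display = display or DisplayModel()
    if not isinstance(axis, ConfusionAxis):
        axis = ConfusionAxis.standard(axis)
    luminance = luminance if luminance is not None else default_stimulus_luminance(display)
    base_xy = base_xy or default_base_xy(axis, luminance, display)
    y_rel = luminance / display.peak_luminance
    d_max = _max_displacement(axis, base_xy, y_rel, display)
    la, lb, *_ = _pair_points_lab(axis, base_xy, y_rel, d_max, display)
    return delta_e(la, lb)


def confusion_pair(
    axis: ConfusionAxis | AxisName | str,
    requested_de: float,
    base_xy: tuple[float, float] | None = None,
    luminance: float | None = None,
    display: DisplayModel | None = None,
    tol: float = 0.01,
) -> ColorPair:
    """Build an isoluminant color pair separated by ``requested_de`` CIE76
    units, placed symmetrically about ``base_xy`` along the confusion line
    through the axis copunctal point.

    The displacement is found by bisection; the achieved ΔE is within
    ``tol`` of the request (well inside the 0.1 ΔE contract).

    Raises
    ------
    GamutExceededError
        If the request exceeds the gamut headroom along this line.
    """
    display = display or DisplayModel()
    if not isinstance(axis, ConfusionAxis):
        axis = ConfusionAxis.standard(axis)
    if requested_de < 0:
        raise ValueError("requested_de must be non-negative")
    luminance = luminance if luminance is not None else default_stimulus_luminance(display)
    base_xy = base_xy or default_base_xy(axis, luminance, display)
    y_rel = luminance / display.peak_luminance
    if not _in_gamut_at(base_xy, y_rel, display):
        raise ValueError("base chromaticity out of gamut at this luminance")

    d_hi = _max_displacement(axis, base_xy, y_rel, display)

    def de_at(d: float) -> float:
        la, lb, *_ = _pair_points_lab(axis, base_xy, y_rel, d, display)
        return delta_e(la, lb)

    de_max = de_at(d_hi)
    if requested_de > de_max + 1e-9:
        raise GamutExceededError(requested_de, de_max)

    lo, hi = 0.0, d_hi
    d = 0.0
    for _ in range(60):
        d = 0.5 * (lo + hi)
        err = de_at(d) - requested_de
        if abs(err) <= tol:
            break
        if err < 0:
            lo = d
        else:
            hi = d
    if requested_de == 0:
        d = 0.0

    la, lb, xy_a, xy_b = _pair_points_lab(axis, base_xy, y_rel, d, display)
    rgb_a = lab_to_rgb(la, display)
    rgb_b = lab_to_rgb(lb, display)
    return ColorPair(
        axis=axis,
        base_xy=tuple(base_xy),
        luminance=luminance,
        requested_de=requested_de,
        arrow_rgb=tuple(float(v) for v in rgb_a.rgb),
        background_rgb=tuple(float(v) for v in rgb_b.rgb),
        achieved_de=delta_e(la, lb),
        arrow_xy=xy_a,
        background_xy=xy_b,
    )
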