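"""Simulated observers and cohorts.

A simulated observer is a Weibull psychometric function per confusion axis
plus a simple touch model: on a "perceived" trial the observer touches the
arrowhead with isotropic Gaussian motor noise; on a "not perceived" trial it
either touches a uniformly random screen location (which can hit by chance)
or does not touch at all.  Cohort generators draw per-axis thresholds from
truncated normal distributions parameterized per diagnostic group, emulating
the group structure observed in the validation study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .colorimetry import AxisName
from .stimulus import PlateStimulus, ViewingGeometry, HIT_RADIUS_CM

__all__ = [
    "SimulatedObserver",
    "GroupSpec",
    "CohortSpec",
    "p_correct",
    "respond",
    "preset_observer",
    "generate_cohort",
    "random_touch_guess_rate",
    "DEFAULT_COHORT_SPEC",
]

DEFAULT_SLOPE = 3.5
DEFAULT_LAPSE = 0.02
DEFAULT_TOUCH_SIGMA_CM = 0.15


@dataclass(frozen=True)
class SimulatedObserver:
    """A synthetic subject with per-axis detection thresholds (ΔE).

    ``thresholds`` maps axis -> the ΔE at which the Weibull detection
    probability reaches 1 - 1/e of its range (the scale parameter).
    ``guess_policy`` is "random_touch" (uniform screen touch when the arrow
    is not seen) or "no_touch" (timeout).
    """

    thresholds: dict[AxisName, float]
    slope: float = DEFAULT_SLOPE
    lapse_rate: float = DEFAULT_LAPSE
    guess_policy: str = "random_touch"
    touch_sigma_cm: float = DEFAULT_TOUCH_SIGMA_CM
    label: str = "trichromat"
    observer_id: str = ""

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be positive")
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate outside [0, 0.1]")
        if self.touch_sigma_cm < 0:
            raise ValueError("touch_sigma_cm must be non-negative")
        if self.guess_policy not in ("random_touch", "no_touch"):
            raise ValueError(f"unknown guess policy {self.guess_policy!r}")

    def threshold(self, axis: AxisName | str) -> float:
        return self.thresholds[AxisName(axis)]


def random_touch_guess_rate(geom: ViewingGeometry | None = None,
                            hit_radius_cm: float = HIT_RADIUS_CM) -> float:
    """Probability that a uniformly random screen touch lands in the hit disc.

    Computed from the actual screen and disc areas, not assumed.
    """
    geom = geom or ViewingGeometry()
    d = geom.display
    w_cm = d.width_px * geom.pixel_pitch_mm / 10.0
    h_cm = d.height_px * geom.pixel_pitch_mm / 10.0
    return math.pi * hit_radius_cm**2 / (w_cm * h_cm)


def p_correct(
    observer: SimulatedObserver,
    axis: AxisName | str,
    presented_de: float,
    geom: ViewingGeometry | None = None,
) -> float:
    """Probability of a correct (hit) response at the presented ΔE.

    Weibull psychometric function with guess rate γ (set by the touch
    geometry under the random-touch policy, 0 under no-touch) and lapse λ:

        p(dE) = γ + (1 - γ - λ) · (1 - exp(-(dE / t)^β))
    """
    if presented_de < 0:
        raise ValueError("presented_de must be non-negative")
    t = observer.threshold(axis)
    gamma = random_touch_guess_rate(geom) if observer.guess_policy == "random_touch" else 0.0
    lam = observer.lapse_rate
    return gamma + (1.0 - gamma - lam) * (1.0 - math.exp(-((presented_de / t) ** observer.slope)))


def respond(
    observer: SimulatedObserver,
    plate: PlateStimulus,
    rng: np.random.Generator,
    geom: ViewingGeometry | None = None,
) -> tuple[float, float] | None:
    """Produce a touch point (screen degrees) or ``None`` (no touch).

    Catch plates are answered correctly with probability 1 - λ regardless of
    color thresholds.  A perceived arrow is touched at the arrowhead plus
    isotropic Gaussian noise of ``touch_sigma_cm``; otherwise the guess
    policy applies.
    """
    geom = geom or ViewingGeometry()
    if plate.is_catch_trial:
        p = 1.0 - observer.lapse_rate
    else:
        axis = plate.color_pair.axis.name
        t = observer.threshold(axis)
        lam = observer.lapse_rate
        de = plate.color_pair.achieved_de
        p = (1.0 - lam) * (1.0 - math.exp(-((de / t) ** observer.slope)))
    if rng.random() < p:
        hx, hy = plate.arrowhead_center_deg
        if observer.touch_sigma_cm > 0:
            dx_cm, dy_cm = rng.normal(0.0, observer.touch_sigma_cm, size=2)
            hx += geom.cm_to_deg(dx_cm)
            hy += geom.cm_to_deg(dy_cm)
        return (float(hx), float(hy))
    if observer.guess_policy == "no_touch":
        return None
    half_w, half_h = geom.screen_half_extent_deg
    return (float(rng.uniform(-half_w, half_w)), float(rng.uniform(-half_h, half_h)))


# ---------------------------------------------------------------------------
# presets and cohorts
# ---------------------------------------------------------------------------

#: Group mean per-axis thresholds observed in the validation cohort
#: (protan, deutan, tritan ΔE).
_PRESET_THRESHOLDS = {
    "trichromat_mean": (4.44, 5.38, 8.45),
    "protan_mean": (41.78, 17.69, 8.20),
    "deutan_mean": (14.38, 70.99, 12.00),
}

_PRESET_LABELS = {
    "trichromat_mean": "trichromat",
    "protan_mean": "protan",
    "deutan_mean": "deutan",
}


def preset_observer(name: str, **overrides) -> SimulatedObserver:
    """A named observer at its group's mean thresholds."""
    try:
        tp, td, tt = _PRESET_THRESHOLDS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_THRESHOLDS)}"
        ) from None
    kwargs = dict(
        thresholds={AxisName.PROTAN: tp, AxisName.DEUTAN: td, AxisName.TRITAN: tt},
        label=_PRESET_LABELS[name],
        observer_id=name,
    )
    kwargs.update(overrides)
    return SimulatedObserver(**kwargs)


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of one diagnostic group.

    Per axis: mean, SD and (lo, hi) truncation bounds of a truncated normal
    over thresholds, in ΔE.
    """

    label: str
    count: int
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]
    range: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        for m, (lo, hi) in zip(self.mean, self.range):
            if not (lo <= m <= hi):
                raise ValueError(f"mean {m} outside truncation range ({lo}, {hi})")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]

    @property
    def total(self) -> int:
        return sum(g.count for g in self.groups)


#: Default cohort emulating the validation study: 65 trichromats, 12 protan-
#: and 23 deutan-deficient subjects; per-axis mean/SD/range per group.
DEFAULT_COHORT_SPEC = CohortSpec(
    groups=(
        GroupSpec(
            label="trichromat",
            count=65,
            mean=(4.44, 5.38, 8.45),
            sd=(1.53, 1.46, 2.36),
            range=((2.54, 10.63), (2.51, 9.40), (3.30, 13.04)),
        ),
        GroupSpec(
            label="protan",
            count=12,
            mean=(41.78, 17.69, 8.20),
            sd=(14.06, 4.44, 2.70),
            range=((22.48, 66.75), (11.20, 24.61), (5.02, 14.59)),
        ),
        GroupSpec(
            label="deutan",
            count=23,
            mean=(14.38, 70.99, 12.00),
            sd=(12.23, 14.35, 14.05),
            range=((4.38, 66.75), (27.97, 78.05), (5.28, 75.92)),
        ),
    )
)

_AXES = (AxisName.PROTAN, AxisName.DEUTAN, AxisName.TRITAN)


def _truncnorm_sample(mean, sd, lo, hi, n, rng):
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(
    spec: CohortSpec = DEFAULT_COHORT_SPEC,
    rng_seed: int | np.random.Generator = 0,
    **observer_overrides,
) -> list[SimulatedObserver]:
    """Draw a labeled cohort of simulated observers from a group spec.

    Thresholds are sampled independently per axis from each group's
    truncated normal; sampling is fully determined by the seed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    cohort: list[SimulatedObserver] = []
    for group in spec.groups:
        draws = np.column_stack(
            [
                _truncnorm_sample(m, s, lo, hi, group.count, rng)
                for m, s, (lo, hi) in zip(group.mean, group.sd, group.range)
            ]
        ) if group.count else np.zeros((0, 3))
        for i in range(group.count):
            cohort.append(
                SimulatedObserver(
                    thresholds=dict(zip(_AXES, map(float, draws[i]))),
                    label=group.label,
                    observer_id=f"{group.label}_{i:03d}",
                    **observer_overrides,
                )
            )
    return cohort


def cohort_to_records(cohort: list[SimulatedObserver]) -> list[dict]:
    """Roster rows (id, label, per-axis thresholds, slope, lapse)."""
    return [
        {
            "observer_id": o.observer_id,
            "label": o.label,
            "t_protan": o.thresholds[AxisName.PROTAN],
            "t_deutan": o.thresholds[AxisName.DEUTAN],
            "t_tritan": o.thresholds[AxisName.TRITAN],
            "slope": o.slope,
            "lapse_rate": o.lapse_rate,
        }
        for o in cohort
    ]
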