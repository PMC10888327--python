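"""The adaptive test engine.

Each confusion axis is probed with a weighted transformed up/down staircase
on ΔE, stepped in the log domain (color-difference discrimination behaves
ratio-like across the 1–80 ΔE range).  A correct response lowers the level,
an incorrect one raises it; the down/up step ratio is chosen so the track
converges on the ΔE where the detection probability equals 1 − 1/e — the
scale parameter of a Weibull psychometric function, i.e. the observer's
threshold.  Steps shrink at every reversal down to an effective 1 ΔE, and
the threshold estimate is the geometric mean of the last reversal levels.

Two protocols are provided: a fully extended high-precision track and an
optimized track that stops after a handful of reversals, trading a little
precision for a several-fold reduction in trial count.

The engine is wall-clock free: a stimulus timeout is simply a ``None``
touch from the responder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable

import numpy as np

from .colorimetry import (
    AxisName,
    ColorPair,
    DisplayModel,
    confusion_pair,
    default_stimulus_luminance,
    max_achievable_de,
)
from .stimulus import PlateStimulus, ViewingGeometry, make_catch_plate, make_plate, is_hit
from . import scoring_stats as _scoring

__all__ = [
    "Protocol",
    "FULL_EXTENDED",
    "OPTIMIZED",
    "TrialRecord",
    "AxisResult",
    "SessionResult",
    "run_axis_staircase",
    "run_full_test",
    "trial_count",
]

#: Target proportion correct at convergence: the Weibull scale point.
TARGET_P = 1.0 - math.exp(-1.0)


@dataclass(frozen=True)
class Protocol:
    """Staircase protocol parameters (ΔE units unless noted)."""

    name: str
    start_de: float = 40.0
    initial_step_de: float = 16.0  # first up-step, expressed at start level
    n_reversals_total: int = 14
    n_reversals_averaged: int = 10
    floor_de: float = 1.0
    ceiling_de: float | None = None  # None -> gamut headroom, capped at 80
    catch_every: int = 5
    max_trials_per_axis: int = 80

    def __post_init__(self) -> None:
        if self.floor_de < 1.0:
            raise ValueError("floor_de must be at least 1 ΔE")
        if self.n_reversals_averaged > self.n_reversals_total:
            raise ValueError("cannot average more reversals than are collected")
        if self.start_de <= self.floor_de:
            raise ValueError("start_de must exceed floor_de")
        if self.initial_step_de <= 0 or self.max_trials_per_axis < 3:
            raise ValueError("invalid protocol parameters")

    def ceiling_for(self, axis: AxisName, display: DisplayModel | None = None) -> float:
        if self.ceiling_de is not None:
            return self.ceiling_de
        return min(80.0, max_achievable_de(axis, display=display))


FULL_EXTENDED = Protocol(name="full_extended")
OPTIMIZED = Protocol(
    name="optimized",
    initial_step_de=30.0,
    n_reversals_total=3,
    n_reversals_averaged=2,
    max_trials_per_axis=25,
)

PROTOCOLS = {"full_extended": FULL_EXTENDED, "optimized": OPTIMIZED}


@dataclass(frozen=True)
class TrialRecord:
    axis: AxisName
    presented_de: float
    is_catch: bool
    response: str  # "hit" | "miss" | "timeout"
    touch_point_deg: tuple[float, float] | None
    trial_index: int

    @property
    def correct(self) -> bool:
        return self.response == "hit"


@dataclass(frozen=True)
class AxisResult:
    axis: AxisName
    threshold_de: float
    trials: tuple[TrialRecord, ...]
    reversal_levels: tuple[float, ...]
    at_floor: bool = False
    at_ceiling: bool = False

    @property
    def n_stimulus_trials(self) -> int:
        return sum(1 for t in self.trials if not t.is_catch)


@dataclass(frozen=True)
class SessionResult:
    protocol: Protocol
    thresholds: _scoring.AxisThresholds
    gcs: float
    classification: str
    severity: str | None
    trials: tuple[TrialRecord, ...]
    catch_accuracy: float
    valid: bool
    axis_order: tuple[AxisName, ...]
    axis_results: tuple[AxisResult, ...]


#: Session validity requires at least this fraction of catch trials correct.
MIN_CATCH_ACCURACY = 0.8


@lru_cache(maxsize=8192)
def _cached_pair(axis: AxisName, de: float, display: DisplayModel) -> ColorPair:
    return confusion_pair(axis, de, display=display)


class _CatchState:
    """Session-level catch-trial scheduler and tally."""

    def __init__(self, every: int, rng: np.random.Generator, geom: ViewingGeometry):
        self.every = every
        self.rng = rng
        self.geom = geom
        self.stimulus_count = 0
        self.n_catch = 0
        self.n_catch_correct = 0

    def due(self) -> bool:
        return self.every > 0 and self.stimulus_count > 0 and self.stimulus_count % self.every == 0


def run_axis_staircase(
    responder: Callable[[PlateStimulus], tuple[float, float] | None],
    axis: AxisName | str,
    protocol: Protocol = FULL_EXTENDED,
    rng_seed: int | np.random.Generator = 0,
    geom: ViewingGeometry | None = None,
    _catch_state: _CatchState | None = None,
    _trial_offset: int = 0,
) -> AxisResult:
    """Estimate one axis's ΔE threshold with the protocol's staircase.

    ``responder`` maps a plate to a touch point in screen degrees (or
    ``None`` for a timeout); the engine scores it against the arrowhead hit
    disc.  Correct lowers the level, incorrect raises it, with the weighted
    down/up ratio targeting the 1 − 1/e point.  Terminates on the reversal
    budget, the trial budget, or two consecutive responses pinned at the
    floor or ceiling.
    """
    axis = AxisName(axis)
    geom = geom or ViewingGeometry()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    ceiling = protocol.ceiling_for(axis, geom.display)
    floor = protocol.floor_de
    level = min(protocol.start_de, ceiling)
    # Step sizes live in log space.  down/up ratio per Kaernbach's weighted
    # rule so the track equilibrates where p(correct) = TARGET_P.
    up_step = math.log((protocol.start_de + protocol.initial_step_de) / protocol.start_de)
    down_ratio = (1.0 - TARGET_P) / TARGET_P

    trials: list[TrialRecord] = []
    reversal_levels: list[float] = []
    prev_direction = 0  # -1 down, +1 up
    pinned_floor = 0
    pinned_ceiling = 0
    n_stim = 0
    idx = _trial_offset

    def log_trial(plate: PlateStimulus, presented: float, is_catch: bool) -> TrialRecord:
        nonlocal idx
        touch = responder(plate)
        if touch is None:
            resp = "timeout"
        elif is_hit(touch, plate, geom):
            resp = "hit"
        else:
            resp = "miss"
        rec = TrialRecord(
            axis=axis,
            presented_de=presented,
            is_catch=is_catch,
            response=resp,
            touch_point_deg=touch,
            trial_index=idx,
        )
        idx += 1
        trials.append(rec)
        return rec

    at_floor = at_ceiling = False
    while n_stim < protocol.max_trials_per_axis:
        if _catch_state is not None and _catch_state.due():
            plate = make_catch_plate(_catch_state.rng, geom)
            rec = log_trial(plate, plate.color_pair.achieved_de, True)
            _catch_state.n_catch += 1
            _catch_state.n_catch_correct += rec.correct
            _catch_state.stimulus_count = 0  # reset cadence counter

        pair = _cached_pair(axis, round(level, 4), geom.display)
        plate = make_plate(pair, rng, geom)
        rec = log_trial(plate, level, False)
        n_stim += 1
        if _catch_state is not None:
            _catch_state.stimulus_count += 1

        correct = rec.correct
        # pinned-at-bound rules
        if correct and level <= floor + 1e-9:
            pinned_floor += 1
            if pinned_floor >= 2:
                at_floor = True
                break
        else:
            pinned_floor = 0
        if (not correct) and level >= ceiling - 1e-9:
            pinned_ceiling += 1
            if pinned_ceiling >= 2:
                at_ceiling = True
                break
        else:
            pinned_ceiling = 0

        direction = -1 if correct else +1
        if prev_direction != 0 and direction != prev_direction:
            reversal_levels.append(level)
            up_step /= 2.0
            if len(reversal_levels) >= protocol.n_reversals_total:
                prev_direction = direction
                break
        prev_direction = direction

        # enforce an effective minimum step of 1 ΔE at the current level
        min_step = math.log(1.0 + 1.0 / level)
        step = max(up_step, min_step)
        if correct:
            level = max(floor, level * math.exp(-down_ratio * step))
        else:
            level = min(ceiling, level * math.exp(step))

    if at_floor:
        threshold = floor
    elif at_ceiling:
        threshold = ceiling
    elif reversal_levels:
        tail = reversal_levels[-protocol.n_reversals_averaged:]
        threshold = math.exp(sum(math.log(v) for v in tail) / len(tail))
    else:
        threshold = level

    return AxisResult(
        axis=axis,
        threshold_de=float(threshold),
        trials=tuple(trials),
        reversal_levels=tuple(reversal_levels),
        at_floor=at_floor,
        at_ceiling=at_ceiling,
    )


def run_full_test(
    responder: Callable[[PlateStimulus], tuple[float, float] | None],
    protocol: Protocol = FULL_EXTENDED,
    rng_seed: int | np.random.Generator = 0,
    geom: ViewingGeometry | None = None,
    cutoffs=None,
) -> SessionResult:
    """Run all three axes (randomized order) with interleaved catch trials
    and score the session: thresholds, GCS, classification, severity.

    Deterministic given the responder and the seed.  The session is marked
    invalid when catch-trial accuracy falls below ``MIN_CATCH_ACCURACY``.
    """
    geom = geom or ViewingGeometry()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    axes = [AxisName.PROTAN, AxisName.DEUTAN, AxisName.TRITAN]
    order = [axes[i] for i in rng.permutation(3)]
    catch = _CatchState(protocol.catch_every, rng, geom)

    results: dict[AxisName, AxisResult] = {}
    all_trials: list[TrialRecord] = []
    for ax in order:
        res = run_axis_staircase(
            responder, ax, protocol, rng, geom,
            _catch_state=catch, _trial_offset=len(all_trials),
        )
        results[ax] = res
        all_trials.extend(res.trials)

    thresholds = _scoring.AxisThresholds(
        protan_de=results[AxisName.PROTAN].threshold_de,
        deutan_de=results[AxisName.DEUTAN].threshold_de,
        tritan_de=results[AxisName.TRITAN].threshold_de,
        at_ceiling=tuple(results[ax].at_ceiling for ax in axes),
    )
    score = _scoring.gcs(thresholds)
    classification = _scoring.classify(thresholds, cutoffs)
    sev = None
    if classification != "trichromat":
        ax = AxisName(classification)
        sev = _scoring.severity(thresholds.as_dict()[ax])
    catch_acc = catch.n_catch_correct / catch.n_catch if catch.n_catch else 1.0
    return SessionResult(
        protocol=protocol,
        thresholds=thresholds,
        gcs=score,
        classification=classification,
        severity=sev,
        trials=tuple(all_trials),
        catch_accuracy=catch_acc,
        valid=catch_acc >= MIN_CATCH_ACCURACY,
        axis_order=tuple(order),
        axis_results=tuple(results[ax] for ax in axes),
    )


def trial_count(session: SessionResult) -> int:
    """Number of non-catch stimulus trials in a session (the package's
    proxy for administration time)."""
    return sum(1 for t in session.trials if not t.is_catch)
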