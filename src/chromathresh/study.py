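"""Desk-scale replication of the validation study.

Drives the whole loop with simulated observers: generate a labeled cohort,
run the full-extended protocol on everyone, re-derive what the optimized
protocol would have measured on the same observers, give a retest subsample
a second seeded session, and emit the study's summary tables and agreement
statistics (classification kappa, per-axis Bland–Altman and ICC).

Everything is reproducible from a single master seed: every stage draws its
own child seed from a stable hash of (master seed, stage label), so adding
or reordering stages never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import AxisName
from .stimulus import ViewingGeometry
from .observer_sim import (
    CohortSpec,
    DEFAULT_COHORT_SPEC,
    SimulatedObserver,
    cohort_to_records,
    generate_cohort,
    respond,
)
from .psychophysics import (
    FULL_EXTENDED,
    OPTIMIZED,
    Protocol,
    SessionResult,
    run_full_test,
    trial_count,
)
from . import scoring_stats as sstats

__all__ = ["StudyScenario", "StudyReport", "child_seed", "run_study", "write_report"]

_AXES = (AxisName.PROTAN, AxisName.DEUTAN, AxisName.TRITAN)


def child_seed(master_seed: int, *labels) -> int:
    """Stable per-stage seed: hash of the master seed and stage labels."""
    h = hashlib.sha256(":".join([str(master_seed), *map(str, labels)]).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class StudyScenario:
    """Configuration of one desk-scale study run."""

    cohort_spec: CohortSpec = DEFAULT_COHORT_SPEC
    master_seed: int = 0
    retest_n_trichromat: int = 27
    retest_n_deficient: int = 13
    run_optimized: bool = True

    @property
    def retest_n(self) -> int:
        return self.retest_n_trichromat + self.retest_n_deficient


@dataclass
class StudyReport:
    scenario: StudyScenario
    roster: pd.DataFrame
    sessions: pd.DataFrame  # one row per (observer, protocol, session)
    classification_kappa: float
    kappa_table: np.ndarray
    kappa_categories: list[str]
    icc_per_axis: dict[str, float]
    icc_mean: float
    bland_altman_per_axis: dict[str, sstats.BlandAltmanResult]
    retest_mean_abs_diff: dict[str, dict[str, float]]  # group -> axis -> |mean diff|
    group_summary: pd.DataFrame
    protocol_comparison: pd.DataFrame

    def summary_dict(self) -> dict:
        return {
            "n_subjects": int(self.roster.shape[0]),
            "n_retested": int(self.sessions.query("session == 2").observer_id.nunique()),
            "classification_kappa": self.classification_kappa,
            "icc_per_axis": self.icc_per_axis,
            "icc_mean": self.icc_mean,
            "bland_altman": {
                ax: {
                    "mean_difference": r.mean_difference,
                    "sd_difference": r.sd_difference,
                    "loa_lower": r.loa_lower,
                    "loa_upper": r.loa_upper,
                }
                for ax, r in self.bland_altman_per_axis.items()
            },
            "retest_mean_abs_diff": self.retest_mean_abs_diff,
        }


def _session_row(obs: SimulatedObserver, protocol: str, session: int, res: SessionResult) -> dict:
    return {
        "observer_id": obs.observer_id,
        "label": obs.label,
        "protocol": protocol,
        "session": session,
        "protan_de": res.thresholds.protan_de,
        "deutan_de": res.thresholds.deutan_de,
        "tritan_de": res.thresholds.tritan_de,
        "gcs": res.gcs,
        "classification": res.classification,
        "severity": res.severity or "",
        "n_trials": trial_count(res),
        "catch_accuracy": res.catch_accuracy,
        "valid": res.valid,
    }


def _run_session(
    obs: SimulatedObserver,
    protocol: Protocol,
    seed: int,
    geom: ViewingGeometry,
) -> SessionResult:
    obs_rng = np.random.default_rng(child_seed(seed, "observer"))
    eng_rng = np.random.default_rng(child_seed(seed, "engine"))
    responder = lambda plate: respond(obs, plate, obs_rng, geom)  # noqa: E731
    return run_full_test(responder, protocol, eng_rng, geom)


def run_study(scenario: StudyScenario | None = None, geom: ViewingGeometry | None = None) -> StudyReport:
    """Execute the scenario and assemble the study report."""
    scenario = scenario or StudyScenario()
    geom = geom or ViewingGeometry()
    ms = scenario.master_seed

    cohort = generate_cohort(scenario.cohort_spec, child_seed(ms, "cohort"))
    roster = pd.DataFrame(cohort_to_records(cohort))

    rows = []
    session1: dict[str, SessionResult] = {}
    for obs in cohort:
        res = _run_session(obs, FULL_EXTENDED, child_seed(ms, "s1", obs.observer_id), geom)
        session1[obs.observer_id] = res
        rows.append(_session_row(obs, "full_extended", 1, res))
        if scenario.run_optimized:
            res_o = _run_session(obs, OPTIMIZED, child_seed(ms, "opt", obs.observer_id), geom)
            rows.append(_session_row(obs, "optimized", 1, res_o))

    # retest subsample: seeded draw respecting the group composition
    tri_ids = [o.observer_id for o in cohort if o.label == "trichromat"]
    def_ids = [o.observer_id for o in cohort if o.label != "trichromat"]
    if scenario.retest_n_trichromat > len(tri_ids) or scenario.retest_n_deficient > len(def_ids):
        raise ValueError("retest composition not realizable from cohort labels")
    pick = np.random.default_rng(child_seed(ms, "retest_pick"))
    retest_ids = sorted(
        list(pick.choice(tri_ids, scenario.retest_n_trichromat, replace=False))
        + list(pick.choice(def_ids, scenario.retest_n_deficient, replace=False))
    )
    by_id = {o.observer_id: o for o in cohort}
    session2: dict[str, SessionResult] = {}
    for oid in retest_ids:
        obs = by_id[oid]
        res = _run_session(obs, FULL_EXTENDED, child_seed(ms, "s2", oid), geom)
        session2[oid] = res
        rows.append(_session_row(obs, "full_extended", 2, res))

    sessions = pd.DataFrame(rows)

    # classification agreement against ground truth (full-extended, session 1)
    truth = [o.label for o in cohort]
    predicted = [session1[o.observer_id].classification for o in cohort]
    cats = sorted(set(truth) | set(predicted))
    table = sstats.labels_to_table(truth, predicted, cats)
    kappa = sstats.cohens_kappa(table)

    # retest agreement per axis
    icc = {}
    ba = {}
    for ax in _AXES:
        key = f"{ax.value}_de"
        s1 = np.array([getattr(session1[oid].thresholds, key) for oid in retest_ids])
        s2 = np.array([getattr(session2[oid].thresholds, key) for oid in retest_ids])
        icc[ax.value] = sstats.icc_absolute_agreement(s1, s2)
        ba[ax.value] = sstats.bland_altman(s1, s2)
    icc_mean = float(np.mean(list(icc.values())))

    # per-group |mean difference| between sessions
    mad: dict[str, dict[str, float]] = {}
    for group, ids in (
        ("trichromat", [i for i in retest_ids if by_id[i].label == "trichromat"]),
        ("deficient", [i for i in retest_ids if by_id[i].label != "trichromat"]),
    ):
        mad[group] = {}
        for ax in _AXES:
            key = f"{ax.value}_de"
            d = [
                getattr(session1[i].thresholds, key) - getattr(session2[i].thresholds, key)
                for i in ids
            ]
            mad[group][ax.value] = abs(float(np.mean(d))) if d else float("nan")

    group_summary = _group_summary(sessions)
    protocol_comparison = _protocol_comparison(sessions) if scenario.run_optimized else pd.DataFrame()

    return StudyReport(
        scenario=scenario,
        roster=roster,
        sessions=sessions,
        classification_kappa=float(kappa),
        kappa_table=table,
        kappa_categories=cats,
        icc_per_axis=icc,
        icc_mean=icc_mean,
        bland_altman_per_axis=ba,
        retest_mean_abs_diff=mad,
        group_summary=group_summary,
        protocol_comparison=protocol_comparison,
    )


def _group_summary(sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean (min–max) and SD of each axis threshold and the GCS,
    full-extended first sessions — the shape of the study's outcome table."""
    df = sessions.query("protocol == 'full_extended' and session == 1")
    out = []
    for group, sub in df.groupby("label"):
        for col in ("protan_de", "deutan_de", "tritan_de", "gcs"):
            out.append(
                {
                    "group": group,
                    "measure": col,
                    "mean": sub[col].mean(),
                    "min": sub[col].min(),
                    "max": sub[col].max(),
                    "sd": sub[col].std(ddof=1),
                }
            )
    return pd.DataFrame(out)


def _protocol_comparison(sessions: pd.DataFrame) -> pd.DataFrame:
    """Full-extended vs optimized outcomes and trial counts, by broad group."""
    df = sessions.query("session == 1").copy()
    df["broad"] = np.where(df.label == "trichromat", "trichromat", "dyschromat")
    out = []
    for (broad, proto), sub in df.groupby(["broad", "protocol"]):
        row = {"group": broad, "protocol": proto, "n": len(sub), "mean_trials": sub.n_trials.mean()}
        for col in ("protan_de", "deutan_de", "tritan_de", "gcs"):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_sd"] = sub[col].std(ddof=1)
        out.append(row)
    return pd.DataFrame(out)


def write_report(report: StudyReport, outdir: str, make_figures: bool = True) -> None:
    """Write roster/session CSVs, the summary JSON and Bland–Altman figures."""
    os.makedirs(outdir, exist_ok=True)
    report.roster.to_csv(os.path.join(outdir, "cohort_roster.csv"), index=False)
    report.sessions.to_csv(os.path.join(outdir, "sessions.csv"), index=False)
    report.group_summary.to_csv(os.path.join(outdir, "group_summary.csv"), index=False)
    if len(report.protocol_comparison):
        report.protocol_comparison.to_csv(
            os.path.join(outdir, "protocol_comparison.csv"), index=False
        )
    summary = report.summary_dict()
    summary["kappa_table"] = {
        "categories": report.kappa_categories,
        "counts": report.kappa_table.tolist(),
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    if make_figures:
        _bland_altman_figure(report, os.path.join(outdir, "bland_altman.png"))


def _bland_altman_figure(report: StudyReport, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharey=False)
    for axplt, (name, r) in zip(axes, report.bland_altman_per_axis.items()):
        axplt.scatter(r.means, r.differences, s=14, alpha=0.7)
        axplt.axhline(r.mean_difference, color="k", lw=1)
        axplt.axhline(r.loa_lower, color="k", lw=1, ls="--")
        axplt.axhline(r.loa_upper, color="k", lw=1, ls="--")
        axplt.set_title(f"{name} axis")
        axplt.set_xlabel("mean of sessions (ΔE)")
    axes[0].set_ylabel("session 1 − session 2 (ΔE)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
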