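"""Scoring and agreement statistics.

Scoring: the Global Chromatic Score (GCS) — the mean of the three per-axis
ΔE thresholds — plus deficiency classification (axis with the largest
threshold-to-cutoff ratio) and a three-level severity grade anchored at
ΔE ≈ 22 (low), 40 (mild) and 60 (high).

Statistics: the validation toolkit — Cohen's kappa, Bland–Altman agreement,
the two-way absolute-agreement single-measure ICC, Spearman rank
correlation, the paired t-test and Buderer's sensitivity-driven sample-size
formula — all implemented directly from their defining formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .colorimetry import AxisName

__all__ = [
    "AxisThresholds",
    "DEFAULT_CUTOFFS",
    "SEVERITY_ANCHORS",
    "gcs",
    "classify",
    "severity",
    "cohens_kappa",
    "UndefinedKappaError",
    "bland_altman",
    "BlandAltmanResult",
    "icc_absolute_agreement",
    "spearman_rho",
    "paired_t",
    "sensitivity_sample_size",
]


@dataclass(frozen=True)
class AxisThresholds:
    """Per-axis ΔE thresholds from one completed session."""

    protan_de: float
    deutan_de: float
    tritan_de: float
    at_ceiling: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        if min(self.protan_de, self.deutan_de, self.tritan_de) <= 0:
            raise ValueError("thresholds must be positive")

    def as_dict(self) -> dict[AxisName, float]:
        return {
            AxisName.PROTAN: self.protan_de,
            AxisName.DEUTAN: self.deutan_de,
            AxisName.TRITAN: self.tritan_de,
        }


#: Normal/abnormal per-axis cutoffs (ΔE), set just above the trichromatic
#: maxima observed in the validation cohort; configurable.
DEFAULT_CUTOFFS = {
    AxisName.PROTAN: 11.0,
    AxisName.DEUTAN: 9.5,
    AxisName.TRITAN: 13.5,
}

#: Severity anchors (ΔE): low ≈ 22, mild ≈ 40, high ≈ 60.
SEVERITY_ANCHORS = {"low": 22.0, "mild": 40.0, "high": 60.0}


def gcs(t: AxisThresholds | tuple[float, float, float]) -> float:
    """Global Chromatic Score: mean of the protan, deutan and tritan ΔE
    thresholds."""
    if isinstance(t, AxisThresholds):
        vals = (t.protan_de, t.deutan_de, t.tritan_de)
    else:
        vals = tuple(t)
    return sum(vals) / 3.0


def classify(
    t: AxisThresholds | tuple[float, float, float],
    cutoffs: dict[AxisName, float] | None = None,
) -> str:
    """Classify a session as trichromat or by its most affected axis.

    Trichromat iff no axis exceeds its cutoff; otherwise the axis with the
    largest threshold-to-cutoff ratio (both red-green axes are typically
    elevated in deficient observers, so the *relative* elevation decides).
    """
    cutoffs = cutoffs or DEFAULT_CUTOFFS
    if any(v <= 0 for v in cutoffs.values()):
        raise ValueError("cutoffs must be positive")
    if not isinstance(t, AxisThresholds):
        t = AxisThresholds(*t)
    vals = t.as_dict()
    ratios = {ax: vals[ax] / cutoffs[ax] for ax in vals}
    if all(r <= 1.0 for r in ratios.values()):
        return "trichromat"
    return max(ratios, key=lambda ax: ratios[ax]).value


def severity(threshold_de: float, anchors: dict[str, float] | None = None) -> str:
    """Grade a supra-cutoff threshold by its nearest severity anchor.

    Band edges fall at the midpoints between anchors (31 and 50 ΔE for the
    default 22/40/60 anchors).
    """
    anchors = anchors or SEVERITY_ANCHORS
    names = sorted(anchors, key=lambda k: anchors[k])
    return min(names, key=lambda k: abs(threshold_de - anchors[k]))


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


class UndefinedKappaError(ZeroDivisionError):
    """Kappa is undefined when expected agreement equals 1."""


def cohens_kappa(table) -> float:
    """Unweighted Cohen's kappa from a square contingency table.

    κ = (p_o − p_e) / (1 − p_e), with p_o the observed agreement (diagonal
    mass) and p_e the chance agreement from the marginals.
    """
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValueError("table must be square with at least 2 categories")
    if np.any(m < 0):
        raise ValueError("table counts must be non-negative")
    n = m.sum()
    if n == 0:
        raise ValueError("table is empty")
    po = np.trace(m) / n
    pe = float(np.sum(m.sum(axis=0) * m.sum(axis=1)) / n**2)
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    return float((po - pe) / (1.0 - pe))


def labels_to_table(truth, predicted, categories=None) -> np.ndarray:
    """Square contingency table over the union of observed categories."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("label sequences differ in length")
    cats = list(categories) if categories is not None else sorted(set(truth) | set(predicted))
    idx = {c: i for i, c in enumerate(cats)}
    m = np.zeros((len(cats), len(cats)), dtype=int)
    for a, b in zip(truth, predicted):
        m[idx[a], idx[b]] += 1
    return m


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement between paired measurements x and y.

    Differences are x − y; limits of agreement are mean ± 1.96 SD.  The
    per-pair means and differences are returned as the plotting payload.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = x - y
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=md,
        sd_difference=sd,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        means=(x + y) / 2.0,
        differences=diff,
    )


def icc_absolute_agreement(session1, session2) -> float:
    """ICC(A,1): two-way, absolute-agreement, single-measure intraclass
    correlation for two sessions per subject.

    From the mean squares of the subjects × sessions ANOVA with n subjects
    and k = 2 sessions:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    """
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 subjects with 2 sessions each")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise ZeroDivisionError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ZeroDivisionError("constant input; correlation undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test: one-sample t on the differences, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero difference variance; t undefined")
    n = len(d)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * _sps.t.sf(abs(t), df=n - 1))
    return t, p


def sensitivity_sample_size(
    sensitivity: float,
    alpha: float = 0.05,
    prevalence: float = 0.35,
    precision_halfwidth: float = 0.10,
) -> int:
    """Minimum n to estimate a diagnostic sensitivity to a given precision
    (Buderer's formula):

        n = ⌈ z²_{1−α/2} · Se(1−Se) / (d² · prevalence) ⌉
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("alpha", alpha),
        ("precision_halfwidth", precision_halfwidth),
    ):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must be in (0, 1)")
    if not (0.0 < prevalence <= 1.0):
        raise ValueError("prevalence must be in (0, 1]")
    z = _sps.norm.ppf(1.0 - alpha / 2.0)
    n = z**2 * sensitivity * (1.0 - sensitivity) / (precision_halfwidth**2 * prevalence)
    return int(math.ceil(n))
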