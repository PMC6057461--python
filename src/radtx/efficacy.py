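"""Preclinical quantitative endpoints.

Caliper tumor volumes (width^2 x length / 2), percent growth inhibition
against controls, iso-effect relative biological effectiveness (RBE),
radiotracer biodistribution (%ID/g, tumor-to-muscle ratio), time to
progression with Kaplan-Meier / log-rank comparison, and the
immunohistochemistry indices (microvessel density per high-power field and
the Ki-67 proliferation index).

Percent endpoints are returned at full precision; reports conventionally
round them to the nearest integer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "tumor_volume",
    "growth_inhibition",
    "rbe_iso_effect",
    "tmr",
    "tmr_change",
    "pid_per_gram",
    "time_to_progression",
    "KMResult",
    "km_estimate",
    "logrank",
    "mvd",
    "ki67_index",
    "TTestResult",
    "ttest",
]


def tumor_volume(width: float, length: float) -> float:
    """Ellipsoid caliper volume (width^2 x length) / 2 in mm^3.

    By convention width <= length; swapped with a warning otherwise.
    """
    width = np.asarray(width, dtype=float)
    length = np.asarray(length, dtype=float)
    if (width <= 0).any() if width.ndim else width <= 0:
        raise ValueError("width must be positive")
    if (length <= 0).any() if length.ndim else length <= 0:
        raise ValueError("length must be positive")
    swapped = width > length
    if np.any(swapped):
        warnings.warn("caliper width exceeded length; dimensions swapped", stacklevel=2)
        width, length = np.where(swapped, length, width), np.where(swapped, width, length)
    out = width**2 * length / 2.0
    return float(out) if out.ndim == 0 else out


def growth_inhibition(treated_mean: float, control_mean: float) -> float:
    """Percent tumor growth inhibition, 100 * (1 - treated/control)."""
    if control_mean <= 0:
        raise ValueError("control mean volume must be positive")
    return 100.0 * (1.0 - treated_mean / control_mean)


def rbe_iso_effect(photon_total_dose: float, carbon_total_dose: float) -> float:
    """Relative biological effectiveness from iso-effective total doses.

    The caller asserts that the two schedules produced the same biological
    effect; the RBE is then the photon/carbon physical dose ratio.
    """
    if photon_total_dose <= 0 or carbon_total_dose <= 0:
        raise ValueError("doses must be positive")
    return photon_total_dose / carbon_total_dose


def tmr(tumor: float, muscle: float) -> float:
    """Tumor-to-muscle ratio of %ID/g uptake."""
    if muscle <= 0:
        raise ValueError("muscle uptake must be positive")
    return tumor / muscle


def tmr_change(after: float, before: float) -> float:
    """Percent change of the tumor-to-muscle ratio, 100 * (after - before)/before."""
    if before <= 0:
        raise ValueError("baseline TMR must be positive")
    return 100.0 * (after - before) / before


def pid_per_gram(
    organ_activity: float, injected_activity: float, organ_weight: float
) -> float:
    """Percent injected dose per gram: 100 * (organ/injected) / weight."""
    if injected_activity <= 0:
        raise ValueError("injected activity must be positive")
    if organ_weight <= 0:
        raise ValueError("organ weight must be positive")
    return 100.0 * (organ_activity / injected_activity) / organ_weight


def time_to_progression(
    growth: pd.DataFrame, threshold_mm3: float = 500.0
) -> pd.DataFrame:
    """First-crossing progression events from per-animal caliper series.

    ``growth`` is tidy with columns (animal_id, day, width_mm, length_mm).
    An animal's event time is the first study day its volume reaches
    ``threshold_mm3``; animals never crossing are censored at their last
    observation. No interpolation between measurement days. Returns a frame
    (animal_id, time, event) plus the animal's arm if present in the input.
    """
    required = {"animal_id", "day", "width_mm", "length_mm"}
    if growth.empty or not required.issubset(growth.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")
    rows = []
    for animal, series in growth.groupby("animal_id", sort=True):
        series = series.sort_values("day")
        vol = tumor_volume(series["width_mm"].to_numpy(), series["length_mm"].to_numpy())
        crossed = np.flatnonzero(vol >= threshold_mm3)
        if crossed.size:
            t, event = float(series["day"].iloc[crossed[0]]), True
        else:
            t, event = float(series["day"].iloc[-1]), False
        row = {"animal_id": animal, "time": t, "event": event}
        if "arm" in series:
            row["arm"] = series["arm"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class KMResult:
    """Product-limit survival curve with its median."""

    times: np.ndarray  # event/censor times in ascending order
    survival: np.ndarray  # S(t) just after each time
    median: float | None  # first time S(t) <= 0.5; None if never reached


def km_estimate(events: pd.DataFrame) -> KMResult:
    """Kaplan-Meier product-limit estimate of time to progression.

    ``events`` needs columns (time, event). The median is the first time at
    which the survival probability drops to 0.5 or below; ``None`` (flagged
    in the log) when the curve never reaches 0.5, e.g. all animals censored.
    """
    if events.empty:
        raise ValueError("no events given")
    kmf = KaplanMeierFitter()
    kmf.fit(events["time"], event_observed=events["event"].astype(bool))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    if median is None:
        logger.warning("median time to progression undefined (curve stays above 0.5)")
    return KMResult(times=times, survival=surv, median=median)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p).

    Ties are handled by the standard aggregated-risk-set formulation.
    """
    for g in (group_a, group_b):
        if g.empty:
            raise ValueError("both groups need at least one record")
    res = logrank_test(
        group_a["time"],
        group_b["time"],
        event_observed_A=group_a["event"].astype(bool),
        event_observed_B=group_b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def mvd(counts: pd.DataFrame) -> float:
    """Microvessel density: mean CD31+ vessel count per high-power field."""
    if counts.empty or "vessels" not in counts.columns:
        raise ValueError("counts table needs a 'vessels' column with >= 1 HPF")
    return float(counts["vessels"].mean())


def ki67_index(counts: pd.DataFrame) -> float:
    """Ki-67 proliferation index.

    Per section, the Ki-67-positive count summed over its high-power fields
    divided by the summed DAPI-positive count; the index is the mean over
    sections. HPFs with zero DAPI-positive cells are excluded with a warning.
    """
    required = {"section_id", "ki67_pos", "dapi"}
    if counts.empty or not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    bad = counts["dapi"] <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} HPFs with zero DAPI cells excluded", stacklevel=2)
        counts = counts.loc[~bad]
    if counts.empty:
        raise ValueError("no HPF with DAPI-positive cells")
    per_section = counts.groupby("section_id").apply(
        lambda s: s["ki67_pos"].sum() / s["dapi"].sum(), include_groups=False
    )
    return float(per_section.mean())


@dataclass
class TTestResult:
    statistic: float
    p: float
    significance: str  # "ns", "significant" (p<0.05) or "highly significant" (p<0.01)


def ttest(a, b, welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled-variance Student's by default.

    Welch's unequal-variance variant behind ``welch=True``. Annotates
    significance at p < 0.05 and high significance at p < 0.01.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    if p < 0.01:
        label = "highly significant"
    elif p < 0.05:
        label = "significant"
    else:
        label = "ns"
    return TTestResult(statistic=float(stat), p=float(p), significance=label)
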