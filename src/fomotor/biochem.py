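"""Biochemical-assay data reduction and summary-statistics inference.

Implements the reduction chain of the ATP-synthesis luciferase assay
(baseline-subtracted slope, stepwise ATP calibration, specific activity
with first-order error propagation, expression normalization by LDAO
ATPase activity), the ACMA proton-pump quench metric, DCCD sensitivity,
and the inference used on per-mutant activity summaries: a pooled-variance
Student's t-test computed from (mean, SD, n) and an ordinary least-squares
regression of activity on mutation separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AnalysisError(ValueError):
    """Raised when an input trace or summary cannot be reduced."""


@dataclass(frozen=True)
class ActivitySummary:
    """Per-mutant replicate summary (mean, SD, n)."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise AnalysisError("sd must be >= 0")
        if self.n < 2:
            raise AnalysisError("n must be >= 2")


@dataclass(frozen=True)
class Measurement:
    """A value with a one-sigma uncertainty."""

    value: float
    sd: float

    def __iter__(self):
        yield self.value
        yield self.sd


@dataclass(frozen=True)
class TraceSeries:
    """Instrument time series with timestamped annotation marks."""

    time: np.ndarray            # seconds, strictly increasing
    signal: np.ndarray
    annotations: dict           # label -> time or list of times

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) != len(self.signal):
            raise AnalysisError("time and signal must be 1-d, equal length")
        if not (np.diff(t) > 0).all():
            raise AnalysisError("time must be strictly increasing")
        for lab, val in self.annotations.items():
            for x in np.atleast_1d(val):
                if not (t[0] <= x <= t[-1]):
                    raise AnalysisError(
                        f"annotation {lab!r} at {x} outside the time span")

    def window(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.time >= t0) & (self.time <= t1)
        return np.asarray(self.time)[m], np.asarray(self.signal)[m]


def _window_slope(trace: TraceSeries, t0: float, t1: float
                  ) -> tuple[float, float]:
    t, y = trace.window(t0, t1)
    if len(t) < 3:
        raise AnalysisError(f"window [{t0}, {t1}] has fewer than 3 samples")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def synthesis_slope(trace: TraceSeries, pre_s: float = 90.0,
                    post_s: float = 50.0) -> Measurement:
    """Baseline-subtracted ATP-synthesis slope of a luminescence trace.

    Least-squares slope over ``post_s`` seconds after the NADH addition
    minus the slope over ``pre_s`` seconds before it; standard errors
    combine in quadrature.
    """
    if "NADH" not in trace.annotations:
        raise AnalysisError("trace has no NADH annotation")
    t_nadh = float(np.atleast_1d(trace.annotations["NADH"])[0])
    if t_nadh - pre_s < trace.time[0] - 1e-9:
        raise AnalysisError(f"need {pre_s} s of baseline before NADH")
    if t_nadh + post_s > trace.time[-1] + 1e-9:
        raise AnalysisError(f"need {post_s} s of signal after NADH")
    pre, se_pre = _window_slope(trace, t_nadh - pre_s, t_nadh)
    post, se_post = _window_slope(trace, t_nadh, t_nadh + post_s)
    return Measurement(post - pre, math.hypot(se_pre, se_post))


def atp_calibration(trace: TraceSeries, atp_amount: float = 1.0,
                    window_s: float = 5.0) -> Measurement:
    """Luminescence increase per amount of ATP from four stepwise additions.

    Each step height is the mean signal over ``window_s`` seconds right
    after the addition minus the mean over ``window_s`` seconds right
    before it; the calibration is the mean height over the four additions
    divided by the ATP amount, with the SD over the four.
    """
    if "ATP" not in trace.annotations:
        raise AnalysisError("trace has no ATP annotations")
    times = np.atleast_1d(trace.annotations["ATP"]).astype(float)
    if len(times) != 4:
        raise AnalysisError("expected exactly 4 ATP additions")
    if atp_amount <= 0:
        raise AnalysisError("atp_amount must be positive")
    heights = []
    t = np.asarray(trace.time)
    y = np.asarray(trace.signal)
    for ta in times:
        # the addition takes effect just after ta: ta belongs to "before"
        y_pre = y[(t > ta - window_s) & (t <= ta)]
        y_post = y[(t > ta) & (t <= ta + window_s)]
        if len(y_pre) < 2 or len(y_post) < 2:
            raise AnalysisError(
                f"missing {window_s}-s windows around ATP addition at {ta}")
        heights.append(float(np.mean(y_post) - np.mean(y_pre)))
    heights = np.asarray(heights) / atp_amount
    return Measurement(float(heights.mean()), float(heights.std(ddof=1)))


def propagate_ratio_error(a: float, sa: float, b: float, sb: float
                          ) -> Measurement:
    """First-order (independent) uncertainty of the ratio a/b."""
    if b == 0:
        raise AnalysisError("denominator must be nonzero")
    r = a / b
    if a == 0:
        s = math.hypot(sa / b, 0.0)
    else:
        s = abs(r) * math.hypot(sa / a, sb / b)
    return Measurement(r, abs(s))


def propagate_product_error(a: float, sa: float, b: float, sb: float
                            ) -> Measurement:
    """First-order (independent) uncertainty of the product a*b."""
    p = a * b
    s = math.hypot(b * sa, a * sb)
    return Measurement(p, abs(s))


def specific_activity(slope: Measurement, calibration: Measurement,
                      protein_mg: float) -> Measurement:
    """ATP synthesis activity, amount per minute per mg protein.

    Baseline-subtracted slope divided by (luminescence per ATP amount) and
    by membrane protein mass, uncertainties propagated to first order.
    """
    if calibration.value <= 0:
        raise AnalysisError("calibration must be positive")
    if protein_mg <= 0:
        raise AnalysisError("protein mass must be positive")
    per_atp = propagate_ratio_error(slope.value, slope.sd,
                                    calibration.value, calibration.sd)
    return Measurement(per_atp.value / protein_mg, per_atp.sd / protein_mg)


def expression_normalize(activities: dict[str, Measurement],
                         ldao_activities: dict[str, Measurement],
                         reference_labels: tuple = ("e", "ef", "eg", "eh")
                         ) -> dict[str, Measurement]:
    """Rescale activities to a common ATP-synthase expression level.

    Each mutant's synthesis activity is divided by its LDAO-activated
    ATPase activity (proportional to the amount of enzyme) and multiplied
    by the mean LDAO activity of the reference mutants.
    """
    missing = [l for l in reference_labels if l not in ldao_activities]
    if missing:
        raise AnalysisError(f"missing LDAO values for {missing}")
    ref = [ldao_activities[l] for l in reference_labels]
    ref_mean = float(np.mean([m.value for m in ref]))
    ref_sd = float(np.sqrt(np.sum([m.sd ** 2 for m in ref])) / len(ref))
    out = {}
    for lab, act in activities.items():
        ldao = ldao_activities[lab]
        if ldao.value == 0:
            raise AnalysisError(f"zero LDAO activity for {lab!r}")
        ratio = propagate_ratio_error(act.value, act.sd, ldao.value, ldao.sd)
        out[lab] = propagate_product_error(ratio.value, ratio.sd,
                                           ref_mean, ref_sd)
    return out


def acma_quench(trace: TraceSeries, at_s: float = 180.0,
                plateau_window_s: float = 30.0) -> float:
    """ACMA fluorescence quench (%) as the proton-pump activity metric.

    100 * (F_postFCCP - F(t_ATP + at_s)) / F_postFCCP, where the post-FCCP
    plateau is the mean of the final ``plateau_window_s`` seconds.
    """
    for lab in ("ATP", "FCCP"):
        if lab not in trace.annotations:
            raise AnalysisError(f"trace has no {lab} annotation")
    t_atp = float(np.atleast_1d(trace.annotations["ATP"])[0])
    t_fccp = float(np.atleast_1d(trace.annotations["FCCP"])[0])
    t_q = t_atp + at_s
    if t_q > trace.time[-1] or t_q > t_fccp:
        raise AnalysisError("quench readout time not available before FCCP")
    f_q = float(np.interp(t_q, trace.time, trace.signal))
    t_p, y_p = trace.window(trace.time[-1] - plateau_window_s, trace.time[-1])
    if len(y_p) == 0 or t_p[0] < t_fccp:
        raise AnalysisError("post-FCCP plateau window not available")
    plateau = float(np.mean(y_p))
    if plateau == 0:
        raise AnalysisError("zero post-FCCP plateau")
    return 100.0 * (plateau - f_q) / plateau


def dccd_sensitivity(activity_minus: float, activity_plus: float) -> float:
    """DCCD-sensitive fraction of ATPase activity: 1 - (+DCCD)/(-DCCD)."""
    if activity_minus <= 0:
        raise AnalysisError("-DCCD activity must be positive")
    return 1.0 - activity_plus / activity_minus


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def pooled_t_test(summary1: ActivitySummary, summary2: ActivitySummary
                  ) -> TTestResult:
    """Two-sample Student's t-test with pooled variance from summaries.

    Uses the unbiased variance estimates implied by the printed SDs;
    df = n1 + n2 - 2; two-sided p.
    """
    s1, s2 = summary1, summary2
    df = s1.n + s2.n - 2
    pooled_var = ((s1.n - 1) * s1.sd ** 2 + (s2.n - 1) * s2.sd ** 2) / df
    if pooled_var == 0:
        if s1.mean == s2.mean:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.inf if s1.mean > s2.mean else -math.inf,
                           df, 0.0, degenerate=True)
    t, p = stats.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=True)
    return TTestResult(float(t), df, float(p))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p: float
    degenerate: bool = False


def distance_regression(points) -> RegressionResult:
    """OLS of activity on mutation separation; two-sided p for slope != 0.

    ``points`` is a sequence of (separation, activity) pairs; pass
    replicate-level pairs when available, per-mutant means otherwise.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise AnalysisError("points must be (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise AnalysisError("need at least 3 distinct separations")
    if np.allclose(y, y[0]):
        return RegressionResult(0.0, float(y[0]), 1.0)
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    degenerate = bool(np.allclose(resid, 0.0))
    p = 0.0 if degenerate else float(res.pvalue)
    return RegressionResult(float(res.slope), float(res.intercept), p,
                            degenerate)


def summary_table_t_tests(summaries: dict[str, ActivitySummary]
                          ) -> pd.DataFrame:
    """All pairwise pooled t-tests of a set of activity summaries."""
    labels = list(summaries)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = pooled_t_test(summaries[a], summaries[b])
            rows.append((a, b, res.t, res.df, res.p))
    return pd.DataFrame(rows, columns=["label1", "label2", "t", "df", "p"])
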