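"""Growth, dose-response and flow-cytometry quantification.

Colony-area (or OD) time series are reduced to the area under the growth
curve over a fixed horizon (composite trapezoidal rule), and each
strain's mean AUC is normalized by the mean AUC of the wild-type grown
on the same plate and medium to give a dimensionless relative fitness.
Dose-response series are summarized by fitting the two-parameter Hill
model r(c) = 1 / (1 + (c/IC50)^h) to growth normalized by the drug-free
condition, and by transforming maximum growth rates into inhibition
coefficients (0% at the drug-free rate, 100% at no growth).  Flow
cytometry events are QC-gated on forward/side scatter and scored for dye
retention above per-channel thresholds chosen to separate negative and
positive control samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GrowthCurve",
    "FitnessRecord",
    "DoseResponseFit",
    "RetentionResult",
    "auc",
    "relative_fitness",
    "max_growth_rate",
    "inhibition_coefficient",
    "fit_hill",
    "hill_response",
    "gate_flow_events",
    "rhodamine_retention",
]


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate growth trajectory (colony area or OD600 vs hours)."""

    strain: str
    medium: str
    replicate: str
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # arbitrary units >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(t) < 2:
            raise ValueError("a growth curve needs at least 2 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(t))):
            raise ValueError("times and values must be finite")


@dataclass(frozen=True)
class FitnessRecord:
    strain: str
    medium: str
    auc_mean: float  # AU*h over [0, t_max]
    relative_fitness: float  # mean AUC / mean WT AUC
    n_replicates: int
    n_wt_replicates: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    hill_h: float
    residual_sse: float
    converged: bool
    inhibition_curve: pd.DataFrame | None = None  # concentration, inhibition_pct
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RetentionResult:
    sample_id: str
    green_threshold: float
    orange_threshold: float
    percent_above_both: float
    n_events: int
    flags: tuple[str, ...] = ()


def auc(curve: GrowthCurve, t_max: float) -> float:
    """Area under the growth curve on [0, t_max], composite trapezoid.

    If ``t_max`` falls between samples the last interval is closed by
    linear interpolation; if it exceeds the last time point the curve is
    truncated there with a warning.  Exact for piecewise-linear data, so
    a linear f(t)=t on [0, 22] gives exactly 242 on any grid.
    """
    t, v = curve.times, curve.values
    if t_max <= t[0]:
        raise ValueError(f"t_max={t_max} does not cover any interval from t0={t[0]}")
    if t_max > t[-1]:
        warnings.warn(
            f"t_max={t_max} beyond last sample {t[-1]}; truncating", stacklevel=2
        )
        t_max = float(t[-1])
    keep = t <= t_max
    tt, vv = t[keep], v[keep]
    if tt[-1] < t_max:
        v_end = float(np.interp(t_max, t, v))
        tt = np.append(tt, t_max)
        vv = np.append(vv, v_end)
    if len(tt) < 2:
        raise ValueError("fewer than 2 usable points below t_max")
    return float(np.trapezoid(vv, tt))


def relative_fitness(
    strain_aucs, wt_aucs, strain: str = "", medium: str = ""
) -> FitnessRecord:
    """Mean strain AUC over mean wild-type AUC from the same plate/medium."""
    s = np.asarray(strain_aucs, dtype=float)
    w = np.asarray(wt_aucs, dtype=float)
    if len(s) == 0 or len(w) == 0:
        raise ValueError("need at least one replicate AUC for strain and WT")
    wt_mean = float(w.mean())
    flags: tuple[str, ...] = ()
    if wt_mean == 0:
        rel = math.nan
        flags = ("wt-mean-zero",)
    else:
        rel = float(s.mean() / wt_mean)
    return FitnessRecord(
        strain=strain,
        medium=medium,
        auc_mean=float(s.mean()),
        relative_fitness=rel,
        n_replicates=len(s),
        n_wt_replicates=len(w),
        flags=flags,
    )


def max_growth_rate(
    curve: GrowthCurve, window_points: int = 5, detection_floor: float = 1e-6
) -> float:
    """Maximum specific growth rate (per hour) by sliding log-linear fit.

    The slope of ln(value) vs time is estimated by least squares in every
    contiguous window of ``window_points`` samples; the maximum slope is
    returned.  Non-positive values are lifted to ``detection_floor``
    (with a warning), which mimics a detection limit.
    """
    t, v = curve.times, curve.values
    if len(t) < window_points:
        raise ValueError(f"need at least {window_points} samples, got {len(t)}")
    if np.any(v <= 0):
        warnings.warn("non-positive values offset to detection floor", stacklevel=2)
        v = np.maximum(v, detection_floor)
    logv = np.log(v)
    best = -math.inf
    for i in range(len(t) - window_points + 1):
        tw = t[i : i + window_points]
        yw = logv[i : i + window_points]
        tc = tw - tw.mean()
        denom = float((tc**2).sum())
        slope = float((tc * (yw - yw.mean())).sum()) / denom
        best = max(best, slope)
    return best


def inhibition_coefficient(
    rate_c: float, rate_0: float, clip_at_zero: bool = False
) -> float:
    """Percent growth inhibition: 100 * (1 - rate_c / rate_0).

    0% corresponds to the maximum growth rate measured without drug;
    stimulation shows as a negative coefficient unless ``clip_at_zero``.
    """
    if rate_0 <= 0:
        raise ValueError("rate_0 must be positive (no drug-free growth)")
    coef = 100.0 * (1.0 - rate_c / rate_0)
    return max(coef, 0.0) if clip_at_zero else coef


def hill_response(c, ic50: float, h: float):
    """Two-parameter Hill decay: r(c) = 1 / (1 + (c/ic50)^h), r(0) = 1."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        return 1.0 / (1.0 + np.power(np.where(c > 0, c / ic50, 0.0), h))


def fit_hill(concentrations, normalized_responses) -> DoseResponseFit:
    """Least-squares Hill fit of drug-free-normalized responses.

    Responses must be normalized so the zero-concentration response is 1;
    only c > 0 points enter the fit.  Parameters are optimized on a log
    scale to enforce positivity.  IC50 is initialized at the geometric
    mean of the concentrations bracketing r = 0.5 (falling back to the
    geometric mean of all c > 0), h at 1.  Non-convergence is reported in
    the result flags, not raised.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(normalized_responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if len(np.unique(c)) < 4 or 0.0 not in c:
        raise ValueError("need >= 4 distinct concentrations including 0")
    pos = c > 0
    cp, rp = c[pos], r[pos]
    order = np.argsort(cp)
    cs, rs = cp[order], rp[order]

    # bracket r = 0.5 on the (mean-per-concentration) response profile
    prof = pd.Series(rs).groupby(cs).mean()
    below = prof[prof < 0.5]
    above = prof[prof >= 0.5]
    if len(below) and len(above):
        ic50_0 = math.sqrt(above.index.max() * below.index.min())
    else:
        ic50_0 = math.exp(float(np.mean(np.log(cs))))

    def resid(theta):
        ic50, h = np.exp(theta)
        return hill_response(cp, ic50, h) - rp

    sol = least_squares(resid, x0=[math.log(ic50_0), 0.0], method="lm")
    ic50, h = (float(x) for x in np.exp(sol.x))
    sse = float((sol.fun**2).sum())
    flags = () if sol.success else ("non-convergence",)
    curve = pd.DataFrame(
        {
            "concentration": np.unique(c),
            "inhibition_pct": 100.0 * (1.0 - hill_response(np.unique(c), ic50, h)),
        }
    )
    return DoseResponseFit(
        ic50=ic50,
        hill_h=h,
        residual_sse=sse,
        converged=sol.success,
        inhibition_curve=curve,
        flags=flags,
    )


def gate_flow_events(
    events: pd.DataFrame, fsc_min: float = 2000.0, ssc_min: float = 300.0
) -> pd.DataFrame:
    """QC gate: drop events with FSC below ``fsc_min`` or SSC below ``ssc_min``.

    The comparisons are strict ("below"), so events exactly at the bound
    are kept.  FSC-normalized fluorescence columns (``green_norm``,
    ``orange_norm``) are (re)computed on the survivors.
    """
    kept = events[(events["fsc"] >= fsc_min) & (events["ssc"] >= ssc_min)].copy()
    if len(kept) == 0:
        warnings.warn("no events survive the FSC/SSC gate", stacklevel=2)
        return kept
    for chan in ("green", "orange"):
        if chan in kept.columns:
            kept[f"{chan}_norm"] = kept[chan] / kept["fsc"]
    return kept


def _youden_threshold(neg: np.ndarray, pos: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing (frac neg below) + (frac pos above).

    Candidates are the unique pooled control values plus midpoints
    between consecutive ones; ties go to the larger threshold
    (conservative: fewer events called retention-high).
    """
    pooled = np.unique(np.concatenate([neg, pos]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if len(pooled) > 1 else np.array([])
    candidates = np.unique(np.concatenate([pooled, mids]))
    best_j, best_t = -math.inf, candidates[0]
    for t in candidates:
        j = float((neg < t).mean()) + float((pos >= t).mean())
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return best_t, best_j


def rhodamine_retention(
    samples: dict[str, pd.DataFrame],
    negative_control_events: pd.DataFrame,
    positive_control_events: pd.DataFrame,
    fsc_min: float = 2000.0,
    ssc_min: float = 300.0,
) -> list[RetentionResult]:
    """Score dye retention per sample against control-derived thresholds.

    All event tables are QC-gated and FSC-normalized first.  For each
    fluorescence channel a threshold is chosen on the normalized values
    to jointly maximize the fraction of untreated-control events below it
    and efflux-null-control events above it (Youden-style).  Each sample
    is reported as the percentage of its events above BOTH thresholds —
    high retention means low efflux capacity.
    """
    neg = gate_flow_events(negative_control_events, fsc_min, ssc_min)
    pos = gate_flow_events(positive_control_events, fsc_min, ssc_min)
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("control samples are empty after QC gating")
    thresholds = {}
    separations = {}
    for chan in ("green_norm", "orange_norm"):
        t, j = _youden_threshold(neg[chan].to_numpy(), pos[chan].to_numpy())
        thresholds[chan] = t
        separations[chan] = j
    low_sep = tuple(
        f"low-separation-{c}" for c, j in separations.items() if j < 1.5
    )
    results = []
    for sample_id, ev in samples.items():
        gated = gate_flow_events(ev, fsc_min, ssc_min)
        if len(gated) == 0:
            results.append(
                RetentionResult(
                    sample_id,
                    thresholds["green_norm"],
                    thresholds["orange_norm"],
                    math.nan,
                    0,
                    flags=low_sep + ("no-events",),
                )
            )
            continue
        above = (
            (gated["green_norm"] >= thresholds["green_norm"])
            & (gated["orange_norm"] >= thresholds["orange_norm"])
        ).mean()
        results.append(
            RetentionResult(
                sample_id,
                thresholds["green_norm"],
                thresholds["orange_norm"],
                100.0 * float(above),
                len(gated),
                flags=low_sep,
            )
        )
    return results
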