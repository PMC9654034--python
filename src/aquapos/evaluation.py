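"""Accuracy evaluation against a reference GPS track.

A towed transmitter with an onboard handheld GPS gives ground truth that
is *not* time-synchronized with the tag, so a solved fix must first be
matched to a reference sample.  Three matching rules are provided:

* space: nearest reference point in space among those within a time
  window (default 30 s) — most accurate spatially, largest time offsets;
* time: nearest reference point in time — smallest time offsets, worst
  spatial errors;
* spacetime: minimizes sqrt(dd^2 + dt^2) with configurable meter/second
  weights — the compromise used for headline numbers.

On matched pairs the module reports mean/SD/median spatial error overall
and split inside/outside the receiver mesh (convex hull of the array),
plus the reconstruction-rate curve: the reference path is interpolated
to high resolution, cut into fixed segments (21 s for a 3 s pinger, i.e.
7 expected emissions per segment), and the fraction of expected
positions actually solved is related to the distance from the segment
midpoint to the farthest receiver.  A linear regression of that curve
estimates the distance at which the rate drops to one third.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from scipy.stats import linregress, t as t_dist

from .simulator import Receiver
from .tdoa import PositionFix


class EvalDomainError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceTrack:
    """Strictly time-ordered ground-truth positions in the local frame."""

    times: np.ndarray       # seconds
    xy: np.ndarray          # (n, 2) meters
    stated_accuracy_m: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.xy):
            raise EvalDomainError("times and positions must align")
        if len(self.times) == 0:
            raise EvalDomainError("reference track is empty")
        if np.any(np.diff(self.times) <= 0):
            raise EvalDomainError("reference times must be strictly increasing")


def _fixes_to_arrays(fixes: Sequence[PositionFix] | pd.DataFrame):
    if isinstance(fixes, pd.DataFrame):
        return fixes["time"].to_numpy(float), fixes[["x", "y"]].to_numpy(float)
    t = np.array([f.solve_time for f in fixes], dtype=float)
    xy = np.array([[f.position.x, f.position.y] for f in fixes], dtype=float)
    return t, xy


def _match_frame(t_fix, xy_fix, ref, idx, matched_mask):
    n = len(t_fix)
    out = pd.DataFrame(
        {
            "fix_time": t_fix,
            "fix_x": xy_fix[:, 0],
            "fix_y": xy_fix[:, 1],
            "matched": matched_mask,
            "ref_index": idx,
            "ref_time": np.nan,
            "ref_x": np.nan,
            "ref_y": np.nan,
            "spatial_error": np.nan,
            "time_difference": np.nan,
        }
    )
    m = matched_mask
    sel = idx[m]
    out.loc[m, "ref_time"] = ref.times[sel]
    out.loc[m, "ref_x"] = ref.xy[sel, 0]
    out.loc[m, "ref_y"] = ref.xy[sel, 1]
    out.loc[m, "spatial_error"] = np.linalg.norm(
        xy_fix[m] - ref.xy[sel], axis=1
    )
    out.loc[m, "time_difference"] = np.abs(t_fix[m] - ref.times[sel])
    return out


def match_space(
    fixes, ref: ReferenceTrack, window: float = 30.0
) -> pd.DataFrame:
    """Nearest-in-space match among reference samples within the window.

    Fixes with no reference sample within ``window`` seconds are left
    unmatched (``matched`` False) and excluded from reports.
    """
    t_fix, xy_fix = _fixes_to_arrays(fixes)
    idx = np.zeros(len(t_fix), dtype=int)
    ok = np.zeros(len(t_fix), dtype=bool)
    for i, (tf, pf) in enumerate(zip(t_fix, xy_fix)):
        cand = np.flatnonzero(np.abs(ref.times - tf) <= window)
        if len(cand) == 0:
            continue
        d = np.linalg.norm(ref.xy[cand] - pf, axis=1)
        idx[i] = cand[np.argmin(d)]
        ok[i] = True
    return _match_frame(t_fix, xy_fix, ref, idx, ok)


def match_time(fixes, ref: ReferenceTrack) -> pd.DataFrame:
    """Nearest-in-time match; ties go to the earlier reference sample."""
    t_fix, xy_fix = _fixes_to_arrays(fixes)
    dt = np.abs(ref.times[None, :] - t_fix[:, None])
    idx = np.argmin(dt, axis=1)  # argmin takes the first (earlier) on ties
    ok = np.ones(len(t_fix), dtype=bool)
    return _match_frame(t_fix, xy_fix, ref, idx, ok)


def match_spacetime(
    fixes,
    ref: ReferenceTrack,
    space_weight: float = 1.0,
    time_weight: float = 1.0,
) -> pd.DataFrame:
    """Match minimizing sqrt((w_d * dd)^2 + (w_t * dt)^2), dd in meters
    and dt in seconds (unit weights by default)."""
    t_fix, xy_fix = _fixes_to_arrays(fixes)
    idx = np.zeros(len(t_fix), dtype=int)
    for i, (tf, pf) in enumerate(zip(t_fix, xy_fix)):
        dd = np.linalg.norm(ref.xy - pf, axis=1)
        dt = np.abs(ref.times - tf)
        idx[i] = int(np.argmin((space_weight * dd) ** 2 + (time_weight * dt) ** 2))
    ok = np.ones(len(t_fix), dtype=bool)
    return _match_frame(t_fix, xy_fix, ref, idx, ok)


MATCHERS = {
    "space": match_space,
    "time": match_time,
    "spacetime": match_spacetime,
}


def receiver_hull(receivers: Sequence[Receiver]) -> Delaunay:
    pts = np.array([[r.position.x, r.position.y] for r in receivers])
    if len(pts) < 3:
        raise EvalDomainError("mesh membership needs at least 3 receivers")
    return Delaunay(pts[ConvexHull(pts).vertices])


def inside_mesh(xy: np.ndarray, receivers: Sequence[Receiver]) -> np.ndarray:
    """True where a point lies in the convex hull of the receivers
    (boundary counts as inside)."""
    hull = receiver_hull(receivers)
    return hull.find_simplex(np.atleast_2d(xy)) >= 0


@dataclass(frozen=True)
class AccuracyReport:
    split: str
    n: int
    mean_error_m: float
    sd_error_m: float
    median_error_m: float
    mean_time_difference_s: float

    @staticmethod
    def from_errors(split: str, err: np.ndarray, tdiff: np.ndarray) -> "AccuracyReport":
        if len(err) == 0:
            return AccuracyReport(split, 0, float("nan"), float("nan"),
                                  float("nan"), float("nan"))
        sd = float(np.std(err, ddof=1)) if len(err) > 1 else 0.0
        return AccuracyReport(
            split, len(err), float(np.mean(err)), sd,
            float(np.median(err)), float(np.mean(tdiff)),
        )


def accuracy_report(
    matches: pd.DataFrame, receivers: Sequence[Receiver]
) -> dict[str, AccuracyReport]:
    """Mean/SD/median spatial error overall and inside/outside the mesh.

    Only matched fixes enter the statistics; the unmatched count is
    reported under the "unmatched" key of the returned dict.
    """
    m = matches[matches["matched"]]
    if m.empty:
        raise EvalDomainError("no matched fixes to report on")
    xy = m[["fix_x", "fix_y"]].to_numpy(float)
    inside = inside_mesh(xy, receivers)
    err = m["spatial_error"].to_numpy(float)
    tdiff = m["time_difference"].to_numpy(float)
    reports = {
        "overall": AccuracyReport.from_errors("overall", err, tdiff),
        "inside": AccuracyReport.from_errors("inside", err[inside], tdiff[inside]),
        "outside": AccuracyReport.from_errors("outside", err[~inside], tdiff[~inside]),
    }
    reports["unmatched"] = int((~matches["matched"]).sum())
    return reports


def interpolate_track(ref: ReferenceTrack, step: float = 1.0) -> ReferenceTrack:
    """Linear time-interpolation of the reference path at a fixed step."""
    if step <= 0:
        raise EvalDomainError("interpolation step must be positive")
    t = np.arange(ref.times[0], ref.times[-1] + 1e-9, step)
    x = np.interp(t, ref.times, ref.xy[:, 0])
    y = np.interp(t, ref.times, ref.xy[:, 1])
    return ReferenceTrack(t, np.column_stack([x, y]), ref.stated_accuracy_m)


def reconstruction_rate(
    fixes,
    ref: ReferenceTrack,
    receivers: Sequence[Receiver],
    period: float = 3.0,
    segment: float = 21.0,
    interp_step: float = 1.0,
) -> pd.DataFrame:
    """Reconstruction-rate curve over fixed time segments.

    Each full ``segment``-second window expects segment/period emissions
    (7 for the 21 s / 3 s defaults); the observed count is the number of
    solved fixes whose times fall in the window.  Each segment is placed
    at the distance from its midpoint path position to the receiver
    farthest from it.  Returns columns segment_start, distance, expected,
    observed, rate.
    """
    if abs(segment / period - round(segment / period)) > 1e-9:
        raise EvalDomainError("segment length must be a multiple of the period")
    hi = interpolate_track(ref, interp_step)
    t_fix, _ = _fixes_to_arrays(fixes)
    expected = int(round(segment / period))
    rpos = np.array([[r.position.x, r.position.y] for r in receivers])
    rows = []
    start = ref.times[0]
    while start + segment <= ref.times[-1] + 1e-9:
        mid = start + segment / 2.0
        j = int(np.argmin(np.abs(hi.times - mid)))
        midpoint = hi.xy[j]
        distance = float(np.max(np.linalg.norm(rpos - midpoint, axis=1)))
        observed = int(np.sum((t_fix >= start) & (t_fix < start + segment)))
        rows.append(
            {
                "segment_start": start,
                "distance": distance,
                "expected": expected,
                "observed": observed,
                "rate": observed / expected,
            }
        )
        start += segment
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    distance_m: float
    slope: float
    intercept: float
    slope_stderr: float
    ci_low_m: float
    ci_high_m: float
    crossed: bool


def threshold_distance(
    curve: pd.DataFrame,
    threshold: float = 1.0 / 3.0,
    fit_range: tuple[float, float] | None = None,
    confidence: float = 0.95,
) -> ThresholdResult:
    """Distance at which an OLS fit of rate on distance hits the threshold.

    Regresses rate on distance over ``fit_range`` (default: the full
    observed range) and solves fitted(d) == threshold.  A non-negative
    slope means the line never crosses going down; the result is then
    flagged (``crossed`` False) with NaN distance.  The confidence
    interval comes from the delta method on (slope, intercept).
    """
    sub = curve
    if fit_range is not None:
        sub = curve[(curve["distance"] >= fit_range[0])
                    & (curve["distance"] <= fit_range[1])]
    if len(sub) < 2:
        raise EvalDomainError("need at least two curve points in the fit range")
    d = sub["distance"].to_numpy(float)
    r = sub["rate"].to_numpy(float)
    fit = linregress(d, r)
    if fit.slope >= 0:
        return ThresholdResult(float("nan"), fit.slope, fit.intercept,
                               fit.stderr, float("nan"), float("nan"), False)
    x_star = (threshold - fit.intercept) / fit.slope
    # delta method: var(x*) from the OLS covariance of (intercept, slope)
    n = len(d)
    resid = r - (fit.intercept + fit.slope * d)
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((d - d.mean()) ** 2))
    var_b = s2 / sxx
    var_a = s2 * (1.0 / n + d.mean() ** 2 / sxx)
    cov_ab = -s2 * d.mean() / sxx
    g = np.array([-1.0 / fit.slope, -x_star / fit.slope])  # d x*/d(a, b)
    var_x = float(g @ np.array([[var_a, cov_ab], [cov_ab, var_b]]) @ g)
    half = t_dist.ppf(0.5 + confidence / 2.0, dof) * np.sqrt(max(var_x, 0.0))
    return ThresholdResult(
        float(x_star), fit.slope, fit.intercept, fit.stderr,
        float(x_star - half), float(x_star + half), True,
    )
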