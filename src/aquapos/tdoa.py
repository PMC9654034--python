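"""Emission grouping and time-difference-of-arrival multilateration.

Synchronized receivers timestamp the arrivals of a tag's acoustic signal.
For a pair of receivers the arrival-time difference Δt fixes the range
difference Δd = c·Δt, which constrains the source to one branch of a
hyperbola (2D) or hyperboloid (3D); with three receivers a 2D position is
determined, with four a 3D one.  This module clusters raw detections into
per-emission groups and solves the resulting nonlinear least-squares
problem by damped Gauss-Newton (Levenberg) iteration with an analytic
Jacobian.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geo import LocalPoint
from .simulator import Receiver


class TdoaError(ValueError):
    pass


class InsufficientReceivers(TdoaError):
    pass


class DegenerateArray(TdoaError):
    pass


@dataclass(frozen=True)
class MediumModel:
    """Propagation medium: a single constant sound speed (m/s)."""

    sound_speed: float = 1500.0

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise TdoaError("sound speed must be positive")


@dataclass(frozen=True)
class Detection:
    """One time-stamped arrival of a tag's signal at one receiver."""

    receiver_id: str
    tag_id: str
    arrival_time: float
    receiver_position: LocalPoint

    def __post_init__(self) -> None:
        if not math.isfinite(self.arrival_time):
            raise TdoaError("arrival time must be finite")


@dataclass(frozen=True)
class EmissionGroup:
    """Detections of a single emission: one per receiver, earliest first."""

    tag_id: str
    detections: tuple[Detection, ...]

    def __post_init__(self) -> None:
        if len(self.detections) < 2:
            raise TdoaError("a group needs at least two detections")
        ids = [d.receiver_id for d in self.detections]
        if len(set(ids)) != len(ids):
            raise TdoaError("at most one detection per receiver")

    @property
    def reference(self) -> Detection:
        return min(self.detections, key=lambda d: (d.arrival_time, d.receiver_id))

    @property
    def n_receivers(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class PositionFix:
    """A solved tag position with residual diagnostics."""

    tag_id: str
    solve_time: float
    position: LocalPoint
    n_receivers: int
    residual_rms_m: float
    converged: bool


def max_baseline(receivers: Sequence[Receiver]) -> float:
    """Largest pairwise receiver distance (meters)."""
    if len(receivers) < 2:
        return 0.0
    return max(
        float(np.linalg.norm(a.position.as_array() - b.position.as_array()))
        for a, b in itertools.combinations(receivers, 2)
    )


def group_detections(
    detections: pd.DataFrame,
    receivers: Sequence[Receiver],
    c: float = 1500.0,
    guard: float = 0.05,
) -> tuple[list[EmissionGroup], pd.DataFrame]:
    """Cluster raw detections into per-emission groups, greedily.

    Working per tag in arrival order (ties broken by receiver id), a group
    opens at the earliest unconsumed detection and absorbs subsequent
    detections from receivers not yet in the group while they arrive
    within max_baseline/c + guard of the opener — the longest physically
    possible arrival spread for one emission plus a timing margin.  A
    repeat of a receiver already in the window opens the next group.
    Groups of fewer than two detections are returned unassigned.
    """
    if c <= 0:
        raise TdoaError("sound speed must be positive")
    recv_pos = {r.receiver_id: r.position for r in receivers}
    window = max_baseline(receivers) / c + guard
    groups: list[EmissionGroup] = []
    leftovers: list[dict] = []
    for tag_id, sub in detections.groupby("tag_id", sort=True):
        rows = sub.sort_values(
            ["arrival_time", "receiver_id"], kind="stable"
        ).to_dict("records")
        i = 0
        while i < len(rows):
            start = rows[i]["arrival_time"]
            members = [rows[i]]
            used = {rows[i]["receiver_id"]}
            j = i + 1
            while j < len(rows) and rows[j]["arrival_time"] - start <= window:
                if rows[j]["receiver_id"] in used:
                    break
                members.append(rows[j])
                used.add(rows[j]["receiver_id"])
                j += 1
            if len(members) >= 2:
                groups.append(
                    EmissionGroup(
                        tag_id=str(tag_id),
                        detections=tuple(
                            Detection(
                                receiver_id=m["receiver_id"],
                                tag_id=str(tag_id),
                                arrival_time=float(m["arrival_time"]),
                                receiver_position=recv_pos[m["receiver_id"]],
                            )
                            for m in members
                        ),
                    )
                )
            else:
                leftovers.extend(members)
            i += len(members)
    unassigned = (
        pd.DataFrame(leftovers)
        if leftovers
        else detections.iloc[0:0].copy()
    )
    return groups, unassigned


def tdoa_deltas(group: EmissionGroup, c: float) -> pd.DataFrame:
    """Per-pair (Δt, Δd) against the reference (earliest) receiver.

    Δd = c·Δt; the reference paired with itself gives zero.
    """
    if c <= 0:
        raise TdoaError("sound speed must be positive")
    ref = group.reference
    rows = [
        {
            "receiver_id": d.receiver_id,
            "reference_id": ref.receiver_id,
            "delta_t": d.arrival_time - ref.arrival_time,
            "delta_d": c * (d.arrival_time - ref.arrival_time),
        }
        for d in group.detections
    ]
    return pd.DataFrame(rows)


def _pair_arrays(group: EmissionGroup):
    ref = group.reference
    others = [d for d in group.detections if d.receiver_id != ref.receiver_id]
    pos = np.array([d.receiver_position.as_array() for d in others])
    dts = np.array([d.arrival_time - ref.arrival_time for d in others])
    return ref.receiver_position.as_array(), pos, dts


def _residuals_and_jacobian(
    x: np.ndarray, ref_pos: np.ndarray, other_pos: np.ndarray, delta_d: np.ndarray,
    free: np.ndarray,
):
    """Residuals r_i = (|x-p_i| - |x-p_ref|) - Δd_i and d r / d x[free]."""
    diff_i = x[None, :] - other_pos
    diff_r = x - ref_pos
    dist_i = np.linalg.norm(diff_i, axis=1)
    dist_r = np.linalg.norm(diff_r)
    r = (dist_i - dist_r) - delta_d
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = diff_i / dist_i[:, None] - (diff_r / dist_r)[None, :]
    grad = np.nan_to_num(grad)
    return r, grad[:, free]


def _levenberg_solve(
    x0: np.ndarray,
    ref_pos: np.ndarray,
    other_pos: np.ndarray,
    delta_d: np.ndarray,
    free: np.ndarray,
    max_iter: int = 100,
    step_tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    x = x0.copy()
    lam = 1e-3
    r, J = _residuals_and_jacobian(x, ref_pos, other_pos, delta_d, free)
    cost = float(r @ r)
    converged = False
    for _ in range(max_iter):
        if cost < 1e-24:
            converged = True
            break
        A = J.T @ J
        g = J.T @ r
        if np.max(np.abs(g)) < 1e-14:  # stationary point
            converged = True
            break
        try:
            step = np.linalg.solve(A + lam * np.eye(A.shape[0]), -g)
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        x_new = x.copy()
        x_new[free] = x[free] + step
        r_new, J_new = _residuals_and_jacobian(
            x_new, ref_pos, other_pos, delta_d, free
        )
        cost_new = float(r_new @ r_new)
        if cost_new < cost:
            x, r, J, cost = x_new, r_new, J_new, cost_new
            lam = max(lam / 10.0, 1e-12)
            if np.linalg.norm(step) < step_tol:
                converged = True
                break
        else:
            lam *= 10.0
            if lam > 1e12:
                break
    return x, cost, converged


def _check_geometry(points: np.ndarray, mode: str) -> None:
    centered = points - points.mean(axis=0)
    if mode == "2D":
        rank = np.linalg.matrix_rank(centered[:, :2], tol=1e-6)
        if rank < 2:
            raise DegenerateArray("receivers are collinear; 2D solve is degenerate")
    else:
        rank = np.linalg.matrix_rank(centered, tol=1e-6)
        if rank < 3:
            raise DegenerateArray("receivers are coplanar; 3D solve is degenerate")


def solve_position(
    group: EmissionGroup,
    medium: MediumModel = MediumModel(),
    mode: Literal["2D", "3D"] = "2D",
    assumed_depth: float = 0.0,
) -> PositionFix:
    """Solve one emission group for the tag position.

    Minimises the sum over receiver pairs of (measured Δd − predicted
    Δd(x))² by Levenberg-damped Gauss-Newton from the receiver centroid,
    restarting from each receiver position if needed.  2D mode fixes the
    depth at ``assumed_depth``.
    """
    need = 3 if mode == "2D" else 4
    if group.n_receivers < need:
        raise InsufficientReceivers(
            f"{mode} positioning needs >= {need} receivers, got {group.n_receivers}"
        )
    ref_pos, other_pos, dts = _pair_arrays(group)
    all_pos = np.vstack([ref_pos[None, :], other_pos])
    _check_geometry(all_pos, mode)
    delta_d = medium.sound_speed * dts
    free = np.array([True, True, mode == "3D"])
    centroid = all_pos.mean(axis=0)
    # receiver starts are pulled slightly toward the centroid so no start
    # sits exactly on a receiver (where the Jacobian is singular)
    starts = [centroid] + [0.9 * p + 0.1 * centroid for p in all_pos]
    candidates = []
    for s in starts:
        x0 = s.astype(float).copy()
        if mode == "2D":
            x0[2] = assumed_depth
        candidates.append(
            _levenberg_solve(x0, ref_pos, other_pos, delta_d, free)
        )
    best_cost = min(c[1] for c in candidates)
    # With the minimal receiver count the hyperbolae can intersect twice,
    # leaving two zero-residual solutions; among near-ties prefer the one
    # nearest the array centroid (the ghost branch lies far outside).
    ties = [c for c in candidates if c[1] <= best_cost + 1e-9]
    x, cost, ok = min(ties, key=lambda c: np.linalg.norm(c[0] - centroid))
    n_pairs = len(delta_d)
    n_pairs = len(delta_d)
    rms = math.sqrt(cost / n_pairs) if n_pairs else 0.0
    return PositionFix(
        tag_id=group.tag_id,
        solve_time=group.reference.arrival_time,
        position=LocalPoint(float(x[0]), float(x[1]), float(x[2])),
        n_receivers=group.n_receivers,
        residual_rms_m=rms,
        converged=bool(ok),
    )


def residual_rms(fix: PositionFix, group: EmissionGroup, medium: MediumModel) -> float:
    """RMS over pairs of (measured Δd − predicted Δd at the fix position)."""
    ref_pos, other_pos, dts = _pair_arrays(group)
    delta_d = medium.sound_speed * dts
    x = fix.position.as_array()
    pred = np.linalg.norm(x - other_pos, axis=1) - np.linalg.norm(x - ref_pos)
    r = pred - delta_d
    return float(np.sqrt(np.mean(r**2))) if len(r) else 0.0


def solve_all(
    groups: Sequence[EmissionGroup],
    medium: MediumModel = MediumModel(),
    mode: Literal["2D", "3D"] = "2D",
    assumed_depth: float = 0.0,
    min_receivers: int | None = None,
) -> list[PositionFix]:
    """Solve every group with enough receivers; skip the rest."""
    need = min_receivers or (3 if mode == "2D" else 4)
    fixes = []
    for g in groups:
        if g.n_receivers < need:
            continue
        try:
            fixes.append(solve_position(g, medium, mode, assumed_depth))
        except DegenerateArray:
            continue
    return fixes
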