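"""Geometric classification of biaxial signature trajectories.

Pairs of pseudotime profiles fall into recurring geometric modes:

- ``switch_like`` — one program completes most of its excursion before
  the other starts (an L-shaped curve, e.g. oxphos saturating before
  proliferation ramps up);
- ``parallel_anticorrelated`` — a straight-ish anti-diagonal (one
  program's gain mirrors the other's loss, e.g. active vs poised
  promoters);
- ``divergent`` — across two branches (cultures), anti-correlated
  trajectories ending in opposite corners (the MITF/AXL antagonism);
  with a single branch this is indistinguishable from
  parallel_anticorrelated and the simpler label is used;
- ``orthogonal`` — the programs move independently: negligible
  correlation, one axis essentially unchanged while the other is active;
- ``curved`` — a bent but coupled trajectory (partial correlation with
  a direction change, e.g. glycolysis vs oxphos).

Statistics are computed on a *macro curve*: the relative-activity-scaled
smooth values averaged within rank bins along pseudotime. Bin averaging
suppresses the smoothing wiggle that would otherwise inflate the path
length of a noisy-but-straight trajectory, so the curvature index
measures macro-scale bending only. Axis orientation is judged from the
first- versus last-quarter means rather than the endpoints, because a
signature that completes early often drifts back late (gene set scores
are relative per-cell measures: a plateaued program loses score when
other programs surge).

The classifier reports four statistics — Pearson correlation r of the
macro axes, derivative cross-correlation lag, curvature index
kappa = 1 - chord/path-length, and a plateau fraction — and applies
fixed, configurable thresholds in a deterministic order. The thresholds
are this module's committed definitions of the qualitative modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import TrajectoryPair


@dataclass
class TypologyThresholds:
    """Committed cut-offs defining the qualitative trajectory modes."""

    r_anti: float = -0.8        # "anti-correlated" ceiling on Pearson r
    r_orthogonal: float = 0.3   # |r| ceiling for independence
    kappa_anti: float = 0.35    # curvature ceiling for the anti-diagonal
    kappa_curved: float = 0.1   # curvature floor for "curved"
    completion_lead: float = 0.8  # leader's completed fraction (switch)
    completion_lag: float = 0.2   # laggard's completed fraction (switch)
    near_constant: float = 0.3  # max net movement of the "constant" axis
    min_net_change: float = 0.25  # net endpoint change for switch eligibility
    plateau_speed: float = 0.2  # step-length fraction counted as plateau
    macro_bins: int = 12        # rank bins of the macro curve


@dataclass
class TypologyCall:
    """Label plus the geometric statistics it was derived from."""

    pair: tuple[str, str]
    label: str
    r: float
    lag: float
    curvature: float
    plateau_fraction: float
    leading_axis: str | None = None


def _rescale(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        raise ValueError("constant trajectory axis: rescale to relative "
                         "activity is undefined")
    return (values - lo) / (hi - lo)


def _macro(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average within rank bins along PT; identity when too few points."""
    if len(values) <= n_bins:
        return values.copy()
    return np.array([chunk.mean()
                     for chunk in np.array_split(values, n_bins)])


def _orientation(values: np.ndarray) -> int:
    """+1 rising (minimum precedes maximum along PT), else -1.

    Judging direction from the positions of the extremes instead of the
    endpoints keeps a leader that completes early and then drifts back
    (a relative-score artifact of late-surging programs) correctly
    oriented.
    """
    return 1 if int(np.argmin(values)) < int(np.argmax(values)) else -1


def _progress(values: np.ndarray, orientation: int) -> np.ndarray:
    """Completion fraction of a directed axis (values already in [0,1])."""
    return values if orientation > 0 else 1.0 - values


def _first_crossing(progress: np.ndarray, level: float) -> int:
    hits = np.flatnonzero(progress >= level)
    return int(hits[0]) if len(hits) else len(progress)


def _curvature(a: np.ndarray, b: np.ndarray) -> float:
    steps = np.hypot(np.diff(a), np.diff(b))
    path = float(steps.sum())
    if path <= 0:
        return 0.0
    chord = float(np.hypot(a[-1] - a[0], b[-1] - b[0]))
    return 1.0 - chord / path


def _plateau_fraction(a: np.ndarray, b: np.ndarray, speed_frac: float) -> float:
    steps = np.hypot(np.diff(a), np.diff(b))
    if steps.sum() <= 0:
        return 1.0
    return float(np.mean(steps < speed_frac * steps.mean()))


def _derivative_lag(a: np.ndarray, b: np.ndarray, pt: np.ndarray) -> float:
    """PT offset maximizing cross-correlation of the two derivatives."""
    da, db = np.diff(a), np.diff(b)
    n = len(da)
    if n < 3 or da.std() == 0 or db.std() == 0:
        return 0.0
    da = (da - da.mean()) / da.std()
    db = (db - db.mean()) / db.std()
    max_shift = n // 2
    best_shift, best_corr = 0, -np.inf
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            x, y = da[shift:], db[:n - shift]
        else:
            x, y = da[:n + shift], db[-shift:]
        if len(x) < 3:
            continue
        corr = float(np.mean(x * y))
        if corr > best_corr:
            best_corr, best_shift = corr, shift
    spacing = (pt[-1] - pt[0]) / max(n - 1, 1)
    return best_shift * spacing


def _corner(a_end: float, b_end: float) -> tuple[int, int]:
    return (int(round(a_end)), int(round(b_end)))


def _opposite_corners(corners: list[tuple[int, int]]) -> bool:
    for i in range(len(corners)):
        for j in range(i + 1, len(corners)):
            ci, cj = corners[i], corners[j]
            if ci[0] != cj[0] and ci[1] != cj[1]:
                return True
    return False


def _macro_axes(pair: TrajectoryPair, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    a = _rescale(_macro(np.asarray(pair.a, dtype=float), n_bins))
    b = _rescale(_macro(np.asarray(pair.b, dtype=float), n_bins))
    return a, b


def classify_trajectory(pair: TrajectoryPair,
                        branches: list[TrajectoryPair] | None = None,
                        thresholds: TypologyThresholds | None = None) -> TypologyCall:
    """Assign one of the five trajectory modes to a biaxial curve.

    Parameters
    ----------
    pair
        The trajectory to classify (smoothed curves; axes are rescaled
        to relative activity internally).
    branches
        Optional additional trajectories of the *same* signature pair
        from other datasets/branches. Divergence — anti-correlated
        branches ending in opposite corners — is only identifiable with
        multiple branches; a single anti-correlated branch collapses to
        ``parallel_anticorrelated``.
    """
    th = thresholds or TypologyThresholds()
    if len(pair.pt) < 10:
        raise ValueError("need at least 10 curve points to classify")

    a, b = _macro_axes(pair, th.macro_bins)
    pt = np.asarray(pair.pt, dtype=float)

    r = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
    kappa = _curvature(a, b)
    lag = _derivative_lag(a, b, pt[np.linspace(0, len(pt) - 1, len(a)).astype(int)])
    plateau = _plateau_fraction(a, b, th.plateau_speed)

    dir_a = _orientation(a)
    dir_b = _orientation(b)

    label: str | None = None
    leading: str | None = None

    # 1. switch_like: one axis completes its excursion before the other
    # starts. Axes that return to their starting level (humps) are not
    # eligible — a program that rises and fully falls back within the
    # window is not switching into anything.
    eligible_a = abs(a[-1] - a[0]) >= th.min_net_change
    eligible_b = abs(b[-1] - b[0]) >= th.min_net_change
    if eligible_a and eligible_b:
        prog_a = _progress(a, dir_a)
        prog_b = _progress(b, dir_b)
        a_done = _first_crossing(prog_a, th.completion_lead)
        b_started = _first_crossing(prog_b, th.completion_lag)
        b_done = _first_crossing(prog_b, th.completion_lead)
        a_started = _first_crossing(prog_a, th.completion_lag)
        if a_done <= b_started and a_done < len(a):
            label, leading = "switch_like", pair.set_a
        elif b_done <= a_started and b_done < len(b):
            label, leading = "switch_like", pair.set_b

    # 2./3. anti-correlated: parallel, or divergent across branches
    if label is None and r <= th.r_anti and kappa <= th.kappa_anti:
        label = "parallel_anticorrelated"
        if branches:
            corners = [_corner(a[-1], b[-1])]
            branch_anti = True
            for branch in branches:
                ba, bb = _macro_axes(branch, th.macro_bins)
                br = (float(np.corrcoef(ba, bb)[0, 1])
                      if ba.std() > 0 and bb.std() > 0 else 0.0)
                branch_anti &= br <= th.r_anti
                corners.append(_corner(ba[-1], bb[-1]))
            if branch_anti and _opposite_corners(corners):
                label = "divergent"

    # 4. orthogonal: negligible coupling, one axis idle while the other moves
    if label is None and abs(r) <= th.r_orthogonal:
        for moving, moving_dir, idle in ((a, dir_a, b), (b, dir_b, a)):
            prog = _progress(moving, moving_dir)
            window = (prog >= 0.1) & (prog <= 0.9)
            if window.sum() >= 2:
                idle_in_window = idle[window]
                if abs(idle_in_window[-1] - idle_in_window[0]) <= th.near_constant:
                    label = "orthogonal"
                    break

    # 5. curved: bent but none of the above
    if label is None and kappa > th.kappa_curved:
        label = "curved"

    return TypologyCall(pair=(pair.set_a, pair.set_b),
                        label=label or "unclassified",
                        r=r, lag=lag, curvature=kappa,
                        plateau_fraction=plateau, leading_axis=leading)
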