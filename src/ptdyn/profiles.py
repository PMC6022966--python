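"""Pseudotime profiles: LOESS smoothing, relative activity, biaxial curves.

Raw per-cell signature activities (GSZ) are noisy; the pseudotime
profile of a program is its LOESS smooth along PT. For comparison
across programs with different dynamic ranges, a smoothed profile is
rescaled to a *relative activity* in [0, 1] (profile minimum -> 0,
maximum -> 1). Pairing two smoothed profiles point-wise along PT gives
the biaxial trajectory of the two programs, the object classified by
:mod:`ptdyn.typology`.

The LOESS here is the classical tri-cube-weighted local polynomial
estimator: at each evaluation point the nearest ``ceil(span * n)``
observations are fitted with a degree-1 or degree-2 weighted
polynomial. Degree 2 (the default) tracks curved profiles such as a
saturating plateau without flattening them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def loess_fit(x: np.ndarray, y: np.ndarray, eval_points: np.ndarray,
              span: float = 0.5, degree: int = 2) -> np.ndarray:
    """Tri-cube weighted local polynomial regression.

    Parameters
    ----------
    x, y
        Observations (x need not be sorted).
    eval_points
        Where to evaluate the fit.
    span
        Fraction of observations in each local window, in (0, 1].
    degree
        Local polynomial degree, 1 or 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if n < max(5, degree * 3):
        raise ValueError(f"need at least {max(5, degree * 3)} observations")
    window = int(np.ceil(span * n))
    if window < degree + 2:
        raise ValueError(
            f"window of {window} points is too small for degree {degree}; "
            "increase span")

    fitted = np.empty(len(eval_points))
    for i, x0 in enumerate(np.asarray(eval_points, dtype=float)):
        dist = np.abs(x - x0)
        idx = np.argpartition(dist, window - 1)[:window]
        local_d = dist[idx]
        d_max = local_d.max()
        if d_max == 0:  # all window points coincide with x0
            fitted[i] = y[idx].mean()
            continue
        w = np.clip(1.0 - (local_d / d_max) ** 3, 0.0, None) ** 3
        if np.count_nonzero(w) <= degree:
            raise ValueError(
                "too few positively weighted points in local window; "
                "increase span")
        centered = x[idx] - x0
        design = np.vander(centered, degree + 1, increasing=True)
        sqrt_w = np.sqrt(w)
        coef, _, _, _ = np.linalg.lstsq(design * sqrt_w[:, None],
                                        y[idx] * sqrt_w, rcond=None)
        fitted[i] = coef[0]
    return fitted


@dataclass
class SignatureProfile:
    """A signature's raw and LOESS-smoothed activity along pseudotime."""

    set_name: str
    pt_sorted_cells: list[str]
    pt: np.ndarray
    raw: np.ndarray
    smooth: np.ndarray
    span: float
    degree: int

    def __post_init__(self) -> None:
        n = len(self.pt_sorted_cells)
        if not (len(self.pt) == len(self.raw) == len(self.smooth) == n):
            raise ValueError("profile fields must have one entry per cell")


def loess_smooth(pt: pd.Series, values: pd.Series, span: float = 0.5,
                 degree: int = 2, set_name: str = "") -> SignatureProfile:
    """Smooth per-cell values along pseudotime, evaluated at observed PT.

    Cells are sorted by PT (ties broken by cell id for determinism); the
    smooth is the tri-cube local polynomial fit at each cell's own PT.
    """
    common = pt.index.intersection(values.index)
    if len(common) != len(pt) or len(common) != len(values):
        raise ValueError("pt and values must cover identical cells")
    order = sorted(common, key=lambda c: (pt[c], c))
    x = pt.loc[order].to_numpy(dtype=float)
    y = values.loc[order].to_numpy(dtype=float)
    smooth = loess_fit(x, y, x, span=span, degree=degree)
    return SignatureProfile(set_name=set_name or str(values.name or ""),
                            pt_sorted_cells=[str(c) for c in order],
                            pt=x, raw=y, smooth=smooth, span=span, degree=degree)


@dataclass
class RelativeActivity:
    """A smoothed profile rescaled so its minimum is 0 and maximum is 1."""

    set_name: str
    pt: np.ndarray
    values: np.ndarray


def relative_activity(profile: SignatureProfile) -> RelativeActivity:
    """Min-max rescale a smoothed profile to relative activity in [0, 1].

    Raises
    ------
    ValueError
        For a (numerically) constant smooth — the rescaling would divide
        by zero ("degenerate profile").
    """
    lo = float(profile.smooth.min())
    hi = float(profile.smooth.max())
    if hi - lo < 1e-12:
        raise ValueError(f"degenerate profile {profile.set_name!r}: "
                         "constant smooth has no relative activity")
    return RelativeActivity(set_name=profile.set_name, pt=profile.pt.copy(),
                            values=(profile.smooth - lo) / (hi - lo))


@dataclass
class TrajectoryPair:
    """Two smoothed profiles paired point-wise along ascending PT."""

    set_a: str
    set_b: str
    pt: np.ndarray
    a: np.ndarray
    b: np.ndarray


def biaxial_trajectory(profile_a: SignatureProfile,
                       profile_b: SignatureProfile) -> TrajectoryPair:
    """Pair two profiles over identical cells into a biaxial trajectory.

    The curve is parameterized by PT: point i is (smooth_a[i], smooth_b[i]).
    Swapping the inputs transposes the curve.
    """
    if profile_a.pt_sorted_cells != profile_b.pt_sorted_cells:
        raise ValueError("profiles cover different cells or orders; "
                         "smooth both against the same pseudotime")
    return TrajectoryPair(set_a=profile_a.set_name, set_b=profile_b.set_name,
                          pt=profile_a.pt.copy(),
                          a=profile_a.smooth.copy(), b=profile_b.smooth.copy())


def profile_table(profiles: list[SignatureProfile]) -> pd.DataFrame:
    """Long-format table (set, cell_id, pt, raw_gsz, smooth, relative)."""
    frames = []
    for profile in profiles:
        try:
            rel = relative_activity(profile).values
        except ValueError:
            rel = np.full(len(profile.pt), np.nan)
        frames.append(pd.DataFrame({
            "set": profile.set_name,
            "cell_id": profile.pt_sorted_cells,
            "pt": profile.pt,
            "raw_gsz": profile.raw,
            "smooth": profile.smooth,
            "relative": rel,
        }))
    return pd.concat(frames, ignore_index=True)


def plot_profiles(profiles: list[SignatureProfile], path: str) -> None:
    """Write a per-signature PT-profile figure (relative activity vs PT)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for profile in profiles:
        try:
            rel = relative_activity(profile)
        except ValueError:
            continue
        ax.plot(rel.pt, rel.values, label=profile.set_name)
    ax.set_xlabel("pseudotime")
    ax.set_ylabel("relative activity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_biaxial(pair: TrajectoryPair, path: str) -> None:
    """Write a biaxial trajectory figure (signature vs signature)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    points = ax.scatter(pair.a, pair.b, c=pair.pt, cmap="viridis", s=12)
    fig.colorbar(points, label="pseudotime")
    ax.set_xlabel(pair.set_a)
    ax.set_ylabel(pair.set_b)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
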