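"""Rotation-translation coupling and diffusion analysis of trajectories.

The azimuthal angle of the tracked centre of mass about the DNA (Z) axis is
computed with the two-argument arctangent and unwrapped; a least-squares
line of theta against Z gives the coupling slope.  A slope near -2*pi/34
rad/Å (one turn per B-DNA pitch) indicates sliding; a slope near zero
indicates hopping.  Diffusion coefficients come from the slope of the
sliding-origin-averaged MSD, which equals 2 d D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulator import Trajectory

__all__ = [
    "AngularTrace",
    "CouplingResult",
    "MechanismSummary",
    "MSDResult",
    "ClassificationThresholds",
    "DEFAULT_THRESHOLDS",
    "SLIDING_SLOPE",
    "angular_trace",
    "fit_theta_z",
    "classify_slope",
    "classify_mechanism",
    "msd",
]

#: Ideal rotation-coupled slope magnitude: one full turn (2*pi) per 34 Å.
SLIDING_SLOPE = 2.0 * np.pi / 34.0


@dataclass(frozen=True)
class ClassificationThresholds:
    """Bands on the mean theta/Z slope (rad/Å).

    sliding: slope within ``sliding_band`` of -2*pi/34; hopping: |slope| <=
    ``hopping_band``; anything else is intermediate.
    """

    sliding_band: float = 0.03
    hopping_band: float = 0.05


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class AngularTrace:
    z: np.ndarray          # (F,) unwrapped COM Z, Å
    theta: np.ndarray      # (F,) unwrapped azimuth, rad
    radius: np.ndarray     # (F,) COM distance from the axis, Å
    selection: str = "protein"

    @property
    def n_frames(self) -> int:
        return int(self.z.shape[0])


@dataclass(frozen=True)
class CouplingResult:
    slope: float           # rad/Å
    stderr: float
    intercept: float
    r_squared: float
    n_frames: int
    classification: str


@dataclass(frozen=True)
class MechanismSummary:
    mean_slope: float
    stderr: float
    n_replicates: int
    classification: str


@dataclass
class MSDResult:
    lags: np.ndarray       # (L+1,) lag times (frame units * frame_dt)
    msd: np.ndarray        # (L+1,) Å^2; msd[0] == 0
    fit_window: tuple[int, int]
    dimensionality: int
    diffusion_coefficient: float
    slope: float
    nonlinear: bool        # linear fit questionable (curvature detected)


def _resolve_selection(traj: Trajectory, selection: str) -> np.ndarray:
    if selection == "protein":
        return np.ones(traj.n_beads, dtype=bool)
    if selection.startswith("monomer:"):
        chain = selection.split(":", 1)[1]
        chains = np.asarray(traj.metadata.get("chain_ids", []))
        if chains.size != traj.n_beads:
            raise ValueError("trajectory metadata lacks chain ids for monomer selection")
        mask = chains == chain
        if not mask.any():
            raise ValueError(f"no beads on chain {chain!r}")
        return mask
    raise ValueError(f"unknown selection {selection!r}")


def angular_trace(traj: Trajectory, selection: str = "protein") -> AngularTrace:
    """COM azimuth (unwrapped) and axial position per frame.

    Z is unwrapped with the DNA period when the trajectory was run with
    periodic Z, so multi-period drifts remain continuous.
    """
    mask = _resolve_selection(traj, selection)
    com = traj.com_selection(mask)
    x, y, z = com[:, 0], com[:, 1], com[:, 2]
    r = np.hypot(x, y)
    if np.any(r == 0.0):
        bad = int(np.argmax(r == 0.0))
        raise ValueError(f"COM lies on the DNA axis at frame {bad}; angle undefined")
    theta = np.unwrap(np.arctan2(y, x))
    period = float(traj.metadata.get("z_period", 0.0) or 0.0)
    if period > 0.0:
        z = np.unwrap(z, period=period)
    return AngularTrace(z=z, theta=theta, radius=r, selection=selection)


def classify_slope(
    slope: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> str:
    if abs(slope + SLIDING_SLOPE) <= thresholds.sliding_band:
        return "sliding"
    if abs(slope) <= thresholds.hopping_band:
        return "hopping"
    return "intermediate"


def fit_theta_z(
    trace: AngularTrace,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    min_z_range: float = 1e-9,
    burn_in: float = 0.0,
) -> CouplingResult:
    """Ordinary least squares of theta on Z.

    ``burn_in`` discards that leading fraction of frames before fitting —
    used to drop the initial approach/association transient of a simulated
    trajectory, which is uncorrelated with the bound-state dynamics.  A
    trace without significant translation (degenerate Z range) cannot be
    fitted; it is classified "undetermined" with an undefined slope.
    """
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    start = int(burn_in * trace.n_frames)
    z, theta = trace.z[start:], trace.theta[start:]
    if z.shape[0] < 10:
        raise ValueError("need at least 10 frames to fit a coupling slope")
    if np.ptp(z) <= min_z_range:
        return CouplingResult(
            slope=float("nan"), stderr=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), n_frames=int(z.shape[0]),
            classification="undetermined",
        )
    fit = stats.linregress(z, theta)
    return CouplingResult(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_frames=int(z.shape[0]),
        classification=classify_slope(float(fit.slope), thresholds),
    )


def classify_mechanism(
    results: list[CouplingResult],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> MechanismSummary:
    """Aggregate replicate fits: unweighted mean slope +/- standard error."""
    if not results:
        raise ValueError("no replicate results to aggregate")
    slopes = np.array([r.slope for r in results if np.isfinite(r.slope)])
    if slopes.size == 0:
        return MechanismSummary(float("nan"), float("nan"), 0, "undetermined")
    mean = float(slopes.mean())
    se = float(slopes.std(ddof=1) / np.sqrt(slopes.size)) if slopes.size > 1 else 0.0
    return MechanismSummary(mean, se, int(slopes.size), classify_slope(mean, thresholds))


def msd(
    series: np.ndarray | Trajectory,
    dimensionality: int = 1,
    fit_window: tuple[int, int] = (1, 200),
    frame_dt: float = 1.0,
    curvature_tolerance: float = 0.2,
) -> MSDResult:
    """Sliding-origin MSD and the diffusion coefficient from its slope.

    MSD(tau) = <|r(t0+tau) - r(t0)|^2> averaged over every valid origin t0.
    The diffusion coefficient is slope / (2 d), with the slope fitted over
    ``fit_window`` lag indices.  With d = 1 the Z coordinate is used; with
    d = 3 the full COM.  A curvature check flags visibly non-linear MSD
    curves (e.g. ballistic motion) via ``nonlinear``.
    """
    if isinstance(series, Trajectory):
        com = series.com()
        period = float(series.metadata.get("z_period", 0.0) or 0.0)
        z = np.unwrap(com[:, 2], period=period) if period > 0 else com[:, 2]
        if dimensionality == 1:
            coords = z[:, None]
        elif dimensionality == 3:
            coords = np.column_stack([com[:, 0], com[:, 1], z])
        else:
            raise ValueError("dimensionality must be 1 or 3 for trajectories")
    else:
        coords = np.asarray(series, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        if coords.shape[1] != dimensionality:
            raise ValueError(
                f"series has {coords.shape[1]} components but d={dimensionality}"
            )

    n = coords.shape[0]
    lo, hi = fit_window
    if not (1 <= lo < hi):
        raise ValueError("fit window must satisfy 1 <= lo < hi")
    if hi >= n:
        raise ValueError(f"fit window {fit_window} exceeds trajectory length {n}")

    max_lag = hi
    curve = np.zeros(max_lag + 1)
    for tau in range(1, max_lag + 1):
        diff = coords[tau:] - coords[:-tau]
        curve[tau] = float((diff ** 2).sum(axis=1).mean())

    lags = np.arange(max_lag + 1) * frame_dt
    fit = stats.linregress(lags[lo:hi + 1], curve[lo:hi + 1])
    slope = float(fit.slope)
    d_coeff = max(slope, 0.0) / (2.0 * dimensionality)

    # quadratic term large relative to the linear span -> not diffusive
    quad = np.polyfit(lags[lo:hi + 1], curve[lo:hi + 1], 2)
    span = abs(curve[hi] - curve[lo]) or 1.0
    nonlinear = abs(quad[0]) * (lags[hi] - lags[lo]) ** 2 > curvature_tolerance * span

    return MSDResult(
        lags=lags, msd=curve, fit_window=(lo, hi),
        dimensionality=dimensionality,
        diffusion_coefficient=d_coeff, slope=slope, nonlinear=bool(nonlinear),
    )
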