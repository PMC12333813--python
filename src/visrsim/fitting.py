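"""Fit tracked displacement profiles to the MSD creep model.

The three parameters (omega_n, tau, S) are estimated by Nelder-Mead
minimization of the sum of squared residuals between the profile and the
closed-form forward solution.  The "unconstrained" search runs on
log-transformed parameters, which keeps all three positive without hard
bounds.  Relative elasticity RE = 1/S and relative viscosity RV = tau/S
are derived from the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .msd import (
    DisplacementProfile,
    MSDParams,
    PushSequence,
    forward_displacement,
    re_rv_from_params,
)

__all__ = ["FitResult", "fit_msd", "roi_summary"]


@dataclass(frozen=True)
class FitResult:
    omega_n: float
    tau: float
    S: float
    RE: float
    RV: float
    residual_rms: float
    converged: bool
    n_iter: int
    location: tuple[float, int] = (0.0, 0)

    def __post_init__(self) -> None:
        if not np.isclose(self.RE * self.S, 1.0, rtol=1e-12):
            raise ValueError("RE must equal 1/S")
        if not np.isclose(self.RV, self.tau / self.S, rtol=1e-12):
            raise ValueError("RV must equal tau/S")
        if self.residual_rms < 0.0:
            raise ValueError("residual_rms must be non-negative")


def _default_init(profile: DisplacementProfile, seq: PushSequence) -> np.ndarray:
    """Heuristic start: S from the peak, omega_n from the time-to-peak.

    The peak of the creep response arrives roughly half an oscillation
    period after the pushes begin, so omega_n0 ~ pi / t_peak; tau0 takes
    the critically damped value 2/omega_n0.
    """
    z = profile.z
    t = profile.times
    peak = float(np.max(np.abs(z)))
    t_peak = float(t[int(np.argmax(np.abs(z)))])
    if t_peak <= 0.0:
        t_peak = seq.push_edges[3] + 1.0 / seq.prf
    omega_n0 = np.pi / t_peak
    tau0 = 2.0 / omega_n0
    return np.log(np.array([omega_n0, tau0, peak]))


def fit_msd(
    profile: DisplacementProfile,
    seq: PushSequence,
    init: np.ndarray | None = None,
    n_starts: int = 1,
    maxiter: int = 2000,
    seed: int = 0,
) -> FitResult:
    """Least-squares MSD fit of one displacement profile.

    ``init`` optionally gives (omega_n, tau, S) starting values in linear
    units.  ``n_starts > 1`` runs additional jittered starts and keeps the
    best objective (ties broken toward smaller omega_n).  Non-convergence
    is reported through ``converged=False``, never as an exception.
    """
    z = np.asarray(profile.z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("profile contains non-finite displacement")
    if np.all(z == 0.0):
        raise ValueError("all-zero profile: nothing to fit")
    t = profile.times
    scale = float(np.max(np.abs(z)))

    def objective(logp: np.ndarray) -> float:
        wn, tau, S = np.exp(logp)
        try:
            p = MSDParams(omega_n=wn, tau=tau, S=S)
        except (ValueError, OverflowError):
            return np.inf
        model = forward_displacement(p, seq, times=t).z
        r = (z - model) / scale
        return float(np.dot(r, r))

    if init is not None:
        x0 = np.log(np.asarray(init, dtype=float))
    else:
        x0 = _default_init(profile, seq)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(x0 + rng.normal(0.0, 0.3, size=3))

    best = None
    for x_start in starts:
        res = optimize.minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": 1e-9,
                "fatol": 1e-14,
                "adaptive": False,
            },
        )
        if best is None:
            best = res
        elif res.fun < best.fun or (
            res.fun == best.fun and res.x[0] < best.x[0]
        ):
            best = res

    wn, tau, S = np.exp(best.x)
    p = MSDParams(omega_n=wn, tau=tau, S=S)
    RE, RV = re_rv_from_params(p)
    resid = z - forward_displacement(p, seq, times=t).z
    return FitResult(
        omega_n=wn,
        tau=tau,
        S=S,
        RE=RE,
        RV=RV,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=bool(best.success),
        n_iter=int(best.nit),
        location=profile.location,
    )


def roi_summary(
    fits: list[FitResult],
    roi: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Mean and sample standard deviation of RE over converged fits.

    ``roi = (depth_lo, depth_hi)`` optionally restricts to fits whose
    location depth falls inside the analysis window; by default all fits
    are in the ROI.  Raises if no converged fit remains.
    """
    kept = [
        f
        for f in fits
        if f.converged and (roi is None or roi[0] <= f.location[0] <= roi[1])
    ]
    if not kept:
        raise ValueError("no converged fits in the requested ROI")
    values = np.array([f.RE for f in kept])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd
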