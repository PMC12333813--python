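"""Mass-spring-damper (MSD) creep model and its closed-form forward solution.

VisR ultrasound approximates the tissue response to two successive acoustic
radiation force (ARF) pushes by a second-order linear system,

    z'' + omega_n^2 tau z' + omega_n^2 z = S omega_n^2 f(t),

where ``f`` is the normalized double-rectangle forcing (two pushes of
duration ``t_arf`` separated by ``t_s``), ``omega_n = sqrt(mu/m)`` is the
natural frequency, ``tau = eta/mu`` the relaxation time constant and
``S = A/mu`` the static sensitivity.  The forward displacement is the
superposition of four Heaviside step responses with alternating signs.

Relative elasticity and viscosity are RE = 1/S = mu/A and RV = tau/S =
eta/A; both are relative to the unknown, spatially constant push
amplitude A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MSDParams",
    "PushSequence",
    "DisplacementProfile",
    "unit_step_response",
    "forward_displacement",
    "re_rv_from_params",
]

#: |zeta - 1| below which the exact critically damped branch is used
_CRITICAL_GUARD = 1e-9


@dataclass(frozen=True)
class MSDParams:
    """(omega_n, tau, S) triplet, optionally backed by the physical quartet.

    When ``mu`` (spring constant, N/m), ``eta`` (damper, N s/m), ``m_mass``
    (kg) and ``A`` (push force, N) are all given, the triplet must satisfy
    omega_n = sqrt(mu/m), tau = eta/mu, S = A/mu.
    """

    omega_n: float
    tau: float
    S: float
    mu: float | None = None
    eta: float | None = None
    m_mass: float | None = None
    A: float | None = None

    def __post_init__(self) -> None:
        for name in ("omega_n", "tau", "S"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        quartet = (self.mu, self.eta, self.m_mass, self.A)
        if all(v is not None for v in quartet):
            mu, eta, m_mass, A = quartet
            checks = {
                "omega_n": (self.omega_n, np.sqrt(mu / m_mass)),
                "tau": (self.tau, eta / mu),
                "S": (self.S, A / mu),
            }
            for name, (got, want) in checks.items():
                if not np.isclose(got, want, rtol=1e-12, atol=0.0):
                    raise ValueError(
                        f"{name}={got!r} inconsistent with physical quartet ({want!r})"
                    )

    @classmethod
    def from_physical(cls, mu: float, eta: float, m_mass: float, A: float) -> "MSDParams":
        return cls(
            omega_n=float(np.sqrt(mu / m_mass)),
            tau=eta / mu,
            S=A / mu,
            mu=mu,
            eta=eta,
            m_mass=m_mass,
            A=A,
        )

    @property
    def zeta(self) -> float:
        """Damping ratio zeta = tau * omega_n / 2."""
        return 0.5 * self.tau * self.omega_n


@dataclass(frozen=True)
class PushSequence:
    """Timing of the two ARF pushes and the tracking ensemble.

    Push 1 occupies [0, t_arf]; push 2 occupies [t_arf + t_s,
    2 t_arf + t_s]; ``t_s`` is the end-to-start separation.
    ``sample_times`` are the slow-time instants at which displacement is
    observed (the tracking ensemble at the pulse repetition frequency).
    """

    t_arf: float
    t_s: float
    prf: float
    t_total: float
    sample_times: np.ndarray

    def __post_init__(self) -> None:
        if self.t_arf <= 0.0:
            raise ValueError("t_arf must be positive")
        if self.t_s < 0.0:
            raise ValueError("t_s must be non-negative")
        t = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "sample_times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("sample_times must be a 1-D array with >= 2 entries")
        if np.any(np.diff(t) <= 0.0):
            raise ValueError("sample_times must be strictly increasing")
        if t[0] < 0.0 or t[-1] > self.t_total + 1e-12:
            raise ValueError("sample_times must lie within [0, t_total]")
        dt = np.diff(t)
        # ensemble spacing must be a whole multiple of the PRF interval
        if np.any(np.abs(dt / (1.0 / self.prf) - np.round(dt * self.prf)) > 1e-6):
            raise ValueError("sample_times spacing inconsistent with prf")

    @property
    def push_edges(self) -> tuple[float, float, float, float]:
        """(push1 on, push1 off, push2 on, push2 off) times."""
        return (
            0.0,
            self.t_arf,
            self.t_arf + self.t_s,
            2.0 * self.t_arf + self.t_s,
        )

    @classmethod
    def default(
        cls,
        t_arf: float = 70e-6,
        t_s: float = 0.4e-3,
        prf: float = 10e3,
        t_total: float = 4.35e-3,
    ) -> "PushSequence":
        """Conventional VisR ensemble: 10 kHz tracking over 4.35 ms.

        Samples fall on the PRF grid, starting at the pre-push reference
        (t = 0); instants falling inside either push (when the tracking
        line cannot be fired) are dropped.
        """
        grid = np.arange(0.0, t_total + 1e-12, 1.0 / prf)
        on1, off1, on2, off2 = 0.0, t_arf, t_arf + t_s, 2.0 * t_arf + t_s
        inside_push = ((grid > on1) & (grid < off1)) | ((grid > on2) & (grid < off2))
        keep = ~inside_push
        return cls(t_arf=t_arf, t_s=t_s, prf=prf, t_total=t_total, sample_times=grid[keep])


@dataclass
class DisplacementProfile:
    """Axial displacement versus slow time at one spatial location."""

    times: np.ndarray
    z: np.ndarray
    location: tuple[float, int] = (0.0, 0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.shape != self.z.shape:
            raise ValueError("times and z must have equal length")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.z))):
            raise ValueError("times and z must be finite")


def unit_step_response(p: MSDParams, t: float | np.ndarray) -> np.ndarray | float:
    """Closed-form response to the forcing S omega_n^2 H(t).

    Covers the underdamped, critically damped and overdamped regimes;
    returns 0 for t < 0.  The response rises from rest to the steady
    state S.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.zeros_like(t_arr)
    pos = t_arr > 0.0
    tp = t_arr[pos]
    wn, zeta, S = p.omega_n, p.zeta, p.S
    if abs(zeta - 1.0) < _CRITICAL_GUARD:
        out[pos] = S * (1.0 - np.exp(-wn * tp) * (1.0 + wn * tp))
    elif zeta < 1.0:
        wd = wn * np.sqrt(1.0 - zeta * zeta)
        out[pos] = S * (
            1.0
            - np.exp(-zeta * wn * tp)
            * (np.cos(wd * tp) + zeta * wn / wd * np.sin(wd * tp))
        )
    else:
        root = wn * np.sqrt(zeta * zeta - 1.0)
        r1 = -zeta * wn + root
        r2 = -zeta * wn - root
        # z/S = 1 - (r2 e^{r1 t} - r1 e^{r2 t}) / (r2 - r1)
        out[pos] = S * (
            1.0 - (r2 * np.exp(r1 * tp) - r1 * np.exp(r2 * tp)) / (r2 - r1)
        )
    return out[0] if scalar else out


def forward_displacement(
    p: MSDParams, seq: PushSequence, times: np.ndarray | None = None
) -> DisplacementProfile:
    """Forward z(t) under the double rectangular push train.

    Superposition of four step responses: + at each push onset, - at each
    push offset.  ``times`` defaults to ``seq.sample_times``.
    """
    t = seq.sample_times if times is None else np.asarray(times, dtype=float)
    on1, off1, on2, off2 = seq.push_edges
    z = (
        unit_step_response(p, t - on1)
        - unit_step_response(p, t - off1)
        + unit_step_response(p, t - on2)
        - unit_step_response(p, t - off2)
    )
    return DisplacementProfile(times=t, z=z)


def re_rv_from_params(p: MSDParams) -> tuple[float, float]:
    """Relative elasticity RE = 1/S (1/m) and relative viscosity RV = tau/S (s/m)."""
    if p.S <= 0.0:
        raise ValueError("S must be positive to derive RE/RV")
    return 1.0 / p.S, p.tau / p.S
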