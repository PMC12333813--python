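"""1-D axial normalized cross-correlation (NCC) displacement tracking.

Each tracked RF line is compared against the fixed pre-push reference
line (creep-recovery tracking).  For every depth window, the kernel from
the reference line is slid over the tracked line within the search
region centered on the running displacement estimate; the lag maximizing
the normalized correlation, refined to sub-sample precision, gives the
axial displacement via ``lag * c / (2 fs)``.

Sub-sample refinement defaults to parabolic interpolation of the
correlation peak over its two neighbors; a cosine fit (exact for a
carrier-dominated correlation function) is available by configuration.
Peaks landing on the search-region boundary are flagged, not silently
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msd import DisplacementProfile
from .synth import RFEnsemble

__all__ = ["NCCConfig", "TrackedDisplacement", "ncc_track"]


@dataclass(frozen=True)
class NCCConfig:
    kernel_len_um: float = 512.0
    search_um: float = 80.0
    fs: float = 40e6
    c_sound: float = 1540.0
    subsample: str = "parabolic"  # or "cosine"
    progressive: bool = False  # track against previous line instead of reference
    min_corr: float = 0.5  # peaks below this correlation are flagged

    def __post_init__(self) -> None:
        if self.kernel_len_um <= 0 or self.search_um <= 0:
            raise ValueError("kernel and search lengths must be positive")
        if self.subsample not in ("parabolic", "cosine"):
            raise ValueError(f"unknown subsample method {self.subsample!r}")
        if self.kernel_samples < 3:
            raise ValueError("kernel shorter than 3 samples at this fs")

    @property
    def sample_um(self) -> float:
        """Axial extent of one fast-time sample, micrometers."""
        return self.c_sound / (2.0 * self.fs) * 1e6

    @property
    def kernel_samples(self) -> int:
        return int(round(self.kernel_len_um / self.sample_um))

    @property
    def search_samples(self) -> int:
        """Half-width of the search region in samples (+- about the estimate)."""
        return max(1, int(round(self.search_um / self.sample_um)))


@dataclass
class TrackedDisplacement:
    """Displacement (m) and correlation quality, depth x slow time."""

    depths: np.ndarray
    times: np.ndarray
    disp: np.ndarray
    ncc: np.ndarray
    flagged: np.ndarray  # peak on search boundary: estimate unreliable

    def profiles(self) -> list[DisplacementProfile]:
        return [
            DisplacementProfile(times=self.times, z=self.disp[i], location=(d, i))
            for i, d in enumerate(self.depths)
        ]


def _refine_peak(c_m1: float, c_0: float, c_p1: float, method: str) -> float:
    """Sub-sample offset of the correlation peak from its integer location."""
    if c_0 >= 1.0 - 1e-12:  # perfect match: the integer lag is exact
        return 0.0
    denom = c_m1 - 2.0 * c_0 + c_p1
    if method == "parabolic" or c_0 <= 0.0:
        if denom >= 0.0:  # not a local maximum shape; refuse to extrapolate
            return 0.0
        delta = 0.5 * (c_m1 - c_p1) / denom
    else:  # cosine fit: c(l) ~ a cos(w (l - d))
        arg = (c_m1 + c_p1) / (2.0 * c_0)
        if not -1.0 < arg < 1.0:
            return 0.0
        w = np.arccos(arg)
        if w == 0.0:
            return 0.0
        delta = -np.arctan2(c_m1 - c_p1, 2.0 * c_0 * np.sin(w)) / w
    return float(np.clip(delta, -1.0, 1.0))


def _ncc_at_lags(ref_kernel: np.ndarray, line: np.ndarray, start: int, lags: np.ndarray) -> np.ndarray:
    """Normalized correlation of the kernel vs windows of ``line`` at integer lags."""
    k = ref_kernel - ref_kernel.mean()
    k_norm = np.sqrt(np.sum(k * k))
    out = np.full(lags.shape, -np.inf)
    n = ref_kernel.size
    for j, lag in enumerate(lags):
        lo = start + lag
        if lo < 0 or lo + n > line.size:
            continue
        w = line[lo : lo + n]
        wc = w - w.mean()
        w_norm = np.sqrt(np.sum(wc * wc))
        if k_norm == 0.0 or w_norm == 0.0:
            out[j] = 0.0
        else:
            out[j] = float(np.dot(k, wc) / (k_norm * w_norm))
    return out


def ncc_track(
    ensemble: RFEnsemble,
    cfg: NCCConfig | None = None,
    depths: np.ndarray | None = None,
) -> TrackedDisplacement:
    """Track axial displacement versus slow time at each analysis depth.

    ``depths`` defaults to the ensemble's ROI sampled at half-kernel
    spacing.  The first slow-time line is the reference and has zero
    displacement by construction.
    """
    if cfg is None:
        cfg = NCCConfig(fs=ensemble.fs, c_sound=ensemble.c_sound)
    rf = ensemble.rf
    n_fast, n_slow = rf.shape
    dz = ensemble.c_sound / (2.0 * ensemble.fs)
    if depths is None:
        lo, hi = ensemble.roi
        step = cfg.kernel_len_um * 1e-6 / 2.0
        depths = np.arange(lo, hi + 1e-9, step)
    depths = np.asarray(depths, dtype=float)

    half_k = cfg.kernel_samples // 2
    n_kernel = 2 * half_k + 1
    if n_fast < n_kernel + 2 * cfg.search_samples + 2:
        raise ValueError("RF lines shorter than one kernel plus search region")

    disp = np.zeros((depths.size, n_slow))
    ncc = np.ones((depths.size, n_slow))
    flagged = np.zeros((depths.size, n_slow), dtype=bool)
    grid0 = ensemble.depth0

    for i, depth in enumerate(depths):
        center = int(round((depth - grid0) / dz))
        start = center - half_k
        if start < 0 or start + n_kernel > n_fast:
            raise ValueError(f"depth {depth} outside the sampled fast-time span")
        ref = rf[start : start + n_kernel, 0]
        running = 0
        for k in range(1, n_slow):
            if cfg.progressive:
                ref = rf[start + running : start + running + n_kernel, k - 1]
            lags = np.arange(running - cfg.search_samples, running + cfg.search_samples + 1)
            corr = _ncc_at_lags(ref, rf[:, k], start, lags)
            j = int(np.argmax(corr))
            on_boundary = j == 0 or j == lags.size - 1
            if on_boundary or corr[j] < cfg.min_corr:
                flagged[i, k] = True
            if on_boundary:
                delta = 0.0
            else:
                delta = _refine_peak(corr[j - 1], corr[j], corr[j + 1], cfg.subsample)
            lag = lags[j]
            disp[i, k] = (lag + delta) * dz
            ncc[i, k] = corr[j]
            running = int(lag)
    return TrackedDisplacement(
        depths=depths, times=ensemble.sample_times, disp=disp, ncc=ncc, flagged=flagged
    )
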