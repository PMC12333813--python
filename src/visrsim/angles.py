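"""dRE curves, regression slopes and rank statistics.

dRE is the percent change of relative elasticity at a given ARF-AoS
incidence angle relative to the same realization's RE at normal (90
degree) incidence.  Slopes of dRE against the deviation angle
``delta = 90 - incidence`` summarize each material's angle sensitivity;
their relation to the muL/EL ratio is assessed with Spearman rank
correlation across materials and pairwise Wilcoxon rank-sum tests on
per-realization slopes.

The rank statistics are implemented from first principles (midranks for
ties; exact rank-sum enumeration for the small per-material replicate
counts used here) so their null distributions are under the package's
control and can be checked against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "DeltaRECurve",
    "SlopeEstimate",
    "delta_re",
    "slope_fit",
    "midranks",
    "spearman_rho",
    "wilcoxon_ranksum",
]

#: largest C(n+m, n) enumerated exactly before the normal approximation is used
_EXACT_LIMIT = comb(20, 10)


@dataclass
class DeltaRECurve:
    """dRE (%) per angle per realization for one material/orientation."""

    angles_deg: np.ndarray  # incidence angles, 90 included
    dre_pct: np.ndarray  # (n_realizations, n_angles)
    re_ref: np.ndarray  # RE at 90 deg, one per realization
    label: str = ""
    orientation: str = "longitudinal"

    @property
    def delta_deg(self) -> np.ndarray:
        return 90.0 - self.angles_deg

    def mean_dre(self) -> np.ndarray:
        return self.dre_pct.mean(axis=0)


@dataclass
class SlopeEstimate:
    """OLS slope of dRE vs deviation angle, with per-realization replicates."""

    slope: float  # % per degree, mean of replicate slopes
    intercept: float
    r_squared: float
    replicate_slopes: np.ndarray
    label: str = ""


def delta_re(
    angles_deg: np.ndarray,
    re_values: np.ndarray,
    label: str = "",
    orientation: str = "longitudinal",
) -> DeltaRECurve:
    """Percent change of RE relative to the 90-degree reference.

    ``re_values`` has shape (n_realizations, n_angles); the reference is
    taken within each realization.
    """
    angles = np.asarray(angles_deg, dtype=float)
    re = np.atleast_2d(np.asarray(re_values, dtype=float))
    if re.shape[1] != angles.size:
        raise ValueError("re_values second axis must match angles")
    ref_idx = np.flatnonzero(angles == 90.0)
    if ref_idx.size == 0:
        raise ValueError("missing 90 degree reference measurement")
    ref = re[:, ref_idx[0]]
    dre = 100.0 * (re - ref[:, None]) / ref[:, None]
    return DeltaRECurve(
        angles_deg=angles, dre_pct=dre, re_ref=ref, label=label, orientation=orientation
    )


def slope_fit(curve: DeltaRECurve) -> SlopeEstimate:
    """Ordinary least-squares line of dRE against the deviation angle.

    Regressing on ``delta = 90 - incidence`` makes the slope positive for
    materials whose RE grows away from normal incidence; the magnitude is
    identical to a fit against the incidence angle itself.  One slope is
    retained per realization; the summary slope/intercept/r^2 come from
    pooling all realizations.
    """
    x = curve.delta_deg
    if np.unique(x).size < 2:
        raise ValueError("slope requires at least two distinct angles")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    y = curve.dre_pct
    rep_slopes = (y - y.mean(axis=1, keepdims=True)) @ xc / denom

    # pooled fit over all realizations
    x_all = np.tile(x, y.shape[0])
    y_all = y.ravel()
    slope_all = float(
        np.dot(x_all - x_all.mean(), y_all - y_all.mean())
        / np.dot(x_all - x_all.mean(), x_all - x_all.mean())
    )
    intercept = float(y_all.mean() - slope_all * x_all.mean())
    fitted = intercept + slope_all * x_all
    ss_res = float(np.sum((y_all - fitted) ** 2))
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SlopeEstimate(
        slope=float(rep_slopes.mean()),
        intercept=intercept,
        r_squared=r2,
        replicate_slopes=rep_slopes,
        label=curve.label,
    )


def midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receiving their midrank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays of size >= 3")
    rx = midranks(x)
    ry = midranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    nx = float(np.dot(sx, sx))
    ny = float(np.dot(sy, sy))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(np.dot(sx, sy) / np.sqrt(nx * ny))


@lru_cache(maxsize=8)
def _combo_index(n_total: int, n_a: int) -> np.ndarray:
    return np.array(list(combinations(range(n_total), n_a)), dtype=np.intp)


def wilcoxon_ranksum(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon rank-sum test with midranks.

    Returns (rank-sum statistic of ``a``, two-sided p, significant at
    ``alpha``).  For group sizes up to 10 the p-value is exact: the
    permutation distribution of the rank sum is enumerated over all
    C(n+m, n) group assignments and the two-sided p is the fraction of
    assignments at least as far from the null mean as observed.  Larger
    samples use the normal approximation with tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have at least two observations")
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    n_a, n = a.size, pooled.size
    w = float(np.sum(ranks[: n_a]))
    mu = n_a * (n + 1) / 2.0

    if comb(n, n_a) <= _EXACT_LIMIT:
        idx = _combo_index(n, n_a)
        sums = ranks[idx].sum(axis=1)
        p = float(np.mean(np.abs(sums - mu) >= np.abs(w - mu) - 1e-12))
    else:
        var = n_a * (n - n_a) / (n * (n - 1)) * float(np.sum((ranks - ranks.mean()) ** 2))
        if var == 0.0:
            p = 1.0
        else:
            from scipy.stats import norm  # standard normal tail only

            z = (w - mu) / np.sqrt(var)
            p = float(2.0 * norm.sf(abs(z)))
    return w, min(p, 1.0), p < alpha
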