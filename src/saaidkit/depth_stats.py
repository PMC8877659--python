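"""Depth-wise nonparametric comparison of SAAID between groups.

At the sample sizes of a typical small-animal imaging study (five animals
per group) asymptotic rank tests are unreliable, so the Mann-Whitney U test
here defaults to the *exact* permutation distribution: all C(n1+n2, n1)
assignments of the pooled observations are enumerated, which is tie-safe
because the observed pooled values themselves (with midranks) are permuted.
The two-sided p-value doubles the smaller tail mass including the observed
statistic (capped at 1); with n1 = n2 = 5 the smallest achievable p is
2/252 ~ 0.0079, so significance at 0.05 requires a nearly complete
separation of the groups.

Applied per depth to the per-animal (or per-stack) SAAID values of a wound
group versus healthy skin, this yields a p-value-by-depth profile; the
contiguous depth interval with the smallest aggregate p localises the depths
most sensitive to the wound state. No multiplicity adjustment is applied by
default; Holm's step-down is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiler import SAAIDProfile, _common_grid, animal_mean_profiles

__all__ = [
    "MannWhitneyResult",
    "DepthPValueProfile",
    "SensitiveDepthInterval",
    "mann_whitney_u",
    "depthwise_compare",
    "sensitive_depth",
    "pvalue_frame",
]

#: Largest number of group assignments enumerated before ``auto`` falls back
#: to the tie-corrected normal approximation.
EXACT_ENUMERATION_LIMIT = 20_000

Mode = Literal["exact", "normal", "auto"]


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # min(U_xy, U_yx), in [0, n1*n2]
    p_value: float    # two-sided, in (0, 1]
    n1: int
    n2: int
    mode: str         # "exact" or "normal" (what was actually used)


def _u_less(x: np.ndarray, y: np.ndarray) -> float:
    """Count of pairs with x_i < y_j plus half the tied pairs."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff < 0) + 0.5 * np.sum(diff == 0))


def _exact_two_sided(pooled: np.ndarray, n1: int, u1: float) -> float:
    """Exact two-sided p: doubled smaller tail of U1 over all assignments.

    U1 (the x<y count with midrank tie handling) for an assignment with
    x-rank-sum R is ``n1 n2 + n1(n1+1)/2 - R``. With ties and unequal group
    sizes the permutation distribution of U1 need not be symmetric, so the
    two-sided p doubles the *smaller* of the two tail masses that include
    the observed U1; swapping the groups maps the distribution to
    ``n1 n2 - U1`` exactly, making this convention symmetric in x and y.
    """
    n = len(pooled)
    n2 = n - n1
    ranks = stats.rankdata(pooled)
    const = n1 * n2 + n1 * (n1 + 1) / 2.0
    lo_thresh = u1 + 1e-9
    hi_thresh = u1 - 1e-9
    lower = upper = 0
    for idx in combinations(range(n), n1):
        u = const - sum(ranks[i] for i in idx)
        if u <= lo_thresh:
            lower += 1
        if u >= hi_thresh:
            upper += 1
    total = math.comb(n, n1)
    return min(1.0, 2.0 * min(lower, upper) / total)


def _normal_p(pooled: np.ndarray, n1: int, u_min: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(pooled)
    n2 = n - n1
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    z = (u_min + 0.5 - n1 * n2 / 2.0) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.cdf(z)))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: Mode = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, exact by default at small n.

    The reported statistic is the number of pairs with ``x < y`` plus half
    the tied pairs, minimised with its mirror ``n1 n2 - U``. ``exact``
    enumerates the full permutation distribution over the observed pooled
    values (tie-safe) and doubles the smaller tail, which is symmetric under
    exchanging the samples; ``normal`` uses the tie-corrected Gaussian
    approximation with continuity correction; ``auto`` picks exact while
    C(n1+n2, n1) <= 20,000.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    n1, n2 = x.size, y.size
    u1 = _u_less(x, y)
    u_min = min(u1, n1 * n2 - u1)
    pooled = np.concatenate([x, y])
    if mode == "auto":
        mode = "exact" if math.comb(n1 + n2, n1) <= EXACT_ENUMERATION_LIMIT else "normal"
    if mode == "exact":
        p = _exact_two_sided(pooled, n1, u1)
    elif mode == "normal":
        p = _normal_p(pooled, n1, u_min)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MannWhitneyResult(u=u_min, p_value=max(p, 0.0), n1=n1, n2=n2, mode=mode)


@dataclass
class DepthPValueProfile:
    """Per-depth U statistics and two-sided p-values for one group pair."""

    depths_um: np.ndarray
    u: np.ndarray
    p: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    significant: np.ndarray
    tested: np.ndarray
    alpha: float = 0.05
    groups: tuple[str, str] = ("", "")
    day: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("depths_um", "u", "p", "n1", "n2", "significant", "tested"):
            setattr(self, name, np.asarray(getattr(self, name)))
        ok = self.tested.astype(bool)
        if np.any((self.p[ok] <= 0) | (self.p[ok] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        if np.any(self.u[ok] > self.n1[ok] * self.n2[ok]):
            raise ValueError("U exceeds n1*n2")


def _unit_matrix(
    profiles: Sequence[SAAIDProfile], level: str
) -> tuple[np.ndarray, np.ndarray]:
    units = animal_mean_profiles(profiles) if level == "animal" else list(profiles)
    return _common_grid(units), np.vstack([p.saaid for p in units])


def depthwise_compare(
    group_a: Sequence[SAAIDProfile],
    group_b: Sequence[SAAIDProfile],
    alpha: float = 0.05,
    level: Literal["stack", "animal"] = "animal",
    mode: Mode = "auto",
    adjust: Literal[None, "holm"] = None,
) -> DepthPValueProfile:
    """Mann-Whitney comparison of two groups' SAAID at every common depth.

    The replicate unit is the animal by default (stacks are first averaged
    within each animal); per-stack mode treats every stack as a unit. Depths
    with fewer than two defined values in either group are marked untested.
    No multiplicity adjustment is applied unless ``adjust='holm'``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain profiles")
    grid_a, mat_a = _unit_matrix(group_a, level)
    grid_b, mat_b = _unit_matrix(group_b, level)
    if not np.array_equal(grid_a, grid_b):
        raise ValueError("groups are on different depth grids")
    k = grid_a.size
    u = np.full(k, np.nan)
    p = np.full(k, np.nan)
    n1 = np.zeros(k, dtype=int)
    n2 = np.zeros(k, dtype=int)
    tested = np.zeros(k, dtype=bool)
    for i in range(k):
        a = mat_a[:, i][np.isfinite(mat_a[:, i])]
        b = mat_b[:, i][np.isfinite(mat_b[:, i])]
        n1[i], n2[i] = a.size, b.size
        if a.size >= 2 and b.size >= 2:
            res = mann_whitney_u(a, b, mode=mode)
            u[i], p[i] = res.u, res.p_value
            tested[i] = True
    p_eff = p.copy()
    if adjust == "holm":
        idx = np.flatnonzero(tested)
        if idx.size:
            order = idx[np.argsort(p[idx])]
            m = idx.size
            running = 0.0
            for rank, j in enumerate(order):
                running = max(running, min(1.0, (m - rank) * p[j]))
                p_eff[j] = running
    significant = tested & (p_eff < alpha)
    meta_a = group_a[0].meta
    meta_b = group_b[0].meta
    return DepthPValueProfile(
        grid_a.copy(),
        u,
        p_eff,
        n1,
        n2,
        significant,
        tested,
        alpha=alpha,
        groups=(str(meta_a.get("group", "a")), str(meta_b.get("group", "b"))),
        day=meta_a.get("day"),
        meta={"level": level, "mode": mode, "adjust": adjust},
    )


@dataclass(frozen=True)
class SensitiveDepthInterval:
    """Contiguous depth interval with the smallest aggregate p-value."""

    low_um: float
    high_um: float
    localized: bool  # False when the p-profile is flat (no localisation)


def sensitive_depth(
    profiles: DepthPValueProfile | Iterable[DepthPValueProfile],
    factor: float = 2.0,
) -> SensitiveDepthInterval:
    """Localise the depth interval where groups separate most strongly.

    The aggregate per depth is the mean log10 p over the supplied profiles
    (untested depths excluded). The interval is the depths contiguous with
    the minimum whose aggregate stays within ``log10(factor)`` of it; ties
    break to the shallower depth. A flat aggregate returns the whole tested
    range flagged as not localised.
    """
    if isinstance(profiles, DepthPValueProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no p-value profiles given")
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    grid = profiles[0].depths_um
    for pr in profiles[1:]:
        if not np.array_equal(pr.depths_um, grid):
            raise ValueError("profiles are on different depth grids")
    logp = np.vstack(
        [np.where(pr.tested, np.log10(np.clip(pr.p, 1e-300, 1.0)), np.nan) for pr in profiles]
    )
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(logp, axis=0)
    tested = np.isfinite(agg)
    if tested.sum() < 3:
        raise ValueError("need at least 3 tested depths to localise")
    t_idx = np.flatnonzero(tested)
    vals = agg[t_idx]
    if np.ptp(vals) < 1e-12:
        return SensitiveDepthInterval(
            float(grid[t_idx[0]]), float(grid[t_idx[-1]]), localized=False
        )
    best = t_idx[int(np.argmin(vals))]  # argmin takes the first = shallowest tie
    cutoff = agg[best] + np.log10(factor)
    lo = best
    while lo - 1 in t_idx and agg[lo - 1] <= cutoff:
        lo -= 1
    hi = best
    while hi + 1 in t_idx and agg[hi + 1] <= cutoff:
        hi += 1
    return SensitiveDepthInterval(float(grid[lo]), float(grid[hi]), localized=True)


def pvalue_frame(profiles: Iterable[DepthPValueProfile]) -> pd.DataFrame:
    """Tidy table: one row per (group pair, day, depth) with U, p, n, flag."""
    rows = []
    for pr in profiles:
        for i, d in enumerate(pr.depths_um):
            rows.append(
                {
                    "group_a": pr.groups[0],
                    "group_b": pr.groups[1],
                    "day": pr.day,
                    "depth_um": d,
                    "U": pr.u[i],
                    "p": pr.p[i],
                    "n1": int(pr.n1[i]),
                    "n2": int(pr.n2[i]),
                    "tested": bool(pr.tested[i]),
                    "significant": bool(pr.significant[i]),
                }
            )
    return pd.DataFrame(rows)
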