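"""Wound-closure kinetics from caliper diameters, and light-dose arithmetic.

A healing wound is tracked by its major and minor diameters ``A >= B`` (mm);
the area of the elliptical wound is ``S = A B pi / 4`` and the percent
closure at a later day is ``100 (S0 - S) / S0`` against that animal's own
day-0 area. Group summaries are the mean and sample SD of area and closure
per day.

Dose arithmetic ties fluence (J/cm^2), source power (mW) and irradiation
time together through the spot area: ``fluence x spot_area = power x time``.
The spot area is rarely printed with a protocol, so a helper back-solves it
from any known (fluence, power, time) triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack_io import validate_measurements

__all__ = [
    "HealingCurve",
    "DosePlan",
    "ellipse_area",
    "percent_closure",
    "build_healing_curves",
    "healing_curve_frame",
    "compute_exposure_time",
    "spot_area_from_exposure",
]

#: Caliper resolution (mm) of the digital instrument; recorded as metadata,
#: deliberately not propagated into area uncertainties.
CALIPER_RESOLUTION_MM = 0.02


def ellipse_area(A: float, B: float) -> float:
    """Elliptical wound area ``A * B * pi / 4`` (mm^2) from diameters in mm."""
    if B <= 0 or A < B:
        raise ValueError("diameters must satisfy A >= B > 0")
    return A * B * np.pi / 4.0


def percent_closure(S0: float, S: float) -> float:
    """Percent wound closure ``100 (S0 - S) / S0`` relative to the original area."""
    if S0 <= 0:
        raise ValueError("original area S0 must be positive")
    if S < 0:
        raise ValueError("current area S must be non-negative")
    return 100.0 * (S0 - S) / S0


@dataclass
class HealingCurve:
    """Per-day group summary of wound area and percent closure."""

    group: str
    days: np.ndarray
    area_mean: np.ndarray
    area_sd: np.ndarray
    closure_mean: np.ndarray
    closure_sd: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("days", "area_mean", "area_sd", "closure_mean", "closure_sd", "n"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.days[0] != 0 or np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be ascending and include day 0 first")
        if not np.isclose(self.closure_mean[0], 0.0):
            raise ValueError("closure must be 0 at day 0 by construction")


def build_healing_curves(table: pd.DataFrame) -> dict[str, HealingCurve]:
    """Build per-group healing curves from a validated measurement table.

    Every animal must have a day-0 row; its own day-0 area is the ``S0``
    reference for that animal's closure series. Summaries use the sample SD
    (``ddof=1``; 0 when a day has a single animal).
    """
    df = validate_measurements(table)
    df["area_mm2"] = df["A_mm"] * df["B_mm"] * np.pi / 4.0
    curves: dict[str, HealingCurve] = {}
    for group, gdf in df.groupby("group", sort=True):
        s0 = gdf[gdf["day"] == 0].set_index("animal")["area_mm2"]
        missing = sorted(set(gdf["animal"]) - set(s0.index))
        if missing:
            raise ValueError(
                f"animal {missing[0]!r} in group {group!r} has no day-0 measurement"
            )
        gdf = gdf.assign(
            closure_pct=100.0
            * (s0.loc[gdf["animal"]].to_numpy() - gdf["area_mm2"].to_numpy())
            / s0.loc[gdf["animal"]].to_numpy()
        )
        per_day = gdf.groupby("day").agg(
            area_mean=("area_mm2", "mean"),
            area_sd=("area_mm2", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            closure_mean=("closure_pct", "mean"),
            closure_sd=("closure_pct", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n=("animal", "nunique"),
        )
        curves[str(group)] = HealingCurve(
            group=str(group),
            days=per_day.index.to_numpy(),
            area_mean=per_day["area_mean"].to_numpy(),
            area_sd=per_day["area_sd"].to_numpy(),
            closure_mean=per_day["closure_mean"].to_numpy(),
            closure_sd=per_day["closure_sd"].to_numpy(),
            n=per_day["n"].to_numpy(),
        )
    return curves


def healing_curve_frame(curves: dict[str, HealingCurve]) -> pd.DataFrame:
    """Tidy table of healing curves: one row per (group, day)."""
    rows = []
    for curve in curves.values():
        for i, day in enumerate(curve.days):
            rows.append(
                {
                    "group": curve.group,
                    "day": int(day),
                    "area_mean_mm2": curve.area_mean[i],
                    "area_sd_mm2": curve.area_sd[i],
                    "closure_mean_pct": curve.closure_mean[i],
                    "closure_sd_pct": curve.closure_sd[i],
                    "n": int(curve.n[i]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DosePlan:
    """A consistent (power, fluence, spot area, exposure time) quadruple."""

    power_mw: float
    fluence_j_cm2: float
    spot_area_cm2: float
    exposure_time_s: float

    def __post_init__(self) -> None:
        if min(self.power_mw, self.fluence_j_cm2, self.spot_area_cm2) <= 0:
            raise ValueError("power, fluence and spot area must be positive")
        lhs = self.fluence_j_cm2 * self.spot_area_cm2
        rhs = self.power_mw * 1e-3 * self.exposure_time_s
        if not np.isclose(lhs, rhs, rtol=1e-9):
            raise ValueError(
                f"inconsistent dose plan: fluence*area={lhs} J != power*time={rhs} J"
            )


def compute_exposure_time(
    fluence_j_cm2: float, power_mw: float, spot_area_cm2: float
) -> float:
    """Seconds needed to deliver a fluence with a CW source over a spot.

    ``t = fluence * spot_area / power``; strictly linear in fluence, so a
    4x fluence at fixed power takes exactly 4x as long.
    """
    if min(fluence_j_cm2, power_mw, spot_area_cm2) <= 0:
        raise ValueError("fluence, power and spot area must be positive")
    return fluence_j_cm2 * spot_area_cm2 / (power_mw * 1e-3)


def spot_area_from_exposure(
    fluence_j_cm2: float, power_mw: float, exposure_time_s: float
) -> float:
    """Back-solve the illuminated spot area (cm^2) from a known dose triple."""
    if min(fluence_j_cm2, power_mw, exposure_time_s) <= 0:
        raise ValueError("all dose quantities must be positive")
    return power_mw * 1e-3 * exposure_time_s / fluence_j_cm2
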