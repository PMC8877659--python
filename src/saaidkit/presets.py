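"""Named synthetic presets emulating healthy skin and wound-healing stages.

The SAAID-by-depth shapes follow the qualitative course of dermal wound
repair as seen by two-photon imaging on a 0-80 um grid: healthy papillary
dermis shows a mildly negative index at intermediate depth that rises to
about +0.3 at 80 um where collagen dominates; an early wound (days 1-3) is
collagen-poor and stays negative throughout; by day 7 a deep trough of
about -0.4 near 40 um forms with recovery to about +0.2 at 80 um; by day 14
the profile approaches the healthy shape (trough about -0.35 near 25 um,
+0.3 at 80 um). Fibre coherence rises in parallel, from disorganised
early-granulation collagen (0.1) to aligned, cross-linked fibres (0.9).

Healing presets give single-exponential area-decay parameters per treatment
group for a 5 mm excisional wound (about 20 mm^2): an untreated control
closing ~90% by day 14 and photodynamically stimulated groups closing
faster, the 4 J/cm^2 doses faster than the 1 J/cm^2 doses.
"""

from __future__ import annotations

import numpy as np

from .synthetic import HealingModelParams, SyntheticTruth

__all__ = [
    "SAAID_PRESET_KNOTS",
    "saaid_preset",
    "truth_preset",
    "HEALING_PRESETS",
    "healing_preset",
]

#: Piecewise-linear (depth um, SAAID) knots per condition.
SAAID_PRESET_KNOTS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "healthy": ((0.0, 25.0, 55.0, 80.0), (0.0, -0.30, -0.05, 0.30)),
    "day1": ((0.0, 40.0, 80.0), (-0.05, -0.35, -0.10)),
    "day3": ((0.0, 40.0, 80.0), (-0.05, -0.32, 0.0)),
    "day7": ((0.0, 40.0, 80.0), (0.0, -0.40, 0.20)),
    "day14": ((0.0, 25.0, 80.0), (0.0, -0.35, 0.30)),
}

_COHERENCE = {"healthy": 0.9, "day1": 0.1, "day3": 0.3, "day7": 0.6, "day14": 0.9}


def saaid_preset(name: str):
    """Return the (depths, values) knot table of a named SAAID profile."""
    try:
        knots = SAAID_PRESET_KNOTS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(SAAID_PRESET_KNOTS)}"
        ) from None
    return tuple(np.asarray(k, dtype=float) for k in knots)


def truth_preset(name: str, seed: int = 0, **overrides) -> SyntheticTruth:
    """Build a :class:`SyntheticTruth` for a named condition.

    Keyword overrides are passed straight to ``SyntheticTruth`` (e.g. a
    different noise model or fibre density).
    """
    params = dict(
        target_saaid_profile=saaid_preset(name),
        fiber_coherence=_COHERENCE[name],
        seed=seed,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


#: Exponential closure rates per day, from ln(S0/S14)/14 on typical group
#: courses of a 5 mm murine excisional wound under low-dose phototherapy.
HEALING_PRESETS: dict[str, HealingModelParams] = {
    "control": HealingModelParams(S0_mean=20.8, S0_sd=1.4, closure_rate=0.168),
    "ala_1jcm2": HealingModelParams(S0_mean=20.0, S0_sd=0.8, closure_rate=0.220),
    "ala_4jcm2": HealingModelParams(S0_mean=20.4, S0_sd=0.6, closure_rate=0.241),
    "mb_1jcm2": HealingModelParams(S0_mean=21.6, S0_sd=0.5, closure_rate=0.216),
    "mb_4jcm2": HealingModelParams(S0_mean=20.0, S0_sd=1.1, closure_rate=0.313),
}


def healing_preset(name: str, **overrides) -> HealingModelParams:
    """Return a named healing parameter set, optionally overridden."""
    try:
        base = HEALING_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(HEALING_PRESETS)}"
        ) from None
    if not overrides:
        return base
    from dataclasses import replace

    return replace(base, **overrides)
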