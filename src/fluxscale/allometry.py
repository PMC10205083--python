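"""Small allometric (Kleiber) scaling helpers.

Whole-body metabolic rate scales roughly with mass^(3/4), so the rate
per gram of tissue falls as mass increases.  These helpers express the
two bookkeeping quantities used throughout the screen: the per-mass
scaling factor between two organisms and the body-mass fold range of a
species panel.
"""

from __future__ import annotations

__all__ = ["per_mass_scaling_factor", "mass_fold_range", "kleiber_rate_ratio",
           "DEFAULT_BODY_MASS_G"]

#: Adult body masses (grams) of the five screened species.
DEFAULT_BODY_MASS_G = {
    "mouse": 30.0,
    "rat": 300.0,
    "monkey": 8_000.0,
    "human": 70_000.0,
    "cattle": 900_000.0,
}


def per_mass_scaling_factor(mass_ratio: float, rate_ratio: float) -> float:
    """Fold reduction of metabolic rate per gram between two organisms.

    Given that organism B is ``mass_ratio`` times heavier than A but its
    whole-body rate is only ``rate_ratio`` times higher, the rate per
    gram scales down by mass_ratio / rate_ratio (e.g. a 25-million-fold
    heavier animal spending only 20-thousand-fold more energy runs 1250
    times slower per gram).
    """
    if mass_ratio <= 0 or rate_ratio <= 0:
        raise ValueError("ratios must be positive")
    return mass_ratio / rate_ratio


def mass_fold_range(body_mass_g: dict[str, float]) -> float:
    """Largest-to-smallest body-mass ratio of a species panel."""
    masses = list(body_mass_g.values())
    if not masses or min(masses) <= 0:
        raise ValueError("need positive body masses")
    return max(masses) / min(masses)


def kleiber_rate_ratio(mass_ratio: float, exponent: float = 0.75) -> float:
    """Whole-body rate ratio predicted by a power-law scaling exponent."""
    if mass_ratio <= 0:
        raise ValueError("mass ratio must be positive")
    return mass_ratio ** exponent
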