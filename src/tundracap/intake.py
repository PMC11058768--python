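"""Forage intake requirements from body mass.

Daily dry-matter intake of a large herbivore is estimated by the widely used
2%-of-body-mass rule; annual need follows from a 365-day year.  For the
reference megaherbivore (an adult male woolly mammoth proxy at 3.9–5.2 t)
this yields 78–104 kg of dry forage per day, i.e. 28–38 t per year after
rounding.  Downstream carrying-capacity arithmetic always uses the unrounded
annual figure; rounding is presentation-only.

Note the bound convention: the HIGH body mass gives the LOWER density bound
(a heavier animal needs more forage), and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HerbivoreParams", "daily_intake", "annual_intake_tonnes",
           "annual_need_tonnes", "round_half_up"]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class HerbivoreParams:
    """Body-mass range and allometric constants of the modelled herbivore.

    Defaults describe an adult male woolly mammoth of the North Siberian
    form: body mass 3,900–5,200 kg with 4,550 kg as reference mean, 2%
    dry-matter intake, and Damuth's-law coefficients
    log10 D = −0.75 · log10 W + 4.23 (W in grams, D in km⁻²).
    """

    body_mass_low_kg: float = 3900.0
    body_mass_high_kg: float = 5200.0
    body_mass_ref_kg: float = 4550.0
    dmi_rate: float = 0.02
    damuth_slope: float = -0.75
    damuth_intercept: float = 4.23

    def __post_init__(self) -> None:
        if not (0 < self.body_mass_low_kg <= self.body_mass_ref_kg
                <= self.body_mass_high_kg):
            raise ValueError("require 0 < low <= ref <= high body mass")
        if not 0 < self.dmi_rate < 1:
            raise ValueError("dmi_rate must be in (0, 1)")


def daily_intake(body_mass_kg: float, dmi_rate: float = 0.02) -> float:
    """Daily dry-forage requirement (kg day⁻¹) as ``dmi_rate`` × body mass."""
    if body_mass_kg < 0:
        raise ValueError("body mass must be non-negative")
    if not 0 < dmi_rate < 1:
        raise ValueError("dmi_rate must be in (0, 1)")
    return body_mass_kg * dmi_rate


def annual_intake_tonnes(daily_kg: float) -> float:
    """Annual dry-forage requirement (t yr⁻¹), unrounded (365-day year)."""
    if daily_kg < 0:
        raise ValueError("daily intake must be non-negative")
    return daily_kg * DAYS_PER_YEAR / 1000.0


def annual_need_tonnes(body_mass_kg: float, dmi_rate: float = 0.02) -> float:
    """Convenience: unrounded annual need (t yr⁻¹) straight from body mass."""
    return annual_intake_tonnes(daily_intake(body_mass_kg, dmi_rate))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at *decimals*, for printed-value display.

    Banker's rounding (Python's built-in) would turn 0.5 ties the wrong way
    for comparison with conventionally rounded published figures.
    """
    import decimal

    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
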