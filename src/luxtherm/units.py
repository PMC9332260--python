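"""Laboratory unit conversions used when preparing assay solutions."""

from __future__ import annotations

SUCROSE_MOLAR_MASS = 342.30  # g/mol
SUCROSE_30WT_DENSITY = 1.127  # g/mL at 20 C, literature value for 30 wt%

# extinction coefficients used for concentration determination (M^-1 cm^-1)
EPSILON_FMN_445 = 12_400.0
EPSILON_LUCIFERASE_280 = 80_000.0


def concentration_from_absorbance(a: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Beer-Lambert concentration c = A/(epsilon*l) in mol/L."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    if a < 0:
        raise ValueError("absorbance cannot be negative")
    return a / (epsilon * path_cm)


def sucrose_molarity(
    wt_fraction: float,
    density_g_per_ml: float = SUCROSE_30WT_DENSITY,
    molar_mass: float = SUCROSE_MOLAR_MASS,
) -> float:
    """Molarity of a sucrose solution given its weight fraction.

    c = w * rho * 1000 / M  (mol/L).  With the default 30 wt% solution
    density this gives 0.99 M for w = 0.30.
    """
    if not 0 <= wt_fraction < 1:
        raise ValueError("weight fraction must lie in [0, 1)")
    if density_g_per_ml <= 0 or molar_mass <= 0:
        raise ValueError("density and molar mass must be positive")
    return wt_fraction * density_g_per_ml * 1000.0 / molar_mass
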