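"""Body-surface-area dosing and unit conversions for carboplatin.

Intraperitoneal carboplatin is dosed per square metre of body surface.
For pigs the allometric surface-area formula is

    SA = 0.0970 * W ** 0.633        (SA in m², W body weight in kg)

so an 800 mg/m² prescription for a 71–83 kg animal works out to roughly
1,150–1,270 mg.  Human BSA formulas (DuBois, Mosteller) and AUC-targeted
Calvert dosing are out of scope.
"""

from __future__ import annotations

import pandas as pd

from .study_design import StudyConfig

__all__ = [
    "BSA_COEFFICIENT",
    "BSA_EXPONENT",
    "CARBOPLATIN_MOLAR_MASS",
    "body_surface_area",
    "carboplatin_dose",
    "micromolar_to_ug_per_ml",
    "dose_table",
]

BSA_COEFFICIENT = 0.0970
BSA_EXPONENT = 0.633

#: Carboplatin C6H12N2O4Pt, g/mol (standard chemistry reference value).
CARBOPLATIN_MOLAR_MASS = 371.25


def body_surface_area(weight_kg: float) -> float:
    """Porcine body surface area in m² from body weight in kg."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return BSA_COEFFICIENT * weight_kg**BSA_EXPONENT


def carboplatin_dose(weight_kg: float, dose_per_m2: float) -> float:
    """Total dose in mg for a BSA-based prescription (mg/m²).

    Returns the exact product; round to the nearest mg for reporting.
    """
    if dose_per_m2 < 0:
        raise ValueError("dose_per_m2 must be non-negative")
    return dose_per_m2 * body_surface_area(weight_kg)


def micromolar_to_ug_per_ml(conc_um: float, molar_mass_g_per_mol: float = CARBOPLATIN_MOLAR_MASS) -> float:
    """Convert µmol/L to µg/mL: conc * M / 1000."""
    if conc_um <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return conc_um * molar_mass_g_per_mol / 1000.0


def dose_table(config: StudyConfig) -> pd.DataFrame:
    """Per-animal dosing table: animal_id, weight_kg, surface_area_m2, dose_mg.

    dose_mg is rounded to the nearest integer mg, as doses are reported.
    """
    rows = []
    for animal_id, w in zip(config.animal_ids, config.weights_kg):
        sa = body_surface_area(w)
        rows.append(
            {
                "animal_id": animal_id,
                "weight_kg": w,
                "surface_area_m2": sa,
                "dose_mg": round(config.dose_per_m2 * sa),
            }
        )
    return pd.DataFrame(rows)
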