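"""Per-catheter relative recovery from retrodialysis-by-drug samples.

A microdialysis catheter never equilibrates fully with the surrounding
tissue, so the dialysate holds only a fraction of the true free
concentration — the relative recovery (RR).  Retrodialysis estimates RR
by running a known drug concentration through the catheter and measuring
the fraction lost to tissue:

    RR = 100 * (1 - C_dialysate / C_perfusate)      (percent)

Each catheter is calibrated from the mean of two 40-min retrodialysis
samples collected after the study period.  Catheters whose RR falls
outside (0, 100] — e.g. dialysate exceeding perfusate, an apparent
negative recovery — are flagged invalid and excluded wholesale, along
with all their study samples.  No fallback to a compartment-mean RR is
attempted.  Alternative calibration schemes (no-net-flux,
near-equilibrium dialysis) are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "RecoveryPair",
    "CatheterRecovery",
    "relative_recovery",
    "validate_recovery",
    "catheter_recovery",
    "calibrate_study",
]

RECOVERY_COLUMNS = ["animal_id", "compartment", "rr_percent", "valid", "reason"]


def relative_recovery(c_dialysate: float, c_perfusate: float) -> float:
    """RR (%) from one retrodialysis sample: 100 * (1 - Cdial/Cperf)."""
    if c_perfusate <= 0:
        raise ValueError("c_perfusate must be positive")
    if c_dialysate < 0:
        raise ValueError("c_dialysate must be non-negative")
    return 100.0 * (1.0 - c_dialysate / c_perfusate)


def validate_recovery(
    rr_percent: float, bounds: tuple[float, float] = (0.0, 100.0)
) -> tuple[bool, str]:
    """QC gate on an RR estimate.

    RR must lie in (lower, upper] — the default (0, 100].  RR <= 0 means
    the dialysate matched or exceeded the perfusate (apparent negative
    recovery), which is treated as catheter malfunction.
    """
    lower, upper = bounds
    if not math.isfinite(rr_percent):
        return False, "non-finite recovery"
    if rr_percent <= lower:
        return False, f"recovery {rr_percent:.1f}% <= {lower:g}% (apparent negative recovery)"
    if rr_percent > upper:
        return False, f"recovery {rr_percent:.1f}% > {upper:g}%"
    return True, ""


@dataclass(frozen=True)
class RecoveryPair:
    """Two retrodialysis replicates for one catheter."""

    animal_id: str
    compartment: str
    dialysate_1: Optional[float]
    dialysate_2: Optional[float]
    perfusate: float

    def __post_init__(self) -> None:
        if self.perfusate <= 0:
            raise ValueError("perfusate concentration must be positive")


@dataclass(frozen=True)
class CatheterRecovery:
    """Calibration result: RR (%) with validity flag and reason."""

    animal_id: str
    compartment: str
    rr_percent: float
    valid: bool
    reason: str = ""


def _is_missing(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def catheter_recovery(
    pair: RecoveryPair, bounds: tuple[float, float] = (0.0, 100.0)
) -> CatheterRecovery:
    """Calibrate one catheter: mean of the two per-replicate RR values."""
    if _is_missing(pair.dialysate_1) or _is_missing(pair.dialysate_2):
        return CatheterRecovery(
            pair.animal_id, pair.compartment, float("nan"), False, "missing replicate"
        )
    rr = 0.5 * (
        relative_recovery(pair.dialysate_1, pair.perfusate)
        + relative_recovery(pair.dialysate_2, pair.perfusate)
    )
    valid, reason = validate_recovery(rr, bounds)
    return CatheterRecovery(pair.animal_id, pair.compartment, rr, valid, reason)


def calibrate_study(
    calibration: pd.DataFrame, bounds: tuple[float, float] = (0.0, 100.0)
) -> pd.DataFrame:
    """Calibrate every catheter in a tidy calibration table.

    Expects columns animal_id, compartment, replicate, perfusate_conc_ug_per_ml,
    dialysate_conc_ug_per_ml (two replicates per catheter); returns one row
    per catheter: animal_id, compartment, rr_percent, valid, reason.
    Catheters with a missing replicate are reported invalid, not dropped.
    """
    rows = []
    for (animal_id, comp), grp in calibration.groupby(
        ["animal_id", "compartment"], sort=True
    ):
        if len(grp) != 2:
            rows.append(
                CatheterRecovery(animal_id, comp, float("nan"), False, "missing replicate")
            )
            continue
        grp = grp.sort_values("replicate")
        pair = RecoveryPair(
            animal_id=animal_id,
            compartment=comp,
            dialysate_1=float(grp["dialysate_conc_ug_per_ml"].iloc[0]),
            dialysate_2=float(grp["dialysate_conc_ug_per_ml"].iloc[1]),
            perfusate=float(grp["perfusate_conc_ug_per_ml"].iloc[0]),
        )
        rows.append(catheter_recovery(pair, bounds))
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in rows],
            "compartment": [r.compartment for r in rows],
            "rr_percent": [r.rr_percent for r in rows],
            "valid": [r.valid for r in rows],
            "reason": [r.reason for r in rows],
        },
        columns=RECOVERY_COLUMNS,
    )
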