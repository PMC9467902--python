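"""RR-correction of dialysates into free tissue concentration profiles.

A dialysate concentration is only the recovered fraction of the free
tissue concentration, so the absolute concentration is

    C_tissue = 100 * C_dialysate / RR        (RR in percent)

Corrected values are timestamped at the midpoint of their sampling
interval and assembled into per-catheter concentration-time profiles.
Plasma samples pass through unchanged (venous blood measures free drug
directly) but share the midpoint timestamps, since blood was drawn at the
dialysate interval midpoints.

Below-LOQ samples are excluded from profiles by default but counted; an
LOQ/2 imputation policy is available for sensitivity analysis.  Profiles
never interpolate or fill gaps — the NCA operates on observed points only.
Protein-binding correction is a non-goal: microdialysis already samples
the free fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .calibration import CatheterRecovery

__all__ = [
    "ConcentrationTimeProfile",
    "correct_concentration",
    "build_profile",
    "correct_study",
    "LOQ_POLICIES",
]

LOQ_POLICIES = ("exclude", "halve")

PROFILE_COLUMNS = ["animal_id", "compartment", "midpoint_min", "conc_ug_per_ml", "censored"]


def correct_concentration(c_dialysate: float, rr_percent: float) -> float:
    """Absolute free concentration from a dialysate value and RR (%)."""
    if rr_percent <= 0:
        raise ValueError(
            "rr_percent must be positive; catheters with non-positive recovery "
            "should have been excluded during calibration"
        )
    if c_dialysate < 0:
        raise ValueError("c_dialysate must be non-negative")
    return 100.0 * c_dialysate / rr_percent


@dataclass
class ConcentrationTimeProfile:
    """RR-corrected concentration-time points for one animal × compartment.

    ``points`` has columns midpoint_min, conc_ug_per_ml, censored and is
    sorted by time.  Bookkeeping fields record how many samples went in,
    how many were censored, and how many were excluded from the profile;
    an empty profile carries the reason.
    """

    animal_id: str
    compartment: str
    points: pd.DataFrame
    n_samples_in: int
    n_censored: int
    n_excluded: int
    empty_reason: str = ""

    @property
    def is_empty(self) -> bool:
        return len(self.points) == 0


def build_profile(
    samples: pd.DataFrame,
    recovery: Union[CatheterRecovery, float],
    loq_policy: str = "exclude",
    loq_ug_per_ml: float = 0.100,
) -> ConcentrationTimeProfile:
    """Build one catheter's profile from its dialysate samples.

    ``recovery`` is either a calibration result or an RR percentage;
    plasma callers pass 100 (no correction).  Censored samples follow
    ``loq_policy``: "exclude" drops them (counted), "halve" includes them
    at LOQ/2 with the censored flag kept.
    """
    if loq_policy not in LOQ_POLICIES:
        raise ValueError(f"unknown loq_policy {loq_policy!r}; choose from {LOQ_POLICIES}")
    if samples.empty:
        raise ValueError("no samples supplied")
    animals = samples["animal_id"].unique()
    comps = samples["compartment"].unique()
    if len(animals) != 1 or len(comps) != 1:
        raise ValueError("samples must belong to a single animal × compartment")
    animal_id, comp = str(animals[0]), str(comps[0])

    if isinstance(recovery, CatheterRecovery):
        if not recovery.valid:
            raise ValueError(
                f"recovery for {animal_id}/{comp} is invalid ({recovery.reason}); "
                "excluded catheters have no profile"
            )
        rr = recovery.rr_percent
    else:
        rr = float(recovery)

    n_in = len(samples)
    censored_mask = samples["below_loq"].astype(bool).to_numpy()
    n_censored = int(censored_mask.sum())

    work = samples.sort_values("midpoint_min")
    cens = work["below_loq"].astype(bool).to_numpy()
    conc = work["conc_ug_per_ml"].to_numpy(dtype=float)
    def _correct(values: np.ndarray) -> np.ndarray:
        if rr == 100.0:  # full recovery: exact identity (plasma passthrough)
            return values.copy()
        return np.array([correct_concentration(c, rr) for c in values])

    if loq_policy == "exclude":
        keep = ~cens
        times = work["midpoint_min"].to_numpy(dtype=float)[keep]
        values = _correct(conc[keep])
        flags = np.zeros(keep.sum(), dtype=int)
        n_excluded = n_censored
    else:  # halve: impute LOQ/2 on the dialysate scale, then correct
        times = work["midpoint_min"].to_numpy(dtype=float)
        imputed = np.where(cens, loq_ug_per_ml / 2.0, conc)
        values = _correct(imputed)
        flags = cens.astype(int)
        n_excluded = 0

    if len(np.unique(times)) != len(times):
        raise ValueError("duplicate midpoint times within one catheter")
    points = pd.DataFrame(
        {
            "animal_id": animal_id,
            "compartment": comp,
            "midpoint_min": times,
            "conc_ug_per_ml": values,
            "censored": flags,
        },
        columns=PROFILE_COLUMNS,
    )
    reason = "" if len(points) else "all samples censored or excluded"
    return ConcentrationTimeProfile(
        animal_id=animal_id,
        compartment=comp,
        points=points,
        n_samples_in=n_in,
        n_censored=n_censored,
        n_excluded=n_excluded,
        empty_reason=reason,
    )


def correct_study(
    samples: pd.DataFrame,
    recovery: pd.DataFrame,
    loq_policy: str = "exclude",
    loq_ug_per_ml: float = 0.100,
) -> pd.DataFrame:
    """RR-correct a whole study into a tidy profile table.

    Dialysate catheters are matched to their calibration rows; catheters
    with an invalid (or missing) recovery are excluded wholesale.  Plasma
    samples pass through uncorrected.  Returns columns animal_id,
    compartment, midpoint_min, conc_ug_per_ml, censored, sorted by
    animal, compartment, time.
    """
    rec_index = {
        (str(r.animal_id), str(r.compartment)): r
        for r in recovery.itertuples(index=False)
    }
    frames: list[pd.DataFrame] = []
    for (animal_id, comp, stype), grp in samples.groupby(
        ["animal_id", "compartment", "sample_type"], sort=True
    ):
        if stype == "plasma":
            rr: Union[CatheterRecovery, float] = 100.0
        else:
            rec = rec_index.get((str(animal_id), str(comp)))
            if rec is None or not rec.valid:
                continue  # whole-catheter exclusion
            rr = float(rec.rr_percent)
        profile = build_profile(grp, rr, loq_policy=loq_policy, loq_ug_per_ml=loq_ug_per_ml)
        if not profile.is_empty:
            frames.append(profile.points)
    if not frames:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["animal_id", "compartment", "midpoint_min"], ignore_index=True
    )
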