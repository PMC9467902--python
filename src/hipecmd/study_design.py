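"""Study layout shared by the simulator and every analysis stage.

The default design emulates a porcine HIPEC microdialysis experiment:
eight animals each carry eight microdialysis catheters (liver,
hepatoduodenal ligament at 1 mm and 4 mm, peritoneum, rectum at 1 mm and
4 mm, mesentery, bladder wall).  Dialysate is collected over 8 h from
HIPEC initiation — 30-min intervals for the first 4 h, 60-min intervals
thereafter — giving 12 samples per catheter.  Because a dialysate pools
drug over its whole collection window, every measured concentration is
assigned to the midpoint of its sampling interval; this module owns that
convention.

Time is measured in minutes from HIPEC initiation (t = 0 is the start of
perfusion) throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SamplingSchedule",
    "CatheterEntry",
    "CatheterLedger",
    "StudyConfig",
    "DEFAULT_SITES",
    "PLASMA",
    "TISSUE_COMPARTMENTS",
    "OBSERVED_CATHETER_LOSSES",
    "CATHETER_STATUSES",
    "build_schedule",
    "interval_midpoint",
    "build_ledger",
    "apply_qc",
]

CATHETER_STATUSES = frozenset({"ok", "malfunction", "displaced"})

#: Catheter sites of the default design: (compartment, depth_mm).  Depth is
#: recorded only where the design places paired superficial/profound
#: catheters; the flat compartment name is the join key everywhere.
DEFAULT_SITES: tuple[tuple[str, Optional[float]], ...] = (
    ("liver", None),
    ("hepatoduodenal_superficial", 1.0),
    ("hepatoduodenal_profound", 4.0),
    ("peritoneum", None),
    ("rectum_superficial", 1.0),
    ("rectum_profound", 4.0),
    ("mesentery", None),
    ("bladder_wall", None),
)

TISSUE_COMPARTMENTS: tuple[str, ...] = tuple(name for name, _ in DEFAULT_SITES)

#: Plasma is sampled by venous draws at the dialysate interval midpoints and
#: is analysed as its own compartment (no catheter, no recovery correction).
PLASMA = "plasma"

#: Catheter losses observed in the porcine experiment the default design
#: emulates: 3 malfunctions (1 peritoneum, 2 rectum profound) and 8
#: displacements (2 rectum superficial, 1 rectum profound, 5 bladder wall),
#: leaving 53 of 64 catheters active.  The original report does not identify
#: which animals lost catheters, so losses are assigned to the
#: lowest-numbered animals deterministically.
OBSERVED_CATHETER_LOSSES: tuple[tuple[str, str, str], ...] = (
    ("pig01", "peritoneum", "malfunction"),
    ("pig01", "rectum_profound", "malfunction"),
    ("pig02", "rectum_profound", "malfunction"),
    ("pig01", "rectum_superficial", "displaced"),
    ("pig02", "rectum_superficial", "displaced"),
    ("pig03", "rectum_profound", "displaced"),
    ("pig01", "bladder_wall", "displaced"),
    ("pig02", "bladder_wall", "displaced"),
    ("pig03", "bladder_wall", "displaced"),
    ("pig04", "bladder_wall", "displaced"),
    ("pig05", "bladder_wall", "displaced"),
)


def interval_midpoint(interval: tuple[float, float]) -> float:
    """Midpoint of a sampling interval ``(start_min, end_min)``.

    A dialysate integrates drug over its whole collection window, so its
    concentration is reported at the interval midpoint.
    """
    start, end = float(interval[0]), float(interval[1])
    if not end > start:
        raise ValueError(f"degenerate interval ({start}, {end}): end must exceed start")
    return (start + end) / 2.0


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered, contiguous dialysate collection intervals.

    Intervals are ``(start_min, end_min)`` pairs partitioning ``[0, end]``
    exactly: each start equals the previous end, the first start is 0, and
    times are strictly increasing.
    """

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        ivs = tuple((float(s), float(e)) for s, e in self.intervals)
        if ivs[0][0] != 0.0:
            raise ValueError("first interval must start at time 0")
        prev_end = 0.0
        for start, end in ivs:
            if not end > start:
                raise ValueError(f"interval ({start}, {end}) is not increasing")
            if start != prev_end:
                raise ValueError(
                    f"intervals must be contiguous: gap/overlap at {start} (expected {prev_end})"
                )
            prev_end = end
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def end_min(self) -> float:
        return self.intervals[-1][1]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([interval_midpoint(iv) for iv in self.intervals])

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a table: interval_index, start_min, end_min, midpoint_min."""
        return pd.DataFrame(
            {
                "interval_index": np.arange(len(self.intervals)),
                "start_min": [s for s, _ in self.intervals],
                "end_min": [e for _, e in self.intervals],
                "midpoint_min": self.midpoints,
            }
        )


def _check_divisible(span: float, step: float, label: str) -> int:
    n = span / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{label} span of {span} min is not divisible by step {step} min")
    return int(round(n))


def build_schedule(
    fine_step_min: float = 30.0,
    coarse_step_min: float = 60.0,
    switch_min: float = 240.0,
    end_min: float = 480.0,
) -> SamplingSchedule:
    """Build the two-phase sampling schedule.

    Fine intervals of ``fine_step_min`` cover ``[0, switch_min]`` and coarse
    intervals of ``coarse_step_min`` cover ``[switch_min, end_min]``.  The
    defaults (30, 60, 240, 480) give the 12-sample design: midpoints
    15, 45, ..., 225 then 270, 330, 390, 450 min.
    """
    if not (0 < fine_step_min <= switch_min <= end_min):
        raise ValueError(
            "require 0 < fine_step_min <= switch_min <= end_min, got "
            f"({fine_step_min}, {switch_min}, {end_min})"
        )
    if coarse_step_min <= 0:
        raise ValueError("coarse_step_min must be positive")
    n_fine = _check_divisible(switch_min, fine_step_min, "fine")
    n_coarse = _check_divisible(end_min - switch_min, coarse_step_min, "coarse")
    bounds = np.concatenate(
        [
            np.linspace(0.0, switch_min, n_fine + 1),
            np.linspace(switch_min, end_min, n_coarse + 1)[1:],
        ]
    )
    intervals = tuple(zip(bounds[:-1], bounds[1:]))
    return SamplingSchedule(intervals)


@dataclass(frozen=True)
class CatheterEntry:
    """One microdialysis catheter: an animal × compartment placement."""

    animal_id: str
    compartment: str
    depth_mm: Optional[float] = None
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status not in CATHETER_STATUSES:
            raise ValueError(f"unknown catheter status {self.status!r}")


@dataclass(frozen=True)
class CatheterLedger:
    """Accounting of every catheter in the study and its QC status.

    QC never removes rows; displaced or malfunctioning catheters keep their
    entry with the corresponding status, and downstream stages consume only
    ``status == "ok"`` catheters.
    """

    entries: tuple[CatheterEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        keys = [(e.animal_id, e.compartment) for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate animal × compartment entries in ledger")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_ok(self) -> int:
        return sum(1 for e in self.entries if e.status == "ok")

    def ok_entries(self) -> tuple[CatheterEntry, ...]:
        return tuple(e for e in self.entries if e.status == "ok")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [e.animal_id for e in self.entries],
                "compartment": [e.compartment for e in self.entries],
                "depth_mm": [e.depth_mm for e in self.entries],
                "status": [e.status for e in self.entries],
            }
        )


def default_animal_ids(n_animals: int) -> list[str]:
    return [f"pig{i + 1:02d}" for i in range(n_animals)]


def build_ledger(
    n_animals: int,
    sites: Sequence[tuple[str, Optional[float]]] = DEFAULT_SITES,
    animal_ids: Optional[Sequence[str]] = None,
) -> CatheterLedger:
    """Full-design ledger: one ``status="ok"`` entry per animal × site."""
    if n_animals < 1:
        raise ValueError("n_animals must be at least 1")
    names = [name for name, _ in sites]
    if len(set(names)) != len(names):
        raise ValueError("duplicate site names in site table")
    if animal_ids is None:
        animal_ids = default_animal_ids(n_animals)
    elif len(animal_ids) != n_animals:
        raise ValueError("animal_ids length must equal n_animals")
    entries = tuple(
        CatheterEntry(animal_id=a, compartment=name, depth_mm=depth)
        for a in animal_ids
        for name, depth in sites
    )
    return CatheterLedger(entries)


def apply_qc(
    ledger: CatheterLedger,
    exclusions: Iterable[tuple[str, str, str]],
) -> CatheterLedger:
    """Mark catheters lost to malfunction or displacement.

    ``exclusions`` are ``(animal_id, compartment, status)`` triples with
    status ``malfunction`` or ``displaced``.  Excluded catheters are dropped
    wholesale downstream — no partial salvage of their samples.
    """
    index = {(e.animal_id, e.compartment): i for i, e in enumerate(ledger.entries)}
    entries = list(ledger.entries)
    for animal_id, compartment, status in exclusions:
        if status not in CATHETER_STATUSES - {"ok"}:
            raise ValueError(f"exclusion status must be malfunction/displaced, got {status!r}")
        key = (animal_id, compartment)
        if key not in index:
            raise KeyError(f"exclusion references unknown catheter {key}")
        entries[index[key]] = replace(entries[index[key]], status=status)
    return CatheterLedger(tuple(entries))


@dataclass
class StudyConfig:
    """Configuration of one synthetic HIPEC microdialysis study.

    Defaults reproduce the porcine design: 8 animals of 71–83 kg dosed at
    800 mg/m² carboplatin, 90-min perfusion, 12-sample schedule, assay LOQ
    of 0.100 µg/mL, retrodialysis perfusate of 100 µg/mL, and catheter
    dropout probabilities matching the observed loss rates (3/64
    malfunction, 8/64 displacement).  The flow rate is informational
    metadata; the simulator does not model perfusate transport.
    """

    n_animals: int = 8
    weights_kg: Optional[tuple[float, ...]] = None
    dose_per_m2: float = 800.0
    hipec_duration_min: float = 90.0
    fine_step_min: float = 30.0
    coarse_step_min: float = 60.0
    switch_min: float = 240.0
    end_min: float = 480.0
    loq_ug_per_ml: float = 0.100
    calibration_perfusate_ug_per_ml: float = 100.0
    flow_rate_ul_per_min: float = 1.0
    p_malfunction: float = 3.0 / 64.0
    p_displaced: float = 8.0 / 64.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be at least 1")
        if self.weights_kg is None:
            # evenly spaced over the 71-83 kg range of the emulated herd
            self.weights_kg = tuple(np.round(np.linspace(71.0, 83.0, self.n_animals), 1))
        else:
            self.weights_kg = tuple(float(w) for w in self.weights_kg)
        if len(self.weights_kg) != self.n_animals:
            raise ValueError("weights_kg length must equal n_animals")
        if any(w <= 0 for w in self.weights_kg):
            raise ValueError("all body weights must be positive")
        for name in ("dose_per_m2", "hipec_duration_min", "loq_ug_per_ml",
                     "calibration_perfusate_ug_per_ml", "flow_rate_ul_per_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.p_malfunction and 0 <= self.p_displaced
                and self.p_malfunction + self.p_displaced <= 1):
            raise ValueError("dropout probabilities must be in [0, 1] and sum to at most 1")
        # validates the schedule parameters eagerly
        self.schedule()

    def schedule(self) -> SamplingSchedule:
        return build_schedule(
            self.fine_step_min, self.coarse_step_min, self.switch_min, self.end_min
        )

    @property
    def animal_ids(self) -> list[str]:
        return default_animal_ids(self.n_animals)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)
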