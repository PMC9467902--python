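"""Synthetic HIPEC microdialysis studies with closed-form oracles.

Every tissue (and plasma) follows a Bateman-type double-exponential
concentration curve

    C(t) = A * (exp(-k_elim * t) - exp(-k_uptake * t)),   k_uptake > k_elim > 0,

which rises from zero at HIPEC initiation, peaks at
Tmax = ln(k_uptake / k_elim) / (k_uptake - k_elim) — which can fall well
after the 90-min perfusion, as observed in tissue — and decays with
terminal rate k_elim.  Cmax, Tmax, AUC and the terminal half-life all have
closed forms, so the analytic truth is available for every simulated
dataset and the whole analysis pipeline can be checked against it.

What the simulator layers on top of the truth curves:

* dialysates average the curve over their collection interval (closed-form
  integral, no quadrature), then lose a per-catheter fraction of drug —
  the relative recovery, drawn from per-compartment truncated normals;
* multiplicative lognormal assay noise whose CV follows the LC-MS/MS
  intermediate-precision ladder (interpolated in log10 concentration);
* values below the 0.100 µg/mL LOQ are reported censored;
* whole catheters drop out (malfunction/displacement) with configurable
  probabilities;
* retrodialysis calibration pairs: two 40-min samples of drug lost from a
  100 µg/mL perfusate.

The default kinetics are calibrated so that per-compartment population
Cmax and Tmax sit at the centre of the envelope reported for the porcine
experiment (Cmax 10.6-26.0 µg/mL, Tmax 105-206 min).  A mechanistic
perfusate-depot ODE is deliberately out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .study_design import (
    PLASMA,
    CatheterLedger,
    CatheterEntry,
    SamplingSchedule,
    StudyConfig,
    TISSUE_COMPARTMENTS,
)

__all__ = [
    "TissueKinetics",
    "NoiseModel",
    "TrueCatheterState",
    "ClosedFormNCA",
    "SimTruth",
    "StudyData",
    "DEFAULT_PRECISION_LADDER",
    "DEFAULT_PEAK_TARGETS",
    "DEFAULT_RECOVERY_PARAMS",
    "true_concentration",
    "closed_form_nca",
    "interval_average",
    "kinetics_from_peak",
    "default_kinetics",
    "simulate_dialysate_series",
    "simulate_retrodialysis_pair",
    "simulate_study",
]

#: LC-MS/MS intermediate-precision ladder: (target µg/mL, CV %).
DEFAULT_PRECISION_LADDER: tuple[tuple[float, float], ...] = (
    (0.100, 20.8),
    (1.00, 11.1),
    (4.00, 9.7),
    (30.0, 3.5),
    (100.0, 6.8),
)

#: Per-compartment population (Cmax µg/mL, Tmax min) targets used to
#: calibrate the default kinetics; the envelope of the porcine study.
DEFAULT_PEAK_TARGETS: dict[str, tuple[float, float]] = {
    "liver": (13.0, 206.0),
    "hepatoduodenal_superficial": (15.4, 186.0),
    "hepatoduodenal_profound": (12.6, 178.0),
    "peritoneum": (26.0, 196.0),
    "rectum_superficial": (15.1, 175.0),
    "rectum_profound": (20.6, 205.0),
    "mesentery": (12.4, 197.0),
    "bladder_wall": (22.0, 197.0),
    PLASMA: (10.6, 105.0),
}

#: Per-compartment relative-recovery population parameters (mean %, SD %),
#: matching the retrodialysis calibrations of the emulated experiment.
DEFAULT_RECOVERY_PARAMS: dict[str, tuple[float, float]] = {
    "liver": (89.5, 4.6),
    "hepatoduodenal_superficial": (91.0, 8.2),
    "hepatoduodenal_profound": (88.1, 5.1),
    "peritoneum": (75.3, 11.9),
    "rectum_superficial": (93.1, 3.6),
    "rectum_profound": (87.0, 12.7),
    "mesentery": (75.2, 10.1),
    "bladder_wall": (78.7, 12.4),
}

SAMPLE_COLUMNS = [
    "animal_id",
    "compartment",
    "interval_start_min",
    "interval_end_min",
    "midpoint_min",
    "sample_type",
    "conc_ug_per_ml",
    "below_loq",
]

CALIBRATION_COLUMNS = [
    "animal_id",
    "compartment",
    "replicate",
    "perfusate_conc_ug_per_ml",
    "dialysate_conc_ug_per_ml",
]


@dataclass(frozen=True)
class TissueKinetics:
    """Double-exponential truth curve for one compartment.

    ``amplitude`` (µg/mL) scales the curve; ``k_uptake`` and ``k_elim``
    (1/min) are the rise and terminal decay rates, with
    ``k_uptake > k_elim`` strictly (the equal-rate limit is not supported;
    pick distinct rates).
    """

    compartment: str
    amplitude: float
    k_uptake: float
    k_elim: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not (self.k_uptake > self.k_elim > 0):
            raise ValueError("require k_uptake > k_elim > 0 (strictly)")


def true_concentration(kinetics: TissueKinetics, t_min):
    """Evaluate the truth curve at time(s) ``t_min`` (minutes, >= 0)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = kinetics.amplitude * (np.exp(-kinetics.k_elim * t) - np.exp(-kinetics.k_uptake * t))
    return float(out) if np.isscalar(t_min) else out


@dataclass(frozen=True)
class ClosedFormNCA:
    """Analytic NCA parameters of a truth curve over [0, t_last]."""

    cmax: float
    tmax: float
    auc_0_tlast: float
    half_life: float
    t_last: float


def closed_form_nca(kinetics: TissueKinetics, t_last: float) -> ClosedFormNCA:
    """Exact Cmax, Tmax, AUC over [0, t_last] and terminal half-life.

    Tmax = ln(ku/ke)/(ku-ke); AUC is the analytic integral of the two
    exponentials; half-life is ln(2)/k_elim.
    """
    if t_last <= 0:
        raise ValueError("t_last must be positive")
    ku, ke, a = kinetics.k_uptake, kinetics.k_elim, kinetics.amplitude
    tmax = math.log(ku / ke) / (ku - ke)
    cmax = true_concentration(kinetics, tmax)
    auc = a * ((1.0 - math.exp(-ke * t_last)) / ke - (1.0 - math.exp(-ku * t_last)) / ku)
    return ClosedFormNCA(
        cmax=cmax, tmax=tmax, auc_0_tlast=auc, half_life=math.log(2.0) / ke, t_last=t_last
    )


def interval_average(kinetics: TissueKinetics, interval: tuple[float, float]) -> float:
    """Mean of the truth curve over a collection interval, in closed form.

    This is what an ideal (noise-free, full-recovery) dialysate measures.
    """
    start, end = float(interval[0]), float(interval[1])
    if not end > start:
        raise ValueError(f"degenerate interval ({start}, {end})")
    if start < 0:
        raise ValueError("interval must start at non-negative time")
    ku, ke, a = kinetics.k_uptake, kinetics.k_elim, kinetics.amplitude
    width = end - start
    integral = a * (
        (math.exp(-ke * start) - math.exp(-ke * end)) / ke
        - (math.exp(-ku * start) - math.exp(-ku * end)) / ku
    )
    return integral / width


def kinetics_from_peak(
    compartment: str,
    cmax: float,
    tmax: float,
    uptake_ratio: float = 4.0,
) -> TissueKinetics:
    """Kinetics whose truth curve peaks exactly at (tmax, cmax).

    The rate ratio r = k_uptake / k_elim is fixed (default 4, a moderate
    rise-to-decay separation); then k_elim = ln(r) / ((r - 1) * tmax) and
    the amplitude is scaled to hit cmax.
    """
    if cmax <= 0 or tmax <= 0:
        raise ValueError("cmax and tmax must be positive")
    if uptake_ratio <= 1:
        raise ValueError("uptake_ratio must exceed 1")
    ke = math.log(uptake_ratio) / ((uptake_ratio - 1.0) * tmax)
    ku = uptake_ratio * ke
    peak_factor = math.exp(-ke * tmax) - math.exp(-ku * tmax)
    return TissueKinetics(
        compartment=compartment, amplitude=cmax / peak_factor, k_uptake=ku, k_elim=ke
    )


def default_kinetics(
    peak_targets: Mapping[str, tuple[float, float]] = DEFAULT_PEAK_TARGETS,
    uptake_ratio: float = 4.0,
) -> dict[str, TissueKinetics]:
    """Default per-compartment kinetics calibrated to the peak targets."""
    return {
        comp: kinetics_from_peak(comp, cmax, tmax, uptake_ratio)
        for comp, (cmax, tmax) in peak_targets.items()
    }


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal assay noise tied to a precision ladder.

    The CV (%) at a given concentration is interpolated linearly in
    log10(concentration) between the ladder points and clamped at the ends.
    Noise factors are lognormal with unit mean and that CV.
    """

    ladder: tuple[tuple[float, float], ...] = DEFAULT_PRECISION_LADDER
    loq_ug_per_ml: float = 0.100

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.ladder]
        cvs = [cv for _, cv in self.ladder]
        if any(c <= 0 for c in concs) or any(cv <= 0 for cv in cvs):
            raise ValueError("ladder concentrations and CVs must be positive")
        if list(concs) != sorted(concs):
            raise ValueError("ladder must be sorted by concentration")
        if self.loq_ug_per_ml <= 0:
            raise ValueError("LOQ must be positive")

    def cv_percent(self, conc_ug_per_ml):
        conc = np.maximum(np.asarray(conc_ug_per_ml, dtype=float), 1e-12)
        log_c = np.log10(conc)
        xs = np.log10([c for c, _ in self.ladder])
        ys = [cv for _, cv in self.ladder]
        return np.interp(log_c, xs, ys)

    def sigma(self, conc_ug_per_ml):
        """Lognormal sigma giving the ladder CV at this concentration."""
        cv = np.asarray(self.cv_percent(conc_ug_per_ml)) / 100.0
        return np.sqrt(np.log1p(cv**2))

    def factors(self, rng: np.random.Generator, conc_ug_per_ml) -> np.ndarray:
        """Unit-mean lognormal noise factors, one per concentration."""
        conc = np.atleast_1d(np.asarray(conc_ug_per_ml, dtype=float))
        sig = self.sigma(conc)
        z = rng.standard_normal(conc.shape)
        return np.exp(sig * z - 0.5 * sig**2)


@dataclass(frozen=True)
class TrueCatheterState:
    """Ground truth for one catheter: its recovery and failure status."""

    animal_id: str
    compartment: str
    true_rr_percent: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if not (0 < self.true_rr_percent <= 100):
            raise ValueError("true_rr_percent must lie in (0, 100]")


@dataclass
class SimTruth:
    """Everything needed to recompute the simulated observables.

    Holds the seeded config, per-compartment kinetics with their analytic
    NCA parameters (evaluated at the last scheduled midpoint), and the
    per-catheter true recoveries and statuses.
    """

    seed: int
    config: StudyConfig
    kinetics: dict[str, TissueKinetics]
    catheter_states: list[TrueCatheterState]
    closed_form: dict[str, ClosedFormNCA]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "kinetics": {k: asdict(v) for k, v in self.kinetics.items()},
            "catheter_states": [asdict(s) for s in self.catheter_states],
            "closed_form": {k: asdict(v) for k, v in self.closed_form.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class StudyData:
    """One simulated study: tidy samples, calibration pairs, ledger, truth."""

    samples: pd.DataFrame
    calibration: pd.DataFrame
    ledger: CatheterLedger
    truth: SimTruth


def _censor(conc: np.ndarray, loq: float) -> tuple[np.ndarray, np.ndarray]:
    """Apply LOQ reporting: values below LOQ are withheld (set to the LOQ
    marker) and flagged, as an assay reports '<LOQ'."""
    below = conc < loq
    reported = np.where(below, loq, conc)
    return reported, below.astype(int)


def simulate_dialysate_series(
    kinetics: TissueKinetics,
    state: TrueCatheterState,
    schedule: SamplingSchedule,
    noise: Optional[NoiseModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the 12-sample dialysate series for one catheter.

    Each measured value is the interval average of the truth curve scaled
    by the catheter's true recovery fraction, times a lognormal assay-noise
    factor; values below the LOQ are reported censored.  Failed catheters
    yield no samples.
    """
    if state.status != "ok":
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    averages = np.array([interval_average(kinetics, iv) for iv in schedule])
    ideal = averages * (state.true_rr_percent / 100.0)
    if noise is not None:
        measured = ideal * noise.factors(rng, ideal)
        loq = noise.loq_ug_per_ml
    else:
        measured = ideal
        loq = 0.0
    reported, below = _censor(measured, loq) if noise is not None else (measured, np.zeros(len(measured), dtype=int))
    return pd.DataFrame(
        {
            "animal_id": state.animal_id,
            "compartment": state.compartment,
            "interval_start_min": [s for s, _ in schedule],
            "interval_end_min": [e for _, e in schedule],
            "midpoint_min": schedule.midpoints,
            "sample_type": "dialysate",
            "conc_ug_per_ml": reported,
            "below_loq": below,
        }
    )


def simulate_retrodialysis_pair(
    state: TrueCatheterState,
    calibration_conc: float,
    noise: Optional[NoiseModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two 40-min retrodialysis samples for one catheter.

    During retrodialysis the perfusate carries a known drug concentration
    and the dialysate retains the fraction NOT lost to tissue, so each
    replicate measures ``calibration_conc * (1 - RR/100)`` up to assay
    noise.  Failed catheters are not calibrated.
    """
    if calibration_conc <= 0:
        raise ValueError("calibration_conc must be positive")
    if state.status != "ok":
        return pd.DataFrame(columns=CALIBRATION_COLUMNS)
    ideal = calibration_conc * (1.0 - state.true_rr_percent / 100.0)
    values = np.full(2, ideal)
    if noise is not None and ideal > 0:
        values = values * noise.factors(rng, values)
    return pd.DataFrame(
        {
            "animal_id": state.animal_id,
            "compartment": state.compartment,
            "replicate": [1, 2],
            "perfusate_conc_ug_per_ml": calibration_conc,
            "dialysate_conc_ug_per_ml": values,
        }
    )


def _draw_truncated_rr(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to (0, 100] by redraw (RR is a percentage)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        rr = rng.normal(mean, sd)
        if 0 < rr <= 100:
            return float(rr)
    raise RuntimeError("truncated RR draw failed to converge; check mean/SD")


def simulate_study(
    config: StudyConfig,
    kinetics: Optional[Mapping[str, TissueKinetics]] = None,
    recovery_params: Optional[Mapping[str, tuple[float, float]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> StudyData:
    """Simulate a complete study: dialysates, plasma, calibration, truth.

    All randomness flows through one generator seeded from
    ``config.seed`` (unless an ``rng`` is passed), so a config fully
    reproduces its dataset.  Per-catheter recoveries are truncated-normal
    draws from per-compartment means/SDs; catheters fail (malfunction or
    displacement) with the configured probabilities and then contribute
    neither dialysates nor calibration samples.  Plasma is sampled at the
    interval midpoints without recovery loss.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    schedule = config.schedule()
    kin = dict(default_kinetics()) if kinetics is None else dict(kinetics)
    rec = dict(DEFAULT_RECOVERY_PARAMS) if recovery_params is None else dict(recovery_params)
    missing = [c for c in TISSUE_COMPARTMENTS if c not in kin] + (
        [] if PLASMA in kin else [PLASMA]
    )
    if missing:
        raise ValueError(f"kinetics missing for compartments: {missing}")
    noise = NoiseModel(loq_ug_per_ml=config.loq_ug_per_ml) if config.noise else None

    states: list[TrueCatheterState] = []
    entries: list[CatheterEntry] = []
    sample_frames: list[pd.DataFrame] = []
    calib_frames: list[pd.DataFrame] = []
    site_depths = {c: d for c, d in zip(TISSUE_COMPARTMENTS, (None, 1.0, 4.0, None, 1.0, 4.0, None, None))}

    for animal_id in config.animal_ids:
        for comp in TISSUE_COMPARTMENTS:
            if comp not in rec:
                raise ValueError(f"no recovery parameters for compartment {comp!r}")
            u = rng.uniform()
            if u < config.p_malfunction:
                status = "malfunction"
            elif u < config.p_malfunction + config.p_displaced:
                status = "displaced"
            else:
                status = "ok"
            rr = _draw_truncated_rr(rng, *rec[comp])
            state = TrueCatheterState(
                animal_id=animal_id, compartment=comp, true_rr_percent=rr, status=status
            )
            states.append(state)
            entries.append(
                CatheterEntry(
                    animal_id=animal_id, compartment=comp,
                    depth_mm=site_depths[comp], status=status,
                )
            )
            sample_frames.append(
                simulate_dialysate_series(kin[comp], state, schedule, noise, rng)
            )
            calib_frames.append(
                simulate_retrodialysis_pair(
                    state, config.calibration_perfusate_ug_per_ml, noise, rng
                )
            )
        # plasma: venous draws at the dialysate midpoints, no recovery loss
        plasma_true = true_concentration(kin[PLASMA], schedule.midpoints)
        if noise is not None:
            plasma_meas = plasma_true * noise.factors(rng, plasma_true)
            plasma_rep, plasma_below = _censor(plasma_meas, noise.loq_ug_per_ml)
        else:
            plasma_rep, plasma_below = plasma_true, np.zeros(len(schedule), dtype=int)
        sample_frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal_id,
                    "compartment": PLASMA,
                    "interval_start_min": [s for s, _ in schedule],
                    "interval_end_min": [e for _, e in schedule],
                    "midpoint_min": schedule.midpoints,
                    "sample_type": "plasma",
                    "conc_ug_per_ml": plasma_rep,
                    "below_loq": plasma_below,
                }
            )
        )

    samples = pd.concat(
        [f for f in sample_frames if not f.empty], ignore_index=True
    ) if sample_frames else pd.DataFrame(columns=SAMPLE_COLUMNS)
    calibration = pd.concat(
        [f for f in calib_frames if not f.empty], ignore_index=True
    ) if any(not f.empty for f in calib_frames) else pd.DataFrame(columns=CALIBRATION_COLUMNS)

    t_last_mid = float(schedule.midpoints[-1])
    truth = SimTruth(
        seed=config.seed,
        config=config,
        kinetics=kin,
        catheter_states=states,
        closed_form={c: closed_form_nca(k, t_last_mid) for c, k in kin.items()},
    )
    return StudyData(
        samples=samples,
        calibration=calibration,
        ledger=CatheterLedger(tuple(entries)),
        truth=truth,
    )
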