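"""End-to-end driver chaining all stages on one simulated study.

simulate -> calibrate -> correct -> nca -> report, with every
intermediate written as a tidy CSV so stages can also be run (and
re-run) independently from files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .calibration import calibrate_study
from .correction import correct_study
from .dosing import dose_table
from .nca import run_nca
from .report import report
from .simulate import StudyData, simulate_study
from .study_design import StudyConfig


@dataclass
class PipelineResult:
    """All stage outputs of one full run."""

    study: StudyData
    doses: pd.DataFrame
    recovery: pd.DataFrame
    profiles: pd.DataFrame
    nca: pd.DataFrame
    paths: dict[str, Path]


def run_study(
    config: StudyConfig,
    out_dir=None,
    loq_policy: str = "exclude",
    lambda_policy: str = "max_adj_r2",
    holm: bool = False,
) -> PipelineResult:
    """Simulate one study and run the full analysis on it.

    When ``out_dir`` is given, writes samples.csv, calibration.csv,
    ledger.csv, schedule.csv, doses.csv, truth.json, recovery.csv,
    profiles.csv, nca.csv and the report files there.
    """
    study = simulate_study(config)
    doses = dose_table(config)
    recovery = calibrate_study(study.calibration)
    profiles = correct_study(
        study.samples, recovery, loq_policy=loq_policy, loq_ug_per_ml=config.loq_ug_per_ml
    )
    nca = run_nca(profiles, lambda_policy=lambda_policy)

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        writers = {
            "samples": study.samples,
            "calibration": study.calibration,
            "ledger": study.ledger.to_frame(),
            "schedule": config.schedule().to_frame(),
            "doses": doses,
            "recovery": recovery,
            "profiles": profiles,
            "nca": nca,
        }
        for name, frame in writers.items():
            paths[name] = out / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        paths["truth"] = out / "truth.json"
        study.truth.to_json(paths["truth"])
        paths.update(report(out, nca, profiles, holm=holm))
    return PipelineResult(
        study=study, doses=doses, recovery=recovery, profiles=profiles, nca=nca, paths=paths
    )
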