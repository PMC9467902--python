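"""Per-compartment summaries and between-compartment comparisons.

Summaries give the arithmetic mean and two-sided 95% t-interval of each
NCA parameter across animals, per compartment (the shape of the study's
summary table).  Between-compartment comparisons fit a linear mixed model
with compartment as fixed effect and animal as random intercept (REML,
statsmodels), report the overall fixed-effect F-test, and accompany it
with pairwise paired t-tests on within-animal differences over complete
pairs.

Degrees of freedom: the overall test uses a Wald F statistic with
residual denominator degrees of freedom N - k - (n_animals - 1), which
reduces to the classical repeated-measures (n-1)(k-1) in the balanced
case.  This residual-df approximation stands in for the Kenward-Roger
small-sample correction, which needs specialised machinery; with few
animals the reported p-values are therefore approximate, and the paired
t-tests (exact df) are the primary pairwise inference.  Pairwise p-values
are reported unadjusted by default; Holm adjustment is available behind
a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARAMETER_COLUMNS",
    "MixedModelResult",
    "summarize_by_compartment",
    "mixed_model_compare",
    "mean_profiles",
    "report",
    "SUMMARY_COLUMNS",
]

#: Friendly parameter names -> NCA table columns.
PARAMETER_COLUMNS = {
    "auc": "auc0last_min_ugml",
    "cmax": "cmax_ugml",
    "tmax": "tmax_min",
}

SUMMARY_COLUMNS = [
    "compartment",
    "n",
    "auc_mean", "auc_lo", "auc_hi",
    "cmax_mean", "cmax_lo", "cmax_hi",
    "tmax_mean", "tmax_lo", "tmax_hi",
]

COMPARISON_COLUMNS = [
    "parameter",
    "compartment_a",
    "compartment_b",
    "n_pairs",
    "mean_difference",
    "t_stat",
    "p_value",
    "significant",
]


def _t_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and two-sided t-interval; (mean, nan, nan) when n < 2."""
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, float("nan"), float("nan")
    se = float(np.std(values, ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return mean, mean - tcrit * se, mean + tcrit * se


def summarize_by_compartment(nca: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-compartment mean and 95% CI of AUC_0-last, Cmax and Tmax.

    One row per compartment; compartments with a single animal are
    reported without a CI.
    """
    if nca.empty:
        raise ValueError("empty NCA input")
    rows = []
    for comp, grp in nca.groupby("compartment", sort=True):
        row: dict = {"compartment": comp, "n": int(grp["animal_id"].nunique())}
        for name, col in PARAMETER_COLUMNS.items():
            mean, lo, hi = _t_interval(grp[col].to_numpy(dtype=float), level)
            row[f"{name}_mean"], row[f"{name}_lo"], row[f"{name}_hi"] = mean, lo, hi
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass(frozen=True)
class MixedModelResult:
    """Overall fixed-effect test for compartment differences."""

    parameter: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    significant: bool
    n_animals: int
    n_compartments: int


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def mixed_model_compare(
    nca: pd.DataFrame,
    parameter: str,
    alpha: float = 0.05,
    holm: bool = False,
) -> tuple[MixedModelResult, pd.DataFrame]:
    """Compare a PK parameter between compartments.

    Fits ``value ~ compartment`` with a per-animal random intercept by
    REML and tests the compartment effect jointly (Wald F, residual df).
    Pairwise compartment contrasts use paired t-tests on within-animal
    differences over animals observed in both compartments.
    """
    import statsmodels.formula.api as smf

    col = PARAMETER_COLUMNS.get(parameter, parameter)
    if col not in nca.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    data = nca[["animal_id", "compartment", col]].dropna().rename(columns={col: "value"})
    n_comp = data["compartment"].nunique()
    n_animals = data["animal_id"].nunique()
    if n_comp < 2:
        raise ValueError("need at least 2 compartments to compare")
    if n_animals < 3:
        raise ValueError("need at least 3 animals for the mixed model")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(compartment)", data=data, groups=data["animal_id"])
        fit = model.fit(reml=True)

    names = [n for n in fit.model.exog_names if n.startswith("C(compartment)")]
    beta = fit.fe_params[names].to_numpy()
    cov = fit.cov_params().loc[names, names].to_numpy()
    q = len(names)
    chi2 = float(beta @ np.linalg.solve(cov, beta))
    df_den = max(len(data) - n_comp - (n_animals - 1), 1)
    f_stat = chi2 / q
    p_value = float(stats.f.sf(f_stat, q, df_den))
    overall = MixedModelResult(
        parameter=parameter,
        f_stat=f_stat,
        df_num=q,
        df_den=df_den,
        p_value=p_value,
        significant=p_value < alpha,
        n_animals=n_animals,
        n_compartments=n_comp,
    )

    wide = data.pivot_table(index="animal_id", columns="compartment", values="value")
    rows = []
    for a, b in combinations(sorted(wide.columns), 2):
        pair = wide[[a, b]].dropna()
        n_pairs = len(pair)
        if n_pairs < 2:
            rows.append((parameter, a, b, n_pairs, float("nan"), float("nan"), float("nan")))
            continue
        diff = pair[a] - pair[b]
        if float(np.std(diff, ddof=1)) == 0.0:
            # perfectly equal per-animal values: no evidence of a difference
            t_stat, p = (0.0, 1.0) if float(np.mean(diff)) == 0.0 else (float("inf"), 0.0)
        else:
            with warnings.catch_warnings():
                # near-identical pairs trigger scipy precision-loss warnings
                warnings.simplefilter("ignore", RuntimeWarning)
                t_stat, p = stats.ttest_rel(pair[a], pair[b])
        rows.append((parameter, a, b, n_pairs, float(np.mean(diff)), float(t_stat), float(p)))
    comparisons = pd.DataFrame(
        rows, columns=COMPARISON_COLUMNS[:-1]
    )
    pvals = comparisons["p_value"].to_numpy()
    if holm:
        finite = np.isfinite(pvals)
        adj = pvals.copy()
        adj[finite] = _holm(pvals[finite])
        comparisons["p_value"] = adj
    comparisons["significant"] = comparisons["p_value"] < alpha
    return overall, comparisons


def mean_profiles(profiles: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Mean concentration-time profile per compartment with 95% t-CI."""
    rows = []
    for (comp, mid), grp in profiles.groupby(["compartment", "midpoint_min"], sort=True):
        mean, lo, hi = _t_interval(grp["conc_ug_per_ml"].to_numpy(dtype=float), level)
        rows.append(
            {
                "compartment": comp,
                "midpoint_min": mid,
                "n": len(grp),
                "mean_ug_per_ml": mean,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def report(
    out_dir,
    nca: pd.DataFrame,
    profiles: pd.DataFrame,
    parameters: Sequence[str] = ("auc", "cmax", "tmax"),
    alpha: float = 0.05,
    holm: bool = False,
) -> dict[str, Path]:
    """Write summary.csv, comparisons.csv, overall_tests.csv, mean_profiles.csv.

    Deterministic: identical inputs give byte-identical files.
    """
    if nca.empty:
        raise ValueError("empty NCA input")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = summarize_by_compartment(nca)
    paths["summary"] = out / "summary.csv"
    summary.to_csv(paths["summary"], index=False)

    overall_rows = []
    comp_frames = []
    for param in parameters:
        try:
            overall, comps = mixed_model_compare(nca, param, alpha=alpha, holm=holm)
        except ValueError:
            continue  # too little replication for this parameter
        overall_rows.append(
            {
                "parameter": overall.parameter,
                "f_stat": overall.f_stat,
                "df_num": overall.df_num,
                "df_den": overall.df_den,
                "p_value": overall.p_value,
                "significant": overall.significant,
            }
        )
        comp_frames.append(comps)
    paths["overall_tests"] = out / "overall_tests.csv"
    pd.DataFrame(overall_rows).to_csv(paths["overall_tests"], index=False)
    paths["comparisons"] = out / "comparisons.csv"
    (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(columns=COMPARISON_COLUMNS)
    ).to_csv(paths["comparisons"], index=False)

    paths["mean_profiles"] = out / "mean_profiles.csv"
    mean_profiles(profiles).to_csv(paths["mean_profiles"], index=False)
    return paths
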