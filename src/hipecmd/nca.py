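"""Non-compartmental pharmacokinetic analysis per animal × compartment.

Parameters computed from each concentration-time profile:

* Cmax — highest observed concentration; Tmax — its time (ties broken by
  the earliest time, a deterministic convention).
* AUC_0-last — linear up-log down trapezoidal rule: rising (or flat)
  segments use the linear trapezoid (C1+C2)Δt/2; strictly falling
  segments use the log trapezoid (C1-C2)Δt/ln(C1/C2).  The curve is
  assumed zero at t=0 (no drug before HIPEC initiation), so the leading
  segment to the first observed point is a linear rise from zero; this
  can be switched off for sensitivity analysis.
* λz — terminal elimination rate from OLS of ln(concentration) on time
  over a terminal tail of at least three points strictly after Tmax.  The
  default tail selection maximises adjusted R² over the candidate tails
  (last k points, k = 3 … all post-Tmax points), requiring a positive
  slope magnitude; a fixed last-3 policy is available.  T1/2 = ln(2)/λz.

When too few terminal points exist, or no tail yields a positive λz, the
half-life is flagged non-estimable rather than raising — with an 8-h
window and slow terminal decay this is a common, expected outcome.
AUC extrapolation to infinity and compartmental fitting are non-goals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "find_cmax_tmax",
    "auc_lin_up_log_down",
    "auc_linear",
    "fit_lambda_z",
    "half_life",
    "run_nca",
    "NCA_COLUMNS",
]

NCA_COLUMNS = [
    "animal_id",
    "compartment",
    "cmax_ugml",
    "tmax_min",
    "auc0last_min_ugml",
    "lambda_z_per_min",
    "t_half_min",
    "n_lambda_points",
    "lambda_adj_r2",
    "t_half_estimable",
]

LAMBDA_POLICIES = ("max_adj_r2", "last3")


def _as_profile_arrays(times, concs) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size == 0:
        raise ValueError("empty profile")
    if t.size != c.size:
        raise ValueError("times and concentrations must have equal length")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return t, c


def find_cmax_tmax(times, concs) -> tuple[float, float]:
    """Peak concentration and its time; ties resolve to the earliest time."""
    t, c = _as_profile_arrays(times, concs)
    idx = int(np.argmax(c))  # argmax returns the first maximum: earliest time
    return float(c[idx]), float(t[idx])


def auc_lin_up_log_down(times, concs, leading_from_zero: bool = True) -> float:
    """AUC_0-last by the linear up-log down trapezoidal method.

    The log trapezoid requires both endpoint concentrations positive; a
    falling segment touching zero falls back to the linear rule.  With
    ``leading_from_zero`` the area from (0, 0) linearly up to the first
    point is included (skipped if the first point is at t=0).
    """
    t, c = _as_profile_arrays(times, concs)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    auc = 0.0
    if leading_from_zero and t[0] > 0:
        auc += t[0] * c[0] / 2.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            auc += (c1 - c2) * dt / math.log(c1 / c2)
        else:
            auc += (c1 + c2) * dt / 2.0
    return auc


def auc_linear(times, concs, leading_from_zero: bool = True) -> float:
    """All-linear trapezoidal AUC (reference rule for comparisons)."""
    t, c = _as_profile_arrays(times, concs)
    auc = float(np.trapezoid(c, t)) if len(t) > 1 else 0.0
    if leading_from_zero and t[0] > 0:
        auc += t[0] * c[0] / 2.0
    return auc


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal-slope regression result."""

    lambda_z: float
    n_points: int
    adj_r2: float
    estimable: bool
    reason: str = ""


def _regress_tail(t: np.ndarray, log_c: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R² of OLS log-concentration on time."""
    res = stats.linregress(t, log_c)
    n = len(t)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(res.slope), float(adj)


def fit_lambda_z(times, concs, policy: str = "max_adj_r2") -> LambdaZFit:
    """Estimate λz from the terminal log-linear phase of a profile.

    Candidate points lie strictly after Tmax and must be positive (log
    scale).  Returns a non-estimable result — never raises — when fewer
    than three candidates exist or no tail gives a positive λz.
    """
    if policy not in LAMBDA_POLICIES:
        raise ValueError(f"unknown lambda policy {policy!r}; choose from {LAMBDA_POLICIES}")
    t, c = _as_profile_arrays(times, concs)
    _, tmax = find_cmax_tmax(t, c)
    mask = (t > tmax) & (c > 0)
    t_tail, c_tail = t[mask], c[mask]
    if len(t_tail) < 3:
        return LambdaZFit(float("nan"), 0, float("nan"), False, "fewer than 3 terminal points")
    log_c = np.log(c_tail)

    ks = [3] if policy == "last3" else list(range(3, len(t_tail) + 1))
    best: Optional[tuple[float, int, float]] = None  # (adj_r2, n, lambda)
    for k in ks:
        slope, adj = _regress_tail(t_tail[-k:], log_c[-k:])
        lam = -slope
        if lam <= 0 or not math.isfinite(adj):
            continue
        # prefer higher adjusted R²; on a near-tie keep the longer tail
        if best is None or adj > best[0] + 1e-10:
            best = (adj, k, lam)
        elif abs(adj - best[0]) <= 1e-10 and k > best[1]:
            best = (adj, k, lam)
    if best is None:
        return LambdaZFit(
            float("nan"), 0, float("nan"), False, "no terminal tail with positive lambda_z"
        )
    adj, k, lam = best
    return LambdaZFit(lam, k, adj, True)


def half_life(lambda_z: float) -> float:
    """Terminal half-life ln(2)/λz in minutes."""
    if not lambda_z > 0:
        raise ValueError("lambda_z must be positive")
    return math.log(2.0) / lambda_z


@dataclass(frozen=True)
class NCAResult:
    """NCA parameters for one animal × compartment."""

    animal_id: str
    compartment: str
    cmax_ugml: float
    tmax_min: float
    auc0last_min_ugml: float
    lambda_z_per_min: float
    t_half_min: float
    n_lambda_points: int
    lambda_adj_r2: float
    t_half_estimable: bool


def _nca_one(
    animal_id: str,
    compartment: str,
    times,
    concs,
    leading_from_zero: bool,
    lambda_policy: str,
) -> NCAResult:
    cmax, tmax = find_cmax_tmax(times, concs)
    auc = auc_lin_up_log_down(times, concs, leading_from_zero=leading_from_zero)
    fit = fit_lambda_z(times, concs, policy=lambda_policy)
    return NCAResult(
        animal_id=animal_id,
        compartment=compartment,
        cmax_ugml=cmax,
        tmax_min=tmax,
        auc0last_min_ugml=auc,
        lambda_z_per_min=fit.lambda_z if fit.estimable else float("nan"),
        t_half_min=half_life(fit.lambda_z) if fit.estimable else float("nan"),
        n_lambda_points=fit.n_points,
        lambda_adj_r2=fit.adj_r2,
        t_half_estimable=fit.estimable,
    )


def run_nca(
    profiles: pd.DataFrame,
    leading_from_zero: bool = True,
    lambda_policy: str = "max_adj_r2",
) -> pd.DataFrame:
    """NCA over a tidy profile table, one row per animal × compartment.

    Groups with no usable points are skipped (they have no profile rows by
    construction).  Output is sorted by animal then compartment and is a
    deterministic function of the input rows regardless of their order.
    """
    if profiles.empty:
        return pd.DataFrame(columns=NCA_COLUMNS)
    results = []
    for (animal_id, comp), grp in profiles.groupby(["animal_id", "compartment"], sort=True):
        grp = grp.sort_values("midpoint_min")
        res = _nca_one(
            str(animal_id),
            str(comp),
            grp["midpoint_min"].to_numpy(dtype=float),
            grp["conc_ug_per_ml"].to_numpy(dtype=float),
            leading_from_zero,
            lambda_policy,
        )
        results.append(res)
    return pd.DataFrame(
        {
            col: [getattr(r, col) for r in results]
            for col in NCA_COLUMNS
        }
    )
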