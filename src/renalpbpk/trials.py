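"""Virtual-trial simulation and non-compartmental analysis (NCA).

A trial design couples a population parameter set with a drug model and an IV
regimen; subjects are generated, simulated through the PBPK engine, sampled on
a clinical schedule, and summarised by NCA: linear-up/log-down trapezoidal
AUC, terminal slope (lambda_z) by best-adjusted-R^2 log-linear regression,
AUC extrapolated to infinity, Cmax, total and renal clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .drugmodel import DrugParameters
from .pbpk import ConcentrationProfile, DoseEvent, build_model, simulate
from .physiology import REFERENCE_ADULT, ReferencePhysiology
from .population import PopulationParameters, VirtualSubject, generate_population

__all__ = ["TrialDesign", "NCAResult", "nca", "run_trial",
           "DEFAULT_SCHEDULE", "summarize_trials"]

#: default post-dose sampling times (h), typical for IV antibacterials
DEFAULT_SCHEDULE = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass
class TrialDesign:
    """One virtual study: population x drug x regimen x sampling schedule."""

    population: PopulationParameters
    drug: DrugParameters
    regimen: list[DoseEvent]
    n_trials: int = 10
    n_per_trial: int = 10
    sex_ratio_override: Optional[float] = None
    schedule_h: Sequence[float] = DEFAULT_SCHEDULE
    t_end_h: Optional[float] = None  # default: last sample time
    dt_out_h: float = 0.05

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_per_trial < 1:
            raise ValueError("n_trials and n_per_trial must be >= 1")
        if not self.regimen:
            raise ValueError("regimen must contain at least one dose")


@dataclass
class NCAResult:
    """Per-subject NCA parameters; lambda_z-dependent fields may be NaN."""

    auc_last: float  # mg*h/L
    auc_inf: float
    cmax: float  # mg/L
    tmax: float
    lambda_z: float  # 1/h
    t_half: float  # h
    extrap_frac: float
    cl: float  # L/h, Dose/AUC_inf
    clr: float  # L/h
    flagged: bool = False


def _auc_lin_log(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down trapezoidal AUC over the sampled interval."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * 0.5 * (c0 + c1)
    return auc


def _lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float, int]:
    """Terminal slope by unweighted log-linear regression.

    Candidate windows are the last k points (k >= 3) strictly after Cmax;
    the window with the highest adjusted R^2 wins.  Returns (lambda_z,
    n_points); lambda_z <= 0 or an infeasible window yields (nan, 0).
    """
    i_max = int(np.argmax(c))
    pos = (c > 0) & (np.arange(len(c)) > i_max)
    tt, cc = t[pos], np.log(c[pos])
    best = (float("nan"), 0, -np.inf)
    for k in range(3, len(tt) + 1):
        x, yv = tt[-k:], cc[-k:]
        n = len(x)
        slope, intercept = np.polyfit(x, yv, 1)
        resid = yv - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if adj > best[2] and slope < 0:
            best = (-slope, n, adj)
    return best[0], best[1]


def nca(
    profile_t: np.ndarray,
    profile_c: np.ndarray,
    dose_mg: float,
    ae_renal_frac: Optional[float] = None,
) -> NCAResult:
    """NCA of one sampled concentration-time course after a single IV dose.

    ``ae_renal_frac`` is the renal fraction of total elimination (from the
    simulator's cumulative-excretion bookkeeping); renal clearance is then
    CLr = CL * ae_renal_frac.
    """
    t = np.asarray(profile_t, dtype=float)
    c = np.asarray(profile_c, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 sampled points for NCA")
    cmax = float(c.max())
    tmax = float(t[int(np.argmax(c))])
    auc_last = _auc_lin_log(t, c)
    lz, n_lz = _lambda_z(t, c)
    if not (lz > 0):
        return NCAResult(auc_last, float("nan"), cmax, tmax, float("nan"),
                         float("nan"), float("nan"), float("nan"),
                         float("nan"), flagged=True)
    c_last = c[c > 0][-1]
    auc_inf = auc_last + c_last / lz
    cl = dose_mg / auc_inf
    clr = cl * ae_renal_frac if ae_renal_frac is not None else float("nan")
    return NCAResult(
        auc_last=float(auc_last),
        auc_inf=float(auc_inf),
        cmax=cmax,
        tmax=tmax,
        lambda_z=float(lz),
        t_half=float(math.log(2) / lz),
        extrap_frac=float((auc_inf - auc_last) / auc_inf),
        cl=float(cl),
        clr=float(clr),
    )


def _sample_profile(
    profile: ConcentrationProfile, schedule: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    sched = np.asarray(schedule, dtype=float)
    conc = np.interp(sched, profile.time_h, profile.plasma_mg_L)
    return sched, conc


def run_trial(
    design: TrialDesign,
    seed: int = 0,
    physiology: ReferencePhysiology = REFERENCE_ADULT,
    keep_profiles: bool = False,
) -> tuple[list[ConcentrationProfile], pd.DataFrame]:
    """Simulate the full virtual study and return per-subject NCA rows.

    Subjects for all trials are generated in one population call (the design
    is equivalent to a single trial of n_trials * n_per_trial subjects); the
    returned frame carries trial and subject indices plus covariates, so
    per-trial and overall summaries can be derived with
    :func:`summarize_trials`.
    """
    n = design.n_trials * design.n_per_trial
    subjects = generate_population(
        design.population, n,
        sex_ratio_override=design.sex_ratio_override, seed=seed,
    )
    t_end = design.t_end_h if design.t_end_h is not None else max(design.schedule_h)
    dose_total = sum(d.amount_mg for d in design.regimen)
    rows = []
    profiles: list[ConcentrationProfile] = []
    for i, subj in enumerate(subjects):
        try:
            model = build_model(subj, design.drug, physiology)
            prof = simulate(model, design.regimen, t_end, design.dt_out_h)
        except Exception as exc:  # annotate with subject context
            raise RuntimeError(
                f"subject {i} (trial {i // design.n_per_trial}): {exc}"
            ) from exc
        ae_r = prof.ae_renal_mg[-1]
        ae_nr = prof.ae_nonrenal_mg[-1]
        frac = ae_r / (ae_r + ae_nr) if (ae_r + ae_nr) > 0 else float("nan")
        st, sc = _sample_profile(prof, design.schedule_h)
        res = nca(st, sc, dose_total, ae_renal_frac=frac)
        rows.append({
            "trial": i // design.n_per_trial,
            "subject": i,
            "sex": subj.sex,
            "age": subj.age,
            "weight": subj.weight,
            "gfr_norm": subj.gfr_norm,
            **vars(res),
        })
        if keep_profiles:
            profiles.append(prof)
    return profiles, pd.DataFrame(rows)


def summarize_trials(pk: pd.DataFrame, params: Sequence[str] = ("auc_inf", "cmax", "cl", "clr")) -> pd.DataFrame:
    """Per-trial and overall summary statistics of NCA parameters."""

    def _stats(g: pd.DataFrame) -> pd.Series:
        out = {}
        for p in params:
            x = g[p].dropna()
            out[f"{p}_mean"] = x.mean()
            out[f"{p}_sd"] = x.std()
            out[f"{p}_geomean"] = float(np.exp(np.log(x[x > 0]).mean())) if len(x) else float("nan")
            out[f"{p}_p5"] = x.quantile(0.05)
            out[f"{p}_p95"] = x.quantile(0.95)
        out["n"] = len(g)
        return pd.Series(out)

    per_trial = pk.groupby("trial").apply(_stats, include_groups=False)
    overall = _stats(pk).to_frame().T
    overall.index = pd.Index(["overall"], name="trial")
    return pd.concat([per_trial, overall])
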