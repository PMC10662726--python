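"""Facility-experiment driver: stepped perfusion, regression, sweeps.

A facility experiment raises the input (source flow for constant-flow,
reservoir or target pressure for constant-pressure modes) in equal steps,
waits for a steady-state criterion to fire, records the plateau eye pressure
and inflow, and immediately initiates the next step.  Outflow facility is the
slope of the linear regression of steady-state eye inflow F_E on eye pressure
P_E — for the linear model eye it should recover 1/R_T = 0.02326 ul/min/mmHg
(23.26 nl/min/mmHg) exactly in the absence of noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import EyeParams, SystemParams
from .model import ModelState, Simulator, Trace, steady_state
from .detection import (CriterionConfig, DetectionResult, RecursiveFitter,
                        scan_ratio, scan_window, smooth)
from . import noise as noise_mod

__all__ = [
    "ExperimentPlan", "FacilityResult", "StepRecord", "run_experiment",
    "run_cohort", "sweep_step_design", "optimize_filter_width",
    "default_step_size",
]


def default_step_size(mode: str) -> float:
    """Published step sizes: 0.1 ul/min for CF, 5 mmHg for CP modes."""
    return 0.1 if mode == "CF" else 5.0


@dataclass
class ExperimentPlan:
    """Everything needed to run one stepped facility experiment."""

    mode: str = "CPg"
    eye: EyeParams = field(default_factory=EyeParams)
    sys: SystemParams = field(default_factory=lambda: SystemParams(system_resistance=0.6))
    criterion: CriterionConfig = field(default_factory=CriterionConfig)
    noise: Optional[object] = None       # NoiseRecord or None
    n_steps: int = 5
    step_size: Optional[float] = None    # ul/min (CF) or mmHg (CP)
    analog: bool = False

    def resolved_step(self) -> float:
        return self.step_size if self.step_size is not None \
            else default_step_size(self.mode)


@dataclass
class StepRecord:
    """One pressure/flow step of an experiment."""

    level: float
    detection: DetectionResult

    @property
    def converged(self) -> bool:
        return self.detection.converged


@dataclass
class FacilityResult:
    """Regression outcome of one facility experiment."""

    plan: ExperimentPlan
    steps: list[StepRecord]
    facility: float          # ul/min/mmHg
    intercept: float         # ul/min
    pearson_r: float
    total_duration: float    # min, last detection minus first onset
    converged: bool          # all steps converged and regression valid

    @property
    def facility_nl(self) -> float:
        """Facility in nl/min/mmHg, the units facility is usually reported in."""
        return self.facility * 1000.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps, start=1):
            d = s.detection
            rows.append(dict(step=i, level=s.level, criterion=d.criterion,
                             settle_min=d.settle_time, steady_p_e=d.steady_p_e,
                             steady_f_e=d.steady_f_e, converged=d.converged))
        return pd.DataFrame(rows)


def _regress(steps: Sequence[StepRecord]):
    pe = np.array([s.detection.steady_p_e for s in steps if s.converged])
    fe = np.array([s.detection.steady_f_e for s in steps if s.converged])
    if len(pe) < 2:
        return float("nan"), float("nan"), float("nan"), False
    res = stats.linregress(pe, fe)
    return float(res.slope), float(res.intercept), float(res.rvalue), True


def _detect_step(sim: Simulator, plan: ExperimentPlan, level: float,
                 abs_start: int) -> tuple[DetectionResult, int]:
    """Simulate one step until its criterion fires or times out.

    Returns the detection and the number of samples consumed (the simulator
    is left positioned exactly at the detection sample).
    """
    cfg = plan.criterion
    dt_min = sim.dt_min
    eye, sysp = plan.eye, plan.sys
    rc = sysp.cannula_resistance
    if plan.mode == "CF":
        step_pressure = (rc + eye.trabecular_resistance) * plan.resolved_step()
    else:
        step_pressure = plan.resolved_step()
    nf = int(round(cfg.filter_width / dt_min)) if cfg.filter_width > 0 else 0
    w = int(round(cfg.window_length / dt_min))
    min_index = nf + w - 1 if nf else 0

    fitter = RecursiveFitter(cfg, sim.dt_s) if cfg.needs_fit else None
    max_samples = int(round(cfg.timeout / dt_min))
    # first chunk just covers the earliest possible detection
    if cfg.needs_fit:
        first = cfg.fit_start + max(cfg.window_length, cfg.fit_hold) + 1.0
    else:
        first = cfg.window_length + cfg.ratio_hold + cfg.filter_width + 1.0
    chunks: list[Trace] = []
    n_done = 0
    det: Optional[int] = None
    while n_done < max_samples:
        dur = min(first if n_done == 0 else 2.0,
                  (max_samples - n_done) * dt_min)
        tr = sim.run(level, dur)
        chunks.append(tr)
        if fitter is not None:
            fitter.extend(tr.p_s, tr.f_s)
        n_done += len(tr)
        full = Trace.concat(chunks)
        if fitter is not None:
            det = fitter.scan(step_pressure)
        elif cfg.criterion == "window":
            p = smooth(full.p_s, cfg.filter_width, dt_min)
            det = scan_window(p, dt_min, step_pressure, cfg, min_index)
        else:
            p = smooth(full.p_s, cfg.filter_width, dt_min)
            f = smooth(full.f_s, cfg.filter_width, dt_min)
            det = scan_ratio(p, f, dt_min, cfg, min_index)
        if det is not None and det < n_done:
            break
        det = None
    full = Trace.concat(chunks)

    if det is None:  # timed out: truncate to the timeout instant
        det = max_samples - 1
        converged = False
    else:
        converged = True
    if det < len(full) - 1:
        sim.restore(full.states[det], full.t0_min + det * dt_min,
                    abs_start + det, full.p_s[max(0, det - 200):det + 1])
    settle = (det + 1) * dt_min

    if fitter is not None and fitter.fit is not None and converged:
        fit = fitter.fit
        ps, fs = fit.p_plateau, fit.f_plateau
        result = DetectionResult(cfg.criterion, settle, ps, fs,
                                 ps - rc * fs, fs, converged, fit=fit)
    else:
        lo = max(0, det - w + 1)
        result = DetectionResult(
            cfg.criterion, settle,
            float(full.p_s[lo:det + 1].mean()), float(full.f_s[lo:det + 1].mean()),
            float(full.p_e[lo:det + 1].mean()), float(full.f_e[lo:det + 1].mean()),
            converged, fit=None if fitter is None else fitter.fit)
    return result, det + 1


def run_experiment(plan: ExperimentPlan) -> FacilityResult:
    """Run a stepped facility experiment and regress the plateau data.

    Each subsequent step starts the instant the criterion detects steady
    state.  Steps that time out are kept in the duration accounting (at the
    timeout) but excluded from the pressure-flow regression.
    """
    if plan.n_steps < 1:
        raise ValueError("need at least one step")
    sim = Simulator(plan.mode, plan.eye, plan.sys, noise=plan.noise,
                    analog=plan.analog)
    step = plan.resolved_step()
    base = 0.0 if plan.mode == "CF" else plan.eye.resting_iop
    steps: list[StepRecord] = []
    abs_sample = 0
    for i in range(1, plan.n_steps + 1):
        level = base + i * step
        det, used = _detect_step(sim, plan, level, abs_sample)
        abs_sample += used
        steps.append(StepRecord(level=level, detection=det))
    slope, intercept, r, ok = _regress(steps)
    total = sum(s.detection.settle_time for s in steps)
    return FacilityResult(plan=plan, steps=steps, facility=slope,
                          intercept=intercept, pearson_r=r,
                          total_duration=total,
                          converged=ok and all(s.converged for s in steps))


def run_cohort(plan: ExperimentPlan, records: Sequence) -> pd.DataFrame:
    """Run the same experiment over a set of noise records.

    Returns one row per record with duration, facility and convergence; use
    :func:`summarize_cohort` for mean/SD or quartile summaries.
    """
    rows = []
    for i, rec in enumerate(records):
        res = run_experiment(replace(plan, noise=rec))
        rows.append(dict(record=i, label=getattr(rec, "label", "custom"),
                         seed=getattr(rec, "seed", None),
                         duration_min=res.total_duration,
                         facility_nl=res.facility_nl,
                         pearson_r=res.pearson_r,
                         converged=res.converged))
    return pd.DataFrame(rows)


def summarize_cohort(df: pd.DataFrame, style: str = "mean") -> dict:
    """Mean/SD (default) or median/quartile summary of a cohort table."""
    out = {}
    for col in ("duration_min", "facility_nl"):
        x = df[col].to_numpy(float)
        if style == "mean":
            out[col] = (float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            out[col] = (float(med), float(q1), float(q3))
    out["n"] = len(df)
    out["n_converged"] = int(df["converged"].sum())
    return out


def sweep_step_design(plan: ExperimentPlan, records: Sequence,
                      step_sizes: Sequence[float],
                      n_steps_list: Sequence[int]) -> pd.DataFrame:
    """Facility estimates across a grid of step sizes and counts.

    Returns a long-format table with per-cell mean and SD of duration and
    facility across records plus the maximum IOP elevation (size x count).
    Cells with fewer than two steps cannot support a regression and are
    flagged unconverged.
    """
    rows = []
    for size in step_sizes:
        for n in n_steps_list:
            sub = replace(plan, step_size=size, n_steps=n)
            df = run_cohort(sub, records)
            fac = df["facility_nl"].to_numpy(float)
            rows.append(dict(
                step_size=size, n_steps=n, max_elevation=size * n,
                duration_mean=float(df["duration_min"].mean()),
                duration_sd=float(df["duration_min"].std(ddof=1)) if len(df) > 1 else 0.0,
                facility_mean=float(np.nanmean(fac)) if np.isfinite(fac).any() else float("nan"),
                facility_sd=float(np.nanstd(fac, ddof=1)) if np.isfinite(fac).sum() > 1 else float("nan"),
                all_converged=bool(df["converged"].all()),
            ))
    return pd.DataFrame(rows)


def optimize_filter_width(mode: str, records: Sequence, widths_min: Sequence[float],
                          criterion: str = "window",
                          eye: Optional[EyeParams] = None,
                          sys: Optional[SystemParams] = None,
                          step_size: Optional[float] = None,
                          timeout: float = 90.0) -> tuple[float, pd.DataFrame]:
    """Settling time of a single step versus data-filter width.

    For each width and record, one input step is simulated and the criterion
    applied to the filtered response; runs that never detect are counted at
    the timeout.  The best width minimizes mean + SD of settling time across
    records (fastest with least variability).
    """
    if len(records) < 2:
        raise ValueError("need at least two noise records")
    eye = eye or EyeParams()
    sys = sys or SystemParams(system_resistance=0.6)
    step = step_size if step_size is not None else default_step_size(mode)
    rows = []
    for width in widths_min:
        settles = []
        for rec in records:
            cfg = CriterionConfig(criterion=criterion, filter_width=width,
                                  timeout=timeout)
            plan = ExperimentPlan(mode=mode, eye=eye, sys=sys, criterion=cfg,
                                  noise=rec, n_steps=1, step_size=step)
            res = run_experiment(plan)
            settles.append(res.steps[0].detection.settle_time)
        settles = np.array(settles)
        rows.append(dict(width_min=width, mean=float(settles.mean()),
                         sd=float(settles.std(ddof=1)),
                         n_timeout=int(np.sum(settles >= timeout - 1e-9))))
    table = pd.DataFrame(rows)
    table["score"] = table["mean"] + table["sd"]
    best = float(table.loc[table["score"].idxmin(), "width_min"])
    return best, table
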