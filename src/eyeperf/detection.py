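"""Steady-state detection on noisy perfusion traces.

Three criteria decide when a pressure/flow step response has plateaued:

* **window** — the system pressure varied by less than 10% of the input step
  size over a trailing 5-min window;
* **ratio** — the least-squares slope of F_S/P_S over a trailing 5-min window
  stayed below 0.1 nl/min^2/mmHg for 1 min;
* **fitting** — pressure and flow are recursively regressed against
  first-order step responses ``PS* = A(1 - exp(-t/tau)) + B`` and
  ``FS* = C exp(-t/tau) + D`` (shared tau), and steady state is declared once
  the fitted responses vary less than 0.5 mmHg and 0.05 ul/min over a 2-min
  period lying more than 6 tau after step onset.

Raw data may first be smoothed with a trailing moving average of width T;
criterion windows are then only evaluated once the filter is fully
initialized.  The window and ratio criteria can also be applied to the fitted
response — the time series of current-fit predictions, refreshed at 1-s
increments — which is what makes steady-state detection robust to the large
sporadic IOP bumps of conscious animals: early bumps are progressively
outvoted as the regression accumulates data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve

__all__ = [
    "CriterionConfig", "DetectionResult", "FitState", "RecursiveFitter",
    "smooth", "window_criterion", "ratio_criterion", "recursive_fit",
    "fitting_criterion", "optimize_filter_width",
    "scan_window", "scan_ratio",
]


@dataclass(frozen=True)
class CriterionConfig:
    """Thresholds of the steady-state criteria (published defaults)."""

    criterion: str = "window"            # window | ratio | fitting
    window_length: float = 5.0           # min
    window_threshold_fraction: float = 0.10   # of pressure step size
    ratio_slope_threshold: float = 0.1   # nl/min^2/mmHg
    ratio_hold: float = 1.0              # min
    filter_width: float = 0.0            # min; 0 = raw data
    use_fitted: bool = False             # run window/ratio on fitted response
    fit_start: float = 2.0               # min after onset before first fit
    fit_update: float = 1.0              # s between fit refreshes
    fit_press_tol: float = 0.5           # mmHg
    fit_flow_tol: float = 0.05           # ul/min
    fit_hold: float = 2.0                # min
    fit_min_elapsed: float = 6.0         # multiples of fitted tau
    timeout: float = 90.0                # min per step

    def __post_init__(self):
        if self.criterion not in ("window", "ratio", "fitting"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for name in ("window_length", "window_threshold_fraction",
                     "ratio_slope_threshold", "ratio_hold", "fit_press_tol",
                     "fit_flow_tol", "fit_hold", "fit_min_elapsed", "timeout"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.filter_width < 0:
            raise ValueError("filter_width must be >= 0")

    @property
    def needs_fit(self) -> bool:
        return self.criterion == "fitting" or self.use_fitted


@dataclass
class FitState:
    """Parameters of the recursive first-order regression."""

    a: float      # mmHg, pressure excursion
    b: float      # mmHg, pressure offset
    c: float      # ul/min, flow excursion
    d: float      # ul/min, flow asymptote
    tau: float    # min
    press_resid: float
    flow_resid: float
    t_fit: float  # min since onset of the newest sample used
    degenerate: bool = False

    @property
    def p_plateau(self) -> float:
        return self.a + self.b

    @property
    def f_plateau(self) -> float:
        return self.d

    def predict(self, t_min):
        """(PS*, FS*) at times (min since step onset)."""
        e = np.exp(-np.asarray(t_min, float) / self.tau)
        return self.a * (1.0 - e) + self.b, self.c * e + self.d


@dataclass
class DetectionResult:
    """Outcome of one steady-state detection."""

    criterion: str
    settle_time: float        # min from step onset
    steady_p_s: float
    steady_f_s: float
    steady_p_e: float
    steady_f_e: float
    converged: bool
    fit: Optional[FitState] = None


# ---------------------------------------------------------------------------
# smoothing and vectorized scanners

def smooth(y: np.ndarray, width_min: float, dt_min: float) -> np.ndarray:
    """Trailing moving average of width T; grows from the first sample.

    ``width_min = 0`` is the identity.  Early samples average whatever data
    exists (growing window) so the smoothed series starts at the first sample
    rather than after a dead time.
    """
    if width_min <= 0:
        return np.asarray(y, float).copy()
    y = np.asarray(y, float)
    m = max(1, int(round(width_min / dt_min)))
    c = np.concatenate([[0.0], np.cumsum(y)])
    out = np.empty_like(y)
    k = np.arange(len(y))
    full = k >= m - 1
    out[full] = (c[k[full] + 1] - c[k[full] + 1 - m]) / m
    out[~full] = c[k[~full] + 1] / (k[~full] + 1)
    return out


def _trailing_range(y: np.ndarray, w: int):
    """max - min over the trailing window of w samples ending at each index."""
    origin = (w - 1) // 2
    mx = maximum_filter1d(y, w, origin=origin, mode="nearest")
    mn = minimum_filter1d(y, w, origin=origin, mode="nearest")
    return mx - mn


def scan_window(p_s: np.ndarray, dt_min: float, step_pressure: float,
                cfg: CriterionConfig, min_index: int = 0) -> Optional[int]:
    """Earliest sample index satisfying the window criterion, else None.

    ``p_s`` starts at the step onset.  ``min_index`` delays evaluation (used
    when a data filter must initialize first).
    """
    w = int(round(cfg.window_length / dt_min))
    start = max(w - 1, min_index)
    if len(p_s) <= start:
        return None
    rng = _trailing_range(p_s, w)
    ok = rng < cfg.window_threshold_fraction * step_pressure
    ok[:start] = False
    idx = np.nonzero(ok)[0]
    return int(idx[0]) if len(idx) else None


def scan_ratio(p_s: np.ndarray, f_s: np.ndarray, dt_min: float,
               cfg: CriterionConfig, min_index: int = 0) -> Optional[int]:
    """Earliest index satisfying the ratio criterion, else None.

    The least-squares slope of F_S/P_S (nl/min/mmHg against minutes) over the
    trailing window must stay below threshold in absolute value for the hold
    time; detection is at the end of the hold.
    """
    w = int(round(cfg.window_length / dt_min))
    hold = max(1, int(round(cfg.ratio_hold / dt_min)))
    if len(p_s) < max(w + hold - 1, min_index + 1):
        return None
    if np.any(p_s <= 0):
        raise ValueError("ratio criterion undefined: P_S <= 0 in trace")
    ratio_nl = 1000.0 * np.asarray(f_s, float) / np.asarray(p_s, float)
    t = np.arange(w) * dt_min
    tc = t - t.mean()
    kernel = tc[::-1] / np.sum(tc * tc)
    slope = fftconvolve(ratio_nl, kernel, mode="valid")  # ends at w-1 .. n-1
    ok = np.abs(slope) < cfg.ratio_slope_threshold
    if min_index > w - 1:
        ok[:min_index - (w - 1)] = False
    c = np.concatenate([[0], np.cumsum(ok)])
    runs = c[hold:] - c[:-hold]          # ok-count in hold-length windows
    hit = np.nonzero(runs == hold)[0]    # window ends at hit + hold - 1
    if len(hit) == 0:
        return None
    return int(hit[0] + hold - 1 + w - 1)


# ---------------------------------------------------------------------------
# recursive exponential regression

def _exp_design_fit(t: np.ndarray, y: np.ndarray, tau: float):
    """Least squares of y ~ a0 + a1*exp(-t/tau); returns (a0, a1, sse)."""
    e = np.exp(-t / tau)
    n = len(t)
    se, see = e.sum(), (e * e).sum()
    sy, sey = y.sum(), (e * y).sum()
    det = n * see - se * se
    if det <= 1e-12 * max(n * see, 1.0):
        a0 = y.mean()
        return a0, 0.0, float(((y - a0) ** 2).sum())
    a1 = (n * sey - se * sy) / det
    a0 = (sy - a1 * se) / n
    r = y - a0 - a1 * e
    return a0, a1, float((r * r).sum())


def recursive_fit(p_s: np.ndarray, f_s: np.ndarray, t_min: np.ndarray,
                  cfg: CriterionConfig = CriterionConfig(criterion="fitting"),
                  prev: Optional[FitState] = None,
                  flow_weight: float = 100.0) -> FitState:
    """Joint first-order regression of pressure and flow with shared tau.

    Given tau the model is linear, so the fit profiles a weighted sum of the
    two conditional linear least-squares objectives over tau (bounded scalar
    minimization, warm-started from ``prev``).  Flow residuals are weighted
    by the ratio of typical scales (1 mmHg : 0.01 ul/min).
    """
    t = np.asarray(t_min, float)
    p = np.asarray(p_s, float)
    f = np.asarray(f_s, float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to fit")
    span = t[-1] - t[0]
    lo, hi = max(span * 1e-3, 1e-4), span * 5.0
    w2 = flow_weight ** 2

    def objective(log_tau):
        tau = np.exp(log_tau)
        _, _, sp = _exp_design_fit(t, p, tau)
        _, _, sf = _exp_design_fit(t, f, tau)
        return sp + w2 * sf

    # local refinement around the previous tau, else a coarse bracket scan
    if prev is not None and lo < prev.tau < hi and not prev.degenerate:
        a, b = np.log(prev.tau / 4.0), np.log(prev.tau * 4.0)
        a, b = max(a, np.log(lo)), min(b, np.log(hi))
    else:
        grid = np.linspace(np.log(lo), np.log(hi), 25)
        best = grid[np.argmin([objective(g) for g in grid])]
        a, b = best - 0.5, best + 0.5
    res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    tau = float(np.exp(res.x))
    a0p, a1p, sp = _exp_design_fit(t, p, tau)
    a0f, a1f, sf = _exp_design_fit(t, f, tau)
    # pressure: PS* = (A+B) - A e  -> a0 = A+B, a1 = -A
    # flow:     FS* = D + C e      -> a0 = D,   a1 = C
    scale_p = max(np.ptp(p), 1e-9)
    scale_f = max(np.ptp(f), 1e-9)
    degenerate = (abs(a1p) < 1e-3 * max(scale_p, 1e-3)
                  and abs(a1f) < 1e-3 * max(scale_f, 1e-3)) \
        or tau >= hi * 0.999 or tau <= lo * 1.001
    return FitState(a=-a1p, b=a0p + a1p, c=a1f, d=a0f, tau=tau,
                    press_resid=np.sqrt(sp / len(t)),
                    flow_resid=np.sqrt(sf / len(t)),
                    t_fit=float(t[-1]), degenerate=degenerate)


class RecursiveFitter:
    """Accumulates a step response and refits it at fixed increments.

    Raw samples (model update rate) are block-averaged to the fit update
    interval (1 s by default); each new block past ``fit_start`` triggers a
    refit on all data since onset, warm-started from the previous fit.  The
    *fitted response* is the series of current-fit predictions, one per
    block, with the first fit backfilling predictions from step onset.
    """

    def __init__(self, cfg: CriterionConfig, dt_s: float):
        self.cfg = cfg
        self.dt_s = dt_s
        self.block = max(1, int(round(cfg.fit_update / dt_s)))
        self.block_min = self.block * dt_s / 60.0
        self._raw_p: list[np.ndarray] = []
        self._raw_f: list[np.ndarray] = []
        self._nraw = 0
        self.t_blocks = np.empty(0)
        self.p_blocks = np.empty(0)
        self.f_blocks = np.empty(0)
        self.ps_star = np.empty(0)
        self.fs_star = np.empty(0)
        # per-update fitted asymptotes: the steady-state predictions whose
        # stability the fitting criterion monitors
        self.p_plat = np.empty(0)
        self.f_plat = np.empty(0)
        self.fit: Optional[FitState] = None
        self.first_fit_index: Optional[int] = None  # block of the first fit
        self.ever_converged = False

    def extend(self, p_chunk: np.ndarray, f_chunk: np.ndarray) -> None:
        self._raw_p.append(np.asarray(p_chunk, float))
        self._raw_f.append(np.asarray(f_chunk, float))
        self._nraw += len(p_chunk)
        n_blocks = self._nraw // self.block
        if n_blocks <= len(self.t_blocks):
            return
        p = np.concatenate(self._raw_p)
        f = np.concatenate(self._raw_f)
        self._raw_p, self._raw_f = [p], [f]
        m = n_blocks * self.block
        pb = p[:m].reshape(n_blocks, self.block).mean(axis=1)
        fb = f[:m].reshape(n_blocks, self.block).mean(axis=1)
        tb = (np.arange(n_blocks) + 1) * self.block_min  # block end times
        new_lo = len(self.t_blocks)
        self.t_blocks, self.p_blocks, self.f_blocks = tb, pb, fb
        preds_p = list(self.ps_star)
        preds_f = list(self.fs_star)
        plat_p = list(self.p_plat)
        plat_f = list(self.f_plat)
        for i in range(new_lo, n_blocks):
            if tb[i] >= self.cfg.fit_start and i + 1 >= 3:
                try:
                    self.fit = recursive_fit(pb[:i + 1], fb[:i + 1],
                                             tb[:i + 1], self.cfg, self.fit)
                    self.ever_converged = True
                    if self.first_fit_index is None:
                        self.first_fit_index = i
                except Exception:
                    pass  # keep previous fit
            if self.fit is not None:
                if len(preds_p) < i:  # first fit: backfill from onset
                    tfill = tb[len(preds_p):i]
                    pp, ff = self.fit.predict(tfill)
                    preds_p.extend(pp)
                    preds_f.extend(ff)
                    plat_p.extend([self.fit.p_plateau] * (i - len(plat_p)))
                    plat_f.extend([self.fit.f_plateau] * (i - len(plat_f)))
                pp, ff = self.fit.predict(tb[i])
                preds_p.append(float(pp))
                preds_f.append(float(ff))
                plat_p.append(self.fit.p_plateau)
                plat_f.append(self.fit.f_plateau)
        self.ps_star = np.array(preds_p)
        self.fs_star = np.array(preds_f)
        self.p_plat = np.array(plat_p)
        self.f_plat = np.array(plat_f)

    @property
    def pred_offset(self) -> int:
        """Index of the first block that has a prediction."""
        return len(self.t_blocks) - len(self.ps_star)

    def scan(self, step_pressure: float, min_index_blocks: int = 0) -> Optional[int]:
        """Detection index (raw-sample units) for the configured criterion."""
        cfg = self.cfg
        if len(self.ps_star) == 0:
            return None
        off = self.pred_offset
        if cfg.criterion == "window":
            i = scan_window(self.ps_star, self.block_min, step_pressure, cfg,
                            min_index=max(min_index_blocks - off, 0))
        elif cfg.criterion == "ratio":
            i = scan_ratio(self.ps_star, self.fs_star, self.block_min, cfg,
                           min_index=max(min_index_blocks - off, 0))
        else:
            i = self._scan_fitting()
        if i is None:
            return None
        return (i + off + 1) * self.block - 1

    def _scan_fitting(self) -> Optional[int]:
        """Stability of the fitted responses and their asymptotes.

        Both the prediction series and the per-update fitted plateaus must
        deviate less than the pressure/flow tolerances over the trailing
        hold window; monitoring the asymptotes is what stops a fast fitted
        time constant from declaring steady state while the plateau estimate
        is still drifting.
        """
        cfg = self.cfg
        if self.fit is None:
            return None
        hold = int(round(cfg.fit_hold / self.block_min))
        w = hold  # trailing window of fit_hold minutes
        n = len(self.ps_star)
        if n < w:
            return None
        rng_p = np.maximum(_trailing_range(self.ps_star, w),
                           _trailing_range(self.p_plat, w))
        rng_f = np.maximum(_trailing_range(self.fs_star, w),
                           _trailing_range(self.f_plat, w))
        off = self.pred_offset
        t = self.t_blocks[off:]
        # the hold window must lie beyond fit_min_elapsed * tau after onset
        tau = self.fit.tau if not self.fit.degenerate else 0.0
        ok = (rng_p < cfg.fit_press_tol) & (rng_f < cfg.fit_flow_tol) \
            & (t - cfg.fit_hold >= cfg.fit_min_elapsed * tau)
        # the hold window must consist entirely of genuine fit updates, not
        # predictions backfilled by the first fit
        first = (self.first_fit_index or 0) - off
        ok[:max(w - 1, first + w - 1)] = False
        idx = np.nonzero(ok)[0]
        return int(idx[0]) if len(idx) else None


# ---------------------------------------------------------------------------
# one-shot criterion application to complete traces

def _steady_from_window(trace, det: int, w: int) -> tuple:
    lo = max(0, det - w + 1)
    return (float(trace.p_s[lo:det + 1].mean()),
            float(trace.f_s[lo:det + 1].mean()),
            float(trace.p_e[lo:det + 1].mean()),
            float(trace.f_e[lo:det + 1].mean()))


def _timeout_result(criterion, trace, cfg) -> DetectionResult:
    w = int(round(cfg.window_length / trace.dt_min))
    p, f, pe, fe = _steady_from_window(trace, len(trace) - 1, w)
    return DetectionResult(criterion, min(len(trace) * trace.dt_min, cfg.timeout),
                           p, f, pe, fe, converged=False)


def window_criterion(trace, pressure_step_size: float,
                     cfg: CriterionConfig = CriterionConfig()) -> DetectionResult:
    """Apply the window criterion to a single-step trace (onset at sample 0).

    Steady-state values are means over the final criterion window.  For
    constant-flow steps pass the pressure-equivalent step size
    ``(R_C + R_T) * dF``, since the 10% rule is expressed in pressure units.
    """
    dt = trace.dt_min
    p = smooth(trace.p_s, cfg.filter_width, dt)
    nf = int(round(cfg.filter_width / dt)) if cfg.filter_width > 0 else 0
    w = int(round(cfg.window_length / dt))
    det = scan_window(p, dt, pressure_step_size, cfg, min_index=nf + w - 1 if nf else 0)
    if det is None:
        return _timeout_result("window", trace, cfg)
    ps, fs, pe, fe = _steady_from_window(trace, det, w)
    return DetectionResult("window", (det + 1) * dt, ps, fs, pe, fe, True)


def ratio_criterion(trace, cfg: CriterionConfig = CriterionConfig(criterion="ratio")
                    ) -> DetectionResult:
    """Apply the ratio criterion to a single-step trace (onset at sample 0)."""
    dt = trace.dt_min
    p = smooth(trace.p_s, cfg.filter_width, dt)
    f = smooth(trace.f_s, cfg.filter_width, dt)
    nf = int(round(cfg.filter_width / dt)) if cfg.filter_width > 0 else 0
    w = int(round(cfg.window_length / dt))
    det = scan_ratio(p, f, dt, cfg,
                     min_index=nf + w - 1 if nf else 0)
    if det is None:
        return _timeout_result("ratio", trace, cfg)
    ps, fs, pe, fe = _steady_from_window(trace, det, w)
    return DetectionResult("ratio", (det + 1) * dt, ps, fs, pe, fe, True)


def fitting_criterion(trace, cfg: CriterionConfig = CriterionConfig(criterion="fitting"),
                      cannula_resistance: float = 0.36) -> DetectionResult:
    """Apply the fitting criterion to a single-step trace (onset at sample 0).

    Steady-state values are the fitted asymptotes, mapped to eye pressure and
    inflow through the plateau relations ``F_E = F_S`` and
    ``P_E = P_S - R_C F_S``.
    """
    fitter = RecursiveFitter(cfg, trace.sample_period)
    fitter.extend(trace.p_s, trace.f_s)
    det = fitter.scan(step_pressure=np.inf)
    if det is None or fitter.fit is None:
        res = _timeout_result("fitting", trace, cfg)
        res.fit = fitter.fit
        return res
    fit = fitter.fit
    ps, fs = fit.p_plateau, fit.f_plateau
    return DetectionResult("fitting", (det + 1) * trace.dt_min, ps, fs,
                           ps - cannula_resistance * fs, fs, True, fit=fit)


def optimize_filter_width(mode: str, records, widths_min, criterion: str,
                          **kwargs):
    """Pick the data-filter width that settles fastest with least variability.

    Thin wrapper over :func:`eyeperf.experiment.optimize_filter_width`; see
    that function for the simulation details.
    """
    from .experiment import optimize_filter_width as _impl
    return _impl(mode, records, widths_min, criterion, **kwargs)
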