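"""Perfusion control schemes as input policies over the circuit model.

Four schemes are modelled.  CF fixes the source flow.  CPg sets a reservoir
pressure that drives flow through the system resistance R_S (analog,
instantaneous feedback with gain 1/R_S).  CPp commands pump flow
proportionally to the error between target and measured pressure,
``F_S = K (P_T - P_S)``, updated digitally once per update interval with a
one-update delay.  CPpx is a low-gain CPp variant (K = 0.3 by default) whose
feedback signal is smoothed with a trailing moving average (15 s by default)
— the combination that trades a little speed for much lower flow noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import EyeParams, SystemParams, ParameterError
from .model import MODES, Simulator, steady_state, settling_time

__all__ = [
    "ControllerSpec", "StepInput", "make_input", "commanded_flow",
    "controller_system", "gain_sweep",
]

#: published gain presets: CPg1/CPg2 are the high/low flow-sensor impedances,
#: CPp the pump gain scaled for rat eyes, CPpx the smoothed low-gain pump
PRESETS = {
    "CPg1": dict(mode="CPg", gain=10.0),
    "CPg2": dict(mode="CPg", gain=0.6),
    "CPp": dict(mode="CPp", gain=7.0),
    "CPpx": dict(mode="CPpx", gain=0.3, feedback_filter_width=15.0),
}


@dataclass(frozen=True)
class ControllerSpec:
    """A perfusion scheme plus its gain and options.

    ``gain`` is R_S (mmHg*min/ul) for CPg and K (ul/min/mmHg) for CPp/CPpx;
    CF ignores it.  ``feedback_filter_width`` (s) smooths the pump's feedback
    signal; required > 0 for CPpx.  ``flow_limit`` optionally saturates the
    commanded pump flow (off by default, as published sources are
    unsaturated); negative commanded flow (withdrawal) is permitted.
    """

    mode: str = "CF"
    gain: Optional[float] = None
    feedback_filter_width: float = 0.0   # s
    flow_limit: Optional[float] = None   # ul/min

    def __post_init__(self):
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mode != "CF" and (self.gain is None or self.gain <= 0):
            raise ParameterError(f"{self.mode} requires a positive gain")
        if self.mode == "CPpx" and self.feedback_filter_width <= 0:
            raise ParameterError("CPpx requires feedback_filter_width > 0")

    @classmethod
    def preset(cls, name: str) -> "ControllerSpec":
        if name == "CF":
            return cls(mode="CF")
        return cls(**PRESETS[name])


def controller_system(spec: ControllerSpec,
                      base: Optional[SystemParams] = None) -> SystemParams:
    """System parameters with the controller's gain fields filled in."""
    base = base or SystemParams()
    kw = dict(system_resistance=None, feedback_gain=None,
              feedback_filter_width=spec.feedback_filter_width)
    if spec.mode == "CPg":
        kw["system_resistance"] = spec.gain
    elif spec.mode in ("CPp", "CPpx"):
        kw["feedback_gain"] = spec.gain
    return replace(base, **kw)


@dataclass(frozen=True)
class StepInput:
    """A staircase schedule for the controller's input level.

    ``kind`` is "flow" (F_S, CF), "pressure" (reservoir P, CPg) or "target"
    (P_T, CPp/CPpx).  Step ``i`` (0-based) raises the level to
    ``start + (i + 1) * magnitude`` at ``onsets_min[i]``.
    """

    kind: str
    magnitude: float              # ul/min or mmHg per step
    onsets_min: tuple = (0.0,)
    start: float = 0.0            # pre-step level

    def __post_init__(self):
        if self.kind not in ("flow", "pressure", "target"):
            raise ValueError(f"unknown step kind {self.kind!r}")
        if list(self.onsets_min) != sorted(self.onsets_min):
            raise ValueError("onsets must be nondecreasing")

    @classmethod
    def defaults(cls, mode: str, n_steps: int = 1,
                 spacing_min: float = 30.0, resting_iop: float = 15.0):
        """Published defaults: 0.1 ul/min flow steps (CF), 5 mmHg CP steps."""
        onsets = tuple(i * spacing_min for i in range(n_steps))
        if mode == "CF":
            return cls("flow", 0.1, onsets, start=0.0)
        kind = "pressure" if mode == "CPg" else "target"
        return cls(kind, 5.0, onsets, start=resting_iop)


_KIND_FOR_MODE = {"CF": "flow", "CPg": "pressure", "CPp": "target",
                  "CPpx": "target"}


def make_input(spec: ControllerSpec, steps: StepInput):
    """Piecewise-constant input schedule ``t_min -> level`` for a controller.

    For CF the level is the source flow; for CPg the reservoir pressure; for
    CPp/CPpx the target pressure that the simulator's digital proportional
    loop (with the spec's feedback smoothing) chases.
    """
    if steps.kind != _KIND_FOR_MODE[spec.mode]:
        raise ParameterError(
            f"{spec.mode} expects step kind {_KIND_FOR_MODE[spec.mode]!r}, "
            f"got {steps.kind!r}")
    onsets = np.asarray(steps.onsets_min, float)
    start, mag = steps.start, steps.magnitude

    def input_fn(t_min: float) -> float:
        return start + mag * int(np.searchsorted(onsets, t_min, side="right"))

    return input_fn


def commanded_flow(spec: ControllerSpec, target: float, measured: float) -> float:
    """Instantaneous proportional pump command F_S = K (P_T - P_S).

    With the published K = 7 a fresh 5-mmHg error commands 35 ul/min — about
    tenfold the eventual plateau flow, which is what makes high-gain pump
    systems fast (and briefly violent).
    """
    if spec.mode not in ("CPp", "CPpx"):
        raise ParameterError("commanded_flow applies to pump modes only")
    f = spec.gain * (target - measured)
    if spec.flow_limit is not None:
        f = float(np.clip(f, -spec.flow_limit, spec.flow_limit))
    return f


def gain_sweep(mode: str, gains: Sequence[float], eye: Optional[EyeParams] = None,
               base: Optional[SystemParams] = None,
               step_level: Optional[float] = None,
               max_duration_min: float = 600.0,
               convention: str = "excursion") -> pd.DataFrame:
    """Noise-free settling time versus feedback gain.

    ``gains`` are R_S values for CPg and K values for CPp; CF has no gain
    dependence and simply repeats its settling time across the grid.  The
    step is the published default (0.1 ul/min flow or a 5-mmHg pressure
    step).  Settling times are measured against the analytic plateau; the
    simulation horizon doubles until the response settles (NaN past
    ``max_duration_min``).
    """
    eye = eye or EyeParams()
    base = base or SystemParams()
    rows = []
    for g in gains:
        if mode == "CF":
            sysp = base
            level = step_level if step_level is not None else 0.1
        elif mode == "CPg":
            sysp = replace(base, system_resistance=float(g), feedback_gain=None)
            level = step_level if step_level is not None else eye.resting_iop + 5.0
        elif mode in ("CPp", "CPpx"):
            sysp = replace(base, feedback_gain=float(g), system_resistance=None)
            level = step_level if step_level is not None else eye.resting_iop + 5.0
        else:
            raise ParameterError(f"unknown mode {mode!r}")
        plat = steady_state(mode, level, eye, sysp)
        pre = steady_state(mode, 0.0 if mode == "CF" else eye.resting_iop,
                           eye, sysp)
        # very low R_S makes the system stiff; keep the RK4 step inside the
        # stability region (|h lambda| < 2.78) by refining dt where needed
        from .model import build_state_space
        realization = {"CF": "flow", "CPg": "gravity", "CPp": "flow",
                       "CPpx": "flow"}[mode]
        A, _, _ = build_state_space(eye, sysp, realization)
        lam_max = float(np.max(np.abs(np.linalg.eigvals(A))))
        dt_s = min(sysp.update_interval, 60.0 * 2.0 / lam_max)
        dur = 30.0
        t = float("nan")
        while dur <= max_duration_min:
            sim = Simulator(mode, eye, sysp, dt_s=dt_s)
            tr = sim.run(level, dur)
            t = settling_time(tr, plat, pre, convention=convention)
            if np.isfinite(t):
                break
            dur *= 2.0
        # Fig-2B-style feedback gain: 1/R_S for gravity systems, K for pumps
        geq = 1.0 / g if mode == "CPg" else (float(g) if mode != "CF" else np.nan)
        rows.append(dict(mode=mode, gain=float(g), gain_equivalent=geq,
                         settling_min=t))
    return pd.DataFrame(rows)
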