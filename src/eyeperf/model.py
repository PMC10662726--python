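"""Dynamical core: the viscoelastic eye + perfusion-system circuit model.

The eye and perfusion hardware form a linear hydraulic circuit.  Fluid is
driven either by a flow source F_S (constant-flow and pump-driven
constant-pressure modes) or by a reservoir pressure P through the system
resistance R_S (gravity-driven constant-pressure mode), charges the system
compliance C_S at pressure P_S, and enters the eye through the cannula
resistance R_C at pressure P_E.  The eye drains through the trabecular
resistance R_T toward the resting pressure and distends its viscoelastic wall,
a standard linear solid: compliance C_W2 in series with the parallel pair
(R_W, C_W1).

The model is integrated as a 3-state system (states: P_S and the pressures
across C_W1 and C_W2) with a fixed-step fourth-order Runge-Kutta scheme at the
feedback update interval (0.1 s by default).  Because the system is linear and
inputs are held constant over each update, the RK4 step reduces to a
precomputed affine map (the fourth-order Taylor propagator), which is applied
either sample-by-sample (digital feedback) or vectorized through a
diagonalized recurrence.  The scalar third-order pressure equation in P_S is
recovered exactly: the characteristic polynomial of the state matrix equals
(alpha*R_C*C_S, alpha + beta*C_S, gamma, 1), with the gravity-mode variant
including R_S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Union

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .params import EyeParams, SystemParams, ParameterError, compute_coefficients

__all__ = [
    "MODES", "Trace", "ModelState", "SteadyState", "Simulator",
    "build_state_space", "integrate", "steady_state", "settling_time",
    "recover_eye_state", "SimulationDiverged",
]

MODES = ("CF", "CPg", "CPp", "CPpx")

#: internal input conventions for the state-space builder
_REALIZATIONS = ("flow", "gravity", "pump_analog")


class SimulationDiverged(RuntimeError):
    """Integration produced a non-finite state."""

    def __init__(self, time_min: float):
        self.time_min = time_min
        super().__init__(f"simulation diverged at t = {time_min:.3f} min")


class SteadyState(NamedTuple):
    """Plateau pressures (mmHg) and flows (ul/min)."""

    p_s: float
    f_s: float
    p_e: float
    f_e: float


def build_state_space(eye: EyeParams, sys: SystemParams, realization: str = "flow",
                      gain: Optional[float] = None):
    """Continuous-time affine system dx/dt = A x + B u + c.

    States are ``x = (P_S, u1, u2)`` where ``u1`` is the pressure across the
    parallel (R_W, C_W1) element and ``u2`` the pressure across C_W2, so that
    ``P_E = u1 + u2``.  The input ``u`` is the source flow F_S
    (``realization="flow"``), the reservoir pressure P (``"gravity"``, flow
    enters as (P - P_S)/R_S), or the target pressure P_T (``"pump_analog"``,
    flow enters as gain*(P_T - P_S) continuously).
    """
    if realization not in _REALIZATIONS:
        raise ValueError(f"unknown realization {realization!r}")
    rc = sys.cannula_resistance
    cs = sys.system_compliance
    rt = eye.trabecular_resistance
    rw = eye.wall_resistance
    c1, c2 = eye.wall_compliance_1, eye.wall_compliance_2
    pe_bar = eye.resting_iop
    if cs <= 0:
        raise ParameterError("integration requires system_compliance > 0")
    a = 1.0 / rc
    b = 1.0 / rt
    # wall inflow f_w = a*(P_S - P_E) - b*(P_E - Pbar);  P_E = u1 + u2
    A = np.array([
        [-a / cs, a / cs, a / cs],
        [a / c1, (-(a + b) - (1.0 / rw if rw > 0 else 0.0)) / c1, -(a + b) / c1],
        [a / c2, -(a + b) / c2, -(a + b) / c2],
    ])
    B = np.array([1.0 / cs, 0.0, 0.0])
    c = np.array([0.0, b * pe_bar / c1, b * pe_bar / c2])
    if rw == 0:
        # parallel element shorted: u1 is pinned at zero, order drops by one
        A[1, :] = 0.0
        c[1] = 0.0
    if realization == "gravity":
        rs = sys.system_resistance
        if rs is None:
            raise ParameterError("gravity realization requires system_resistance")
        A = A.copy()
        A[0, 0] -= 1.0 / (rs * cs)
        B = np.array([1.0 / (rs * cs), 0.0, 0.0])
    elif realization == "pump_analog":
        if gain is None:
            raise ParameterError("pump_analog realization requires a gain")
        A = A.copy()
        A[0, 0] -= gain / cs
        B = np.array([gain / cs, 0.0, 0.0])
    return A, B, c


def rk4_maps(A: np.ndarray, dt_min: float):
    """One-step RK4 propagator for dx/dt = A x + d with d constant over the step.

    Classical RK4 applied to a linear system equals the fourth-order Taylor
    map: ``x_next = Phi x + M d`` with ``Phi = sum_{j=0..4} (h A)^j / j!`` and
    ``M = sum_{j=1..4} h^j A^{j-1} / j!``.
    """
    n = A.shape[0]
    eye_n = np.eye(n)
    phi = eye_n.copy()
    m = np.zeros_like(A)
    a_pow = eye_n.copy()  # A^(j-1) running power
    fact = 1.0
    for j in range(1, 5):
        fact *= j
        m = m + a_pow * dt_min**j / fact
        a_pow = a_pow @ A
        phi = phi + a_pow * dt_min**j / fact
    return phi, m


@dataclass
class ModelState:
    """Full dynamical state at an instant.

    ``x = (P_S, u1, u2)`` maps invertibly to the scalar-form triple
    (P_S, dP_S/dt, d2P_S/dt2) given the instantaneous input level; see
    :meth:`scalar_view` / :meth:`from_scalar`.
    """

    time_min: float
    x: np.ndarray  # (P_S, u1, u2), mmHg

    @classmethod
    def resting(cls, eye: EyeParams, time_min: float = 0.0) -> "ModelState":
        """Equilibrium at resting pressure with no source flow."""
        return cls(time_min, np.array([eye.resting_iop, 0.0, eye.resting_iop]))

    @property
    def p_s(self) -> float:
        return float(self.x[0])

    @property
    def p_e(self) -> float:
        return float(self.x[1] + self.x[2])

    def scalar_view(self, eye: EyeParams, sys: SystemParams, u: float,
                    realization: str = "flow", gain: Optional[float] = None):
        """(P_S, dP_S/dt, d2P_S/dt2) for a constant input level ``u``."""
        A, B, c = build_state_space(eye, sys, realization, gain)
        dx = A @ self.x + B * u + c
        ddx = A @ dx
        return float(self.x[0]), float(dx[0]), float(ddx[0])

    @classmethod
    def from_scalar(cls, ps: float, dps: float, d2ps: float,
                    eye: EyeParams, sys: SystemParams, u: float,
                    realization: str = "flow", gain: Optional[float] = None,
                    time_min: float = 0.0) -> "ModelState":
        """Invert :meth:`scalar_view` (unique for a nondegenerate wall)."""
        A, B, c = build_state_space(eye, sys, realization, gain)
        # unknowns (u1, u2); two linear conditions from dP_S and d2P_S
        rhs1 = dps - A[0, 0] * ps - B[0] * u - c[0]
        row2 = A[0] @ A
        rhs2 = d2ps - row2[0] * ps - (A @ (B * u + c))[0]
        mat = np.array([[A[0, 1], A[0, 2]], [row2[1], row2[2]]])
        u1, u2 = np.linalg.solve(mat, [rhs1, rhs2])
        return cls(time_min, np.array([ps, u1, u2]))


@dataclass
class Trace:
    """Uniformly sampled record of a simulation.

    ``p_s``/``f_s`` are the system pressure (mmHg) and source flow (ul/min) as
    a data-acquisition system would record them (including injected pressure
    noise); ``p_e``/``f_e`` are the eye pressure and eye inflow.  ``states``
    optionally keeps the full model state per sample so a run can be resumed
    from any instant.
    """

    sample_period: float  # s
    p_s: np.ndarray
    f_s: np.ndarray
    p_e: np.ndarray
    f_e: np.ndarray
    t0_min: float = 0.0
    states: Optional[np.ndarray] = None  # (n, 3)

    def __post_init__(self):
        n = len(self.p_s)
        if not (len(self.f_s) == len(self.p_e) == len(self.f_e) == n):
            raise ValueError("trace series must have equal length")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")

    def __len__(self) -> int:
        return len(self.p_s)

    @property
    def dt_min(self) -> float:
        return self.sample_period / 60.0

    @property
    def t_min(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.t0_min + np.arange(len(self)) * self.dt_min

    def slice(self, i0: int, i1: Optional[int] = None) -> "Trace":
        sl = slice(i0, i1)
        return Trace(self.sample_period,
                     self.p_s[sl], self.f_s[sl], self.p_e[sl], self.f_e[sl],
                     t0_min=self.t0_min + i0 * self.dt_min,
                     states=None if self.states is None else self.states[sl])

    @staticmethod
    def concat(traces: list["Trace"]) -> "Trace":
        first = traces[0]
        states = None
        if all(t.states is not None for t in traces):
            states = np.concatenate([t.states for t in traces])
        return Trace(first.sample_period,
                     np.concatenate([t.p_s for t in traces]),
                     np.concatenate([t.f_s for t in traces]),
                     np.concatenate([t.p_e for t in traces]),
                     np.concatenate([t.f_e for t in traces]),
                     t0_min=first.t0_min, states=states)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t_min * 60.0,
            "p_s_mmHg": self.p_s,
            "f_s_ul_min": self.f_s,
            "p_e_mmHg": self.p_e,
            "f_e_ul_min": self.f_e,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("trace file needs at least two samples")
        dt_s = float(np.median(np.diff(t)))
        return cls(dt_s, df["p_s_mmHg"].to_numpy(float),
                   df["f_s_ul_min"].to_numpy(float),
                   df["p_e_mmHg"].to_numpy(float),
                   df["f_e_ul_min"].to_numpy(float),
                   t0_min=float(t[0]) / 60.0)


def steady_state(mode: str, level: float, eye: EyeParams,
                 sys: SystemParams) -> SteadyState:
    """Closed-form plateau for a constant input level.

    * CF: ``level`` is the source flow F_S; P_S = Pbar + (R_C + R_T) F_S.
    * CPg: ``level`` is the reservoir pressure P;
      F_S = (P - Pbar) / (R_S + R_C + R_T).
    * CPp/CPpx: ``level`` is the target pressure P_T;
      F_S = K (P_T - Pbar) / (1 + K (R_C + R_T)).

    At plateau F_E = F_S and P_E = P_S - R_C F_S for every mode.
    """
    rc, rt = sys.cannula_resistance, eye.trabecular_resistance
    pbar = eye.resting_iop
    if mode == "CF":
        f = level
    elif mode == "CPg":
        rs = sys.system_resistance
        if rs is None:
            raise ParameterError("CPg requires system_resistance")
        f = (level - pbar) / (rs + rc + rt)
    elif mode in ("CPp", "CPpx"):
        k = sys.feedback_gain
        if k is None:
            raise ParameterError("CPp requires feedback_gain")
        f = k * (level - pbar) / (1.0 + k * (rc + rt))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p_s = pbar + (rc + rt) * f
    p_e = p_s - rc * f
    if p_e < 0:
        raise ParameterError(f"input level {level} drives P_E below zero")
    return SteadyState(p_s=p_s, f_s=f, p_e=p_e, f_e=f)


class Simulator:
    """Stateful fixed-step simulator for one controller mode.

    The simulator owns the model state, the pressure-noise cursor and the
    controller's measurement history, so successive :meth:`run` calls continue
    seamlessly — exactly what a stepped facility experiment needs.

    Parameters
    ----------
    mode:
        "CF", "CPg", "CPp" or "CPpx".
    noise:
        Optional pressure disturbance: a ``NoiseRecord`` or a plain array of
        mmHg samples at the update rate.  Applied additively to the P_S state
        at each update; the record wraps when exhausted.
    analog:
        For CPp only: regulate flow continuously inside the integrator
        (equivalent to a gravity system with R_S = 1/K) instead of the
        digital, one-update-delayed regulation a real pump performs.
    """

    def __init__(self, mode: str, eye: EyeParams, sys: SystemParams,
                 noise=None, analog: bool = False,
                 dt_s: Optional[float] = None,
                 initial: Optional[ModelState] = None,
                 record_states: bool = True,
                 flow_limit: Optional[float] = None):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.eye = eye
        self.sys = sys
        self.analog = analog
        self.dt_s = float(dt_s if dt_s is not None else sys.update_interval)
        if self.dt_s <= 0:
            raise ParameterError("dt must be > 0")
        self.dt_min = self.dt_s / 60.0
        self.record_states = record_states
        self.flow_limit = flow_limit
        if mode == "CPg" and sys.system_resistance is None:
            raise ParameterError("CPg requires system_resistance")
        if mode in ("CPp", "CPpx") and sys.feedback_gain is None:
            raise ParameterError("CPp/CPpx requires feedback_gain")
        if mode == "CPpx" and sys.feedback_filter_width <= 0:
            raise ParameterError("CPpx requires feedback_filter_width > 0")

        realization = {"CF": "flow", "CPg": "gravity",
                       "CPp": "flow", "CPpx": "flow"}[mode]
        if mode == "CPp" and analog:
            realization = "pump_analog"
        self._A, self._B, self._c = build_state_space(
            eye, sys, realization, gain=sys.feedback_gain)
        self._phi, m = rk4_maps(self._A, self.dt_min)
        self._mb = m @ self._B
        self._mc = m @ self._c

        self.state = initial if initial is not None else ModelState.resting(eye)
        self.state = ModelState(self.state.time_min, np.asarray(self.state.x, float).copy())
        self._prev_noise = 0.0
        self._noise = self._prepare_noise(noise)
        self._noise_idx = 0
        # controller memory: recent measured P_S (most recent last); grows
        # from a single pre-step sample so feedback smoothing warms up on
        # whatever data exists rather than delaying control start
        self._nfilt = max(1, int(round(sys.feedback_filter_width / self.dt_s))) \
            if mode in ("CPp", "CPpx") else 1
        self._delay = int(sys.feedback_delay)
        self._depth = max(self._delay, 1) + self._nfilt + 1
        self._meas = [self.state.p_s]

    # -- noise plumbing ----------------------------------------------------
    def _prepare_noise(self, noise):
        if noise is None:
            return None
        samples = getattr(noise, "samples", noise)
        rate = getattr(noise, "sample_rate", 1.0 / self.dt_s)
        samples = np.asarray(samples, float)
        if abs(rate * self.dt_s - 1.0) > 1e-9:
            from .noise import NoiseRecord, resample
            rec = noise if hasattr(noise, "sample_rate") else \
                NoiseRecord(label="custom", sample_rate=rate, samples=samples)
            samples = resample(rec, 1.0 / self.dt_s).samples
        return samples

    def restore(self, x: np.ndarray, time_min: float, abs_sample: int,
                meas_tail) -> None:
        """Rewind to a previously recorded sample.

        ``abs_sample`` is the 0-based index of that sample counted over the
        whole simulation (it anchors the noise cursor so the disturbance
        sequence continues exactly where the restored sample left it);
        ``meas_tail`` re-seeds the controller's measurement history.
        """
        self.state = ModelState(time_min, np.asarray(x, float).copy())
        if self._noise is not None:
            n = len(self._noise)
            self._noise_idx = (abs_sample + 1) % n
            self._prev_noise = float(self._noise[abs_sample % n])
        self._meas = list(meas_tail)[-self._depth:] or [self.state.p_s]

    # -- main loop ---------------------------------------------------------
    def run(self, level: Union[float, Callable[[float], float]],
            duration_min: float) -> Trace:
        """Advance the simulation, holding or scheduling the input level.

        ``level`` may be a constant or a callable ``t_min -> level`` (time is
        absolute simulator time).  Returns the trace for this segment and
        leaves the simulator positioned at its end.
        """
        n = int(round(duration_min / self.dt_min))
        if n <= 0:
            raise ValueError("duration too short for one step")
        const = not callable(level)
        fast = (const and self.flow_limit is None and
                (self.mode in ("CF", "CPg") or
                 (self.mode == "CPp" and
                  (self.analog or (self._nfilt == 1 and self._delay == 1)))))
        with np.errstate(over="ignore", invalid="ignore"):
            if fast:
                tr = self._run_fast(float(level), n)
            else:
                tr = self._run_loop(level, n, const)
        if not np.isfinite(tr.p_s[-1]):
            bad = np.nonzero(~np.isfinite(tr.p_s))[0][0]
            raise SimulationDiverged(tr.t0_min + bad * self.dt_min)
        return tr

    def _noise_values(self, n: int) -> np.ndarray:
        """Noise samples (mmHg) overlaid on P_S for the next n samples."""
        if self._noise is None:
            return np.zeros(n)
        idx = (self._noise_idx + np.arange(n)) % len(self._noise)
        return self._noise[idx]

    def _finish(self, ps, fs, states, vals, n):
        # the noise is a common perturbation of the system and eye pressures,
        # so both recorded pressures carry it and the cannula flow does not
        pe = states[:, 1] + states[:, 2] + vals
        fe = (ps - pe) / self.sys.cannula_resistance
        t0 = self.state.time_min
        self.state = ModelState(t0 + n * self.dt_min, states[-1].copy())
        if self._noise is not None:
            self._prev_noise = float(vals[-1])
            self._noise_idx = (self._noise_idx + n) % len(self._noise)
        self._meas = (self._meas + list(ps[-self._depth:]))[-self._depth:]
        # samples sit one update after the segment start
        return Trace(self.dt_s, ps, fs, pe, fe, t0_min=t0 + self.dt_min,
                     states=states if self.record_states else None)

    def _run_fast(self, level: float, n: int) -> Trace:
        """Vectorized diagonalized recurrence for LTI-per-update modes."""
        vals = self._noise_values(n)
        phi, mb, mc = self._phi, self._mb, self._mc
        if self.mode == "CPp" and not self.analog:
            # the input held over each update interval is computed from the
            # noisy pressure measured at the interval's start (one-update
            # delay): u_j = K (P_T - ps_{j-1}), a linear closed loop with the
            # measurement noise entering through the pump command
            k = self.sys.feedback_gain
            tgt = level
            phi = phi - np.outer(mb * k, [1.0, 0.0, 0.0])
            drive = mb * k * tgt + mc
            prev_noise = np.concatenate([[self._prev_noise], vals[:-1]])
            states = _linear_recurrence(phi, drive, -k * mb, prev_noise,
                                        self.state.x)
            ps = states[:, 0] + vals
            prev_meas = np.concatenate([[self._meas[-1]],
                                        states[:-1, 0] + vals[:-1]])
            fs = k * (tgt - prev_meas)
        else:
            drive = mb * level + mc
            states = _linear_recurrence(phi, drive, np.zeros_like(mb),
                                        vals, self.state.x)
            ps = states[:, 0] + vals
            if self.mode == "CF":
                fs = np.full(n, level)
            elif self.mode == "CPg":
                fs = (level - ps) / self.sys.system_resistance
            else:  # analog pump
                fs = self.sys.feedback_gain * (level - ps)
        return self._finish(ps, fs, states, vals, n)

    def _run_loop(self, level, n: int, const: bool) -> Trace:
        """Reference per-sample loop (digital feedback with filtering/delay)."""
        phi, mb, mc = self._phi, self._mb, self._mc
        x = self.state.x.copy()
        vals = self._noise_values(n)
        ps = np.empty(n)
        fs = np.empty(n)
        states = np.empty((n, 3))
        meas = list(self._meas)
        k_gain = self.sys.feedback_gain
        nf = self._nfilt
        delay = max(self._delay, 1)
        t0 = self.state.time_min
        mode = self.mode
        pump = mode in ("CPp", "CPpx") and not self.analog
        lim = self.flow_limit
        for j in range(n):
            # input held over the interval (t_{j-1}, t_j]
            lv = level if const else level(t0 + j * self.dt_min)
            if pump:
                end = len(meas) - delay + 1
                start = max(0, end - nf)
                window = meas[start:end] if end > 0 else [meas[-1]]
                u = k_gain * (lv - sum(window) / len(window))
                if lim is not None:
                    u = min(max(u, -lim), lim)
            else:
                u = lv
            x = phi @ x + mb * u + mc
            noisy = x[0] + vals[j]
            ps[j] = noisy
            states[j] = x
            if mode == "CF":
                fs[j] = u
            elif mode == "CPg":
                fs[j] = (lv - noisy) / self.sys.system_resistance
            elif self.analog:
                fs[j] = k_gain * (lv - noisy)
            else:
                fs[j] = u
            meas.append(noisy)
        return self._finish(ps, fs, states, vals, n)


def _linear_recurrence(phi: np.ndarray, drive: np.ndarray,
                       gain_vec: np.ndarray, series: np.ndarray,
                       x0: np.ndarray) -> np.ndarray:
    """Solve x_j = phi x_{j-1} + drive + gain_vec*series_j (x_{-1} = x0).

    Diagonalizes phi and runs one first-order IIR filter per eigenmode, which
    is the same recurrence the per-sample loop performs, evaluated
    vectorized.  Falls back to the dense loop for a defective phi.
    """
    n = len(series)
    dim = phi.shape[0]
    try:
        lam, v = np.linalg.eig(phi)
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        out = np.empty((n, dim))
        x = x0.copy()
        for j in range(n):
            x = phi @ x + drive + gain_vec * series[j]
            out[j] = x
        return out
    # forcing in eigen-coordinates: g_j = vinv @ (drive + gain_vec*series_j)
    g = np.outer(series, vinv @ gain_vec) + vinv @ drive  # (n, dim)
    y0 = vinv @ x0.astype(complex)
    out = np.empty((n, dim), complex)
    for i in range(dim):
        zi = np.array([lam[i] * y0[i]])
        out[:, i], _ = lfilter([1.0], [1.0, -lam[i]], g[:, i], zi=zi)
    return np.real(out @ v.T)


def integrate(mode: str, input_fn, eye: EyeParams, sys: SystemParams,
              duration_min: float, dt_s: Optional[float] = None,
              initial: Optional[ModelState] = None,
              disturbance=None, analog: bool = False) -> Trace:
    """Integrate one controller mode for a fixed duration.

    ``input_fn`` is either a constant level or a callable ``t_min -> level``
    (flow for CF, reservoir pressure for CPg, target pressure for CPp/CPpx).
    """
    sim = Simulator(mode, eye, sys, noise=disturbance, analog=analog,
                    dt_s=dt_s, initial=initial)
    return sim.run(input_fn, duration_min)


def recover_eye_state(p_s: np.ndarray, f_s: np.ndarray, sys: SystemParams,
                      dt_s: float):
    """Recover eye pressure and inflow from recorded P_S and F_S.

    ``P_E = R_C C_S dP_S/dt + P_S - R_C F_S`` and
    ``F_E = F_S - C_S dP_S/dt``, with dP_S/dt estimated by centered first
    differences (one-sided at the endpoints).
    """
    p_s = np.asarray(p_s, float)
    f_s = np.asarray(f_s, float)
    if len(p_s) < 2:
        raise ValueError("need at least two samples for the derivative stencil")
    dps = np.gradient(p_s, dt_s / 60.0)  # mmHg/min
    rc, cs = sys.cannula_resistance, sys.system_compliance
    p_e = rc * cs * dps + p_s - rc * f_s
    f_e = f_s - cs * dps
    return p_e, f_e


def settling_time(trace: Trace, plateau: SteadyState,
                  pre: Optional[SteadyState] = None,
                  threshold: float = 0.01,
                  convention: str = "excursion") -> float:
    """Time (min, from trace start) for P_S and F_S to settle at the plateau.

    A channel settles at the last instant it leaves the band
    ``threshold * excursion`` around its plateau, where the excursion is the
    plateau minus the pre-step level (``convention="excursion"``) or the
    plateau magnitude itself (``convention="absolute"``).  Channels with zero
    excursion (F_S under constant flow) are skipped.  Returns NaN if either
    channel is still outside its band at the end of the trace.
    """
    if pre is None:
        pre = SteadyState(trace.p_s[0], trace.f_s[0], trace.p_e[0], trace.f_e[0])
    t_rel = np.arange(len(trace)) * trace.dt_min
    worst = 0.0
    for series, plat, pre_level in ((trace.p_s, plateau.p_s, pre.p_s),
                                    (trace.f_s, plateau.f_s, pre.f_s)):
        if convention == "excursion":
            exc = abs(plat - pre_level)
        elif convention == "absolute":
            exc = abs(plat)
        else:
            raise ValueError(f"unknown convention {convention!r}")
        if exc == 0:
            continue
        outside = np.abs(series - plat) > threshold * exc
        if outside[-1]:
            return float("nan")
        if outside.any():
            worst = max(worst, t_rel[np.nonzero(outside)[0][-1]] + trace.dt_min)
    return worst
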