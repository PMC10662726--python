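"""Physical parameters of the model eye and perfusion hardware.

The defaults describe an adult Brown-Norway rat eye cannulated with a 33g
needle and connected to published constant-flow / constant-pressure perfusion
setups.  Units follow the perfusion literature: pressures in mmHg, flows in
ul/min, resistances in mmHg*min/ul, compliances in ul/mmHg, time in minutes
(sampling intervals are stated in seconds and converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional

import yaml


class ParameterError(ValueError):
    """Raised when a physical parameter is outside its valid range."""


@dataclass(frozen=True)
class EyeParams:
    """Lumped viscoelastic eye.

    The globe wall is a standard linear solid: compliance ``wall_compliance_2``
    in series with the parallel pair (``wall_resistance``,
    ``wall_compliance_1``).  The quasi-static series compliance is
    ``1/C_W = 1/C_W1 + 1/C_W2``; by default both elements are set to twice the
    measured globe compliance of 0.09 ul/mmHg.  ``resting_iop`` absorbs aqueous
    production, uveoscleral outflow and episcleral venous pressure (Goldmann
    equilibrium), so the trabecular branch drains toward it.
    """

    resting_iop: float = 15.0            # P_E_bar, mmHg
    trabecular_resistance: float = 43.0  # R_T, mmHg*min/ul
    wall_resistance: float = 2.3         # R_W, mmHg*min/ul
    wall_compliance_1: float = 0.18      # C_W1, ul/mmHg
    wall_compliance_2: float = 0.18      # C_W2, ul/mmHg

    def __post_init__(self) -> None:
        if self.trabecular_resistance <= 0:
            raise ParameterError("trabecular_resistance (R_T) must be > 0")
        for name in ("resting_iop", "wall_resistance",
                     "wall_compliance_1", "wall_compliance_2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def wall_compliance(self) -> float:
        """Series wall compliance C_W with 1/C_W = 1/C_W1 + 1/C_W2."""
        c1, c2 = self.wall_compliance_1, self.wall_compliance_2
        if c1 == 0 or c2 == 0:
            return 0.0
        return 1.0 / (1.0 / c1 + 1.0 / c2)

    @property
    def facility(self) -> float:
        """True conventional outflow facility 1/R_T (ul/min/mmHg)."""
        return 1.0 / self.trabecular_resistance


@dataclass(frozen=True)
class SystemParams:
    """Perfusion-system hardware around the eye.

    ``system_resistance`` (R_S) is the flow-sensor impedance of a
    gravity-driven constant-pressure system; ``feedback_gain`` (K) is the
    proportional gain of a pump-driven one.  Exactly one of the two is active
    depending on the controller mode.  ``update_interval`` is the simulation
    and feedback update resolution (seconds); pump feedback acts on the
    pressure measured ``feedback_delay`` updates earlier, optionally smoothed
    by a trailing moving average of ``feedback_filter_width`` seconds.
    """

    cannula_resistance: float = 0.36     # R_C, mmHg*min/ul
    system_compliance: float = 0.05      # C_S, ul/mmHg
    system_resistance: Optional[float] = None  # R_S, CPg only
    feedback_gain: Optional[float] = None      # K, ul/min/mmHg, CPp only
    update_interval: float = 0.1         # s
    feedback_delay: int = 1              # in update intervals
    feedback_filter_width: float = 0.0   # s, 0 = no feedback smoothing

    def __post_init__(self) -> None:
        if self.cannula_resistance <= 0:
            raise ParameterError("cannula_resistance (R_C) must be > 0")
        if self.system_compliance < 0:
            raise ParameterError("system_compliance (C_S) must be >= 0")
        if self.system_resistance is not None and self.system_resistance <= 0:
            raise ParameterError("system_resistance (R_S) must be > 0")
        if self.feedback_gain is not None and self.feedback_gain <= 0:
            raise ParameterError("feedback_gain (K) must be > 0")
        if self.update_interval <= 0:
            raise ParameterError("update_interval must be > 0")
        if self.feedback_delay < 0:
            raise ParameterError("feedback_delay must be >= 0")
        if self.feedback_filter_width < 0:
            raise ParameterError("feedback_filter_width must be >= 0")

    @property
    def dt_min(self) -> float:
        """Update interval in minutes."""
        return self.update_interval / 60.0


@dataclass(frozen=True)
class CoefficientSet:
    """Coefficients of the governing third-order pressure equation."""

    alpha: float  # mmHg*min^3/ul
    beta: float   # mmHg*min^2/ul
    gamma: float  # min


def compute_coefficients(eye: EyeParams, sys: SystemParams) -> CoefficientSet:
    """Evaluate alpha, beta, gamma of the governing equations.

    alpha = R_T R_W C_W1 C_W2
    beta  = R_C R_W C_W1 + R_C R_W C_W2 + R_C R_T C_W2
            + R_T R_W C_W1 + R_T R_W C_W2
    gamma = R_C C_S + R_T C_S + R_W C_W1 + R_W C_W2 + R_T C_W2
    """
    rt, rw = eye.trabecular_resistance, eye.wall_resistance
    c1, c2 = eye.wall_compliance_1, eye.wall_compliance_2
    rc, cs = sys.cannula_resistance, sys.system_compliance
    alpha = rt * rw * c1 * c2
    beta = rc * rw * c1 + rc * rw * c2 + rc * rt * c2 + rt * rw * c1 + rt * rw * c2
    gamma = rc * cs + rt * cs + rw * c1 + rw * c2 + rt * c2
    return CoefficientSet(alpha=alpha, beta=beta, gamma=gamma)


def save_config(path, eye: EyeParams, sys: SystemParams, **extra) -> None:
    """Write eye and system parameters (plus arbitrary extras) to a YAML file."""
    doc = {"eye": asdict(eye), "system": asdict(sys)}
    doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[EyeParams, SystemParams, dict]:
    """Read parameters saved by :func:`save_config`.

    Unknown top-level keys are returned verbatim in the third element.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    eye = EyeParams(**doc.pop("eye", {}))
    sys_ = SystemParams(**doc.pop("system", {}))
    return eye, sys_, doc


def with_overrides(base, **kw):
    """Return a copy of a frozen parameter set with fields replaced."""
    return replace(base, **kw)
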