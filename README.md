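# eyeperf

Simulation of eye-perfusion techniques for measuring conventional outflow
facility — the hydraulic conductance of the eye's trabecular drainage
pathway and a central quantity in glaucoma research.

Facility is measured by cannulating an eye, driving fluid into it, and
regressing steady-state flow on steady-state pressure: the slope is the
facility C = 1/R_T.  Three techniques are in routine use — constant flow
(CF), gravity-driven constant pressure (CPg, a reservoir feeding through a
flow sensor of impedance R_S), and pump-driven constant pressure (CPp, a
pump commanding F_S = K(P_T − P_S) at 0.1-s updates).  `eyeperf` models all
of them around a lumped-parameter viscoelastic eye (trabecular resistance
R_T, standard-linear-solid globe wall R_W/C_W1/C_W2, cannula R_C, system
compliance C_S; third-order linear dynamics in the system pressure P_S) and
simulates complete facility experiments with physiologically realistic
pressure noise for enucleated eyes, anesthetized animals, and conscious
animals.  Steady state on noisy responses is detected with the published
window and ratio criteria, optional moving-average filtering, and a
recursive exponential-regression method that fits incoming data to
PS* = A(1−e^(−t/τ)) + B and FS* = C·e^(−t/τ) + D and is robust to the
large spontaneous IOP bumps of awake animals.

The library is the primary interface (see `examples/`); a thin `eyeperf`
command-line tool wraps it for one-off runs (`simulate`, `experiment`,
`make-noise`, `sweep`).

## Worked example

Five 5-mmHg reservoir steps on a low-impedance gravity system (R_S = 0.6)
with synthetic enucleated-eye noise, steps gated by the ratio criterion:

```python
import eyeperf as ep

record = ep.synth_exvivo(duration_min=120.0, seed=42)   # SD 0.04 mmHg
plan = ep.ExperimentPlan(
    mode="CPg",
    sys=ep.SystemParams(system_resistance=0.6),
    criterion=ep.CriterionConfig(criterion="ratio"),
    noise=record,
)
result = ep.run_experiment(plan)
print(f"facility {result.facility_nl:.2f} nl/min/mmHg, "
      f"R = {result.pearson_r:.5f}, {result.total_duration:.1f} min")
```

```
facility 23.29 nl/min/mmHg, R = 1.00000, 62.0 min
```

The regression slope inverts to an outflow resistance of 42.9
mmHg·min·µl⁻¹, recovering the R_T = 43 built into the model eye; the
62-minute duration is the price of the ratio criterion's strict slope
threshold under noise.  `python examples/facility_experiment.py` prints the
per-step plateaus as well; the other example scripts cover step-response
dynamics, the three noise regimes, and the recursive-regression speedup on
conscious noise.

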