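"""Recursive regression versus lowpass filtering on conscious-animal noise.

Conscious IOP records carry large erratic bumps that defeat the raw window
and ratio criteria; heavy moving-average filtering (about 14 min for the
low-impedance gravity scheme) makes them usable but slow.  Recursively
fitting the incoming data to the eye's first-order step response produces a
prediction series that grows smoother as data accumulate, so the same
criteria fire much earlier at no cost in facility accuracy.
"""

import eyeperf as ep

records = ep.make_records("conscious", 3, 150.0, seed=7)
sysp = ep.SystemParams(system_resistance=0.6)

print("CPg2, window criterion, 3 conscious noise records:")
for label, cfg in [
        ("best-filtered (14 min)",
         ep.CriterionConfig(criterion="window", filter_width=14.0)),
        ("recursively fitted",
         ep.CriterionConfig(criterion="window", use_fitted=True))]:
    plan = ep.ExperimentPlan(mode="CPg", sys=sysp, criterion=cfg)
    df = ep.run_cohort(plan, records)
    print(f"  {label:22s} duration {df.duration_min.mean():6.1f} min, "
          f"facility {df.facility_nl.mean():5.1f} nl/min/mmHg")

print("\nThe fitted response reaches steady state about an hour sooner")
print("while the regression slope stays at the eye's true facility (~23.3).")
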