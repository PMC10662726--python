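"""Generate and characterize the three pressure-noise regimes.

Ex vivo noise is lowpass-filtered white noise (SD 0.04 mmHg); the
anesthetized surrogate is more variable (SD 0.23 mmHg) with sporadic signed
transients; the conscious surrogate adds large positive IOP bumps, which
skew its distribution.  Skewness is the tell-tale of conscious recordings.
"""

import eyeperf as ep

for regime, make in [
        ("exvivo", lambda: ep.synth_exvivo(60.0, seed=1)),
        ("anesthetized", lambda: ep.synth_surrogate("anesthetized", 60.0, seed=1)),
        ("conscious", lambda: ep.synth_surrogate("conscious", 60.0, seed=1))]:
    rec = make()
    s = ep.characterize(rec)
    peak = s.psd_freq[s.psd.argmax()]
    print(f"{regime:13s} SD = {s.sd:5.3f} mmHg   skew = {s.skewness:+5.2f}   "
          f"PSD peak near {peak:5.3f} Hz")

print("\nAll records are zero-mean fluctuations about the prevailing IOP;")
print("a simulator overlays them on the measured system pressure, so")
print("pressure-clamp controllers feed the noise back into commanded flow.")
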