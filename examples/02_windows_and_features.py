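"""Window a record and extract the waveform feature sets.

Signals are cut into overlapping 1-min frames updated every 30 s; each
frame is delineated into beats and reduced to named features: 18 from
the PPG pulse shape, 6 from per-beat systolic/diastolic pressure, 6 from
the pulse-rate series.  The printout contrasts an early baseline window
with a late hemorrhage window: pulse amplitude and area shrink, pulse
rate rises, and pressures fall as volume is lost.
"""

from blvest import SimConfig, generate_cohort, assemble, segment

cohort = generate_cohort(2, SimConfig(), seed=3)
rec = cohort[0]
wins = segment(rec)
print(f"{rec.subject_id}: {len(wins)} windows of 60 s at 30-s hops")

early = next(w for w in wins if w.phase == "baseline")
late = wins[-2]
vec_e = assemble("PPG&ABP", early)
vec_l = assemble("PPG&ABP", late)

print(f"\n{'feature':35s} {'baseline':>10s} {'late bleed':>10s}")
for name in ("PPG Peak-Foot Amplitude", "Total Pulse Area", "PIR",
             "Mean Pulse Rate", "Mean SBP", "Mean DBP", "Mean PP"):
    print(f"{name:35s} {vec_e[name]:10.3f} {vec_l[name]:10.3f}")
print(f"\nlabels: baseline window {early.label_blv:.0f} mL, late window {late.label_blv:.0f} mL lost")
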