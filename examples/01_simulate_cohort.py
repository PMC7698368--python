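"""Simulate a small hemorrhage cohort and inspect one subject.

Each synthetic subject is observed for an 18-31 min baseline and then
bled at 20 mL/min (with rest pauses) until mean arterial pressure falls
to 30 mmHg.  The printed lines show the per-subject protocol outcome:
estimated blood volume (from weight at 67.9 mL/kg), final cumulative
blood loss, and the terminal MAP the bleed stopped at.
"""

from blvest import SimConfig, generate_cohort, physio_trajectory, reference_blv

cohort = generate_cohort(4, SimConfig(), seed=7)

for rec in cohort:
    final = reference_blv(rec.duration, rec.bleed_schedule)
    state = physio_trajectory(rec, rec.duration)
    print(
        f"{rec.subject_id}: weight {rec.weight:5.1f} kg, EBV {rec.ebv:6.0f} mL, "
        f"baseline {rec.baseline_duration / 60:4.1f} min, "
        f"bled {final:6.0f} mL ({100 * final / rec.ebv:4.1f}% EBV) "
        f"over {len(rec.bleed_schedule)} pump segments, terminal MAP {state.map:.1f} mmHg"
    )

rec = cohort[0]
print(f"\n{rec.subject_id} HCT draws (dilution lags the bleed):")
for t, h in rec.hct_draws:
    print(f"  t = {t / 60:6.1f} min  HCT = {h:4.1f} %   BLV = {reference_blv(t, rec.bleed_schedule):6.0f} mL")
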