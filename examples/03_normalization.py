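"""Why baseline normalization is needed, and the two ways to fit it.

PPG units are device- and subject-dependent: two subjects at the same
physiological state show very different raw amplitudes.  Dividing every
feature by its average baseline value (person-specific) or by the other
subjects' baseline average (group-specific, usable without a personal
baseline) removes that offset.  After person normalization, every
subject's baseline features average exactly 1.
"""

from blvest import SimConfig, generate_cohort
from blvest.features import design_matrix, extract_cohort_features
from blvest.normalize import apply_center, fit_group_center, fit_person_center

cohort = generate_cohort(3, SimConfig(), seed=5)
feats = extract_cohort_features(cohort)
X, meta = design_matrix(feats, "PPG")

print("raw baseline 'PPG Peak-Foot Amplitude' by subject (arbitrary units):")
for sid in meta["subject_id"].unique():
    rows = X[(meta["subject_id"] == sid) & (meta["phase"] == "baseline")]
    print(f"  {sid}: mean {rows['PPG Peak-Foot Amplitude'].mean():.3f}")

print("\nafter person-specific normalization every baseline mean is 1:")
for sid in meta["subject_id"].unique():
    center = fit_person_center(X, meta, sid)
    rows = meta["subject_id"] == sid
    Xn = apply_center(center, X[rows])
    bl = Xn[(meta[rows]["phase"] == "baseline").to_numpy()]
    print(f"  {sid}: normalized baseline mean {bl['PPG Peak-Foot Amplitude'].mean():.6f}")

target = meta["subject_id"].unique()[0]
others = [s for s in meta["subject_id"].unique() if s != target]
gc = fit_group_center(X, meta, others)
print(
    f"\ngroup center for {target} uses only {gc.source_subjects} "
    "(deployable when no personal baseline exists)"
)
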