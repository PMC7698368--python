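"""Train and evaluate blood-loss regressors under leave-one-animal-out CV.

Every subject is held out once; the model (here a random forest with the
combined 30-feature PPG+ABP vector and person-specific normalization) is
trained on the remaining subjects and predicts the held-out subject's
windows.  Errors are summarized overall and by blood-loss severity
class; mean error is bias (positive = overestimate) and SD is spread.
A small cohort keeps this example quick; accuracy improves with the
full-size cohort.
"""

import numpy as np

from blvest import SimConfig, generate_cohort
from blvest.evaluate import summarize_errors
from blvest.features import extract_cohort_features
from blvest.models import ModelSpec, loao_cv, rank_features

cohort = generate_cohort(6, SimConfig(), seed=11)
feats = extract_cohort_features(cohort)
print(f"{len(feats)} usable windows from {len(cohort)} subjects")

spec = ModelSpec(method="RF", modality="PPG&ABP", normalization="person", seed=11)
cv = loao_cv(spec, feats)

r = np.corrcoef(cv.predictions["predicted_blv"], cv.predictions["label_blv"])[0, 1]
print(f"\nout-of-fold correlation r = {r:.3f}")
print(f"overall error {cv.errors.mean():+.1f} +/- {cv.errors.std(ddof=1):.1f} mL (predicted - reference)")

ebv = {rec.subject_id: rec.ebv for rec in cohort}
print("\nerror by severity class:")
print(summarize_errors(cv, ebv).to_string(index=False))

print("\ntop-5 features by impurity importance (mean over folds):")
print(rank_features(cv).head(5).to_string(index=False))
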