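"""Baseline feature normalization.

Every feature is re-expressed as a ratio to an average baseline value —
the "center".  Person-specific normalization divides subject j's features
by the mean of j's own baseline windows; group-specific normalization
divides by the mean over other subjects' baseline windows (leave-self-out,
or the training-fold subjects during cross-validation, which keeps the
test subject's data out of the fitted parameters).

Centers must be strictly positive: the default feature set is made of
amplitudes, times, areas, ratios and rates, all positive at baseline, and
a zero or negative center would silently flip feature signs, so it is an
error instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BaselineCenter",
    "fit_person_center",
    "fit_group_center",
    "apply_center",
    "normalize_person",
]


@dataclass(frozen=True)
class BaselineCenter:
    """Per-feature baseline averages used as normalization denominators."""

    scope: str                    # "person" | "group"
    centers: dict[str, float]     # feature name -> mean baseline value
    source_subjects: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scope": self.scope,
                    "source_subjects": list(self.source_subjects),
                    "centers": self.centers,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BaselineCenter":
        d = json.loads(Path(path).read_text())
        return cls(d["scope"], d["centers"], tuple(d["source_subjects"]))


def _check_centers(means: pd.Series) -> dict[str, float]:
    bad = [str(k) for k, v in means.items() if not np.isfinite(v) or v == 0.0]
    if bad:
        raise ValueError(
            f"baseline mean is zero or non-finite for feature(s) {bad}; "
            "ratio normalization is undefined"
        )
    return {str(k): float(v) for k, v in means.items()}


def _baseline_rows(X: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    mask = (meta["phase"] == "baseline") & meta["quality_ok"].astype(bool)
    return X.loc[mask[mask].index.intersection(X.index)]


def fit_person_center(X: pd.DataFrame, meta: pd.DataFrame, subject_id: str) -> BaselineCenter:
    """Center = per-feature mean over ``subject_id``'s baseline windows."""
    rows = _baseline_rows(X, meta.loc[meta["subject_id"] == subject_id])
    if len(rows) == 0:
        raise ValueError(f"subject {subject_id!r} has no usable baseline windows")
    return BaselineCenter("person", _check_centers(rows.mean()), (subject_id,))


def fit_group_center(X: pd.DataFrame, meta: pd.DataFrame, subjects) -> BaselineCenter:
    """Center = per-feature mean over all baseline windows of ``subjects``.

    Pass the training-fold subjects for the CV-safe variant, or every
    subject except the target for the leave-self-out form; the per-window
    (not per-subject) mean is used, so subjects with longer baselines
    weigh proportionally more.
    """
    subjects = tuple(subjects)
    if len(subjects) == 0:
        raise ValueError("group center requires at least one source subject")
    rows = _baseline_rows(X, meta.loc[meta["subject_id"].isin(subjects)])
    if len(rows) == 0:
        raise ValueError(f"no usable baseline windows among subjects {subjects}")
    return BaselineCenter("group", _check_centers(rows.mean()), subjects)


def apply_center(center: BaselineCenter, X: pd.DataFrame) -> pd.DataFrame:
    """Elementwise division of features by the center values."""
    missing = [c for c in X.columns if c not in center.centers]
    extra = [c for c in center.centers if c not in X.columns]
    if missing or extra:
        raise ValueError(
            f"feature-name mismatch: missing centers for {missing}, "
            f"unused centers {extra}"
        )
    denom = pd.Series(center.centers)[X.columns]
    return X / denom


def normalize_person(X: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Person-normalize every subject against its own baseline."""
    out = X.copy()
    for sid in meta["subject_id"].unique():
        idx = meta.index[meta["subject_id"] == sid].intersection(X.index)
        center = fit_person_center(X, meta, sid)
        out.loc[idx] = apply_center(center, X.loc[idx])
    return out
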