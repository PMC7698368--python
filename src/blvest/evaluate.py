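"""Severity-stratified error summaries, hematocrit-formula comparators,
and report rendering.

Estimation error is predicted minus reference BLV by default (positive =
overestimate); the opposite convention (reference minus predicted) is
available via ``sign="reference-predicted"`` everywhere errors are
summarized.

Severity classes partition the blood-loss fraction of the estimated blood
volume (EBV) at 15 %, 30 % and 45 %, with baseline windows forming a
separate no-bleeding class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SubjectRecord, reference_blv
from .models import CVResult

__all__ = [
    "SEVERITY_CLASSES",
    "classify_severity",
    "summarize_errors",
    "hct_blood_loss",
    "compare_hct_vs_model",
    "summarize_hct_comparison",
    "render_report",
]

# (name, lower fraction, upper fraction); the no-bleeding class is keyed
# off the window phase rather than the fraction.
SEVERITY_CLASSES = [
    ("no_bleeding", None, None),
    ("lt15", 0.0, 0.15),
    ("b15_30", 0.15, 0.30),
    ("b30_45", 0.30, 0.45),
    ("gt45", 0.45, math.inf),
]

def classify_severity(label_blv: float, ebv: float, phase: str) -> str:
    """Severity-class name of one window; every window falls in exactly one."""
    if phase == "baseline":
        return "no_bleeding"
    frac = label_blv / ebv
    for name, lo, hi in SEVERITY_CLASSES[1:]:
        if lo <= frac < hi:
            return name
    return "gt45"


def _signed(errors: pd.Series, sign: str) -> pd.Series:
    if sign == "predicted-reference":
        return errors
    if sign == "reference-predicted":
        return -errors
    raise ValueError("sign must be 'predicted-reference' or 'reference-predicted'")


def summarize_errors(
    cv: CVResult,
    ebv_by_subject: dict[str, float],
    sign: str = "predicted-reference",
) -> pd.DataFrame:
    """Mean +/- SD estimation error overall and per severity class.

    Returns one row per class (n = 0 rows included) plus an ``overall``
    row; the overall mean equals the window-weighted mean of class means.
    """
    df = cv.predictions.copy()
    df["error"] = _signed(cv.errors, sign)
    df["severity"] = [
        classify_severity(l, ebv_by_subject[s], p)
        for l, s, p in zip(df["label_blv"], df["subject_id"], df["phase"])
    ]
    rows = []
    for name, _, _ in SEVERITY_CLASSES:
        sub = df.loc[df["severity"] == name, "error"]
        rows.append(
            {
                "class": name,
                "mean_error_ml": float(sub.mean()) if len(sub) else float("nan"),
                "sd_error_ml": float(sub.std(ddof=1)) if len(sub) > 1 else (0.0 if len(sub) else float("nan")),
                "n_windows": int(len(sub)),
            }
        )
    rows.append(
        {
            "class": "overall",
            "mean_error_ml": float(df["error"].mean()),
            "sd_error_ml": float(df["error"].std(ddof=1)),
            "n_windows": int(len(df)),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hematocrit formulas
# ---------------------------------------------------------------------------

def hct_blood_loss(formula: str, ebv: float, hct_i: float, hct_f: float) -> float:
    """Classic hematocrit-dilution blood-loss estimate, mL.

    - ``ward``:   EBV * ln(Hct_i / Hct_f)           (exact under pure
      exponential dilution of the red-cell mass)
    - ``gross``:  EBV * (Hct_i - Hct_f) / Hct_mean  (first-order form)
    - ``bourke``: EBV * (Hct_i - Hct_f) * (3 - Hct_mean), with the HCTs
      as fractions — the (3 - Hct_mean) factor is only dimensionally
      sensible on the fraction scale, so percent inputs are converted.

    Hct_mean is the arithmetic mean of the two draws.  Ward and Gross are
    scale-invariant and accept percent or fraction alike.
    """
    if not (0.0 < hct_f <= hct_i < 100.0):
        raise ValueError(
            f"require 0 < hct_f <= hct_i < 100, got hct_i={hct_i}, hct_f={hct_f}"
        )
    if formula == "ward":
        return ebv * math.log(hct_i / hct_f)
    if formula == "gross":
        return ebv * (hct_i - hct_f) / ((hct_i + hct_f) / 2.0)
    if formula == "bourke":
        hi, hf = hct_i, hct_f
        if hi > 1.0:  # percent scale
            hi, hf = hi / 100.0, hf / 100.0
        return ebv * (hi - hf) * (3.0 - (hi + hf) / 2.0)
    raise ValueError(f"unknown formula {formula!r}; expected ward|bourke|gross")


HCT_FORMULAS = ("ward", "bourke", "gross")


def compare_hct_vs_model(
    cv: CVResult,
    subjects: list[SubjectRecord],
    formulas=HCT_FORMULAS,
    window_s: float = 60.0,
) -> pd.DataFrame:
    """Model vs HCT-formula estimates at each bleeding-stage blood draw.

    The model estimate at a draw is the prediction of the window ending
    at or nearest before the draw time; the baseline draw supplies Hct_i.
    Returns one row per (subject, draw) with the reference BLV, the model
    and formula estimates, and signed errors in both conventions.
    """
    by_subject = {s.subject_id: s for s in subjects}
    preds = cv.predictions
    rows = []
    for sid, sub_preds in preds.groupby("subject_id"):
        rec = by_subject.get(sid)
        if rec is None or not rec.hct_draws:
            continue
        baseline_draws = [(t, h) for t, h in rec.hct_draws if t <= rec.bleed_start]
        if not baseline_draws:
            continue
        hct_i = baseline_draws[0][1]
        ends = sub_preds["start_s"].to_numpy() + window_s
        for t, hct_f in rec.hct_draws:
            if t <= rec.bleed_start:
                continue
            elig = np.flatnonzero(ends <= t + 1e-9)
            if len(elig) == 0:
                continue
            model_est = float(sub_preds.iloc[elig[-1]]["predicted_blv"])
            ref = reference_blv(t, rec.bleed_schedule)
            row = {
                "subject_id": sid,
                "draw_time_s": t,
                "hct_i": hct_i,
                "hct_f": hct_f,
                "reference_blv": ref,
                "loss_fraction": ref / rec.ebv,
                "model_est": model_est,
                "model_error": model_est - ref,
            }
            for f in formulas:
                hf = min(hct_f, hct_i)  # noise can push a draw above baseline
                est = hct_blood_loss(f, rec.ebv, hct_i, hf)
                row[f"{f}_est"] = est
                row[f"{f}_error"] = est - ref
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_hct_comparison(
    table: pd.DataFrame,
    formulas=HCT_FORMULAS,
    sign: str = "predicted-reference",
) -> pd.DataFrame:
    """Mean +/- SD of draw-time errors, stratified at 30 % EBV loss."""
    if len(table) == 0:
        return pd.DataFrame()
    strata = {
        "blood_loss_lt30": table["loss_fraction"] < 0.30,
        "blood_loss_gt30": table["loss_fraction"] >= 0.30,
        "overall": pd.Series(True, index=table.index),
    }
    flip = -1.0 if sign == "reference-predicted" else 1.0
    rows = []
    for name, mask in strata.items():
        sub = table.loc[mask]
        row = {"stratum": name, "n_draws": int(len(sub))}
        for col in ["model"] + list(formulas):
            err = flip * sub[f"{col}_error"]
            row[f"{col}_mean_error_ml"] = float(err.mean()) if len(err) else float("nan")
            row[f"{col}_sd_error_ml"] = float(err.std(ddof=1)) if len(err) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_CSV_FMT = "%.6g"


def render_report(
    out_dir: str | Path,
    severity_tables: dict[str, pd.DataFrame] | None = None,
    hct_table: pd.DataFrame | None = None,
    lasso_ranks: pd.DataFrame | None = None,
    rf_ranks: pd.DataFrame | None = None,
    cv_results: dict[str, CVResult] | None = None,
    make_plots: bool = True,
) -> list[Path]:
    """Write deterministic CSV tables and, optionally, summary figures.

    ``severity_tables`` maps variant names to :func:`summarize_errors`
    frames, concatenated into ``table1_severity.csv``; the HCT comparison
    goes to ``table2_hct.csv`` and the importance rankings to
    ``table3_lasso_ranks.csv`` / ``table4_rf_ranks.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format=_CSV_FMT)
        written.append(p)

    if severity_tables:
        parts = []
        for variant, tab in severity_tables.items():
            t = tab.copy()
            t.insert(0, "model", variant)
            parts.append(t)
        _write("table1_severity.csv", pd.concat(parts, ignore_index=True))
    if hct_table is not None and len(hct_table):
        _write("table2_hct.csv", hct_table)
    if lasso_ranks is not None:
        _write("table3_lasso_ranks.csv", lasso_ranks)
    if rf_ranks is not None:
        _write("table4_rf_ranks.csv", rf_ranks)

    if make_plots and cv_results:
        written.extend(_render_plots(out_dir, cv_results))
    return written


def _render_plots(out_dir: Path, cv_results: dict[str, CVResult]) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for variant, cv in cv_results.items():
        df = cv.predictions.loc[cv.predictions["phase"] == "bleeding"].copy()
        if len(df) == 0:
            continue
        # align subjects on time since bleed onset, then average across them
        df["t_rel"] = df.groupby("subject_id")["start_s"].transform(lambda s: s - s.min())
        bins = (df["t_rel"] // 300).astype(int) * 5  # 5-min bins
        g = df.groupby(bins)
        fig, ax = plt.subplots(figsize=(7, 4))
        for col, color in (("label_blv", "k"), ("predicted_blv", "C0")):
            mean = g[col].mean()
            sd = g[col].std(ddof=1).fillna(0.0)
            n = g[col].count()
            ci = 1.96 * sd / np.sqrt(n.clip(lower=1))
            ax.plot(mean.index, mean, color=color,
                    label="reference" if col == "label_blv" else "estimated")
            ax.fill_between(mean.index, mean - ci, mean + ci, color=color, alpha=0.2)
        ax.set_xlabel("time since bleed onset (min)")
        ax.set_ylabel("blood loss volume (mL)")
        ax.set_title(variant)
        ax.legend()
        p = out_dir / f"blv_curve_{variant}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
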