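"""Beat delineation and per-window waveform feature extraction.

Each 1-min window is delineated into beats (foot -> systolic peak ->
dicrotic notch -> next foot).  From the PPG channel 18 amplitude/time/area
features are computed; from the ABP channel 6 pressure features; from the
beat sequence 6 pulse-rate features.  Per-beat quantities are averaged
over the window's valid beats, except the "variation" features which are
(max - min)/mean over beats — the classic pulse-pressure-variation form.

Feature-vector dimensions by modality: PPG -> 24 (18 waveform + 6 pulse
rate), ABP -> 12 (6 pressure + 6 pulse rate), PPG&ABP -> 30 (pulse-rate
block included once, derived from the PPG channel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .windows import ObservationWindow

__all__ = [
    "BeatFiducials",
    "PPG_FEATURES",
    "ABP_FEATURES",
    "PR_FEATURES",
    "MODALITIES",
    "META_COLUMNS",
    "modality_features",
    "detect_ppg_beats",
    "detect_abp_beats",
    "ppg_features",
    "abp_features",
    "pr_features",
    "assemble",
    "extract_cohort_features",
    "design_matrix",
]

MIN_VALID_BEATS = 20  # per 60-s window, else the window is unusable

PPG_FEATURES = [
    "PPG Peak Amplitude",
    "PPG Peak Amplitude Variation",
    "PPG Peak-Foot Amplitude",
    "PPG Peak-Foot Amplitude Variation",
    "Slope Transit Time",
    "Systolic Time",
    "Systolic Area",
    "Systolic Area Ratio",
    "Notch Area",
    "Notch Area Ratio",
    "Diastolic Time",
    "Diastolic Area",
    "Diastolic Area Ratio",
    "PIR",
    "PPG Foot Amplitude",
    "PPG Foot Amplitude Variation",
    "Pulse Width Half Amplitude",
    "Total Pulse Area",
]

ABP_FEATURES = [
    "Mean SBP",
    "Mean DBP",
    "Mean PP",
    "Mean SBP Variation",
    "Mean DBP Variation",
    "Mean PP Variation",
]

PR_FEATURES = [
    "Mean Pulse Rate",
    "Min Pulse Rate",
    "Max Pulse Rate",
    "SD Pulse Rate",
    "Median Pulse Rate",
    "RMSSD",
]

MODALITIES = ("PPG", "ABP", "PPG&ABP")

META_COLUMNS = ["subject_id", "start_s", "phase", "label_blv", "quality_ok"]


def modality_features(modality: str) -> list[str]:
    """Canonical ordered feature-name list for a model modality."""
    if modality == "PPG":
        return PPG_FEATURES + PR_FEATURES
    if modality == "ABP":
        return ABP_FEATURES + PR_FEATURES
    if modality == "PPG&ABP":
        return PPG_FEATURES + ABP_FEATURES + PR_FEATURES
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


@dataclass
class BeatFiducials:
    """Sample indices of one beat's landmarks within a window."""

    foot_idx: int
    peak_idx: int
    notch_idx: int
    end_idx: int
    valid: bool
    sbp: float = float("nan")   # per-beat max, ABP only (mmHg)
    dbp: float = float("nan")   # per-beat min, ABP only (mmHg)


# ---------------------------------------------------------------------------
# Beat delineation
# ---------------------------------------------------------------------------

def _find_feet(x: np.ndarray, fs: float) -> np.ndarray:
    """Pulse feet: local minima just before maximal-upslope points."""
    if np.ptp(x) < 1e-6:
        return np.array([], dtype=int)
    d = np.gradient(x) * fs
    min_dist = max(int(fs * 60.0 / 250.0), 1)           # fastest credible rate
    height = 0.3 * np.percentile(d, 99)
    if height <= 0:
        return np.array([], dtype=int)
    upslopes, _ = find_peaks(d, height=height, distance=min_dist)
    back = int(0.35 * fs)
    feet = []
    for p in upslopes:
        a = max(p - back, 0)
        feet.append(a + int(np.argmin(x[a : p + 1])))
    feet = np.unique(np.asarray(feet, dtype=int))
    if len(feet) > 1:                                    # enforce refractory spacing
        keep = [feet[0]]
        for f in feet[1:]:
            if f - keep[-1] >= min_dist:
                keep.append(f)
        feet = np.asarray(keep)
    return feet


def _find_notch(x: np.ndarray, peak: int, end: int, fs: float) -> int | None:
    """First local minimum after the systolic peak; fall back to the first
    zero-crossing of the second derivative on the falling limb."""
    seg = x[peak + 1 : end]
    if len(seg) < 5:
        return None
    # direct extrema scan (strict local minima of the sampled falling limb)
    mid = seg[1:-1]
    minima = np.flatnonzero((mid < seg[:-2]) & (mid <= seg[2:]))
    if len(minima):
        return peak + 2 + int(minima[0])
    d2 = np.diff(seg, 2)
    crossings = np.flatnonzero((d2[:-1] < 0) & (d2[1:] >= 0))
    if len(crossings):
        return peak + 2 + int(crossings[0])
    return None


def _delineate(x: np.ndarray, fs: float, with_bp: bool) -> list[BeatFiducials]:
    if len(x) < int(10 * fs):
        raise ValueError("need at least 10 s of signal to delineate beats")
    feet = _find_feet(np.asarray(x, dtype=np.float64), fs)
    beats: list[BeatFiducials] = []
    xf = np.asarray(x, dtype=np.float64)
    min_len = int(fs * 60.0 / 250.0)
    max_len = int(fs * 60.0 / 40.0)
    for f0, f1 in zip(feet[:-1], feet[1:]):
        if not (min_len <= f1 - f0 <= max_len):
            continue
        peak = f0 + int(np.argmax(xf[f0:f1]))
        notch = _find_notch(xf, peak, f1, fs)
        valid = notch is not None and f0 < peak < notch < f1
        b = BeatFiducials(
            foot_idx=int(f0),
            peak_idx=int(peak),
            notch_idx=int(notch) if notch is not None else -1,
            end_idx=int(f1),
            valid=bool(valid),
        )
        if with_bp:
            b.sbp = float(np.max(xf[f0:f1]))
            b.dbp = float(np.min(xf[f0:f1]))
        beats.append(b)
    return beats


def detect_ppg_beats(x: np.ndarray, fs: float = 250.0) -> list[BeatFiducials]:
    """Delineate PPG beats; beats with broken landmark ordering are
    returned flagged invalid and excluded from feature computation."""
    return _delineate(x, fs, with_bp=False)


def detect_abp_beats(x: np.ndarray, fs: float = 250.0) -> list[BeatFiducials]:
    """Delineate ABP beats with per-beat SBP (max) and DBP (min), mmHg."""
    return _delineate(x, fs, with_bp=True)


# ---------------------------------------------------------------------------
# Per-window features
# ---------------------------------------------------------------------------

def _variation(values: np.ndarray) -> float:
    """(max - min)/mean across beats; the pulse-pressure-variation form."""
    m = float(np.mean(values))
    if m == 0.0:
        return float("nan")
    return float((np.max(values) - np.min(values)) / m)


def ppg_features(x: np.ndarray, beats: list[BeatFiducials], fs: float = 250.0) -> dict[str, float] | None:
    """The 18 PPG waveform features for one window, or None if unusable.

    Areas are integrated above the beat's own foot value so the device DC
    offset cancels from all area features; each area "ratio" divides by
    the total pulse area, and the three sub-areas (systolic, notch,
    diastolic) partition the total exactly.
    """
    xf = np.asarray(x, dtype=np.float64)
    rows = []
    for b in beats:
        if not b.valid:
            continue
        x0 = xf[b.foot_idx]
        xp = xf[b.peak_idx]
        amp = xp - x0
        if amp <= 0 or x0 == 0:
            continue
        beat = xf[b.foot_idx : b.end_idx + 1] - x0
        i_pk = b.peak_idx - b.foot_idx
        i_nt = b.notch_idx - b.foot_idx
        max_slope = float(np.max(np.diff(beat[: i_pk + 1]))) * fs
        if max_slope <= 0:
            continue
        # one cumulative trapezoid; sub-areas share endpoints so the three
        # pieces sum exactly to the total
        ctrap = np.cumsum(beat[:-1] + beat[1:]) / (2.0 * fs)
        a_sys = float(ctrap[i_pk - 1]) if i_pk >= 1 else 0.0
        a_nch = float(ctrap[i_nt - 1] - ctrap[i_pk - 1])
        a_dia = float(ctrap[-1] - ctrap[i_nt - 1])
        a_tot = float(ctrap[-1])
        if a_tot <= 0:
            continue
        half = amp / 2.0
        above = np.flatnonzero(beat >= half)
        width = float((above[-1] - above[0]) / fs) if len(above) else 0.0
        rows.append(
            dict(
                peak=xp,
                amp=amp,
                foot=x0,
                stt=amp / max_slope,
                t_sys=(b.peak_idx - b.foot_idx) / fs,
                t_dia=(b.end_idx - b.peak_idx) / fs,
                a_sys=a_sys,
                a_nch=a_nch,
                a_dia=a_dia,
                a_tot=a_tot,
                pir=xp / x0,
                width=width,
            )
        )
    if len(rows) < 2:
        return None
    g = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    feats = {
        "PPG Peak Amplitude": float(np.mean(g["peak"])),
        "PPG Peak Amplitude Variation": _variation(g["peak"]),
        "PPG Peak-Foot Amplitude": float(np.mean(g["amp"])),
        "PPG Peak-Foot Amplitude Variation": _variation(g["amp"]),
        "Slope Transit Time": float(np.mean(g["stt"])),
        "Systolic Time": float(np.mean(g["t_sys"])),
        "Systolic Area": float(np.mean(g["a_sys"])),
        "Systolic Area Ratio": float(np.mean(g["a_sys"] / g["a_tot"])),
        "Notch Area": float(np.mean(g["a_nch"])),
        "Notch Area Ratio": float(np.mean(g["a_nch"] / g["a_tot"])),
        "Diastolic Time": float(np.mean(g["t_dia"])),
        "Diastolic Area": float(np.mean(g["a_dia"])),
        "Diastolic Area Ratio": float(np.mean(g["a_dia"] / g["a_tot"])),
        "PIR": float(np.mean(g["pir"])),
        "PPG Foot Amplitude": float(np.mean(g["foot"])),
        "PPG Foot Amplitude Variation": _variation(g["foot"]),
        "Pulse Width Half Amplitude": float(np.mean(g["width"])),
        "Total Pulse Area": float(np.mean(g["a_tot"])),
    }
    if not all(np.isfinite(v) for v in feats.values()):
        return None
    return feats


def abp_features(beats: list[BeatFiducials]) -> dict[str, float] | None:
    """The 6 ABP features (mean and variation of SBP, DBP, PP), mmHg."""
    valid = [b for b in beats if b.valid and np.isfinite(b.sbp) and np.isfinite(b.dbp)]
    if len(valid) < 2:
        return None
    sbp = np.array([b.sbp for b in valid])
    dbp = np.array([b.dbp for b in valid])
    pp = sbp - dbp
    feats = {
        "Mean SBP": float(np.mean(sbp)),
        "Mean DBP": float(np.mean(dbp)),
        "Mean PP": float(np.mean(pp)),
        "Mean SBP Variation": _variation(sbp),
        "Mean DBP Variation": _variation(dbp),
        "Mean PP Variation": _variation(pp),
    }
    if not all(np.isfinite(v) for v in feats.values()):
        return None
    return feats


def pr_features(beats: list[BeatFiducials], fs: float = 250.0) -> dict[str, float] | None:
    """The 6 pulse-rate features from inter-foot intervals.

    Instantaneous rate is 60/IBI bpm; RMSSD is the root-mean-square of
    successive inter-beat-interval differences in ms.
    """
    feet = np.array([b.foot_idx for b in beats if b.valid])
    if len(feet) < 3:
        return None
    ibi = np.diff(feet) / fs                 # s
    pr = 60.0 / ibi
    rmssd = math.sqrt(float(np.mean(np.diff(ibi * 1000.0) ** 2))) if len(ibi) >= 2 else 0.0
    return {
        "Mean Pulse Rate": float(np.mean(pr)),
        "Min Pulse Rate": float(np.min(pr)),
        "Max Pulse Rate": float(np.max(pr)),
        "SD Pulse Rate": float(np.std(pr)),
        "Median Pulse Rate": float(np.median(pr)),
        "RMSSD": float(rmssd),
    }


# ---------------------------------------------------------------------------
# Window and cohort assembly
# ---------------------------------------------------------------------------

def _window_feature_row(w: ObservationWindow, fs: float, min_beats: int) -> dict[str, float]:
    """All features of one window on the wide internal layout, with
    per-channel usability flags."""
    row: dict[str, float] = {}
    ppg_ok = abp_ok = False

    try:
        beats = detect_ppg_beats(w.channels["ppg"], fs)
    except ValueError:
        beats = []
    n_valid = sum(b.valid for b in beats)
    if n_valid >= min_beats:
        pf = ppg_features(w.channels["ppg"], beats, fs)
        prf = pr_features(beats, fs)
        if pf is not None and prf is not None:
            row.update(pf)
            row.update({f"{k} [ppg]": v for k, v in prf.items()})
            ppg_ok = True

    try:
        beats = detect_abp_beats(w.channels["abp"], fs)
    except ValueError:
        beats = []
    n_valid = sum(b.valid for b in beats)
    if n_valid >= min_beats:
        af = abp_features(beats)
        prf = pr_features(beats, fs)
        if af is not None and prf is not None:
            row.update(af)
            row.update({f"{k} [abp]": v for k, v in prf.items()})
            abp_ok = True

    row["usable_ppg"] = ppg_ok
    row["usable_abp"] = abp_ok
    return row


def assemble(modality: str, window: ObservationWindow, fs: float = 250.0, min_beats: int = MIN_VALID_BEATS) -> pd.Series | None:
    """Ordered feature vector for one window, or None if unusable.

    Dimensions: 24 (PPG), 12 (ABP), 30 (PPG&ABP).  In the combined
    modality the pulse-rate block appears once, from the PPG channel, so
    the PPG sub-vector equals the PPG-only vector on the same window.
    """
    names = modality_features(modality)
    row = _window_feature_row(window, fs, min_beats)
    need_ppg = "PPG" in modality
    need_abp = "ABP" in modality
    if need_ppg and "ppg" not in window.channels or need_abp and "abp" not in window.channels:
        raise ValueError(f"window lacks a channel required by modality {modality!r}")
    if (need_ppg and not row["usable_ppg"]) or (need_abp and not row["usable_abp"]):
        return None
    pr_suffix = "ppg" if need_ppg else "abp"
    values = {}
    for name in names:
        if name in PR_FEATURES:
            values[name] = row[f"{name} [{pr_suffix}]"]
        else:
            values[name] = row[name]
    return pd.Series(values, index=names)


def extract_cohort_features(
    subjects,
    window_s: float = 60.0,
    hop_s: float = 30.0,
    min_beats: int = MIN_VALID_BEATS,
    max_artifact_overlap: float = 0.0,
) -> pd.DataFrame:
    """Segment, artifact-filter and featurize a cohort.

    Returns one row per kept window: metadata columns, the 18 PPG
    features, the 6 ABP features, and both pulse-rate blocks (suffixed by
    source channel); windows dropped for artifacts or undetectable beats
    are excluded.  The frame carries the per-subject drop counts in
    ``frame.attrs``.
    """
    from .windows import quality_filter, segment  # local import to avoid cycle confusion

    rows = []
    dropped_artifact = 0
    dropped_unusable = 0
    total = 0
    for subj in subjects:
        wins = segment(subj, window_s, hop_s)
        total += len(wins)
        kept, n_drop = quality_filter(
            wins, subj.artifact_mask, subj.sampling_rate, max_artifact_overlap
        )
        dropped_artifact += n_drop
        for w in kept:
            row = _window_feature_row(w, subj.sampling_rate, min_beats)
            if not (row["usable_ppg"] or row["usable_abp"]):
                dropped_unusable += 1
                continue
            rows.append(
                {
                    "subject_id": w.subject_id,
                    "start_s": w.start,
                    "phase": w.phase,
                    "label_blv": w.label_blv,
                    "quality_ok": True,
                    **row,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["n_windows_total"] = total
    frame.attrs["n_dropped_artifact"] = dropped_artifact
    frame.attrs["n_dropped_unusable"] = dropped_unusable
    return frame


def design_matrix(features: pd.DataFrame, modality: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a wide cohort feature frame into (X, meta) for one modality.

    X has the canonical ordered columns of :func:`modality_features`;
    rows unusable for the modality's channels are excluded.
    """
    names = modality_features(modality)
    need_ppg = "PPG" in modality
    need_abp = "ABP" in modality
    ok = pd.Series(True, index=features.index)
    if need_ppg:
        ok &= features["usable_ppg"].astype(bool)
    if need_abp:
        ok &= features["usable_abp"].astype(bool)
    sub = features.loc[ok]
    suffix = "ppg" if need_ppg else "abp"
    cols = {}
    for name in names:
        src = f"{name} [{suffix}]" if name in PR_FEATURES else name
        cols[name] = sub[src]
    X = pd.DataFrame(cols, index=sub.index)[names]
    meta = sub[META_COLUMNS].copy()
    return X, meta
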