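"""Record I/O and sliding-window segmentation.

Continuous signals are divided into overlapping 1-minute observation
windows updated every 30 s; each window carries the cumulative reference
blood-loss volume at its end time as the regression label (zero throughout
the baseline), and windows overlapping artifact-masked samples are dropped
outright.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    BleedSegment,
    SubjectPhysio,
    SubjectRecord,
    reference_blv,
)

__all__ = [
    "ObservationWindow",
    "segment",
    "quality_filter",
    "windows_to_frame",
    "write_record",
    "read_record",
]

WINDOW_S = 60.0
HOP_S = 30.0


class RecordFormatError(ValueError):
    """Raised when an on-disk record is inconsistent or incomplete."""


@dataclass
class ObservationWindow:
    """One 60-s observation frame of a subject's record."""

    subject_id: str
    start: float                      # s
    duration: float                   # s
    channels: dict[str, np.ndarray]   # views into the parent record
    phase: str                        # "baseline" | "bleeding"
    label_blv: float                  # mL at window end
    quality_ok: bool = True

    @property
    def end(self) -> float:
        return self.start + self.duration


def n_windows(total_s: float, window_s: float = WINDOW_S, hop_s: float = HOP_S) -> int:
    """floor((T - window)/hop) + 1 for T >= window, else 0."""
    if total_s < window_s:
        return 0
    return int(math.floor((total_s - window_s) / hop_s + 1e-9)) + 1


def segment(
    subject: SubjectRecord,
    window_s: float = WINDOW_S,
    hop_s: float = HOP_S,
    label_at: str = "end",
) -> list[ObservationWindow]:
    """Tile the record with overlapping windows and attach BLV labels.

    Windows start at 0, hop_s, 2*hop_s, ... covering [0, T - window_s].
    ``label_at`` selects where along the window the cumulative reference
    BLV is read ("end" by default: the label is blood lost so far when the
    window completes; "start" and "center" are available).  A window is
    assigned to the bleeding phase when its labeling time falls past the
    bleed onset, so baseline windows always carry label 0.
    """
    total = subject.duration
    count = n_windows(total, window_s, hop_s)
    if count == 0:
        raise ValueError(
            f"record of {total:.1f} s shorter than one {window_s:.0f}-s window"
        )
    offsets = {"end": window_s, "center": window_s / 2.0, "start": 0.0}
    if label_at not in offsets:
        raise ValueError(f"label_at must be one of {sorted(offsets)}")
    fs = subject.sampling_rate
    bleed_start = subject.bleed_start
    out = []
    for k in range(count):
        start = k * hop_s
        t_label = start + offsets[label_at]
        a = int(round(start * fs))
        b = a + int(round(window_s * fs))
        phase = "bleeding" if t_label > bleed_start else "baseline"
        label = reference_blv(t_label, subject.bleed_schedule) if phase == "bleeding" else 0.0
        out.append(
            ObservationWindow(
                subject_id=subject.subject_id,
                start=float(start),
                duration=float(window_s),
                channels={"ppg": subject.ppg[a:b], "abp": subject.abp[a:b]},
                phase=phase,
                label_blv=float(label),
            )
        )
    return out


def quality_filter(
    windows: list[ObservationWindow],
    artifact_mask: np.ndarray,
    fs: float = 250.0,
    max_overlap_fraction: float = 0.0,
) -> tuple[list[ObservationWindow], int]:
    """Drop windows whose samples overlap the artifact mask.

    A window is dropped when more than ``max_overlap_fraction`` of its
    samples are masked; the default 0.0 is the strict any-overlap rule.
    Returns the kept windows (flagged ``quality_ok``) and the drop count.
    """
    kept: list[ObservationWindow] = []
    dropped = 0
    for w in windows:
        a = int(round(w.start * fs))
        b = a + int(round(w.duration * fs))
        overlap = int(np.count_nonzero(artifact_mask[a:b]))
        if overlap > max_overlap_fraction * (b - a):
            w.quality_ok = False
            dropped += 1
        else:
            w.quality_ok = True
            kept.append(w)
    return kept, dropped


def windows_to_frame(windows: list[ObservationWindow]) -> pd.DataFrame:
    """Tabular handoff: one row per window, no samples."""
    return pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "start_s": [w.start for w in windows],
            "phase": [w.phase for w in windows],
            "label_blv": [w.label_blv for w in windows],
            "quality_ok": [w.quality_ok for w in windows],
        }
    )


# ---------------------------------------------------------------------------
# On-disk format: <dir>/{ppg.csv, abp.csv, meta.json}
# ---------------------------------------------------------------------------

def write_record(record: SubjectRecord, path: str | Path) -> Path:
    """Write a subject as two-column CSVs per channel plus a JSON sidecar.

    Samples are serialized with 9 significant digits, enough to round-trip
    float32 exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fs = record.sampling_rate
    t = np.arange(len(record.ppg)) / fs
    for name, sig in (("ppg", record.ppg), ("abp", record.abp)):
        pd.DataFrame({"time_s": t, "value": sig}).to_csv(
            path / f"{name}.csv", index=False, float_format="%.9g"
        )
    phys = record.physio
    meta = {
        "subject_id": record.subject_id,
        "weight_kg": record.weight,
        "ebv_ml": record.ebv,
        "baseline_duration_s": record.baseline_duration,
        "sampling_rate_hz": fs,
        "n_samples": len(record.ppg),
        "rng_seed": record.rng_seed,
        "bleed_schedule": [
            {"start_s": s.start, "end_s": s.end, "rate_ml_min": s.rate}
            for s in record.bleed_schedule
        ],
        "hct_draws": [{"time_s": t_, "hct_pct": h} for t_, h in record.hct_draws],
        "artifact_segments": [list(seg) for seg in record.artifact_segments],
        "physio": vars(phys).copy(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_record(path: str | Path) -> SubjectRecord:
    """Read a record written by :func:`write_record` (lossless round-trip)."""
    path = Path(path)
    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise RecordFormatError(f"sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    fs = float(meta["sampling_rate_hz"])
    signals = {}
    for name in ("ppg", "abp"):
        f = path / f"{name}.csv"
        if not f.exists():
            raise RecordFormatError(f"channel file {f} is missing")
        df = pd.read_csv(f)
        if len(df) != meta["n_samples"]:
            raise RecordFormatError(
                f"{f}: {len(df)} samples, sidecar says {meta['n_samples']}"
            )
        signals[name] = df["value"].to_numpy(dtype=np.float32)
    return SubjectRecord(
        subject_id=meta["subject_id"],
        weight=meta["weight_kg"],
        ebv=meta["ebv_ml"],
        baseline_duration=meta["baseline_duration_s"],
        bleed_schedule=[
            BleedSegment(s["start_s"], s["end_s"], s["rate_ml_min"])
            for s in meta["bleed_schedule"]
        ],
        sampling_rate=fs,
        ppg=signals["ppg"],
        abp=signals["abp"],
        hct_draws=[(d["time_s"], d["hct_pct"]) for d in meta["hct_draws"]],
        rng_seed=meta["rng_seed"],
        physio=SubjectPhysio(**meta["physio"]),
        artifact_segments=[tuple(seg) for seg in meta["artifact_segments"]],
    )
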