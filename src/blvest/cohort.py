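"""Synthetic hemorrhage cohort generator.

Emulates the experimental conditions of a controlled porcine hemorrhage
study: anesthetized subjects are observed for a stable baseline period and
then bled by a roller pump at a fixed rate (with rest pauses) until their
mean arterial pressure (MAP) falls to a shock threshold.  Each subject
carries continuous 250 Hz photoplethysmography (PPG, arbitrary units) and
invasive arterial blood pressure (ABP, mmHg) waveforms, a bleed schedule
from which the reference blood-loss volume (BLV) is computed, and sparse
hematocrit (HCT) draws following a dilution-with-refill model.

The simulated physiology is deliberately phenomenological rather than a
cardiovascular ODE model: pulse amplitude shrinks and pulse rate rises
monotonically with the effective fractional volume deficit, arterial
pressures are compensated (approximately flat) below a knee and fall
linearly to the shock threshold beyond it, and transcapillary refill
partially restores effective volume during rest pauses.  These are exactly
the qualitative responses the downstream feature/regression pipeline is
designed to exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BleedSegment",
    "PhysioState",
    "SubjectPhysio",
    "SimConfig",
    "SubjectRecord",
    "compensatory_response",
    "generate_cohort",
    "generate_subject",
    "hct_trajectory",
    "inject_artifacts",
    "reference_blv",
    "physio_trajectory",
    "synth_abp_beat",
    "synth_ppg_beat",
]

SAMPLING_RATE = 250.0  # Hz


class ConfigError(ValueError):
    """Raised when a simulation configuration field is out of range."""


@dataclass(frozen=True)
class BleedSegment:
    """One pump interval: active bleed (``rate`` mL/min) or rest (rate 0).

    Times are absolute seconds from the start of the recording, so baseline
    windows (which precede the first segment) get a reference BLV of zero
    without special-casing.
    """

    start: float
    end: float
    rate: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"BleedSegment end {self.end} <= start {self.start}")
        if self.rate < 0:
            raise ValueError("BleedSegment rate must be >= 0")


@dataclass(frozen=True)
class PhysioState:
    """Instantaneous hemodynamic state used to synthesize one beat."""

    blv: float                # cumulative blood loss, mL
    blv_fraction: float       # effective fractional volume deficit
    pulse_rate: float         # bpm
    sbp: float                # mmHg
    dbp: float                # mmHg
    ppg_amp_scale: float      # 1.0 at baseline, falls with volume loss

    def __post_init__(self) -> None:
        if not (0.0 <= self.blv_fraction <= 1.0):
            raise ValueError("blv_fraction outside [0, 1]")
        if not (self.sbp > self.dbp > 0):
            raise ValueError("require sbp > dbp > 0")
        if not (40.0 <= self.pulse_rate <= 250.0):
            raise ValueError("pulse_rate outside physiological range [40, 250] bpm")

    @property
    def map(self) -> float:
        """Mean arterial pressure via the standard 1/3 pulse-pressure rule."""
        return self.dbp + (self.sbp - self.dbp) / 3.0


@dataclass(frozen=True)
class SubjectPhysio:
    """Per-subject physiologic and device parameters (sampled once)."""

    pr0: float                # baseline pulse rate, bpm
    pr_rise: float            # maximal compensatory pulse-rate rise, bpm
    map0: float               # baseline MAP, mmHg
    pp0: float                # baseline pulse pressure, mmHg
    amp_decay: float          # PPG amplitude decay constant vs deficit
    comp_knee: float          # fractional deficit where BP compensation fails
    f_shock: float            # effective deficit fraction at shock MAP
    shock_map: float          # mmHg
    ppg_offset: float         # device DC offset, a.u.
    ppg_gain: float           # device gain, a.u.
    hct0: float               # baseline hematocrit, %
    refill_fraction: float    # fraction of deficit recoverable by refill
    refill_tau_s: float       # waveform-refill time constant, s
    hct_refill_tau_s: float   # HCT dilution lag time constant, s
    hct_noise_sd: float       # HCT measurement noise, % points
    hct_refill: bool          # False => pure exponential dilution (exact mode)


@dataclass
class SimConfig:
    """Cohort-level simulation configuration.

    Defaults reproduce the study conditions: weights ~N(31.82, 3.52^2) kg,
    EBV = 67.9 mL/kg (ratio of the cohort mean blood volume 2160 mL to the
    mean weight), baselines of 18-31 min, bleeding periods targeting
    106-185 min made of 3-6 active 20 mL/min pump segments separated by
    rests, shock at MAP 30 mmHg, ~3.3 % of windows hit by artifacts, and
    baseline HCT ~N(30.8, 6.0^2) %.
    """

    weight_mean_kg: float = 31.82
    weight_sd_kg: float = 3.52
    ebv_coeff_ml_per_kg: float = 67.9
    baseline_min_s: float = 18 * 60.0
    baseline_max_s: float = 31 * 60.0
    bleed_total_min_s: float = 106 * 60.0
    bleed_total_max_s: float = 185 * 60.0
    max_bleed_total_s: float = 240 * 60.0
    n_segments_range: tuple[int, int] = (3, 6)
    pump_rate_ml_min: float = 20.0
    shock_map_mmhg: float = 30.0
    comp_knee: float = 0.15
    shock_fraction_mean: float = 0.40
    shock_fraction_sd: float = 0.10
    shock_fraction_bounds: tuple[float, float] = (0.25, 0.60)
    refill_fraction: float = 0.20
    refill_tau_s: float = 1200.0
    pr0_mean: float = 85.0
    pr0_sd: float = 8.0
    pr_rise_mean: float = 55.0
    pr_rise_sd: float = 8.0
    map0_mean: float = 90.0
    map0_sd: float = 7.0
    pp0_mean: float = 40.0
    pp0_sd: float = 5.0
    amp_decay: float = 2.0
    ppg_offset_range: tuple[float, float] = (1.0, 3.0)
    ppg_gain_range: tuple[float, float] = (0.5, 2.0)
    hrv_jitter: float = 0.02          # per-beat pulse-rate jitter (fractional)
    amp_jitter: float = 0.02          # per-beat amplitude jitter (fractional)
    bp_jitter_mmhg: float = 1.0       # per-beat SBP/DBP jitter
    ppg_noise: float = 0.01           # additive noise, a.u.
    abp_noise_mmhg: float = 0.5
    artifact_fraction: float = 0.033
    artifact_len_s: float = 60.0
    hct0_mean: float = 30.8
    hct0_sd: float = 6.0
    hct_noise_sd: float = 0.5
    hct_refill_tau_s: float = 2400.0
    hct_refill: bool = True
    hct_draw_interval_s: float = 1800.0
    sampling_rate: float = SAMPLING_RATE

    def validate(self) -> None:
        pairs = [
            ("baseline_min_s/baseline_max_s", self.baseline_min_s, self.baseline_max_s),
            ("bleed_total_min_s/bleed_total_max_s", self.bleed_total_min_s, self.bleed_total_max_s),
        ]
        for name, lo, hi in pairs:
            if lo > hi:
                raise ConfigError(f"{name}: min {lo} > max {hi}")
            if lo <= 0:
                raise ConfigError(f"{name}: min must be positive, got {lo}")
        if self.n_segments_range[0] > self.n_segments_range[1] or self.n_segments_range[0] < 1:
            raise ConfigError(f"n_segments_range invalid: {self.n_segments_range}")
        if self.pump_rate_ml_min <= 0:
            raise ConfigError("pump_rate_ml_min must be positive")
        if not (0.0 < self.comp_knee < self.shock_fraction_bounds[0]):
            raise ConfigError(
                f"comp_knee ({self.comp_knee}) must lie strictly below the lower "
                f"shock-fraction bound ({self.shock_fraction_bounds[0]})"
            )
        if not (0.0 <= self.refill_fraction < 1.0):
            raise ConfigError("refill_fraction must be in [0, 1)")
        if not (0.0 <= self.artifact_fraction < 0.5):
            raise ConfigError("artifact_fraction must be in [0, 0.5)")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")


@dataclass
class SubjectRecord:
    """One synthetic subject: metadata, waveforms, schedule, HCT draws."""

    subject_id: str
    weight: float                      # kg
    ebv: float                         # mL, estimated initial blood volume
    baseline_duration: float           # s
    bleed_schedule: list[BleedSegment]
    sampling_rate: float
    ppg: np.ndarray                    # float32, a.u.
    abp: np.ndarray                    # float32, mmHg
    hct_draws: list[tuple[float, float]]
    rng_seed: int
    physio: SubjectPhysio
    artifact_segments: list[tuple[float, float]] = field(default_factory=list)
    _feff_grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def duration(self) -> float:
        return len(self.ppg) / self.sampling_rate

    @property
    def bleed_start(self) -> float:
        return self.bleed_schedule[0].start if self.bleed_schedule else self.duration

    @property
    def artifact_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.ppg), dtype=bool)
        fs = self.sampling_rate
        for a, b in self.artifact_segments:
            mask[int(round(a * fs)): int(round(b * fs))] = True
        return mask

    def feff_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, cumulative fraction, effective fraction) on a 1-s grid."""
        if self._feff_grid is None:
            self._feff_grid = _simulate_feff(
                self.bleed_schedule, self.ebv, self.physio.refill_fraction,
                self.physio.refill_tau_s, self.duration,
            )
        return self._feff_grid

    def effective_fraction(self, t: float | np.ndarray) -> np.ndarray:
        grid_t, _, feff = self.feff_grid()
        return np.interp(t, grid_t, feff)


# ---------------------------------------------------------------------------
# Reference blood loss and effective-volume dynamics
# ---------------------------------------------------------------------------

def reference_blv(t: float, schedule: list[BleedSegment]) -> float:
    """Cumulative pumped volume (mL) at time ``t`` from the bleed schedule.

    Piecewise-linear and nondecreasing in ``t``; zero before the first
    active segment; times beyond the schedule return the terminal volume.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    total = 0.0
    for seg in schedule:
        overlap = min(t, seg.end) - seg.start
        if overlap > 0:
            total += seg.rate * overlap / 60.0
    return total


def _simulate_feff(
    schedule: list[BleedSegment],
    ebv: float,
    refill_fraction: float,
    refill_tau_s: float,
    t_end: float,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the effective volume deficit on a uniform grid.

    The cumulative deficit f(t) = BLV(t)/EBV is relieved by transcapillary
    refill r(t), which relaxes toward ``refill_fraction * f`` with time
    constant ``refill_tau_s`` (first-order, exponential-Euler step).  The
    effective deficit f_eff = f - r drives all hemodynamic responses.
    """
    n = int(math.floor(t_end / dt)) + 1
    t = np.arange(n) * dt
    f = np.array([reference_blv(ti, schedule) for ti in t]) / ebv
    r = np.zeros(n)
    decay = 1.0 - math.exp(-dt / refill_tau_s)
    for i in range(1, n):
        r[i] = r[i - 1] + (refill_fraction * f[i - 1] - r[i - 1]) * decay
    feff = np.clip(f - r, 0.0, 1.0)
    return t, f, feff


# ---------------------------------------------------------------------------
# Compensatory response curves
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def compensatory_response(f: float, phys: SubjectPhysio, blv_ml: float | None = None) -> PhysioState:
    """Hemodynamic state at effective fractional deficit ``f``.

    Pulse rate rises (logistic, anchored to exactly ``pr0`` at f = 0), PPG
    amplitude falls exponentially (exactly 1 at f = 0), pulse pressure
    narrows, and MAP is near-flat below ``comp_knee`` then declines
    linearly, hitting ``shock_map`` exactly at ``f_shock``.
    """
    f = float(f)
    if f < 0:
        raise ValueError("fractional deficit must be >= 0")

    # Pulse rate: logistic rise centered at 25 % deficit, pinned at pr0.
    k, c = 8.0, 0.25
    s0 = _logistic(-k * c)
    pr = phys.pr0 + phys.pr_rise * (_logistic(k * (f - c)) - s0) / (1.0 - s0)
    pr = float(np.clip(pr, 40.0, 250.0))

    amp = math.exp(-phys.amp_decay * f)

    # MAP: 3 % sag across the compensated range, then linear to shock.
    knee = phys.comp_knee
    map_knee = phys.map0 * 0.97
    if f <= knee:
        map_now = phys.map0 - (phys.map0 - map_knee) * f / knee
    else:
        slope = (map_knee - phys.shock_map) / max(phys.f_shock - knee, 1e-6)
        map_now = map_knee - slope * (f - knee)
    map_now = max(map_now, 20.0)

    pp = phys.pp0 * math.exp(-0.8 * f)
    dbp = map_now - pp / 3.0
    sbp = dbp + pp
    if dbp <= 0:  # far beyond shock; keep state physical
        dbp, sbp = 5.0, 5.0 + pp

    return PhysioState(
        blv=blv_ml if blv_ml is not None else 0.0,
        blv_fraction=min(f, 1.0),
        pulse_rate=pr,
        sbp=sbp,
        dbp=dbp,
        ppg_amp_scale=amp,
    )


def physio_trajectory(subject: SubjectRecord, t: float) -> PhysioState:
    """Hemodynamic state of ``subject`` at absolute time ``t`` seconds."""
    if not (0.0 <= t <= subject.duration + 1e-9):
        raise ValueError(f"t={t} outside record span [0, {subject.duration:.1f}] s")
    f = float(subject.effective_fraction(t))
    blv = reference_blv(t, subject.bleed_schedule)
    return compensatory_response(f, subject.physio, blv_ml=blv)


# ---------------------------------------------------------------------------
# Beat morphology
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[tuple[str, int], np.ndarray] = {}

# Two-lobe pulse: a dominant systolic Gaussian plus a delayed, smaller
# reflected (dicrotic) wave; the trough between them is the dicrotic notch.
_PPG_LOBES = ((0.22, 0.045, 1.0), (0.50, 0.10, 0.40))
_ABP_LOBES = ((0.24, 0.050, 1.0), (0.52, 0.10, 0.35))


def _pulse_template(n: int, kind: str = "ppg") -> np.ndarray:
    """Unit-amplitude single-pulse template of ``n`` samples.

    Zero at both endpoints (continuity across beat boundaries), maximum
    exactly 1 at the systolic peak, with a guaranteed dicrotic notch.
    """
    key = (kind, n)
    cached = _TEMPLATE_CACHE.get(key)
    if cached is not None:
        return cached
    lobes = _PPG_LOBES if kind == "ppg" else _ABP_LOBES
    s = np.arange(n) / n
    y = np.zeros(n)
    for mu, sig, a in lobes:
        y += a * np.exp(-0.5 * ((s - mu) / sig) ** 2)
    y_end = sum(a * math.exp(-0.5 * ((1.0 - mu) / sig) ** 2) for mu, sig, a in lobes)
    y -= y[0] + (y_end - y[0]) * s
    y /= y.max()
    _TEMPLATE_CACHE[key] = y
    return y


def synth_ppg_beat(
    state: PhysioState,
    *,
    offset: float = 0.0,
    gain: float = 1.0,
    fs: float = SAMPLING_RATE,
) -> np.ndarray:
    """One PPG pulse at the state's rate, amplitude, device offset/gain.

    The beat spans 60/pulse_rate seconds; its peak-minus-foot amplitude is
    ``gain * ppg_amp_scale`` and its foot sits at ``offset``.
    """
    n = int(round(fs * 60.0 / state.pulse_rate))
    if n < int(0.24 * fs) or n > int(1.5 * fs):
        raise ValueError(f"non-physiological pulse rate {state.pulse_rate:.1f} bpm")
    return offset + gain * state.ppg_amp_scale * _pulse_template(n, "ppg")


def synth_abp_beat(state: PhysioState, *, fs: float = SAMPLING_RATE) -> np.ndarray:
    """One ABP pulse spanning [DBP, SBP] mmHg at the state's rate."""
    n = int(round(fs * 60.0 / state.pulse_rate))
    if n < int(0.24 * fs) or n > int(1.5 * fs):
        raise ValueError(f"non-physiological pulse rate {state.pulse_rate:.1f} bpm")
    return state.dbp + (state.sbp - state.dbp) * _pulse_template(n, "abp")


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(
    signal: np.ndarray,
    fraction: float,
    seed: int,
    *,
    fs: float = SAMPLING_RATE,
    window_s: float = 60.0,
    hop_s: float = 30.0,
    segment_s: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt random hop-aligned segments so ~``fraction`` of analysis
    windows overlap an artifact.

    Segments are placed on the window hop grid; one ``segment_s``-long
    artifact then touches segment_s/hop_s + 1 windows under the strict
    any-overlap drop rule, and the number of segments is chosen (with
    stochastic rounding) so the expected corrupted-window share equals
    ``fraction``.  Artifact content cycles flatline / saturation /
    high-amplitude noise.  Identical seeds give identical placements.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    out = np.array(signal, copy=True)
    mask = np.zeros(len(signal), dtype=bool)
    if fraction == 0.0 or len(signal) == 0:
        return out, mask

    rng = np.random.default_rng(seed)
    total_s = len(signal) / fs
    n_windows = int(math.floor((total_s - window_s) / hop_s)) + 1
    if n_windows <= 0:
        return out, mask
    per_artifact = segment_s / hop_s + 1.0  # windows touched by one aligned segment
    target = fraction * n_windows / per_artifact
    n_seg = int(math.floor(target)) + int(rng.random() < (target - math.floor(target)))
    if n_seg == 0:
        return out, mask

    # candidate starts: hop-aligned, interior (all touched windows exist),
    # spaced so artifacts never merge
    starts = np.arange(hop_s, total_s - window_s - segment_s, hop_s)
    if len(starts) == 0:
        return out, mask
    chosen: list[float] = []
    order = rng.permutation(len(starts))
    for idx in order:
        s = starts[idx]
        if all(abs(s - c) >= segment_s + window_s for c in chosen):
            chosen.append(float(s))
        if len(chosen) >= n_seg:
            break

    lo, hi = float(np.min(signal)), float(np.max(signal))
    span = max(hi - lo, 1e-6)
    for i, s in enumerate(sorted(chosen)):
        a, b = int(round(s * fs)), int(round((s + segment_s) * fs))
        mask[a:b] = True
        kind = i % 3
        if kind == 0:       # flatline at the last clean value
            out[a:b] = out[max(a - 1, 0)]
        elif kind == 1:     # rail saturation
            out[a:b] = hi + 0.2 * span
        else:               # high-amplitude noise burst
            out[a:b] = rng.normal((lo + hi) / 2.0, span, b - a)
    return out, mask


# ---------------------------------------------------------------------------
# Hematocrit
# ---------------------------------------------------------------------------

def hct_trajectory(
    subject: SubjectRecord,
    draw_times: list[float],
    *,
    refill: bool | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """HCT (%) at the requested draw times under exponential dilution.

    With refill lag enabled (default), the diluting volume follows the
    pumped volume through a first-order lag, so the fractional HCT drop
    under-represents the fractional blood loss — HCT-based formulas then
    systematically underestimate BLV.  With ``refill=False`` and zero
    noise, hct(t) = hct0 * exp(-BLV(t)/EBV) exactly, and Ward's
    logarithmic formula inverts the simulation perfectly (the module's
    self-consistency oracle).
    """
    phys = subject.physio
    use_refill = phys.hct_refill if refill is None else refill
    sd = phys.hct_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(subject.rng_seed + 101 if seed is None else seed)

    for t in draw_times:
        if not (0.0 <= t <= subject.duration + 1e-9):
            raise ValueError(f"draw time {t} outside record span")

    if use_refill:
        dt = 1.0
        n = int(math.floor(subject.duration / dt)) + 1
        grid = np.arange(n) * dt
        blv = np.array([reference_blv(t, subject.bleed_schedule) for t in grid])
        lag = np.zeros(n)
        decay = 1.0 - math.exp(-dt / phys.hct_refill_tau_s)
        for i in range(1, n):
            lag[i] = lag[i - 1] + (blv[i - 1] - lag[i - 1]) * decay
        dil = lambda t: float(np.interp(t, grid, lag))  # noqa: E731
    else:
        dil = lambda t: reference_blv(t, subject.bleed_schedule)  # noqa: E731

    draws = []
    for t in draw_times:
        h = phys.hct0 * math.exp(-dil(t) / subject.ebv)
        if sd > 0:
            h += rng.normal(0.0, sd)
        draws.append((float(t), float(np.clip(h, 1.0, 99.0))))
    return draws


def default_draw_times(baseline_duration: float, bleed_start: float, t_end: float, interval_s: float = 1800.0) -> list[float]:
    """Protocol draw schedule: mid-baseline, bleed onset, every 30 min, end."""
    times = [baseline_duration / 2.0, bleed_start]
    t = bleed_start + interval_s
    while t < t_end - 60.0:
        times.append(t)
        t += interval_s
    times.append(t_end)
    return times


# ---------------------------------------------------------------------------
# Subject and cohort generation
# ---------------------------------------------------------------------------

def _sample_physio(rng: np.random.Generator, config: SimConfig) -> SubjectPhysio:
    lo, hi = config.shock_fraction_bounds
    return SubjectPhysio(
        pr0=float(rng.normal(config.pr0_mean, config.pr0_sd)),
        pr_rise=float(abs(rng.normal(config.pr_rise_mean, config.pr_rise_sd))),
        map0=float(rng.normal(config.map0_mean, config.map0_sd)),
        pp0=float(rng.normal(config.pp0_mean, config.pp0_sd)),
        amp_decay=config.amp_decay,
        comp_knee=config.comp_knee,
        f_shock=float(np.clip(rng.normal(config.shock_fraction_mean, config.shock_fraction_sd), lo, hi)),
        shock_map=config.shock_map_mmhg,
        ppg_offset=float(rng.uniform(*config.ppg_offset_range)),
        ppg_gain=float(rng.uniform(*config.ppg_gain_range)),
        hct0=float(np.clip(rng.normal(config.hct0_mean, config.hct0_sd), 15.0, 55.0)),
        refill_fraction=config.refill_fraction,
        refill_tau_s=config.refill_tau_s,
        hct_refill_tau_s=config.hct_refill_tau_s,
        hct_noise_sd=config.hct_noise_sd,
        hct_refill=config.hct_refill,
    )


def _build_schedule(
    rng: np.random.Generator,
    ebv: float,
    baseline_duration: float,
    phys: SubjectPhysio,
    config: SimConfig,
) -> tuple[list[BleedSegment], float]:
    """Plan pump segments and simulate until effective deficit hits shock.

    Active time is pre-split into 3-6 segments separated by rests sized to
    land the bleeding period inside the target duration range; the final
    active segment is truncated (or extended, up to a hard cap) at the
    1-second step where the effective deficit crosses ``f_shock``, so the
    record ends with MAP at the shock threshold.
    """
    rate_per_s = config.pump_rate_ml_min / 60.0
    n_seg = int(rng.integers(config.n_segments_range[0], config.n_segments_range[1] + 1))
    target_total = rng.uniform(config.bleed_total_min_s, config.bleed_total_max_s)
    active_est = phys.f_shock * ebv / rate_per_s / (1.0 - phys.refill_fraction)
    bleed_durs = active_est * rng.dirichlet(np.full(n_seg, 6.0))
    n_rest = n_seg - 1
    rest_total = max(target_total - active_est, 120.0 * max(n_rest, 1))
    rest_durs = rest_total * rng.dirichlet(np.full(n_rest, 6.0)) if n_rest else np.array([])

    dt = 1.0
    decay = 1.0 - math.exp(-dt / phys.refill_tau_s)
    f = r = 0.0
    t = baseline_duration
    segments: list[BleedSegment] = []
    max_end = baseline_duration + config.max_bleed_total_s

    def bleed_until(t: float, f: float, r: float, dur: float | None) -> tuple[float, float, float, bool]:
        """Advance with the pump on; stop at shock, dur, or the hard cap."""
        start = t
        while t < max_end:
            if dur is not None and t - start >= dur:
                return t, f, r, False
            f += rate_per_s * dt / ebv
            r += (phys.refill_fraction * f - r) * decay
            t += dt
            if f - r >= phys.f_shock:
                return t, f, r, True
        return t, f, r, True

    shocked = False
    for i in range(n_seg):
        is_last = i == n_seg - 1
        start = t
        t, f, r, shocked = bleed_until(t, f, r, None if is_last else float(bleed_durs[i]))
        segments.append(BleedSegment(start, t, config.pump_rate_ml_min))
        if shocked:
            break
        if i < n_rest:
            rest = float(rest_durs[i])
            steps = int(rest / dt)
            for _ in range(steps):
                r += (phys.refill_fraction * f - r) * decay
            t += steps * dt
    return segments, t


def generate_subject(
    subject_id: str,
    seed_seq: np.random.SeedSequence,
    config: SimConfig,
) -> SubjectRecord:
    """Generate one subject record (waveforms, schedule, HCT draws)."""
    rng = np.random.default_rng(seed_seq)
    rng_seed = int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)
    fs = config.sampling_rate

    weight = float(rng.normal(config.weight_mean_kg, config.weight_sd_kg))
    weight = max(weight, 5.0)
    ebv = config.ebv_coeff_ml_per_kg * weight
    baseline_duration = float(rng.uniform(config.baseline_min_s, config.baseline_max_s))
    phys = _sample_physio(rng, config)
    schedule, t_end = _build_schedule(rng, ebv, baseline_duration, phys, config)

    grid = _simulate_feff(schedule, ebv, phys.refill_fraction, phys.refill_tau_s, t_end)
    grid_t, _, feff = grid

    # Beat-by-beat synthesis; PPG and ABP share the beat grid (same heart).
    ppg_parts: list[np.ndarray] = []
    abp_parts: list[np.ndarray] = []
    t = 0.0
    n_total = int(round(t_end * fs))
    n_done = 0
    while n_done < n_total:
        f = float(np.interp(t, grid_t, feff))
        state = compensatory_response(f, phys)
        pr_b = state.pulse_rate * (1.0 + rng.normal(0.0, config.hrv_jitter))
        pr_b = float(np.clip(pr_b, 40.0, 250.0))
        amp_b = state.ppg_amp_scale * (1.0 + rng.normal(0.0, config.amp_jitter))
        sbp_b = state.sbp + rng.normal(0.0, config.bp_jitter_mmhg)
        dbp_b = state.dbp + rng.normal(0.0, config.bp_jitter_mmhg / 2.0)
        if sbp_b - dbp_b < 5.0:
            sbp_b = dbp_b + 5.0
        beat = PhysioState(
            blv=0.0, blv_fraction=min(f, 1.0), pulse_rate=pr_b,
            sbp=sbp_b, dbp=dbp_b, ppg_amp_scale=max(amp_b, 1e-3),
        )
        ppg_parts.append(synth_ppg_beat(beat, offset=phys.ppg_offset, gain=phys.ppg_gain, fs=fs))
        abp_parts.append(synth_abp_beat(beat, fs=fs))
        n_done += len(ppg_parts[-1])
        t = n_done / fs

    ppg = np.concatenate(ppg_parts)[:n_total]
    abp = np.concatenate(abp_parts)[:n_total]
    ppg += rng.normal(0.0, config.ppg_noise, n_total)
    abp += rng.normal(0.0, config.abp_noise_mmhg, n_total)

    artifact_segments: list[tuple[float, float]] = []
    if config.artifact_fraction > 0:
        art_seed = int(rng.integers(0, 2**31 - 1))
        ppg, mask = inject_artifacts(
            ppg, config.artifact_fraction, art_seed, fs=fs, segment_s=config.artifact_len_s
        )
        abp, _ = inject_artifacts(
            abp, config.artifact_fraction, art_seed, fs=fs, segment_s=config.artifact_len_s
        )
        artifact_segments = _mask_to_segments(mask, fs)

    record = SubjectRecord(
        subject_id=subject_id,
        weight=weight,
        ebv=ebv,
        baseline_duration=baseline_duration,
        bleed_schedule=schedule,
        sampling_rate=fs,
        ppg=ppg.astype(np.float32),
        abp=abp.astype(np.float32),
        hct_draws=[],
        rng_seed=rng_seed,
        physio=phys,
        artifact_segments=artifact_segments,
        _feff_grid=grid,
    )
    draw_times = default_draw_times(
        baseline_duration, record.bleed_start, record.duration, config.hct_draw_interval_s
    )
    record.hct_draws = hct_trajectory(record, draw_times)
    return record


def _mask_to_segments(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return [(float(a / fs), float(b / fs)) for a, b in zip(edges[::2], edges[1::2])]


def generate_cohort(
    n_subjects: int,
    config: SimConfig | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Generate ``n_subjects`` independent subjects from one master seed.

    Per-subject seeds are spawned from the master seed, so identical
    (config, seed) pairs reproduce byte-identical records while different
    subjects get independent baseline offsets, gains and physiology.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    config = config or SimConfig()
    config.validate()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        generate_subject(f"pig{i:03d}", child, config)
        for i, child in enumerate(children)
    ]
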