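"""Synthetic paired PPG/ABP generator with known ground truth.

Emulates the signal properties the downstream pipeline relies on, without a
full hemodynamic model:

* quasi-periodic arterial pulses built from two Gaussian lobes per beat — a
  systolic upstroke/peak and a smaller dicrotic (reflected) wave after it —
  giving each ABP beat a systolic peak, a dicrotic notch, and a diastolic
  decay to the per-beat minimum;
* exact per-beat pressure targets: each beat's sampled maximum equals the
  record's SBP target and its minimum the DBP target (before noise), because
  the beat shape is min-max rescaled per beat;
* pressure-dependent morphology: dicrotic wave size/timing and systolic
  width vary monotonically with mean and pulse pressure (see
  :func:`_shape_params`), so a window's pressure level is identifiable from
  its shape alone — the working premise of cuffless PPG BP estimation;
* a fixed per-record transit lag: pressure reaches the brachial measurement
  site before the volume pulse reaches the fingertip, so the PPG is the
  delayed channel;
* PPG as a smoothed (short convolution kernel), unit-scaled transform of the
  underlying pulse train, plus sub-0.5 Hz baseline wander and white noise;
* optional artifact segments (ABP flat-lines, PPG rail saturation) of
  0.5-2 s, to exercise artifact screening.

Heart-period jitter makes records quasi-periodic: each beat period is the
nominal period times ``1 + U(-jitter, +jitter)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bp_extract import BP_RANGES, classify_bp_range
from .errors import ParameterError
from .records import SignalRecord

__all__ = ["SimulationParams", "simulate_record", "sample_bp_targets",
           "simulate_cohort"]

# beat shape: phase position of the systolic lobe and width of the dicrotic
_SYS_CENTER = 0.30
_DIC_WIDTH = 0.060


def _shape_params(sbp: float, dbp: float):
    """Morphology as a monotone function of pressure level.

    Cuffless BP estimation from PPG rests on pulse morphology changing with
    pressure: higher mean pressure stiffens the arterial wall, speeding the
    reflected wave (earlier, larger dicrotic wave), while a larger pulse
    pressure sharpens the systolic upstroke. The generator encodes exactly
    that, so the pressure level of a window is identifiable from its shape —
    as the estimation problem presumes of real fingertip PPG.

    Returns ``(sys_width, dic_amp, dic_center, smooth_s)``: the first three
    in beat-phase units, the last in seconds.
    """
    # spans the full physiological MAP/pulse-pressure range of the four BP
    # classes, so no two pressure levels collapse onto the same shape
    mean_p = dbp + (sbp - dbp) / 3.0
    level = min(max((mean_p - 60.0) / 85.0, 0.0), 1.0)
    pp = min(max((sbp - dbp - 20.0) / 75.0, 0.0), 1.0)
    sys_width = 0.105 - 0.015 * pp - 0.015 * level
    # dicrotic wave stays well under the 25% peak-detection prominence so
    # SBP/DBP extraction sees one peak and one valley per beat
    dic_amp = 0.08 + 0.09 * level
    dic_center = 0.72 - 0.20 * level
    # peripheral damping: stiffer (higher-pressure) vessels transmit a
    # sharper volume pulse, so the PPG smoothing narrows with level — a
    # time-domain cue independent of heart rate
    smooth_s = 0.075 - 0.045 * level
    return sys_width, dic_amp, dic_center, smooth_s


@dataclass(frozen=True)
class SimulationParams:
    duration_s: float = 120.0
    fs: float = 125.0
    heart_rate_bpm: float = 75.0
    hr_jitter: float = 0.04        # per-beat period jitter fraction
    sbp_target: float = 120.0      # mmHg
    dbp_target: float = 80.0       # mmHg
    transit_lag_samples: int = 10  # ABP leads PPG by this many samples
    noise_sd: float = 0.0          # fraction of signal amplitude
    baseline_wander_amp: float = 0.0  # fraction of PPG amplitude, < 0.5 Hz
    artifact_rate: float = 0.0     # fraction of 350-sample windows corrupted
    seed: int = 0

    def validate(self) -> None:
        if not self.sbp_target > self.dbp_target > 0:
            raise ParameterError(
                "requires sbp_target > dbp_target > 0, got "
                f"{self.sbp_target}/{self.dbp_target}")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if not 0 <= self.artifact_rate <= 1:
            raise ParameterError("artifact_rate must be in [0, 1]")
        if self.transit_lag_samples < 0:
            raise ParameterError("transit_lag_samples must be >= 0")
        if not 0 <= self.hr_jitter < 1:
            raise ParameterError("hr_jitter must be in [0, 1)")
        if self.heart_rate_bpm <= 0:
            raise ParameterError("heart_rate_bpm must be positive")
        if self.noise_sd < 0 or self.baseline_wander_amp < 0:
            raise ParameterError("noise amplitudes must be >= 0")


def _beat_shape(phase: np.ndarray, sys_width: float, dic_amp: float,
                dic_center: float) -> np.ndarray:
    """Unnormalized pulse shape on phase in [0, 1): systolic + dicrotic lobe."""
    sys_lobe = np.exp(-0.5 * ((phase - _SYS_CENTER) / sys_width) ** 2)
    dic_lobe = dic_amp * np.exp(-0.5 * ((phase - dic_center) / _DIC_WIDTH) ** 2)
    return sys_lobe + dic_lobe


def _pulse_train(n: int, fs: float, hr_bpm: float, jitter: float,
                 shape_params, rng: np.random.Generator):
    """Per-beat min-max normalized pulse train of length n, plus beat spans."""
    period = 60.0 / hr_bpm
    sys_width, dic_amp, dic_center = shape_params
    out = np.empty(n, dtype=np.float64)
    beat_spans = []  # (start, stop) sample index pairs, stop exclusive
    start = 0
    while start < n:
        d = max(4, int(round(period * (1.0 + rng.uniform(-jitter, jitter)) * fs)))
        stop = min(start + d, n)
        # beat-to-beat variability of the reflected wave's size and timing
        # (shared by ABP and PPG): breaks exact periodicity so the true
        # alignment is unique under cross-correlation
        beat_dic = dic_amp * (1.0 + rng.uniform(-0.15, 0.15))
        beat_center = dic_center + rng.uniform(-0.03, 0.03)
        shape = _beat_shape(np.arange(stop - start) / d, sys_width, beat_dic,
                            beat_center)
        lo, hi = shape.min(), shape.max()
        if hi > lo:
            shape = (shape - lo) / (hi - lo)
        out[start:stop] = shape
        beat_spans.append((start, stop, d))
        start = stop
    return out, beat_spans


def simulate_record(params: SimulationParams) -> SignalRecord:
    """Generate one synthetic subject; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration_s * fs))
    lag = int(params.transit_lag_samples)
    span = params.sbp_target - params.dbp_target

    # master pulse train, long enough to cover the lag lead-in
    sys_width, dic_amp, dic_center, smooth_s = _shape_params(
        params.sbp_target, params.dbp_target)
    train, spans = _pulse_train(n + lag, fs, params.heart_rate_bpm,
                                params.hr_jitter,
                                (sys_width, dic_amp, dic_center), rng)

    # ABP reads the train `lag` samples ahead of the PPG
    abp = params.dbp_target + span * train[lag:lag + n]

    # complete beats fully visible in the ABP frame
    beat_starts, beat_sbp, beat_dbp, beat_map = [], [], [], []
    for (s, e, d) in spans:
        s_a, e_a = s - lag, e - lag
        if s_a >= 0 and e_a <= n and (e - s) == d:  # complete beat
            seg = abp[s_a:e_a]
            beat_starts.append(s_a)
            beat_sbp.append(float(seg.max()))
            beat_dbp.append(float(seg.min()))
            beat_map.append(float(seg.mean()))

    # PPG: smoothed, delayed, unit-scaled copy of the pulse train; the
    # kernel width carries the peripheral-damping pressure cue
    klen = max(3, int(round(smooth_s * fs)) | 1)
    kernel = np.hanning(klen + 2)[1:-1]
    kernel /= kernel.sum()
    smoothed = np.convolve(train, kernel, mode="same")
    ppg = smoothed[:n].copy()
    lo, hi = ppg.min(), ppg.max()
    if hi > lo:
        ppg = (ppg - lo) / (hi - lo)

    if params.baseline_wander_amp > 0:
        f_w = rng.uniform(0.1, 0.4)  # below the 0.5 Hz band edge
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        ppg = ppg + params.baseline_wander_amp * np.sin(2 * np.pi * f_w * t + phase)

    if params.noise_sd > 0:
        ppg = ppg + params.noise_sd * rng.standard_normal(n)
        abp = abp + params.noise_sd * span * rng.standard_normal(n)

    # artifact injection: flat-lines / rail saturation of 0.5-2 s
    artifacts = []
    if params.artifact_rate > 0 and n >= 350:
        n_windows = (n - 350) // 250 + 1
        n_seg = int(round(params.artifact_rate * n_windows))
        for _ in range(n_seg):
            seg_len = int(round(rng.uniform(0.5, 2.0) * fs))
            start = int(rng.integers(0, max(1, n - seg_len)))
            kind = rng.choice(["abp-flat", "ppg-rail"])
            if kind == "abp-flat":
                abp[start:start + seg_len] = abp[start]
            else:
                ppg[start:start + seg_len] = float(ppg.max())
            artifacts.append({"kind": str(kind), "start": start,
                              "length": seg_len})

    truth = {
        "sbp_target": params.sbp_target,
        "dbp_target": params.dbp_target,
        "lag": lag,
        "beat_starts": beat_starts,
        "beat_sbp": beat_sbp,
        "beat_dbp": beat_dbp,
        "beat_map": beat_map,
        "artifacts": artifacts,
        "params": params,
    }
    return SignalRecord(subject_id=f"synth-{params.seed}", fs=fs,
                        ppg=ppg, abp=abp, truth=truth)


#: sampling boxes (sbp_lo, sbp_hi, dbp_lo, dbp_hi) guaranteeing the label
_RANGE_BOXES = {
    "normal": (95.0, 119.0, 60.0, 79.0),
    "pre-hypertension": (120.0, 139.0, 70.0, 89.0),
    "stage-1": (140.0, 159.0, 85.0, 99.0),
    "stage-2": (160.0, 190.0, 95.0, 115.0),
}


def sample_bp_targets(bp_range: str, rng: np.random.Generator):
    """Draw a uniform (SBP, DBP) pair that classifies back to ``bp_range``."""
    if bp_range not in _RANGE_BOXES:
        raise ParameterError(
            f"unknown bp_range {bp_range!r}; expected one of {BP_RANGES}")
    s_lo, s_hi, d_lo, d_hi = _RANGE_BOXES[bp_range]
    sbp = float(rng.uniform(s_lo, s_hi))
    dbp = float(rng.uniform(d_lo, d_hi))
    assert classify_bp_range(sbp, dbp) == bp_range
    return sbp, dbp


def simulate_cohort(n_subjects: int, duration_s: float = 120.0,
                    seed: int = 0, bp_ranges=BP_RANGES,
                    base_params: SimulationParams | None = None):
    """Simulate a cohort cycling through the BP ranges.

    Subject ``i`` draws its (SBP, DBP) targets from range
    ``bp_ranges[i % len(bp_ranges)]`` and a heart rate from U(55, 95) bpm;
    every other knob comes from ``base_params``.
    """
    if n_subjects <= 0:
        raise ParameterError("n_subjects must be positive")
    base = base_params or SimulationParams(duration_s=duration_s)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        label = bp_ranges[i % len(bp_ranges)]
        sbp, dbp = sample_bp_targets(label, rng)
        params = replace(
            base, duration_s=duration_s,
            heart_rate_bpm=float(rng.uniform(55, 95)),
            sbp_target=sbp, dbp_target=dbp,
            transit_lag_samples=int(rng.integers(5, 31)),
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        rec = simulate_record(params)
        rec.subject_id = f"subj-{i:03d}"
        rec.truth["bp_range"] = label
        records.append(rec)
    return records
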