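"""Per-window SBP/DBP/MAP extraction from ABP waveforms and BP-range labels.

SBP for a window is the mean of detected systolic peak amplitudes, DBP the
mean of detected diastolic valley amplitudes, and MAP the arithmetic mean of
all samples in the window. Windows in which no beat extrema are detected get
NaN SBP/DBP with a flag; MAP is always defined.

BP ranges follow the JNC7 classification on (SBP, DBP), most severe category
winning: stage-2 hypertension at SBP >= 160 or DBP >= 100, stage-1 at
SBP >= 140 or DBP >= 90, pre-hypertension at SBP >= 120 or DBP >= 80,
otherwise normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError

__all__ = ["BP_RANGES", "BPWindowEstimate", "detect_peaks_valleys",
           "window_bp", "classify_bp_range"]

#: Range labels ordered from least to most severe.
BP_RANGES = ("normal", "pre-hypertension", "stage-1", "stage-2")

#: (label, SBP threshold, DBP threshold) evaluated most-severe-first.
_THRESHOLDS = (("stage-2", 160.0, 100.0),
               ("stage-1", 140.0, 90.0),
               ("pre-hypertension", 120.0, 80.0))


@dataclass(frozen=True)
class BPWindowEstimate:
    sbp: float          # mmHg; NaN when no peaks found
    dbp: float          # mmHg; NaN when no valleys found
    map: float          # mmHg; arithmetic mean of the window
    n_peaks: int
    n_valleys: int
    window_id: str = ""

    @property
    def has_beats(self) -> bool:
        return self.n_peaks > 0 and self.n_valleys > 0


def _light_smooth(x: np.ndarray, fs: float) -> np.ndarray:
    """Short Hann smoothing with edge padding (no boundary taper)."""
    klen = max(3, int(round(0.03 * fs)) | 1)
    kernel = np.hanning(klen + 2)[1:-1]
    kernel /= kernel.sum()
    xp = np.pad(x, klen // 2, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_peaks_valleys(abp_w, fs: float = 125.0,
                         min_separation_s: float = 0.27,
                         prominence_frac: float = 0.25):
    """Locate systolic peaks and diastolic valleys in one ABP window.

    Extrema must be separated by at least ``min_separation_s`` (default caps
    detectable heart rate near 220 bpm) and exceed a prominence of
    ``prominence_frac`` times the window's peak-to-peak amplitude, which
    suppresses dicrotic bumps. Detection runs on a lightly smoothed copy
    (edge-padded 5-tap Hann, ~0.03 s) so single noise samples can neither
    create spurious extrema nor drag the detected amplitude to a noise
    excursion; amplitudes should be read at the returned indices of the
    smoothed window, exposed as the third return value. A constant window
    yields empty results.

    Returns ``(peak_indices, valley_indices, smoothed_window)``.
    """
    x = np.asarray(abp_w, dtype=np.float64)
    ptp = float(np.ptp(x))
    if ptp == 0.0 or not np.isfinite(ptp):
        empty = np.array([], dtype=int)
        return empty, empty, x
    xs = _light_smooth(x, fs)
    distance = max(1, int(round(min_separation_s * fs)))
    prominence = prominence_frac * float(np.ptp(xs))
    peaks, _ = find_peaks(xs, distance=distance, prominence=prominence)
    valleys, _ = find_peaks(-xs, distance=distance, prominence=prominence)
    return peaks, valleys, xs


def window_bp(abp_w, fs: float = 125.0, min_separation_s: float = 0.27,
              prominence_frac: float = 0.25,
              window_id: str = "") -> BPWindowEstimate:
    """Summarize one ABP window into SBP/DBP/MAP."""
    x = np.asarray(abp_w, dtype=np.float64)
    if x.size == 0:
        raise ParameterError("empty window")
    peaks, valleys, xs = detect_peaks_valleys(
        x, fs=fs, min_separation_s=min_separation_s,
        prominence_frac=prominence_frac)
    sbp = float(np.mean(xs[peaks])) if peaks.size else math.nan
    dbp = float(np.mean(xs[valleys])) if valleys.size else math.nan
    return BPWindowEstimate(sbp=sbp, dbp=dbp, map=float(np.mean(x)),
                            n_peaks=int(peaks.size),
                            n_valleys=int(valleys.size),
                            window_id=window_id)


def classify_bp_range(sbp: float, dbp: float) -> str:
    """JNC7 label for an (SBP, DBP) pair; the most severe trigger wins."""
    if not (np.isfinite(sbp) and np.isfinite(dbp)):
        raise ParameterError("sbp and dbp must be finite")
    if sbp <= dbp:
        raise ParameterError(f"sbp ({sbp}) must exceed dbp ({dbp})")
    for label, sbp_thr, dbp_thr in _THRESHOLDS:
        if sbp >= sbp_thr or dbp >= dbp_thr:
            return label
    return "normal"
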