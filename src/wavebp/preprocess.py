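"""Preprocessing: band-pass filtering, windowing, artifact screening,
cross-correlation phase matching, trimming, and min-max normalization.

The PPG channel is band-passed to 0.5-8 Hz with a linear-phase equiripple
(Parks-McClellan) FIR filter applied forward-backward, so filtering is
zero-phase and introduces no delay; the ABP channel is left untouched.
Records are cut into 350-sample windows with 100-sample overlap, screened
for artifacts, phase-matched per window by the location of the
cross-correlation maximum, and trimmed to 256 samples. Windows whose aligned
overlap is shorter than 256 samples are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (DegenerateWindowError, FilterDesignError, ParameterError,
                     TooShortError)
from .records import SignalRecord

__all__ = [
    "FilterSpec", "RawWindowPair", "WindowPair", "NormalizationParams",
    "ArtifactRules", "design_bandpass", "filter_ppg", "extract_windows",
    "screen_artifacts", "estimate_lag", "align_and_trim",
    "fit_normalization", "normalize", "denormalize", "preprocess_records",
]


@dataclass(frozen=True)
class FilterSpec:
    """Equiripple band-pass design parameters.

    The passband edges are the stated 0.5-8 Hz; the transition bands
    (0.2 -> 0.5 Hz and 8 -> 8.5 Hz) and ripple targets are design choices
    that realize those cutoffs at fs = 125 Hz while keeping the remez
    exchange well-conditioned (a much wider upper transition leaves that
    region unconstrained and produces anomalous response spikes).
    ``n_taps`` defaults to the Bellanger order estimate for the narrower
    transition band, rounded up to odd so the impulse response is symmetric
    about its midpoint (exact linear phase).
    """

    fs: float = 125.0
    pass_lo: float = 0.5
    pass_hi: float = 8.0
    transition_lo: float = 0.3   # width of the lower transition band (Hz)
    transition_hi: float = 0.5   # width of the upper transition band (Hz)
    ripple_pass: float = 0.02    # linear passband deviation per pass
    ripple_stop: float = 0.02    # linear stopband deviation per pass
    n_taps: int | None = None

    def validate(self) -> None:
        if not 0 < self.pass_lo < self.pass_hi < self.fs / 2:
            raise ParameterError(
                "requires 0 < pass_lo < pass_hi < fs/2, got "
                f"{self.pass_lo}/{self.pass_hi} at fs={self.fs}")
        if self.pass_lo - self.transition_lo <= 0:
            raise ParameterError("lower transition band extends below 0 Hz")
        if self.pass_hi + self.transition_hi >= self.fs / 2:
            raise ParameterError("upper transition band reaches Nyquist")
        if self.n_taps is not None and self.n_taps % 2 == 0:
            raise ParameterError("n_taps must be odd for exact linear phase")

    @property
    def taps(self) -> int:
        if self.n_taps is not None:
            return self.n_taps
        # Bellanger estimate for the narrower transition band
        width = min(self.transition_lo, self.transition_hi)
        n = (2.0 / 3.0) * np.log10(
            1.0 / (10.0 * self.ripple_pass * self.ripple_stop)) * self.fs / width
        n = int(np.ceil(n))
        return n if n % 2 else n + 1


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Parks-McClellan linear-phase FIR band-pass coefficients."""
    spec.validate()
    n = spec.taps
    bands = [0.0, spec.pass_lo - spec.transition_lo, spec.pass_lo,
             spec.pass_hi, spec.pass_hi + spec.transition_hi, spec.fs / 2]
    weight = [spec.ripple_pass / spec.ripple_stop, 1.0,
              spec.ripple_pass / spec.ripple_stop]
    try:
        taps = sps.remez(n, bands, [0.0, 1.0, 0.0], weight=weight,
                         fs=spec.fs, maxiter=250)
    except Exception as exc:  # remez convergence failure
        raise FilterDesignError(f"equiripple design failed: {exc}") from exc
    # verify the achieved response at band probes
    w, h = sps.freqz(taps, worN=16384, fs=spec.fs)
    mag = np.abs(h)
    # guard against transition-band anomalies (huge unconstrained spikes
    # that appear when a transition band is much wider than the design
    # order requires)
    if mag.max() > 1.0 + 2.5 * spec.ripple_pass:
        raise FilterDesignError(
            f"response peaks at {mag.max():.2f} (transition-band anomaly); "
            "narrow the transition bands or change n_taps")
    stop = mag[(w <= spec.pass_lo - spec.transition_lo) |
               (w >= spec.pass_hi + spec.transition_hi)]
    pb = mag[(w >= spec.pass_lo * 1.2) & (w <= spec.pass_hi * 0.9)]
    if stop.size and stop.max() > 2.5 * spec.ripple_stop:
        raise FilterDesignError(
            f"achieved stopband ripple {stop.max():.4f} exceeds "
            f"{2.5 * spec.ripple_stop:.4f}; increase n_taps")
    if pb.size and (np.abs(pb - 1.0)).max() > 2.5 * spec.ripple_pass:
        raise FilterDesignError(
            f"achieved passband ripple {np.abs(pb - 1.0).max():.4f} "
            f"exceeds {2.5 * spec.ripple_pass:.4f}; increase n_taps")
    return taps


def filter_ppg(record: SignalRecord, spec: FilterSpec | None = None,
               taps: np.ndarray | None = None) -> SignalRecord:
    """Zero-phase band-pass of the PPG channel; ABP is returned untouched."""
    spec = spec or FilterSpec()
    if record.fs != spec.fs:
        raise ParameterError(
            f"record fs {record.fs} != filter fs {spec.fs}")
    if taps is None:
        taps = design_bandpass(spec)
    if len(record) < 3 * len(taps):
        raise TooShortError(
            f"record of {len(record)} samples is shorter than 3x filter "
            f"length ({3 * len(taps)})")
    out = record.copy()
    out.ppg = sps.filtfilt(taps, [1.0], record.ppg)
    return out


@dataclass
class RawWindowPair:
    """One 350-sample window pair cut from a record, pre-alignment."""
    ppg_w: np.ndarray
    abp_w: np.ndarray
    subject_id: str
    start_index: int

    def __post_init__(self):
        if len(self.ppg_w) != len(self.abp_w):
            raise ParameterError("ppg_w and abp_w must have equal length")


@dataclass
class WindowPair:
    """One aligned, trimmed 256-sample training example."""
    ppg_w: np.ndarray
    abp_w: np.ndarray
    lag: int
    subject_id: str
    start_index: int


@dataclass(frozen=True)
class NormalizationParams:
    """Global min/max used by the affine normalization and its inverse."""
    ppg_min: float
    ppg_max: float
    abp_min: float
    abp_max: float

    def validate(self) -> None:
        if not (self.ppg_min < self.ppg_max and self.abp_min < self.abp_max):
            raise DegenerateWindowError("min must be < max for each modality")

    def to_dict(self) -> dict:
        return {"ppg_min": self.ppg_min, "ppg_max": self.ppg_max,
                "abp_min": self.abp_min, "abp_max": self.abp_max}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(**d)


def extract_windows(record: SignalRecord, win_len: int = 350,
                    overlap: int = 100) -> list[RawWindowPair]:
    """Sequential windows of ``win_len`` samples overlapping by ``overlap``."""
    if not win_len > overlap >= 0:
        raise ParameterError(
            f"requires win_len > overlap >= 0, got {win_len}/{overlap}")
    stride = win_len - overlap
    out = []
    for start in range(0, len(record) - win_len + 1, stride):
        out.append(RawWindowPair(
            ppg_w=record.ppg[start:start + win_len].copy(),
            abp_w=record.abp[start:start + win_len].copy(),
            subject_id=record.subject_id, start_index=start))
    return out


@dataclass(frozen=True)
class ArtifactRules:
    """Rule-based artifact screen.

    A pluggable stand-in for a learned artifact detector: any callable taking
    a :class:`RawWindowPair` and returning ``(accept, reason)`` can replace
    it wherever a detector is expected.
    """

    fs: float = 125.0
    flatline_s: float = 0.5      # max tolerated constant run, either channel
    rail_s: float = 0.25         # max tolerated PPG rail (min==max) run
    abp_lo: float = 20.0         # physiological ABP floor, mmHg
    abp_hi: float = 300.0        # physiological ABP ceiling, mmHg

    def __call__(self, pair: RawWindowPair):
        return screen_artifacts(pair, self)


def _longest_constant_run(x: np.ndarray) -> int:
    """Length (in samples) of the longest run of identical adjacent values."""
    if len(x) == 0:
        return 0
    same = np.diff(x) == 0
    if not same.any():
        return 1
    # runs of True in `same`; run of k Trues = k+1 equal samples
    padded = np.concatenate(([False], same, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return int((edges[1::2] - edges[::2]).max()) + 1


def screen_artifacts(pair: RawWindowPair, rules: ArtifactRules | None = None):
    """Accept/reject one window pair; returns ``(accept, reason)``."""
    rules = rules or ArtifactRules()
    if not (np.isfinite(pair.ppg_w).all() and np.isfinite(pair.abp_w).all()):
        return False, "non-finite"
    if pair.abp_w.min() < rules.abp_lo or pair.abp_w.max() > rules.abp_hi:
        return False, "range"
    flat_limit = rules.flatline_s * rules.fs
    if (_longest_constant_run(pair.abp_w) > flat_limit
            or _longest_constant_run(pair.ppg_w) > flat_limit):
        return False, "flat-line"
    if _longest_constant_run(pair.ppg_w) > rules.rail_s * rules.fs:
        return False, "rail"
    return True, "ok"


def estimate_lag(ppg_w, abp_w, max_lag: int = 125) -> int:
    """Lag (samples) by which ABP must be shifted forward to align with PPG.

    Cross-correlates the mean-removed, unit-scaled windows over lags in
    ``[-max_lag, +max_lag]`` and returns the location of the correlation
    maximum. The correlation at each lag is normalized over the overlap
    region (a per-lag Pearson coefficient): the raw running sum shrinks with
    the overlap length, which for smooth, oversampled pulse waveforms biases
    the plain argmax toward zero lag by one or two samples. Exact ties break
    toward the smallest ``|lag|``.
    """
    ppg_w = np.asarray(ppg_w, dtype=np.float64)
    abp_w = np.asarray(abp_w, dtype=np.float64)
    n = len(ppg_w)
    if n != len(abp_w):
        raise ParameterError("windows must have equal length")
    if not max_lag < n / 2:
        raise ParameterError("max_lag must be < window length / 2")
    if ppg_w.std() == 0 or abp_w.std() == 0:
        raise DegenerateWindowError("zero-variance window")
    best_r = -np.inf
    best_lag = 0
    # candidate order guarantees ties resolve toward the smallest |lag|
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        # ABP shifted forward by `lag`: compare ppg[t] with abp[t - lag]
        if lag >= 0:
            p, a = ppg_w[lag:], abp_w[:n - lag]
        else:
            p, a = ppg_w[:n + lag], abp_w[-lag:]
        pc = p - p.mean()
        ac = a - a.mean()
        denom = np.sqrt(np.dot(pc, pc) * np.dot(ac, ac))
        if denom == 0:
            continue
        r = np.dot(pc, ac) / denom
        if r > best_r:
            best_r = r
            best_lag = lag
    return int(best_lag)


def align_and_trim(pair: RawWindowPair, lag: int,
                   out_len: int = 256) -> WindowPair | None:
    """Shift ABP against the fixed PPG by ``lag`` and trim to ``out_len``.

    The jointly valid overlap after shifting has ``len - |lag|`` samples;
    both channels keep the first ``out_len`` samples of it. Pairs whose
    overlap is shorter than ``out_len`` are rejected (returns ``None``).
    """
    n = len(pair.ppg_w)
    if abs(lag) >= n:
        return None
    if lag >= 0:
        ppg_seg = pair.ppg_w[lag:]
        abp_seg = pair.abp_w[:n - lag]
    else:
        ppg_seg = pair.ppg_w[:n + lag]
        abp_seg = pair.abp_w[-lag:]
    if len(ppg_seg) < out_len:
        return None
    return WindowPair(ppg_w=ppg_seg[:out_len].copy(),
                      abp_w=abp_seg[:out_len].copy(),
                      lag=int(lag), subject_id=pair.subject_id,
                      start_index=pair.start_index)


def fit_normalization(pairs) -> NormalizationParams:
    """Min/max per modality over all samples of the supplied windows.

    Fit on the training split only and reuse the frozen values everywhere:
    the ABP min/max double as the de-normalization factors for predictions.
    """
    pairs = list(pairs)
    if not pairs:
        raise ParameterError("cannot fit normalization on an empty list")
    ppg_all = np.concatenate([p.ppg_w for p in pairs])
    abp_all = np.concatenate([p.abp_w for p in pairs])
    params = NormalizationParams(
        ppg_min=float(ppg_all.min()), ppg_max=float(ppg_all.max()),
        abp_min=float(abp_all.min()), abp_max=float(abp_all.max()))
    params.validate()
    return params


def normalize(x, lo: float, hi: float):
    """Affine map sending ``lo -> 0`` and ``hi -> 1`` (no clipping)."""
    if not lo < hi:
        raise ParameterError(f"requires lo < hi, got {lo}/{hi}")
    return (np.asarray(x, dtype=np.float64) - lo) / (hi - lo)


def denormalize(y, lo: float, hi: float):
    """Exact inverse of :func:`normalize`."""
    if not lo < hi:
        raise ParameterError(f"requires lo < hi, got {lo}/{hi}")
    return np.asarray(y, dtype=np.float64) * (hi - lo) + lo


def preprocess_records(records, filter_spec: FilterSpec | None = None,
                       rules: ArtifactRules | None = None,
                       win_len: int = 350, overlap: int = 100,
                       out_len: int = 256, max_lag: int = 125,
                       detector=None):
    """Full per-record preprocessing chain with window bookkeeping.

    Returns ``(pairs, counts)`` where counts has keys ``extracted``,
    ``rejected_artifact``, ``rejected_length``, ``rejected_degenerate`` and
    ``kept``; kept + rejected always equals extracted.
    """
    filter_spec = filter_spec or FilterSpec()
    detector = detector or rules or ArtifactRules(fs=filter_spec.fs)
    taps = design_bandpass(filter_spec)
    counts = {"extracted": 0, "rejected_artifact": 0, "rejected_length": 0,
              "rejected_degenerate": 0, "kept": 0}
    pairs: list[WindowPair] = []
    for rec in records:
        filtered = filter_ppg(rec, filter_spec, taps=taps)
        for raw in extract_windows(filtered, win_len=win_len, overlap=overlap):
            counts["extracted"] += 1
            ok, _reason = detector(raw)
            if not ok:
                counts["rejected_artifact"] += 1
                continue
            try:
                lag = estimate_lag(raw.ppg_w, raw.abp_w, max_lag=max_lag)
            except DegenerateWindowError:
                counts["rejected_degenerate"] += 1
                continue
            pair = align_and_trim(raw, lag, out_len=out_len)
            if pair is None:
                counts["rejected_length"] += 1
                continue
            counts["kept"] += 1
            pairs.append(pair)
    return pairs, counts
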