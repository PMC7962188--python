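"""Shared container for one subject's synchronized PPG/ABP recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass
class SignalRecord:
    """Paired fingertip PPG (arbitrary units) and ABP (mmHg) time series.

    ``truth`` is populated only for synthetic records and carries the
    ground-truth targets used by round-trip tests: per-beat SBP/DBP/MAP,
    the true ABP->PPG transit lag, and injected artifact segments.
    """

    subject_id: str
    fs: float
    ppg: np.ndarray
    abp: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        self.abp = np.asarray(self.abp, dtype=np.float64)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.ppg.ndim != 1 or self.abp.ndim != 1:
            raise ParameterError("ppg and abp must be 1-D")
        if len(self.ppg) != len(self.abp):
            raise ParameterError(
                f"ppg ({len(self.ppg)}) and abp ({len(self.abp)}) "
                "must have equal length")

    def __len__(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs

    def copy(self) -> "SignalRecord":
        return SignalRecord(self.subject_id, self.fs, self.ppg.copy(),
                            self.abp.copy(),
                            None if self.truth is None else dict(self.truth))
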