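"""Agreement statistics for predicted vs reference blood pressure.

Covers waveform correlation (Fisher-Z averaged Pearson r with percentiles),
per-measurand error metrics (MAE/STD/RMSE/r), BHS cumulative-error grading,
the AAMI mean/SD bound, Bland-Altman agreement pairs, per-range accuracy and
range-confusion matrices, and error histograms.

Two deliberately distinct "STD"s exist in this field's result tables: the
standard deviation of ABSOLUTE errors (the value quoted next to MAE, e.g.
"3.68 +/- 4.42 mmHg") and the standard deviation of SIGNED errors demanded
by the AAMI bound. :func:`error_stats` reports the former;
:func:`aami_check` computes the latter by default and can be switched to
absolute errors for side-by-side comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bp_extract import BP_RANGES, classify_bp_range
from .errors import ParameterError

__all__ = ["ErrorStats", "CorrelationSummary", "BHSResult", "AAMIResult",
           "error_stats", "average_correlation", "bhs_grade", "aami_check",
           "bland_altman", "per_range_accuracy", "error_histogram"]


@dataclass(frozen=True)
class ErrorStats:
    mae: float    # mean absolute error, mmHg
    std: float    # standard deviation of absolute errors, mmHg
    rmse: float   # root mean squared error, mmHg
    r: float      # Pearson correlation (NaN if either vector is constant)
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "std": self.std, "rmse": self.rmse,
                "r": self.r, "n": self.n}


@dataclass(frozen=True)
class CorrelationSummary:
    avg_r: float   # Fisher-Z averaged
    min_r: float
    max_r: float
    p25_r: float
    p75_r: float
    n: int
    clipped: int = 0  # inputs at |r| == 1 clipped before atanh

    def to_dict(self) -> dict:
        return {"avg_r": self.avg_r, "min_r": self.min_r, "max_r": self.max_r,
                "p25_r": self.p25_r, "p75_r": self.p75_r, "n": self.n,
                "clipped": self.clipped}


@dataclass(frozen=True)
class BHSResult:
    cum5: float    # % of absolute errors <= 5 mmHg
    cum10: float   # <= 10 mmHg
    cum15: float   # <= 15 mmHg
    grade: str     # A, B, C or D

    def to_dict(self) -> dict:
        return {"cum5": self.cum5, "cum10": self.cum10, "cum15": self.cum15,
                "grade": self.grade}


#: BHS grading grid: grade -> required cumulative % at (<=5, <=10, <=15) mmHg
BHS_GRID = {"A": (60.0, 85.0, 95.0),
            "B": (50.0, 75.0, 90.0),
            "C": (40.0, 65.0, 85.0)}

#: AAMI bounds: |mean error| <= 5 mmHg and error SD <= 8 mmHg, > 85 subjects
AAMI_MEAN_MMHG = 5.0
AAMI_STD_MMHG = 8.0
AAMI_MIN_SUBJECTS = 85


@dataclass(frozen=True)
class AAMIResult:
    mean_stat: float   # mean error (signed by default), mmHg
    std_stat: float    # SD of errors, mmHg
    n_subjects: int
    passed: bool       # both mmHg bounds hold
    enough_subjects: bool
    statistic: str = "signed"

    def to_dict(self) -> dict:
        return {"mean_stat": self.mean_stat, "std_stat": self.std_stat,
                "n_subjects": self.n_subjects, "passed": self.passed,
                "enough_subjects": self.enough_subjects,
                "statistic": self.statistic}


def _paired(pred, ref):
    pred = np.asarray(pred, dtype=np.float64).ravel()
    ref = np.asarray(ref, dtype=np.float64).ravel()
    if pred.size == 0 or pred.size != ref.size:
        raise ParameterError("pred and ref must be equal-length and nonempty")
    return pred, ref


def error_stats(pred, ref) -> ErrorStats:
    """MAE, SD of absolute errors, RMSE and Pearson r for paired values."""
    pred, ref = _paired(pred, ref)
    abs_err = np.abs(pred - ref)
    if pred.size > 1 and pred.std() > 0 and ref.std() > 0:
        pc = pred - pred.mean()
        rc = ref - ref.mean()
        r = float(np.dot(pc, rc)
                  / np.sqrt(np.dot(pc, pc) * np.dot(rc, rc)))
    else:
        r = math.nan  # undefined for constant input
    return ErrorStats(
        mae=float(abs_err.mean()),
        std=float(abs_err.std(ddof=1)) if abs_err.size > 1 else 0.0,
        rmse=float(np.sqrt(np.mean((pred - ref) ** 2))),
        r=r, n=int(pred.size))


def average_correlation(r_values) -> CorrelationSummary:
    """Fisher-Z averaged correlation with raw-value percentiles.

    Averaging goes through atanh (variance-stabilizing for correlation
    coefficients), the mean is mapped back with tanh; min/max and the
    25th/75th percentiles (linear interpolation) are computed on the raw
    values. Inputs at exactly +/-1 are clipped to 1 - 1e-12 and counted.
    """
    r = np.asarray(r_values, dtype=np.float64).ravel()
    if r.size == 0:
        raise ParameterError("need at least one correlation value")
    if np.abs(r).max() > 1:
        raise ParameterError("correlation values must lie in [-1, 1]")
    clip = 1.0 - 1e-12
    clipped = int(np.sum(np.abs(r) >= 1.0))
    rz = np.clip(r, -clip, clip)
    avg = float(np.tanh(np.mean(np.arctanh(rz))))
    return CorrelationSummary(
        avg_r=avg, min_r=float(r.min()), max_r=float(r.max()),
        p25_r=float(np.percentile(r, 25)), p75_r=float(np.percentile(r, 75)),
        n=int(r.size), clipped=clipped)


def bhs_grade(abs_errors) -> BHSResult:
    """Cumulative percentages within 5/10/15 mmHg and the BHS letter grade."""
    err = np.asarray(abs_errors, dtype=np.float64).ravel()
    if err.size == 0:
        raise ParameterError("need at least one error value")
    if (err < 0).any():
        raise ParameterError("absolute errors must be non-negative")
    cums = tuple(100.0 * float(np.mean(err <= thr)) for thr in (5, 10, 15))
    grade = "D"
    for g in ("C", "B", "A"):  # best grade whose whole row is met
        if all(c >= need for c, need in zip(cums, BHS_GRID[g])):
            grade = g
    return BHSResult(cum5=cums[0], cum10=cums[1], cum15=cums[2], grade=grade)


def aami_check(pred_bp, ref_bp, n_subjects: int,
               statistic: str = "signed") -> AAMIResult:
    """Check the AAMI bound: |mean error| <= 5 and SD <= 8 mmHg.

    ``statistic='signed'`` uses pred - ref differences (the standard's mean
    difference); ``'absolute'`` uses |pred - ref| for comparison with tables
    that list MAE against the same bound.
    """
    pred, ref = _paired(pred_bp, ref_bp)
    if statistic == "signed":
        err = pred - ref
    elif statistic == "absolute":
        err = np.abs(pred - ref)
    else:
        raise ParameterError("statistic must be 'signed' or 'absolute'")
    mean_stat = float(err.mean())
    std_stat = float(err.std(ddof=1)) if err.size > 1 else 0.0
    return AAMIResult(
        mean_stat=mean_stat, std_stat=std_stat, n_subjects=int(n_subjects),
        passed=bool(abs(mean_stat) <= AAMI_MEAN_MMHG
                    and std_stat <= AAMI_STD_MMHG),
        enough_subjects=bool(n_subjects > AAMI_MIN_SUBJECTS),
        statistic=statistic)


def bland_altman(pred, ref, clip: float = 30.0):
    """Bland-Altman pairs plus bias and 1.96-SD limits of agreement.

    Returns ``(points, bias, (loa_lo, loa_hi))`` where each point is
    ``((pred+ref)/2, clip(pred-ref))``; differences beyond ``+/-clip`` mmHg
    are plotted at the clip value, while bias and the limits of agreement
    use the unclipped differences.
    """
    pred, ref = _paired(pred, ref)
    diff = pred - ref
    mean = (pred + ref) / 2.0
    points = np.column_stack([mean, np.clip(diff, -clip, clip)])
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return points, bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def per_range_accuracy(estimates, within_mmhg: float = 10.0):
    """Per-BP-range agreement, grouped by the REFERENCE range label.

    ``estimates`` is a sequence of ``(ref, pred)`` pairs of
    :class:`~wavebp.bp_extract.BPWindowEstimate`. For each range and for
    each of SBP/DBP, reports the fraction of windows whose absolute error is
    within ``within_mmhg`` (NaN for empty groups), and a range-confusion
    matrix of reference vs predicted labels. Both views are emitted because
    a single "prediction rate" conflates them.
    """
    estimates = list(estimates)
    if not estimates:
        raise ParameterError("need at least one estimate pair")
    frac = {rng: {} for rng in BP_RANGES}
    confusion = np.zeros((len(BP_RANGES), len(BP_RANGES)), dtype=int)
    groups = {rng: [] for rng in BP_RANGES}
    for ref, pred in estimates:
        if not (ref.has_beats and pred.has_beats):
            continue
        label_ref = classify_bp_range(ref.sbp, ref.dbp)
        label_pred = classify_bp_range(pred.sbp, pred.dbp)
        groups[label_ref].append((ref, pred))
        confusion[BP_RANGES.index(label_ref), BP_RANGES.index(label_pred)] += 1
    for rng, members in groups.items():
        for key in ("sbp", "dbp"):
            if members:
                errs = [abs(getattr(p, key) - getattr(r, key))
                        for r, p in members]
                frac[rng][key] = float(np.mean(np.asarray(errs) <= within_mmhg))
            else:
                frac[rng][key] = math.nan
        frac[rng]["n"] = len(members)
    return {"within_fraction": frac, "confusion": confusion,
            "labels": BP_RANGES}


def error_histogram(errors, bin_width: float = 1.0):
    """Equal-width histogram with bins centered on zero; counts sum to n."""
    err = np.asarray(errors, dtype=np.float64).ravel()
    if err.size == 0:
        raise ParameterError("need at least one error value")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    half = bin_width / 2.0
    # bins centered at integer multiples of bin_width, covering the data
    k = int(np.ceil(max((np.abs(err).max() - half) / bin_width, 0.0)))
    edges = np.arange(-(k + 0.5), k + 0.5 + 1, 1.0) * bin_width
    counts, edges = np.histogram(err, bins=edges)
    return edges, counts
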