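"""Readers and writers for records, window datasets, and reports.

Canonical interchange formats are deliberately inspectable: CSV with columns
``t_s, ppg, abp`` for records, a compressed ``.npz`` container with a JSON
sidecar for window datasets, and JSON for evaluation reports. WFDB records
(channels ``PLETH``/``ABP``) are read when the optional ``wfdb`` package is
installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .preprocess import NormalizationParams, WindowPair
from .records import SignalRecord

__all__ = ["read_record", "write_record", "save_windows", "load_windows",
           "save_json", "load_json"]

_PPG_NAMES = {"ppg", "pleth"}
_ABP_NAMES = {"abp", "art"}


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def load_json(path):
    return json.loads(Path(path).read_text())


def write_record(path, record: SignalRecord, fmt: str | None = None) -> None:
    """Write a record as CSV (``t_s, ppg, abp``) or an NPZ container.

    Both formats get a JSON sidecar (``<path>.json``) carrying subject id,
    sampling rate, and ground truth when present.
    """
    path = Path(path)
    fmt = fmt or ("npz" if path.suffix == ".npz" else "csv")
    if fmt == "csv":
        t = np.arange(len(record)) / record.fs
        pd.DataFrame({"t_s": t, "ppg": record.ppg, "abp": record.abp}).to_csv(
            path, index=False)
    elif fmt == "npz":
        np.savez_compressed(path, ppg=record.ppg, abp=record.abp,
                            fs=record.fs)
    else:
        raise ParameterError(f"unknown record format {fmt!r}")
    sidecar = {"subject_id": record.subject_id, "fs": record.fs}
    if record.truth is not None:
        sidecar["truth"] = _jsonable(record.truth)
    save_json(sidecar, path.with_suffix(path.suffix + ".json"))


def _find_column(columns, wanted: set, label: str):
    for c in columns:
        if c.strip().lower() in wanted:
            return c
    raise FormatError(
        f"no {label} channel among columns {list(columns)}; "
        f"expected one of {sorted(wanted)}")


def read_record(path, fmt: str | None = None,
                subject_id: str | None = None) -> SignalRecord:
    """Read a record from CSV, NPZ container, or WFDB.

    Channels are identified by name (``ppg``/``PLETH``, ``abp``/``ABP``,
    case-insensitive); unequal channel lengths are truncated to the common
    prefix. Sampling rate comes from the JSON sidecar, the NPZ/WFDB header,
    or the ``t_s`` column.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".npz": "npz"}.get(path.suffix, "wfdb")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = load_json(sidecar_path) if sidecar_path.exists() else {}
    truth = sidecar.get("truth")
    sid = subject_id or sidecar.get("subject_id") or path.stem

    if fmt == "csv":
        df = pd.read_csv(path)
        ppg_col = _find_column(df.columns, _PPG_NAMES, "ppg")
        abp_col = _find_column(df.columns, _ABP_NAMES, "abp")
        fs = sidecar.get("fs")
        if fs is None:
            if "t_s" not in df.columns:
                raise FormatError(
                    "cannot infer sampling rate: no t_s column or sidecar fs")
            dt = np.median(np.diff(df["t_s"].to_numpy()))
            fs = 1.0 / dt
        ppg = df[ppg_col].to_numpy(dtype=np.float64)
        abp = df[abp_col].to_numpy(dtype=np.float64)
    elif fmt == "npz":
        with np.load(path) as data:
            ppg = np.asarray(data["ppg"], dtype=np.float64)
            abp = np.asarray(data["abp"], dtype=np.float64)
            fs = float(data["fs"]) if "fs" in data else sidecar.get("fs")
        if fs is None:
            raise FormatError("npz container lacks fs and no sidecar found")
    elif fmt == "wfdb":
        try:
            import wfdb  # optional dependency
        except ImportError as exc:
            raise FormatError(
                "reading WFDB records requires the optional 'wfdb' package"
            ) from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))
        names = [n.strip().lower() for n in rec.sig_name]
        try:
            ppg_i = next(i for i, n in enumerate(names) if n in _PPG_NAMES)
            abp_i = next(i for i, n in enumerate(names) if n in _ABP_NAMES)
        except StopIteration:
            raise FormatError(
                f"WFDB record channels {rec.sig_name} lack PLETH/ABP") from None
        ppg = np.asarray(rec.p_signal[:, ppg_i], dtype=np.float64)
        abp = np.asarray(rec.p_signal[:, abp_i], dtype=np.float64)
        fs = float(rec.fs)
        sid = subject_id or rec.record_name
    else:
        raise ParameterError(f"unknown record format {fmt!r}")

    n = min(len(ppg), len(abp))
    if len(ppg) != len(abp):
        import warnings
        warnings.warn(f"channel lengths differ ({len(ppg)} vs {len(abp)}); "
                      f"truncating to {n}", stacklevel=2)
    return SignalRecord(subject_id=sid, fs=float(fs), ppg=ppg[:n], abp=abp[:n],
                        truth=truth)


def save_windows(path, pairs, norm: NormalizationParams | None = None,
                 meta: dict | None = None) -> None:
    """Write a window dataset as NPZ plus a JSON sidecar with metadata."""
    pairs = list(pairs)
    if not pairs:
        raise ParameterError("no windows to save")
    path = Path(path)
    np.savez_compressed(
        path,
        ppg=np.stack([p.ppg_w for p in pairs]),
        abp=np.stack([p.abp_w for p in pairs]),
        lag=np.array([p.lag for p in pairs], dtype=np.int64),
        start_index=np.array([p.start_index for p in pairs], dtype=np.int64),
        subject_id=np.array([p.subject_id for p in pairs]))
    sidecar = dict(meta or {})
    sidecar["n_windows"] = len(pairs)
    sidecar["window_len"] = int(pairs[0].ppg_w.shape[0])
    if norm is not None:
        sidecar["norm_params"] = norm.to_dict()
    save_json(sidecar, path.with_suffix(path.suffix + ".json"))


def load_windows(path):
    """Read a window dataset; returns ``(pairs, norm_params_or_None, meta)``."""
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        pairs = [WindowPair(ppg_w=data["ppg"][i], abp_w=data["abp"][i],
                            lag=int(data["lag"][i]),
                            subject_id=str(data["subject_id"][i]),
                            start_index=int(data["start_index"][i]))
                 for i in range(data["ppg"].shape[0])]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = load_json(sidecar_path) if sidecar_path.exists() else {}
    norm = (NormalizationParams.from_dict(meta["norm_params"])
            if "norm_params" in meta else None)
    return pairs, norm, meta
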