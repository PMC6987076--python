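"""Recording container, file formats, manifests and result tables.

EDF (European Data Format) is the canonical multichannel container —
recordings are read through MNE's EDF reader — and plain delimited
matrices (one channel per row) are supported for lightweight interchange;
delimited input carries no rate, so the sampling rate must be given
explicitly.  A minimal EDF writer (16-bit, one-second records) is included
so synthetic cohorts can be exported to the same format as real data; its
quantization (65535 steps over the per-channel amplitude range) bounds the
round-trip error.

Cohort membership is described by a manifest table (file, format, subject,
group, condition, sampling rate) rather than filename conventions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "patient", "unknown")
CONDITIONS = ("eyes_open", "eyes_closed", "unknown")


@dataclass
class Recording:
    """One multichannel recording plus subject metadata.

    ``data`` is a ``(n_channels, n_samples)`` float array; all channels
    share the sampling rate; channel labels are unique montage names.
    """

    data: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    subject_id: str = ""
    group: str = "unknown"
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r} in {self.channel_labels}") from None

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None) -> "Recording":
        """Copy with replaced samples (and optionally rate), keeping metadata."""
        return replace(
            self,
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
        )


# -- delimited matrices -------------------------------------------------------


def read_delimited(path: str | Path, sampling_rate: float | None = None, **metadata) -> Recording:
    """Read a channels-by-samples delimited matrix.

    Rows whose first field is non-numeric are taken as labelled channels;
    otherwise labels ``ch00, ch01, ...`` are generated.  ``sampling_rate``
    is mandatory — the format does not carry one.
    """
    if sampling_rate is None:
        raise ValueError("delimited input requires an explicit sampling_rate")
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse delimited matrix {path}: {exc}") from exc
    first = frame.iloc[:, 0]
    if first.dtype == object:
        labels = [str(v) for v in first]
        values = frame.iloc[:, 1:].to_numpy(dtype=float)
    else:
        labels = [f"ch{i:02d}" for i in range(len(frame))]
        values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite values in {path}")
    return Recording(
        data=values, channel_labels=labels, sampling_rate=float(sampling_rate), **metadata
    )


def write_delimited(recording: Recording, path: str | Path) -> Path:
    """Write a recording as a label-prefixed CSV matrix (one channel per row)."""
    path = Path(path)
    frame = pd.DataFrame(recording.data, index=recording.channel_labels)
    frame.to_csv(path, header=False, float_format="%.8g")
    return path


# -- EDF ----------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file with one-second data records.

    The sampling rate must be a whole number of samples per second and the
    signal is truncated to whole seconds (with a warning).  Per-channel
    physical ranges are integer microvolt bounds enclosing the data, so
    amplitude quantization is ``(max - min) / 65535`` per channel.
    """
    path = Path(path)
    rate = recording.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {rate}")
    spr = int(round(rate))
    n_records = recording.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_records * spr != recording.n_samples:
        warnings.warn(
            f"truncating {recording.n_samples - n_records * spr} trailing samples "
            "to whole EDF records",
            stacklevel=2,
        )
    ns = recording.n_channels
    data = recording.data[:, : n_records * spr]

    pmins = np.floor(data.min(axis=1)) - 1.0
    pmaxs = np.ceil(data.max(axis=1)) + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmaxs - pmins) / (dmax - dmin)
    digital = np.rint((data - pmins[:, None]) / scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(recording.subject_id or "X", 80),
            _edf_field(f"Startdate X {recording.group} {recording.condition}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(ns), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(str(int(p)), 8) for p in pmins),
            b"".join(_edf_field(str(int(p)), 8) for p in pmaxs),
            b"".join(_edf_field(str(dmin), 8) for _ in range(ns)),
            b"".join(_edf_field(str(dmax), 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec_i in range(n_records):
            block = digital[:, rec_i * spr : (rec_i + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path, **metadata) -> Recording:
    """Read an EDF file via MNE; amplitudes are returned in microvolts."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    labels = [lbl.strip() for lbl in raw.ch_names]
    return Recording(
        data=data,
        channel_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
        **metadata,
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    sampling_rate: float | None = None,
    **metadata,
) -> Recording:
    """Read a recording, dispatching on ``format`` (or the file suffix)."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        return read_edf(path, **metadata)
    if fmt in ("delimited", "delimited_matrix", "csv"):
        return read_delimited(path, sampling_rate=sampling_rate, **metadata)
    raise ValueError(f"unknown recording format {fmt!r}")


# -- manifests ----------------------------------------------------------------

MANIFEST_COLUMNS = ["file", "format", "subject", "group", "condition", "sampling_rate"]


def write_manifest(rows: Iterable[dict], path: str | Path) -> Path:
    frame = pd.DataFrame(list(rows))
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest rows missing columns: {missing}")
    frame[MANIFEST_COLUMNS].to_csv(path, index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("file", "subject", "group", "condition") if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    return frame


def load_cohort(manifest_path: str | Path, min_duration: float = 0.0) -> list[Recording]:
    """Load every recording listed in a manifest.

    Paths are resolved relative to the manifest's directory.  Recordings
    shorter than ``min_duration`` seconds are excluded with a warning.
    """
    manifest_path = Path(manifest_path)
    frame = read_manifest(manifest_path)
    base = manifest_path.parent
    recordings = []
    for row in frame.itertuples(index=False):
        p = Path(row.file)
        if not p.is_absolute():
            p = base / p
        rate = getattr(row, "sampling_rate", None)
        rec = read_recording(
            p,
            format=getattr(row, "format", None),
            sampling_rate=None if rate is None or pd.isna(rate) else float(rate),
            subject_id=str(row.subject),
            group=str(row.group),
            condition=str(row.condition),
        )
        if rec.duration < min_duration:
            logger.warning(
                "excluding %s: %.1f s shorter than the %.1f s minimum",
                p.name, rec.duration, min_duration,
            )
            continue
        recordings.append(rec)
    if not recordings:
        raise ValueError(f"manifest {manifest_path} yielded no usable recordings")
    return recordings


# -- result tables and run summaries -----------------------------------------


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def write_run_summary(config, path: str | Path, extra: dict | None = None) -> Path:
    """Persist the full run configuration (and optional extras) as JSON."""
    payload = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    if extra:
        payload = {**payload, **extra}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
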