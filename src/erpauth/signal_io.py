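"""Readers and writers for EEG recordings, event tables and feature matrices.

Recordings are held as a channels x samples matrix in microvolts together
with the sampling rate and the ordered channel names; channel order is
preserved end-to-end and all downstream channel indices refer to it.
EDF (16-bit European Data Format) input goes through :mod:`mne`; delimited
text (CSV with a channel-name header, one column per channel) is supported
for small fixtures and simulator output. Event tables and feature matrices
are plain CSV and round-trip losslessly (full float precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The five acquisition paradigms of the study dataset.
TASK_IDS = (
    "P300-Selected",
    "P300-Assigned",
    "N400-Words",
    "N400-Sentences",
    "N400-Faces",
)

STIMULUS_CLASSES = ("target", "nontarget", "word", "face", "other")

EVENT_COLUMNS = ("onset_sample", "subject_id", "task_id", "stimulus_class")


@dataclass
class Recording:
    """A continuous multi-channel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per row of ``data``, in order.
    reference : {"raw", "average"}
        Referencing state; ``average_reference`` sets it to ``"average"``.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x samples)")
        n_ch, n_s = self.data.shape
        if n_ch < 1 or n_s < 1:
            raise ValueError("Recording needs at least one channel and one sample")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if self.reference not in ("raw", "average"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names))


@dataclass
class EventTable:
    """Stimulus events: onset sample index plus subject/task/class labels.

    Onsets are 0-based sample indices into the recording (not seconds), so
    epoch alignment is exact. Rows are kept sorted by onset.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=list(EVENT_COLUMNS)))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        df = df.loc[:, list(EVENT_COLUMNS)].copy()
        df["onset_sample"] = df["onset_sample"].astype(np.int64)
        df["subject_id"] = df["subject_id"].astype(str)
        if (df["onset_sample"] < 0).any():
            raise ValueError("onset_sample must be >= 0")
        if (df["subject_id"].str.len() == 0).any():
            raise ValueError("subject_id must be non-empty")
        bad_task = set(df["task_id"]) - set(TASK_IDS)
        if bad_task:
            raise ValueError(f"unknown task_id values {sorted(bad_task)}")
        bad_cls = set(df["stimulus_class"]) - set(STIMULUS_CLASSES)
        if bad_cls:
            raise ValueError(f"unknown stimulus_class values {sorted(bad_cls)}")
        df = df.sort_values("onset_sample", kind="stable").reset_index(drop=True)
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset_sample"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()


def read_recording(path: str | Path, format: str | None = None,
                   sfreq: float | None = None,
                   unit_scale: float = 1.0) -> Recording:
    """Read an EEG recording from EDF or delimited text.

    ``format`` is inferred from the suffix when omitted. For delimited input
    the first row must hold the channel names (one column per channel) and
    ``sfreq`` is required; for EDF the rate comes from the header and the
    physical unit is assumed to be microvolts (``unit_scale`` multiplies the
    data if the file is in other units, e.g. 1e6 for volts-labelled files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path, unit_scale)
    if format == "delimited":
        if sfreq is None:
            raise ValueError("sampling rate required for delimited recordings")
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 1 or df.shape[0] < 1:
            raise ValueError("empty delimited recording")
        data = df.to_numpy(dtype=float).T * unit_scale
        return Recording(data=data, sfreq=float(sfreq),
                         channel_names=[str(c) for c in df.columns])
    raise ValueError(f"unknown recording format {format!r}")


def _read_edf(path: Path, unit_scale: float) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne returns SI volts for uV-dimensioned channels; Recording is in uV
    data = raw.get_data() * 1e6 * unit_scale
    return Recording(data=data, sfreq=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names))


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as delimited text (samples as rows, header row of
    channel names). The sampling rate is not stored; pass it at read time."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> EventTable:
    """Read and validate an event table CSV (header ``onset_sample,
    subject_id,task_id,stimulus_class``); rows are returned sorted by onset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={"subject_id": str})
    return EventTable(df)


def write_events(events: EventTable, path: str | Path) -> None:
    events.table.to_csv(path, index=False)


def write_feature_matrix(matrix: np.ndarray, labels: Sequence[str],
                         path: str | Path) -> None:
    """Write a samples x features matrix with one label per row.

    The CSV has a ``label`` column followed by ``f000..`` feature columns;
    floats are written with 17 significant digits so the round-trip is
    bit-exact.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("feature matrix must be 2-D and non-empty")
    if matrix.shape[0] != len(labels):
        raise ValueError(
            f"{len(labels)} labels for {matrix.shape[0]} feature rows")
    cols = [f"f{j:03d}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "label", [str(l) for l in labels])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={"label": str},
                     float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError("feature CSV missing 'label' column")
    labels = df["label"].tolist()
    matrix = df.drop(columns="label").to_numpy(dtype=float)
    return matrix, labels


def write_edf(rec: Recording, path: str | Path,
              physical_unit: str = "uV") -> None:
    """Write a recording as 16-bit EDF (one-second data records).

    Values are scaled into the int16 digital range, so the round-trip is
    exact only to the 16-bit quantization step of the physical range. The
    sampling rate must be an integer for the one-second record layout.
    """
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1 s record
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2000", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (1 + n_ch)), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f(str(n_ch), 4),
    ])
    sig_fields = [
        [f(name, 16) for name in rec.channel_names],
        [f("", 80)] * n_ch,
        [f(physical_unit, 8)] * n_ch,
        [f(f"{v:g}"[:8], 8) for v in pmin],
        [f(f"{v:g}"[:8], 8) for v in pmax],
        [f(str(dmin), 8)] * n_ch,
        [f(str(dmax), 8)] * n_ch,
        [f("", 80)] * n_ch,
        [f(str(spr), 8)] * n_ch,
        [f("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in sig_fields:
            fh.write(b"".join(group))
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
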