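"""Stimulus-locked epoch extraction.

Epochs span ``tmin`` to ``tmax`` seconds around each event onset with both
endpoint samples kept, so a -0.1..0.9 s window at 256 Hz has 257 timepoints
(the inclusive convention is what makes 1 s of signal at 256 Hz come out as
256 + 1 samples). Extraction is a pure gather from the recording; events
whose window would run outside the recording are dropped and counted.
Baseline correction is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .signal_io import EventTable, Recording

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Trials x channels x timepoints array time-locked to stimuli."""

    data: np.ndarray          # (n_epochs, n_channels, n_timepoints), uV
    times: np.ndarray         # seconds relative to stimulus, tmin..tmax
    labels: np.ndarray        # subject_id per epoch
    sfreq: float
    channel_names: list[str]
    task_id: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length must match n_timepoints")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def tmin(self) -> float:
        return float(self.times[0])

    @property
    def tmax(self) -> float:
        return float(self.times[-1])


def segment(rec: Recording, events: EventTable, tmin: float = -0.1,
            tmax: float = 0.9, task_id: str | None = None) -> EpochSet:
    """Cut one epoch per event, inclusive of both window endpoints.

    The sample window for an event at ``onset`` is
    ``[onset + round(tmin*sfreq), onset + round(tmax*sfreq)]`` inclusive.
    Events whose window exceeds the recording bounds are dropped (logged and
    counted in ``n_dropped``). ``task_id`` optionally restricts to one
    paradigm's events.
    """
    if not (tmin < 0 < tmax):
        raise ValueError("need tmin < 0 < tmax")
    df = events.table
    if task_id is not None:
        df = df[df["task_id"] == task_id]
    off_lo = int(round(tmin * rec.sfreq))
    off_hi = int(round(tmax * rec.sfreq))
    n_tp = off_hi - off_lo + 1
    times = (np.arange(off_lo, off_hi + 1)) / rec.sfreq

    chunks, labels = [], []
    dropped = 0
    for onset, subj in zip(df["onset_sample"], df["subject_id"]):
        start, stop = onset + off_lo, onset + off_hi
        if start < 0 or stop >= rec.n_samples:
            dropped += 1
            continue
        chunks.append(rec.data[:, start : stop + 1])
        labels.append(subj)
    if dropped:
        logger.warning("segment: dropped %d/%d events outside recording bounds",
                       dropped, len(df))
    if not chunks:
        raise ValueError("no events produced an epoch inside the recording")
    data = np.stack(chunks, axis=0)
    assert data.shape[2] == n_tp
    return EpochSet(data=data, times=times, labels=np.array(labels, dtype=object),
                    sfreq=rec.sfreq, channel_names=list(rec.channel_names),
                    task_id=task_id, n_dropped=dropped)


def baseline_correct(ep: EpochSet, window: tuple[float, float] | None = None
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``window`` (default:
    the pre-stimulus interval [tmin, 0])."""
    if window is None:
        window = (ep.tmin, 0.0)
    lo, hi = window
    if lo < ep.tmin - 1e-12 or hi > ep.tmax + 1e-12:
        raise ValueError("baseline window outside the epoch window")
    mask = (ep.times >= lo - 1e-12) & (ep.times <= hi + 1e-12)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - base)
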