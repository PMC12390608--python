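"""ERP temporal features, Welch band-power spectral features, and their
fusion into the per-sample feature vector.

A *sample* is built from a group of epochs of one subject: the ERP is the
arithmetic mean over the group's epochs (per channel and timepoint),
reduced to one value per timepoint by averaging across channels (257
temporal features for the -0.1..0.9 s window at 256 Hz); the spectral part
averages per-epoch Welch PSDs over the group and summarizes five canonical
EEG bands on six configured channels (30 spectral features). Concatenation
gives the 287-dimensional sample vector: temporal indices 0-256, spectral
indices 257-286.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .epoching import EpochSet

logger = logging.getLogger(__name__)

#: canonical EEG band edges in Hz (half-open bins, last band closed)
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: default six PSD channels: frontal / parietal / occipital spread on the
#: 14-channel Emotiv montage
DEFAULT_PSD_CHANNELS = ("F3", "F4", "P7", "P8", "O1", "O2")

#: default channel subset for the temporal (ERP) reduction: the posterior
#: sites where P300/N400 components are maximal. Averaging the full
#: montage would return exactly zero on average-referenced data.
DEFAULT_ERP_CHANNELS = ("P7", "O1", "O2", "P8")

N_TEMPORAL = 257
N_SPECTRAL = 30


@dataclass
class ERPFeature:
    """Across-epoch average waveform and its channel-reduced form."""

    values: np.ndarray            # (n_timepoints, n_channels), uV
    channel_names: list[str]
    times: np.ndarray
    reduced: np.ndarray | None = None   # (n_timepoints,) after reduce_channels


@dataclass
class PSDFeature:
    """Welch PSD averaged over a group of epochs, plus band summaries."""

    psd: np.ndarray               # (n_freqs, n_channels), power per Hz
    freqs: np.ndarray
    channel_names: list[str]
    band_powers: np.ndarray | None = None   # (n_bands, n_psd_channels)
    flat: np.ndarray | None = None          # row-major flattening


@dataclass
class FeatureVector:
    """Fused temporal+spectral sample with its identity label."""

    values: np.ndarray
    label: str
    task_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def erp_average(ep: EpochSet, group: np.ndarray | list[int] | None = None
                ) -> ERPFeature:
    """Arithmetic mean over epochs: ``values[t, ch] = mean_i X_ch^(i)(t)``.

    ``group`` selects the epochs to average (indices); all epochs by default.
    """
    idx = np.arange(ep.n_epochs) if group is None else np.asarray(group, int)
    if len(idx) == 0:
        raise ValueError("cannot average an empty epoch group")
    mean = ep.data[idx].mean(axis=0)          # (n_channels, n_timepoints)
    return ERPFeature(values=mean.T, channel_names=list(ep.channel_names),
                      times=ep.times)


def reduce_channels(erp: ERPFeature, mode: str = "mean_across_channels",
                    channels: tuple[str, ...] | None = None) -> np.ndarray:
    """Collapse the (timepoints, channels) ERP matrix to the temporal
    feature vector.

    ``mean_across_channels`` (default) averages channels at each timepoint,
    one value per timepoint; ``channels`` optionally restricts the mean to
    a named subset — the pipeline default averages the six posterior-heavy
    PSD channels because under the average reference the mean over *all*
    channels is identically zero and carries no information.
    ``per_channel`` flattens the full matrix row-major instead.
    """
    if mode == "mean_across_channels":
        values = erp.values
        if channels is not None:
            missing = [c for c in channels if c not in erp.channel_names]
            if missing:
                raise ValueError(f"channels not in ERP matrix: {missing}")
            values = values[:, [erp.channel_names.index(c) for c in channels]]
        reduced = values.mean(axis=1)
    elif mode == "per_channel":
        reduced = erp.values.reshape(-1)
    else:
        raise ValueError(f"unknown reduction mode {mode!r}")
    erp.reduced = reduced
    return reduced


def welch_psd(ep: EpochSet, group: np.ndarray | list[int] | None = None,
              seg_len: int = 256, overlap: float = 0.5,
              window: str = "hann", fmin: float = 0.5,
              fmax: float = 45.0) -> PSDFeature:
    """Welch PSD per channel, averaged over the group's epochs.

    Each epoch is split into ``seg_len``-sample segments with ``overlap``
    fractional overlap, Hann-windowed modified periodograms are averaged
    (epochs shorter than ``seg_len`` use one full-epoch segment), and the
    per-epoch PSDs are then averaged across the group. The grid is cropped
    to [fmin, fmax]; the default top of 45 Hz gives the gamma band support
    even though the upstream band-pass leaves little power there.
    """
    idx = np.arange(ep.n_epochs) if group is None else np.asarray(group, int)
    if len(idx) == 0:
        raise ValueError("cannot compute a PSD over an empty epoch group")
    data = ep.data[idx]                       # (n, n_channels, n_timepoints)
    nper = min(seg_len, data.shape[2])
    nover = int(nper * overlap)
    freqs, psd = sps.welch(data, fs=ep.sfreq, window=window, nperseg=nper,
                           noverlap=nover, axis=2)
    psd = psd.mean(axis=0)                    # average across epochs
    keep = (freqs >= fmin) & (freqs <= fmax)
    return PSDFeature(psd=psd[:, keep].T, freqs=freqs[keep],
                      channel_names=list(ep.channel_names))


def band_powers(psd: PSDFeature,
                bands: dict[str, tuple[float, float]] | None = None,
                channels6: tuple[str, ...] = DEFAULT_PSD_CHANNELS
                ) -> np.ndarray:
    """Mean PSD per band and configured channel, flattened row-major.

    Bins are assigned half-open ``lo <= f < hi`` except the last band, which
    also includes its upper edge. Returns the (n_bands, n_channels) matrix
    and stores the flat vector on ``psd.flat``.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    missing = [c for c in channels6 if c not in psd.channel_names]
    if missing:
        raise ValueError(f"channels not in recording: {missing}")
    ch_idx = [psd.channel_names.index(c) for c in channels6]
    names = list(bands)
    out = np.empty((len(bands), len(channels6)))
    for bi, name in enumerate(names):
        lo, hi = bands[name]
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        if bi == len(names) - 1:
            mask |= np.isclose(psd.freqs, hi)
        if not mask.any():
            raise ValueError(f"band {name!r} [{lo}, {hi}) covers no PSD bins")
        out[bi] = psd.psd[mask][:, ch_idx].mean(axis=0)
    psd.band_powers = out
    psd.flat = out.reshape(-1)
    return out


def assemble_feature_vector(temporal: np.ndarray, spectral: np.ndarray,
                            label: str, task_id: str | None = None,
                            strict: bool = True) -> FeatureVector:
    """Concatenate temporal and spectral parts into one sample vector.

    In strict mode the parts must have the canonical 257 and 30 lengths
    (fused length 287); relaxed mode allows toy sizes.
    """
    temporal = np.asarray(temporal, float).ravel()
    spectral = np.asarray(spectral, float).ravel()
    if strict and (len(temporal) != N_TEMPORAL or len(spectral) != N_SPECTRAL):
        raise ValueError(
            f"expected {N_TEMPORAL}+{N_SPECTRAL} features, got "
            f"{len(temporal)}+{len(spectral)}")
    return FeatureVector(values=np.concatenate([temporal, spectral]),
                         label=str(label), task_id=task_id)


def build_samples(ep: EpochSet, epochs_per_sample: int = 10,
                  reduction: str = "mean_across_channels",
                  erp_channels: tuple[str, ...] | None = DEFAULT_ERP_CHANNELS,
                  psd_channels: tuple[str, ...] = DEFAULT_PSD_CHANNELS,
                  bands: dict[str, tuple[float, float]] | None = None,
                  strict: bool | None = None) -> list[FeatureVector]:
    """Build one fused feature vector per non-overlapping group of
    ``epochs_per_sample`` consecutive epochs of each subject.

    Epochs are grouped per subject in recording order; leftover epochs that
    do not fill a group are dropped and logged. Raises if no subject has a
    complete group. ``erp_channels`` restricts the temporal channel-mean to
    a subset (None averages the whole montage — identically zero on
    average-referenced data); if the named channels are absent from this
    EpochSet (toy montages) the full mean is used instead.
    """
    if epochs_per_sample < 1:
        raise ValueError("epochs_per_sample must be >= 1")
    if erp_channels is not None and \
            not set(erp_channels) <= set(ep.channel_names):
        erp_channels = None
    if strict is None:
        strict = (ep.n_timepoints == N_TEMPORAL
                  and reduction == "mean_across_channels"
                  and len(psd_channels) * len(bands or DEFAULT_BANDS)
                  == N_SPECTRAL)
    labels = np.asarray(ep.labels)
    samples: list[FeatureVector] = []
    n_left = 0
    for subj in dict.fromkeys(labels):        # preserves first-seen order
        idx = np.flatnonzero(labels == subj)
        n_groups = len(idx) // epochs_per_sample
        n_left += len(idx) - n_groups * epochs_per_sample
        for g in range(n_groups):
            grp = idx[g * epochs_per_sample : (g + 1) * epochs_per_sample]
            erp = erp_average(ep, grp)
            temporal = reduce_channels(erp, mode=reduction,
                                       channels=erp_channels)
            psd = welch_psd(ep, grp)
            spectral = band_powers(psd, bands=bands,
                                   channels6=psd_channels).reshape(-1)
            samples.append(assemble_feature_vector(
                temporal, spectral, label=subj, task_id=ep.task_id,
                strict=strict))
    if n_left:
        logger.info("build_samples: dropped %d leftover epochs (< group size)",
                    n_left)
    if not samples:
        raise ValueError("no subject had a complete epoch group")
    return samples


def feature_matrix(samples: list[FeatureVector]) -> tuple[np.ndarray, list[str]]:
    """Stack samples into a (n_samples, n_features) matrix plus labels."""
    X = np.stack([s.values for s in samples])
    y = [s.label for s in samples]
    return X, y
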