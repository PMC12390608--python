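"""Synthetic multi-subject EEG with subject-specific ERP and spectral
signatures.

Each simulated subject gets (i) an ERP template — a Gaussian bump per
channel with subject-specific amplitude, peak latency and random spatial
weights; positive with latency in 250-500 ms for the p300 paradigm,
negative with latency in 300-500 ms for n400 — and (ii) a subject-specific
alpha (10 Hz) oscillation amplitude. Continuous recordings are built by
placing jittered copies of the template at stimulus onsets spaced 1.5-2.5 s
apart on top of pink (1/f) plus white background noise. A single
``separability`` scalar multiplies everything that distinguishes subjects
(the ERP template and each subject's deviation from the population-mean
alpha amplitude): at 0 all subjects are statistically identical, so
classifiers can only reach chance; raising it makes identification easier.

Everything is drawn from one seeded generator, so identical (config, seed)
pairs reproduce recordings bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_io import EventTable, Recording

#: the 14-channel Emotiv EPOC+ montage
EMOTIV_CHANNELS = ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
                   "O2", "P8", "T8", "FC6", "F4", "F8", "AF4")

#: fixed scalp topographies (per-channel gains) the subject-specific
#: weights jitter around: ERP components are posterior-dominant, the alpha
#: rhythm occipital-dominant. Focal profiles matter because the average
#: reference removes any spatially uniform signal.
ERP_PROFILE = {"AF3": 0.1, "F7": 0.1, "F3": 0.15, "FC5": 0.2, "T7": 0.3,
               "P7": 1.0, "O1": 0.9, "O2": 0.9, "P8": 1.0, "T8": 0.3,
               "FC6": 0.2, "F4": 0.15, "F8": 0.1, "AF4": 0.1}
ALPHA_PROFILE = {"AF3": 0.15, "F7": 0.15, "F3": 0.15, "FC5": 0.15,
                 "T7": 0.3, "P7": 0.8, "O1": 1.0, "O2": 1.0, "P8": 0.8,
                 "T8": 0.3, "FC6": 0.15, "F4": 0.15, "F8": 0.15,
                 "AF4": 0.15}
#: fronto-central mu-beta (sensorimotor) rhythm topography; this montage
#: has no C3/C4, so the rhythm projects onto the frontal-central sites
MU_PROFILE = {"AF3": 0.3, "F7": 0.4, "F3": 0.9, "FC5": 1.0, "T7": 0.6,
              "P7": 0.3, "O1": 0.15, "O2": 0.15, "P8": 0.3, "T8": 0.6,
              "FC6": 1.0, "F4": 0.9, "F8": 0.4, "AF4": 0.3}
#: frontal-midline theta topography
THETA_PROFILE = {"AF3": 0.9, "F7": 0.5, "F3": 1.0, "FC5": 0.7, "T7": 0.3,
                 "P7": 0.15, "O1": 0.1, "O2": 0.1, "P8": 0.15, "T8": 0.3,
                 "FC6": 0.7, "F4": 1.0, "F8": 0.5, "AF4": 0.9}


#: paradigm -> (polarity, latency window in seconds, default task tag)
PARADIGMS = {
    "p300": (+1.0, (0.250, 0.500), "P300-Selected"),
    "n400": (-1.0, (0.300, 0.500), "N400-Faces"),
}


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the simulator.

    Amplitudes are in microvolts, latencies in seconds. ``separability``
    scales every subject-distinguishing effect; 1 is the default study
    condition, 0 removes identity information entirely.
    """

    n_subjects: int = 10
    n_trials_per_subject: int = 40
    sfreq: float = 256.0
    channel_names: tuple[str, ...] = EMOTIV_CHANNELS
    paradigm: str = "p300"
    # ERP component (population level); posterior P300/N400 amplitudes of
    # 10-20 uV are typical of strong oddball/semantic designs
    amplitude_mean_uv: float = 15.0
    amplitude_sd_uv: float = 4.0        # between-subject amplitude spread
    width_s: float = 0.05               # Gaussian bump sd
    # trial-to-trial jitter
    trial_latency_sd_s: float = 0.020
    trial_amplitude_cv: float = 0.1
    # background noise
    pink_rms_uv: float = 10.0
    white_rms_uv: float = 2.0
    alpha_freq_hz: float = 10.0
    alpha_amp_range_uv: tuple[float, float] = (1.0, 12.0)
    mu_freq_hz: float = 16.0
    mu_amp_range_uv: tuple[float, float] = (0.5, 4.5)
    theta_freq_hz: float = 6.0
    theta_amp_range_uv: tuple[float, float] = (0.5, 5.0)
    #: per-subject 1/f exponent spread (the spectral slope is a stable
    #: individual trait); exponent = 1 +- uniform(jitter), scaled by
    #: separability
    pink_exponent_jitter: float = 0.25
    #: per-subject, per-channel broadband gain spread (anatomy and
    #: electrode-coupling differences); gain = 1 +- uniform(jitter)
    channel_gain_jitter: float = 0.25
    #: per-subject global amplitude gain range (overall EEG power differs
    #: severalfold between individuals)
    global_gain_range: tuple[float, float] = (0.7, 1.4)
    # stimulus timing
    isi_range_s: tuple[float, float] = (1.5, 2.5)
    lead_in_s: float = 2.0
    min_duration_s: float = 36.0        # keeps short runs filterable
    epoch_window_s: tuple[float, float] = (-0.1, 0.9)
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial")
        lat_lo, lat_hi = PARADIGMS[self.paradigm][1]
        if lat_hi > self.epoch_window_s[1]:
            raise ValueError("component latency window outside the epoch")

    @property
    def task_id(self) -> str:
        return PARADIGMS[self.paradigm][2]

    def subject_ids(self) -> list[str]:
        return [f"s{i:02d}" for i in range(self.n_subjects)]


@dataclass
class SubjectTraits:
    amplitude_uv: float
    latency_s: float
    spatial_weights: np.ndarray      # (n_channels,)
    alpha_amp_uv: float
    alpha_weights: np.ndarray        # (n_channels,)
    alpha_phase: float
    pink_exponent: float = 1.0
    mu_amp_uv: float = 0.0
    mu_weights: np.ndarray | None = None
    mu_phase: float = 0.0
    theta_amp_uv: float = 0.0
    theta_weights: np.ndarray | None = None
    theta_phase: float = 0.0
    channel_gains: np.ndarray | None = None
    global_gain: float = 1.0


@dataclass
class GroundTruth:
    """Everything needed to audit a generated dataset."""

    config: SyntheticConfig
    traits: dict[str, SubjectTraits]
    templates: dict[str, np.ndarray]   # (n_channels, n_epoch_samples)
    template_times: np.ndarray
    events: dict[str, pd.DataFrame] = field(default_factory=dict)


def _profile(names, table, default: float = 0.5) -> np.ndarray:
    return np.array([table.get(n, default) for n in names])


def _subject_traits(cfg: SyntheticConfig, rng: np.random.Generator
                    ) -> SubjectTraits:
    _, (lat_lo, lat_hi), _ = PARADIGMS[cfg.paradigm]
    amp = max(float(rng.normal(cfg.amplitude_mean_uv, cfg.amplitude_sd_uv)),
              0.25 * cfg.amplitude_mean_uv)
    lat = float(rng.uniform(lat_lo, lat_hi))
    n_ch = len(cfg.channel_names)
    erp_prof = _profile(cfg.channel_names, ERP_PROFILE)
    alpha_prof = _profile(cfg.channel_names, ALPHA_PROFILE)
    return SubjectTraits(
        amplitude_uv=amp,
        latency_s=lat,
        spatial_weights=erp_prof * rng.uniform(0.6, 1.4, size=n_ch),
        alpha_amp_uv=float(rng.uniform(*cfg.alpha_amp_range_uv)),
        alpha_weights=alpha_prof * rng.uniform(0.7, 1.3, size=n_ch),
        alpha_phase=float(rng.uniform(0, 2 * np.pi)),
        pink_exponent=1.0 + float(rng.uniform(-cfg.pink_exponent_jitter,
                                              cfg.pink_exponent_jitter)),
        mu_amp_uv=float(rng.uniform(*cfg.mu_amp_range_uv)),
        mu_weights=_profile(cfg.channel_names, MU_PROFILE)
        * rng.uniform(0.7, 1.3, size=n_ch),
        mu_phase=float(rng.uniform(0, 2 * np.pi)),
        theta_amp_uv=float(rng.uniform(*cfg.theta_amp_range_uv)),
        theta_weights=_profile(cfg.channel_names, THETA_PROFILE)
        * rng.uniform(0.7, 1.3, size=n_ch),
        theta_phase=float(rng.uniform(0, 2 * np.pi)),
        channel_gains=1.0 + rng.uniform(-cfg.channel_gain_jitter,
                                        cfg.channel_gain_jitter, size=n_ch),
        global_gain=float(rng.uniform(*cfg.global_gain_range)),
    )


def subject_traits(cfg: SyntheticConfig, subject: int) -> SubjectTraits:
    """Replay the generator's draws to recover one subject's traits."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(subject):
        _subject_traits(cfg, rng)
    return _subject_traits(cfg, rng)


def template_times(cfg: SyntheticConfig) -> np.ndarray:
    """Epoch time grid on exact sample indices (same rounding as epoching)."""
    tmin, tmax = cfg.epoch_window_s
    lo = int(round(tmin * cfg.sfreq))
    hi = int(round(tmax * cfg.sfreq))
    return np.arange(lo, hi + 1) / cfg.sfreq


def _bump(times: np.ndarray, amp: float, latency: float, width: float,
          polarity: float) -> np.ndarray:
    wave = polarity * amp * np.exp(-0.5 * ((times - latency) / width) ** 2)
    return np.where(times > 0, wave, 0.0)


def erp_template(cfg: SyntheticConfig, traits: SubjectTraits | int,
                 channel: int | None = None) -> np.ndarray:
    """Noise-free stimulus-locked template over the epoch window.

    ``traits`` may be a SubjectTraits or a subject index (replayed from the
    config seed). Returns (n_channels, n_samples), or one channel's
    waveform when ``channel`` is given. Zero before stimulus onset; scaled
    by ``separability``.
    """
    if isinstance(traits, (int, np.integer)):
        traits = subject_traits(cfg, int(traits))
    polarity = PARADIGMS[cfg.paradigm][0]
    times = template_times(cfg)
    base = _bump(times, traits.amplitude_uv, traits.latency_s, cfg.width_s,
                 polarity)
    tpl = cfg.separability * traits.spatial_weights[:, None] * base[None, :]
    return tpl[channel] if channel is not None else tpl


def _pink_noise(n: int, sfreq: float, rng: np.random.Generator,
                exponent: float = 1.0, f_floor: float = 0.5) -> np.ndarray:
    """1/f^exponent power noise via spectral shaping, unit RMS.

    Below ``f_floor`` the profile rolls off toward zero instead of
    diverging: infra-slow 1/f drift is electrode/skin artifact rather than
    neural background, and a diverging low end would make long stretches of
    one recording share a recording-specific offset — a session fingerprint
    that would leak identity even with all subject traits disabled.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    nz = freqs >= f_floor
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    lo = (freqs > 0) & (freqs < f_floor)
    shape[lo] = f_floor ** (-exponent / 2.0) * (freqs[lo] / f_floor)
    out = np.fft.irfft(spec * shape, n)
    return out / out.std()


def generate_dataset(cfg: SyntheticConfig
                     ) -> tuple[dict[str, Recording], dict[str, EventTable],
                                GroundTruth]:
    """One continuous recording and event table per subject, plus the
    ground truth that produced them."""
    rng = np.random.default_rng(cfg.seed)
    subjects = cfg.subject_ids()
    traits = {s: _subject_traits(cfg, rng) for s in subjects}

    tmin, tmax = cfg.epoch_window_s
    tpl_times = template_times(cfg)
    templates = {s: erp_template(cfg, traits[s]) for s in subjects}

    alpha_mean = float(np.mean(cfg.alpha_amp_range_uv))
    polarity = PARADIGMS[cfg.paradigm][0]
    stim_class = "target" if cfg.paradigm == "p300" else "face"

    recordings: dict[str, Recording] = {}
    events: dict[str, EventTable] = {}
    gt = GroundTruth(config=cfg, traits=traits, templates=templates,
                     template_times=tpl_times)
    n_ch = len(cfg.channel_names)

    for subj in subjects:
        tr = traits[subj]
        isi = rng.uniform(*cfg.isi_range_s, size=cfg.n_trials_per_subject)
        onsets_s = cfg.lead_in_s + np.concatenate([[0.0], np.cumsum(isi[:-1])])
        duration = max(onsets_s[-1] + tmax + cfg.isi_range_s[0],
                       cfg.min_duration_s)
        n_samp = int(np.ceil(duration * cfg.sfreq))
        t = np.arange(n_samp) / cfg.sfreq

        # separability also controls how far this subject's spectral slope
        # deviates from the population 1/f
        pink_exp = 1.0 + cfg.separability * (tr.pink_exponent - 1.0)
        data = np.empty((n_ch, n_samp))
        for c in range(n_ch):
            data[c] = cfg.pink_rms_uv * _pink_noise(n_samp, cfg.sfreq, rng,
                                                    exponent=pink_exp)
        data += cfg.white_rms_uv * rng.standard_normal((n_ch, n_samp))

        # subject-specific alpha rhythm; only its deviation from the
        # population mean carries identity, so it is what separability scales
        # every subject-distinguishing deviation (amplitude and per-channel
        # weight pattern) is pulled toward the population value by
        # (1 - separability) so that separability 0 leaves no identity cue
        sep = cfg.separability
        for freq, amp_range, amp_s, w_s, prof_tbl, phase in (
                (cfg.alpha_freq_hz, cfg.alpha_amp_range_uv, tr.alpha_amp_uv,
                 tr.alpha_weights, ALPHA_PROFILE, tr.alpha_phase),
                (cfg.mu_freq_hz, cfg.mu_amp_range_uv, tr.mu_amp_uv,
                 tr.mu_weights, MU_PROFILE, tr.mu_phase),
                (cfg.theta_freq_hz, cfg.theta_amp_range_uv, tr.theta_amp_uv,
                 tr.theta_weights, THETA_PROFILE, tr.theta_phase)):
            amp_mean = float(np.mean(amp_range))
            amp = amp_mean + sep * (amp_s - amp_mean)
            prof = _profile(cfg.channel_names, prof_tbl)
            weights = prof + sep * (w_s - prof)
            osc = np.sin(2 * np.pi * freq * t + phase)
            data += amp * weights[:, None] * osc[None, :]

        onset_samples = np.round(onsets_s * cfg.sfreq).astype(int)
        for onset in onset_samples:
            a_trial = tr.amplitude_uv * (
                1.0 + cfg.trial_amplitude_cv * rng.standard_normal())
            lat_trial = tr.latency_s + cfg.trial_latency_sd_s * \
                rng.standard_normal()
            stop = min(onset + int(1.5 * cfg.sfreq), n_samp)
            seg_t = (np.arange(onset, stop) - onset) / cfg.sfreq
            bump = _bump(seg_t, a_trial, lat_trial, cfg.width_s, polarity)
            data[:, onset:stop] += cfg.separability * \
                tr.spatial_weights[:, None] * bump[None, :]

        # anatomy/electrode gain field scales the whole channel signal
        gains = 1.0 + sep * (tr.channel_gains - 1.0)
        gains = gains * (1.0 + sep * (tr.global_gain - 1.0))
        data *= gains[:, None]

        recordings[subj] = Recording(data=data, sfreq=cfg.sfreq,
                                     channel_names=list(cfg.channel_names))
        df = pd.DataFrame({
            "onset_sample": onset_samples,
            "subject_id": subj,
            "task_id": cfg.task_id,
            "stimulus_class": stim_class,
        })
        events[subj] = EventTable(df)
        gt.events[subj] = df

    return recordings, events, gt


def merge_epoch_sets(epoch_sets):
    """Concatenate per-subject EpochSets (same window/channels) into one."""
    first = epoch_sets[0]
    data = np.concatenate([e.data for e in epoch_sets], axis=0)
    labels = np.concatenate([e.labels for e in epoch_sets])
    return replace(first, data=data, labels=labels,
                   n_dropped=sum(e.n_dropped for e in epoch_sets))


def recovery_experiment(cfg: SyntheticConfig, classifier="rf", seed: int = 0,
                        epochs_per_sample: int = 4, train_frac: float = 0.8):
    """Full-chain identity-recovery run on simulated data.

    Generates the dataset, band-pass filters (0.1-30 Hz) and average-
    references each recording, epochs -0.1..0.9 s, builds fused feature
    samples from groups of ``epochs_per_sample`` epochs, does a stratified
    split, trains the requested classifier and returns the test-set
    MetricsReport (identification metrics plus pooled FAR/FRR/EER).
    """
    from .epoching import segment
    from .eval_metrics import evaluate_model
    from .features import build_samples, feature_matrix
    from .models import stratified_split, train_classifier
    from .preprocess import apply_zero_phase, average_reference, \
        design_bandpass_fir

    cfg = replace(cfg, seed=cfg.seed)
    recordings, events, gt = generate_dataset(cfg)
    spec = design_bandpass_fir(0.1, 30.0, cfg.sfreq)
    per_subject = []
    for subj, rec in recordings.items():
        rec = apply_zero_phase(rec, spec)
        rec = average_reference(rec)
        per_subject.append(segment(rec, events[subj],
                                   tmin=cfg.epoch_window_s[0],
                                   tmax=cfg.epoch_window_s[1]))
    epochs = merge_epoch_sets(per_subject)
    samples = build_samples(epochs, epochs_per_sample=epochs_per_sample)
    X, y = feature_matrix(samples)
    y = np.asarray(y)
    tr, te = stratified_split(X, y, train_frac=train_frac, seed=seed)
    model = train_classifier(X[tr], y[tr], classifier, seed=seed)
    report = evaluate_model(model, X[te], y[te])
    report.extra.update(n_samples=len(y), n_train=len(tr), n_test=len(te),
                        ground_truth=gt, model=model)
    return report
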