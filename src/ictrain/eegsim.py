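"""Synthetic continuous EEG with embedded evoked components.

Generates multichannel scalp recordings (nine sites F3/Fz/F4, C3/Cz/C4,
P3/Pz/P4 plus vertical and horizontal EOG) in microvolts, already
referenced, with event markers.  Each stimulus event adds Gaussian-bump
evoked components on top of spectrally shaped background noise: a frontal
negative deflection in the N2 range and a parietal-maximal positive
deflection in the P3 range, both with trial-to-trial latency jitter and
larger amplitude on Nogo (inhibition) trials.  Optional blink artifacts —
large slow deflections dominant at the EOG and frontal sites — are sized to
exceed the downstream +/-100 uV epoch-rejection threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .assessment import TrialSequence

SCALP_SITES = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")
EOG_SITES = ("VEOG", "HEOG")
ALL_CHANNELS = SCALP_SITES + EOG_SITES


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian evoked bump: peak latency, width and site topography."""

    name: str
    latency_ms: float
    width_ms: float
    topography_uv: dict  # site -> peak amplitude in uV (sign included)

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")
        if not all(np.isfinite(list(self.topography_uv.values()))):
            raise ValueError("topography amplitudes must be finite")


def default_n2() -> ComponentSpec:
    return ComponentSpec(
        name="N2",
        latency_ms=250.0,
        width_ms=45.0,
        topography_uv={
            "F3": -4.5, "Fz": -6.0, "F4": -4.5,
            "C3": -2.5, "Cz": -3.5, "C4": -2.5,
            "P3": -1.0, "Pz": -1.5, "P4": -1.0,
        },
    )


def default_p3() -> ComponentSpec:
    return ComponentSpec(
        name="P3",
        latency_ms=420.0,
        width_ms=80.0,
        topography_uv={
            "F3": 5.0, "Fz": 6.5, "F4": 5.0,
            "C3": 6.0, "Cz": 8.0, "C4": 6.0,
            "P3": 7.5, "Pz": 10.0, "P4": 7.5,
        },
    )


@dataclass(frozen=True)
class EvokedSimSpec:
    """Generative settings for one synthetic recording."""

    sfreq_hz: float = 500.0
    components: tuple[ComponentSpec, ...] = field(
        default_factory=lambda: (default_n2(), default_p3())
    )
    noise_sd_uv: float = 3.0
    noise_ar_coef: float = 0.95  # AR(1) shaping: low-frequency-dominant background
    latency_jitter_sd_ms: float = 8.0
    nogo_gain: float = 1.3  # inhibition trials evoke larger N2/P3
    blink_rate_hz: float = 0.0
    blink_amp_uv: float = 180.0
    blink_width_ms: float = 150.0
    #: attenuation of the blink field moving back from the eyes
    blink_row_gain: dict = field(
        default_factory=lambda: {"F": 0.7, "C": 0.3, "P": 0.1}
    )

    def __post_init__(self) -> None:
        if self.sfreq_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.blink_rate_hz > 0 and self.blink_amp_uv * max(
            self.blink_row_gain.values()
        ) <= 100.0:
            raise ValueError(
                "blink amplitude must exceed the +/-100 uV rejection threshold "
                "at some scalp site when artifact injection is enabled"
            )


@dataclass
class EEGRecording:
    """Continuous multichannel recording in uV with event markers."""

    data_uv: np.ndarray  # (n_channels, n_samples)
    sfreq_hz: float
    ch_names: tuple[str, ...]
    events: list  # [(sample_index, label), ...]

    def __post_init__(self) -> None:
        missing = set(SCALP_SITES) - set(self.ch_names)
        if missing:
            raise ValueError(f"missing scalp channels: {sorted(missing)}")
        n = self.data_uv.shape[1]
        if any(not 0 <= s < n for s, _ in self.events):
            raise ValueError("event marker outside the recording")

    @property
    def n_samples(self) -> int:
        return int(self.data_uv.shape[1])

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)


def _gauss_bump(t_s: np.ndarray, center_s: float, width_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_s - center_s) / width_s) ** 2)


def synthesize_eeg(
    spec: EvokedSimSpec,
    events: TrialSequence,
    rng: np.random.Generator,
    tail_ms: float = 1200.0,
    lead_ms: float = 500.0,
) -> EEGRecording:
    """Render a continuous recording containing the given stimulus events.

    Every event contributes each component's bump (scaled by ``nogo_gain``
    on Nogo trials and jittered in latency); blink artifacts arrive as a
    Poisson process at ``blink_rate_hz``.  Bit-reproducible under a fixed
    generator.
    """
    fs = spec.sfreq_hz
    # lead-in keeps the first event's prestimulus baseline inside the record
    onsets = np.asarray(events.onsets_ms, dtype=float) + lead_ms
    duration_s = (onsets[-1] + tail_ms) / 1000.0 if len(onsets) else tail_ms / 1000.0
    n = int(math.ceil(duration_s * fs))
    t = np.arange(n) / fs
    n_ch = len(ALL_CHANNELS)

    if spec.noise_sd_uv > 0:
        white = rng.standard_normal((n_ch, n))
        shaped = signal.lfilter([1.0], [1.0, -spec.noise_ar_coef], white, axis=1)
        # stationary AR(1) sd is 1/sqrt(1-a^2); rescale to the requested sd
        shaped *= spec.noise_sd_uv * math.sqrt(1.0 - spec.noise_ar_coef**2)
        data = shaped
    else:
        data = np.zeros((n_ch, n))

    ch_idx = {name: i for i, name in enumerate(ALL_CHANNELS)}
    markers = []
    for onset_ms, label in zip(onsets, events.labels):
        s = int(round(onset_ms / 1000.0 * fs))
        markers.append((s, label))
        gain = spec.nogo_gain if label == "nogo" else 1.0
        for comp in spec.components:
            jitter = (
                rng.normal(0.0, spec.latency_jitter_sd_ms)
                if spec.latency_jitter_sd_ms > 0
                else 0.0
            )
            center = (onset_ms + comp.latency_ms + jitter) / 1000.0
            width = comp.width_ms / 1000.0 / 2.355  # FWHM -> sd
            lo = max(0, int((center - 4 * width) * fs))
            hi = min(n, int((center + 4 * width) * fs) + 1)
            if hi <= lo:
                continue
            bump = _gauss_bump(t[lo:hi], center, width)
            for site, amp in comp.topography_uv.items():
                data[ch_idx[site], lo:hi] += gain * amp * bump

    if spec.blink_rate_hz > 0:
        n_blinks = rng.poisson(spec.blink_rate_hz * duration_s)
        blink_times = rng.uniform(0.0, duration_s, size=n_blinks)
        width = spec.blink_width_ms / 1000.0 / 2.355
        for bt in blink_times:
            lo = max(0, int((bt - 4 * width) * fs))
            hi = min(n, int((bt + 4 * width) * fs) + 1)
            if hi <= lo:
                continue
            bump = spec.blink_amp_uv * _gauss_bump(t[lo:hi], bt, width)
            data[ch_idx["VEOG"], lo:hi] += bump
            for site in SCALP_SITES:
                gain = spec.blink_row_gain.get(site[0], 0.0)
                data[ch_idx[site], lo:hi] += gain * bump

    return EEGRecording(
        data_uv=data, sfreq_hz=fs, ch_names=ALL_CHANNELS, events=markers
    )


def inject_blinks_at(
    rec: EEGRecording,
    sample_indices,
    amp_uv: float = 180.0,
    width_ms: float = 150.0,
    row_gain: dict | None = None,
) -> EEGRecording:
    """Add blink bumps at known sample positions (for rejection tests)."""
    row_gain = {"F": 0.7, "C": 0.3, "P": 0.1} if row_gain is None else row_gain
    data = rec.data_uv.copy()
    fs = rec.sfreq_hz
    t = np.arange(rec.n_samples) / fs
    width = width_ms / 1000.0 / 2.355
    for s in sample_indices:
        bump = amp_uv * _gauss_bump(t, s / fs, width)
        data[rec.channel_index("VEOG")] += bump
        for site in SCALP_SITES:
            data[rec.channel_index(site)] += row_gain.get(site[0], 0.0) * bump
    return EEGRecording(
        data_uv=data, sfreq_hz=fs, ch_names=rec.ch_names, events=list(rec.events)
    )
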