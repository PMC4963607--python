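"""ERP quantification chain: filter, epoch, reject, average, measure peaks.

The processing order mirrors standard stimulus-locked ERP practice: the
continuous recording is zero-phase low-pass filtered (-3 dB at 24 Hz),
divided into epochs from -100 ms prestimulus to +900 ms poststimulus,
baseline-corrected to the prestimulus mean, screened with an amplitude
criterion (any scalp-site sample outside +/-100 uV rejects the whole
epoch; EOG channels never trigger rejection), and averaged separately per
condition.  Peak measurement is reference-locked: the N2 latency is the
largest negativity at Fz in 190-300 ms, the P3 latency the largest
positivity at Pz in 300-580 ms, and amplitudes at every scalp site are
read at exactly that latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .eegsim import EEGRecording, SCALP_SITES

N2 = "N2"
P3 = "P3"

#: component -> (reference site, search window in ms, polarity)
COMPONENT_DEFAULTS = {
    N2: ("Fz", (190.0, 300.0), "min"),
    P3: ("Pz", (300.0, 580.0), "max"),
}

REJECT_THRESHOLD_UV = 100.0


class EmptyConditionError(ValueError):
    """Averaging requested for a condition with no accepted epochs."""


@dataclass
class EpochSet:
    """Stimulus-locked epochs with accept/reject bookkeeping.

    ``data_uv`` has shape (n_epochs, n_channels, n_times); ``times_ms`` is
    shared across epochs; ``accepted``/``reject_reason`` track the amplitude
    screen.
    """

    data_uv: np.ndarray
    times_ms: np.ndarray
    ch_names: tuple[str, ...]
    labels: np.ndarray  # per-epoch condition label, e.g. "go"/"nogo"
    sfreq_hz: float
    accepted: np.ndarray = None
    reject_reason: np.ndarray = None

    def __post_init__(self) -> None:
        n = self.data_uv.shape[0]
        if self.accepted is None:
            self.accepted = np.ones(n, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * n, dtype=object)

    def __len__(self) -> int:
        return int(self.data_uv.shape[0])

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def scalp_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.ch_names) if c in SCALP_SITES]


@dataclass
class ERPWaveform:
    """Per-site average waveform over accepted epochs of one condition."""

    data_uv: np.ndarray  # (n_channels, n_times)
    times_ms: np.ndarray
    ch_names: tuple[str, ...]
    n_epochs: int
    label: str = ""

    def channel(self, name: str) -> np.ndarray:
        return self.data_uv[self.ch_names.index(name)]


@dataclass(frozen=True)
class PeakMeasure:
    """Component latency at the reference site plus site-wise amplitudes there."""

    component: str
    reference_site: str
    window_ms: tuple[float, float]
    latency_ms: float
    amplitudes_uv: dict  # scalp site -> uV at the reference latency
    boundary_peak: bool  # extremum fell on a window endpoint


def _butter_lowpass(cutoff_hz: float, sfreq_hz: float, order: int = 4):
    # filtfilt applies the filter twice, squaring the magnitude response;
    # widen the design cutoff so the *two-pass* response is -3 dB at cutoff
    wn = cutoff_hz / (10.0 ** (3.0 / 20.0) - 1.0) ** (1.0 / (2.0 * order))
    return signal.butter(order, wn, btype="low", fs=sfreq_hz)


def lowpass_filter(
    rec: EEGRecording, cutoff_hz: float = 24.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth low-pass, -3 dB at ``cutoff_hz``."""
    if cutoff_hz >= rec.sfreq_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = _butter_lowpass(cutoff_hz, rec.sfreq_hz, order)
    filtered = signal.filtfilt(b, a, rec.data_uv, axis=1)
    return EEGRecording(
        data_uv=filtered,
        sfreq_hz=rec.sfreq_hz,
        ch_names=rec.ch_names,
        events=list(rec.events),
    )


def extract_epochs(
    rec: EEGRecording,
    events=None,
    window_ms: tuple[float, float] = (-100.0, 900.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked, baseline-corrected epochs around event markers.

    Windows are half-open sample intervals [start, end) after ms-to-sample
    rounding; the per-channel mean over the baseline interval is subtracted.
    Events whose window would leave the recording are dropped with a warning.
    """
    fs = rec.sfreq_hz
    events = rec.events if events is None else events
    i0 = int(round(window_ms[0] / 1000.0 * fs))
    i1 = int(round(window_ms[1] / 1000.0 * fs))
    times = np.arange(i0, i1) / fs * 1000.0
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    if not bmask.any():
        raise ValueError("baseline interval contains no samples")
    epochs, labels = [], []
    n_dropped = 0
    for s, label in events:
        lo, hi = s + i0, s + i1
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        ep = rec.data_uv[:, lo:hi].copy()
        ep -= ep[:, bmask].mean(axis=1, keepdims=True)
        epochs.append(ep)
        labels.append(label)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} event(s) too close to the recording edge",
            stacklevel=2,
        )
    if not epochs:
        raise ValueError("no event leaves a full epoch inside the recording")
    return EpochSet(
        data_uv=np.stack(epochs),
        times_ms=times,
        ch_names=rec.ch_names,
        labels=np.array(labels, dtype=object),
        sfreq_hz=fs,
    )


def reject_epochs(
    epochs: EpochSet, threshold_uv: float = REJECT_THRESHOLD_UV
) -> EpochSet:
    """Flag epochs with any scalp-channel sample outside +/-threshold.

    EOG channels are deliberately excluded from the criterion: blinks are
    detected through their propagation onto the scalp sites.  Monotone in
    the threshold — raising it never rejects more epochs.
    """
    scalp = epochs.scalp_indices()
    bad = np.abs(epochs.data_uv[:, scalp, :]).max(axis=(1, 2)) > threshold_uv
    accepted = epochs.accepted & ~bad
    reason = epochs.reject_reason.copy()
    newly = bad & epochs.accepted
    reason[newly] = f"amplitude>{threshold_uv:g}uV"
    return EpochSet(
        data_uv=epochs.data_uv,
        times_ms=epochs.times_ms,
        ch_names=epochs.ch_names,
        labels=epochs.labels,
        sfreq_hz=epochs.sfreq_hz,
        accepted=accepted,
        reject_reason=reason,
    )


def average_erp(epochs: EpochSet, condition: str | None = None) -> ERPWaveform:
    """Point-wise mean over accepted epochs of one condition."""
    mask = epochs.accepted.copy()
    if condition is not None:
        mask &= epochs.labels == condition
    if not mask.any():
        raise EmptyConditionError(
            f"no accepted epochs for condition {condition!r}"
        )
    return ERPWaveform(
        data_uv=epochs.data_uv[mask].mean(axis=0),
        times_ms=epochs.times_ms,
        ch_names=epochs.ch_names,
        n_epochs=int(mask.sum()),
        label=condition or "all",
    )


def quantify_peak_locked(
    erp: ERPWaveform,
    component: str,
    window_ms: tuple[float, float] | None = None,
    lock_site: str | None = None,
) -> PeakMeasure:
    """Reference-locked peak measurement for N2 or P3.

    The component latency is the argmin (N2) or argmax (P3) of the
    reference-site trace within the component window (earliest sample on
    ties); amplitudes at all nine scalp sites are read at exactly that
    latency.  ``lock_site`` and ``window_ms`` may override the defaults so
    the locking site and the reporting convention stay independent.
    """
    try:
        default_site, default_window, polarity = COMPONENT_DEFAULTS[component]
    except KeyError:
        raise ValueError(f"unknown component {component!r}") from None
    site = default_site if lock_site is None else lock_site
    window = default_window if window_ms is None else window_ms
    if site not in erp.ch_names:
        raise ValueError(f"reference channel {site!r} missing from waveform")
    mask = (erp.times_ms >= window[0]) & (erp.times_ms <= window[1])
    if not mask.any():
        raise ValueError("waveform does not cover the component window")
    idx = np.flatnonzero(mask)
    trace = erp.channel(site)[idx]
    j = int(np.argmin(trace) if polarity == "min" else np.argmax(trace))
    peak_idx = idx[j]
    latency = float(erp.times_ms[peak_idx])
    amplitudes = {
        s: float(erp.channel(s)[peak_idx]) for s in SCALP_SITES if s in erp.ch_names
    }
    return PeakMeasure(
        component=component,
        reference_site=site,
        window_ms=(float(window[0]), float(window[1])),
        latency_ms=latency,
        amplitudes_uv=amplitudes,
        boundary_peak=j in (0, len(idx) - 1),
    )


def grand_mean(erps) -> ERPWaveform:
    """Unweighted point-wise mean across participant-level waveforms."""
    erps = list(erps)
    if not erps:
        raise ValueError("no waveforms to average")
    ref = erps[0]
    for e in erps[1:]:
        if e.ch_names != ref.ch_names or not np.array_equal(e.times_ms, ref.times_ms):
            raise ValueError("waveforms must share sites and time axis")
    return ERPWaveform(
        data_uv=np.mean([e.data_uv for e in erps], axis=0),
        times_ms=ref.times_ms.copy(),
        ch_names=ref.ch_names,
        n_epochs=len(erps),
        label=ref.label,
    )


def high_variance_mask(
    rec: EEGRecording, window_ms: float = 500.0, z_thresh: float = 4.0
) -> np.ndarray:
    """Automated stand-in for manual muscle-artifact screening.

    Marks samples belonging to windows whose pooled scalp-channel variance
    exceeds ``z_thresh`` robust z-scores of the across-window median.
    Returns a boolean per-sample mask (True = flagged).  Optional: the
    epoch-level +/-100 uV rule is the primary artifact gate.
    """
    fs = rec.sfreq_hz
    w = max(1, int(round(window_ms / 1000.0 * fs)))
    scalp = [i for i, c in enumerate(rec.ch_names) if c in SCALP_SITES]
    n_win = rec.n_samples // w
    mask = np.zeros(rec.n_samples, dtype=bool)
    if n_win < 2:
        return mask
    segs = rec.data_uv[scalp, : n_win * w].reshape(len(scalp), n_win, w)
    v = segs.var(axis=2).mean(axis=0)
    med = np.median(v)
    mad = np.median(np.abs(v - med)) or 1e-12
    flagged = (v - med) / (1.4826 * mad) > z_thresh
    for k in np.flatnonzero(flagged):
        mask[k * w : (k + 1) * w] = True
    return mask
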