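"""Signal conditioning and event extraction for extracellular recordings.

The pipeline order is fixed: bandpass -> common median reference ->
normalize -> detect -> extract.  Each detected event is cut into a 90-sample
(3 ms at 30 kHz) segment re-centred so that its absolute-maximum sample sits
at index 45; these segments are the feature vectors consumed by the
autoencoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: samples per segment (3 ms at 30 kHz)
SEGMENT_LEN = 90
#: index of the aligned peak inside a segment
PEAK_INDEX = 45
#: reference sampling rate of the feature space, Hz
TARGET_RATE = 30_000.0

# MAD -> sigma for a Gaussian
_MAD_SCALE = 0.6744897501960817


@dataclass
class RecordingBuffer:
    """Multichannel extracellular samples in microvolts, channels x time."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class DetectedEvent:
    """A threshold crossing, located at the local extremum of its excursion."""

    peak_sample: int
    channel: int
    peak_amplitude: float  # signed, uV


@dataclass
class FeatureVector:
    """90-sample peak-aligned segment z fed to the autoencoder."""

    z: np.ndarray
    peak_index: int = PEAK_INDEX
    source: DetectedEvent | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.shape != (SEGMENT_LEN,):
            raise ValueError(f"feature vector must have {SEGMENT_LEN} samples, got {self.z.shape}")


def bandpass(recording: RecordingBuffer, low: float = 300.0, high: float = 6000.0,
             order: int = 3) -> RecordingBuffer:
    """Zero-phase Butterworth bandpass; removes DC and out-of-band power."""
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) Hz for Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate,
                        output="sos")
    out = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return RecordingBuffer(out, recording.sampling_rate)


def common_median_reference(recording: RecordingBuffer) -> RecordingBuffer:
    """Subtract the per-sample median across channels from every channel.

    Removes noise shared by all channels (e.g. mains pickup or reference
    drift) while leaving spikes, which are local to a few channels, intact.
    """
    if recording.n_channels < 2:
        warnings.warn("common median reference requires >= 2 channels; passing through")
        return RecordingBuffer(recording.samples.copy(), recording.sampling_rate)
    med = np.median(recording.samples, axis=0, keepdims=True)
    return RecordingBuffer(recording.samples - med, recording.sampling_rate)


def noise_sigma(channel_samples: np.ndarray) -> float:
    """Robust noise-scale estimate, sigma = median(|x|) / 0.6745.

    Insensitive to sparse spikes, unlike the plain standard deviation.
    """
    x = np.asarray(channel_samples, dtype=np.float64).ravel()
    if x.size < 1000:
        raise ValueError(f"need >= 1000 samples for a noise estimate, got {x.size}")
    return float(np.median(np.abs(x)) / _MAD_SCALE)


def normalize(recording: RecordingBuffer, target_sigma: float = 10.0) -> RecordingBuffer:
    """Apply a global gain so the estimated noise floor equals ``target_sigma``.

    The MSLE threshold learned at a 10 uV training noise floor only transfers
    to a new recording if that recording's noise floor is commensurate, so the
    whole recording is rescaled (noise and spikes alike); per-event amplitude
    information is preserved.
    """
    sigma = float(np.median([noise_sigma(ch) for ch in recording.samples]))
    if sigma <= 0.0:
        raise ValueError("noise estimate is zero; cannot normalize")
    return RecordingBuffer(recording.samples * (target_sigma / sigma), recording.sampling_rate)


def detect_events(recording: RecordingBuffer, k_sigma: float = 5.0,
                  dead_time_ms: float = 1.0) -> list[DetectedEvent]:
    """Negative-going threshold detection at ``-k_sigma * sigma`` per channel.

    One event per excursion, placed at the local minimum.  Crossings on
    several channels within the dead time are merged and assigned to the
    channel with the largest absolute peak.  Events too close to the
    recording edges for a full segment are dropped.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    dead = max(1, int(round(dead_time_ms * 1e-3 * recording.sampling_rate)))
    half = int(round(PEAK_INDEX * recording.sampling_rate / TARGET_RATE))
    candidates: list[tuple[int, int, float]] = []
    for ch in range(recording.n_channels):
        x = recording.samples[ch]
        if not np.any(x):
            continue
        sigma = noise_sigma(x) if x.size >= 1000 else float(np.std(x))
        if sigma == 0.0:
            continue
        peaks, _ = signal.find_peaks(-x, height=k_sigma * sigma, distance=dead)
        for p in peaks:
            candidates.append((int(p), ch, float(x[p])))
    candidates.sort()
    events: list[DetectedEvent] = []
    for p, ch, amp in candidates:
        if events and p - events[-1].peak_sample < dead:
            if abs(amp) > abs(events[-1].peak_amplitude):
                events[-1] = DetectedEvent(p, ch, amp)
            continue
        events.append(DetectedEvent(p, ch, amp))
    lo, hi = half, recording.n_samples - half
    return [e for e in events if lo <= e.peak_sample <= hi - 1]


def extract_segment(recording: RecordingBuffer, event: DetectedEvent) -> FeatureVector | None:
    """Cut the 90-sample window around an event, abs-max aligned to index 45.

    Recordings not sampled at 30 kHz are resampled (polyphase) on the event's
    channel before cutting.  Returns ``None`` (with a warning) if the window
    would run off the edge of the recording.
    """
    x = recording.samples[event.channel]
    peak = event.peak_sample
    if recording.sampling_rate != TARGET_RATE:
        from fractions import Fraction
        frac = Fraction(TARGET_RATE / recording.sampling_rate).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
        peak = int(round(peak * TARGET_RATE / recording.sampling_rate))
    # locate the true absolute maximum near the detected peak, ties -> earliest
    lo, hi = peak - PEAK_INDEX, peak + SEGMENT_LEN - PEAK_INDEX
    if lo < 0 or hi > x.size:
        warnings.warn(f"event at sample {event.peak_sample} too close to edge; skipped")
        return None
    win = x[lo:hi]
    m = lo + int(np.argmax(np.abs(win)))
    lo2, hi2 = m - PEAK_INDEX, m + SEGMENT_LEN - PEAK_INDEX
    if lo2 < 0 or hi2 > x.size:
        warnings.warn(f"event at sample {event.peak_sample} too close to edge; skipped")
        return None
    return FeatureVector(x[lo2:hi2].copy(), PEAK_INDEX, event)


def snr(segment: FeatureVector | np.ndarray, sigma: float) -> float:
    """Linear SNR: absolute peak amplitude over the background noise sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = segment.z if isinstance(segment, FeatureVector) else np.asarray(segment)
    idx = segment.peak_index if isinstance(segment, FeatureVector) else PEAK_INDEX
    return float(abs(z[idx]) / sigma)
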