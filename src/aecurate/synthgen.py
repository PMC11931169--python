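"""Labeled synthetic extracellular data with MEArec-like statistics.

Generates everything the curation pipeline needs for training and
evaluation without downloads: a parametric bank of tri-phasic spike
templates (a positive deflection, a pronounced negative peak at the
alignment sample, a slow repolarization), Poisson spike trains with a
refractory period, periodic Type I artifacts (sine / sawtooth / square
plus noise), low-SNR Type II events emulating remote sources buried in
high noise, whole labeled recordings, and labeled sorted units for
triage experiments.

Event classes follow the spike / non-neural taxonomy:

* NEURAL  - spike template with linear SNR >= ``snr_threshold`` in 10 uV
  Gaussian background noise (the training regime).
* TYPE1   - non-biological interference: periodic waveform plus noise.
* TYPE2   - a spike so distorted by noise (default 30 uV, amplitudes of
  remote sources) that its linear SNR falls below ``snr_threshold``.

All event segments are re-aligned so their absolute-maximum sample sits at
index 45, exactly as the segment-extraction step aligns detected events.
For low-SNR events that aligned sample is usually a noise excursion rather
than the true spike peak -- a property, not a bug: it is what makes these
events poorly reconstructable by an autoencoder trained on clean spikes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal

from .curation import SortedUnit
from .preprocess import PEAK_INDEX, SEGMENT_LEN, TARGET_RATE

#: default linear SNR separating neural from Type II events
SNR_THRESHOLD = 10.0
#: padding used to generate events with realistic surrounding noise
_LONG = 2 * SEGMENT_LEN


class EventLabel(str, Enum):
    NEURAL = "NEURAL"
    TYPE1 = "TYPE1"
    TYPE2 = "TYPE2"

    __str__ = str.__str__  # keep numpy coercions on the plain value


class ArtifactKind(str, Enum):
    SINE = "SINE"
    SAWTOOTH = "SAWTOOTH"
    SQUARE = "SQUARE"

    __str__ = str.__str__


def snr_threshold_from_db(db: float) -> float:
    """Alternative reading of the SNR rule: a bound stated in decibels."""
    return float(10.0 ** (db / 20.0))


@dataclass(frozen=True)
class SpikeTemplate:
    waveform: np.ndarray  # 90 samples, uV
    peak_index: int
    amplitude: float  # |negative peak|, uV
    template_id: int


# ---------------------------------------------------------------------------
# templates

def make_template(template_id: int, amplitude: float, width_ms: float,
                  seed: int = 0) -> SpikeTemplate:
    """A parametric tri-phasic spike template, 90 samples at 30 kHz.

    The waveform is a sum of three Gaussian lobes: a small positive
    pre-peak, the main negative lobe (width ``width_ms`` FWHM), and a slow
    positive repolarization.  Lobe ratios, offsets and widths are jittered
    per (seed, template_id), giving a diverse bank from one generator.  The
    analytic waveform is sampled so that its minimum lands exactly on
    index 45, and a Tukey taper drives the endpoints to zero.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if not (0.2 <= width_ms <= 1.5):
        raise ValueError(f"width must be in [0.2, 1.5] ms, got {width_ms}")
    rng = np.random.default_rng([seed, template_id])
    w = width_ms / 2.355  # Gaussian sigma from FWHM, ms
    r_pre = rng.uniform(0.10, 0.45)
    r_post = rng.uniform(0.05, 0.40)
    c_pre = -rng.uniform(1.0, 1.8) * width_ms / 2.0
    c_post = rng.uniform(1.2, 2.4) * width_ms / 2.0
    w_post = w * rng.uniform(1.5, 3.0)

    def f(t):
        return (-np.exp(-t ** 2 / (2 * w ** 2))
                + r_pre * np.exp(-(t - c_pre) ** 2 / (2 * (0.7 * w) ** 2))
                + r_post * np.exp(-(t - c_post) ** 2 / (2 * w_post ** 2)))

    tf = np.linspace(-0.8, 0.8, 3201)
    tmin = tf[np.argmin(f(tf))]
    t = (np.arange(SEGMENT_LEN) - PEAK_INDEX) / 30.0 + tmin  # ms
    wave = f(t) * signal.windows.tukey(SEGMENT_LEN, 0.25)
    wave *= amplitude / -wave.min()
    assert int(np.argmin(wave)) == PEAK_INDEX
    return SpikeTemplate(wave, PEAK_INDEX, amplitude, template_id)


def make_template_bank(n_templates: int, seed: int,
                       amp_range: tuple[float, float] = (100.0, 250.0),
                       width_range: tuple[float, float] = (0.2, 0.7)) -> list[SpikeTemplate]:
    rng = np.random.default_rng(seed)
    return [make_template(i, rng.uniform(*amp_range), rng.uniform(*width_range), seed=seed)
            for i in range(n_templates)]


# ---------------------------------------------------------------------------
# spike trains

def poisson_train(rate: float, duration: float, refractory: float = 0.0,
                  seed: int = 0) -> np.ndarray:
    """Poisson spike times on [0, duration) with an absolute refractory gap."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    times = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        times.append(t)
        t += refractory + rng.exponential(1.0 / rate)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# single-event operations

def _periodic_wave(kind: ArtifactKind, arg: np.ndarray) -> np.ndarray:
    if kind == ArtifactKind.SINE:
        return np.sin(arg)
    if kind == ArtifactKind.SAWTOOTH:
        return signal.sawtooth(arg)
    if kind == ArtifactKind.SQUARE:
        return signal.square(arg)
    raise ValueError(f"unknown artifact kind {kind!r}")


def make_type1_event(kind: ArtifactKind | str, freq: float, amplitude: float,
                     noise_sigma: float, seed: int = 0) -> np.ndarray:
    """90 samples of a periodic artifact plus i.i.d. Gaussian noise."""
    kind = ArtifactKind(kind)
    if freq <= 0:
        raise ValueError("freq must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    t = np.arange(SEGMENT_LEN) / TARGET_RATE
    wave = amplitude * _periodic_wave(kind, 2 * np.pi * freq * t)
    if noise_sigma > 0:
        wave = wave + np.random.default_rng(seed).normal(0.0, noise_sigma, SEGMENT_LEN)
    return wave


def make_type2_event(template: SpikeTemplate, noise_sigma: float, seed: int = 0,
                     snr_threshold: float = SNR_THRESHOLD) -> np.ndarray:
    """A spike template buried in noise so its linear SNR is below threshold.

    The template amplitude is preserved when it already satisfies the bound
    and attenuated (to 80% of the bound) otherwise; noise is redrawn in the
    rare case a noise excursion pushes the peak sample back over the bound.
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive to construct a low-SNR event")
    wave = template.waveform.copy()
    limit = snr_threshold * noise_sigma
    if template.amplitude >= limit:
        wave *= 0.8 * limit / template.amplitude
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seg = wave + rng.normal(0.0, noise_sigma, SEGMENT_LEN)
        if abs(seg[PEAK_INDEX]) / noise_sigma < snr_threshold:
            return seg
    raise RuntimeError("could not satisfy the SNR bound")  # pragma: no cover


# ---------------------------------------------------------------------------
# vectorized event-set generation

def _realign_batch(long: np.ndarray) -> np.ndarray:
    """Cut 90-sample windows with the absolute maximum at index 45."""
    n = long.shape[0]
    centre = slice(PEAK_INDEX, PEAK_INDEX + SEGMENT_LEN)
    m = PEAK_INDEX + np.argmax(np.abs(long[:, centre]), axis=1)
    idx = m[:, None] + np.arange(-PEAK_INDEX, SEGMENT_LEN - PEAK_INDEX)
    return long[np.arange(n)[:, None], idx]


def _aligned(seg: np.ndarray) -> np.ndarray:
    """True where the cut window's absolute maximum really sits at index 45
    (a flank sample outside the search window can occasionally exceed it)."""
    return np.abs(seg[:, PEAK_INDEX]) >= np.abs(seg).max(axis=1)


def _neural_batch(bank: np.ndarray, n: int, noise_sigma: float, rng,
                  snr_threshold: float = SNR_THRESHOLD) -> np.ndarray:
    out = np.empty((n, SEGMENT_LEN))
    todo = np.arange(n)
    while todo.size:
        long = rng.normal(0.0, noise_sigma, (todo.size, _LONG))
        long[:, PEAK_INDEX:PEAK_INDEX + SEGMENT_LEN] += bank[rng.integers(bank.shape[0], size=todo.size)]
        seg = _realign_batch(long)
        ok = (np.abs(seg[:, PEAK_INDEX]) / noise_sigma >= snr_threshold) & _aligned(seg)
        out[todo[ok]] = seg[ok]
        todo = todo[~ok]
    return out


def _type1_batch(n: int, noise_sigma: float, rng,
                 freq_range: tuple[float, float] = (300.0, 3000.0),
                 amp_range_sigma: tuple[float, float] = (2.0, 10.0)) -> np.ndarray:
    t = np.arange(_LONG) / TARGET_RATE
    out = np.empty((n, SEGMENT_LEN))
    todo = np.arange(n)
    while todo.size:
        k = todo.size
        freq = rng.uniform(*freq_range, k)
        amp = noise_sigma * rng.uniform(*amp_range_sigma, k)
        phase = rng.uniform(0.0, 2 * np.pi, k)
        arg = 2 * np.pi * freq[:, None] * t + phase[:, None]
        kind = rng.integers(3, size=k)
        wave = np.where(kind[:, None] == 0, np.sin(arg),
                        np.where(kind[:, None] == 1, signal.sawtooth(arg), signal.square(arg)))
        seg = _realign_batch(amp[:, None] * wave + rng.normal(0.0, noise_sigma, (k, _LONG)))
        ok = _aligned(seg)
        out[todo[ok]] = seg[ok]
        todo = todo[~ok]
    return out


def _type2_batch(bank: np.ndarray, n: int, noise_sigma: float, rng,
                 amp_range_sigma: tuple[float, float] = (1.0, 3.16),
                 snr_threshold: float = SNR_THRESHOLD) -> np.ndarray:
    shapes = bank / -bank.min(axis=1, keepdims=True)  # unit negative peak
    out = np.empty((n, SEGMENT_LEN))
    todo = np.arange(n)
    while todo.size:
        amp = noise_sigma * rng.uniform(*amp_range_sigma, todo.size)
        long = rng.normal(0.0, noise_sigma, (todo.size, _LONG))
        long[:, PEAK_INDEX:PEAK_INDEX + SEGMENT_LEN] += \
            amp[:, None] * shapes[rng.integers(shapes.shape[0], size=todo.size)]
        seg = _realign_batch(long)
        ok = (np.abs(seg[:, PEAK_INDEX]) / noise_sigma < snr_threshold) & _aligned(seg)
        out[todo[ok]] = seg[ok]
        todo = todo[~ok]
    return out


#: evaluation-set class mix: ~25% of detected events are non-neural,
#: split evenly between artifact and low-SNR contamination
DEFAULT_COMPOSITION = (0.75, 0.125, 0.125)
NEURAL_NOISE_SIGMA = 10.0
TYPE2_NOISE_SIGMA = 30.0


def make_event_dataset(n_events: int, seed: int,
                       composition: tuple[float, float, float] = DEFAULT_COMPOSITION,
                       n_templates: int = 20,
                       neural_sigma: float = NEURAL_NOISE_SIGMA,
                       type2_sigma: float = TYPE2_NOISE_SIGMA,
                       snr_threshold: float = SNR_THRESHOLD,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """A labeled evaluation set of peak-aligned event segments.

    Returns ``(segments, labels)`` with segments of shape (n_events, 90)
    and labels an array of :class:`EventLabel`.  The three classes are
    generated from a template bank seeded by ``seed`` (use a different seed
    than the training set so evaluation templates are unseen).
    """
    if abs(sum(composition) - 1.0) > 1e-9 or min(composition) < 0:
        raise ValueError("composition must be non-negative and sum to 1")
    rng = np.random.default_rng([seed, 1])
    bank = np.asarray([t.waveform for t in make_template_bank(n_templates, seed)])
    n_n = round(n_events * composition[0])
    n_1 = round(n_events * composition[1])
    n_2 = n_events - n_n - n_1
    segs = np.concatenate([
        _neural_batch(bank, n_n, neural_sigma, rng, snr_threshold),
        _type1_batch(n_1, neural_sigma, rng),
        _type2_batch(bank, n_2, type2_sigma, rng, snr_threshold=snr_threshold),
    ])
    labels = np.asarray([EventLabel.NEURAL] * n_n + [EventLabel.TYPE1] * n_1
                        + [EventLabel.TYPE2] * n_2, dtype=object)
    order = rng.permutation(n_events)
    return segs[order], labels[order]


def make_training_set(n_segments: int, seed: int, n_templates: int = 40,
                      noise_sigma: float = NEURAL_NOISE_SIGMA) -> np.ndarray:
    """Clean neural spike segments for autoencoder training (no contaminants)."""
    rng = np.random.default_rng([seed, 2])
    bank = np.asarray([t.waveform for t in make_template_bank(n_templates, seed)])
    return _neural_batch(bank, n_segments, noise_sigma, rng)


# ---------------------------------------------------------------------------
# whole recordings

@dataclass
class SimConfig:
    """Conditions for a simulated multichannel recording.

    Defaults mirror the training regime: a tetrode-like probe, 30 kHz, 10 uV
    Gaussian background noise, Poisson firing with a 2.5 ms refractory gap,
    and a 10% / 10% admixture of Type I and Type II events.
    """

    n_channels: int = 4
    duration: float = 60.0
    sampling_rate: float = TARGET_RATE
    noise_sigma: float = 10.0
    firing_rate: float = 5.0
    n_cells: int = 20
    refractory: float = 0.0025
    type1_fraction: float = 0.10
    type2_fraction: float = 0.10
    seed: int = 0
    snr_threshold: float = SNR_THRESHOLD

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for f in (self.type1_fraction, self.type2_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.type1_fraction + self.type2_fraction > 1.0:
            raise ValueError("contaminant fractions must sum to <= 1")


@dataclass
class LabeledRecording:
    samples: np.ndarray  # channels x time, uV
    sampling_rate: float
    true_events: list[tuple[float, int, EventLabel, int]] = field(default_factory=list)
    true_units: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = self.samples.shape[1] / self.sampling_rate
        for t, ch, _, _ in self.true_events:
            if not 0.0 <= t < T:
                raise ValueError(f"event time {t} outside recording of {T} s")
        for tid, times in self.true_units.items():
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"unit {tid} spike times not strictly increasing")


def assemble_recording(config: SimConfig) -> LabeledRecording:
    """Synthesize a labeled recording: noise + spikes + contaminant events.

    Each cell's template is inserted peak-aligned on its home channel at
    every spike time.  Type I artifacts and Type II (low-SNR, remote-source)
    spikes are placed at uniform random times on random channels in the
    configured proportions of the total event count.  Overlaps are allowed,
    as in real data.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 3])
    fs = cfg.sampling_rate
    T = int(round(cfg.duration * fs))
    samples = rng.normal(0.0, cfg.noise_sigma, (cfg.n_channels, T))
    margin = PEAK_INDEX / fs
    sigma = cfg.noise_sigma

    bank = make_template_bank(cfg.n_cells, cfg.seed,
                              amp_range=(10.0 * sigma, 25.0 * sigma))
    events: list[tuple[float, int, EventLabel, int]] = []
    units: dict[int, np.ndarray] = {}

    def insert(ch: int, time_s: float, wave: np.ndarray) -> bool:
        idx = int(round(time_s * fs))
        lo, hi = idx - PEAK_INDEX, idx + SEGMENT_LEN - PEAK_INDEX
        if lo < 0 or hi > T:
            return False
        samples[ch, lo:hi] += wave
        return True

    for tid, tpl in enumerate(bank):
        train_times = poisson_train(cfg.firing_rate, cfg.duration - 2 * margin,
                                    cfg.refractory, seed=rng.integers(2 ** 31)) + margin
        kept = [t for t in train_times if insert(tid % cfg.n_channels, t, tpl.waveform)]
        units[tid] = np.asarray(kept)
        events += [(t, tid % cfg.n_channels, EventLabel.NEURAL, tid) for t in kept]

    n_neural = len(events)
    neural_frac = 1.0 - cfg.type1_fraction - cfg.type2_fraction
    total = n_neural / neural_frac if neural_frac > 0 else 0.0
    n_1 = round(total * cfg.type1_fraction)
    n_2 = round(total * cfg.type2_fraction)

    t_seg = np.arange(SEGMENT_LEN) / TARGET_RATE
    for _ in range(n_1):
        ch = int(rng.integers(cfg.n_channels))
        time_s = rng.uniform(margin, cfg.duration - margin)
        kind = ArtifactKind(list(ArtifactKind)[rng.integers(3)])
        wave = sigma * rng.uniform(2.0, 10.0) * _periodic_wave(
            kind, 2 * np.pi * rng.uniform(300.0, 3000.0) * t_seg + rng.uniform(0, 2 * np.pi))
        if insert(ch, time_s, wave):
            events.append((time_s, ch, EventLabel.TYPE1, -1))

    shapes = np.asarray([t.waveform / t.amplitude for t in bank])
    for _ in range(n_2):
        ch = int(rng.integers(cfg.n_channels))
        time_s = rng.uniform(margin, cfg.duration - margin)
        amp = sigma * rng.uniform(1.0, 0.95 * cfg.snr_threshold)
        if insert(ch, time_s, amp * shapes[rng.integers(cfg.n_cells)]):
            events.append((time_s, ch, EventLabel.TYPE2, -1))

    occupancy = (n_neural + n_1 + n_2) * SEGMENT_LEN / (cfg.n_channels * T)
    if occupancy > 0.5:
        warnings.warn(f"event density high (occupancy {occupancy:.0%}); many overlaps expected")

    events.sort(key=lambda e: e[0])
    return LabeledRecording(samples, fs, events, units)


# ---------------------------------------------------------------------------
# labeled sorted units

@dataclass
class SyntheticUnitSpec:
    """Recipe for one labeled sorted unit used in triage experiments."""

    n_events: int
    neural_fraction: float
    contaminant_kinds: tuple[EventLabel, ...] = (EventLabel.TYPE1, EventLabel.TYPE2)
    seed: int = 0
    unit_rate: float = 10.0  # Hz; sets the unit's nominal duration
    burst_size: int = 4      # contaminant events arrive in bursts
    burst_jitter: float = 0.002  # s, half-width of a burst

    def __post_init__(self) -> None:
        if not 0.0 <= self.neural_fraction <= 1.0:
            raise ValueError("neural_fraction must lie in [0, 1]")
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")


def build_labeled_units(spec: SyntheticUnitSpec,
                        templates: list[SpikeTemplate],
                        unit_id: int = 0) -> tuple[SortedUnit, np.ndarray]:
    """One sorted unit with ground-truth event labels.

    Neural spikes fire as a refractory Poisson process, so a pure unit has
    no ISI violations.  Contaminants arrive in short bursts (clustered
    interference), drawn 2:1 Type I : Type II when both kinds are allowed,
    which reproduces the very high pairwise ISI-violation rates of
    artifact-dominated units.  Returns the unit and its label array.
    """
    n_neural = round(spec.n_events * spec.neural_fraction)
    n_cont = spec.n_events - n_neural
    if n_neural > 0 and not templates:
        raise ValueError("need templates to build neural events")
    if n_cont > 0 and not spec.contaminant_kinds:
        raise ValueError("need contaminant kinds to build contaminant events")
    rng = np.random.default_rng([spec.seed, 4])
    duration = spec.n_events / spec.unit_rate

    # neural spike times: refractory-gapped exponential intervals
    refractory = 0.0025
    if n_neural:
        mean_gap = max(duration / n_neural - refractory, 1e-4)
        t_neural = np.cumsum(refractory + rng.exponential(mean_gap, n_neural))
    else:
        t_neural = np.empty(0)

    if n_cont:
        n_bursts = int(np.ceil(n_cont / spec.burst_size))
        centres = rng.uniform(0.0, duration, n_bursts)
        t_cont = np.sort((np.repeat(centres, spec.burst_size)
                          + rng.uniform(-spec.burst_jitter, spec.burst_jitter,
                                        n_bursts * spec.burst_size))[:n_cont])
        t_cont = np.clip(t_cont, 0.0, duration)
    else:
        t_cont = np.empty(0)

    bank = np.asarray([t.waveform for t in templates]) if templates else np.empty((0, SEGMENT_LEN))
    seg_neural = _neural_batch(bank, n_neural, NEURAL_NOISE_SIGMA, rng) if n_neural else \
        np.empty((0, SEGMENT_LEN))

    kinds = list(spec.contaminant_kinds)
    if kinds == [EventLabel.TYPE1, EventLabel.TYPE2] or kinds == [EventLabel.TYPE2, EventLabel.TYPE1]:
        cont_labels = rng.choice(np.asarray([EventLabel.TYPE1, EventLabel.TYPE2],
                                            dtype=object), size=n_cont, p=[2 / 3, 1 / 3])
    else:
        cont_labels = np.asarray([kinds[0]] * n_cont, dtype=object) if n_cont else \
            np.empty(0, dtype=object)
    seg_cont = np.empty((n_cont, SEGMENT_LEN))
    is1 = cont_labels == EventLabel.TYPE1
    if np.any(is1):
        seg_cont[is1] = _type1_batch(int(is1.sum()), NEURAL_NOISE_SIGMA, rng)
    if np.any(~is1) and n_cont:
        seg_cont[~is1] = _type2_batch(bank if bank.size else
                                      np.asarray([make_template(0, 60.0, 0.5).waveform]),
                                      int((~is1).sum()), TYPE2_NOISE_SIGMA, rng)

    times = np.concatenate([t_neural, t_cont])
    segs = np.concatenate([seg_neural, seg_cont])
    labels = np.concatenate([np.asarray([EventLabel.NEURAL] * n_neural, dtype=object),
                             cont_labels]) if spec.n_events else np.empty(0, dtype=object)
    order = np.argsort(times, kind="stable")
    # break exact ties so unit times are strictly increasing
    times = times[order]
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 1e-6
    return SortedUnit(unit_id, times, segs[order]), labels[order]
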