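"""Generator invariants: template geometry, trains, event classes, recordings."""

import numpy as np
import pytest

import aecurate as ac
from aecurate.preprocess import PEAK_INDEX, SEGMENT_LEN
from aecurate.synthgen import EventLabel, SNR_THRESHOLD, snr_threshold_from_db


@pytest.mark.parametrize("tid,amp,width", [(0, 60.0, 0.6), (3, 40.0, 0.6),
                                           (7, 180.0, 0.25), (2, 95.0, 1.4)])
def test_template_geometry(tid, amp, width):
    tpl = ac.make_template(tid, amp, width, seed=1)
    w = tpl.waveform
    assert w.shape == (SEGMENT_LEN,)
    assert np.argmin(w) == PEAK_INDEX
    assert np.isclose(w[PEAK_INDEX], -amp)
    # tri-phasic: positive deflection before the trough, repolarization after
    assert w[:PEAK_INDEX].max() > 0
    assert w[PEAK_INDEX + 1:].max() > 0
    # endpoints decay toward zero
    assert abs(w[0]) < 0.1 * amp and abs(w[-1]) < 0.1 * amp


def test_template_determinism_and_distinctness():
    a = ac.make_template(0, 60, 0.6, seed=1).waveform
    b = ac.make_template(0, 60, 0.6, seed=1).waveform
    np.testing.assert_array_equal(a, b)
    c = ac.make_template(3, 40, 0.6, seed=1).waveform
    assert np.corrcoef(a, c)[0, 1] < 0.99


def test_template_bank_diversity():
    bank = np.asarray([t.waveform for t in ac.make_template_bank(20, seed=1)])
    corr = np.corrcoef(bank)
    mean_offdiag = corr[np.triu_indices(20, 1)].mean()
    assert mean_offdiag < 0.9


def test_template_rejects_bad_parameters():
    with pytest.raises(ValueError):
        ac.make_template(0, -5.0, 0.6)
    with pytest.raises(ValueError):
        ac.make_template(0, 50.0, 0.1)


def test_poisson_train_contract():
    assert ac.poisson_train(0.0, 60.0, 0.002, seed=0).size == 0
    with pytest.raises(ValueError):
        ac.poisson_train(-1.0, 60.0)
    counts = []
    for seed in range(100):
        t = ac.poisson_train(5.0, 60.0, 0.002, seed=seed)
        assert np.all(t >= 0) and np.all(t < 60.0)
        if t.size > 1:
            assert np.diff(t).min() >= 0.002
        counts.append(t.size)
    # Poisson tail bound around rate * duration
    assert abs(np.mean(counts) - 300) < 4 * np.sqrt(300) / np.sqrt(100) + 3


def test_type1_event_shapes():
    sine = ac.make_type1_event("SINE", 1000.0, 50.0, 0.0, seed=0)
    assert sine.shape == (SEGMENT_LEN,)
    assert sine.max() == pytest.approx(50.0, rel=0.01)  # 3 full cycles over 3 ms
    assert np.isclose(sine[0], 0.0)
    square = ac.make_type1_event("SQUARE", 500.0, 50.0, 0.0, seed=0)
    assert set(np.round(np.abs(square), 9)) == {50.0}
    a = ac.make_type1_event("SAWTOOTH", 700.0, 40.0, 10.0, seed=2)
    b = ac.make_type1_event("SAWTOOTH", 700.0, 40.0, 10.0, seed=2)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        ac.make_type1_event("TRIANGLE", 700.0, 40.0, 10.0)


def test_type2_event_snr_bound(template_bank):
    big = ac.make_template(99, 400.0, 0.5, seed=0)
    seg = ac.make_type2_event(big, 30.0, seed=0)
    assert abs(seg[PEAK_INDEX]) / 30.0 < SNR_THRESHOLD  # attenuated to fit
    with pytest.raises(ValueError):
        ac.make_type2_event(template_bank[0], 0.0)
    for i in range(1000):
        tpl = template_bank[i % len(template_bank)]
        seg = ac.make_type2_event(tpl, 30.0, seed=i)
        assert ac.snr(seg, 30.0) < SNR_THRESHOLD


def test_snr_threshold_db_reading():
    assert snr_threshold_from_db(10.0) == pytest.approx(3.1623, rel=1e-3)


def test_event_dataset_composition_and_consistency():
    X, y = ac.make_event_dataset(2000, seed=5)
    assert X.shape == (2000, SEGMENT_LEN)
    counts = {k: int(np.sum(y == k)) for k in
              (EventLabel.NEURAL, EventLabel.TYPE1, EventLabel.TYPE2)}
    assert counts[EventLabel.NEURAL] == 1500
    assert counts[EventLabel.TYPE1] == 250 and counts[EventLabel.TYPE2] == 250
    # label/SNR consistency among spike-shaped events
    for seg in X[y == EventLabel.NEURAL]:
        assert ac.snr(seg, 10.0) >= SNR_THRESHOLD
    for seg in X[y == EventLabel.TYPE2]:
        assert ac.snr(seg, 30.0) < SNR_THRESHOLD
    # all segments are abs-max aligned
    assert np.all(np.abs(X[:, PEAK_INDEX]) == np.abs(X).max(axis=1))
    X2, y2 = ac.make_event_dataset(2000, seed=5)
    np.testing.assert_array_equal(X, X2)
    assert all(a == b for a, b in zip(y, y2))


def test_empty_recording_is_pure_noise():
    cfg = ac.SimConfig(n_cells=0, type1_fraction=0.0, type2_fraction=0.0,
                       duration=5.0, seed=1)
    rec = ac.assemble_recording(cfg)
    assert len(rec.true_events) == 0
    assert rec.samples.std() == pytest.approx(10.0, rel=0.02)


def test_recording_noise_floor_and_labels():
    cfg = ac.SimConfig(duration=20.0, n_cells=10, seed=0)
    rec = ac.assemble_recording(cfg)
    assert len(rec.true_events) > 500
    # mask out event windows, check the background std per channel
    fs = rec.sampling_rate
    mask = np.ones(rec.samples.shape, dtype=bool)
    for t, ch, _, _ in rec.true_events:
        idx = int(round(t * fs))
        mask[ch, max(0, idx - 60):idx + 60] = False
    for ch in range(cfg.n_channels):
        assert 9.5 < rec.samples[ch][mask[ch]].std() < 10.5
    # per-unit spike times strictly increasing
    for times in rec.true_units.values():
        if times.size > 1:
            assert np.all(np.diff(times) > 0)


def test_recording_determinism():
    cfg = ac.SimConfig(duration=4.0, n_cells=5, seed=42)
    a = ac.assemble_recording(cfg)
    b = ac.assemble_recording(cfg)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert a.true_events == b.true_events


def test_firing_rate_recovery():
    cfg = ac.SimConfig(duration=30.0, n_cells=3, firing_rate=5.0, seed=7,
                       type1_fraction=0.0, type2_fraction=0.0)
    rates = []
    for seed in range(20):
        cfg.seed = seed
        rec = ac.assemble_recording(cfg)
        rates += [times.size / cfg.duration for times in rec.true_units.values()]
    se = np.std(rates) / np.sqrt(len(rates))
    assert abs(np.mean(rates) - 5.0) < 3 * se + 0.15


@pytest.mark.parametrize("n,frac", [(100, 0.96), (10, 0.0), (200, 0.7)])
def test_build_labeled_units_composition(n, frac, template_bank):
    spec = ac.SyntheticUnitSpec(n_events=n, neural_fraction=frac, seed=9)
    unit, labels = ac.build_labeled_units(spec, template_bank)
    assert unit.n_events == n
    assert int(np.sum(labels == EventLabel.NEURAL)) == round(n * frac)
    assert np.all(np.diff(unit.event_times) > 0)
    unit2, labels2 = ac.build_labeled_units(spec, template_bank)
    np.testing.assert_array_equal(unit.event_times, unit2.event_times)
    np.testing.assert_array_equal(unit.segments, unit2.segments)


def test_build_labeled_units_requires_templates():
    with pytest.raises(ValueError):
        ac.build_labeled_units(ac.SyntheticUnitSpec(50, 0.5), [])
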