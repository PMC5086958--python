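"""Preprocessing chain: interpolation, reference, filters, ICA, epoching."""
import numpy as np
import pytest

from tmseeg.containers import ContinuousEEG, EpochedEEG
from tmseeg.preprocess import (ICACriteria, bandpass_filter, epoch,
                               interpolate_tms_artifact, notch_filter,
                               preprocess_continuous, reject_epochs,
                               rereference_average, run_ica_cleanup)

SFREQ = 1000.0


def continuous(data, events=(), labels=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return ContinuousEEG(data, SFREQ, labels, list(events))


# ---------------------------------------------------------------------------
# TMS artifact interpolation


def test_cubic_input_is_reproduced_exactly():
    t = np.arange(3000) / SFREQ
    poly = 2.0 - 3.0 * t + 4.0 * t ** 2 - 1.5 * t ** 3
    raw = continuous(np.vstack([poly, 0.5 * poly]), events=[(1500, "TMS")])
    out = interpolate_tms_artifact(raw)
    np.testing.assert_allclose(out.data, raw.data, atol=1e-9)


def test_spike_inside_window_is_replaced_by_the_ramp():
    t = np.arange(3000) / SFREQ
    ramp = 10.0 * t
    spiked = ramp.copy()
    spiked[1500:1508] += 500.0  # artifact inside [0, 10] ms after the pulse
    raw = continuous(spiked[None, :], events=[(1500, "TMS")])
    out = interpolate_tms_artifact(raw)
    np.testing.assert_allclose(out.data[0], ramp, atol=1e-9)


def test_samples_outside_the_window_are_bit_unchanged(rng):
    data = rng.normal(size=(3, 3000))
    raw = continuous(data.copy(), events=[(1500, "TMS")])
    out = interpolate_tms_artifact(raw, window=(-0.001, 0.010))
    lo = 1500 - 1
    hi = 1500 + 10
    assert np.array_equal(out.data[:, :lo], data[:, :lo])
    assert np.array_equal(out.data[:, hi:], data[:, hi:])


def test_window_beyond_the_record_is_an_error(rng):
    epochs = EpochedEEG(rng.normal(size=(2, 3, 2000)), SFREQ, -1.0,
                        ["a", "b", "c"])
    with pytest.raises(ValueError, match="bounds"):
        interpolate_tms_artifact(epochs, window=(-0.5, 1.5))


# ---------------------------------------------------------------------------
# reference


def test_average_reference_worked_example():
    raw = continuous(np.array([[1.0], [2.0], [3.0]]))
    out = rereference_average(raw)
    np.testing.assert_allclose(out.data.ravel(), [-1.0, 0.0, 1.0])


def test_average_reference_is_idempotent_and_zero_mean(rng):
    raw = continuous(rng.normal(size=(31, 1000)))
    once = rereference_average(raw)
    twice = rereference_average(once)
    assert np.abs(once.data.mean(axis=0)).max() < 1e-12
    np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


def test_single_channel_reference_is_an_error():
    with pytest.raises(ValueError, match="2 scalp channels"):
        rereference_average(continuous(np.zeros((1, 10))))


def test_eog_channels_do_not_enter_the_average(rng):
    data = rng.normal(size=(4, 500))
    raw = continuous(data, labels=["a", "b", "c", "EOG1"])
    out = rereference_average(raw)
    assert np.abs(out.data[:3].mean(axis=0)).max() < 1e-12
    np.testing.assert_array_equal(out.data[3], data[3])


# ---------------------------------------------------------------------------
# filters


def sinusoid(freq, seconds=4.0):
    t = np.arange(int(seconds * SFREQ)) / SFREQ
    return np.sin(2 * np.pi * freq * t)[None, :], t


def test_passband_sinusoid_preserved_with_zero_lag():
    x, t = sinusoid(20.0)
    out = bandpass_filter(continuous(x, labels=["a"]))
    mid = slice(500, -500)  # ignore filter edge effects
    amp = out.data[0, mid].max()
    assert 0.95 <= amp <= 1.05
    lag = np.argmax(np.correlate(out.data[0, mid], x[0, mid], "full")) \
        - (x[0, mid].size - 1)
    assert lag == 0


def test_notch_removes_the_line_frequency():
    x, _ = sinusoid(50.0)
    out = notch_filter(continuous(x, labels=["a"]))
    mid = slice(500, -500)
    assert np.sqrt(np.mean(out.data[0, mid] ** 2)) \
        < 0.1 * np.sqrt(np.mean(x[0, mid] ** 2))


def test_bandpass_removes_dc_offset():
    raw = continuous(np.full((2, 4000), 10.0))
    out = bandpass_filter(raw)
    assert np.abs(out.data[:, 500:-500].mean()) < 0.5


def test_invalid_band_edges_raise():
    raw = continuous(np.zeros((2, 4000)))
    with pytest.raises(ValueError, match="band edges"):
        bandpass_filter(raw, low=1.0, high=600.0)


def test_filter_and_rereference_commute(rng):
    raw = continuous(rng.normal(size=(8, 4000)))
    a = rereference_average(bandpass_filter(raw))
    b = bandpass_filter(rereference_average(raw))
    np.testing.assert_allclose(a.data, b.data, atol=1e-9)


# ---------------------------------------------------------------------------
# epoching and rejection


def test_one_epoch_per_marker_with_the_study_trial_count(rng):
    n = 80
    sfreq = 250.0
    markers = [int(sfreq * (1.5 + 2.5 * k)) for k in range(n)]
    raw = ContinuousEEG(rng.normal(size=(3, int(sfreq * 210))), sfreq,
                        ["a", "b", "c"], [(s, "TMS") for s in markers])
    epochs = epoch(raw, window=(-1.0, 1.0))
    assert epochs.n_trials == n
    assert epochs.n_samples == int(2 * sfreq)
    assert epochs.tmin == pytest.approx(-1.0)


def test_marker_at_the_record_edge_is_an_error(rng):
    raw = ContinuousEEG(rng.normal(size=(2, 1000)), SFREQ, ["a", "b"],
                        [(10, "TMS")])
    with pytest.raises(ValueError, match="edge"):
        epoch(raw, window=(-0.5, 0.5))


def test_planted_excursion_masks_exactly_that_trial(rng):
    data = rng.normal(0, 5.0, size=(6, 3, 500))
    data[2, 1, 100] += 150.0
    epochs = EpochedEEG(data, SFREQ, -0.25, ["a", "b", "c"])
    out = reject_epochs(epochs, amplitude_threshold=100.0)
    assert out.rejection_mask.tolist() == [False, False, True, False, False, False]
    assert out.data.shape == data.shape  # flagged, not deleted


def test_infinite_threshold_masks_nothing(rng):
    epochs = EpochedEEG(rng.normal(size=(5, 2, 100)), SFREQ, -0.05, ["a", "b"])
    out = reject_epochs(epochs, amplitude_threshold=np.inf)
    assert not out.rejection_mask.any()


# ---------------------------------------------------------------------------
# ICA


def _blink_recording(rng, n_ch=8, n_s=8_000):
    """Clean rhythmic sources plus one stereotyped blink source."""
    t = np.arange(n_s) / SFREQ
    sources = np.vstack([np.sin(2 * np.pi * f * t + p)
                         for f, p in [(9.0, 0.1), (17.0, 1.2), (5.0, 2.0)]])
    blink = np.zeros(n_s)
    for t0 in np.arange(0.8, n_s / SFREQ - 0.8, 1.1):
        blink += np.exp(-((t - t0) ** 2) / (2 * 0.06 ** 2))
    blink *= 40.0
    mix = rng.normal(size=(n_ch, 3))
    blink_topo = np.linspace(1.5, 0.05, n_ch)  # frontal-dominant projection
    data = mix @ sources + blink_topo[:, None] * blink[None, :]
    data += rng.normal(0, 0.2, size=data.shape)
    eog = 3.0 * blink + rng.normal(0, 0.2, size=n_s)
    labels = [f"ch{i}" for i in range(n_ch)] + ["EOG1"]
    return ContinuousEEG(np.vstack([data, eog]), SFREQ, labels), blink_topo, blink


@pytest.fixture(scope="module")
def blink_case():
    rng = np.random.default_rng(12345)
    raw, blink_topo, blink = _blink_recording(rng)
    cleaned, result = run_ica_cleanup(raw, seed=0)
    return raw, blink, cleaned, result


def test_planted_blink_component_is_detected_and_removed(blink_case):
    raw, blink, cleaned, result = blink_case
    flagged = [c for c in result.classification if c["status"] == "rejected"]
    assert any(c["eog_correlation"] >= 0.7 for c in flagged)
    # frontal blink residual reduced by at least 80 %
    front = raw.data[0] - raw.data[0].mean()
    front_clean = cleaned.data[0] - cleaned.data[0].mean()
    blink_power = lambda x: float(np.dot(x, blink) ** 2 / np.dot(blink, blink))  # noqa: E731
    assert blink_power(front_clean) < 0.2 * blink_power(front)


def test_disabled_criteria_reproduce_the_input(blink_case):
    raw = blink_case[0]
    cleaned, result = run_ica_cleanup(raw, criteria=ICACriteria.disabled(), seed=0)
    assert result.rejected == []
    np.testing.assert_allclose(cleaned.data, raw.data, atol=1e-6)


def test_same_seed_gives_identical_unmixing(blink_case):
    raw = blink_case[0]
    _, r1 = run_ica_cleanup(raw, seed=5)
    _, r2 = run_ica_cleanup(raw, seed=5)
    np.testing.assert_array_equal(r1.unmixing, r2.unmixing)


def test_unmixing_composed_with_mixing_is_identity(blink_case):
    result = blink_case[3]
    ident = result.unmixing @ result.mixing
    np.testing.assert_allclose(ident, np.eye(ident.shape[0]), atol=1e-8)


def test_insufficient_data_for_ica_is_an_error(rng):
    raw = continuous(rng.normal(size=(10, 50)))
    with pytest.raises(ValueError, match="insufficient"):
        run_ica_cleanup(raw, seed=0)


# ---------------------------------------------------------------------------
# stage order


def test_noncanonical_stage_order_is_refused(rng):
    raw = continuous(rng.normal(size=(4, 8000)), events=[(4000, "TMS")])
    with pytest.raises(ValueError, match="canonical"):
        preprocess_continuous(raw, stage_order=("rereference", "interpolate",
                                                "bandpass", "notch", "ica",
                                                "epoch", "reject"),
                              run_ica=False)


def test_full_chain_produces_clean_epochs_with_provenance(rng):
    sfreq = 500.0
    n = 8
    markers = [int(sfreq * (1.5 + 2.5 * k)) for k in range(n)]
    data = rng.normal(0, 3.0, size=(6, int(sfreq * 25)))
    data += 2.0 * np.sin(2 * np.pi * 50.0 * np.arange(data.shape[1]) / sfreq)
    raw = ContinuousEEG(data, sfreq, [f"ch{i}" for i in range(6)],
                        [(s, "TMS") for s in markers])
    epochs, _ = preprocess_continuous(raw, epoch_window=(-1.0, 1.0),
                                      run_ica=False)
    assert epochs.n_trials == n
    stages = [p["stage"] for p in epochs.provenance]
    assert stages == ["interpolate", "rereference", "bandpass", "notch",
                      "epoch", "reject"]
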