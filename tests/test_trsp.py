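"""Morlet TRSP: wavelet power, baseline normalization, band averaging, ANOVA."""
import numpy as np
import pandas as pd
import pytest

from tmseeg.containers import EpochedEEG
from tmseeg.trsp import (BANDS, TimeFrequencyRepresentation, WaveletParams,
                         _trial_mean_power, band_bins, band_roi_average,
                         baseline_normalize, morlet_power, trsp_anova,
                         trsp_difference_anova)

SFREQ = 1000.0
N_S = 2000
PARAMS = WaveletParams()


def epochs_from(data, labels=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[1])]
    return EpochedEEG(data, SFREQ, -1.0, labels)


def test_frequency_grid_is_23_linear_steps_from_4_to_50():
    f = PARAMS.frequencies
    assert f.size == 23
    assert f[0] == 4.0 and f[-1] == 50.0
    assert np.allclose(np.diff(f), np.diff(f)[0])


def test_zero_signal_gives_zero_power():
    tfr = morlet_power(epochs_from(np.zeros((3, 2, N_S))))
    np.testing.assert_allclose(tfr.power, 0.0, atol=1e-20)


def test_sinusoid_peaks_at_the_nearest_frequency_bin():
    t = np.arange(N_S) / SFREQ - 1.0
    x = np.sin(2 * np.pi * 10.0 * t)
    tfr = morlet_power(epochs_from(np.tile(x, (2, 1, 1))))
    interior = tfr.valid_mask.all(axis=0)
    peak_bins = tfr.power[0, :, interior].argmax(axis=1)
    nearest = np.abs(PARAMS.frequencies - 10.0).argmin()
    assert (peak_bins == nearest).mean() > 0.99
    # power at the peak bin is near-constant over interior time
    trace = tfr.power[0, nearest, interior]
    assert trace.std() / trace.mean() < 0.05


def test_power_scales_quadratically_with_amplitude(rng):
    data = rng.normal(size=(3, 2, N_S))
    p1 = morlet_power(epochs_from(data)).power
    p2 = morlet_power(epochs_from(2.0 * data)).power
    np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-10)


def test_trial_order_does_not_change_trsp(rng):
    data = rng.normal(size=(6, 2, N_S))
    p1 = morlet_power(epochs_from(data)).power
    p2 = morlet_power(epochs_from(data[::-1])).power
    np.testing.assert_allclose(p1, p2, rtol=1e-12)


def test_masked_trials_are_excluded(rng):
    data = rng.normal(size=(4, 1, N_S))
    ep = epochs_from(data)
    ep.rejection_mask[2] = True
    p = morlet_power(ep).power
    ref = morlet_power(epochs_from(data[[0, 1, 3]])).power
    np.testing.assert_allclose(p, ref)


def test_short_epoch_is_rejected(rng):
    with pytest.raises(ValueError, match="support"):
        morlet_power(epochs_from(rng.normal(size=(2, 1, 600))))


def test_matches_mne_tfr_array_morlet(rng):
    from mne.time_frequency import tfr_array_morlet

    data = rng.normal(size=(3, 2, N_S))
    ours = morlet_power(epochs_from(data)).power
    ref = tfr_array_morlet(data, sfreq=SFREQ, freqs=PARAMS.frequencies,
                           n_cycles=3.5, output="power",
                           zero_mean=True).mean(axis=0)
    np.testing.assert_allclose(ours, ref, rtol=1e-10)


def test_power_of_well_separated_components_is_additive():
    t = np.arange(N_S) / SFREQ - 1.0
    f_low, f_high = PARAMS.frequencies[1], PARAMS.frequencies[17]
    s1 = np.sin(2 * np.pi * f_low * t)
    s2 = np.sin(2 * np.pi * f_high * t + 0.3)
    p1 = morlet_power(epochs_from(s1[None, None, :])).power
    p2 = morlet_power(epochs_from(s2[None, None, :])).power
    p12 = morlet_power(epochs_from((s1 + s2)[None, None, :])).power
    tfr = morlet_power(epochs_from(s1[None, None, :]))
    interior = tfr.valid_mask.all(axis=0)
    for b in (1, 17):
        np.testing.assert_allclose(p12[0, b, interior],
                                   (p1 + p2)[0, b, interior], rtol=0.05)


def test_half_power_bandwidth_scales_with_frequency():
    """Constant cycles: spectral width grows proportionally to f."""
    t = np.arange(N_S) / SFREQ - 1.0
    widths = {}
    for f0 in (6.0, 20.0, 40.0):
        probe = np.linspace(0.5 * f0, 1.5 * f0, 81)
        x = np.sin(2 * np.pi * f0 * t)[None, None, :]
        power = _trial_mean_power(x, SFREQ, probe, 3.5)[0, :, 900:1100].mean(axis=1)
        above = probe[power >= 0.5 * power.max()]
        widths[f0] = above.max() - above.min()
    assert widths[20.0] / widths[6.0] == pytest.approx(20.0 / 6.0, rel=0.2)
    assert widths[40.0] / widths[20.0] == pytest.approx(2.0, rel=0.2)


# ---------------------------------------------------------------------------
# baseline normalization


def test_baseline_mean_is_exactly_zero_after_normalization(rng):
    tfr = morlet_power(epochs_from(rng.normal(size=(3, 2, N_S))))
    out = baseline_normalize(tfr, (-0.55, -0.15))
    idx = out.time_indices((-0.55, -0.15))
    np.testing.assert_allclose(out.power[:, :, idx].mean(axis=2), 0.0, atol=1e-10)
    assert out.normalized


def test_stationary_noise_normalizes_to_near_zero_post_stimulus(rng):
    """Mean normalized power over post-stimulus time ~ 0 across blocks."""
    means = []
    for _ in range(30):
        tfr = morlet_power(epochs_from(rng.normal(size=(8, 1, N_S))))
        out = baseline_normalize(tfr)
        idx = out.time_indices((0.01, 0.30))
        means.append(out.power[:, :, idx].mean())
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means)) < 3 * se + 1e-3


def test_planted_burst_raises_only_the_beta_band(rng):
    t = np.arange(N_S) / SFREQ - 1.0
    burst_env = np.exp(-((t - 0.15) ** 2) / (2 * 0.05 ** 2))
    data = rng.normal(0, 0.5, size=(20, 1, N_S))
    data[:, 0, :] += 3.0 * burst_env * np.cos(
        2 * np.pi * 20.0 * t + rng.uniform(0, 2 * np.pi, 20)[:, None])
    out = baseline_normalize(morlet_power(epochs_from(data)))
    values = band_roi_average(out, ["ch0"], (0.01, 0.30))
    assert values["beta"] > 10 * max(abs(values["theta"]), abs(values["gamma"]))
    assert values["beta"] > 0


def test_post_stimulus_baseline_window_is_refused(rng):
    tfr = morlet_power(epochs_from(rng.normal(size=(2, 1, N_S))))
    with pytest.raises(ValueError, match="before the TMS pulse"):
        baseline_normalize(tfr, (-0.2, 0.2))


def test_baseline_overlapping_edge_invalid_samples_is_refused(rng):
    tfr = morlet_power(epochs_from(rng.normal(size=(2, 1, N_S))))
    with pytest.raises(ValueError, match="edge-invalid"):
        baseline_normalize(tfr, (-0.95, -0.55))


# ---------------------------------------------------------------------------
# band averaging


def uniform_tfr(value_fn):
    freqs = PARAMS.frequencies
    times = np.arange(N_S) / SFREQ - 1.0
    power = np.zeros((2, freqs.size, times.size))
    for i, f in enumerate(freqs):
        power[:, i, :] = value_fn(f)
    return TimeFrequencyRepresentation(
        power, freqs, times, ["ch0", "ch1"],
        np.ones((freqs.size, times.size), bool), normalized=True,
        baseline_window=(-0.5, -0.2))


def test_uniform_power_gives_unit_band_values():
    tfr = uniform_tfr(lambda f: 1.0)
    values = band_roi_average(tfr, ["ch0", "ch1"])
    assert all(v == pytest.approx(1.0) for v in values.values())


def test_alpha_indicator_lands_only_in_alpha():
    tfr = uniform_tfr(lambda f: 1.0 if 7.0 <= f <= 13.0 else 0.0)
    values = band_roi_average(tfr, ["ch0", "ch1"])
    assert values["alpha"] == pytest.approx(1.0)
    assert values["theta"] == values["beta"] == values["gamma"] == 0.0


def test_two_channel_roi_averages_the_channels():
    tfr = uniform_tfr(lambda f: 1.0)
    tfr.power[0] *= 2.0  # ch0 = 2, ch1 = 1... then (2+4)/2 = 3 with ch1*4
    tfr.power[1] *= 4.0
    values = band_roi_average(tfr, ["ch0", "ch1"])
    assert values["theta"] == pytest.approx(3.0)


def test_theta_alpha_gap_bins_belong_to_neither():
    freqs = PARAMS.frequencies
    in_gap = (freqs > 6.0) & (freqs < 7.0)
    assert in_gap.sum() >= 1  # the printed integer edges leave a 6-7 Hz gap
    for band in BANDS.values():
        assert not np.any(in_gap[band_bins(freqs, band)])


def test_unnormalized_tfr_is_refused_for_band_averaging(rng):
    tfr = morlet_power(epochs_from(rng.normal(size=(2, 1, N_S))))
    with pytest.raises(ValueError, match="normalized"):
        band_roi_average(tfr, ["ch0"])


# ---------------------------------------------------------------------------
# ANOVA wrappers


def band_table(rng, effect=0.0):
    rows = []
    for s in range(8):
        base = rng.normal(0, 1)
        for cond in ("cTBS", "iTBS"):
            for phase in ("pre", "post"):
                for band in ("theta", "alpha", "beta", "gamma"):
                    val = base + rng.normal(0, 1)
                    if cond == "cTBS" and phase == "post" and band == "alpha":
                        val -= effect
                    rows.append((f"s{s}", cond, phase, band, val))
    return pd.DataFrame(rows, columns=["subject", "condition", "phase",
                                       "band", "value"])


def test_trsp_anova_reports_the_three_way_interaction(rng):
    res = trsp_anova(band_table(rng, effect=3.0))
    assert "condition x phase x band" in res.effects
    assert res.effects["condition x phase x band"].p < 0.05
    assert res.posthoc is not None
    cell = res.posthoc[(res.posthoc["tbs"] == "cTBS")
                       & (res.posthoc["band"] == "alpha")]
    assert len(cell) == 1


def test_difference_anova_interaction_matches_three_way(rng):
    """Collapsing time to post-pre reproduces the TBS x band interaction F."""
    table = band_table(rng, effect=2.0)
    three = trsp_anova(table, posthoc=False)
    diff = trsp_difference_anova(table, posthoc=False)
    assert diff.effects["condition x band"].F == pytest.approx(
        three.effects["condition x phase x band"].F)


def test_subject_relabeling_leaves_f_unchanged(rng):
    table = band_table(rng, effect=1.0)
    relabeled = table.copy()
    mapping = {f"s{i}": f"z{7 - i}" for i in range(8)}
    relabeled["subject"] = relabeled["subject"].map(mapping)
    f1 = trsp_anova(table, posthoc=False).effects["condition x phase x band"].F
    f2 = trsp_anova(relabeled, posthoc=False).effects["condition x phase x band"].F
    assert f1 == pytest.approx(f2)
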