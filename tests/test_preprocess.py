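"""Unit and property tests for the deterministic cleaning chain."""

import numpy as np
import pytest

from icf_histology.preprocess import (
    EpochSet,
    PreprocessParams,
    baseline_correct,
    channel_variability_scores,
    detect_bad_channels,
    excise_and_interpolate,
    filter_and_resample,
    interpolate_bad_channels,
    reject_epochs,
    rereference_average,
    run_preprocessing,
)

from conftest import make_epochs, noise_epochs


# ---------------------------------------------------------------------------
# EpochSet invariants
# ---------------------------------------------------------------------------


def test_epochset_validation():
    with pytest.raises(ValueError):
        EpochSet(
            data=np.zeros((2, 3)),  # not 3-D
            ch_names=["A", "B", "C"],
            sfreq=1.0,
            times=np.arange(3.0),
        )
    eps = make_epochs(np.zeros((2, 3, 10)))
    assert eps.n_trials == 2 and eps.n_channels == 3
    with pytest.raises(ValueError):
        EpochSet(
            data=np.zeros((1, 2, 3)),
            ch_names=["A", "B"],
            sfreq=1.0,
            times=np.array([0.0, 0.0, 1.0]),  # not strictly increasing
        )


def test_time_mask_inclusive():
    eps = make_epochs(np.zeros((1, 2, 11)), sfreq=1000.0, t0=0.0)
    mask = eps.time_mask((2.0, 5.0))
    assert list(eps.times[mask]) == [2.0, 3.0, 4.0, 5.0]


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------


def test_baseline_constant_channel_becomes_zero():
    eps = make_epochs(5.0 * np.ones((2, 3, 801)))
    out = baseline_correct(eps)
    assert np.allclose(out.data, 0.0)


def test_baseline_offset_removed_signal_kept():
    rng = np.random.default_rng(0)
    sig = rng.standard_normal((1, 2, 801))
    eps = make_epochs(sig + 10.0)
    out = baseline_correct(eps)
    mask = out.time_mask((-500.0, -150.0))
    base_mean = sig[:, :, mask].mean(axis=2, keepdims=True)
    assert np.allclose(out.data, sig - base_mean)


def test_baseline_mean_below_tolerance_random():
    rng = np.random.default_rng(1)
    out = baseline_correct(noise_epochs(rng))
    mask = out.time_mask((-500.0, -150.0))
    assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-9


def test_baseline_empty_window_raises():
    eps = make_epochs(np.zeros((1, 2, 100)), t0=0.0)
    with pytest.raises(ValueError):
        baseline_correct(eps, (-500.0, -150.0))


# ---------------------------------------------------------------------------
# bad channel detection
# ---------------------------------------------------------------------------


def test_scaled_channel_flagged():
    rng = np.random.default_rng(2)
    eps = noise_epochs(rng, n_channels=16)
    i = eps.ch_index("Fpz")  # unprotected
    eps.data[:, i, :] *= 50.0
    _, flagged = detect_bad_channels(eps)
    assert flagged == ["Fpz"]


def test_protected_channel_never_flagged():
    rng = np.random.default_rng(3)
    eps = noise_epochs(rng, n_channels=16)
    eps.data[:, eps.ch_index("F3"), :] *= 50.0
    _, flagged = detect_bad_channels(eps)
    assert flagged == []


def test_homogeneous_channels_rarely_flagged():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        eps = noise_epochs(rng, n_trials=8, n_channels=16, n_t=801)
        _, flagged = detect_bad_channels(eps)
        hits += bool(flagged)
    assert hits <= 1  # empty list in >= 99% of seeded runs


def test_metric_options():
    rng = np.random.default_rng(4)
    eps = noise_epochs(rng)
    for metric in ("mad", "sd", "variance", "ptp"):
        z = channel_variability_scores(eps, metric)
        assert z.shape == (eps.n_channels,)
    with pytest.raises(ValueError):
        channel_variability_scores(eps, "kurtosis")


def test_all_unprotected_flagged_raises():
    # a median-centred score cannot put every channel above its own median,
    # so the corrupt-recording guard is exercised with a threshold below the
    # score range (every unprotected channel exceeds it)
    rng = np.random.default_rng(5)
    eps = noise_epochs(rng, n_channels=8)
    with pytest.raises(RuntimeError):
        detect_bad_channels(eps, z_threshold=-10.0)


# ---------------------------------------------------------------------------
# epoch rejection
# ---------------------------------------------------------------------------


def test_spike_trial_removed():
    rng = np.random.default_rng(6)
    eps = noise_epochs(rng, n_trials=5, sd=5.0)
    t_idx = np.argmin(np.abs(eps.times - 100.0))
    eps.data[2, 0, t_idx] = 1200.0
    out = reject_epochs(eps)
    assert list(out.trial_ids) == [0, 1, 3, 4]
    assert out.log[-1]["removed_trials"] == [2]


def test_subthreshold_trials_kept():
    eps = make_epochs(900.0 * np.ones((4, 3, 801)))
    out = reject_epochs(eps)
    assert out.n_trials == 4


def test_rejection_ignores_excision_window_and_bad_channels():
    rng = np.random.default_rng(7)
    eps = noise_epochs(rng, n_trials=4, sd=5.0)
    # huge transient inside the excision window: not a rejection reason
    t_idx = np.argmin(np.abs(eps.times - 10.0))
    eps.data[1, 2, t_idx] = 5000.0
    # huge value on an already-flagged channel: ignored
    eps.bad_channels = [eps.ch_names[0]]
    eps.data[3, 0, -1] = 5000.0
    out = reject_epochs(eps)
    assert out.n_trials == 4


def test_all_epochs_removed_raises():
    eps = make_epochs(2000.0 * np.ones((2, 3, 801)))
    with pytest.raises(RuntimeError):
        reject_epochs(eps)


# ---------------------------------------------------------------------------
# excision + cubic interpolation
# ---------------------------------------------------------------------------


def test_cubic_polynomial_reconstructed_exactly():
    eps = make_epochs(np.zeros((2, 3, 801)))
    t = eps.times
    for tr in range(2):
        for ch in range(3):
            c = [0.1 * (tr + 1), -0.02 * (ch + 1), 0.5, 3.0]
            eps.data[tr, ch] = np.polyval(c, t / 50.0)
    truth = eps.data.copy()
    out = excise_and_interpolate(eps)
    assert np.abs(out.data - truth).max() < 1e-6


def test_transient_removed_and_outside_untouched():
    rng = np.random.default_rng(8)
    eps = noise_epochs(rng, n_trials=3)
    inside = eps.time_mask((-5.0, 30.0))
    eps.data[:, :, inside] += 5000.0 * np.exp(
        -0.5 * ((eps.times[inside] - 10.0) / 4.0) ** 2
    )
    before = eps.data.copy()
    out = excise_and_interpolate(eps)
    assert np.abs(out.data[:, :, inside]).max() < 100.0
    assert np.array_equal(out.data[:, :, ~inside], before[:, :, ~inside])


def test_excision_at_epoch_edge_raises():
    # only one context sample left of the excision window
    eps = make_epochs(np.zeros((1, 2, 40)), t0=-6.0)
    with pytest.raises(ValueError):
        excise_and_interpolate(eps, (-5.0, 30.0))


# ---------------------------------------------------------------------------
# filtering and resampling
# ---------------------------------------------------------------------------


def test_resample_length_ratio():
    eps = make_epochs(np.zeros((1, 2, 12001)), sfreq=3000.0, t0=-2000.0)
    out = filter_and_resample(eps)
    assert out.sfreq == 1000.0
    assert abs(out.data.shape[2] - 4001) <= 1


# the 0.5 Hz high-pass has a multi-second settling time, so the steady-state
# response tests use a 10 s record and read out the central second only


def test_50hz_attenuated():
    eps = make_epochs(np.zeros((1, 1, 30001)), sfreq=3000.0, t0=-5000.0)
    eps.data[0, 0] = 100.0 * np.sin(2 * np.pi * 50.0 * eps.times / 1000.0)
    out = filter_and_resample(eps)
    central = out.time_mask((-500.0, 500.0))
    assert np.abs(out.data[0, 0, central]).max() < 10.0


def test_10hz_preserved():
    eps = make_epochs(np.zeros((1, 1, 30001)), sfreq=3000.0, t0=-5000.0)
    eps.data[0, 0] = 100.0 * np.sin(2 * np.pi * 10.0 * eps.times / 1000.0)
    out = filter_and_resample(eps)
    central = out.time_mask((-500.0, 500.0))
    peak = np.abs(out.data[0, 0, central]).max()
    assert abs(peak - 100.0) / 100.0 < 0.05


def test_dc_attenuated():
    eps = make_epochs(50.0 * np.ones((1, 1, 30001)), sfreq=3000.0, t0=-5000.0)
    out = filter_and_resample(eps)
    central = out.time_mask((-500.0, 500.0))
    assert np.abs(out.data[0, 0, central]).max() < 5.0


def test_invalid_band_edges():
    eps = make_epochs(np.zeros((1, 1, 3001)), sfreq=3000.0, t0=-1500.0)
    with pytest.raises(ValueError):
        filter_and_resample(eps, bandpass=(0.5, 600.0))
    with pytest.raises(ValueError):
        filter_and_resample(eps, target_rate=6000.0)


def test_filter_marked_non_idempotent_in_log():
    eps = make_epochs(np.zeros((1, 1, 3001)), sfreq=3000.0, t0=-1500.0)
    out = filter_and_resample(eps)
    assert out.log[-1]["idempotent"] is False


# ---------------------------------------------------------------------------
# spherical interpolation
# ---------------------------------------------------------------------------


def test_interpolation_noop_without_flags():
    rng = np.random.default_rng(9)
    eps = noise_epochs(rng, n_trials=2, n_t=101)
    out = interpolate_bad_channels(eps)
    assert np.array_equal(out.data, eps.data)


def test_interpolation_recovers_smooth_field():
    # each time sample holds a different smooth function of scalp position;
    # the interpolated channel should track the true values across samples
    import mne

    from icf_histology.atlas import CHANNELS_64

    montage = mne.channels.make_standard_montage("colin27_1005")
    pos = montage.get_positions()["ch_pos"]
    names = list(CHANNELS_64)
    xyz = np.array([pos[c] for c in names])
    xyz = xyz / np.abs(xyz).max()
    rng = np.random.default_rng(42)
    n_t = 40
    coefs = rng.standard_normal((n_t, 3))
    fields = 30.0 * (xyz @ coefs.T)  # channels x time, linear in position
    eps = make_epochs(fields[None, :, :], ch_names=names)
    truth = eps.data[0, eps.ch_index("Cz"), :].copy()
    eps.data[0, eps.ch_index("Cz"), :] = 999.0
    eps.bad_channels = ["Cz"]
    out = interpolate_bad_channels(eps)
    rec = out.data[0, out.ch_index("Cz"), :]
    assert not np.allclose(rec, 999.0)  # fully replaced
    assert np.corrcoef(rec, truth)[0, 1] > 0.9
    assert out.bad_channels == []


def test_interpolation_majority_flagged_raises():
    rng = np.random.default_rng(10)
    eps = noise_epochs(rng, n_trials=1, n_channels=8, n_t=51)
    eps.bad_channels = eps.ch_names[:5]
    with pytest.raises(RuntimeError):
        interpolate_bad_channels(eps)


# ---------------------------------------------------------------------------
# average reference
# ---------------------------------------------------------------------------


def test_reref_zero_mean_and_idempotent():
    rng = np.random.default_rng(11)
    eps = noise_epochs(rng, n_trials=3, n_t=101)
    out = rereference_average(eps)
    assert np.abs(out.data.mean(axis=1)).max() < 1e-9
    twice = rereference_average(out)
    assert np.allclose(twice.data, out.data)
    assert out.reference == "average"


def test_reref_preserves_bipolar_differences():
    rng = np.random.default_rng(12)
    eps = noise_epochs(rng, n_trials=2, n_t=51)
    out = rereference_average(eps)
    assert np.allclose(
        out.data[:, 0] - out.data[:, 1], eps.data[:, 0] - eps.data[:, 1]
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def test_chain_order_logged(small_dataset):
    eps = small_dataset.epochs[("sub-T001", "single")]
    out = run_preprocessing(eps)
    steps = [rec["step"] for rec in out.log]
    assert steps == [
        "baseline_correct",
        "detect_bad_channels",
        "reject_epochs",
        "excise_and_interpolate",
        "filter_and_resample",
        "interpolate_bad_channels",
        "rereference_average",
        "run_preprocessing",
    ]
    assert out.sfreq == 1000.0
    assert np.abs(out.data.mean(axis=1)).max() < 1e-9


def test_chain_clean_data_nothing_removed(small_dataset):
    eps = small_dataset.epochs[("sub-H001", "paired")]
    out = run_preprocessing(eps)
    by_step = {rec["step"]: rec for rec in out.log}
    assert by_step["detect_bad_channels"]["flagged"] == []
    assert by_step["reject_epochs"]["removed_trials"] == []
    assert out.n_trials == eps.n_trials


def test_chain_reports_planted_artifacts(artifact_dataset):
    subj = "sub-T001"
    truth = artifact_dataset.ground_truth
    for cond in ("single", "paired"):
        out = run_preprocessing(artifact_dataset.epochs[(subj, cond)])
        by_step = {rec["step"]: rec for rec in out.log}
        assert by_step["detect_bad_channels"]["flagged"] == (
            truth.bad_channels[subj][cond]
        )
        assert sorted(by_step["reject_epochs"]["removed_trials"]) == (
            truth.bad_epochs[subj][cond]
        )


def test_params_validation():
    with pytest.raises(ValueError):
        PreprocessParams(baseline_window=(-3000.0, -150.0))
    with pytest.raises(ValueError):
        PreprocessParams(channel_z_threshold=0.0)
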