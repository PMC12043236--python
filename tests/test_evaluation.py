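"""Envelope features, seizure masks, metrics, spikes and permutation test."""

import numpy as np
import pytest
from scipy import stats

from epicohort.evaluation import (EnvelopeFeature, Recording, binary_agreement,
                                  binary_overlap, classify_so_sp,
                                  compare_recordings, contrast_flag_and_mark,
                                  default_threshold, detect_spikes, envelope,
                                  flag_and_mark, iis_correlation, iis_count,
                                  jaccard, mask_correlation, permutation_test,
                                  resample_mask, signal_power)

FS = 1000.0


def test_envelope_zero_and_dc_signals():
    z = envelope(np.zeros((2, 5000)), FS)
    assert np.allclose(z, 0.0)
    dc = envelope(np.full((1, 5000), 7.0), FS)
    assert dc.max() < 1e-6  # high-pass removes DC


def test_envelope_localizes_a_burst():
    t = np.arange(int(60 * FS)) / FS
    sig = np.zeros_like(t)
    burst = (t >= 30) & (t < 35)
    sig[burst] = np.sin(2 * np.pi * 20 * t[burst])
    env = envelope(sig, FS)[0]
    inside = env[(t >= 31) & (t < 34)].mean()
    outside = env[(t < 25) | (t > 40)].max()
    assert inside > 10 * outside


def test_flag_and_mark_burst_interval():
    t = np.arange(int(60 * FS)) / FS
    sig = np.zeros((1, t.size))
    burst = (t >= 30) & (t < 35)
    sig[0, burst] = np.sin(2 * np.pi * 20 * t[burst])
    env = envelope(sig, FS)
    feat, mask = flag_and_mark(env, FS, threshold=0.5 * env.max())
    assert feat.flags.tolist() == [True]
    runs = np.diff(np.concatenate([[0], mask.mask[0], [0]]))
    assert (runs == 1).sum() == 1  # exactly one contiguous interval
    assert 29 < feat.onsets[0] / FS < 31.5
    assert 34 < feat.offsets[0] / FS < 37


def test_flag_and_mark_threshold_above_max_flags_nothing():
    env = np.abs(np.random.default_rng(0).normal(size=(3, 1000)))
    feat, mask = flag_and_mark(env, FS, threshold=env.max() + 1)
    assert not feat.flags.any()
    assert mask.mask.sum() == 0


def test_mask_correlation_hand_values():
    assert mask_correlation([[1, 1, 0, 0]], [[1, 1, 0, 0]]) == pytest.approx(1.0)
    assert mask_correlation([[1, 0]], [[0, 1]]) == pytest.approx(-1.0)
    assert mask_correlation([[1, 1, 0, 0]], [[1, 0, 0, 0]]) == \
        pytest.approx(1.0 / np.sqrt(3.0))
    with pytest.raises(ValueError):
        mask_correlation([[0, 0]], [[1, 0]])


def test_binary_overlap_hand_values():
    assert binary_overlap([[1, 1, 0, 0]], [[1, 0, 0, 0]]) == pytest.approx(0.5)
    assert binary_overlap([[1, 1]], [[1, 1]]) == pytest.approx(1.0)
    assert binary_overlap([[1, 0]], [[0, 1]]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        binary_overlap([[0, 0]], [[1, 1]])
    # prose variant: identical-sample fraction
    assert binary_agreement([[1, 1, 0, 0]], [[1, 0, 0, 0]]) == pytest.approx(0.75)


def test_masks_of_unequal_length_are_resampled():
    a = np.array([[1, 1, 0, 0]])
    b = np.repeat(a, 3, axis=1)  # same pattern on a 3x finer grid
    assert mask_correlation(a, b) == pytest.approx(1.0, abs=0.01)
    assert np.array_equal(resample_mask(a, 4), a)  # identity on same grid


def test_metrics_invariant_to_channel_reordering(rng):
    a = (rng.random((6, 40)) > 0.7).astype(int)
    b = (rng.random((6, 40)) > 0.7).astype(int)
    perm = rng.permutation(6)
    assert binary_overlap(a, b) == pytest.approx(binary_overlap(a[perm], b[perm]))
    assert jaccard({"A", "B"}, {"B"}) == jaccard({"B", "A"}, {"B"})


def _feature(onsets, offsets):
    n = len(onsets)
    flags = np.array([o >= 0 for o in onsets])
    return EnvelopeFeature(np.zeros((n, 10)), FS, 1.0, flags,
                           np.array(onsets), np.array(offsets))


def test_so_sp_classification():
    labels = ["c1", "c2", "c3"]
    # onsets at 0% and 50% of a 1000-sample seizure, one silent channel
    feat = _feature([0, 500, -1], [1000, 900, -1])
    classes = classify_so_sp(feat, labels, window_fraction=0.10)
    assert classes == {"c1": "SO", "c2": "SP", "c3": "none"}
    # all simultaneous onsets -> all SO
    feat = _feature([100, 100], [900, 800])
    assert set(classify_so_sp(feat, labels[:2]).values()) == {"SO"}
    # single flagged channel defines the start -> SO
    feat = _feature([400, -1], [900, -1])
    assert classify_so_sp(feat, labels[:2])["c1"] == "SO"


def test_so_sp_invariant_to_time_rescaling():
    labels = ["c1", "c2"]
    slow = _feature([0, 300], [1000, 1000])
    fast = _feature([0, 30], [100, 100])
    assert classify_so_sp(slow, labels) == classify_so_sp(fast, labels)


def test_jaccard_small_sets():
    assert jaccard({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
    assert jaccard({"A"}, {"A"}) == 1.0
    assert jaccard({"A"}, {"B"}) == 0.0
    assert jaccard(set(), set()) == 1.0  # agreement on absence


def test_signal_power_normalization():
    data = np.vstack([np.full(30, 2.0), np.array([1.0, 2.0, 3.0] * 10)])
    p = signal_power(data)
    # mean squares are 4 and 14/3; the larger channel normalizes to 1
    assert p[1] == 1.0
    assert p[0] == pytest.approx(4.0 / (14.0 / 3.0))
    with pytest.raises(ValueError):
        signal_power(np.zeros((2, 5)))


def test_spike_threshold_recovers_gaussian_sigma(rng):
    x = rng.normal(0.0, 2.5, size=100000)
    sigma_hat = np.median(np.abs(x)) / 0.6745
    assert abs(sigma_hat - 2.5) / 2.5 < 0.02


def test_detect_spikes_on_constructed_signal(rng):
    n = int(120 * FS)
    noise = rng.normal(0.0, 1.0, size=n)
    for where in (10.0, 50.0, 100.0):
        i = int(where * FS)
        noise[i:i + 20] += 20.0 * np.hanning(20)
    found = detect_spikes(noise, FS)
    big = [i for i in found if min(abs(i / FS - w) for w in (10, 50, 100)) < 0.2]
    assert len(big) == 3
    # two transients 100 ms apart merge into one spike
    sig = rng.normal(0.0, 1.0, size=int(20 * FS))
    sig[int(5 * FS):int(5 * FS) + 20] += 25.0 * np.hanning(20)
    sig[int(5.1 * FS):int(5.1 * FS) + 20] += 25.0 * np.hanning(20)
    found = detect_spikes(sig, FS)
    near = [i for i in found if abs(i / FS - 5.05) < 0.3]
    assert len(near) == 1


def test_detect_spikes_edge_cases():
    assert len(detect_spikes(np.zeros(5000), FS)) == 0
    with pytest.raises(ValueError):
        detect_spikes(np.zeros(5000), fs=100.0)
    with pytest.raises(ValueError):
        detect_spikes(np.zeros(10), FS)


def test_iis_count_and_correlation():
    assert np.allclose(iis_count([2, 3, 5]), [0.2, 0.3, 0.5])
    assert iis_count([0, 0, 7]).tolist() == [0.0, 0.0, 1.0]
    assert np.isclose(iis_count([1, 2, 3, 4]).sum(), 1.0)
    with pytest.raises(ValueError):
        iis_count([0, 0, 0])
    assert iis_correlation([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(1.0)
    # frozen from direct Pearson evaluation of the reversed vector
    assert iis_correlation([0.2, 0.3, 0.5], [0.5, 0.3, 0.2]) == \
        pytest.approx(-0.92857, abs=1e-4)
    with pytest.raises(ValueError):
        iis_correlation([1.0, 1.0], [0.5, 0.3])


def test_permutation_identical_groups_give_p_one():
    assert permutation_test([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]) == 1.0


def test_permutation_exact_enumeration_case():
    # only the original split of C(6,3)=20 has a difference this extreme
    assert permutation_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0]) == pytest.approx(0.05)


def test_permutation_monte_carlo_matches_exact(rng):
    for _ in range(3):
        a = rng.normal(0.5, 1.0, size=4)
        b = rng.normal(0.0, 1.0, size=5)
        exact = permutation_test(a, b)
        mc = permutation_test(a, b, n_perm=20000, seed=7, exact_max_n=0)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(mc - exact) <= max(3 * se, 1e-3)


def test_permutation_matches_scipy_oracle(rng):
    a = rng.normal(0.8, 1.0, size=4)
    b = rng.normal(0.0, 1.0, size=4)
    ours = permutation_test(a, b)
    ref = stats.permutation_test(
        (a, b), lambda x, y, axis=None: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        permutation_type="independent", alternative="greater", n_resamples=np.inf)
    assert ours == pytest.approx(ref.pvalue, abs=1e-9)


def test_self_comparison_is_perfect(rng):
    t = np.arange(int(40 * FS)) / FS
    data = 0.1 * rng.normal(size=(4, t.size))
    seiz = (t > 15) & (t < 25)
    data[0, seiz] += 5 * np.sin(2 * np.pi * 15 * t[seiz])
    data[1, (t > 17) & (t < 25)] += 5 * np.sin(2 * np.pi * 18 * t[seiz][:((t > 17) & (t < 25)).sum()])
    rec = Recording(data, ["a", "b", "c", "d"], FS)
    rep = compare_recordings(rec, rec)
    assert rep.correlation == pytest.approx(1.0)
    assert rep.binary_overlap == pytest.approx(1.0)
    assert rep.so_jaccard == 1.0 and rep.sp_jaccard == 1.0
    with pytest.raises(ValueError):
        compare_recordings(rec, Recording(data, ["x", "y", "z", "w"], FS))
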