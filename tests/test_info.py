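import numpy as np
import pytest

from popnoise.info import (
    mi_vs_population_size,
    plugin_mi,
    pt_bias_bits,
    pt_corrected_mi,
    quantize_responses,
)


def mi_table_oracle(joint_counts):
    """Hand-summed entropies on a contingency table (stimuli x responses)."""
    j = np.asarray(joint_counts, dtype=float)
    n = j.sum()
    p = j / n
    p_s = p.sum(axis=1)
    p_r = p.sum(axis=0)
    h_r = -sum(q * np.log2(q) for q in p_r if q > 0)
    h_rs = 0.0
    for s in range(j.shape[0]):
        if p_s[s] == 0:
            continue
        for r in range(j.shape[1]):
            if p[s, r] > 0:
                h_rs -= p[s, r] * np.log2(p[s, r] / p_s[s])
    return h_r - h_rs


def expand(joint):
    stim, resp = [], []
    for s, row in enumerate(joint):
        for r, c in enumerate(row):
            stim += [f"s{s}"] * c
            resp += [f"r{r}"] * c
    return stim, resp


def test_noiseless_channel():
    stim, resp = expand(np.eye(12, dtype=int) * 5)
    est = plugin_mi(stim, resp)
    assert est.mi_bits == pytest.approx(np.log2(12))
    assert est.h_noise_bits == pytest.approx(0.0)


def test_independent_exact_counts_zero():
    joint = np.array([[10, 10, 10], [20, 20, 20]])
    est = plugin_mi(*expand(joint))
    assert est.mi_bits == pytest.approx(0.0, abs=1e-12)


def test_binary_symmetric_channel():
    joint = np.array([[75, 25], [25, 75]])
    h2 = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
    assert plugin_mi(*expand(joint)).mi_bits == pytest.approx(1 - h2)


def test_plugin_matches_table_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        joint = rng.integers(0, 6, size=(4, 4))
        if joint.sum() == 0:
            continue
        est = plugin_mi(*expand(joint))
        assert est.mi_bits == pytest.approx(mi_table_oracle(joint), abs=1e-12)


def test_mi_bounds_and_permutation_invariance():
    rng = np.random.default_rng(1)
    stim = rng.integers(0, 5, 200)
    resp = rng.integers(0, 7, 200)
    est = plugin_mi(stim, resp)
    assert est.mi_bits >= -1e-12
    assert est.mi_bits <= est.h_response_bits + 1e-12
    assert est.mi_bits <= np.log2(est.n_stimuli) + 1e-12
    perm = rng.permutation(200)
    est2 = plugin_mi(stim[perm], resp[perm])
    assert est2.mi_bits == pytest.approx(est.mi_bits, abs=1e-12)


def test_empty_input_raises():
    with pytest.raises(ValueError):
        plugin_mi([], [])


def test_pt_bias_closed_form():
    # 2 stimuli x 10 trials, each stimulus occupying all 8 response bins:
    # bias = (2*7 - 7) / (2 * 20 * ln 2)
    stim = ["a"] * 10 + ["b"] * 10
    resp = [0, 1, 2, 3, 4, 5, 6, 7, 0, 1] * 2
    bias = pt_bias_bits(stim, resp)
    assert bias == pytest.approx(7 / (2 * 20 * np.log(2)))
    est = pt_corrected_mi(stim, resp)
    assert est.mi_bits == pytest.approx(plugin_mi(stim, resp).mi_bits - bias)


def test_pt_deterministic_channel_bias():
    # R_s = 1 per stimulus -> bias = -(R-1)/(2N ln2); corrected <= plugin
    stim, resp = expand(np.eye(4, dtype=int) * 10)
    plugin = plugin_mi(stim, resp)
    corrected = pt_corrected_mi(stim, resp)
    n = len(stim)
    assert corrected.mi_bits == pytest.approx(
        plugin.mi_bits + 3 / (2 * n * np.log(2))
    )


def test_pt_bias_vanishes_large_n():
    rng = np.random.default_rng(2)
    stim = rng.integers(0, 2, 100_000)
    resp = (stim * 2 + rng.integers(0, 2, 100_000)).astype(int)
    plugin = plugin_mi(stim, resp)
    corrected = pt_corrected_mi(stim, resp)
    assert abs(corrected.mi_bits - plugin.mi_bits) < 1e-3


def test_bias_correction_reduces_positive_bias():
    rng = np.random.default_rng(3)
    plug, corr = [], []
    for _ in range(30):
        stim = np.repeat(np.arange(13), 10)
        counts = rng.poisson(5.0, size=(130, 3))
        symbols, _ = quantize_responses(counts, n_bins=2)
        plug.append(plugin_mi(stim, symbols).mi_bits)
        corr.append(pt_corrected_mi(stim, symbols).mi_bits)
    assert np.mean(plug) > 0
    assert np.mean(np.abs(corr)) < np.mean(plug)


def test_quantize_median_split():
    symbols, n = quantize_responses(np.array([[1], [2], [3], [4]]), n_bins=2)
    assert n == 2
    assert list(symbols[:2]) != list(symbols[2:])


def test_quantize_constant_unit_single_symbol():
    symbols, n = quantize_responses(np.full((10, 1), 7.0), n_bins=4)
    assert n == 1


def test_quantize_population_symbol_bound():
    rng = np.random.default_rng(4)
    symbols, n = quantize_responses(rng.poisson(5, (100, 3)), n_bins=2)
    assert n <= 8


def test_quantize_requires_two_bins():
    with pytest.raises(ValueError):
        quantize_responses(np.zeros((5, 1)), n_bins=1)


def test_mi_curve_redundant_unit(young_recording):
    from popnoise.info import stimulus_response_arrays

    stim, resp = stimulus_response_arrays(young_recording)
    one = resp[:, [0]]
    dup = resp[:, [0, 0]]
    s1, _ = quantize_responses(one, 2)
    s2, _ = quantize_responses(dup, 2)
    assert plugin_mi(stim, s1).mi_bits == pytest.approx(plugin_mi(stim, s2).mi_bits)


def test_mi_curve_shapes_and_size_one(young_recording):
    curve = mi_vs_population_size(young_recording, sizes=[1, 2, 3], n_subsets=5, seed=0)
    assert curve.population_sizes == (1, 2, 3)
    assert len(curve.mi_mean_bits) == 3
    with pytest.raises(ValueError):
        mi_vs_population_size(young_recording, sizes=[], n_subsets=5)
    with pytest.raises(ValueError):
        mi_vs_population_size(young_recording, sizes=[999], n_subsets=5)


def test_mi_monotone_for_noiseless_tuned_population():
    # deterministic distinct tuning: response identifies stimulus better as
    # units are added
    rng = np.random.default_rng(5)
    stim = np.repeat(np.arange(6), 20)
    resp = np.stack([(stim + u) % 6 // 3 for u in range(4)], axis=1).astype(float)
    mis = []
    for m in (1, 2, 3):
        symbols, _ = quantize_responses(resp[:, :m], 2)
        mis.append(plugin_mi(stim, symbols).mi_bits)
    assert mis[0] <= mis[1] + 1e-9 <= mis[2] + 2e-9
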