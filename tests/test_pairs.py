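import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popnoise.pairs import (
    BinnedRelation,
    bin_relation,
    compute_pair_stats,
    decorrelation_index,
    noise_correlation,
    pair_rsc,
    paired_z_scores,
    response_covariance,
    trial_z_scores,
)


def rsc_expectation_oracle(za, zb):
    """Direct evaluation of the printed expectation-form correlation."""
    za, zb = np.asarray(za, float), np.asarray(zb, float)
    num = np.mean(za * zb) - np.mean(za) * np.mean(zb)
    return num / (np.std(za) * np.std(zb))


def cov_expectation_oracle(na, nb):
    na, nb = np.asarray(na, float), np.asarray(nb, float)
    return np.mean(na * nb) - np.mean(na) * np.mean(nb)


def test_trial_z_hand_example():
    z = trial_z_scores({0: [12, 8]})
    np.testing.assert_allclose(z, [1.0, -1.0])


def test_trial_z_drops_constant_condition():
    z = trial_z_scores({0: [5, 5, 5], 30: [1, 2, 3]})
    assert z.size == 3


def test_trial_z_block_standardization():
    rng = np.random.default_rng(0)
    conds = {d: rng.poisson(5, 10) + 1 for d in range(0, 360, 30)}
    z = trial_z_scores(conds)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert np.std(z) == pytest.approx(1.0, abs=1e-12)


def test_trial_z_all_constant_raises():
    with pytest.raises(ValueError):
        trial_z_scores({0: [5, 5, 5]})


def test_paired_z_joint_drop():
    a = {0: [1, 2, 3], 30: [4, 4, 4]}
    b = {0: [3, 1, 2], 30: [1, 2, 3]}
    za, zb = paired_z_scores(a, b)
    assert za.size == zb.size == 3  # condition 30 dropped for both


def test_noise_correlation_self_and_anti():
    z = np.array([1.0, -0.5, 0.25, -0.75])
    assert noise_correlation(z, z) == pytest.approx(1.0)
    assert noise_correlation(z, -z) == pytest.approx(-1.0)


def test_noise_correlation_independent_small(independent_recording):
    rec = independent_recording
    rs = []
    for i in range(0, 6):
        for j in range(i + 1, 6):
            rs.append(pair_rsc(rec, f"u{i:03d}", f"u{j:03d}"))
    assert abs(np.mean(rs)) < 0.1


@settings(max_examples=100, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=3, max_size=20
    )
)
def test_noise_correlation_matches_expectation_oracle(data):
    za = np.array([d[0] for d in data])
    zb = np.array([d[1] for d in data])
    if np.std(za) == 0 or np.std(zb) == 0:
        return
    assert noise_correlation(za, zb) == pytest.approx(
        rsc_expectation_oracle(za, zb), abs=1e-12
    )


def test_covariance_examples():
    assert response_covariance([1, 2, 3], [1, 2, 3]) == pytest.approx(2 / 3)
    assert response_covariance([1, 2, 3], [7, 7, 7]) == 0.0
    with pytest.raises(ValueError):
        response_covariance([1, 2], [1, 2, 3])


@settings(max_examples=100, deadline=None)
@given(
    data=st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=2, max_size=20)
)
def test_covariance_matches_oracle(data):
    na = [d[0] for d in data]
    nb = [d[1] for d in data]
    assert response_covariance(na, nb) == pytest.approx(
        cov_expectation_oracle(na, nb), abs=1e-12
    )


def test_rsc_affine_invariance():
    rng = np.random.default_rng(2)
    conds_a = {d: rng.poisson(6, 10).astype(float) + 1 for d in range(0, 360, 30)}
    conds_b = {d: rng.poisson(6, 10).astype(float) + 1 for d in range(0, 360, 30)}
    za, zb = paired_z_scores(conds_a, conds_b)
    base = noise_correlation(za, zb)
    scaled_a = {d: 3.0 * v + d for d, v in conds_a.items()}
    za2, zb2 = paired_z_scores(scaled_a, conds_b)
    assert noise_correlation(za2, zb2) == pytest.approx(base, abs=1e-12)


def test_pair_symmetry(young_recording):
    rec = young_recording
    ua, ub = rec.unit_ids[0], rec.unit_ids[3]
    assert pair_rsc(rec, ua, ub) == pytest.approx(pair_rsc(rec, ub, ua))
    na = np.concatenate([rec.counts_for(ua, d) for d in rec.grating_conditions])
    nb = np.concatenate([rec.counts_for(ub, d) for d in rec.grating_conditions])
    assert response_covariance(na, nb) == response_covariance(nb, na)


def test_decorrelation_index():
    assert decorrelation_index(0.3, 0.1) == 0.0
    assert decorrelation_index(0.1, 0.3) == pytest.approx(-0.2)
    assert decorrelation_index(0.2, 0.2) == 0.0


@given(ev=st.floats(-1, 1), sp=st.floats(-1, 1))
def test_decorrelation_never_positive(ev, sp):
    assert decorrelation_index(ev, sp) <= 0.0


def test_compute_pair_stats_shape(young_recording):
    df = compute_pair_stats(young_recording)
    n = young_recording.n_units
    assert len(df) == n * (n - 1) // 2
    assert (df["distance_um"] >= 0).all()
    finite = df["rsc_evoked"].dropna()
    assert ((finite >= -1) & (finite <= 1)).all()


def test_bin_relation_single_pair():
    df = pd.DataFrame(
        {"rate_mean_hz": [5.0], "distance_um": [10.0], "delta_po_deg": [1.0],
         "rsc_evoked": [0.2]}
    )
    rel = bin_relation(df, "rate")
    assert rel.bin_ns[0] == 1
    assert rel.bin_means[0] == pytest.approx(0.2)
    assert sum(rel.bin_ns) == 1


def test_bin_relation_empty_bin_and_overflow():
    df = pd.DataFrame(
        {"distance_um": [10.0, 400.0], "rate_mean_hz": [1, 1], "delta_po_deg": [0, 0],
         "rsc_evoked": [0.1, 0.9]}
    )
    rel = bin_relation(df, "distance")
    assert rel.bin_ns[1] == 0 and np.isnan(rel.bin_means[1])
    assert rel.overflow_n == 1
    assert rel.overflow_mean == pytest.approx(0.9)


def test_bin_relation_constant_signal_recovery():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "distance_um": rng.uniform(0, 299, 100),
            "rate_mean_hz": rng.uniform(0, 49, 100),
            "delta_po_deg": rng.uniform(0, 89, 100),
            "rsc_evoked": np.full(100, 0.3),
        }
    )
    rel = bin_relation(df, "distance")
    for m, n in zip(rel.bin_means, rel.bin_ns):
        if n:
            assert m == pytest.approx(0.3)


def test_bin_relation_bad_edges():
    df = pd.DataFrame({"rate_mean_hz": [1.0], "rsc_evoked": [0.1],
                       "distance_um": [0.0], "delta_po_deg": [0.0]})
    with pytest.raises(ValueError):
        bin_relation(df, "rate", edges=[10, 5, 0])
    with pytest.raises(ValueError):
        bin_relation(df, "nope")
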