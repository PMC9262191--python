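"""TC3 splitting, anchor heuristics, Viterbi decoding and annotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotrack.sync import (SyncStates, apply_annotation, classical_sync,
                            detect_ip, load_annotations, reposition_ma,
                            state_probabilities, tc3_split, viterbi_decode,
                            viterbi_path, zscore_columns)


def tc3_oracle(x):
    """Independent double-loop within-cluster cost evaluator."""
    x = np.asarray(x, float)
    best_s, best = None, np.inf
    for s in range(1, len(x)):
        cost = 0.0
        for half in (x[:s], x[s:]):
            mu = half.mean(axis=0)
            for row in half:
                cost += float(((row - mu) ** 2).sum())
        if cost < best - 1e-12:
            best, best_s = cost, s
    return best_s, best


def test_noiseless_step_split():
    seq = np.array([0, 0, 0, 0, 10, 10, 10], float)
    x = np.column_stack([seq] * 4)
    s, _ = tc3_split(x)
    assert s == 4


def test_constant_sequence_earliest_split():
    x = np.ones((9, 4))
    s, _ = tc3_split(x)
    assert s == 1


def test_split_equals_exhaustive_oracle_on_random_sequences():
    rng = np.random.default_rng(17)
    for _ in range(60):
        n = rng.integers(4, 40)
        x = rng.normal(0, 1, (n, 4))
        s, cost = tc3_split(x)
        s_oracle, cost_oracle = tc3_oracle(zscore_columns(x))
        assert s == s_oracle
        assert cost == pytest.approx(cost_oracle, abs=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1),
       st.integers(min_value=4, max_value=25))
def test_split_oracle_property(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, 2))
    s, _ = tc3_split(x)
    assert s == tc3_oracle(zscore_columns(x))[0]


def test_noisy_step_recovered_within_one_frame():
    rng = np.random.default_rng(23)
    hits = 0
    for _ in range(100)  :
        true_s = int(rng.integers(5, 25))
        x = rng.normal(0, 1, (30, 4))
        x[true_s:] += 5.0               # 5-sigma step
        s, _ = tc3_split(x)
        hits += abs(s - true_s) <= 1
    assert hits >= 95


def test_tc3_needs_two_frames():
    with pytest.raises(ValueError):
        tc3_split(np.ones((5, 4)), search_range=(0, 1))


def test_detect_ip_flags_flat_trajectory():
    rng = np.random.default_rng(0)
    _, low = detect_ip(rng.normal(0, 1, (30, 4)), 30)
    assert low
    step = rng.normal(0, 0.2, (30, 4))
    step[12:] += 5.0
    ip, low = detect_ip(step, 30)
    assert ip == 12 and not low


def test_detect_ip_clamps_inside_search_range():
    x = np.zeros((30, 4))
    x[29] = 100.0                        # step at the very edge
    ip, _ = detect_ip(x, 30)
    assert 1 <= ip <= 29


def test_reposition_first_crossing():
    d = np.array([0.0, 0.0, 2.0, 4.0, 7.0, 11.0])
    assert reposition_ma(d, division_index=2, threshold_px=6.0) == 4
    assert reposition_ma(d, division_index=2, threshold_px=100.0) == 2


def viterbi_oracle(probs, transitions, start):
    """Brute-force enumeration over all 4^T state sequences."""
    t_len = len(probs)
    best_score, best_path = -np.inf, None
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
        log_a = np.log(transitions)
        log_s = np.log(start)
    for flat in range(4 ** t_len):
        path, rest = [], flat
        for _ in range(t_len):
            path.append(rest % 4)
            rest //= 4
        score = log_s[path[0]] + logp[0, path[0]]
        for t in range(1, t_len):
            score += log_a[path[t - 1], path[t]] + logp[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path), best_score


def path_score(path, probs, transitions, start):
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
        log_a = np.log(transitions)
        log_s = np.log(start)
    score = log_s[path[0]] + logp[0, path[0]]
    for t in range(1, len(path)):
        score += log_a[path[t - 1], path[t]] + logp[t, path[t]]
    return score


def test_viterbi_noiseless_sequence_decoded_exactly():
    states = [1, 1, 2, 2, 3]
    probs = np.full((5, 4), 1e-9)
    for t, s in enumerate(states):
        probs[t, s] = 1.0
    decoded = viterbi_decode(probs / probs.sum(1, keepdims=True))
    assert decoded.valid
    assert decoded.states.tolist() == states


def test_viterbi_never_emits_illegal_transitions():
    probs = np.array([[0.01, 0.97, 0.01, 0.01],
                      [0.01, 0.01, 0.01, 0.97],
                      [0.01, 0.01, 0.97, 0.01]])   # favours 1, 3, 2
    path = viterbi_path(probs)
    diffs = np.diff(path)
    assert np.all(diffs >= 0)
    assert set(np.unique(path)) <= {0, 1, 2, 3}


def test_viterbi_matches_bruteforce_enumeration():
    from mitotrack.sync import DEFAULT_START, DEFAULT_TRANSITIONS

    rng = np.random.default_rng(31)
    for _ in range(20):
        t_len = int(rng.integers(2, 7))
        probs = rng.uniform(0.01, 1.0, (t_len, 4))
        probs /= probs.sum(axis=1, keepdims=True)
        path = viterbi_path(probs)
        oracle_path, oracle_score = viterbi_oracle(
            probs, DEFAULT_TRANSITIONS, DEFAULT_START)
        assert path_score(path, probs, DEFAULT_TRANSITIONS,
                          DEFAULT_START) == pytest.approx(oracle_score,
                                                          abs=1e-9)


def test_viterbi_rejects_zero_probability_frame():
    probs = np.ones((4, 4)) / 4
    probs[2] = 0.0
    with pytest.raises(ValueError, match="degenerate"):
        viterbi_decode(probs)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1),
       st.integers(min_value=2, max_value=40))
def test_decoded_states_always_monotone_blocks(seed, t_len):
    rng = np.random.default_rng(seed)
    probs = rng.uniform(0.0, 1.0, (t_len, 4)) + 1e-6
    probs /= probs.sum(axis=1, keepdims=True)
    decoded = viterbi_decode(probs)
    assert decoded.is_monotone_block()


def test_state_probability_rows_sum_to_one():
    rng = np.random.default_rng(5)
    probs = state_probabilities(rng.normal(0, 1, (40, 4)),
                                np.r_[np.zeros(20), np.full(20, 15.0)])
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_hmm_pathway_matches_truth_on_fixture(small_project, small_params):
    """Built-in probability model + Viterbi finds both anchors within +-1."""
    project = small_project
    hits = 0
    for i in range(project.n_cells):
        feats = np.column_stack([project.ts[k][i] for k in
                                 ("area", "circularity", "mean_int",
                                  "std_int")])
        dist_px = project.ts["sister_distance"][i] / project.pixel_size
        decoded = viterbi_decode(state_probabilities(feats, dist_px))
        if (decoded.valid
                and abs(decoded.ip_index - project.ip[i]) <= 1
                and abs(decoded.ma_index - project.ma[i]) <= 1):
            hits += 1
    assert hits >= 0.9 * project.n_cells


def test_classical_sync_monotone_and_anchored():
    rng = np.random.default_rng(11)
    feats = rng.normal(0, 0.1, (90, 4))
    feats[20:30] += 4.0                 # condensed block before division
    feats[30:] += 2.0
    dist = np.r_[np.zeros(30), 12.0 + 1.5 * np.arange(60)]
    sync = classical_sync(feats, dist, division_index=30)
    assert sync.valid and sync.is_monotone_block()
    assert sync.ip_index == 20
    assert sync.ma_index == 30


def test_annotation_index_arithmetic():
    a, b = apply_annotation(90, last_interphase_frame=29,
                            early_anaphase_frame=31)
    assert (a.states == 1).sum() == 30
    assert (a.states == 2).sum() == 2
    assert (a.states == 3).sum() == 58
    assert np.array_equal(a.states, b.states)    # sibling copy, bit-identical


def test_annotation_reject_marks_invalid():
    a, b = apply_annotation(90, 29, 31, reject=True)
    assert not a.valid and not b.valid
    assert np.all(a.states == 0) and np.all(b.states == 0)


def test_annotation_bad_order_rejected():
    with pytest.raises(ValueError, match="not after"):
        apply_annotation(90, last_interphase_frame=31, early_anaphase_frame=30)


def test_load_annotations_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame({"cell_id": ["pair0a"], "last_interphase_frame": [29],
                       "early_anaphase_frame": [31], "reject": [False]})
    path = tmp_path / "ann.csv"
    df.to_csv(path, index=False)
    back = load_annotations(path)
    assert back.iloc[0].cell_id == "pair0a"
    with pytest.raises(ValueError, match="lacks columns"):
        df.drop(columns=["reject"]).to_csv(path, index=False)
        load_annotations(path)


def test_sync_states_invariant_enforced():
    with pytest.raises(ValueError):
        SyncStates.from_anchors(10, 5, 5)
    s = SyncStates.from_anchors(10, 3, 7)
    assert s.is_monotone_block()
    assert SyncStates.invalid(10).is_monotone_block()
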