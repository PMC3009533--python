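import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puseq.datasets import PUDataset, SequenceRecord
from puseq.pu_core import (
    PUState,
    SpyConfig,
    expand_rn,
    extract_rn_spy,
    predict,
    run_pu,
    select_spies,
    spy_threshold,
    write_history,
)
from puseq.pu_core import PUModel


class TestSelectSpies:
    def test_fifteen_percent_of_200(self):
        S, rest = select_spies([f"p{i}" for i in range(200)], 0.15, seed=0)
        assert len(S) == 30 and len(rest) == 170

    def test_half_of_four(self):
        S, rest = select_spies(["a", "b", "c", "d"], 0.5, seed=1)
        assert len(S) == 2 and len(rest) == 2

    def test_seeded_determinism(self):
        ids = [f"p{i}" for i in range(50)]
        assert select_spies(ids, 0.15, seed=9) == select_spies(ids, 0.15, seed=9)

    def test_n_spies_override(self):
        S, _ = select_spies([f"p{i}" for i in range(232)], 0.15, seed=0, n_spies=30)
        assert len(S) == 30

    def test_degenerate_fraction(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_spies(["a", "b", "c"], 0.01, seed=0)

    def test_disjoint_partition(self):
        ids = [f"p{i}" for i in range(40)]
        S, rest = select_spies(ids, 0.3, seed=2)
        assert sorted(S + rest) == sorted(ids)


class TestSpyThreshold:
    def test_min_rule(self):
        assert spy_threshold([0.62, 0.81, 0.55]) == 0.55

    def test_singleton(self):
        assert spy_threshold([0.9]) == 0.9

    def test_strictly_below_semantics(self):
        t = spy_threshold([0.62, 0.81, 0.55])
        unlabeled = np.array([0.10, 0.55, 0.70])
        assert (unlabeled < t).sum() == 1

    def test_empty(self):
        with pytest.raises(ValueError):
            spy_threshold([])

    def test_noise_skips_lowest(self):
        probs = [0.05, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        assert spy_threshold(probs, noise=0.15) == 0.4

    def test_noise_zero_is_min(self):
        probs = [0.3, 0.2, 0.9]
        assert spy_threshold(probs, noise=0.0) == 0.2

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bruteforce_oracle(self, probs):
        # largest t (among candidates) with all spies >= t
        candidates = sorted(probs)
        best = max(c for c in candidates if all(p >= c for p in probs))
        assert spy_threshold(probs) == best


def _toy_pu(n_pos=20, n_neg=30, n_hidden=5):
    """Feature-space toy: positives at +1, negatives at -1, hidden at +1."""
    p_ids = [f"p{i}" for i in range(n_pos)]
    p_X = np.ones((n_pos, 1))
    u_ids = [f"n{i}" for i in range(n_neg)] + [f"h{i}" for i in range(n_hidden)]
    u_X = np.vstack([-np.ones((n_neg, 1)), np.ones((n_hidden, 1))])
    return p_ids, p_X, u_ids, u_X


class TestExtractRnSpy:
    def test_separable_toy(self):
        p_ids, p_X, u_ids, u_X = _toy_pu()
        state = extract_rn_spy(p_ids, p_X, u_ids, u_X, SpyConfig(seed=0))
        assert state.converged
        assert state.rn == {f"n{i}" for i in range(30)}
        assert state.q == {f"h{i}" for i in range(5)}

    def test_duplicates_of_p_raise(self):
        # hidden positives identical to P members score exactly like spies,
        # so nothing falls strictly below the threshold
        rng = np.random.default_rng(0)
        p_ids = [f"p{i}" for i in range(20)]
        p_X = rng.normal(size=(20, 3))
        u_ids = [f"u{i}" for i in range(20)]
        with pytest.raises(ValueError, match="no reliable negatives"):
            extract_rn_spy(p_ids, p_X, u_ids, p_X.copy(), SpyConfig(seed=0))

    def test_history_monotone(self):
        p_ids, p_X, u_ids, u_X = _toy_pu()
        state = extract_rn_spy(p_ids, p_X, u_ids, u_X, SpyConfig(seed=1))
        rn_sizes = [h.n_rn for h in state.history]
        q_sizes = [h.n_q for h in state.history]
        assert rn_sizes == sorted(rn_sizes)
        assert q_sizes == sorted(q_sizes, reverse=True)
        assert all(r + q == len(u_ids) for r, q in zip(rn_sizes, q_sizes))

    def test_no_spy_in_rn(self):
        p_ids, p_X, u_ids, u_X = _toy_pu()
        state = extract_rn_spy(p_ids, p_X, u_ids, u_X, SpyConfig(seed=2))
        spy_ids = set(state.history[0].spy_ids)
        assert not (spy_ids & state.rn)


class TestExpandRn:
    def test_requires_nonempty_rn(self):
        p_ids, p_X, u_ids, u_X = _toy_pu()
        state = PUState(rn=set(), q=set(u_ids), iteration=0)
        with pytest.raises(ValueError):
            expand_rn(p_ids, p_X, state, u_ids, u_X, SpyConfig(seed=0))

    def test_first_w_empty_returns_unchanged(self):
        p_ids, p_X, u_ids, u_X = _toy_pu()
        # RN = the true negatives, Q = hidden positives: nothing left to move
        state = PUState(
            rn={f"n{i}" for i in range(30)}, q={f"h{i}" for i in range(5)}, iteration=0
        )
        out = expand_rn(p_ids, p_X, state, u_ids, u_X, SpyConfig(seed=0))
        assert out.converged
        assert out.rn == {f"n{i}" for i in range(30)}

    def test_q_members_identical_to_rn_move(self):
        # 3 undecided examples with feature vectors identical to RN members
        # land in the same leaf and are classified negative on iteration 1
        p_ids = [f"p{i}" for i in range(10)]
        p_X = np.ones((10, 1))
        u_ids = [f"n{i}" for i in range(10)] + ["q0", "q1", "q2"]
        u_X = np.vstack([-np.ones((10, 1)), -np.ones((3, 1))])
        state = PUState(rn={f"n{i}" for i in range(10)}, q={"q0", "q1", "q2"}, iteration=0)
        out = expand_rn(p_ids, p_X, state, u_ids, u_X, SpyConfig(seed=0))
        assert out.rn >= {"q0", "q1", "q2"}

    def test_conservation(self):
        p_ids, p_X, u_ids, u_X = _toy_pu()
        state = PUState(rn={f"n{i}" for i in range(10)},
                        q=set(u_ids) - {f"n{i}" for i in range(10)}, iteration=0)
        out = expand_rn(p_ids, p_X, state, u_ids, u_X, SpyConfig(seed=0))
        assert out.rn | out.q == set(u_ids)
        assert not (out.rn & out.q)


class TestRunPU:
    def test_end_to_end_determinism(self, small_dataset):
        m1 = run_pu(small_dataset, cfg=SpyConfig(seed=7))
        m2 = run_pu(small_dataset, cfg=SpyConfig(seed=7))
        assert m1.state.rn == m2.state.rn
        assert m1.state.q == m2.state.q
        pred1 = predict(m1, small_dataset.U[:10])
        pred2 = predict(m2, small_dataset.U[:10])
        assert pred1 == pred2

    def test_variants_share_rn_on_default_benchmark(self, protocol_grid):
        orig, _ = protocol_grid[(1.0, 42, "original")]
        mod, _ = protocol_grid[(1.0, 42, "modified")]
        assert orig.state.rn == mod.state.rn

    def test_partition_and_spy_safety(self, small_dataset):
        model = run_pu(small_dataset, cfg=SpyConfig(seed=3))
        u_ids = {r.id for r in small_dataset.U}
        assert model.state.rn | model.state.q == u_ids
        assert not (model.state.rn & model.state.q)
        p_ids = {r.id for r in small_dataset.P}
        assert not (model.state.rn & p_ids)

    def test_training_positives_rescore_positive(self, small_dataset):
        model = run_pu(small_dataset, cfg=SpyConfig(seed=3))
        preds = predict(model, small_dataset.P[:20])
        assert all(p.label == "positive" for p in preds)

    def test_invalid_variant(self):
        with pytest.raises(ValueError):
            SpyConfig(variant="rocchio")

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SpyConfig(s=1.5)


class TestPredict:
    def test_probability_bounds(self, small_dataset):
        model = run_pu(small_dataset, cfg=SpyConfig(seed=5))
        preds = predict(model, small_dataset.U[:25])
        assert all(0 <= p.prob_positive <= 1 for p in preds)

    def test_zero_effective_length_flagged(self, small_dataset):
        model = run_pu(small_dataset, cfg=SpyConfig(seed=5))
        preds = predict(model, [SequenceRecord("weird", "XXXX")])
        assert preds[0].zero_effective_length

    def test_empty_input(self, small_dataset):
        model = run_pu(small_dataset, cfg=SpyConfig(seed=5))
        assert predict(model, []) == []


def test_model_save_load_roundtrip(tmp_path, small_dataset):
    model = run_pu(small_dataset, cfg=SpyConfig(seed=11))
    path = tmp_path / "model.pkl"
    model.save(path)
    loaded = PUModel.load(path)
    assert loaded.state.rn == model.state.rn
    p1 = predict(model, small_dataset.U[:5])
    p2 = predict(loaded, small_dataset.U[:5])
    assert p1 == p2


def test_write_history(tmp_path, small_dataset):
    model = run_pu(small_dataset, cfg=SpyConfig(seed=11))
    path = tmp_path / "history.tsv"
    write_history(model.state, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "phase\titeration\tn_rn\tn_q\tthreshold"
    assert len(lines) == len(model.state.history) + 1
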