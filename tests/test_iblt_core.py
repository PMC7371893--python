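"""Memory-core unit and property tests: base-level decay, partial matching,
logistic noise, the latency law and argmax retrieval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmdibl import (
    Instance,
    MemoryStore,
    ModelParams,
    Probe,
    activation,
    base_level_activation,
    mismatch,
    retrieval_time,
    retrieve,
)
from dmdibl.exceptions import (
    ContractError,
    NoHistoryError,
    ParameterError,
    RetrievalError,
    VocabularyError,
)
from dmdibl.iblt_core import logistic_noise, noise_draw

COLORS = ("red", "green", "blue", "yellow")


def inst(events, color="red", word="red"):
    return Instance(color=color, word=word, retrieval_events=list(events))


class TestBaseLevelActivation:
    @pytest.mark.parametrize("d", [0.0, 0.5, 4.0, 10.0])
    def test_single_event_at_lag_one_is_zero(self, d):
        assert base_level_activation(inst([4]), now=5, d=d) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "events, now, d, expected",
        [
            ([1], 5, 0.5, -0.5 * math.log(4)),          # closed form -d*ln(lag)
            ([3, 4], 5, 0.5, math.log(1 + 2 ** -0.5)),  # direct two-term sum
            ([0, 5, 9], 10, 4.0, math.log(10.0 ** -4 + 5.0 ** -4 + 1.0)),
        ],
    )
    def test_worked_values(self, events, now, d, expected):
        got = base_level_activation(inst(events), now, d)
        assert got == pytest.approx(expected, abs=1e-9)

    @given(lag=st.integers(min_value=1, max_value=10_000),
           d=st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=200, deadline=None)
    def test_closed_form_for_single_event(self, lag, d):
        got = base_level_activation(inst([0]), now=lag, d=d)
        assert got == pytest.approx(-d * math.log(lag), rel=1e-9, abs=1e-9)

    def test_empty_history_rejected(self):
        with pytest.raises(NoHistoryError):
            base_level_activation(inst([]), now=3, d=0.5)

    def test_future_event_rejected(self):
        with pytest.raises(ContractError):
            base_level_activation(inst([5]), now=5, d=0.5)


class TestMismatch:
    def test_equal_values_no_penalty(self):
        assert mismatch("red", "red") == 0.0

    def test_binary_full_mismatch(self):
        assert mismatch("red", "blue") == -1.0

    def test_graded_similarity(self):
        sim = {frozenset(("red", "pink")): 0.4}
        assert mismatch("red", "pink", similarity=sim) == pytest.approx(-0.6)

    @given(a=st.sampled_from(COLORS), b=st.sampled_from(COLORS))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        m = mismatch(a, b)
        assert m == mismatch(b, a)
        assert -1.0 <= m <= 0.0
        assert (m == 0.0) == (a == b)

    def test_vocabulary_enforced(self):
        with pytest.raises(VocabularyError):
            mismatch("red", "mauve", vocabulary=COLORS)


class TestNoise:
    def test_median_uniform_gives_zero(self):
        assert logistic_noise(3.7, 0.5) == 0.0

    def test_worked_value(self):
        assert logistic_noise(2.0, 0.75) == pytest.approx(2 * math.log(1 / 3))

    def test_zero_scale(self, rng):
        assert noise_draw(0.0, rng) == 0.0

    def test_negative_scale_rejected(self, rng):
        with pytest.raises(ParameterError):
            noise_draw(-1.0, rng)

    def test_logistic_moments(self, rng):
        s = 2.0
        draws = np.array([noise_draw(s, rng) for _ in range(100_000)])
        assert abs(np.median(draws)) < 0.05
        expected_var = s ** 2 * math.pi ** 2 / 3
        assert np.var(draws) == pytest.approx(expected_var, rel=0.05)


class TestActivation:
    def probe(self, color="red", word="red", P=1.0):
        return Probe(requested={"color": color, "word": word},
                     weights={"color": P, "word": P})

    def test_matching_probe_is_base_level(self):
        params = ModelParams(d=0.5, P=1.0)
        a = activation(inst([4]), self.probe(), params, now=5, noise_on=False)
        assert a == pytest.approx(0.0)

    def test_single_full_mismatch_costs_one_penalty(self):
        params = ModelParams(d=0.5, P=1.0)
        a = activation(inst([4], word="blue"), self.probe(), params, now=5,
                       noise_on=False)
        assert a == pytest.approx(-1.0)

    def test_worked_combination(self):
        # lags {1, 2} at d=0.5 with one mismatched slot at P=1
        params = ModelParams(d=0.5, P=1.0)
        a = activation(inst([3, 4], word="blue"), self.probe(), params, now=5,
                       noise_on=False)
        assert a == pytest.approx(math.log(1 + 2 ** -0.5) - 1.0)

    def test_added_mismatch_never_raises_activation(self):
        params = ModelParams(d=0.5, P=1.0)
        one_slot = Probe(requested={"color": "red"}, weights={"color": 1.0})
        both = self.probe(word="green")
        target = inst([2, 4], color="red", word="blue")
        a1 = activation(target, one_slot, params, now=5, noise_on=False)
        a2 = activation(target, both, params, now=5, noise_on=False)
        assert a2 <= a1


class TestRetrievalTime:
    @pytest.mark.parametrize("F, f, a, expected", [
        (1.0, 0.7, 0.0, 1.0),
        (1.0, 0.005, -1.0, math.exp(0.005)),
        (1.0, 0.003, 2.0, math.exp(-0.006)),
        (0.0, 0.5, 3.0, 0.0),
    ])
    def test_worked_values(self, F, f, a, expected):
        assert retrieval_time(a, F, f) == pytest.approx(expected, rel=1e-9)

    @given(a1=st.floats(-50, 50), a2=st.floats(-50, 50),
           f=st.floats(1e-4, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_activation(self, a1, a2, f):
        lo, hi = sorted((a1, a2))
        if hi - lo < 1e-6:  # below float resolution of exp(-f*A)
            return
        assert retrieval_time(hi, 1.0, f) < retrieval_time(lo, 1.0, f)

    def test_negative_latency_factor_rejected(self):
        with pytest.raises(ParameterError):
            retrieval_time(0.0, -1.0, 0.1)


class TestRetrieve:
    def store_with(self, *instances):
        store = MemoryStore(now=10)
        for i in instances:
            store.add(i.color, i.word, events=i.retrieval_events)
        return store

    def test_single_candidate(self):
        params = ModelParams(F=1.0, f=0.01, d=0.5)
        store = self.store_with(inst([9]))
        probe = Probe(requested={"word": "red"}, weights={"word": params.P})
        out = retrieve(store, probe, params, noise_on=False)
        assert out.instance is store.instances[0]
        assert out.rt == pytest.approx(retrieval_time(0.0, 1.0, 0.01))

    def test_matching_instance_beats_mismatching(self):
        params = ModelParams(d=0.5, P=1.0)
        store = self.store_with(inst([9], word="blue"), inst([9], word="red"))
        probe = Probe(requested={"word": "red"}, weights={"word": 1.0})
        out = retrieve(store, probe, params, noise_on=False)
        assert out.instance.word == "red"

    def test_commit_appends_event_and_advances_clock(self):
        params = ModelParams(d=0.5)
        store = self.store_with(inst([9]))
        probe = Probe(requested={"word": "red"}, weights={"word": 1.0})
        retrieve(store, probe, params, noise_on=False)
        assert store.instances[0].retrieval_events == [9, 10]
        assert store.now == 11

    def test_unreachable_threshold_fails(self):
        params = ModelParams(d=0.5, tau=10.0)
        store = self.store_with(inst([9]))
        probe = Probe(requested={"word": "red"}, weights={"word": 1.0})
        out = retrieve(store, probe, params, noise_on=False)
        assert out.failed and out.instance is None
        assert store.now == 10  # nothing committed

    def test_empty_store_rejected(self):
        params = ModelParams()
        with pytest.raises(RetrievalError):
            retrieve(MemoryStore(), Probe(requested={}, weights={}), params)

    def test_deterministic_under_identical_seeds(self):
        params = ModelParams(d=2.0, s=3.0)
        probe = Probe(requested={"word": "red"}, weights={"word": 1.0})
        picks = []
        for _ in range(2):
            store = self.store_with(inst([3], word="red"), inst([9], word="blue"))
            out = retrieve(store, probe, params,
                           rng=np.random.default_rng(77), noise_on=True)
            picks.append((out.instance.word, out.rt))
        assert picks[0] == picks[1]

    def test_noise_tie_break_prefers_earliest_created(self):
        params = ModelParams(d=0.5)
        store = self.store_with(inst([9], word="red", color="red"),
                                inst([9], word="red", color="green"))
        probe = Probe(requested={"word": "red"}, weights={"word": 1.0})
        out = retrieve(store, probe, params, noise_on=False)
        assert out.instance is store.instances[0]

    def test_activation_matches_term_by_term_oracle(self, rng):
        """Every instance's score equals an independent re-evaluation of
        base level + penalties on stores of <= 10 instances."""
        params = ModelParams(d=1.7, P=2.5)
        for _ in range(20):
            store = MemoryStore(now=60)
            n = int(rng.integers(1, 11))
            for i in range(n):
                events = sorted(rng.choice(59, size=rng.integers(1, 8),
                                           replace=False).tolist())
                store.add(color=f"c{i}", word=str(rng.integers(0, 3)),
                          events=events)
            probe = Probe(requested={"word": "1"}, weights={"word": params.P})
            out = retrieve(store, probe, params, noise_on=False, advance=False)
            # brute force, term by term
            best = None
            for i, it in enumerate(store.instances):
                b = math.log(math.fsum((store.now - t) ** -params.d
                                       for t in it.retrieval_events))
                pen = 0.0 if it.word == "1" else -params.P
                a = b + pen
                if best is None or a > best[1] + 1e-12:
                    best = (i, a)
            assert out.instance is store.instances[best[0]]
            assert out.activation == pytest.approx(best[1], abs=1e-9)


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        {"F": 1.5}, {"f": -0.1}, {"d": 11.0}, {"s": -2.0},
        {"P": -1.0}, {"t_nonretrieval": -0.5},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParams(**kwargs)

    def test_fitted_rows_are_valid(self):
        from dmdibl import FITTED_PARAMS
        assert set(FITTED_PARAMS) == {"control", "dmd"}
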