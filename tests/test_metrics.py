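from itertools import combinations

import numpy as np
import pytest

from precoss.corpus import SentenceStimulus
from precoss.inference import RecognitionTrace
from precoss.metrics import (
    bic,
    entropy_trace,
    entropy_weighted_overlap,
    evaluate,
    input_indicator,
    integration_efficacy,
    lcs_length,
    lcs_metric,
    normalized_entropy,
    overlap,
    recognized_sequence,
    sentence_loglik,
)


def make_sentence(ids, durations):
    durations = np.asarray(durations)
    offsets = np.cumsum(durations)
    return SentenceStimulus(
        syllable_ids=tuple(ids), onsets_ms=offsets - durations, offsets_ms=offsets, seed=0
    )


def make_trace(softmax, markers=None, z_pe=None, omega=None, h=None):
    """Minimal hand-built recognition trace for metric tests."""
    softmax = np.asarray(softmax, dtype=float)
    T, N = softmax.shape
    if markers is None:
        markers = np.array([0, T])
    return RecognitionTrace(
        omega=np.zeros((T, N)) if omega is None else np.asarray(omega, float),
        softmax_omega=softmax,
        y=np.zeros((T, 8)),
        z=np.zeros((T, 6)),
        z_pe=np.zeros((T, N)) if z_pe is None else np.asarray(z_pe, float),
        gamma_pe=np.zeros((T, 8)),
        input_pe=np.zeros((T, 7)),
        logv_omega=np.zeros(T),
        logv_gamma=np.zeros(T),
        h=np.ones(T) if h is None else np.asarray(h, float),
        reset_gate=np.zeros(T),
        markers=np.asarray(markers),
        status="ok",
        n_state_variables=17,
        variant="stationary",
        psi=20.0,
    )


class TestInputIndicator:
    def test_tiling_column_sums(self):
        s = input_indicator(make_sentence([1, 2], [100, 100]), 200)
        assert np.all(s.sum(axis=0) == 1)

    def test_row_sums_equal_durations(self):
        sent = make_sentence([3, 1, 2], [50, 70, 80])
        s = input_indicator(sent, 200)
        assert np.array_equal(s.sum(axis=1), sent.durations_ms)

    def test_half_open_boundary_sample(self):
        # 4-sample toy: boundary sample belongs to the second syllable only
        s = input_indicator(make_sentence([1, 2], [2, 2]), 4)
        assert s[0, 1] == 1 and s[0, 2] == 0
        assert s[1, 2] == 1


class TestRecognizedSequence:
    def test_constant_belief_winner(self):
        psi = np.tile([0.7, 0.3], (50, 1))
        M, r = recognized_sequence(psi, [0, 50])
        assert np.argmax(M[0]) == 0
        assert np.all(r[0] == 1) and np.all(r[1] == 0)

    def test_tie_broken_toward_lowest_index(self):
        psi = np.array([[0.3, 0.7], [0.7, 0.3]])
        M, r = recognized_sequence(psi, [0, 2])
        assert np.allclose(M[0], [0.5, 0.5])
        assert np.all(r[0] == 1)

    def test_window_count(self):
        psi = np.tile([0.5, 0.5], (100, 1))
        M, _ = recognized_sequence(psi, [0, 25, 50, 100])
        assert M.shape[0] == 3

    def test_degenerate_window_skipped(self):
        psi = np.tile([1.0, 0.0], (10, 1))
        M, _ = recognized_sequence(psi, [0, 5, 5, 10])
        assert M.shape[0] == 2


class TestOverlap:
    def test_perfect_recognition(self):
        s = input_indicator(make_sentence([1, 2], [100, 100]), 200)
        assert overlap(s, s) == 1.0

    def test_fully_wrong(self):
        s = input_indicator(make_sentence([1, 2], [100, 100]), 200)
        assert overlap(s, s[::-1]) == 0.0

    def test_half_right(self):
        truth = make_sentence([1, 2], [100, 100])
        s = input_indicator(truth, 200)
        r = np.zeros_like(s)
        r[0] = 1.0  # recognized syllable 1 throughout
        assert overlap(s, r) == 0.5


class TestEntropy:
    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_uniform_is_one(self, n):
        assert normalized_entropy(np.full(n, 1 / n)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_one_hot_is_zero(self, n):
        p = np.zeros(n)
        p[0] = 1.0
        assert normalized_entropy(p) == pytest.approx(0.0)

    def test_binary_closed_form(self):
        assert normalized_entropy(np.array([0.75, 0.25])) == pytest.approx(
            0.811278, abs=1e-6
        )

    def test_needs_two_outcomes(self):
        with pytest.raises(ValueError):
            normalized_entropy(np.array([1.0]), N=1)

    def test_weighted_overlap_limits(self):
        s = input_indicator(make_sentence([1, 2], [50, 50]), 100)
        assert entropy_weighted_overlap(s, s, np.zeros(100)) == overlap(s, s)
        assert entropy_weighted_overlap(s, s, np.ones(100)) == 0.0

    def test_weighted_never_exceeds_plain(self):
        rng = np.random.default_rng(0)
        s = input_indicator(make_sentence([1, 2, 1], [30, 40, 30]), 100)
        r = np.zeros_like(s)
        r[rng.integers(0, 3, 100), np.arange(100)] = 1
        E = rng.uniform(0, 1, 100)
        assert entropy_weighted_overlap(s, r, E) <= overlap(s, r)

    def test_nonfinite_entropy_rejected(self):
        s = input_indicator(make_sentence([1], [10]), 10)
        E = np.full(10, np.nan)
        with pytest.raises(ValueError):
            entropy_weighted_overlap(s, s, E)


def lcs_bruteforce(a, b):
    """Exhaustive subsequence enumeration (oracle for short sequences)."""
    def is_subsequence(sub, seq):
        j = 0
        for x in sub:
            while j < len(seq) and seq[j] != x:
                j += 1
            if j == len(seq):
                return False
            j += 1
        return True

    for k in range(min(len(a), len(b)), 0, -1):
        for idx in combinations(range(len(a)), k):
            if is_subsequence([a[i] for i in idx], b):
                return k
    return 0


class TestLCS:
    def test_worked_example(self):
        a = [8, 1, 3, 2, 4, 5, 5, 7]
        b = [1, 2, 3, 4, 5, 6, 7, 8]
        assert lcs_length(a, b) == 5  # witness: [1, 2, 4, 5, 7]

    def test_identical_sequences(self):
        assert lcs_length(range(12), range(12)) == 12

    def test_empty(self):
        assert lcs_length([], [1, 2]) == 0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = list(rng.integers(1, 6, rng.integers(0, 10)))
            b = list(rng.integers(1, 6, rng.integers(0, 10)))
            assert lcs_length(a, b) == lcs_length(b, a)

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            a = list(rng.integers(1, 8, rng.integers(0, 11)))
            b = list(rng.integers(1, 8, rng.integers(0, 11)))
            assert lcs_length(a, b) == lcs_bruteforce(a, b)

    def test_metric_examples(self):
        assert lcs_metric([1, 2, 3], [1, 2, 3], 3) == 1.0
        assert lcs_metric([1, 2, 3], [4, 5], 3) == 0.0
        assert lcs_metric([1, 2, 3], [1, 3], 3) == pytest.approx(2 / 3)


class TestIntegrationEfficacy:
    def test_three_sample_toy(self):
        sent = make_sentence([1], [3])
        omega = np.cumsum([[0.5], [-0.5], [-1.0]], axis=0)
        tr = make_trace(
            softmax=np.ones((3, 1)),
            z_pe=[[1.0], [-1.0], [2.0]],
            omega=omega,
        )
        # r = (1*0.5 + (-1)*(-0.5) + 0) / 3
        assert integration_efficacy(tr, sent) == pytest.approx(1 / 3)

    def test_masked_out_everywhere_is_zero(self):
        sent = make_sentence([1], [3])
        tr = make_trace(
            softmax=np.ones((3, 1)),
            z_pe=[[1.0], [1.0], [1.0]],
            omega=np.cumsum(np.ones((3, 1)), axis=0),
            h=np.zeros(3),
        )
        assert integration_efficacy(tr, sent) == 0.0

    def test_codirected_movement_is_positive(self):
        sent = make_sentence([1], [4])
        z = np.array([[1.0], [-2.0], [0.5], [-1.0]])
        tr = make_trace(
            softmax=np.ones((4, 1)), z_pe=z, omega=np.cumsum(z, axis=0)
        )
        assert integration_efficacy(tr, sent) > 0


class TestLoglikAndBic:
    def test_certain_truth_gives_zero(self):
        sent = make_sentence([1, 2], [50, 50])
        psi = input_indicator(sent, 100).T
        tr = make_trace(softmax=psi)
        assert sentence_loglik(tr, sent) == pytest.approx(0.0)

    def test_half_probability_closed_form(self):
        sent = make_sentence([1, 2, 1], [40, 60, 100])
        tr = make_trace(softmax=np.full((200, 2), 0.5))
        assert sentence_loglik(tr, sent) == pytest.approx(3 * np.log(0.5))

    def test_never_positive(self):
        rng = np.random.default_rng(3)
        sent = make_sentence([1, 2], [30, 30])
        p = rng.dirichlet(np.ones(2), 60)
        assert sentence_loglik(make_trace(softmax=p), sent) <= 0

    def test_bic_penalty_closed_form(self):
        assert bic(np.zeros(220), 220, 19) == pytest.approx(
            -0.5 * 220 * np.log(19), abs=0.01
        )

    def test_single_parameter_unpenalized(self):
        assert bic([-1.0, -2.0], 2, 1) == pytest.approx(-3.0)

    def test_fewer_parameters_score_higher(self):
        ll = [-5.0, -7.0]
        assert bic(ll, 2, 17) > bic(ll, 2, 19)


class TestEvaluatePerfectTrace:
    def test_perfect_recognition_fixed_point(self):
        """A trace whose softmax equals the input indicator scores 1 on all
        sequence metrics and 0 log-likelihood."""
        sent = make_sentence([2, 1, 3], [60, 80, 60])
        T = 200
        # softmax rows are indexed by inventory id (1-based -> row id-1)
        psi = np.zeros((T, 3))
        for sid, a, b in zip(sent.syllable_ids, sent.onsets_ms, sent.offsets_ms):
            psi[a:b, sid - 1] = 1.0
        tr = make_trace(softmax=psi, markers=[0, 60, 140, 200])
        rep = evaluate(tr, sent)
        assert rep.overlap == 1.0
        assert rep.ent_overlap == 1.0
        assert rep.lcs_ratio == 1.0
        assert rep.loglik == pytest.approx(0.0)
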