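import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chiscan as cs
from chiscan.words import (
    _analytic_sd,
    count_all_kmers,
    count_word,
    expected_count,
    fit_markov,
    null_distribution,
    score_all_models,
    simulate_from_model,
    zscore_word,
)
from chiscan._codes import encode_word


def naive_count(seqs, word):
    k = len(word)
    return sum(
        sum(1 for i in range(len(s) - k + 1) if s[i : i + k] == word)
        for s in seqs
    )


class TestCountWord:
    @pytest.mark.parametrize(
        "seqs,word,expected",
        [
            (["GCTGGTGGCTGGTGG"], "GCTGGTGG", 2),  # overlapping pair
            (["AAAA"], "AA", 3),
            (["GCTG", "GTGG"], "GCTGGTGG", 0),  # no cross-boundary window
            (["AANAA"], "AA", 2),  # N windows skipped
        ],
    )
    def test_examples(self, seqs, word, expected):
        assert count_word(seqs, word) == expected

    def test_word_with_n_rejected(self):
        with pytest.raises(ValueError):
            count_word(["ACGT"], "AN")

    @settings(max_examples=60, deadline=None)
    @given(
        s=st.text(alphabet="ACGTN", min_size=1, max_size=300),
        w=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_matches_naive_scan(self, s, w):
        assert count_word([s], w) == naive_count([s], w)


class TestCountAllKmers:
    def test_monomers(self):
        assert count_all_kmers(["ACGT"], 1) == {"A": 1, "C": 1, "G": 1, "T": 1}

    def test_dimers_window_total(self):
        counts = count_all_kmers(["ACGT"], 2)
        assert counts == {"AC": 1, "CG": 1, "GT": 1}
        assert sum(counts.values()) == 4 - 2 + 1

    def test_n_rule(self):
        assert count_all_kmers(["ANA"], 2) == {}

    def test_k_exceeding_lengths_warns(self):
        with pytest.warns(UserWarning):
            assert count_all_kmers(["ACG"], 5) == {}

    @settings(max_examples=30, deadline=None)
    @given(
        s=st.text(alphabet="ACGTN", min_size=3, max_size=200),
        k=st.integers(min_value=1, max_value=3),
    )
    def test_total_equals_valid_windows(self, s, k):
        counts = count_all_kmers([s], k)
        n_valid = sum(
            1
            for i in range(len(s) - k + 1)
            if "N" not in s[i : i + k]
        )
        assert sum(counts.values()) == n_valid


class TestFitMarkov:
    def test_degenerate_order0(self):
        m = fit_markov(["AAAA"], 0)
        assert m.transition_matrix()[0, 0] == 1.0

    def test_order1_transitions(self):
        m = fit_markov(["AACA"], 1)
        probs = m.transition_matrix()
        assert probs[0, 0] == pytest.approx(0.5)  # p(A|A)
        assert probs[0, 1] == pytest.approx(0.5)  # p(C|A)

    def test_order_exceeding_length(self):
        with pytest.raises(ValueError):
            fit_markov(["ACGTA"], 6)

    def test_counts_nested(self):
        m = fit_markov(["GCTGGTGGA"], 2)
        # every (m+1)-mer count <= its length-m prefix count
        for kmer, c in m.kmer_counts_m1.items():
            assert c <= m.kmer_counts_m[kmer[:2]]


class TestExpectedCount:
    def test_order0_hand_computation(self):
        m = fit_markov(["ATATATAT"], 0)
        # N(A)=4, N(T)=4, N(empty)=8 -> 4*4/8 = 2
        assert expected_count(m, "AT") == pytest.approx(2.0)

    def test_order1_formula_instantiation(self):
        m = fit_markov(["ATGATGAC"], 1)
        n = count_all_kmers(["ATGATGAC"], 2)
        n1 = count_all_kmers(["ATGATGAC"], 1)
        want = n["AT"] * n["TG"] / n1["T"]
        assert expected_count(m, "ATG") == pytest.approx(want)

    def test_order5_formula_instantiation(self):
        seq = "GCTGGTGG" * 5
        m = fit_markov([seq], 5)
        n6 = count_all_kmers([seq], 6)
        n5 = count_all_kmers([seq], 5)
        want = (
            n6["GCTGGT"] * n6["CTGGTG"] * n6["TGGTGG"]
            / (n5["CTGGT"] * n5["TGGTG"])
        )
        assert expected_count(m, "GCTGGTGG") == pytest.approx(want)

    def test_plug_in_identity(self):
        seqs = ["GCTGGTGGATCGA", "TTACGGACGT"]
        m = fit_markov(seqs, 3)
        # h = m+1: the estimator degenerates to the observed count
        for word in ("GCTG", "ACGT", "TTTT"):
            assert expected_count(m, word) == count_word(seqs, word)

    def test_zero_denominator_not_evaluable(self):
        m = fit_markov(["AAAA"], 1)
        assert expected_count(m, "ACA") is None

    def test_word_shorter_than_order(self):
        m = fit_markov(["ACGTACGT"], 2)
        with pytest.raises(ValueError):
            expected_count(m, "AC")


class TestSimulateFromModel:
    def test_degenerate_chain(self):
        m = fit_markov(["AAAA"], 0)
        assert simulate_from_model(m, [5], seed=0) == ["AAAAA"]

    def test_determinism(self):
        m = fit_markov(["ACGTTGCA" * 10], 1)
        a = simulate_from_model(m, [50, 30], seed=7)
        b = simulate_from_model(m, [50, 30], seed=7)
        assert a == b

    def test_dinucleotide_frequencies_recovered(self, background_200kb):
        m = fit_markov([background_200kb[:50_000]], 1)
        (sim,) = simulate_from_model(m, [200_000], seed=3)
        probs = m.transition_matrix()
        counts2 = count_all_kmers([sim], 2)
        counts1 = count_all_kmers([sim], 1)
        for ctx_i, ctx in enumerate("ACGT"):
            for b_i, b in enumerate("ACGT"):
                phat = counts2.get(ctx + b, 0) / counts1[ctx]
                p = probs[ctx_i, b_i]
                se = np.sqrt(p * (1 - p) / counts1[ctx])
                assert abs(phat - p) < 3 * se + 1e-9


class TestNullDistribution:
    def test_degenerate_model_exact_moments(self):
        m = fit_markov(["AAAA"], 0)
        null = null_distribution(m, 2, [10, 6], B=20, seed=0)
        mean, sd = null["AA"]
        assert mean == (10 - 1) + (6 - 1)
        assert sd == 0.0

    def test_mean_tracks_expected_count(self, background_200kb):
        core = background_200kb[:30_000]
        m = fit_markov([core], 1)
        null = null_distribution(m, 4, [30_000], B=200, seed=5)
        for word in ("ACGT", "GGCC", "TTAA"):
            exp = expected_count(m, word)
            mean, sd = null[word]
            se = sd / np.sqrt(200)
            assert abs(mean - exp) < 4 * se + 1e-9

    def test_determinism(self):
        m = fit_markov(["ACGTTGCA" * 20], 0)
        a = null_distribution(m, 2, [100], B=10, seed=9)
        b = null_distribution(m, 2, [100], B=10, seed=9)
        assert a == b

    def test_b_below_two_rejected(self):
        m = fit_markov(["ACGT"], 0)
        with pytest.raises(ValueError):
            null_distribution(m, 2, [10], B=1, seed=0)


class TestZscoreWord:
    def test_zero_when_observed_equals_expected(self):
        # on AATT*50: N(AA) = 50 observed; order-0 expectation
        # N(A)^2/N(eps) = 100^2/200 = 50 exactly
        st_ = zscore_word(["AATT" * 50], "AA", 0, B=50, seed=1)
        assert st_.observed == 50
        assert st_.expected == pytest.approx(50.0)
        assert st_.z == pytest.approx(0.0)

    def test_planted_word_strongly_overrepresented(self):
        rng = np.random.default_rng(8)
        seqs = []
        for _ in range(50):
            s = "".join(
                rng.choice(list("ACGT"), size=400, p=[0.4, 0.1, 0.1, 0.4])
            )
            # plant at 3 fixed offsets per sequence
            s = s[:50] + "GCTGGTGG" + s[58:200] + "GCTGGTGG" + s[208:]
            seqs.append(s)
        st_ = zscore_word(seqs, "GCTGGTGG", 0, B=200, seed=2)
        assert st_.evaluable and st_.z > 4

    def test_absent_word_negative_z(self, background_200kb):
        core = background_200kb[:20_000]
        # pick an octamer genuinely absent from this fixed background
        word = next(
            w
            for w in ("GCGCGCAT", "ATGCGCGC", "CGCGATAT", "TACGCGCG")
            if count_word([core], w) == 0
        )
        st_ = zscore_word([core], word, 0, B=100, seed=3)
        assert st_.z is not None and st_.z < 0

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            zscore_word(["ACGTACGT" * 10], "ACGTACGT", -1)
        with pytest.raises(ValueError):
            zscore_word(["ACGTACGT" * 10], "ACG", 2)  # h < order+2

    def test_analytic_agrees_with_bootstrap(self, background_200kb):
        """Gate on the analytic fast path: on a 100 kb core the
        analytic and bootstrap z must agree within 0.3 at B=1000."""
        core = background_200kb[:100_000]
        for order in (0, 1, 2):
            zb = zscore_word(
                [core], "GCTGGTGG", order, method="bootstrap", B=1000,
                seed=40 + order,
            )
            za = zscore_word([core], "GCTGGTGG", order, method="analytic")
            assert za.evaluable and zb.evaluable
            assert abs(za.z - zb.z) <= 0.3

    def test_analytic_handles_self_overlap(self):
        # periodic word: overlap correction path must still be finite
        core = cs.simulate_genome(50_000, gc=0.5, seed=77).sequence
        st_ = zscore_word([core], "GCGCGCGC", 1, method="analytic")
        assert st_.evaluable and np.isfinite(st_.z)


class TestScoreAllModels:
    def test_six_statistics_share_observed(self, background_200kb):
        core = background_200kb[:10_000]
        stats = score_all_models([core], "GCTGGTGG", B=20, seed=0)
        assert len(stats) == 6
        assert len({s.observed for s in stats}) == 1
        assert [s.model_order for s in stats] == [0, 1, 2, 3, 4, 5]

    def test_single_order(self, background_200kb):
        stats = score_all_models(
            [background_200kb[:5000]], "GCTGGTGG", orders=[0], B=20, seed=0
        )
        assert len(stats) == 1

    def test_reproducible(self, background_200kb):
        core = [background_200kb[:5000]]
        a = score_all_models(core, "GCTGGTGG", B=30, seed=4)
        b = score_all_models(core, "GCTGGTGG", B=30, seed=4)
        assert [s.z for s in a] == [s.z for s in b]
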