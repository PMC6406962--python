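"""Matrix construction, scoring, information content, and chi-square comparison."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import deamfoot as df
from deamfoot.motif_matrix import (
    BASES,
    DegenerateMatrixError,
    WeightMatrix,
    encode_bases,
    read_matrix_tsv,
    write_matrix_tsv,
)

WINDOWS_ST = st.text(alphabet="ACGT", min_size=11, max_size=11).filter(
    lambda s: s[5] == "C"
)


# ---------------------------------------------------------------------------
# Independent naive oracle for the scoring pipeline


def naive_percent_score(W_table, scoring_positions, window7):
    """Brute-force log-odds scoring with explicit loops, table given as dicts."""
    s = 0.0
    smin = 0.0
    smax = 0.0
    for k, j in enumerate(scoring_positions):
        col = [W_table[(b, j)] for b in "ACGT"]
        s += W_table[(window7[k], j)]
        smin += min(col)
        smax += max(col)
    return 100.0 * (s - smin) / (smax - smin)


def wm_as_dict(wm):
    return {
        (b, j): wm.W[i, j + 5] for i, b in enumerate("ACGT") for j in range(-5, 6)
    }


class TestCountContexts:
    def test_single_sequence(self):
        fm = df.count_contexts(["AAAAACAAAAA"])
        f = fm.frequencies
        assert f[BASES.index("C"), 5] == 1.0
        for j in range(11):
            if j != 5:
                assert f[BASES.index("A"), j] == 1.0
        assert fm.n_sequences == 1

    def test_generator_truth_at_n200(self, t_minus1_contexts):
        fm = df.count_contexts(t_minus1_contexts)
        f = fm.frequencies
        assert f[BASES.index("T"), 4] == 1.0  # T fixed at -1
        assert f[BASES.index("C"), 5] == 1.0
        # uniform positions hover around 0.25 (binomial 99.9% band at n=200)
        assert np.all(np.abs(f[:, 0] - 0.25) < 0.11)

    def test_duplication_invariance(self):
        one = df.count_contexts(["ATGCACTGCAT"])
        two = df.count_contexts(["ATGCACTGCAT", "ATGCACTGCAT"])
        assert np.allclose(one.frequencies, two.frequencies)
        assert two.n_sequences == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no training contexts"):
            df.count_contexts([])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            df.count_contexts(["AAAAACAAAAA", "AAACAAA"])

    def test_frequencies_column_normalized(self, specs):
        for spec in specs.values():
            fm = df.count_contexts(df.simulate_context_set(spec, 97, seed=3))
            assert np.allclose(fm.frequencies.sum(axis=0), 1.0)


class TestBackground:
    def test_uniform_fixed_point(self):
        fm = df.FrequencyMatrix(counts=np.full((4, 11), 25.0), n_sequences=100)
        bg = df.background_frequencies(fm)
        assert np.allclose(bg.e, 0.25)

    def test_hand_computed_mean_of_four_flanks(self):
        # f(A) = 0.1, 0.2 at -5,-4 and 0.3, 0.4 at +4,+5 -> e(A) = 0.25
        counts = np.zeros((4, 11))
        a_counts = {0: 1, 1: 2, 9: 3, 10: 4}
        for j in range(11):
            a = a_counts.get(j, 0)
            counts[BASES.index("A"), j] = a
            counts[BASES.index("C"), j] = 10 - a
        bg = df.background_frequencies(df.FrequencyMatrix(counts, n_sequences=10))
        assert bg.e[BASES.index("A")] == pytest.approx(0.25)

    def test_degenerate_flank(self):
        counts = np.zeros((4, 11))
        counts[BASES.index("A"), [0, 1, 9, 10]] = 10
        counts[BASES.index("C"), [2, 3, 4, 5, 6, 7, 8]] = 10
        bg = df.background_frequencies(df.FrequencyMatrix(counts, n_sequences=10))
        assert bg.e[BASES.index("A")] == 1.0
        assert bg.e[1:].sum() == 0.0


class TestBuildWeightMatrix:
    def test_flat_matrix_is_degenerate(self):
        fm = df.FrequencyMatrix(counts=np.full((4, 11), 25.0), n_sequences=100)
        with pytest.raises(DegenerateMatrixError, match="degenerate"):
            df.build_weight_matrix(fm)

    def test_fourfold_enrichment_limit(self):
        # f(T,-1)=1 against e(T)=0.25 approaches log2(4) = 2 bits for large n
        n = 100_000
        counts = np.full((4, 11), n / 4.0)
        counts[:, 4] = [0, 0, 0, n]  # T fixed at -1
        counts[:, 5] = [0, n, 0, 0]  # C center
        fm = df.FrequencyMatrix(counts, n_sequences=n)
        wm = df.build_weight_matrix(fm)
        assert wm.W[BASES.index("T"), 4] == pytest.approx(2.0, abs=0.01)

    def test_smin_smax_match_bruteforce(self, t_minus1_wm):
        table = wm_as_dict(t_minus1_wm)
        smin = sum(min(table[(b, j)] for b in "ACGT") for j in range(-3, 4))
        smax = sum(max(table[(b, j)] for b in "ACGT") for j in range(-3, 4))
        assert t_minus1_wm.smin == pytest.approx(smin)
        assert t_minus1_wm.smax == pytest.approx(smax)

    def test_order_invariance(self, t_minus1_contexts):
        fwd = df.build_weight_matrix(df.count_contexts(t_minus1_contexts))
        rev = df.build_weight_matrix(df.count_contexts(t_minus1_contexts[::-1]))
        assert np.allclose(fwd.W, rev.W)

    def test_roundtrip_serialization(self, t_minus1_wm, tmp_path):
        path = tmp_path / "wm.tsv"
        write_matrix_tsv(t_minus1_wm, path)
        back = read_matrix_tsv(path)
        assert np.allclose(back.W, t_minus1_wm.W)
        assert back.scoring_positions == t_minus1_wm.scoring_positions
        assert back.smin == pytest.approx(t_minus1_wm.smin)


class TestScoring:
    def test_maximizer_and_minimizer(self, a3a_wm):
        cols = a3a_wm.scoring_columns
        best = "".join(BASES[int(a3a_wm.W[:, c].argmax())] for c in cols)
        worst = "".join(BASES[int(a3a_wm.W[:, c].argmin())] for c in cols)
        assert df.matching_score(a3a_wm, best) == pytest.approx(a3a_wm.smax)
        assert df.matching_score(a3a_wm, worst) == pytest.approx(a3a_wm.smin)
        assert df.percent_score(a3a_wm, best) == pytest.approx(100.0)
        assert df.percent_score(a3a_wm, worst) == pytest.approx(0.0)

    def test_manual_lookup_7mer(self, a3a_wm):
        window = "ATCGCAT"  # aligned to -3..+3
        expected = sum(
            a3a_wm.W[BASES.index(b), j + 5] for b, j in zip(window, range(-3, 4))
        )
        assert df.matching_score(a3a_wm, window) == pytest.approx(expected)

    def test_ambiguous_base_rejected(self, a3a_wm):
        with pytest.raises(ValueError, match="ambiguous"):
            df.matching_score(a3a_wm, "ATNGCAT")

    def test_exhaustive_enumeration_matches_naive_oracle(self, t_minus1_wm):
        """All 4^7 scoring windows: bounded in [0,100] and equal to brute force."""
        table = wm_as_dict(t_minus1_wm)
        positions = list(range(-3, 4))
        scores = []
        for combo in itertools.product("ACGT", repeat=7):
            w7 = "".join(combo)
            got = df.percent_score(t_minus1_wm, w7)
            want = naive_percent_score(table, positions, w7)
            assert got == pytest.approx(want, abs=1e-9)
            assert 0.0 <= got <= 100.0
            scores.append(got)
        # median also agrees with the brute-force distribution
        naive_median = np.median(
            [naive_percent_score(table, positions, "".join(c))
             for c in itertools.product("ACGT", repeat=7)]
        )
        assert np.median(scores) == pytest.approx(naive_median)

    @given(window=WINDOWS_ST, col=st.integers(-3, 3), delta=st.floats(-3, 3))
    def test_column_shift_invariance(self, a3a_wm, window, col, delta):
        """Adding a constant to a whole column of W leaves the percent score fixed."""
        W2 = a3a_wm.W.copy()
        W2[:, col + 5] += delta
        wm2 = WeightMatrix(W=W2, scoring_positions=a3a_wm.scoring_positions)
        assert df.percent_score(a3a_wm, window) == pytest.approx(
            df.percent_score(wm2, window), abs=1e-8
        )

    def test_random_pairs_match_naive(self, rng):
        """>=100 random (matrix, window) pairs agree with the naive pipeline."""
        for trial in range(10):
            spec = df.MotifSpec.from_pattern(
                f"r{trial}", {-1: ("T", 0.5 + 0.04 * trial)}
            )
            wm = df.build_weight_matrix(
                df.count_contexts(df.simulate_context_set(spec, 50, seed=trial))
            )
            table = wm_as_dict(wm)
            for _ in range(12):
                w7 = "".join(rng.choice(list("ACGT"), 7))
                assert df.percent_score(wm, w7) == pytest.approx(
                    naive_percent_score(table, list(range(-3, 4)), w7)
                )


class TestInformationContent:
    def test_uniform_and_point_columns(self):
        counts = np.full((4, 11), 25.0)
        counts[:, 5] = [0, 100, 0, 0]
        ic, cons = df.information_content(df.FrequencyMatrix(counts, n_sequences=100))
        assert ic[0] == pytest.approx(0.0)
        assert ic[5] == pytest.approx(2.0)
        assert cons[5] == "C"
        assert cons[0] == "."

    def test_bounds_and_center(self, specs):
        for spec in specs.values():
            fm = df.count_contexts(df.simulate_context_set(spec, 300, seed=5))
            ic, _ = df.information_content(fm)
            assert np.all((ic >= 0.0) & (ic <= 2.0))
            assert ic[5] == pytest.approx(2.0)  # strand-normalized center

    def test_tc_motif_peak_at_minus1(self, specs):
        """TC-type deaminases: T at -1 is the most informative flank position."""
        for name in ("APOBEC1", "APOBEC3A", "APOBEC3B"):
            fm = df.count_contexts(df.simulate_context_set(specs[name], 2000, seed=8))
            ic, cons = df.information_content(fm)
            flank_ic = np.delete(ic, 5)
            flank_pos = np.delete(np.arange(-5, 6), 5)
            assert flank_pos[int(flank_ic.argmax())] == -1
            assert cons[4] == "T"


class TestChi2Comparison:
    def test_identical_sets(self, t_minus1_contexts):
        cmp = df.compare_matrices_chi2(t_minus1_contexts, t_minus1_contexts)
        assert cmp.chi2 == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)

    def test_symmetry(self, specs):
        a = df.simulate_context_set(specs["AID"], 150, seed=1)
        b = df.simulate_context_set(specs["APOBEC3G"], 150, seed=2)
        assert df.compare_matrices_chi2(a, b).chi2 == pytest.approx(
            df.compare_matrices_chi2(b, a).chi2
        )

    def test_hand_tabulated_recomputation(self):
        """chi2 equals an explicit sum of (O-E)^2/E over the 10 flank positions."""
        set_a = ["AAAAACAAAAA", "AAAAACAAAAT", "ATGCACTGCAT"]
        set_b = ["TTTTTCTTTTT", "AAAAACAAAAA", "GGGGGCGGGGG"]
        expected = 0.0
        for j in [k for k in range(11) if k != 5]:
            ca = Counter(s[j] for s in set_a)
            cb = Counter(s[j] for s in set_b)
            bases = [b for b in "ACGT" if ca[b] + cb[b] > 0]
            tot = sum(ca[b] + cb[b] for b in bases)
            na, nb = sum(ca[b] for b in bases), sum(cb[b] for b in bases)
            for b in bases:
                for obs, nrow in ((ca[b], na), (cb[b], nb)):
                    e = nrow * (ca[b] + cb[b]) / tot
                    expected += (obs - e) ** 2 / e
        got = df.compare_matrices_chi2(set_a, set_b)
        assert got.chi2 == pytest.approx(expected)
        assert got.df == 30
        assert got.low_expected  # tiny sets trip the expected-count warning

    def test_df_override(self, specs):
        a = df.simulate_context_set(specs["AID"], 100, seed=1)
        b = df.simulate_context_set(specs["APOBEC1"], 100, seed=2)
        assert df.compare_matrices_chi2(a, b, df=42).df == 42

    def test_bonferroni_critical_value(self):
        assert round(df.chi2_critical_value(0.05, 15, 42), 1) == 71.1


def test_encode_bases_roundtrip():
    assert list(encode_bases("ACGT")) == [0, 1, 2, 3]
    assert encode_bases("N")[0] == 255


def test_context_set_io_text_and_fasta(tmp_path, t_minus1_contexts):
    from deamfoot.motif_matrix import read_context_set, write_context_set

    txt = tmp_path / "ctx.tsv"
    write_context_set(t_minus1_contexts[:20], txt)
    assert [w.bases for w in read_context_set(txt)] == [
        w.bases for w in t_minus1_contexts[:20]
    ]
    fa = tmp_path / "ctx.fa"
    with open(fa, "w") as fh:
        for i, w in enumerate(t_minus1_contexts[:20]):
            fh.write(f">w{i}\n{w.bases}\n")
    assert [w.bases for w in read_context_set(fa)] == [
        w.bases for w in t_minus1_contexts[:20]
    ]


def test_logo_table_columns(t_minus1_contexts):
    from deamfoot.motif_matrix import count_contexts, logo_table

    tbl = logo_table(count_contexts(t_minus1_contexts))
    assert list(tbl["position_1based"]) == list(range(1, 12))
    heights = tbl[[f"height_{b}" for b in "ACGT"]].sum(axis=1)
    assert np.allclose(heights, tbl["ic_bits"])
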