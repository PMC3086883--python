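"""Kernel correctness against brute-force enumeration oracles, plus the
Gram-matrix invariants (symmetry, PSD, normalization, combination)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calpcleave import (
    KernelConfig,
    KernelMatrix,
    WindowSpec,
    binary_encode,
    build_matrix,
    combine,
    k_linear,
    k_rbf,
    k_spectrum,
    k_string,
    normalize,
)
from calpcleave.kernels import kernel_value
from oracles import spectrum_oracle, string_oracle

ABC = "ACD"  # 3-letter test alphabet (all valid residues)


def random_strings(rng, n, length, alphabet=ABC + "X"):
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]


# --- pairwise kernels ------------------------------------------------------

class TestLinearRbf:
    def test_linear_examples(self):
        x, y = binary_encode("AC"), binary_encode("AD")
        assert k_linear(x, x) == 2.0      # identical 'X'-free windows
        assert k_linear(x, y) == 1.0      # one shared position
        assert k_linear(binary_encode("AC"), binary_encode("DG")) == 0.0

    def test_linear_length_mismatch(self):
        with pytest.raises(ValueError):
            k_linear(binary_encode("A"), binary_encode("AC"))

    def test_rbf_zero_distance(self):
        x = binary_encode("ACD")
        assert k_rbf(x, x, 1.0) == 1.0

    def test_rbf_single_substitution(self):
        # one-hot windows differing at one position: squared distance 2
        x, y = binary_encode("AC"), binary_encode("AD")
        assert k_rbf(x, y, 1.0) == pytest.approx(math.exp(-1.0))

    def test_rbf_matches_formula(self, rng):
        for _ in range(20):
            x, y = rng.random(15), rng.random(15)
            sigma = rng.uniform(0.3, 3.0)
            expected = math.exp(-sum((a - b) ** 2 for a, b in zip(x, y))
                                / (2 * sigma ** 2))
            assert k_rbf(x, y, sigma) == pytest.approx(expected)

    def test_rbf_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            k_rbf(np.ones(3), np.ones(3), 0.0)


class TestStringKernel:
    def test_self_similarity_counts_all_kmers(self):
        assert k_string("AAA", "AAA", 2) == 5  # three 1-mers + two 2-mers

    def test_partial_match(self):
        # 1-mers at offsets 0,1 plus the 2-mer "AC"
        assert k_string("ACD", "ACF", 2) == string_oracle("ACD", "ACF", 2) == 3

    def test_disjoint(self):
        assert k_string("ACD", "EFG", 3) == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k_string("AC", "ACD", 1)

    def test_closed_form_self_similarity(self):
        # X-free identical strings of length L: sum_{k<=d} (L-k+1)
        for L, d in [(5, 2), (8, 4), (6, 6)]:
            s = "ACDEFGHI"[:L]
            assert k_string(s, s, d) == sum(L - k + 1 for k in range(1, d + 1))

    def test_x_never_matches(self):
        assert k_string("AXC", "AXC", 2) == 2  # only the two flanking 1-mers

    def test_matches_oracle_exhaustive_short(self):
        for L in (1, 2, 3):
            for s in map("".join, itertools.product(ABC + "X", repeat=L)):
                for t in map("".join, itertools.product(ABC, repeat=L)):
                    for d in (1, L):
                        assert k_string(s, t, d) == string_oracle(s, t, d)

    def test_matches_oracle_random_long(self, rng):
        for L in (5, 8):
            ss = random_strings(rng, 15, L)
            ts = random_strings(rng, 15, L)
            for s, t in zip(ss, ts):
                assert k_string(s, t, 4) == string_oracle(s, t, 4)

    def test_order_one_equals_linear_on_encodings(self, rng):
        for s, t in zip(random_strings(rng, 10, 6, ABC),
                        random_strings(rng, 10, 6, ABC)):
            assert k_string(s, t, 1) == k_linear(binary_encode(s),
                                                 binary_encode(t))


class TestSpectrumKernel:
    def test_self_dot_product(self):
        # "AB"-analogue: counts A:1, C:1, AC:1 -> dot with itself = 3
        assert k_spectrum("AC", "AC", 2, 0) == 3

    def test_composition_dot_product(self):
        # d'=1, g=0: pure residue composition
        assert k_spectrum("AAC", "CAA", 1, 0) == 2 * 2 + 1 * 1

    def test_disjoint_alphabets(self):
        assert k_spectrum("AAA", "CCC", 3, 1) == 0

    def test_gapped_pattern_matches(self):
        # ACA vs ADA: A-composition dot 2*2 plus the wildcard 3-mer A.A
        assert k_spectrum("ACA", "ADA", 3, 1) == \
            spectrum_oracle("ACA", "ADA", 3, 1) == 5

    def test_unequal_lengths_allowed(self):
        assert k_spectrum("ACDA", "CA", 2, 0) == \
            spectrum_oracle("ACDA", "CA", 2, 0)

    def test_matches_oracle_exhaustive_short(self):
        for Ls, Lt in [(1, 1), (2, 2), (3, 2), (3, 3)]:
            for s in map("".join, itertools.product(ABC + "X", repeat=Ls)):
                for t in map("".join, itertools.product(ABC, repeat=Lt)):
                    assert k_spectrum(s, t, 3, 1) == spectrum_oracle(s, t, 3, 1)

    def test_matches_oracle_random_long(self, rng):
        for _ in range(10):
            s, t = random_strings(rng, 2, 8)
            for dprime, g in [(3, 0), (4, 2), (8, 3)]:
                assert k_spectrum(s, t, dprime, g) == \
                    spectrum_oracle(s, t, dprime, g)

    def test_g0_d1_equals_composition(self, rng):
        for s, t in zip(random_strings(rng, 8, 7, ABC),
                        random_strings(rng, 8, 5, ABC)):
            comp = sum(s.count(c) * t.count(c) for c in set(ABC))
            assert k_spectrum(s, t, 1, 0) == comp


@given(s=st.text(alphabet=ABC + "X", min_size=1, max_size=7),
       t=st.text(alphabet=ABC + "X", min_size=1, max_size=7))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_kernel_symmetry_and_cauchy_schwarz(s, t):
    for f in (lambda a, b: k_spectrum(a, b, 3, 1),
              lambda a, b: k_string(a.ljust(7, "X"), b.ljust(7, "X"), 3)):
        kxy, kxx, kyy = f(s, t), f(s, s), f(t, t)
        assert kxy == f(t, s)
        assert abs(kxy) <= math.sqrt(kxx * kyy) + 1e-9


# --- Gram matrices ---------------------------------------------------------

class TestBuildMatrix:
    def test_single_instance_normalized(self, small_instances, default_configs):
        one = type(small_instances)(small_instances.instances[:1],
                                    small_instances.spec)
        for cfg in default_configs:
            K = build_matrix(one, cfg)
            assert K.values.shape == (1, 1)
            assert K.values[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("kind,track", [
        ("linear", "sequence"), ("rbf", "sequence"),
        ("string", "sequence"), ("spectrum", "ss"),
    ])
    def test_symmetry_and_psd(self, small_instances, kind, track):
        cfg = KernelConfig(kind, track, WindowSpec(4, 4), sigma=1.5,
                           order_d=3, order_dprime=3, gaps_g=1)
        K = build_matrix(small_instances, cfg).values
        assert np.allclose(K, K.T, atol=1e-9)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_entries_match_pairwise_calls(self, small_instances):
        cfg = KernelConfig("string", "sequence", WindowSpec(3, 3), order_d=2,
                           normalize=False)
        insts = small_instances.instances[:10]
        K = build_matrix(insts, cfg, small_instances.spec).values
        for i in range(10):
            for j in range(10):
                assert K[i, j] == pytest.approx(kernel_value(
                    cfg, insts[i], insts[j], small_instances.spec))

    def test_spec_wider_than_stored_rejected(self, small_instances):
        cfg = KernelConfig("linear", "sequence", WindowSpec(20, 20))
        with pytest.raises(ValueError):
            build_matrix(small_instances, cfg, small_instances.spec)


class TestNormalizeCombine:
    def test_unit_diagonal_and_idempotence(self, small_instances):
        cfg = KernelConfig("spectrum", "sequence", WindowSpec(4, 4),
                           order_dprime=2, gaps_g=0, normalize=False)
        K = build_matrix(small_instances, cfg)
        N = normalize(K)
        assert np.allclose(np.diag(N.values), 1.0)
        assert np.allclose(normalize(N).values, N.values)

    def test_rank_one_cosine(self):
        K = KernelMatrix(np.array([[4.0, 2.0], [2.0, 1.0]]))
        assert np.allclose(normalize(K).values, 1.0)

    def test_zero_row_handling(self):
        K = KernelMatrix(np.array([[0.0, 0.0], [0.0, 3.0]]))
        N = normalize(K).values
        assert N[0, 0] == 1.0 and N[0, 1] == 0.0 and N[1, 1] == 1.0

    def test_combine_identity_and_zero(self, small_instances, default_configs):
        Ks = [build_matrix(small_instances, c) for c in default_configs]
        assert np.allclose(combine(Ks, [1, 0, 0]).values, Ks[0].values)
        assert np.allclose(combine(Ks, [0, 0, 0]).values, 0.0)

    def test_combination_stays_psd(self, small_instances, default_configs, rng):
        Ks = [build_matrix(small_instances, c) for c in default_configs]
        betas = rng.dirichlet(np.ones(3))
        C = combine(Ks, betas).values
        assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_combine_rejects_negative_weight(self, small_instances,
                                             default_configs):
        Ks = [build_matrix(small_instances, c) for c in default_configs]
        with pytest.raises(ValueError):
            combine(Ks, [1.0, -0.1, 0.1])


def test_kernel_matrix_tsv_roundtrip(tmp_path, small_instances, default_configs):
    K = build_matrix(small_instances, default_configs[1])
    p = tmp_path / "k.tsv"
    K.to_tsv(p)
    K2 = KernelMatrix.from_tsv(p)
    assert K2.ids == K.ids
    assert np.allclose(K2.values, K.values, atol=1e-10)
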