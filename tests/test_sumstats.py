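import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupdiv import sumstats as ss
from dupdiv.msio import MISSING, HaplotypeMatrix

from conftest import brute_force_pi, random_matrix

# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def test_pi_single_pair_counts_differences():
    m = np.array([[0, 1, 0, 1, 1], [1, 1, 1, 0, 1]])
    assert ss.nucleotide_diversity(m) == 3.0


def test_pi_no_segregating_sites():
    assert ss.nucleotide_diversity(np.zeros((4, 0), dtype=int)) == 0.0


def test_pi_matches_brute_force_on_fuzzed_matrices(rng):
    for _ in range(100):
        m = random_matrix(rng)
        assert ss.nucleotide_diversity(m) == pytest.approx(
            brute_force_pi(m.alleles), abs=1e-12
        )


def test_pi_requires_two_sequences():
    with pytest.raises(ValueError):
        ss.nucleotide_diversity(np.ones((1, 3), dtype=int))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def _tajima_oracle(arr):
    """Step-by-step evaluation of the 1989 constants, independent of the
    implementation under test."""
    n, _ = arr.shape
    counts = arr.sum(axis=0)
    seg = [c for c in counts if 0 < c < n]
    S = len(seg)
    if S == 0:
        return math.nan
    pi = brute_force_pi(arr)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # degenerate at n=2, where the D variance vanishes
        return math.nan
    return (pi - S / a1) / math.sqrt(var)


def test_tajimas_d_hand_matrix_matches_formula_oracle():
    arr = np.array(
        [
            [0, 0, 1],
            [1, 0, 1],
            [1, 1, 0],
            [0, 0, 0],
            [1, 0, 1],
        ]
    )
    assert ss.tajimas_d(arr) == pytest.approx(_tajima_oracle(arr), rel=1e-12)


def test_tajimas_d_fuzz_against_oracle(rng):
    for _ in range(50):
        m = random_matrix(rng)
        got = ss.tajimas_d(m)
        want = _tajima_oracle(m.alleles)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-10)


def test_tajimas_d_nan_when_no_segregating_sites():
    assert math.isnan(ss.tajimas_d(np.zeros((5, 0), dtype=int)))
    assert math.isnan(ss.tajimas_d(np.ones((5, 2), dtype=int)))  # fixed columns


# ---------------------------------------------------------------------------
# Fay & Wu's H
# ---------------------------------------------------------------------------


def test_fay_wu_h_is_zero_for_two_sequences(rng):
    for _ in range(20):
        m = random_matrix(rng, n_max=2, n_min=2)
        h = ss.fay_wu_h(m)
        if not math.isnan(h):
            assert h == pytest.approx(0.0, abs=1e-12)


def test_fay_wu_h_high_frequency_derived_example():
    # one site at derived count 9 of n=10: H = 2*9/90 - 2*81/90 = -1.6
    arr = np.vstack([np.ones((9, 1), dtype=int), np.zeros((1, 1), dtype=int)])
    assert ss.fay_wu_h(arr) == pytest.approx(-1.6)


def test_fay_wu_h_sign_flips_under_spectrum_reflection():
    """On a spectrum skewed toward high-frequency derived alleles H is
    negative; replacing derived counts i by n-i flips the sign."""
    n = 12
    rng = np.random.default_rng(7)
    counts = rng.integers(n - 3, n, size=30)  # high-frequency skew

    def matrix_from_counts(cs):
        cols = [np.concatenate([np.ones(c, int), np.zeros(n - c, int)]) for c in cs]
        return np.column_stack(cols)

    h = ss.fay_wu_h(matrix_from_counts(counts))
    h_flipped = ss.fay_wu_h(matrix_from_counts(n - counts))
    assert h < 0 < h_flipped


# ---------------------------------------------------------------------------
# haplotype diversity
# ---------------------------------------------------------------------------


def test_dh_identical_rows_is_zero():
    assert ss.haplotype_diversity(np.ones((6, 4), dtype=int)) == 0.0


def test_dh_all_distinct_is_one():
    arr = np.eye(5, dtype=int)
    assert ss.haplotype_diversity(arr) == pytest.approx(1.0)


def test_dh_two_classes():
    arr = np.vstack([np.zeros((30, 1), int), np.ones((20, 1), int)])
    assert ss.haplotype_diversity(arr) == pytest.approx(
        50 / 49 * (1 - (0.6**2 + 0.4**2))
    )
    assert ss.haplotype_diversity(arr) == pytest.approx(0.489796, abs=1e-6)


# ---------------------------------------------------------------------------
# permutation invariance (applies to every statistic)
# ---------------------------------------------------------------------------


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_statistics_invariant_to_row_and_column_order(seed):
    rng = np.random.default_rng(seed)
    arr = random_matrix(rng, n_max=8, s_max=8).alleles
    perm = arr[rng.permutation(arr.shape[0])][:, rng.permutation(arr.shape[1])]
    for fn in (
        ss.nucleotide_diversity,
        ss.tajimas_d,
        ss.fay_wu_h,
        ss.haplotype_diversity,
        ss.segregating_sites,
    ):
        a, b = fn(arr), fn(perm)
        if isinstance(a, float) and math.isnan(a):
            assert math.isnan(b)
        else:
            assert a == pytest.approx(b, rel=1e-10)


# ---------------------------------------------------------------------------
# genotype pi
# ---------------------------------------------------------------------------


def test_genotype_pi_monomorphic_is_zero():
    assert ss.genotype_pi(np.zeros((5, 10), dtype=int), 1000.0) == 0.0


def test_genotype_pi_all_heterozygous_example():
    g = np.ones((1, 20), dtype=int)
    assert ss.genotype_pi(g, 5000.0) == pytest.approx((40 / 39) * 0.5 / 5000)


def test_genotype_pi_equals_haplotype_pi_for_any_phasing(rng):
    """pi depends only on per-site allele counts, so collapsing phased
    haplotype pairs into unphased genotypes must preserve it exactly."""
    for _ in range(30):
        m = random_matrix(rng, n_max=10, n_min=4)
        if m.n_sequences % 2:
            m = HaplotypeMatrix(
                m.alleles[:-1], m.positions, block_length=m.block_length
            )
        hap = m.alleles
        geno = (hap[0::2] + hap[1::2]).T  # (sites, diploids)
        L = 777.0
        # haplotype pi uses n(n-1); genotype pi uses the identical unbiased
        # per-site factor, so the two agree exactly
        assert ss.genotype_pi(geno, L) == pytest.approx(
            ss.nucleotide_diversity(hap) / L, rel=1e-12
        )


def test_genotype_pi_missingness_uses_per_site_m():
    g = np.array([[1, 1, MISSING, MISSING]])  # 2 informative diploids, both het
    assert ss.genotype_pi(g, 1.0) == pytest.approx((4 / 3) * 2 * 0.5 * 0.5)


def test_genotype_pi_rejects_bad_length():
    with pytest.raises(ValueError):
        ss.genotype_pi(np.zeros((1, 4), int), 0.0)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Full enumeration over heterozygote counts with the same allele totals."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    probs = {}
    for h in range(min(n_alt, 2 * n - n_alt) + 1):
        if (n_alt - h) % 2:
            continue
        alt_hom = (n_alt - h) // 2
        ref_hom = n - h - alt_hom
        if ref_hom < 0:
            continue
        log_p = (
            math.lgamma(n + 1)
            - math.lgamma(ref_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(alt_hom + 1)
            + h * math.log(2.0)
        )
        probs[h] = math.exp(log_p)
    total = sum(probs.values())
    obs = probs[n_het] / total
    return sum(p for p in probs.values() if p / total <= obs * (1 + 1e-9)) / total


def test_hwe_monomorphic_is_one():
    assert ss.hwe_exact_test(1, 0, 0) == 1.0
    assert ss.hwe_exact_test(0, 0, 7) == 1.0


def test_hwe_all_heterozygotes_is_extreme():
    assert ss.hwe_exact_test(0, 20, 0) < 0.05


def test_hwe_small_example_matches_enumeration():
    assert ss.hwe_exact_test(2, 2, 2) == pytest.approx(
        hwe_enumeration_oracle(2, 2, 2), rel=1e-9
    )


def test_hwe_matches_enumeration_for_all_small_tables():
    for n_ref, n_het, n_alt in itertools.product(range(0, 11), repeat=3):
        if n_ref + n_het + n_alt == 0 or n_ref + n_het + n_alt > 30:
            continue
        got = ss.hwe_exact_test(n_ref, n_het, n_alt)
        want = hwe_enumeration_oracle(n_ref, n_het, n_alt)
        assert got == pytest.approx(want, rel=1e-8), (n_ref, n_het, n_alt)
        assert 0.0 < got <= 1.0


def test_hwe_rejection_rate_conservative_under_null(rng):
    """Under binomially sampled HWE genotypes, the exact test rejects at
    most ~alpha of the time (it is conservative)."""
    n_sites, n = 3000, 30
    rejections = 0
    for _ in range(n_sites):
        p = rng.uniform(0.1, 0.9)
        g = rng.binomial(2, p, size=n)
        pval = ss.hwe_exact_test(
            int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
        )
        rejections += pval < 0.05
    rate = rejections / n_sites
    se = math.sqrt(0.05 * 0.95 / n_sites)
    assert rate <= 0.05 + 2 * se


def test_hwe_rejects_empty_table():
    with pytest.raises(ValueError):
        ss.hwe_exact_test(0, 0, 0)
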