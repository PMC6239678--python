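import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dupdiv import cnvdiv
from dupdiv.cnvdiv import (
    CNStatus,
    FlankError,
    PairedComparison,
    apply_min_snv_filter,
    classify_cn,
    define_flanks,
    draw_groups,
    hwe_filtered_pi,
    hwe_fractions,
    paired_comparison,
    run_pipeline,
    select_eligible_cnvs,
)
from dupdiv.msio import CNVTable
from dupdiv.synthgen import SynthConfig, generate_cohort

# ---------------------------------------------------------------------------
# CN classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pair,status",
    [
        ((0, 0), CNStatus.CN_MINUS),
        ((0, 1), CNStatus.CN_MINUS),
        ((1, 1), CNStatus.CN_REF),
        ((1, 2), CNStatus.CN_PLUS),
        ((0, 2), CNStatus.CN_PLUS),
        ((2, 3), CNStatus.CN_PLUS),
    ],
)
def test_classify_cn_examples(pair, status):
    assert classify_cn(pair) is status


def test_classify_cn_partitions_all_pairs():
    seen = {s: 0 for s in CNStatus}
    for pair in itertools.product(range(5), repeat=2):
        seen[classify_cn(pair)] += 1
    assert sum(seen.values()) == 25
    assert all(v > 0 for v in seen.values())


def test_classify_cn_symmetric_in_allele_order():
    for pair in itertools.product(range(4), repeat=2):
        assert classify_cn(pair) is classify_cn(pair[::-1])


# ---------------------------------------------------------------------------
# eligibility and group draws
# ---------------------------------------------------------------------------


def _table_with_counts(n_ref, n_plus, n_minus=0):
    rows = []
    sid = 0
    for count, pair in ((n_ref, (1, 1)), (n_plus, (1, 2)), (n_minus, (0, 1))):
        for _ in range(count):
            rows.append(("c1", "chr1", 50_000, 55_000, f"s{sid}", *pair))
            sid += 1
    return CNVTable(pd.DataFrame(rows, columns=list(CNVTable.REQUIRED)))


def test_eligibility_threshold_is_twenty_per_group():
    assert select_eligible_cnvs(_table_with_counts(50, 19)) == []
    assert select_eligible_cnvs(_table_with_counts(20, 20)) == ["c1"]
    assert select_eligible_cnvs(_table_with_counts(19, 50)) == []


def test_no_eligible_cnvs_is_clean():
    tab = _table_with_counts(5, 5)
    report = run_pipeline(
        _empty_genotypes(tab), tab, seed=1
    )
    assert len(report.region_pi) == 0
    assert len(report.paired_tests) == 0


def _empty_genotypes(tab):
    from dupdiv.msio import GenotypeMatrix

    return GenotypeMatrix(
        tab.samples, "chr1", np.empty(0, np.int64),
        np.zeros((0, len(tab.samples)), np.int8),
    )


def test_draw_groups_exact_availability_returns_full_sets():
    statuses = {f"r{i}": CNStatus.CN_REF for i in range(20)}
    statuses |= {f"p{i}": CNStatus.CN_PLUS for i in range(20)}
    cnr, cnp = draw_groups(statuses, seed=3)
    assert sorted(cnr) == sorted(s for s in statuses if s.startswith("r"))
    assert sorted(cnp) == sorted(s for s in statuses if s.startswith("p"))


def test_draw_groups_deterministic_and_validated():
    statuses = {f"r{i}": CNStatus.CN_REF for i in range(30)}
    statuses |= {f"p{i}": CNStatus.CN_PLUS for i in range(30)}
    assert draw_groups(statuses, seed=9) == draw_groups(statuses, seed=9)
    with pytest.raises(ValueError, match="insufficient"):
        draw_groups({"a": CNStatus.CN_REF}, n_per_group=20)


def test_draw_groups_uniform_over_samples():
    """Inclusion frequencies across reseeded draws are uniform (chi-square)."""
    n_avail, n_draw, reps = 25, 20, 10_000
    statuses = {f"r{i}": CNStatus.CN_REF for i in range(n_avail)}
    statuses |= {f"p{i}": CNStatus.CN_PLUS for i in range(25)}
    counts = {f"r{i}": 0 for i in range(n_avail)}
    rng = np.random.default_rng(17)
    for _ in range(reps):
        cnr, _ = draw_groups(statuses, rng=rng)
        for s in cnr:
            counts[s] += 1
    observed = np.array(list(counts.values()))
    expected = reps * n_draw / n_avail
    chi2 = ((observed - expected) ** 2 / expected).sum()
    assert sps.chi2.sf(chi2, n_avail - 1) > 1e-3


# ---------------------------------------------------------------------------
# flanks
# ---------------------------------------------------------------------------


def _flank_table(extra=()):
    rows = [("c1", "chr1", 100_000, 105_000, "s0", 1, 1)]
    for i, (start, end) in enumerate(extra):
        rows.append((f"x{i}", "chr1", start, end, "s0", 1, 1))
    return CNVTable(pd.DataFrame(rows, columns=list(CNVTable.REQUIRED)))


def test_define_flanks_arithmetic():
    f5, f3, masked = define_flanks(("chr1", 100_000, 105_000), _flank_table(),
                                   region_id="c1")
    assert f5 == ("chr1", 94_000, 99_000)
    assert f3 == ("chr1", 106_000, 111_000)
    assert masked == []


def test_define_flanks_masks_other_cnv_overlap():
    tab = _flank_table(extra=[(94_500, 95_000)])
    _, _, masked = define_flanks(("chr1", 100_000, 105_000), tab, region_id="c1")
    assert masked == [(94_500, 95_000)]


def test_define_flanks_below_zero_is_unusable():
    with pytest.raises(FlankError):
        define_flanks(("chr1", 3000, 8000), _flank_table(), region_id="c1")


def test_flank_lengths_equal_cnv_length_with_exact_gaps(rng):
    for _ in range(30):
        start = int(rng.integers(10_000, 10**6))
        length = int(rng.integers(100, 8000))
        f5, f3, _ = define_flanks(("chr1", start, start + length), _flank_table(),
                                  region_id="c1")
        assert f5[2] - f5[1] == length and f3[2] - f3[1] == length
        assert start - f5[2] == 1000 and f3[1] - (start + length) == 1000


# ---------------------------------------------------------------------------
# min-SNV filter
# ---------------------------------------------------------------------------


def test_min_snv_filter_thresholds():
    counts = pd.DataFrame(
        [
            ("a", "flank5", 5), ("a", "cnv", 1), ("a", "flank3", 5),
            ("b", "flank5", 2), ("b", "cnv", 2), ("b", "flank3", 2),
        ],
        columns=["cnv_id", "region_type", "n_snvs"],
    )
    assert apply_min_snv_filter(counts) == ["b"]
    assert apply_min_snv_filter(counts.iloc[:0]) == []


# ---------------------------------------------------------------------------
# HWE fractions and filtered pi
# ---------------------------------------------------------------------------


def test_hwe_fraction_half_when_one_of_two_sites_fails():
    # site 1: 20 diploids all heterozygous (extreme excess, p < 0.05);
    # site 2: perfect HWE proportions 5/10/5
    g = np.vstack([
        np.ones(20, dtype=np.int8),
        np.array([0] * 5 + [1] * 10 + [2] * 5, dtype=np.int8),
    ])
    res = hwe_fractions(g, cnv_id="c", group="CN+")
    assert res.fraction == pytest.approx(0.5)
    assert res.n_snvs == 2


def test_hwe_fraction_zero_for_well_behaved_sites():
    g = np.tile(np.array([0] * 8 + [1] * 16 + [2] * 8, dtype=np.int8), (4, 1))
    assert hwe_fractions(g).fraction == 0.0


def test_hwe_fraction_undefined_without_polymorphism():
    assert hwe_fractions(np.zeros((3, 10), dtype=np.int8)) is None
    assert hwe_fractions(np.zeros((0, 10), dtype=np.int8)) is None


def test_hwe_fraction_bounded_on_fuzzed_input(rng):
    for _ in range(30):
        g = rng.integers(0, 3, size=(rng.integers(1, 15), 20)).astype(np.int8)
        res = hwe_fractions(g)
        if res is not None:
            assert 0.0 <= res.fraction <= 1.0


def test_hwe_filtered_pi_identity_and_zero():
    in_hwe = np.array([[0] * 5 + [1] * 10 + [2] * 5], dtype=np.int8)
    from dupdiv.sumstats import genotype_pi

    assert hwe_filtered_pi(in_hwe, 100.0) == pytest.approx(
        genotype_pi(in_hwe, 100.0)
    )
    all_failing = np.ones((3, 20), dtype=np.int8)
    assert hwe_filtered_pi(all_failing, 100.0) == 0.0


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------


def test_paired_comparison_closed_form():
    cmp_ = paired_comparison([10.0, 10.0, 10.0], [11.0, 12.0, 13.0])
    assert cmp_.n == 3 and cmp_.df == 2
    assert cmp_.mean_difference == pytest.approx(2.0)
    assert cmp_.percent_increase == pytest.approx(20.0)
    t_want = 2.0 / (1.0 / math.sqrt(3))  # mean/ (sd/sqrt(n)) with sd=1
    assert cmp_.t_statistic == pytest.approx(t_want)
    assert cmp_.p_value == pytest.approx(2 * sps.t.sf(t_want, 2))


def test_paired_comparison_zero_deltas():
    cmp_ = paired_comparison([1.0, 2.0], [1.0, 2.0])
    assert cmp_.mean_difference == 0.0
    assert cmp_.percent_increase == 0.0
    assert math.isnan(cmp_.p_value)


def test_paired_comparison_antisymmetric():
    a, b = [1.0, 2.0, 4.0], [2.0, 2.5, 7.0]
    fwd = paired_comparison(a, b)
    rev = paired_comparison(b, a)
    assert rev.mean_difference == pytest.approx(-fwd.mean_difference)
    assert rev.t_statistic == pytest.approx(-fwd.t_statistic)
    assert rev.p_value == pytest.approx(fwd.p_value)


def test_paired_comparison_needs_two_pairs():
    with pytest.raises(ValueError):
        paired_comparison([1.0], [2.0])


# ---------------------------------------------------------------------------
# full pipeline on synthetic cohorts
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def psv_cohort():
    return generate_cohort(
        SynthConfig(n_samples=100, n_cnvs=10, cnv_length=2000, psv_count=3, seed=55)
    )


def test_pipeline_deterministic_given_seed(psv_cohort):
    a = run_pipeline(psv_cohort.genotypes, psv_cohort.cnv_table, seed=4)
    b = run_pipeline(psv_cohort.genotypes, psv_cohort.cnv_table, seed=4)
    pd.testing.assert_frame_equal(a.region_pi, b.region_pi)
    pd.testing.assert_frame_equal(a.paired_tests, b.paired_tests)


def test_pipeline_conserves_every_eligible_cnv(psv_cohort):
    report = run_pipeline(psv_cohort.genotypes, psv_cohort.cnv_table, seed=4)
    eligible = set(select_eligible_cnvs(psv_cohort.cnv_table))
    analyzed = set(report.region_pi["cnv_id"])
    pi_excluded = {
        c for _, (p, c, r) in report.exclusions.iterrows()
        if "zero_snv_group" not in r
    }
    assert analyzed | pi_excluded == eligible
    assert not analyzed & pi_excluded


def test_pipeline_recovers_planted_signal(psv_cohort):
    report = run_pipeline(psv_cohort.genotypes, psv_cohort.cnv_table, seed=4)
    row = report.paired_tests.query("region_type == 'cnv'").iloc[0]
    assert row["mean_difference"] > 0
    assert row["p_value"] < 0.05
    # HWE-failure fraction higher among duplication carriers
    hwe_row = report.hwe_tests.query("subset == 'all'").iloc[0]
    assert hwe_row["mean_difference"] > 0


def test_pipeline_per_population_scopes():
    coh = generate_cohort(
        SynthConfig(n_samples=120, n_cnvs=6, cnv_length=2000, psv_count=2, seed=77)
    )
    ids = coh.genotypes.sample_ids
    pops = {"POP1": ids[:60], "POP2": ids[60:]}
    report = run_pipeline(coh.genotypes, coh.cnv_table, populations=pops, seed=5)
    scopes = set(report.paired_tests["scope"])
    assert "pooled" in scopes
    # per-population rows appear whenever a population has >= 2 analyzed CNVs
    analyzed = report.region_pi.groupby("population")["cnv_id"].nunique()
    for pop, n in analyzed.items():
        if n >= 2:
            assert pop in scopes


def test_pipeline_report_round_trip(tmp_path, psv_cohort):
    report = run_pipeline(psv_cohort.genotypes, psv_cohort.cnv_table, seed=4)
    report.write(tmp_path)
    for name in (
        "region_pi.tsv", "paired_tests.tsv", "hwe_fractions.tsv",
        "hwe_tests.tsv", "filtered_tests.tsv", "exclusions.log",
        "summary.txt", "flanks.bed",
    ):
        assert (tmp_path / name).exists()
    back = pd.read_csv(tmp_path / "region_pi.tsv", sep="\t")
    assert len(back) == len(report.region_pi)
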