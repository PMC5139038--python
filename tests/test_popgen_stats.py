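import itertools
import math

import numpy as np
import pytest

from svbalscan import (
    DegenerateInput,
    Region,
    cross_group_tmrca,
    delta_ihh,
    ehh_curve,
    hudson_fst,
    nucleotide_diversity,
    sliding_window_scan,
    tajimas_d,
    watterson_theta,
    window_spans,
)
from svbalscan.popgen_stats import TajimaConstants

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_pairwise_oracle(alleles):
    """O(n²) mean pairwise Hamming distance."""
    n = len(alleles)
    total = sum(
        np.sum(alleles[i] != alleles[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def tajima_oracle(alleles):
    """Independently coded Tajima (1989) D."""
    n, _ = alleles.shape
    counts = alleles.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    k = pi_pairwise_oracle(alleles)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def random_matrices(n_matrices, max_n=30, max_sites=100, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_matrices):
        n = int(rng.integers(4, max_n + 1)) // 2 * 2
        s = int(rng.integers(1, max_sites + 1))
        freq = rng.random(s)
        yield (rng.random((n, s)) < freq).astype(np.int8)


# ---------------------------------------------------------------------------
# π / θ_W / Tajima's D
# ---------------------------------------------------------------------------

class TestNucleotideDiversity:
    def test_three_haplotypes_one_site(self):
        h = make_matrix(["0", "0", "1"])
        assert nucleotide_diversity(h) == pytest.approx(2 / 3)

    def test_monomorphic_is_zero(self):
        h = make_matrix(["00", "00", "00"])
        assert nucleotide_diversity(h) == 0.0

    def test_four_haplotypes_two_sites(self):
        h = make_matrix(["00", "01", "10", "11"])
        assert nucleotide_diversity(h) == pytest.approx(4 / 3)

    def test_matches_pairwise_oracle_on_random_matrices(self):
        for alleles in random_matrices(200, seed=12):
            h = make_matrix(alleles)
            assert nucleotide_diversity(h) == pytest.approx(
                pi_pairwise_oracle(alleles), abs=1e-9
            )

    def test_per_bp_variant_scales_by_span(self):
        h = make_matrix(["01", "10"], positions=[0, 999])
        assert nucleotide_diversity(h, per_bp=True) == pytest.approx(
            nucleotide_diversity(h) / 1000
        )


class TestWattersonTheta:
    def test_closed_form_n4(self):
        assert watterson_theta(3, 4) == pytest.approx(18 / 11)

    def test_n2_denominator_is_one(self):
        assert watterson_theta(5, 2) == pytest.approx(5.0)

    def test_zero_sites(self):
        assert watterson_theta(0, 17) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            watterson_theta(3, 1)


class TestTajimasD:
    def test_two_balanced_sites_n4(self):
        h = make_matrix(["11", "11", "00", "00"])
        assert tajimas_d(h) == pytest.approx(1.893, abs=1e-3)

    def test_monomorphic_is_missing(self):
        h = make_matrix(["00", "00", "00", "00"])
        assert tajimas_d(h) is None

    def test_all_singletons_negative(self):
        alleles = np.eye(20, dtype=np.int8)
        h = make_matrix(alleles)
        assert tajimas_d(h) < 0
        assert tajimas_d(h) == pytest.approx(tajima_oracle(alleles), abs=1e-9)

    def test_matches_constants_oracle_on_random_matrices(self):
        for alleles in random_matrices(200, seed=99):
            h = make_matrix(alleles)
            expected = tajima_oracle(alleles)
            got = tajimas_d(h)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_site_and_haplotype_order(self):
        rng = np.random.default_rng(4)
        alleles = (rng.random((12, 40)) < 0.3).astype(np.int8)
        h = make_matrix(alleles)
        shuffled = alleles[rng.permutation(12)][:, rng.permutation(40)]
        h2 = make_matrix(shuffled)
        assert tajimas_d(h) == pytest.approx(tajimas_d(h2), abs=1e-12)

    def test_too_few_haplotypes_rejected(self):
        h = make_matrix(["01", "10"])
        with pytest.raises(DegenerateInput):
            tajimas_d(h)

    def test_constants_satisfy_identities(self):
        k = TajimaConstants.for_n(25)
        assert k.a1 == pytest.approx(sum(1 / i for i in range(1, 25)))
        assert k.e1 == pytest.approx(k.c1 / k.a1)
        assert k.e2 == pytest.approx(k.c2 / (k.a1**2 + k.a2))


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def fst_site_oracle(p1, p2, n1, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def two_pop_matrix(freqs_a, freqs_b, n_per=10, seed=0):
    rng = np.random.default_rng(seed)
    cols_a, cols_b = [], []
    for pa, pb in zip(freqs_a, freqs_b):
        ca = np.zeros(n_per, dtype=np.int8)
        ca[: int(round(pa * n_per))] = 1
        cb = np.zeros(n_per, dtype=np.int8)
        cb[: int(round(pb * n_per))] = 1
        cols_a.append(ca)
        cols_b.append(cb)
    alleles = np.concatenate(
        [np.stack(cols_a, axis=1), np.stack(cols_b, axis=1)], axis=0
    )
    return make_matrix(alleles, pops=["A"] * n_per + ["B"] * n_per)


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        h = two_pop_matrix([1.0], [0.0])
        assert hudson_fst(h, "A", "B") == pytest.approx(1.0)

    def test_intermediate_divergence_matches_hand_value(self):
        h = two_pop_matrix([0.2], [0.8])
        expected = (0.36 - 2 * 0.16 / 9) / 0.68
        assert hudson_fst(h, "A", "B") == pytest.approx(expected)
        assert hudson_fst(h, "A", "B") == pytest.approx(0.4771, abs=1e-4)

    def test_equal_frequencies_give_negative_finite_sample_value(self):
        h = two_pop_matrix([0.5], [0.5])
        num, den = fst_site_oracle(0.5, 0.5, 10, 10)
        assert hudson_fst(h, "A", "B") == pytest.approx(num / den)
        assert hudson_fst(h, "A", "B") < 0

    def test_fixed_same_allele_site_skipped(self):
        h = two_pop_matrix([1.0, 0.2], [1.0, 0.8])
        num, den = fst_site_oracle(0.2, 0.8, 10, 10)
        assert hudson_fst(h, "A", "B") == pytest.approx(num / den)

    def test_window_value_is_ratio_of_averages(self):
        h = two_pop_matrix([0.1, 0.9, 0.5], [0.3, 0.4, 0.5])
        nums, dens = zip(*(
            fst_site_oracle(a, b, 10, 10)
            for a, b in [(0.1, 0.3), (0.9, 0.4), (0.5, 0.5)]
        ))
        assert hudson_fst(h, "A", "B") == pytest.approx(sum(nums) / sum(dens))

    def test_self_split_is_near_zero_across_replicates(self):
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(100):
            freq = rng.random(40) * 0.8 + 0.1
            alleles = (rng.random((40, 40)) < freq).astype(np.int8)
            labels = np.array(["A"] * 20 + ["B"] * 20)
            rng.shuffle(labels)
            h = make_matrix(alleles, pops=labels.tolist())
            v = hudson_fst(h, "A", "B")
            if v is not None:
                vals.append(v)
        assert abs(np.mean(vals)) < 0.05


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

class TestEHH:
    def test_identical_class_stays_at_one(self):
        h = make_matrix(["0101", "0101", "0101", "1010", "1010", "1010"])
        res = ehh_curve(h, {"c": np.arange(3)}, "down", anchor=0)
        assert np.allclose(res.ehh["c"], 1.0)

    def test_offset_zero_is_one_by_definition(self):
        h = make_matrix(["01", "10", "11", "00"])
        res = ehh_curve(h, {"c": np.arange(4)}, "down", anchor=0)
        assert res.ehh["c"][0] == 1.0
        assert res.distances["c"][0] == 0.0

    def test_two_two_split_gives_one_third(self):
        h = make_matrix(["0", "0", "1", "1"])
        res = ehh_curve(h, {"c": np.arange(4)}, "down", anchor=0)
        # C(2,2)+C(2,2) over C(4,2)
        assert res.ehh["c"][1] == pytest.approx(1 / 3)

    def test_curve_is_non_increasing(self):
        rng = np.random.default_rng(23)
        h = make_matrix((rng.random((10, 30)) < 0.4).astype(np.int8))
        res = ehh_curve(h, {"c": np.arange(10)}, "down", anchor=0, truncate=0.0)
        assert np.all(np.diff(res.ehh["c"]) <= 1e-12)

    def test_singleton_class_rejected(self):
        h = make_matrix(["01", "10"])
        with pytest.raises(DegenerateInput, match="degenerate core class"):
            ehh_curve(h, {"c": np.array([0])}, "down")


class TestDeltaIHH:
    def test_identical_classes_give_zero_delta(self):
        h = make_matrix(
            ["0101", "0101", "0101", "0101"], positions=[100, 200, 300, 400]
        )
        ihh_c, ihh_n, d = delta_ihh(h, [1, 1, 0, 0],
                                    core_span=Region("chr1", 240, 260))
        assert ihh_c == pytest.approx(ihh_n)
        assert d == pytest.approx(0.0)

    def test_trapezoid_area_for_known_curve(self):
        # carrier class: 4 identical haplotypes (EHH stays 1)
        # non-carrier: splits 2/2 at the single downstream site -> EHH 1/3
        rows = ["0", "0", "0", "0", "0", "0", "1", "1"]
        h = make_matrix(rows, positions=[1000])
        ihh_c, ihh_n, d = delta_ihh(h, [1, 1, 1, 1, 0, 0, 0, 0],
                                    core_span=Region("chr1", 0, 1))
        # distance from core end (0 half-open -> anchor 1) to site = 999
        assert ihh_c == pytest.approx(999.0)          # EHH 1 throughout
        assert ihh_n == pytest.approx((1 + 1 / 3) / 2 * 999)
        assert d == pytest.approx(ihh_n - ihh_c)

    def test_ihh_additive_over_concatenated_intervals(self):
        rng = np.random.default_rng(31)
        alleles = (rng.random((8, 20)) < 0.3).astype(np.int8)
        h = make_matrix(alleles, positions=np.arange(20) * 50 + 100)
        res = ehh_curve(h, {"c": np.arange(8)}, "down", anchor=0, truncate=0.0)
        d, e = res.distances["c"], res.ehh["c"]
        split = 10
        left = np.trapezoid(e[: split + 1], d[: split + 1])
        right = np.trapezoid(e[split:], d[split:])
        assert left + right == pytest.approx(res.ihh["c"])


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

class TestSlidingWindows:
    def test_full_window_count(self):
        region = Region("chr1", 0, 36_000)
        spans = window_spans(region, 30_000, 3_000)
        full = [s for s, partial in spans if not partial]
        assert len(full) == 3

    def test_window_pi_equals_direct_subset_computation(self):
        rng = np.random.default_rng(6)
        h = make_matrix((rng.random((10, 50)) < 0.3).astype(np.int8),
                        positions=np.sort(rng.choice(10_000, 50, replace=False)))
        region = Region("chr1", 0, 10_000)
        windows = sliding_window_scan(h, region, window=2_000, step=1_000)
        for w in windows:
            assert w.pi == pytest.approx(nucleotide_diversity(h.subset_region(w.window)))

    def test_short_region_yields_single_partial_window(self):
        region = Region("chr1", 0, 5_000)
        spans = window_spans(region, 30_000, 3_000)
        assert len(spans) == 1
        assert spans[0][1] is True
        assert spans[0][0].length == 5_000


# ---------------------------------------------------------------------------
# cross-group TMRCA
# ---------------------------------------------------------------------------

class TestCrossGroupTmrca:
    def test_known_mean_difference(self):
        # classes differ at exactly 4 sites
        h = make_matrix(["1111", "1111", "0000", "0000"])
        t = cross_group_tmrca(h, ([0, 1], [2, 3]), mu=2.5e-8, length_bp=5000)
        assert t == pytest.approx(16_000)

    def test_identical_classes_give_zero(self):
        h = make_matrix(["0101", "0101", "0101", "0101"])
        assert cross_group_tmrca(h, ([0, 1], [2, 3]), 1e-8, 1000) == 0.0

    def test_nonpositive_mu_rejected(self):
        h = make_matrix(["01", "10"])
        with pytest.raises(ValueError):
            cross_group_tmrca(h, ([0], [1]), 0.0, 1000)
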