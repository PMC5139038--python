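import numpy as np
import pytest

from svbalscan import (
    Region,
    SimulationConfig,
    degrade_to_ancient,
    drop_mutations,
    overlay_deletion,
    simulate_depth,
    simulate_genealogy,
    tajimas_d,
)
from svbalscan.genomic_io import MISSING
from svbalscan.popgen_stats import TajimaConstants
from svbalscan.synthetic_data import simulate_bundle, simulate_chunked_matrix


class TestGenealogy:
    def test_pairwise_tmrca_expectation_n2(self):
        """E[T2] = 1 in units of 2N generations."""
        ts = []
        for seed in range(2000):
            g = simulate_genealogy(SimulationConfig(model="neutral", n_hap=2, seed=seed))
            ts.append(g.time[g.root])
        se = np.std(ts, ddof=1) / np.sqrt(len(ts))
        assert abs(np.mean(ts) - 1.0) < 3 * se

    def test_balancing_cross_class_pairs_older_than_split(self):
        cfg = SimulationConfig(model="balancing", n_hap=20, t_split=4.0,
                               migration=0.0, seed=11)
        g = simulate_genealogy(cfg)
        tm = g.tmrca_matrix()
        carriers = np.flatnonzero(g.class_labels == 1)
        others = np.flatnonzero(g.class_labels == 0)
        assert len(carriers) and len(others)
        assert (tm[np.ix_(carriers, others)] >= 4.0).all()

    def test_zero_sweep_scale_collapses_to_star(self):
        cfg = SimulationConfig(model="sweep", n_hap=10, sweep_scale=0.0, seed=3)
        g = simulate_genealogy(cfg)
        assert g.tmrca_matrix().max() == 0.0
        assert g.total_branch_length() == 0.0

    def test_unit_sweep_scale_recovers_neutral_tree(self):
        neutral = simulate_genealogy(SimulationConfig(model="neutral", n_hap=12, seed=9))
        sweep = simulate_genealogy(
            SimulationConfig(model="sweep", n_hap=12, sweep_scale=1.0, seed=9)
        )
        assert np.allclose(neutral.time, sweep.time)
        assert np.array_equal(neutral.parent, sweep.parent)

    def test_ultrametric_leaves_and_binary_topology(self):
        g = simulate_genealogy(SimulationConfig(model="neutral", n_hap=15, seed=2))
        assert np.all(g.time[:15] == 0.0)
        assert g.n_nodes == 2 * 15 - 1
        children = np.bincount(g.parent[g.parent >= 0], minlength=g.n_nodes)
        assert (children[15:] == 2).all()


class TestMutations:
    def test_watterson_expectation(self):
        """Mean S over seeded reps ~ theta * a1(n)."""
        theta, n = 5.0, 10
        S = []
        for seed in range(1000):
            g = simulate_genealogy(SimulationConfig(model="neutral", n_hap=n, seed=seed))
            S.append(drop_mutations(g, theta, 100_000, seed=50_000 + seed).n_site)
        a1 = TajimaConstants.for_n(n).a1
        expect = theta * a1
        # Var(S) = theta*a1 + theta^2*a2
        a2 = TajimaConstants.for_n(n).a2
        se = np.sqrt((theta * a1 + theta**2 * a2) / len(S))
        assert abs(np.mean(S) - expect) < 3 * se

    def test_zero_length_tree_gives_no_sites(self):
        g = simulate_genealogy(SimulationConfig(model="sweep", n_hap=6,
                                                sweep_scale=0.0, seed=1))
        m = drop_mutations(g, 5.0, 1000, seed=2)
        assert m.n_site == 0

    def test_same_seed_identical_output(self):
        g = simulate_genealogy(SimulationConfig(model="neutral", n_hap=8, seed=5))
        m1 = drop_mutations(g, 5.0, 10_000, seed=77)
        m2 = drop_mutations(g, 5.0, 10_000, seed=77)
        assert np.array_equal(m1.alleles, m2.alleles)
        assert np.array_equal(m1.positions, m2.positions)

    def test_all_sites_segregating_with_sorted_positions(self):
        g = simulate_genealogy(SimulationConfig(model="neutral", n_hap=10, seed=6))
        m = drop_mutations(g, 10.0, 10_000, seed=8)
        counts = m.alleles.sum(axis=0)
        assert ((counts > 0) & (counts < 10)).all()
        assert (np.diff(m.positions) > 0).all()


class TestOverlayDeletion:
    def test_dosages_from_consecutive_pairs(self):
        cfg = SimulationConfig(model="balancing", n_hap=4, t_split=2.0, seed=0)
        g = simulate_genealogy(cfg)
        g.class_labels = np.array([1, 1, 0, 0], dtype=np.int8)
        m = drop_mutations(g, 2.0, 1000, seed=1)
        sv = overlay_deletion(m, g)
        assert sv.dosage.tolist() == [2, 0]
        assert sv.hap_carrier.tolist() == [1, 1, 0, 0]

    def test_cross_class_fixed_site_is_perfect_tag(self):
        from svbalscan import find_tag_sites

        cfg = SimulationConfig(model="balancing", n_hap=20, t_split=4.0, seed=14)
        g = simulate_genealogy(cfg)
        m = drop_mutations(g, 10.0, 10_000, seed=15)
        sv = overlay_deletion(m, g)
        carriers = g.class_labels == 1
        fixed = [
            j for j in range(m.n_site)
            if (m.alleles[carriers, j] == m.alleles[carriers, j][0]).all()
            and (m.alleles[~carriers, j] == m.alleles[~carriers, j][0]).all()
            and m.alleles[carriers, j][0] != m.alleles[~carriers, j][0]
        ]
        assert fixed, "deep split should fix at least one cross-class site"
        reports = find_tag_sites(m, sv, threshold=0.9)
        for j in fixed:
            assert reports[j].r2 == pytest.approx(1.0)
            assert reports[j].is_tag


class TestDegradeToAncient:
    def _matrix(self, seed=0):
        g = simulate_genealogy(SimulationConfig(model="neutral", n_hap=8, seed=seed))
        return drop_mutations(g, 8.0, 10_000, seed=seed + 1)

    def test_full_missingness(self):
        m = self._matrix()
        anc = degrade_to_ancient(m, 1.0, False, ages=[1000] * 4, seed=3)
        for s in anc:
            assert (s.calls == MISSING).all()

    def test_zero_missingness_diploid_preserves_genotypes(self):
        m = self._matrix()
        anc = degrade_to_ancient(m, 0.0, False, ages=[1000] * 4, seed=3)
        for i, s in enumerate(anc):
            assert np.array_equal(s.calls[:, 0], m.alleles[2 * i])
            assert np.array_equal(s.calls[:, 1], m.alleles[2 * i + 1])

    def test_pseudo_haploid_draw_is_fair_for_heterozygotes(self):
        # one diploid sample heterozygous at one site, drawn 2000 times
        from conftest import make_matrix

        h = make_matrix(["0", "1"])
        ones = 0
        n = 2000
        for seed in range(n):
            s = degrade_to_ancient(h, 0.0, True, ages=[1000], seed=seed)[0]
            ones += int(s.calls[0, 0] == 1)
        se = np.sqrt(0.25 / n)
        assert abs(ones / n - 0.5) < 3 * se


class TestSimulateDepth:
    def test_heterozygote_halves_inside_coverage(self):
        span = Region("chr1", 10_000, 15_000)
        pos, dep = simulate_depth(1, span, 2000, coverage=30.0, seed=5)
        inside = (pos >= span.start) & (pos < span.end)
        se = np.sqrt(15.0 / inside.sum())
        assert abs(dep[inside].mean() - 15.0) < 3 * se

    def test_no_deletion_uniform_coverage(self):
        span = Region("chr1", 10_000, 12_000)
        pos, dep = simulate_depth(0, span, 2000, coverage=30.0, seed=6)
        inside = (pos >= span.start) & (pos < span.end)
        assert abs(dep[inside].mean() - dep[~inside].mean()) < 1.0

    def test_homozygous_deletion_noise_floor(self):
        span = Region("chr1", 10_000, 15_000)
        pos, dep = simulate_depth(2, span, 2000, coverage=30.0, seed=7)
        inside = (pos >= span.start) & (pos < span.end)
        assert dep[inside].mean() == pytest.approx(0.3, abs=0.1)


class TestModelSignatures:
    """The three generative regimes leave their expected marks on Tajima's D."""

    def _d(self, model, seed, **kw):
        cfg = SimulationConfig(model=model, n_hap=50, theta=10.0, seed=seed, **kw)
        g = simulate_genealogy(cfg)
        m = drop_mutations(g, 10.0, 100_000, seed=90_000 + seed)
        return tajimas_d(m) if m.n_site else None

    def test_neutral_mean_d_near_zero(self):
        ds = [self._d("neutral", s) for s in range(300)]
        ds = [d for d in ds if d is not None]
        assert -0.2 < np.mean(ds) < 0.2

    def test_balancing_median_d_strongly_positive(self):
        ds = [self._d("balancing", s, t_split=4.0) for s in range(100)]
        assert np.median([d for d in ds if d is not None]) > 1

    def test_sweep_median_d_strongly_negative(self):
        ds = [self._d("sweep", s, sweep_scale=0.05) for s in range(100)]
        assert np.median([d for d in ds if d is not None]) < -1


class TestChunkedMatrix:
    def test_deterministic_and_shared_labels(self):
        cfg = SimulationConfig(model="balancing", n_hap=20, theta=8.0,
                               region_length_bp=6000, t_split=4.0, seed=19)
        m1, l1 = simulate_chunked_matrix(cfg)
        m2, l2 = simulate_chunked_matrix(cfg)
        assert np.array_equal(m1.alleles, m2.alleles)
        assert np.array_equal(l1, l2)
        assert m1.positions.max() < 6000


class TestBundle:
    def test_bundle_files_exist_and_truth_consistent(self, tmp_path):
        b = simulate_bundle(tmp_path / "b", model="balancing", seed=7,
                            n_neutral=4, n_control=2)
        for p in [b.vcf, b.sv_table, b.pop_map, b.neutral_bed, b.control_bed,
                  b.ancient_calls, b.ancient_meta]:
            assert p.exists()
        assert len(b.truth["hap_carrier"]) == 100
        # stratified carriers: equal frequency in every population
        from svbalscan import read_phased_vcf, read_pop_map, read_sv_panel

        pm = read_pop_map(b.pop_map)
        h = read_phased_vcf(b.vcf, pop_map=pm)
        carrier = np.asarray(b.truth["hap_carrier"])
        pops = np.asarray(h.pop_labels)
        freqs = [carrier[pops == p].mean() for p in ("CEU", "CHB", "YRI")]
        assert max(freqs) - min(freqs) < 0.05

    def test_same_seed_same_truth(self, tmp_path):
        b1 = simulate_bundle(tmp_path / "x", model="neutral", seed=3,
                             n_neutral=2, n_control=1)
        b2 = simulate_bundle(tmp_path / "y", model="neutral", seed=3,
                            n_neutral=2, n_control=1)
        assert b1.truth["dosage"] == b2.truth["dosage"]
        assert b1.vcf.read_text() == b2.vcf.read_text()
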