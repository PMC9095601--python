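"""LD detection from pooled counts: likelihood, gradient, LRT, scan."""

import numpy as np
import pytest

from raresum import (
    HaplotypeModel,
    LDPair,
    LDScanVariant,
    SixSetCounts,
    loglik_genotype,
    loglik_summary,
    lrt_genotype,
    lrt_summary,
    mnv_compare,
    partition_six_sets,
    scan_gene_pairs,
    simulate_ld_sets,
)
from raresum.ld import _negloglik_z, genotype_table_as_sets


class TestParametrization:
    @pytest.mark.parametrize(
        "s,t,theta",
        [(0.01, 0.02, 50.0), (0.3, 0.4, 0.2), (0.001, 0.001, 500.0), (0.5, 0.5, 1.0)],
    )
    def test_marginals_round_trip(self, s, t, theta):
        m = HaplotypeModel.from_marginals(s, t, theta)
        assert m.s == pytest.approx(s, abs=1e-10)
        assert m.t == pytest.approx(t, abs=1e-10)
        assert m.theta == pytest.approx(theta, rel=1e-6)
        assert m.p11 + m.p10 + m.p01 + m.p00 == pytest.approx(1.0, abs=1e-10)

    def test_haplotype_probs_round_trip(self):
        m0 = HaplotypeModel(p11=0.004, p10=0.006, p01=0.016, p00=0.974)
        m1 = HaplotypeModel.from_marginals(m0.s, m0.t, m0.theta)
        for attr in ("p11", "p10", "p01", "p00"):
            assert getattr(m1, attr) == pytest.approx(getattr(m0, attr), abs=1e-10)


class TestLikelihood:
    def test_independence_zero_counts_closed_form(self):
        s, t = 0.01, 0.02
        m = HaplotypeModel.from_marginals(s, t, 1.0)
        data = SixSetCounts(x=[0, 0], y=[0, 0], n=[100, 50])
        expected = 150 * np.log(m.p00)
        assert loglik_summary(m, data) == pytest.approx(expected, rel=1e-10)

    def test_brute_force_sum_over_latent_haplotypes(self):
        """Direct probability-space marginalization matches log-sum-exp."""
        from math import comb

        rng = np.random.default_rng(40)
        m = HaplotypeModel.from_marginals(0.1, 0.15, 4.0)
        for _ in range(10):
            n = int(rng.integers(2, 15))
            x = int(rng.integers(0, n + 1))
            y = int(rng.integers(0, n + 1))
            total = 0.0
            for r in range(max(0, x + y - n), min(x, y) + 1):
                coef = (
                    comb(n, r) * comb(n - r, x - r) * comb(n - x, y - r)
                )
                total += (
                    coef
                    * m.p11**r
                    * m.p10 ** (x - r)
                    * m.p01 ** (y - r)
                    * m.p00 ** (n - x - y + r)
                )
            ll = loglik_summary(m, SixSetCounts(x=[x], y=[y], n=[n]))
            assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_genotype_likelihood_equals_n2_summary_reduction(self):
        rng = np.random.default_rng(41)
        m = HaplotypeModel.from_marginals(0.1, 0.2, 5.0)
        c = rng.integers(0, 6, size=(3, 3))
        assert loglik_genotype(c, m) == pytest.approx(
            loglik_summary(m, genotype_table_as_sets(c)), rel=1e-12
        )

    def test_all_mass_at_double_reference(self):
        c = np.zeros((3, 3))
        c[0, 0] = 17
        m = HaplotypeModel(p11=0.0, p10=0.0, p01=0.0, p00=1.0)
        assert loglik_genotype(c, m) == pytest.approx(0.0)
        m2 = HaplotypeModel.from_marginals(0.1, 0.1, 1.0)
        assert loglik_genotype(c, m2) < 0.0

    def test_impossible_data_is_minus_infinity(self):
        c = np.zeros((3, 3))
        c[2, 2] = 1
        m = HaplotypeModel(p11=0.0, p10=0.1, p01=0.1, p00=0.8)
        assert loglik_genotype(c, m) == -np.inf

    def test_analytic_gradient_matches_finite_differences(self):
        data = SixSetCounts(
            x=[3, 5, 0, 2, 4, 1], y=[2, 6, 1, 0, 3, 2],
            n=[2000, 3000, 1000, 1500, 2500, 800],
        )
        for z in ([-5.0, -4.5, 1.2], [-6.0, -6.0, 0.0], [-4.0, -5.0, -1.0]):
            z = np.array(z)
            _, g = _negloglik_z(z, data)
            for i in range(3):
                e = np.zeros(3)
                e[i] = 1e-6
                fp, _ = _negloglik_z(z + e, data)
                fm, _ = _negloglik_z(z - e, data)
                assert g[i] == pytest.approx((fp - fm) / 2e-6, abs=1e-4, rel=1e-5)


class TestLrt:
    def test_swap_and_permutation_invariance(self):
        data = SixSetCounts(
            x=[5, 2, 7, 0, 3, 1], y=[4, 3, 6, 1, 2, 0],
            n=[1000, 800, 1200, 500, 900, 400],
        )
        base = lrt_summary(data)
        swapped = lrt_summary(SixSetCounts(x=data.y, y=data.x, n=data.n))
        perm = np.array([3, 1, 4, 0, 5, 2])
        permuted = lrt_summary(
            SixSetCounts(x=data.x[perm], y=data.y[perm], n=data.n[perm])
        )
        assert base.statistic == pytest.approx(swapped.statistic, abs=1e-5)
        assert base.statistic == pytest.approx(permuted.statistic, abs=1e-5)

    def test_negatively_associated_data_gives_t_zero_p_one(self):
        # alt alleles never co-occur: theta_hat <= 1
        data = SixSetCounts(x=[5, 0, 6, 0], y=[0, 5, 0, 6], n=[50, 50, 50, 50])
        res = lrt_summary(data)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_uninformative_pair_skipped(self):
        data = SixSetCounts(x=[0, 0], y=[3, 1], n=[100, 100])
        res = lrt_summary(data)
        assert res.skipped and res.p_value == 1.0

    def test_perfect_ld_is_highly_significant(self):
        n = [2000, 3000, 1000, 1500, 2500, 800]
        x = [max(1, v // 100) for v in n]
        res = lrt_summary(SixSetCounts(x=x, y=x, n=n))
        assert res.p_value < 1e-3
        assert res.theta_hat > 150

    def test_genotype_test_power_exceeds_summary_at_same_size(self):
        """Planted LD: full genotypes give a larger statistic than the pooled
        counts of the same haplotype draws."""
        rng = np.random.default_rng(42)
        m = HaplotypeModel.from_marginals(0.01, 0.01, 100.0)
        probs = [m.p11, m.p10, m.p01, m.p00]
        stats_g, stats_s = [], []
        for _ in range(10):
            h1 = rng.choice(4, size=2000, p=probs)
            h2 = rng.choice(4, size=2000, p=probs)
            g1 = (h1 <= 1).astype(int) + (h2 <= 1).astype(int)
            g2 = np.isin(h1, (0, 2)).astype(int) + np.isin(h2, (0, 2)).astype(int)
            c = np.zeros((3, 3))
            for a, b in zip(g1, g2):
                c[a, b] += 1
            stats_g.append(lrt_genotype(c).statistic)
            # pooled version: one set holding everything
            stats_s.append(
                lrt_summary(
                    SixSetCounts(x=[g1.sum()], y=[g2.sum()], n=[4000])
                ).statistic
            )
        assert np.mean(stats_g) > np.mean(stats_s)

    def test_doubly_homozygous_table_hits_theta_bound(self):
        c = np.zeros((3, 3))
        c[2, 2] = 5
        c[0, 0] = 95
        res = lrt_genotype(c)
        assert res.theta_hat > 1e6
        assert res.p_value < 1e-6


class TestSimulateLdSets:
    def test_independent_draws_uncorrelated(self):
        rng = np.random.default_rng(43)
        xs, ys = [], []
        for _ in range(300):
            d = simulate_ld_sets(0.01, 0.01, 1.0, [5000], rng)
            xs.append(d.x[0])
            ys.append(d.y[0])
        r = np.corrcoef(xs, ys)[0, 1]
        assert abs(r) < 0.15

    def test_extreme_ld_forces_equal_counts(self):
        rng = np.random.default_rng(44)
        d = simulate_ld_sets(0.01, 0.01, 1e14, [20000] * 6, rng)
        assert np.array_equal(d.x, d.y)

    def test_infeasible_combination_raises(self):
        with pytest.raises(ValueError):
            simulate_ld_sets(1.5, 0.01, 2.0, [100])


def make_per_stratum(ac_by_set, an_by_set, stratum="nfe"):
    """Assemble gnomAD-style nested per-stratum fields from six disjoint sets.

    Sets are ordered (controls, non_cancer_non_controls, cancer) x
    (female, male); nested cumulative fields are controls <= non_cancer <= all.
    """
    out = {}
    for i, sex in enumerate(("female", "male")):
        c, ncnc, canc = ac_by_set[3 * i : 3 * i + 3]
        nc_, nncnc, ncanc = an_by_set[3 * i : 3 * i + 3]
        out[f"controls_{stratum}_{sex}"] = (c, nc_, None)
        out[f"non_cancer_{stratum}_{sex}"] = (c + ncnc, nc_ + nncnc, None)
        out[f"{stratum}_{sex}"] = (c + ncnc + canc, nc_ + nncnc + ncanc, None)
    return out


class TestPartition:
    def test_round_trip_recovers_disjoint_sets(self):
        ac1 = [3, 1, 2, 4, 0, 5]
        ac2 = [2, 2, 1, 3, 1, 0]
        an = [1000, 400, 600, 1100, 500, 700]
        ps1 = make_per_stratum(ac1, an)
        ps2 = make_per_stratum(ac2, an)
        d = partition_six_sets(ps1, ps2, "nfe")
        # partition order: per sex (controls, non_cancer_non_controls, cancer)
        assert sorted(d.x.tolist()) == sorted(ac1)
        assert sorted(d.y.tolist()) == sorted(ac2)
        assert d.x.sum() == sum(ac1) and d.y.sum() == sum(ac2)

    def test_no_other_disease_samples_gives_zero_middle_subset(self):
        ac = [3, 0, 2, 4, 0, 5]
        an = [1000, 0, 600, 1100, 0, 700]
        d = partition_six_sets(
            make_per_stratum(ac, an), make_per_stratum(ac, an), "nfe"
        )
        # the zero-AN middle sets are dropped; totals conserved
        assert d.x.sum() == sum(ac)
        assert len(d.x) == 4

    def test_negative_subtraction_raises(self):
        ps = make_per_stratum([3, 1, 2, 4, 0, 5], [1000] * 6)
        bad = dict(ps)
        bad["non_cancer_nfe_female"] = (1, 900, None)  # < controls AC of 3
        with pytest.raises(ValueError):
            partition_six_sets(bad, ps, "nfe")


class TestScan:
    def make_variant(self, key, pos, counts, n_sets, af=0.005, ac=None):
        counts = np.asarray(counts)
        return LDScanVariant(
            key=key,
            chrom="1",
            pos=pos,
            counts=counts,
            an=np.asarray(n_sets),
            af=af,
            ac=int(counts.sum()) if ac is None else ac,
        )

    def test_single_variant_gene_produces_no_tests(self):
        v = self.make_variant("1-100-A-G", 100, [5, 5, 5, 5, 5, 5], [2000] * 6)
        assert scan_gene_pairs({"GENE": [v]}) == []

    def test_low_ac_variant_excluded(self):
        n = [2000] * 6
        v1 = self.make_variant("1-100-A-G", 100, [2, 2, 2, 1, 1, 1], n)  # AC=9
        v2 = self.make_variant("1-200-A-G", 200, [5, 5, 5, 5, 5, 5], n)
        assert scan_gene_pairs({"GENE": [v1, v2]}) == []

    def test_planted_pair_recovered_at_fdr_005(self):
        """A near-perfect-LD (MNV-like) pair among independent variants.

        Pooled counts identify LD through the covariance of the six
        independent (x, y) observations, so only strong LD is reliably
        detectable -- the regime the scan targets.
        """
        rng = np.random.default_rng(45)
        n = [20000] * 6
        planted = simulate_ld_sets(0.005, 0.005, 5e4, n, rng)
        v1 = self.make_variant("1-100-A-G", 100, planted.x, n)
        v2 = self.make_variant("1-101-C-T", 101, planted.y, n)
        independents = [
            self.make_variant(
                f"1-{300 + i}-A-G",
                300 + i,
                rng.binomial(np.array(n), 0.005),
                n,
            )
            for i in range(4)
        ]
        pairs = scan_gene_pairs({"GENE": [v1, v2] + independents})
        hits = [
            p
            for p in pairs
            if {p.key1, p.key2} == {"1-100-A-G", "1-101-C-T"}
        ]
        assert len(hits) == 1
        assert hits[0].fdr < 0.05
        assert hits[0].high_ld
        assert hits[0].distance_bp == 1


class TestMnvCompare:
    def make_pair(self, k1, k2, dist, theta=500.0):
        return LDPair(
            key1=k1, key2=k2, stratum="nfe", theta_hat=theta,
            statistic=30.0, p_value=1e-7, fdr=1e-5, distance_bp=dist,
            high_ld=theta > 150,
        )

    def test_empty_reference(self):
        pairs = [self.make_pair("a", "b", 1)]
        assert mnv_compare(pairs, [])["overlap_fraction"] == 0.0

    def test_identical_sets(self):
        pairs = [self.make_pair("a", "b", 1), self.make_pair("c", "d", 2)]
        rep = mnv_compare(pairs, [("a", "b"), ("d", "c")])
        assert rep["overlap_fraction"] == 1.0

    def test_constructed_90_percent_overlap(self):
        pairs = [self.make_pair(f"v{i}", f"w{i}", 1) for i in range(10)]
        ref = [(f"v{i}", f"w{i}") for i in range(9)]
        rep = mnv_compare(pairs, ref)
        assert rep["overlap_fraction"] == pytest.approx(0.9)

    def test_distant_and_weak_pairs_excluded(self):
        pairs = [
            self.make_pair("a", "b", 10),  # too far
            self.make_pair("c", "d", 1, theta=20.0),  # not high LD
        ]
        rep = mnv_compare(pairs, [("a", "b"), ("c", "d")])
        assert rep["n_detected"] == 0
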