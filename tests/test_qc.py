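"""Consistent QC, coverage summaries, AF filtering, categories, blacklist."""

import numpy as np
import pytest

from raresum import (
    BlacklistEntry,
    QCConfig,
    VariantSummary,
    af_filter,
    build_blacklist,
    consistent_variant_filter,
    coverage_summarize,
    joint_af,
    select_category,
    site_coverage_filter,
    stratified_max_joint_af,
)
from raresum.io import CoverageTrack
from raresum.qc import (
    NONFUNCTIONAL_RULE,
    PATHOGENIC_RULE,
    FilterLog,
    exact_two_proportion_pvalue,
)


def vs(pos, ac, an, nhom=0, status="PASS", per_stratum=None, annotations=None):
    return VariantSummary(
        chrom="1", pos=pos, ref="A", alt="G", ac=ac, an=an, nhomalt=nhom,
        filter_status=status, per_stratum=per_stratum or {},
        annotations=annotations or {},
    )


class TestCoverageSummarize:
    def test_worked_example(self):
        depths = np.array([[10], [10], [9]])
        track = coverage_summarize(depths, [("1", 100)], thresholds=(10,))
        assert track.fraction_at("1", 100, 10) == pytest.approx(2 / 3)

    def test_zero_depth_fails_every_threshold(self):
        depths = np.zeros((4, 2), dtype=int)
        track = coverage_summarize(
            depths, [("1", 1), ("1", 2)], thresholds=(1, 10)
        )
        assert track.fraction_at("1", 1, 1) == 0.0
        assert track.fraction_at("1", 2, 10) == 0.0

    def test_against_per_position_counting_oracle(self):
        rng = np.random.default_rng(50)
        depths = rng.integers(0, 60, size=(50, 100))
        positions = [("1", p) for p in range(1, 101)]
        thresholds = (1, 5, 10, 15, 20, 25, 30, 50, 100)
        track = coverage_summarize(depths, positions, thresholds)
        for j, pos in enumerate(positions):
            for i, t in enumerate(thresholds):
                expected = np.mean(depths[:, j] >= t)
                assert track.fractions[pos][i] == pytest.approx(expected)

    def test_fractions_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(51)
        depths = rng.poisson(15, size=(30, 20))
        positions = [("1", p) for p in range(1, 21)]
        track = coverage_summarize(depths, positions)
        for arr in track.fractions.values():
            assert np.all(np.diff(arr) <= 1e-12)

    def test_empty_sample_set_is_an_error(self):
        with pytest.raises(ValueError):
            coverage_summarize(np.empty((0, 3)), [("1", 1), ("1", 2), ("1", 3)])


class TestSiteCoverageFilter:
    def make_track(self, frac_by_pos):
        return CoverageTrack(
            thresholds=(10,),
            fractions={("1", p): np.array([f]) for p, f in frac_by_pos.items()},
        )

    def test_kept_and_dropped(self):
        cfg = QCConfig()
        case = self.make_track({1: 0.95, 2: 0.95})
        ctrl = self.make_track({1: 0.91, 2: 0.89})
        kept = site_coverage_filter(case, ctrl, cfg)
        assert kept == {("1", 1)}

    def test_position_absent_from_one_track_fails(self):
        cfg = QCConfig()
        case = self.make_track({1: 0.99})
        ctrl = self.make_track({})
        assert site_coverage_filter(case, ctrl, cfg, [("1", 1)]) == set()

    def test_against_set_intersection_oracle(self):
        rng = np.random.default_rng(52)
        cfg = QCConfig()
        case_f = {p: float(rng.random()) for p in range(1, 200)}
        ctrl_f = {p: float(rng.random()) for p in range(1, 200)}
        kept = site_coverage_filter(
            self.make_track(case_f), self.make_track(ctrl_f), cfg
        )
        oracle = {
            ("1", p)
            for p in case_f
            if case_f[p] >= 0.9 and ctrl_f[p] >= 0.9
        }
        assert kept == oracle


class TestConsistentVariantFilter:
    def test_pass_in_cases_fail_in_controls_excluded(self):
        log = FilterLog()
        kept = consistent_variant_filter(
            [vs(100, 2, 600)],
            [vs(100, 5, 16000, status="RF")],
            case_n=300,
            control_n=8000,
            log=log,
        )
        assert kept == []
        assert log.reasons["1-100-A-G"] == "failed_filter_either_cohort"

    def test_low_missingness_retained(self):
        # missingness 0.05 cases (an=570/600), 0.08 controls
        kept = consistent_variant_filter(
            [vs(100, 2, 570)], [vs(100, 5, 14720)], case_n=300, control_n=8000
        )
        assert len(kept) == 1

    def test_against_predicate_oracle_and_symmetry(self):
        rng = np.random.default_rng(53)
        case_vars, ctrl_vars = [], []
        for pos in range(1, 60):
            status_c = "PASS" if rng.random() < 0.8 else "fail"
            status_g = "PASS" if rng.random() < 0.8 else "fail"
            an_c = int(rng.integers(400, 601))
            an_g = int(rng.integers(13000, 16001))
            case_vars.append(vs(pos, 1, an_c, status=status_c))
            ctrl_vars.append(vs(pos, 3, an_g, status=status_g))
        kept = consistent_variant_filter(
            case_vars, ctrl_vars, case_n=300, control_n=8000
        )
        oracle = {
            c.key
            for c, g in zip(case_vars, ctrl_vars)
            if c.passed
            and g.passed
            and 1 - c.an / 600 <= 0.1
            and 1 - g.an / 16000 <= 0.1
        }
        assert {c.key for c, g in kept} == oracle
        # symmetry: swapping roles (and cohort sizes) retains the same keys
        swapped = consistent_variant_filter(
            ctrl_vars, case_vars, case_n=8000, control_n=300
        )
        assert {c.key for c, g in swapped} == oracle


class TestJointAf:
    def test_worked_example(self):
        assert joint_af(1, 672, 5, 16350) == pytest.approx(6 / 17022)

    def test_all_reference(self):
        assert joint_af(0, 100, 0, 100) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            joint_af(0, 0, 0, 0)

    def test_stratified_max_against_loop_oracle(self):
        rng = np.random.default_rng(54)
        strata = ("nfe", "afr", "eas")
        case_ps = {
            s: (int(rng.integers(0, 5)), 400, None) for s in strata
        }
        ctrl_ps = {
            s: (int(rng.integers(0, 50)), 20000, None) for s in strata
        }
        c = vs(100, sum(v[0] for v in case_ps.values()), 1200, per_stratum=case_ps)
        g = vs(100, sum(v[0] for v in ctrl_ps.values()), 60000, per_stratum=ctrl_ps)
        got = stratified_max_joint_af(c, g, strata)
        oracle = max(
            (case_ps[s][0] + ctrl_ps[s][0]) / (case_ps[s][1] + ctrl_ps[s][1])
            for s in strata
        )
        assert got == pytest.approx(oracle)


class TestAfFilter:
    def test_below_threshold_kept(self):
        cfg = QCConfig(joint_af_threshold=1e-3)
        pairs = [(vs(100, 0, 600), vs(100, 2, 25000))]  # joint AF ~ 8e-5
        assert len(af_filter(pairs, cfg)) == 1

    def test_population_specific_common_variant_caught_by_stratified_max(self):
        """A variant common in one ancestry but rare pooled must be excluded."""
        cfg = QCConfig(joint_af_threshold=1e-3)
        # afr AF 0.1122, nfe AF 2.196e-4; pooled diluted below threshold
        ctrl_ps = {"afr": (897, 8000, None), "nfe": (25, 113000, None)}
        case_ps = {"afr": (0, 40, None), "nfe": (0, 600, None)}
        c = vs(100, 0, 640, per_stratum=case_ps)
        g = vs(100, 922, 121000, per_stratum=ctrl_ps)
        # pooled joint AF below 1e-2-level thresholds used under recessive scans
        pooled_cfg = QCConfig(joint_af_threshold=1e-2)
        assert len(af_filter([(c, g)], pooled_cfg)) == 1  # pooled rule misses it
        assert af_filter([(c, g)], pooled_cfg, strata=("afr", "nfe")) == []

    def test_stratified_max_never_more_permissive_than_pooled(self):
        rng = np.random.default_rng(55)
        cfg = QCConfig(joint_af_threshold=5e-3)
        strata = ("nfe", "afr")
        pairs = []
        for pos in range(1, 40):
            acs_c = rng.integers(0, 3, size=2)
            acs_g = rng.integers(0, 60, size=2)
            c_ps = {s: (int(a), 500, None) for s, a in zip(strata, acs_c)}
            g_ps = {s: (int(a), 10000, None) for s, a in zip(strata, acs_g)}
            pairs.append(
                (
                    vs(pos, int(acs_c.sum()), 1000, per_stratum=c_ps),
                    vs(pos, int(acs_g.sum()), 20000, per_stratum=g_ps),
                )
            )
        kept_strat = {c.key for c, g in af_filter(pairs, cfg, strata=strata)}
        kept_pooled = {c.key for c, g in af_filter(pairs, cfg)}
        assert kept_strat.issubset(kept_pooled)

    def test_popmax_annotation_filter(self):
        cfg = QCConfig(joint_af_threshold=1e-2, use_popmax=True, popmax_threshold=1e-3)
        g = vs(100, 2, 25000, annotations={"AF_popmax": 0.05})
        assert af_filter([(vs(100, 0, 600), g)], cfg) == []


class TestSelectCategory:
    def test_truncating_variant_needs_no_score(self):
        v = vs(100, 1, 600, annotations={"gene": "X", "consequence": "stopgain"})
        out = select_category([v], [PATHOGENIC_RULE])
        assert out["pathogenic"] == [v]

    def test_missense_revel_boundary(self):
        lo = vs(100, 1, 600, annotations={"consequence": "nonsynonymous", "REVEL": 0.64})
        hi = vs(101, 1, 600, annotations={"consequence": "nonsynonymous", "REVEL": 0.65})
        out = select_category([lo, hi], [PATHOGENIC_RULE])
        assert out["pathogenic"] == [hi]

    def test_nonfunctional_rule_for_proxecat_denominator(self):
        syn = vs(100, 1, 600, annotations={"consequence": "synonymous"})
        benign = vs(101, 1, 600, annotations={"consequence": "nonsynonymous", "REVEL": 0.1})
        damaging = vs(102, 1, 600, annotations={"consequence": "nonsynonymous", "REVEL": 0.9})
        out = select_category([syn, benign, damaging], [NONFUNCTIONAL_RULE])
        assert out["nonfunctional"] == [syn, benign]

    def test_missing_score_on_gated_consequence_logged(self):
        log = FilterLog()
        v = vs(100, 1, 600, annotations={"consequence": "nonsynonymous"})
        out = select_category([v], [PATHOGENIC_RULE], log=log)
        assert out["pathogenic"] == []
        assert "missing_revel" in log.reasons[v.key]


class TestBlacklist:
    def test_platform_filter_failure_blacklisted(self):
        entries = build_blacklist(
            [vs(100, 5, 10000, status="VQSR_fail")], [vs(100, 5, 10000)]
        )
        assert entries == [
            BlacklistEntry(key="1-100-A-G", reason="failed_gnomad_filter")
        ]

    def test_concordant_afs_not_blacklisted(self):
        entries = build_blacklist(
            [vs(100, 100, 10000)], [vs(100, 100, 10000)]
        )
        assert entries == []

    def test_tenfold_discrepancy_blacklisted(self):
        # AF 50/10000 vs 5/10000: exact two-proportion P < 1e-5, fold 10
        assert exact_two_proportion_pvalue(50, 10000, 5, 10000) < 1e-5
        entries = build_blacklist([vs(100, 50, 10000)], [vs(100, 5, 10000)])
        assert entries == [
            BlacklistEntry(key="1-100-A-G", reason="wes_wgs_af_discrepancy")
        ]

    def test_significant_but_small_fold_change_spared(self):
        # large counts make small differences significant; fold < 5 spares them
        p = exact_two_proportion_pvalue(4000, 100000, 3000, 100000)
        assert p < 1e-5
        entries = build_blacklist(
            [vs(100, 4000, 100000)], [vs(100, 3000, 100000)]
        )
        assert entries == []
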