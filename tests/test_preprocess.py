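import math

import numpy as np
import pytest

from metaseed.chem import mz_from_neutral_mass
from metaseed.peak_io import Peak, PeakTable
from metaseed.preprocess import (
    ARTIFACT,
    INVALID_RT,
    ISOTOPOLOGUE,
    NON_BIOLOGICAL,
    PRIMARY,
    RETAINED,
    SECONDARY,
    TERTIARY,
    AccountingSummary,
    FeatureRecord,
    IsotopePattern,
    ToleranceConfig,
    accounting_summary,
    classify_tiers,
    detect_isotopologues,
    differential_stats,
    filter_rt,
    mass_difference_matrix,
    preprocess_table,
    remove_adducts_multimers,
)
from metaseed.synthetic import SimulationConfig, make_mini_db, simulate_peak_table

CFG = ToleranceConfig()


def peak(pid, mz, rt, inten=100.0):
    return Peak(pid, mz, rt, {"c1": inten, "t1": inten})


class TestFilterRt:
    @pytest.mark.parametrize("rt, kept", [
        (60.0, False),   # before the void-volume cut
        (1000.0, True),
        (120.0, True),   # closed interval
        (2030.0, True),  # closed interval
        (2031.0, False),
    ])
    def test_window(self, rt, kept, design_2x2):
        p = Peak("x", 200.0, rt, {"c1": 1.0})
        table = PeakTable([p], design_2x2)
        inside, flagged = filter_rt(table, CFG)
        assert (p in inside) is kept
        assert (p in flagged) is not kept


class TestMassDifferenceMatrix:
    def test_single_pair(self):
        m = mass_difference_matrix([peak("a", 100, 300), peak("b", 150, 300)])
        pairs = list(m.pairs())
        assert pairs == [(0, 1, 50.0)]

    def test_pair_count(self):
        peaks = [peak(f"p{i}", 100 + i, 300) for i in range(6)]
        m = mass_difference_matrix(peaks)
        assert m.n_pairs == 15

    def test_antisymmetry(self):
        m = mass_difference_matrix([peak("a", 100, 300), peak("b", 150, 300)])
        assert m.delta(0, 1) == -m.delta(1, 0)


class TestAdductRemoval:
    def test_dimer_flagged(self):
        mono = peak("mono", 179.056112, 300)
        dimer = peak("dimer", 359.119500, 305)
        kept, flagged = remove_adducts_multimers([mono, dimer], CFG)
        assert kept == [mono]
        assert flagged[0][0] is dimer and flagged[0][1] == "[2M-H]-"

    def test_chloride_adduct_flagged(self):
        mono = peak("mono", 179.056112, 300)
        adduct = peak("cl", 215.032241, 302)
        kept, flagged = remove_adducts_multimers([mono, adduct], CFG)
        assert kept == [mono]
        assert flagged[0][1] == "[M+Cl]-"

    def test_rt_gate_blocks_match(self):
        mono = peak("mono", 179.056112, 300)
        adduct = peak("cl", 215.032241, 600)
        kept, flagged = remove_adducts_multimers([mono, adduct], CFG)
        assert len(kept) == 2 and not flagged

    def test_water_loss_keeps_heavier_anchor(self):
        anchor = peak("anchor", 215.032241, 300)
        loss = peak("loss", 215.032241 - 18.010565, 301)
        kept, flagged = remove_adducts_multimers([anchor, loss], CFG)
        assert kept == [anchor]
        assert flagged[0][1] == "[M-H2O-H]-"

    def test_no_coeluting_pairs_no_artifacts(self):
        peaks = [peak(f"p{i}", 150.0 + 7.1 * i, 300 + 200 * i) for i in range(5)]
        kept, flagged = remove_adducts_multimers(peaks, CFG)
        assert len(kept) == 5 and not flagged

    def test_anchor_of_match_never_flagged(self, sim_default):
        _cfg, _db, table, _truth, _model = sim_default
        kept, flagged = remove_adducts_multimers(table.peaks, CFG)
        kept_ids = {p.peak_id for p in kept}
        assert not kept_ids & {p.peak_id for p, _lab in flagged}


class TestIsotopologues:
    def test_13c_partner_grouped(self):
        mono = peak("mono", 200.0, 300, inten=100.0)
        iso = peak("iso", 201.003355, 301, inten=2.0)
        grouped, flagged = detect_isotopologues([mono, iso], cfg=CFG)
        assert flagged == [iso]
        (p, pattern), = [g for g in grouped]
        assert p is mono
        assert pattern.relative("M+1(13C)") == pytest.approx(0.02)

    def test_15n_partner_grouped(self):
        mono = peak("mono", 200.0, 300, inten=100.0)
        iso = peak("iso", 200.997035, 300, inten=3.0)
        grouped, flagged = detect_isotopologues([mono, iso], cfg=CFG)
        assert flagged == [iso]
        assert grouped[0][1].relative("M+1(15N)") == pytest.approx(0.03)

    def test_intensity_gate(self):
        mono = peak("mono", 200.0, 300, inten=2.0)
        heavy = peak("heavy", 201.003355, 300, inten=100.0)
        grouped, flagged = detect_isotopologues([mono, heavy], cfg=CFG)
        assert not flagged and len(grouped) == 2

    def test_rt_gap_blocks_assignment(self):
        mono = peak("mono", 200.0, 300, inten=100.0)
        iso = peak("iso", 201.003355, 500, inten=2.0)
        _grouped, flagged = detect_isotopologues([mono, iso], cfg=CFG)
        assert not flagged

    def test_planted_13c_recovery_on_synthetic(self, sim_default):
        """>=99% of planted 13C partners are grouped at 2 ppm / 60 s."""
        _cfg, _db, table, truth, model = sim_default
        features, _acct = preprocess_table(table, model)
        c13 = truth.decorations_with_label("13C")
        flagged = sum(1 for f in features
                      if f.peak_id in set(c13) and f.status == ISOTOPOLOGUE)
        assert flagged / len(c13) >= 0.99


class TestDifferentialStats:
    def dpeak(self, ctrl, treat):
        vals = {f"c{i+1}": v for i, v in enumerate(ctrl)}
        vals.update({f"t{i+1}": v for i, v in enumerate(treat)})
        return Peak("x", 200.0, 300.0, vals)

    def test_increase(self, design_2x2):
        pct, fold, p = differential_stats(
            self.dpeak([100, 100], [125, 125]), design_2x2, 10.0)
        assert pct == pytest.approx(25.0)
        assert fold == pytest.approx(1.25)

    def test_decrease_signed_fold(self, design_2x2):
        pct, fold, _p = differential_stats(
            self.dpeak([100, 100], [50, 50]), design_2x2, 10.0)
        assert pct == pytest.approx(-50.0)
        assert fold == pytest.approx(-2.0)

    def test_identical_groups(self, design_2x2):
        pct, fold, p = differential_stats(
            self.dpeak([100, 100], [100, 100]), design_2x2, 10.0)
        assert pct == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_control_sentinel(self, design_2x2):
        pct, fold, _p = differential_stats(
            self.dpeak([0, 0], [50, 60]), design_2x2, 10.0)
        assert pct is None
        assert math.isinf(fold) and fold > 0

    def test_swapped_conditions_fold_reciprocal(self, design_2x2):
        _pct, fold_fwd, _ = differential_stats(
            self.dpeak([100, 120], [300, 340]), design_2x2, 10.0)
        _pct, fold_rev, _ = differential_stats(
            self.dpeak([300, 340], [100, 120]), design_2x2, 10.0)
        # +r and -1/r multiply to 1 in ratio space
        assert fold_fwd * (-1.0 / fold_rev) == pytest.approx(1.0)

    def test_missing_treatment_errors(self, design_2x2):
        with pytest.raises(ValueError, match="treatment"):
            differential_stats(self.dpeak([1, 1], [1, 1]), design_2x2, 99.0)


class TestTierClassification:
    def make_feature(self, pct, with_pattern):
        f = FeatureRecord("x", 200.0, 300.0, 201.007)
        f.percent_change = pct
        f.fold_change = 1.0
        if with_pattern:
            f.pattern = IsotopePattern([("M+1(13C)", 0.05)])
        return f

    @pytest.mark.parametrize("pct, with_pattern, tier", [
        (30.0, True, PRIMARY),
        (10.0, True, SECONDARY),
        (500.0, False, TERTIARY),
        (-30.0, True, PRIMARY),
        (20.0, True, SECONDARY),  # threshold is strict
    ])
    def test_rules(self, pct, with_pattern, tier):
        f = self.make_feature(pct, with_pattern)
        classify_tiers([f])
        assert f.tier == tier


class TestAccounting:
    @pytest.mark.parametrize(
        "total, cats, eliminated, retained, pct_ret, pct_bio",
        [
            (2294, (646, 82, 145, 339), 1212, 1082, 47.2, 6.3),
            (4416, (989, 168, 672, 387), 2216, 2200, 49.8, 15.2),
        ],
    )
    def test_summary_arithmetic(self, total, cats, eliminated, retained,
                                pct_ret, pct_bio):
        acct = AccountingSummary(total, *cats)
        assert acct.n_eliminated == eliminated
        assert acct.n_retained == retained
        assert acct.pct_retained == pct_ret
        assert acct.pct_non_biological == pct_bio

    def test_formula_percentage(self):
        acct = AccountingSummary(2294, 646, 82, 145, 339, n_formulas=270)
        assert acct.pct_formulas == 11.8

    def test_empty_input(self):
        acct = accounting_summary([])
        assert acct.n_features == 0 and acct.n_eliminated == 0

    def test_identity_fuzzed(self):
        """retained + all eliminated categories == total on random tables."""
        for seed in range(25):
            cfg = SimulationConfig(seed=seed, n_pathways=4,
                                   compounds_per_pathway=4, n_noise=10)
            db = make_mini_db(cfg)
            table, _truth = simulate_peak_table(db, cfg)
            from metaseed.compound_db import build_mass_defect_model
            features, acct = preprocess_table(table, build_mass_defect_model(db))
            assert acct.n_features == len(table)
            assert acct.n_retained + acct.n_eliminated == acct.n_features
            by_status = {s: sum(1 for f in features if f.status == s)
                         for s in (RETAINED, INVALID_RT, ARTIFACT,
                                   NON_BIOLOGICAL, ISOTOPOLOGUE)}
            assert by_status[RETAINED] == acct.n_retained

    def test_rerun_is_idempotent(self, sim_default):
        _cfg, _db, table, _truth, model = sim_default
        f1, a1 = preprocess_table(table, model)
        f2, a2 = preprocess_table(table, model)
        assert a1 == a2
        assert [(f.peak_id, f.status, f.tier) for f in f1] == \
            [(f.peak_id, f.status, f.tier) for f in f2]
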