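"""Quantitative strategy units: normalization, global dispersion,
verdicts, BH adjustment, and end-to-end hit calling on tiny screens."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from baitcall import (
    DataError,
    GlobalStats,
    QuantConfig,
    StatsError,
    average_triplicate,
    bh_adjust,
    control_verdict,
    global_stats,
    make_table,
    normalize_and_log,
    quantitative_hits,
)
from baitcall.simulate import CLASS_PREY, CLASS_RESIN, CLASS_TAG, SimParams, generate_dataset

from conftest import toy_design


class TestNormalizeAndLog:
    def test_median_normalization_hand_example(self):
        # nonzero median of [10, 20, 40] is 20; 0 maps to 0 via the 0->1 rule
        t = make_table(["A", "B", "C", "D"], ["r1"], [[10.0], [20.0], [40.0], [0.0]])
        out = normalize_and_log(t, "r1")
        expected = [math.log10(0.5), 0.0, math.log10(2.0), 0.0]
        assert np.allclose(out.to_numpy(), expected, atol=1e-12)
        assert out.loc["A"] == pytest.approx(-0.30103, abs=1e-5)

    def test_equal_nonzero_values_all_map_to_zero(self):
        t = make_table(["A", "B"], ["r1"], [[7.0], [7.0]])
        assert (normalize_and_log(t, "r1").to_numpy() == 0.0).all()

    def test_all_zero_run_yields_zero_column(self, caplog):
        t = make_table(["A", "B"], ["r1"], [[0.0], [0.0]])
        with caplog.at_level("WARNING", logger="baitcall.quantitative"):
            out = normalize_and_log(t, "r1")
        assert (out.to_numpy() == 0.0).all()
        assert any("no nonzero" in m for m in caplog.messages)


class TestGlobalStats:
    def test_identical_values_give_zero_sd(self):
        s = global_stats([[1.0, 1.0], [1.0, 1.0]])
        assert s.global_sd == 0.0

    def test_sample_and_population_modes(self):
        vals = [[0.0, 0.0], [1.0, 1.0]]
        assert global_stats(vals, mode="sample").global_sd == pytest.approx(
            0.5773502691896258, abs=1e-12
        )
        assert global_stats(vals, mode="population").global_sd == 0.5

    def test_pooling_is_grouping_invariant(self):
        a = global_stats([[0.3, -0.1, 0.7, 0.2]])
        b = global_stats([[0.3], [-0.1, 0.7], [0.2]])
        assert (a.global_variance, a.global_sd, a.n_values) == (
            b.global_variance, b.global_sd, b.n_values
        )

    def test_sd_is_sqrt_of_variance(self):
        s = global_stats([np.linspace(-1, 1, 11)])
        assert s.global_sd == math.sqrt(s.global_variance)

    def test_too_few_values_rejected(self):
        with pytest.raises(StatsError):
            global_stats([[1.0]])


class TestAverageTriplicate:
    def test_means(self):
        assert average_triplicate([0.0, 0.0, 0.0]) == 0.0
        assert average_triplicate([1.0, 2.0, 3.0]) == 2.0

    def test_permutation_invariant(self):
        assert average_triplicate([3.0, 1.0, 2.0]) == average_triplicate([1.0, 2.0, 3.0])

    def test_arity_enforced(self):
        with pytest.raises(DataError):
            average_triplicate([1.0, 2.0])


class TestControlVerdict:
    stats = GlobalStats("c", 0.04, 0.2, 100)
    cfg = QuantConfig()

    def test_absent_control_needs_no_test(self):
        v = control_verdict(5.0, 0.0, self.stats, self.cfg)
        assert v.verdict == "absent_in_control"
        assert math.isnan(v.z) and math.isnan(v.p)

    def test_equal_averages_rejected_by_fold_filter(self):
        v = control_verdict(1.3, 1.3, self.stats, self.cfg)
        assert v.verdict == "rejected"
        assert v.log2fc == 0.0

    def test_boundary_fold_is_inclusive_with_z_and_p(self):
        # a log10 difference of 0.4515449935 is exactly log2 fold 1.5
        diff = 0.4515449935
        v = control_verdict(1.0 + diff, 1.0, self.stats, self.cfg)
        assert v.verdict == "enriched"
        assert v.log2fc == pytest.approx(1.5, abs=1e-9)
        assert v.z == pytest.approx(2.2577, abs=2e-4)
        # independent numerical oracle for the one-sided upper tail
        assert v.p == pytest.approx(scipy.stats.norm.sf(v.z), rel=1e-12)
        assert v.p == pytest.approx(0.01199, abs=1e-5)

    def test_zero_global_sd_gives_p_zero_by_convention(self):
        flat = GlobalStats("c", 0.0, 0.0, 10)
        v = control_verdict(2.0, 1.0, flat, self.cfg)
        assert v.p == 0.0 and math.isinf(v.z)

    def test_mean_of_three_scaling(self):
        raw = control_verdict(2.0, 1.0, self.stats, self.cfg)
        scaled = control_verdict(
            2.0, 1.0, self.stats, QuantConfig(zscore_scale="mean_of_three")
        )
        assert scaled.z == pytest.approx(raw.z / math.sqrt(2 / 3), rel=1e-12)

    def test_log10_fold_scale_mode(self):
        cfg = QuantConfig(fold_scale="log10")
        # log10 difference 1.4 < 1.5 fails in log10 mode but passes in log2 mode
        assert control_verdict(2.4, 1.0, self.stats, cfg).verdict == "rejected"
        assert control_verdict(2.4, 1.0, self.stats, self.cfg).verdict == "enriched"


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_outside_unit_interval_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(DataError):
            bh_adjust([-0.1])

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=150, derandomize=True)
    def test_matches_statsmodels_and_is_monotone(self, ps):
        mine = bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(mine, theirs, atol=1e-12)
        assert (mine >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(mine[order]) >= -1e-15).all()


class TestQuantitativeHits:
    def test_absent_from_all_controls_is_hit_regardless_of_level(self, small_screen):
        table, design = small_screen
        rec = quantitative_hits(table, design, "BaitA1", "LB_log").set_index("accession")
        assert bool(rec.loc["ACC2", "final_hit"])
        assert rec.loc["ACC2", "verdict_c1"] == "absent_in_control"
        assert rec.loc["ACC2", "verdict_c2"] == "absent_in_control"

    def test_missing_one_replicate_blocks_hit(self, small_screen):
        table, design = small_screen
        rec = quantitative_hits(table, design, "BaitA1", "LB_log").set_index("accession")
        assert not bool(rec.loc["ACC3", "final_hit"])
        assert not bool(rec.loc["ACC3", "present_all_reps"])

    def test_flat_background_rejected(self, small_screen):
        table, design = small_screen
        rec = quantitative_hits(table, design, "BaitA1", "LB_log").set_index("accession")
        assert rec.loc["ACC1", "verdict_c1"] == "rejected"
        assert not bool(rec.loc["ACC1", "final_hit"])

    def test_records_cover_every_protein_detected_in_any_exp_replicate(self, small_screen):
        table, design = small_screen
        rec = quantitative_hits(table, design, "BaitA1", "LB_log")
        assert sorted(rec["accession"]) == ["ACC0", "ACC1", "ACC2", "ACC3"]

    def test_padj_at_least_p(self, small_screen):
        table, design = small_screen
        rec = quantitative_hits(table, design, "BaitA1", "LB_log")
        tested = rec[rec["verdict_c1"] == "enriched"]
        assert (tested["padj_c1"] >= tested["p_c1"] - 1e-15).all()

    def test_missing_control_group_is_design_error(self, small_screen):
        table, design = small_screen
        from baitcall import DesignError

        with pytest.raises(DesignError):
            quantitative_hits(table, design, "BaitA1", "M9_ac_ON")


class TestParameterRecovery:
    """Sensitivity grows with the planted effect; the false-positive rate
    among background binders at effect 0 stays within Monte-Carlo reach
    of the nominal FDR level."""

    effects = [0.0, 1.0, 2.0, 3.0]
    n_sims = 12

    def _sim(self, effect, seed):
        params = SimParams(
            n_proteins=60, n_baits=1, preys_per_bait=5, n_resin_binders=10,
            n_tag_binders=5, effect_log10=effect, prey_mode="enriched",
            conditions=("LB_log",), seed=seed,
        )
        table, design, truth = generate_dataset(params)
        rec = quantitative_hits(table, design, "Bait1", "LB_log")
        hits = set(rec.loc[rec["final_hit"], "accession"])
        return truth, hits

    def test_sensitivity_monotone_and_fpr_bounded(self):
        sens = []
        fp, n_binders = 0, 0
        for effect in self.effects:
            tp = total = 0
            for seed in range(self.n_sims):
                truth, hits = self._sim(effect, seed=1000 + seed)
                preys = truth.preys_of("Bait1")
                tp += len(preys & hits)
                total += len(preys)
                if effect == 0.0:
                    binders = truth.members(CLASS_RESIN) | truth.members(CLASS_TAG)
                    fp += len(binders & hits)
                    n_binders += len(binders)
            sens.append(tp / total)
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:])), sens
        assert sens[-1] == 1.0
        fpr = fp / n_binders
        mcse = math.sqrt(max(fpr * (1 - fpr), 1e-9) / n_binders)
        assert fpr <= 0.01 + 3 * mcse


def test_bait_and_exclusive_preys_called_in_default_world():
    table, design, truth = generate_dataset(SimParams(conditions=("LB_log",)))
    rec = quantitative_hits(table, design, "Bait2", "LB_log")
    hits = set(rec.loc[rec["final_hit"], "accession"])
    assert truth.preys_of("Bait2") <= hits
    assert not (truth.members(CLASS_RESIN) & hits)
    assert not (truth.members(CLASS_TAG) & hits)
    # preys planted for other baits never surface in this pull-down
    assert not (truth.preys_of("Bait1") & hits)
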