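"""ΔΔCq expression, RFU abundance, translation efficiency, statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from acidtol.quant import (
    CqMeasurement,
    FluorescenceReading,
    RelativeLevel,
    percent_difference,
    relative_abundance,
    relative_expression,
    replicate_summary,
    rfu,
    significance_stars,
    stress_te_gain,
    translation_efficiency,
    two_group_test,
)


def cq_rows(d):
    """{(sample, gene): cq or [cq...]} -> list of CqMeasurement."""
    out = []
    for (s, g), v in d.items():
        vals = v if isinstance(v, (list, tuple)) else [v]
        out.extend(
            CqMeasurement(sample=s, gene=g, cq=c, replicate=i + 1)
            for i, c in enumerate(vals)
        )
    return out


class TestRelativeExpression:
    def test_all_equal_cq_gives_level_one(self):
        cq = cq_rows({("s", "T"): 20, ("s", "R"): 15,
                      ("cal", "T"): 20, ("cal", "R"): 15})
        levels = relative_expression(cq, "T", "R", "cal")
        assert all(lv.level == pytest.approx(1.0) for lv in levels)

    def test_one_cycle_lower_target_doubles_level(self):
        cq = cq_rows({("s", "T"): 19, ("s", "R"): 15,
                      ("cal", "T"): 20, ("cal", "R"): 15})
        by = {lv.sample: lv.level for lv in relative_expression(cq, "T", "R", "cal")}
        assert by["s"] == pytest.approx(2.0)
        assert by["cal"] == 1.0  # calibrator exactly 1

    def test_replicates_averaged_before_delta_arithmetic(self):
        cq = cq_rows({("s", "T"): [19.0, 21.0], ("s", "R"): 15,
                      ("cal", "T"): 20, ("cal", "R"): 15})
        by = {lv.sample: lv.level for lv in relative_expression(cq, "T", "R", "cal")}
        assert by["s"] == pytest.approx(1.0)  # mean Cq 20 == calibrator

    def test_shift_invariance(self):
        """Adding a constant to every Cq of a run leaves all levels unchanged."""
        base = {("s", "T"): 18.3, ("s", "R"): 14.1,
                ("cal", "T"): 20.2, ("cal", "R"): 15.0}
        ref = {lv.sample: lv.level
               for lv in relative_expression(cq_rows(base), "T", "R", "cal")}
        shifted = {k: v + 3.7 for k, v in base.items()}
        got = {lv.sample: lv.level
               for lv in relative_expression(cq_rows(shifted), "T", "R", "cal")}
        for s in ref:
            assert got[s] == pytest.approx(ref[s])

    def test_missing_reference_raises(self):
        cq = cq_rows({("s", "T"): 20, ("cal", "T"): 20, ("cal", "R"): 15})
        with pytest.raises(ValueError, match="missing Cq"):
            relative_expression(cq, "T", "R", "cal")

    @pytest.mark.parametrize("eff", [0.0, -1.0, 1.0, 2.5])
    def test_efficiency_outside_unit_interval_rejected(self, eff):
        cq = cq_rows({("cal", "T"): 20, ("cal", "R"): 15})
        with pytest.raises(ValueError, match="efficiency"):
            relative_expression(cq, "T", "R", "cal", efficiency=eff)


class TestRfuAndAbundance:
    def test_rfu_is_fi_over_od(self):
        assert rfu(FluorescenceReading("s", fi=800, od600=0.8)) == pytest.approx(1000)
        assert rfu(FluorescenceReading("s", fi=0, od600=0.5)) == 0.0

    def test_rfu_rejects_nonpositive_od(self):
        with pytest.raises(ValueError, match="od600"):
            rfu(FluorescenceReading("s", fi=10, od600=0.0))

    def test_background_subtraction(self):
        assert rfu(FluorescenceReading("s", fi=900, od600=1.0), blank_fi=100) == 800

    def test_relative_abundance_calibrator_is_one(self):
        levels = {lv.sample: lv.level for lv in relative_abundance(
            {"cal": 500.0, "s": 800.0, "t": 500.0}, "cal", gene="UME6")}
        assert levels["cal"] == 1.0
        assert levels["s"] == pytest.approx(1.6)
        assert levels["t"] == levels["cal"]

    def test_nonpositive_calibrator_rfu_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            relative_abundance({"cal": 0.0, "s": 2.0}, "cal")


class TestTranslationEfficiency:
    def _lv(self, level, kind, sample="s", cal="cal"):
        return RelativeLevel(sample=sample, gene="UME6", level=level, kind=kind,
                             calibrator=cal)

    def test_unity_levels_give_te_one(self):
        te = translation_efficiency(self._lv(1, "protein"), self._lv(1, "mRNA"))
        assert te.te == 1.0

    def test_acid_inductions_control_strain(self):
        """Protein 2.4x over mRNA 1.6x -> TE 1.5 under acid stress."""
        te = translation_efficiency(self._lv(2.4, "protein"), self._lv(1.6, "mRNA"))
        assert te.te == pytest.approx(1.5)

    def test_acid_inductions_overexpressor_strain(self):
        te = translation_efficiency(self._lv(4.1, "protein"), self._lv(2.7, "mRNA"))
        assert te.te == pytest.approx(1.519, abs=1e-3)

    def test_calibrator_mismatch_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            translation_efficiency(
                self._lv(2, "protein", cal="a"), self._lv(1, "mRNA", cal="b")
            )

    def test_calibrator_consistency_under_recalibration(self):
        """Re-expressing all levels against another calibrator scales them by
        one constant and leaves TE ratios and percent differences unchanged."""
        protein = {"a": 1.0, "b": 1.6, "c": 2.4}
        mrna = {"a": 1.0, "b": 1.1, "c": 1.6}
        te_a = {s: protein[s] / mrna[s] for s in protein}
        # recalibrate to sample "b"
        protein_b = {s: v / protein["b"] for s, v in protein.items()}
        mrna_b = {s: v / mrna["b"] for s, v in mrna.items()}
        te_b = {s: protein_b[s] / mrna_b[s] for s in protein}
        scale = te_a["b"]
        for s in protein:
            assert te_b[s] * scale == pytest.approx(te_a[s])
        assert percent_difference(te_a["c"], te_a["b"]) == pytest.approx(
            percent_difference(te_b["c"], te_b["b"])
        )


class TestPercentDifferenceAndWorkedChain:
    def test_equal_values_zero_percent(self):
        assert percent_difference(1.5, 1.5) == 0.0
        assert percent_difference(3.0, 1.5) == pytest.approx(100.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)

    def test_te_advantage_chain_reproduces_69_percent(self):
        """Baseline TE advantage 67% (ratio 1.67) combined with acid
        inductions 4.1/2.7 vs 2.4/1.6 yields a 69% TE advantage."""
        gain = stress_te_gain(
            baseline_te_ratio=1.67,
            mrna_fold_control=1.6, mrna_fold_treated=2.7,
            protein_fold_control=2.4, protein_fold_treated=4.1,
        )
        assert round(gain) == 69
        assert gain == pytest.approx(69.0, abs=1.0)


class TestReplicateStatistics:
    def test_constant_values(self):
        mean, sd, n = replicate_summary([1.0, 1.0, 1.0])
        assert (mean, sd, n) == (1.0, 0.0, 3)

    def test_sample_sd_uses_n_minus_one(self):
        _, sd, _ = replicate_summary([1.0, 3.0])
        assert sd == pytest.approx(math.sqrt(2.0))

    def test_identical_groups_not_significant(self):
        p = two_group_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(1.0)
        assert significance_stars(p) == ""

    def test_single_value_group_refused(self):
        with pytest.raises(ValueError, match=">= 2"):
            two_group_test([1.0], [1.0, 2.0])

    def test_stars_thresholds(self):
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""

    def test_power_for_large_planted_shift(self):
        """A 5-sd shift at n=3 per group is detected (P < 0.05) in >= 95%
        of 1000 simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 3)
            b = rng.normal(5.0, 1.0, 3)
            if two_group_test(a, b) < 0.05:
                hits += 1
        assert hits / n_sim >= 0.95
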