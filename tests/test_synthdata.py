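"""Round-trip tests: every generator's output, analysed, matches its truth."""

from __future__ import annotations

import numpy as np
import pytest

from acidtol.genesets import consistency_union
from acidtol.motifscan import census, profile_protein
from acidtol.quant import relative_expression
from acidtol.regulon import ConsensusPattern, classify_direct_targets, scan_consensus
from acidtol.synthdata import (
    DEFAULT_OVERLAP_SPEC,
    simulate_expression,
    simulate_fluorescence,
    simulate_growth,
    simulate_proteome,
    simulate_regulon,
    simulate_screens,
    write_fasta,
)


class TestSimulateProteome:
    def test_planted_census_recovered_exactly(self):
        spec = {"2×3P": 10, "1×4P": 7, "1×3P": 20}
        records, truth = simulate_proteome(
            n_proteins=500, pattern_spec=spec, seed=42
        )
        profiles = [profile_protein(r) for r in records]
        c = census(profiles)
        assert c.counts == spec == truth.motif_census
        assert c.n_with_any_run == 37
        assert c.n_high_dependence == 17  # 2×3P and 1×4P both qualify

    def test_empty_spec_plants_nothing(self):
        records, truth = simulate_proteome(n_proteins=50, seed=1)
        assert census([profile_protein(r) for r in records]).n_with_any_run == 0
        assert truth.motif_census == {}

    def test_same_seed_reproduces_identical_fasta_bytes(self, tmp_path):
        for name in ("a", "b"):
            records, _ = simulate_proteome(
                n_proteins=30, pattern_spec={"1×3P": 5}, seed=9
            )
            write_fasta(records, tmp_path / f"{name}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_background_proline_mode_truth_recomputed(self):
        records, truth = simulate_proteome(
            n_proteins=100, pattern_spec={"1×3P": 4}, background_p_freq=0.08, seed=3
        )
        c = census([profile_protein(r) for r in records])
        assert c.counts == truth.motif_census  # truth rescanned post hoc

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_proteome(n_proteins=2, pattern_spec={"1×3P": 5}, seed=0)
        with pytest.raises(ValueError):
            simulate_proteome(
                n_proteins=5, length_range=(4, 4), pattern_spec={"1×9P": 1}, seed=0
            )


class TestSimulateScreens:
    def test_default_spec_unions_to_1031(self):
        sets, truth = simulate_screens(seed=0)
        assert [len(s) for s in sets] == [216, 650, 409]
        res = consistency_union(sets)
        assert res.union_size == 1031 == truth.union_size

    def test_disjoint_spec_union_is_sum(self):
        spec = {"s1_only": 5, "s2_only": 7, "s3_only": 3,
                "s1_s2": 0, "s1_s3": 0, "s2_s3": 0, "all": 0}
        sets, truth = simulate_screens(
            universe_size=100, set_sizes=(5, 7, 3), overlap_spec=spec, seed=1
        )
        assert consistency_union(sets).union_size == 15

    def test_identical_spec_union_is_s1(self):
        spec = {"s1_only": 0, "s2_only": 0, "s3_only": 0,
                "s1_s2": 0, "s1_s3": 0, "s2_s3": 0, "all": 6}
        sets, _ = simulate_screens(
            universe_size=50, set_sizes=(6, 6, 6), overlap_spec=spec, seed=1
        )
        assert consistency_union(sets).union_size == 6
        assert sets[0].ids == sets[1].ids == sets[2].ids

    def test_inconsistent_spec_rejected(self):
        bad = dict(DEFAULT_OVERLAP_SPEC, s1_only=999)
        with pytest.raises(ValueError, match="implies"):
            simulate_screens(overlap_spec=bad, seed=0)


class TestSimulateRegulon:
    def test_direct_count_round_trip(self):
        table, promoters, truth = simulate_regulon(
            n_targets=100, n_direct=17, promoter_len=400, seed=0
        )
        pat = ConsensusPattern(truth.regulon["pattern"])
        classified = classify_direct_targets(table, promoters, pat)
        assert sorted(classified.direct_ids) == truth.regulon["direct_targets"]
        assert len(classified.direct_ids) == 17

    def test_zero_direct(self):
        table, promoters, truth = simulate_regulon(
            n_targets=20, n_direct=0, promoter_len=300, seed=2
        )
        classified = classify_direct_targets(
            table, promoters, ConsensusPattern("TCGGCGGCT")
        )
        assert classified.direct_ids == frozenset()

    def test_planted_positions_recovered(self):
        _, promoters, truth = simulate_regulon(
            n_targets=60, n_direct=25, promoter_len=500, seed=7
        )
        pat = ConsensusPattern("TCGGCGGCT")
        by_gene = {p.gene: p for p in promoters}
        for gene, positions in truth.site_positions.items():
            hits = {h.position for h in scan_consensus(by_gene[gene], pat)}
            assert set(positions) <= hits

    def test_strand_flipped_sites_need_both_strand_scanning(self):
        # with many planted sites ~half land on the minus strand; a
        # forward-only scan must then miss some direct targets
        table, promoters, truth = simulate_regulon(
            n_targets=40, n_direct=40, promoter_len=300, seed=11
        )
        both = classify_direct_targets(
            table, promoters, ConsensusPattern("TCGGCGGCT", scan_both_strands=True)
        )
        fwd = classify_direct_targets(
            table, promoters, ConsensusPattern("TCGGCGGCT", scan_both_strands=False)
        )
        assert len(both.direct_ids) == 40
        assert len(fwd.direct_ids) < 40


class TestSimulateMeasurements:
    def test_unit_folds_recover_levels_near_one(self):
        folds = {"cal": {"UME6": 1.0}, "s1": {"UME6": 1.0}, "s2": {"UME6": 1.0}}
        df, truth = simulate_expression(folds, noise_sd=0.01, seed=0)
        levels = relative_expression(df, "UME6", "ACT1", "cal")
        for lv in levels:
            assert lv.level == pytest.approx(1.0, rel=0.1)

    def test_planted_fold_recovered_within_10_percent(self):
        folds = {"cal": {"G": 1.0}, "stress": {"G": 3.5}}
        df, _ = simulate_expression(folds, noise_sd=0.1, n_replicates=3, seed=8)
        by = {lv.sample: lv.level
              for lv in relative_expression(df, "G", "ACT1", "cal")}
        assert by["stress"] == pytest.approx(3.5, rel=0.1)

    def test_te_round_trip_reproduces_69_percent_gain(self):
        """Planted mRNA inductions 1.6/2.7 and protein 2.4/4.1 on a 1.67
        baseline recover a ~69% stressed TE advantage through the full
        qPCR + fluorescence pipeline."""
        from acidtol.quant import relative_abundance, rfu, percent_difference
        from acidtol.quant import FluorescenceReading, translation_efficiency

        mrna_folds = {
            "ctrl_0": {"UME6": 1.0}, "ctrl_aa": {"UME6": 1.6},
            "over_0": {"UME6": 1.0}, "over_aa": {"UME6": 2.7},
        }
        df, _ = simulate_expression(mrna_folds, calibrator_sample="ctrl_0",
                                    noise_sd=0.0, seed=0)
        mrna = {lv.sample: lv
                for lv in relative_expression(df, "UME6", "ACT1", "ctrl_0")}
        abundance = {"ctrl_0": 1.0, "ctrl_aa": 2.4, "over_0": 1.67,
                     "over_aa": 1.67 * 4.1}
        od = {s: 0.8 for s in abundance}
        plate, _ = simulate_fluorescence(abundance, od, noise_sd=0.0, seed=0)
        rfus = {
            r.sample: rfu(FluorescenceReading(r.sample, r.FI, r.od600))
            for r in plate.itertuples()
        }
        protein = {lv.sample: lv
                   for lv in relative_abundance(rfus, "ctrl_0", gene="UME6")}
        te = {s: translation_efficiency(protein[s], mrna[s]).te for s in mrna}
        gain = percent_difference(te["over_aa"], te["ctrl_aa"])
        assert gain == pytest.approx(69.06, abs=2.0)

    def test_growth_generator_determinism_and_flat_rate_zero(self):
        a, _ = simulate_growth(noise_sd=0.03, seed=6)
        b, _ = simulate_growth(noise_sd=0.03, seed=6)
        assert np.array_equal(a.od, b.od)
        from acidtol.growth import growth_variables
        flat, _ = simulate_growth(rate=0.0, noise_sd=0.0, seed=0)
        assert growth_variables(flat).rate == 0.0
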