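"""Proteolysis simulator: enzyme rules, event semantics, determinism."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from degradograph import ProteinRecord
from degradograph.simulate import (
    EnzymeRule,
    SimConfig,
    apply_detection_filter,
    delta_vs_extent,
    get_enzyme,
    load_enzyme_rules,
    replay_events,
    simulate,
    synthetic_benchmark_proteins,
)


class TestEnzymeRules:
    def test_trypsin_cuts_after_kr(self):
        sites = get_enzyme("trypsin").cleavage_sites("AAKAAA")
        assert sites == [3]

    def test_trypsin_proline_block(self):
        assert get_enzyme("trypsin").cleavage_sites("AKPA") == []

    def test_trypsin_literal_requires_proline(self):
        assert get_enzyme("trypsin-literal").cleavage_sites("AKPA") == [2]
        assert get_enzyme("trypsin-literal").cleavage_sites("AKAA") == []

    def test_elastase_sites(self):
        assert get_enzyme("elastase").cleavage_sites("KAKVK") == [2, 4]

    def test_terminal_positions_excluded(self):
        # a match at position 0 or len(seq) would not be a cut
        assert get_enzyme("elastase").cleavage_sites("AA") == [1]

    def test_malformed_pattern_rejected(self):
        with pytest.raises(Exception):
            EnzymeRule("bad", "(?<=[KR")

    def test_rule_file_round_trip(self, tmp_path):
        p = tmp_path / "enz.json"
        p.write_text('{"name": "argC", "regex": "(?<=R)"}')
        rule = load_enzyme_rules(p)
        assert rule.cleavage_sites("ARA") == [2]

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(KeyError):
            get_enzyme("pepsinX")


@pytest.fixture
def protein():
    return ProteinRecord("p", "MKAYRLKDDAIKAYRLKDDA")


class TestSimulate:
    def test_pure_exo_trims_one_terminal_residue(self):
        prot = ProteinRecord("p", "MKAYR")
        rec = simulate(
            prot, get_enzyme("trypsin"),
            SimConfig(endo_probability=0.0, target_peptide_count=3, seed=1),
        )
        for kind, iv, _ in rec.event_log:
            assert kind == "exo"
        for u, v in rec.true_graph.edges:
            a, b = rec.true_graph.nodes[u], rec.true_graph.nodes[v]
            assert len(a) - len(b) == 1
            assert (b.start, b.end) in {(a.start + 1, a.end), (a.start, a.end - 1)}

    def test_endo_fragments_tile_substrate(self, protein):
        rec = simulate(
            protein, get_enzyme("trypsin"),
            SimConfig(endo_probability=1.0, target_peptide_count=6, seed=3),
        )
        for kind, iv, cuts in rec.event_log:
            assert kind == "endo"
            bounds = [iv[0], *cuts, iv[1]]
            assert bounds == sorted(bounds)
            frags = [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]
            assert 2 <= len(frags) <= 3
            assert frags[0][0] == iv[0] and frags[-1][1] == iv[1]
            for (_, e1), (s2, _) in zip(frags, frags[1:]):
                assert e1 == s2  # no gaps, no overlap

    def test_endo_cuts_respect_enzyme_sites(self, protein):
        tryp_sites = set(get_enzyme("trypsin").cleavage_sites(protein.sequence))
        rec = simulate(
            protein, get_enzyme("trypsin"),
            SimConfig(endo_probability=1.0, target_peptide_count=6, seed=3),
        )
        for kind, iv, cuts in rec.event_log:
            sub = protein.sequence[iv[0]:iv[1]]
            local = set(get_enzyme("trypsin").cleavage_sites(sub))
            for c in cuts:
                assert (c - iv[0]) in local

    def test_same_seed_bit_identical(self, protein):
        cfg = SimConfig(target_peptide_count=8, seed=42)
        a = simulate(protein, get_enzyme("trypsin"), cfg)
        b = simulate(protein, get_enzyme("trypsin"), cfg)
        assert a.event_log == b.event_log
        assert a.final_units == b.final_units
        assert np.array_equal(a.true_graph.weights, b.true_graph.weights)

    def test_pool_mass_conserved(self, protein):
        cfg = SimConfig(target_peptide_count=10, seed=5)
        rec = simulate(protein, get_enzyme("trypsin"), cfg)
        assert sum(rec.final_units.values()) == pytest.approx(
            cfg.target_peptide_count
        )

    def test_event_log_replays_to_final_state(self, protein):
        cfg = SimConfig(target_peptide_count=10, seed=7)
        rec = simulate(protein, get_enzyme("trypsin"), cfg)
        replayed = replay_events(protein, rec.event_log, cfg.target_peptide_count)
        for iv, units in rec.final_units.items():
            assert replayed.get(iv, 0.0) == pytest.approx(units)

    def test_impossible_endo_only_run_errors(self):
        prot = ProteinRecord("p", "AAAWWW")  # no tryptic site anywhere
        with pytest.raises(RuntimeError):
            simulate(
                prot, get_enzyme("trypsin"),
                SimConfig(endo_probability=1.0, target_peptide_count=3, seed=1),
            )

    def test_short_fragments_flagged(self, protein):
        rec = simulate(
            protein, get_enzyme("elastase"),
            SimConfig(target_peptide_count=12, seed=9, min_length=4),
        )
        for iv in rec.short_flagged:
            assert iv[1] - iv[0] < 4

    def test_true_graph_weights_are_stochastic(self, protein):
        rec = simulate(
            protein, get_enzyme("trypsin"), SimConfig(target_peptide_count=10, seed=2)
        )
        rec.true_graph.validate_weights()

    def test_observed_distribution_normalized(self, protein):
        rec = simulate(
            protein, get_enzyme("trypsin"), SimConfig(target_peptide_count=10, seed=2)
        )
        assert sum(rec.observed().values()) == pytest.approx(1.0)


class TestDetectionFilter:
    def test_zero_dropout_is_identity(self, protein):
        rec = simulate(
            protein, get_enzyme("trypsin"), SimConfig(target_peptide_count=10, seed=2)
        )
        assert apply_detection_filter(rec, 0.0) == rec.observed()

    def test_survivor_count_matches_binomial_expectation(self, protein):
        rec = simulate(
            protein, get_enzyme("elastase"),
            SimConfig(target_peptide_count=20, seed=4),
        )
        n = len(rec.observed())
        dropout = 0.8
        survivors = []
        for s in range(300):
            try:
                survivors.append(len(apply_detection_filter(rec, dropout, seed=s)))
            except ValueError:
                survivors.append(0)  # every peptide dropped in this draw
        expected = n * (1 - dropout)
        sd = np.sqrt(n * dropout * (1 - dropout))
        assert abs(np.mean(survivors) - expected) < 3 * sd / np.sqrt(300) + 0.2

    def test_filtered_distribution_renormalized(self, protein):
        rec = simulate(
            protein, get_enzyme("elastase"),
            SimConfig(target_peptide_count=15, seed=4),
        )
        filt = apply_detection_filter(rec, 0.5, seed=1)
        assert sum(filt.values()) == pytest.approx(1.0)

    def test_invalid_dropout_rejected(self, protein):
        rec = simulate(
            protein, get_enzyme("trypsin"), SimConfig(target_peptide_count=5, seed=2)
        )
        with pytest.raises(ValueError):
            apply_detection_filter(rec, 1.0)


class TestDeltaVsExtent:
    def test_shallow_degradation_has_delta_near_one(self):
        prot = synthetic_benchmark_proteins()[1]
        tab = delta_vs_extent(
            prot, get_enzyme("trypsin"), [2, 4], replicates=5, seed=3
        )
        assert tab["delta_mean"].iloc[0] < 1.5

    def test_delta_grows_with_degradation_extent(self):
        prot = synthetic_benchmark_proteins()[1]
        tab = delta_vs_extent(
            prot, get_enzyme("trypsin"), [5, 15, 30, 60], replicates=8, seed=2
        )
        rho = spearmanr(tab["n_edges"], tab["delta_mean"]).statistic
        assert rho > 0

    def test_needs_two_extents(self):
        prot = synthetic_benchmark_proteins()[1]
        with pytest.raises(ValueError):
            delta_vs_extent(prot, get_enzyme("trypsin"), [5], replicates=2)


class TestSyntheticProteins:
    def test_four_proteins_with_fixed_lengths(self):
        prots = synthetic_benchmark_proteins()
        assert [len(p) for p in prots] == [375, 147, 622, 267]
        assert all("synthetic" in p.identifier for p in prots)

    def test_generation_is_deterministic(self):
        a = synthetic_benchmark_proteins()
        b = synthetic_benchmark_proteins()
        assert [p.sequence for p in a] == [p.sequence for p in b]
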