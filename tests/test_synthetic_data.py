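import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from antigenome import library_build as lb
from antigenome import profiles as pf
from antigenome import synthetic_data as sd


class TestGenerateProteome:
    def test_cds_translates_to_protein(self, small_proteome):
        for protein in small_proteome.proteins[:10]:
            assert str(Seq(protein.cds).translate()) == protein.aa_sequence

    def test_all_shared_overlap(self):
        proteome = sd.generate_proteome(4, overlap_config={"shared_fraction": 1.0}, seed=1)
        member = proteome.source_expression > 0
        assert member.all().all()

    def test_exclusive_proteins_reported(self):
        proteome = sd.generate_proteome(
            20,
            overlap_config={"shared_fraction": 0.5, "exclusive": {"hep2": 2}},
            seed=2,
        )
        pool = sd.build_fragment_library(proteome, candidates_per_source=400, seed=3)
        # complexity over the proteome membership itself, not sampling noise
        member = proteome.source_expression > 0
        only_hep2 = member["hep2"] & ~member[["astrocyte", "brain", "pbmc"]].any(axis=1)
        assert only_hep2.sum() == 2

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        a = sd.generate_proteome(10, seed=5)
        b = sd.generate_proteome(10, seed=5)
        path_a, path_b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        a.write_fasta(path_a)
        b.write_fasta(path_b)
        assert path_a.read_bytes() == path_b.read_bytes()

    def test_invalid_length_dist(self):
        with pytest.raises(sd.ConfigurationError, match="mean_aa"):
            sd.generate_proteome(5, length_dist={"mean_aa": -1})

    def test_invalid_overlap(self):
        with pytest.raises(sd.ConfigurationError, match="shared_fraction"):
            sd.generate_proteome(5, overlap_config={"shared_fraction": 2.0})

    def test_every_protein_expressed_somewhere(self, small_proteome):
        assert (small_proteome.source_expression > 0).any(axis=1).all()


class TestBuildFragmentLibrary:
    def test_no_flip_stop_free_sequences_all_pass(self):
        # proteome of lysine-only proteins: AAA/AAG codons, no stop possible
        proteins = [sd.Protein(f"P{i}", "K" * 100, "AAA" * 100) for i in range(5)]
        expr = pd.DataFrame(1.0, index=[p.protein_id for p in proteins], columns=["s"])
        proteome = sd.SimulatedProteome(proteins, expr)
        pool = sd.build_fragment_library(
            proteome, insert_size_spec={"s": (90.0, 10.0)},
            orientation_flip_p=0.0, candidates_per_source=200, seed=7,
        )
        assert pool.screen_stats["passed"].all()

    def test_all_flipped_none_pass(self):
        proteins = [sd.Protein(f"P{i}", "K" * 100, "AAA" * 100) for i in range(5)]
        expr = pd.DataFrame(1.0, index=[p.protein_id for p in proteins], columns=["s"])
        proteome = sd.SimulatedProteome(proteins, expr)
        pool = sd.build_fragment_library(
            proteome, insert_size_spec={"s": (90.0, 10.0)},
            orientation_flip_p=1.0, candidates_per_source=200, seed=7,
        )
        assert not pool.screen_stats["passed"].any()
        assert len(pool) == 0

    def test_pass_fraction_matches_analytic_probability(self, small_proteome):
        flip_p = 0.05
        pool = sd.build_fragment_library(
            small_proteome, orientation_flip_p=flip_p,
            candidates_per_source=2000, seed=8,
        )
        stats = pool.screen_stats
        expected = np.array(
            [sd.candidate_pass_probability(l, flip_p) for l in stats["length"]]
        )
        mean_expected = expected.mean()
        se = math.sqrt((expected * (1 - expected)).sum()) / len(expected)
        observed = stats["passed"].mean()
        assert abs(observed - mean_expected) <= 3 * se + 0.01

    def test_short_proteins_skipped_with_warning(self):
        proteins = [
            sd.Protein("P0", "K" * 5, "AAA" * 5),
            sd.Protein("P1", "K" * 200, "AAA" * 200),
        ]
        expr = pd.DataFrame(1.0, index=["P0", "P1"], columns=["s"])
        proteome = sd.SimulatedProteome(proteins, expr)
        with pytest.warns(UserWarning, match="shorter than the minimum"):
            pool = sd.build_fragment_library(
                proteome, insert_size_spec={"s": (60.0, 5.0)},
                candidates_per_source=100, seed=9, orientation_flip_p=0.0,
            )
        assert {f.protein_id for f in pool.fragments} == {"P1"}

    def test_equal_pooling_by_source(self, small_pool):
        table = small_pool.to_frame()
        per_source = table.groupby("source")["input_abundance"].sum()
        assert np.allclose(per_source, per_source.iloc[0], rtol=1e-9)

    def test_pool_abundance_normalised(self, small_pool):
        assert small_pool.input_abundance.sum() == pytest.approx(1.0, abs=1e-9)


class TestGenerateSerumCohort:
    def test_zero_prevalence_no_carriers(self, small_proteome):
        _, truth = sd.generate_serum_cohort(
            {"groups": {"HC": 5, "PBO-A": 5}, "time_points": [0]},
            small_proteome,
            {"groups": ["PBO-A"], "antigens": ["P00001"], "prevalence": 0.0, "effect": 5},
            seed=1,
        )
        assert all(len(v) == 0 for v in truth.carriers.values())

    def test_full_prevalence_all_carriers(self, small_proteome):
        antigens = ["P00001", "P00002", "P00003"]
        _, truth = sd.generate_serum_cohort(
            {"groups": {"HC": 3, "PBO-A": 6}, "time_points": [0]},
            small_proteome,
            {"groups": ["PBO-A"], "antigens": antigens, "prevalence": 1.0, "effect": 5},
            seed=2,
        )
        for donor, group in truth.donor_groups.items():
            if group == "PBO-A":
                assert set(truth.carriers[donor]) == set(antigens)
            else:
                assert truth.carriers[donor] == []

    def test_study_design_manifest_arithmetic(self, small_proteome):
        profiles, _ = sd.generate_serum_cohort(
            {
                "groups": {"HC": 43, "PBO-NA": 21, "PBO-A": 27, "RNF-NA": 27, "RNF-A": 27},
                "time_points": [0, 6, 24],
            },
            small_proteome,
            seed=3,
        )
        case_rows = [p for p in profiles if p.group != "HC"]
        hc_rows = [p for p in profiles if p.group == "HC"]
        assert len(case_rows) == 306  # 102 patients x 3 visits
        assert len(hc_rows) == 129  # 43 donors x 3 visits

    def test_empty_pool_with_positive_prevalence(self, small_proteome):
        with pytest.raises(sd.ConfigurationError, match="empty"):
            sd.generate_serum_cohort(
                {"groups": {"PBO-A": 2}, "time_points": [0]},
                small_proteome,
                {"groups": ["PBO-A"], "antigens": [], "prevalence": 0.5, "effect": 5},
                seed=4,
            )

    def test_targets_persist_across_time_points(self, small_proteome):
        profiles, _ = sd.generate_serum_cohort(
            {"groups": {"PBO-A": 4}, "time_points": [0, 6, 24]},
            small_proteome,
            {"groups": ["PBO-A"], "antigens": ["P00004"], "prevalence": 1.0, "effect": 5},
            seed=5,
        )
        by_donor = {}
        for profile in profiles:
            by_donor.setdefault(profile.donor_id, []).append(profile.targets)
        for visits in by_donor.values():
            assert all(v == visits[0] for v in visits)

    def test_realized_prevalence_within_binomial_error(self, small_proteome):
        prevalence = 0.3
        n_donors = 60
        antigens = [f"P{i:05d}" for i in range(20)]
        _, truth = sd.generate_serum_cohort(
            {"groups": {"PBO-A": n_donors}, "time_points": [0]},
            small_proteome,
            {"groups": ["PBO-A"], "antigens": antigens, "prevalence": prevalence,
             "effect": 5},
            seed=6,
        )
        realized = truth.realized_prevalence("PBO-A")
        se = math.sqrt(prevalence * (1 - prevalence) / n_donors)
        mean_realized = np.mean(list(realized.values()))
        # averaging over 20 antigens shrinks the error further; 3 SE is generous
        assert abs(mean_realized - prevalence) <= 3 * se


class TestSimulateScreen:
    @staticmethod
    def _null_profile():
        return sd.SerumProfile("d0", "HC", 0, "B1", [], background=1e-4)

    def test_counts_sum_to_depth(self, small_pool):
        counts = sd.simulate_screen(small_pool, self._null_profile(), depth=12345, seed=1)
        assert counts.sum() == 12345

    def test_zero_depth_all_zero(self, small_pool):
        counts = sd.simulate_screen(small_pool, self._null_profile(), depth=0, seed=1)
        assert (counts == 0).all()

    def test_null_profile_matches_input_proportions(self, small_pool):
        depth = 1_000_000
        counts = sd.simulate_screen(small_pool, self._null_profile(), depth=depth, seed=2)
        p = small_pool.input_abundance
        se = np.sqrt(p * (1 - p) * depth)
        # 4 multinomial SEs, plus a half-count floor for tiny cells
        assert (np.abs(counts - depth * p) <= 4 * se + 0.5 + 4).all()

    def test_single_strong_target_dominates(self, small_pool):
        target_protein = small_pool.fragments[0].protein_id
        length = small_pool.protein_lengths[target_protein]
        profile = sd.SerumProfile(
            "d0", "PBO-A", 0, "B1",
            [sd.Target(target_protein, 0, length, 1000.0)], background=1e-4,
        )
        counts = sd.simulate_screen(small_pool, profile, depth=100_000, seed=3)
        idx = [
            i for i, f in enumerate(small_pool.fragments)
            if f.protein_id == target_protein
        ]
        assert counts[idx].sum() > 0.5 * counts.sum()

    def test_unknown_target_protein_errors(self, small_pool):
        profile = sd.SerumProfile(
            "d0", "HC", 0, "B1", [sd.Target("NOPE", 0, 10, 1.0)], background=1e-4
        )
        with pytest.raises(ValueError, match="absent from the pool"):
            sd.simulate_screen(small_pool, profile, depth=100, seed=4)

    def test_dispersion_inflates_variance(self, small_pool):
        depth = 50_000
        tight = np.array([
            sd.simulate_screen(small_pool, self._null_profile(), depth, 0.0, seed=s)
            for s in range(15)
        ])
        loose = np.array([
            sd.simulate_screen(small_pool, self._null_profile(), depth, 0.05, seed=s)
            for s in range(15)
        ])
        assert loose.var(axis=0).sum() > tight.var(axis=0).sum()


class TestEmitDataset:
    def test_round_trip(self, sim_bundle, tmp_path):
        paths = sd.emit_dataset(
            tmp_path / "out", sim_bundle["proteome"], sim_bundle["pool"],
            sim_bundle["counts"], sim_bundle["meta"], sim_bundle["truth"],
        )
        reloaded = pf.read_counts_tsv(paths["antigen_counts"])
        pd.testing.assert_frame_equal(reloaded, sim_bundle["antigen_counts"])
        truth2 = sd.TruthTable.from_json(paths["truth"])
        assert truth2.planted_antigens() == sim_bundle["truth"].planted_antigens()
        meta2 = pf.read_meta_tsv(paths["samples"])
        assert list(meta2["sample_id"]) == list(sim_bundle["meta"]["sample_id"])

    def test_different_seeds_same_schema(self, sim_bundle, tmp_path):
        counts2, meta2 = sd.simulate_cohort(
            sim_bundle["pool"], sim_bundle["profiles"], sim_bundle["truth"],
            depth=100_000, seed=99,
        )
        assert list(counts2.index) == list(sim_bundle["counts"].index)
        assert list(counts2.columns) == list(sim_bundle["counts"].columns)
        assert not counts2.equals(sim_bundle["counts"])

    def test_cohort_simulation_deterministic(self, sim_bundle):
        counts2, _ = sd.simulate_cohort(
            sim_bundle["pool"], sim_bundle["profiles"], sim_bundle["truth"],
            depth=100_000, seed=25,
        )
        pd.testing.assert_frame_equal(counts2, sim_bundle["counts"])
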