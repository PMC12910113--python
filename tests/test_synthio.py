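"""Generator determinism, mutation-model fidelity and planted structure."""

import numpy as np
import pandas as pd
import pytest

from tedyn import landscape, synthio
from tedyn.synthio import SimParams


class TestParams:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimParams(pingpong_fraction=1.5)

    def test_wave_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimParams(waves=((1, 1, 0.5), (2, 1, 0.2)),
                      truncation_prob_by_wave=(0.1, 0.1))


class TestLibrary:
    def test_seeded_fasta_byte_identical(self, tmp_path):
        params = SimParams(seed=7, n_families=10)
        for name in ("a.fa", "b.fa"):
            synthio.write_fasta(synthio.gen_library(params), tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_orfs_start_atg_end_stop(self, intact_library):
        for cons in intact_library.values():
            for orf in cons.orfs:
                s = cons.sequence[orf.start : orf.end]
                assert s[:3] == "ATG"
                assert s[-3:] in {"TAA", "TAG", "TGA"}
                assert len(s) % 3 == 0

    def test_zero_families_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_library(SimParams(n_families=0))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            synthio.gen_library(SimParams(n_families=2), names=["x", "x"])


class TestMutateK2P:
    def test_k_zero_is_identity(self, one_consensus):
        assert synthio.mutate_k2p(one_consensus.sequence, 0.0, 2.0, 1) == one_consensus.sequence

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            synthio.mutate_k2p("ACGT", -1.0, 2.0, 1)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            synthio.mutate_k2p("ACGN", 0.1, 2.0, 1)

    def test_length_preserved(self, one_consensus):
        out = synthio.mutate_k2p(one_consensus.sequence, 0.3, 2.0, 5)
        assert len(out) == len(one_consensus.sequence)

    def test_divergence_recovered_at_01702(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        out = synthio.mutate_k2p(seq, 0.1702, 2.0, 99)
        assert 0.15 <= landscape.kimura_distance(seq, out).K <= 0.19

    @pytest.mark.parametrize("target", [0.5, 2.0, 5.0, 11.0, 25.0])
    def test_roundtrip_median_within_10_percent(self, target, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        ks = [
            100 * landscape.kimura_distance(
                seq, synthio.mutate_k2p(seq, target / 100, 2.0, 1000 + i)
            ).K
            for i in range(30)
        ]
        assert abs(np.median(ks) - target) / target < 0.10


class TestBuildGenome:
    def test_truth_row_per_planted_copy(self, small_genome):
        params, _, _, truth, hits = small_genome
        assert len(truth) == params.n_families * params.copies_per_family
        assert len(hits) == len(truth)

    def test_truth_intervals_partition_te_bp(self, small_genome):
        _, _, _, truth, _ = small_genome
        t = truth.sort_values("start")
        assert (t["end"] > t["start"]).all()
        assert (t["start"].to_numpy()[1:] >= t["end"].to_numpy()[:-1]).all()

    def test_wave_mixture_trimodal(self):
        params = SimParams(seed=3)
        library = synthio.gen_library(params)
        _, truth, _ = synthio.build_genome(params, library)
        assert len(truth) == 300
        modes = truth.groupby("wave")["target_K"].mean()
        for wave, (mean_k, _, _) in zip(sorted(modes.index), params.waves):
            assert abs(modes[wave] - mean_k) <= 0.2 * max(mean_k, 1.0)

    def test_no_truncation_means_fraction_one(self):
        params = SimParams(seed=5, n_families=4, copies_per_family=4,
                           genome_length=400_000,
                           truncation_prob_by_wave=(0.0, 0.0, 0.0))
        library = synthio.gen_library(params)
        _, truth, _ = synthio.build_genome(params, library)
        assert (truth["length_fraction"] == 1.0).all()

    def test_insufficient_space_names_shortfall(self):
        params = SimParams(seed=1, n_families=5, copies_per_family=10, genome_length=10_000)
        library = synthio.gen_library(params)
        with pytest.raises(ValueError, match="short by"):
            synthio.build_genome(params, library)

    def test_seeded_rerun_identical(self):
        params = SimParams(seed=9, n_families=3, copies_per_family=3, genome_length=200_000)
        library = synthio.gen_library(params)
        g1, t1, _ = synthio.build_genome(params, library)
        g2, t2, _ = synthio.build_genome(params, library)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1, t2)


class TestSmallRnaSim:
    def test_full_1u_bias(self, one_consensus):
        reads = synthio.sim_small_rnas(one_consensus, 500, 0.0, 1.0, seed=2)
        assert (reads["sequence"].str[0] == "T").all()

    def test_zero_reads_empty_table(self, one_consensus):
        assert len(synthio.sim_small_rnas(one_consensus, 0, 0.5, 0.5, seed=1)) == 0

    def test_bad_pingpong_fraction(self, one_consensus):
        with pytest.raises(ValueError):
            synthio.sim_small_rnas(one_consensus, 10, 1.2, 0.5, seed=1)

    def test_lengths_in_pirna_range(self, one_consensus):
        reads = synthio.sim_small_rnas(one_consensus, 400, 0.5, 0.8, seed=3)
        assert reads["length"].between(23, 29).all()

    def test_reads_are_exact_substrings(self, one_consensus):
        from tedyn._util import revcomp
        reads = synthio.sim_small_rnas(one_consensus, 200, 0.5, 0.8, seed=4)
        cons = one_consensus.sequence
        for row in reads.itertuples():
            probe = row.sequence if row.strand == "sense" else revcomp(row.sequence)
            assert probe in cons


class TestTracks:
    def test_intervals_sorted_non_overlapping(self, small_genome):
        params, _, genome, truth, _ = small_genome
        truth, _ = synthio.sim_strain_calls(truth, 0.3, seed=1, strains=params.strains)
        clen = {c: len(s) for c, s in genome.items()}
        tracks = synthio.sim_tracks(truth, params.strains, clen, seed=1)
        for chip, inp in tracks.values():
            for s, e, _v in chip.data.values():
                assert (np.diff(s) > 0).all()
                assert (e[:-1] <= s[1:]).all()

    def test_out_of_bounds_insertion_rejected(self, small_genome):
        params, _, genome, truth, _ = small_genome
        bad = truth.head(1).copy()
        bad.loc[:, "end"] = 10**9
        with pytest.raises(ValueError, match="bounds"):
            synthio.sim_tracks(bad.assign(strains="strain_1"), params.strains,
                               {c: len(s) for c, s in genome.items()}, seed=1)

    def test_bad_decay_rejected(self, small_genome):
        params, _, genome, truth, _ = small_genome
        with pytest.raises(ValueError):
            synthio.sim_tracks(truth.assign(strains=""), params.strains,
                               {c: len(s) for c, s in genome.items()},
                               spread_decay=0.0, seed=1)


class TestStrainCalls:
    def test_full_sharing_leaves_nothing_unique(self, small_genome):
        _, _, _, truth, _ = small_genome
        t, _ = synthio.sim_strain_calls(truth, 1.0, seed=2)
        assert not t["unique"].any()

    def test_no_sharing_makes_all_unique(self, small_genome):
        _, _, _, truth, _ = small_genome
        t, calls = synthio.sim_strain_calls(truth, 0.0, seed=2)
        assert t["unique"].all()
        assert sum(len(c) for c in calls.values()) == len(truth)

    def test_taf_in_unit_interval(self, small_genome):
        _, _, _, truth, _ = small_genome
        _, calls = synthio.sim_strain_calls(truth, 0.3, seed=3)
        for df in calls.values():
            assert df["taf"].between(0, 1).all()

    def test_excessive_jitter_rejected(self, small_genome):
        _, _, _, truth, _ = small_genome
        with pytest.raises(ValueError):
            synthio.sim_strain_calls(truth, 0.3, seed=1, jitter=5000)


class TestExpressionSim:
    @pytest.fixture(scope="class")
    def truth_with_strains(self, small_genome):
        _, _, _, truth, _ = small_genome
        t, _ = synthio.sim_strain_calls(truth, 0.3, seed=4)
        return t

    def test_seeded_rerun_identical(self, truth_with_strains):
        a = synthio.sim_expression(truth_with_strains, {0: -1.0}, seed=5)
        b = synthio.sim_expression(truth_with_strains, {0: -1.0}, seed=5)
        for x, y in zip(a[:2], b[:2]):
            pd.testing.assert_frame_equal(x, y)

    def test_te_mean_tracks_copy_number(self, truth_with_strains):
        _, te, _ = synthio.sim_expression(truth_with_strains, {}, seed=6, reps=40,
                                          dispersion=0.01)
        strain = te.columns.get_level_values("strain")[0]
        mem = truth_with_strains["strains"].apply(lambda s: strain in s.split(","))
        cn = truth_with_strains[mem]["family"].value_counts()
        means = te[strain].mean(axis=1)
        pairs = [(f1, f2) for f1 in cn.index for f2 in cn.index
                 if cn[f1] >= 2 * cn[f2] and cn[f2] > 0]
        assert pairs, "fixture lacks a 2x copy-number contrast"
        f1, f2 = max(pairs, key=lambda p: cn[p[1]])
        assert means[f1] / means[f2] == pytest.approx(cn[f1] / cn[f2], rel=0.25)

    def test_negative_dispersion_rejected(self, truth_with_strains):
        with pytest.raises(ValueError):
            synthio.sim_expression(truth_with_strains, {}, seed=1, dispersion=-0.5)


class TestSpeciesPanel:
    @pytest.fixture(scope="class")
    def panel(self, intact_library):
        return synthio.sim_species_panel(intact_library, {list(intact_library)[0]},
                                         gene_dS_mean=0.15, seed=10)

    def test_ht_family_near_identity(self, intact_library, panel):
        from tedyn import horizontal
        fam = list(intact_library)[0]
        cons = intact_library[fam].sequence
        for sp in panel.species:
            row = panel.te_coords.query("species == @sp and family == @fam").iloc[0]
            copy = panel.genomes[sp][row["start"] : row["end"]]
            mism = sum(a != b for a, b in zip(cons, copy))
            assert 1 - mism / len(cons) >= 0.995

    def test_gene_ds_in_target_window(self, panel):
        from tedyn import horizontal
        ds = [
            horizontal.ds_ng86(aln["focal"], aln[sp]).dS
            for aln in panel.gene_alignments.values()
            for sp in panel.species[:1]
        ]
        assert 0.12 <= np.median(ds) <= 0.18

    def test_seeded_rerun_identical(self, intact_library):
        a = synthio.sim_species_panel(intact_library, set(), seed=11)
        b = synthio.sim_species_panel(intact_library, set(), seed=11)
        assert a.genomes == b.genomes

    def test_empty_panel_rejected(self, intact_library):
        with pytest.raises(ValueError):
            synthio.sim_species_panel(intact_library, set(), species=[])

    def test_unknown_ht_family_rejected(self, intact_library):
        with pytest.raises(ValueError):
            synthio.sim_species_panel(intact_library, {"nope"})
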