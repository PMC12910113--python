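"""Signal tracks, spreading tests, feature annotation, gene effects, association."""

import numpy as np
import pandas as pd
import pytest

from tedyn import epigenome, synthio
from tedyn.epigenome import SignalTrack, _window_bounds


def flat_track(value, length=100_000, contig="c1"):
    return SignalTrack({contig: (np.array([0]), np.array([length]), np.array([value]))})


class TestSignalTrack:
    def test_bin_means_piecewise(self):
        t = SignalTrack({"c": (np.array([0, 100]), np.array([100, 200]), np.array([1.0, 3.0]))})
        np.testing.assert_allclose(t.bin_means("c", 0, 200, 50), [1, 1, 3, 3])
        # straddling bin averages by coverage
        np.testing.assert_allclose(t.bin_means("c", 50, 150, 100), [2.0])

    def test_gaps_read_zero(self):
        t = SignalTrack({"c": (np.array([0]), np.array([100]), np.array([4.0]))})
        np.testing.assert_allclose(t.bin_means("c", 100, 200, 50), [0, 0])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack({"c": (np.array([0, 50]), np.array([100, 150]), np.array([1.0, 2.0]))})

    def test_bedgraph_roundtrip(self, tmp_path):
        t = SignalTrack({"c": (np.array([0, 100]), np.array([100, 250]), np.array([1.5, 0.25]))})
        p = tmp_path / "t.bedGraph"
        t.to_bedgraph(p)
        back = SignalTrack.from_bedgraph(p)
        np.testing.assert_allclose(back.data["c"][2], t.data["c"][2])


class TestEnrichmentMatrix:
    def test_constant_signal_difference(self):
        ins = pd.DataFrame({"contig": ["c1"], "start": [50_000], "end": [52_000],
                            "copy_id": ["i1"]})
        mat = epigenome.enrichment_matrix(flat_track(3.0), flat_track(1.0), ins)
        for label, w in mat["i1"].items():
            assert not w["truncated"]
            np.testing.assert_allclose(w["values"], 2.0)
            assert len(w["values"]) == 100

    def test_negative_enrichment_retained(self):
        ins = pd.DataFrame({"contig": ["c1"], "start": [50_000], "end": [51_000],
                            "copy_id": ["i1"]})
        mat = epigenome.enrichment_matrix(flat_track(1.0), flat_track(4.0), ins)
        assert (mat["i1"][1]["values"] < 0).all()

    def test_contig_edge_flags_truncated(self):
        ins = pd.DataFrame({"contig": ["c1"], "start": [1500], "end": [2000],
                            "copy_id": ["i1"]})
        mat = epigenome.enrichment_matrix(flat_track(2.0), flat_track(1.0), ins,
                                          contig_lengths={"c1": 100_000})
        assert mat["i1"][-2]["truncated"] and mat["i1"][-4]["truncated"]
        assert not mat["i1"][-1]["truncated"]
        assert len(mat["i1"][-2]["values"]) == 50  # [-500, 0) clipped away

    def test_windows_tile_flank_exactly(self):
        bounds = _window_bounds(10_000, 12_000, flank=4000, window=1000)
        up = sorted(b for label, b in bounds.items() if label < 0)
        dn = sorted(b for label, b in bounds.items() if label > 0)
        assert up[0][0] == 6000 and up[-1][1] == 10_000
        assert dn[0][0] == 12_000 and dn[-1][1] == 16_000
        for (s1, e1), (s2, e2) in zip(up, up[1:]):
            assert e1 == s2
        for (s1, e1), (s2, e2) in zip(dn, dn[1:]):
            assert e1 == s2


class TestSpreadTest:
    def test_complete_separation_exact_p(self):
        res = epigenome.test_spreading(
            {1: np.array([5.0, 5, 5, 5, 5])},
            [{1: np.array([1.0, 1, 1, 1, 1])}],
        )
        assert res.p_by_window[1] == pytest.approx(2 / 252)

    def test_identical_signal_p_one(self):
        res = epigenome.test_spreading(
            {1: np.ones(50)}, [{1: np.ones(50)}, {1: np.ones(50)}]
        )
        assert res.p_by_window[1] == 1.0

    def test_no_control_strain_rejected(self):
        with pytest.raises(ValueError):
            epigenome.test_spreading({1: np.ones(5)}, [])

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(3)
        results = []
        for i in range(20):
            r = epigenome.SpreadResult(insertion_id=str(i), p_by_window={1: float(rng.uniform())})
            r.enrichment_present[1] = 1.0
            r.enrichment_absent[1] = 0.0
            results.append(r)
        epigenome.finalize_spread(results)
        ordered = sorted(results, key=lambda r: r.p_by_window[1])
        qs = [r.q_by_window[1] for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_planted_spreading_recovered_end_to_end(self):
        params = synthio.SimParams(
            seed=31, n_families=4, copies_per_family=5, genome_length=1_500_000,
            status_weights=(1.0, 0, 0), spread_prob_full_length=1.0,
            truncation_prob_by_wave=(0.3, 0.3, 0.3),
        )
        library = synthio.gen_library(params)
        genome, truth, _ = synthio.build_genome(params, library)
        truth, _ = synthio.sim_strain_calls(truth, 0.0, seed=31, strains=params.strains)
        ins = truth[truth["unique"] & truth["full_length"]]
        clen = {c: len(s) for c, s in genome.items()}
        tracks = synthio.sim_tracks(ins, params.strains, clen, 5.0, 1500.0, seed=31)
        res = epigenome.spreading_analysis(tracks, ins, contig_lengths=clen)
        planted = ins.set_index("copy_id")["spread_planted"]
        rates = pd.Series({r.insertion_id: r.spreading for r in res})
        assert rates[planted[planted].index].mean() >= 0.9
        assert max(r.max_distance_kb for r in res) <= 4


class TestAnnotateFeature:
    @pytest.fixture
    def models(self):
        genes = pd.DataFrame(
            [{"gene_id": "g1", "contig": "c", "strand": "+", "start": 10_000, "end": 20_000}]
        )
        exons = pd.DataFrame(
            [
                {"gene_id": "g1", "start": 10_000, "end": 10_300, "kind": "5UTR"},
                {"gene_id": "g1", "start": 10_300, "end": 11_000, "kind": "CDS"},
                {"gene_id": "g1", "start": 15_000, "end": 19_500, "kind": "CDS"},
                {"gene_id": "g1", "start": 19_500, "end": 20_000, "kind": "3UTR"},
            ]
        )
        return genes, exons

    def test_promoter_within_1kb_upstream(self, models):
        assert epigenome.annotate_feature(9500, "c", *models) == "promoter"

    def test_beyond_promoter_is_intergenic(self, models):
        assert epigenome.annotate_feature(8900, "c", *models) == "intergenic"

    def test_cds_exon(self, models):
        assert epigenome.annotate_feature(10_500, "c", *models) == "exon_CDS"

    def test_utr_kinds(self, models):
        assert epigenome.annotate_feature(10_100, "c", *models) == "exon_5UTR"
        assert epigenome.annotate_feature(19_700, "c", *models) == "exon_3UTR"

    def test_intron_near_vs_distal_boundary(self, models):
        assert epigenome.annotate_feature(11_900, "c", *models) == "intron_near"
        assert epigenome.annotate_feature(12_300, "c", *models) == "intron_distal"

    def test_minus_strand_promoter(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "contig": "c", "strand": "-", "start": 5000, "end": 9000}]
        )
        exons = pd.DataFrame([{"gene_id": "g", "start": 5000, "end": 9000, "kind": "CDS"}])
        assert epigenome.annotate_feature(9400, "c", genes, exons) == "promoter"
        assert epigenome.annotate_feature(4600, "c", genes, exons) == "intergenic"

    def test_matches_interval_membership_oracle(self, rng):
        genes = pd.DataFrame(
            [{"gene_id": "g", "contig": "c", "strand": "+", "start": 50_000, "end": 60_000}]
        )
        exons = pd.DataFrame(
            [
                {"gene_id": "g", "start": 50_000, "end": 52_000, "kind": "CDS"},
                {"gene_id": "g", "start": 57_000, "end": 60_000, "kind": "CDS"},
            ]
        )
        for _ in range(300):
            pos = int(rng.integers(45_000, 65_000))
            got = epigenome.annotate_feature(pos, "c", genes, exons)
            if 50_000 <= pos < 52_000 or 57_000 <= pos < 60_000:
                want = "exon_CDS"
            elif 49_000 <= pos < 50_000:
                want = "promoter"
            elif 52_000 <= pos < 57_000:
                d = min(abs(pos - 52_000 + 1), abs(57_000 - pos))
                want = "intron_near" if d <= 1000 else "intron_distal"
            else:
                want = "intergenic"
            assert got == want, (pos, got, want)


class TestGeneEffects:
    def test_planted_effect_in_first_bin_only(self, small_genome):
        _, _, _, truth, _ = small_genome
        truth, _ = synthio.sim_strain_calls(truth, 0.3, seed=41)
        counts, _, meta = synthio.sim_expression(truth, {0: -1.0}, seed=41)
        bins, genes = epigenome.gene_effects_by_distance(counts, meta)
        assert bool(bins.loc[bins["distance_bin"] == 0, "significant"].iloc[0])
        assert not bool(bins.loc[bins["distance_bin"] == 4, "significant"].iloc[0])
        assert bins.loc[bins["distance_bin"] == 0, "median_log2FC"].iloc[0] < -0.5

    def test_overlapping_gene_in_bin_zero(self, small_genome):
        _, _, _, truth, _ = small_genome
        truth, _ = synthio.sim_strain_calls(truth, 0.3, seed=42)
        counts, _, meta = synthio.sim_expression(truth, {}, seed=42)
        meta.loc[meta.index[0], "distance"] = 0.0
        assert int(meta.iloc[0]["distance"] // 1000) == 0


class TestAssociation:
    def test_hand_computed_chi2(self):
        res = epigenome.associate_spreading_downregulation(
            [True] * 40 + [False] * 60,
            [True] * 30 + [False] * 10 + [True] * 15 + [False] * 45,
        )
        assert res.chi2 == pytest.approx(24.24, abs=0.005)
        assert res.df == 1
        assert res.p < 1e-6

    def test_independent_margins_zero(self):
        res = epigenome.associate_spreading_downregulation(
            [True] * 40 + [False] * 40,
            ([True] * 20 + [False] * 20) * 2,
        )
        assert res.chi2 == pytest.approx(0.0)

    def test_degenerate_table_flagged(self):
        res = epigenome.associate_spreading_downregulation([True, True], [True, False])
        assert not res.reliable
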