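"""Hit parsing, filtering, defragmentation, copy and ORF classification."""

import numpy as np
import pytest

from tedyn import repeatio, synthio
from tedyn.repeatio import ORFModel, TEConsensus, TEHit


def make_hit(**kw):
    base = dict(contig="c1", genome_start=0, genome_end=500, strand="+", family="fam",
                consensus_start=0, consensus_end=500, percent_divergence=5.0, hit_id=0)
    base.update(kw)
    return TEHit(**base)


class TestParseRmOut:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "hits.out"
        p.write_text("100 5.0 0.0 0.0 c1 101 200 (0) + fam Unspecified 1 100 (400) 1\n")
        (hit,) = repeatio.parse_rm_out(p)
        assert (hit.genome_start, hit.genome_end) == (100, 200)
        assert hit.length == 100
        assert (hit.consensus_start, hit.consensus_end) == (0, 100)

    def test_complement_line_normalized(self, tmp_path):
        p = tmp_path / "hits.out"
        p.write_text("100 5.0 0.0 0.0 c1 101 200 (0) C fam Unspecified (400) 100 1 1\n")
        (hit,) = repeatio.parse_rm_out(p)
        assert hit.strand == "-"
        assert hit.consensus_start < hit.consensus_end

    def test_truncated_line_names_line_number(self, tmp_path):
        p = tmp_path / "hits.out"
        p.write_text("ok-header ignored\n" if False else "100 5.0 0.0\n")
        with pytest.raises(ValueError, match="line 1"):
            repeatio.parse_rm_out(p)

    def test_roundtrip_through_writer(self, tmp_path, small_genome):
        *_, hits = small_genome
        path = tmp_path / "rt.out"
        repeatio.write_rm_out(hits, path)
        back = repeatio.parse_rm_out(path)
        key = lambda h: (h.genome_start, h.family)
        for a, b in zip(sorted(hits, key=key), sorted(back, key=key)):
            assert (a.genome_start, a.genome_end, a.strand) == (b.genome_start, b.genome_end, b.strand)
            assert (a.consensus_start, a.consensus_end) == (b.consensus_start, b.consensus_end)


class TestFilterHits:
    def test_identity_and_length_thresholds_are_strict(self):
        removed_low_id = make_hit(percent_divergence=11.0, genome_end=200)   # 89% identity
        at_boundary_len = make_hit(genome_end=50)                            # exactly 50 bp
        kept = make_hit(percent_divergence=5.0, genome_end=200)
        out = repeatio.filter_hits([removed_low_id, at_boundary_len, kept])
        assert out == [kept]

    def test_exactly_90_identity_removed(self):
        out = repeatio.filter_hits([make_hit(percent_divergence=10.0, genome_end=200)])
        assert out == []

    def test_low_complexity_overlap(self):
        hit = make_hit(genome_start=0, genome_end=200)
        lc_small = {"c1": [(0, 20)]}     # 10% overlap: retained
        lc_half = {"c1": [(0, 100)]}     # exactly 50%: removed (strict <)
        assert repeatio.filter_hits([hit], lc_small) == [hit]
        assert repeatio.filter_hits([hit], lc_half) == []

    def test_idempotent(self, small_genome):
        *_, hits = small_genome
        once = repeatio.filter_hits(hits)
        assert repeatio.filter_hits(once) == once

    def test_low_complexity_screen_flags_repeats(self, rng):
        random = "".join(rng.choice(list("ACGT"), size=2000))
        polya = random[:800] + "A" * 300 + random[1100:]
        assert repeatio.low_complexity_intervals(random) == []
        ivs = repeatio.low_complexity_intervals(polya)
        assert any(s <= 900 <= e for s, e in ivs)


class TestDefragment:
    def test_two_fragment_chain(self):
        # consensus ranges 1-500 then 510-900 (1-based), genomic gap 40 bp
        h1 = make_hit(genome_start=1000, genome_end=1500, consensus_start=0,
                      consensus_end=500, hit_id=1)
        h2 = make_hit(genome_start=1540, genome_end=1930, consensus_start=509,
                      consensus_end=900, hit_id=2)
        (copy,) = repeatio.defragment([h1, h2])
        assert copy.copy_length == 890
        assert copy.hit_ids == (1, 2)
        assert (copy.consensus_start, copy.consensus_end) == (0, 900)

    def test_different_families_stay_apart(self):
        h1 = make_hit(hit_id=1)
        h2 = make_hit(family="other", genome_start=510, genome_end=900, hit_id=2)
        assert len(repeatio.defragment([h1, h2])) == 2

    def test_single_hit_identity(self):
        h = make_hit(hit_id=9)
        (copy,) = repeatio.defragment([h])
        assert copy.copy_length == h.length
        assert copy.hit_ids == (9,)

    def test_large_gap_not_chained(self):
        h1 = make_hit(hit_id=1, consensus_end=500)
        h2 = make_hit(genome_start=7000, genome_end=7400, consensus_start=500,
                      consensus_end=900, hit_id=2)
        assert len(repeatio.defragment([h1, h2])) == 2

    def test_every_hit_in_exactly_one_copy(self, small_genome):
        *_, hits = small_genome
        copies = repeatio.defragment(hits)
        seen = [hid for c in copies for hid in c.hit_ids]
        assert sorted(seen) == sorted(h.hit_id for h in hits)


class TestClassifyCopyLength:
    @pytest.fixture
    def consensus(self):
        seq = "ACGT" * 1250  # 5000 bp
        return TEConsensus(family="fam", sequence=seq, status="intact")

    def test_boundary_inclusive_at_90_percent(self, consensus):
        copy = _copy(copy_length=4500)
        assert repeatio.classify_copy_length(copy, consensus) == "full_length"

    def test_just_below_boundary_truncated(self, consensus):
        copy = _copy(copy_length=4499)
        assert repeatio.classify_copy_length(copy, consensus) == "truncated"

    def test_partial_family_always_truncated(self, consensus):
        partial = TEConsensus(family="fam", sequence=consensus.sequence, status="partial")
        copy = _copy(copy_length=5000)
        assert repeatio.classify_copy_length(copy, partial) == "truncated"

    def test_agrees_with_fraction_oracle(self, rng):
        for _ in range(1000):
            clen = int(rng.integers(100, 8000))
            plen = int(rng.integers(50, clen + 1))
            status = rng.choice(["intact", "partial", "remnant"])
            cons = TEConsensus(family="fam", sequence="A" * clen, status=status)
            got = repeatio.classify_copy_length(_copy(copy_length=plen), cons)
            want = "full_length" if (plen / clen >= 0.9 and status == "intact") else "truncated"
            assert got == want


def _copy(copy_length):
    return repeatio.TECopy(
        copy_id="x", family="fam", contig="c1", start=0, end=copy_length, strand="+",
        hit_ids=(0,), copy_length=copy_length, consensus_start=0, consensus_end=copy_length,
    )


class TestOrfIntegrity:
    @pytest.fixture
    def consensus(self, one_consensus):
        return one_consensus

    def test_identical_copy_complete(self, consensus):
        out = repeatio.assess_orf_integrity(consensus.sequence, consensus, 0)
        assert all(a.status == "complete" and a.fraction_of_canonical_orf == 1.0 for a in out)

    def test_premature_stop_disrupts(self, consensus):
        orf = consensus.orfs[0]
        pos = orf.start + 3 * int(0.4 * orf.n_codons)
        seq = consensus.sequence[:pos] + "TAA" + consensus.sequence[pos + 3 :]
        (a,) = repeatio.assess_orf_integrity(seq, consensus, 0)
        assert a.status == "disrupted"
        assert a.fraction_of_canonical_orf < 0.9

    def test_fraction_exactly_090_with_domains_complete(self):
        # ORF of 100 coding codons; copy starts 10 codons in, with an ATG
        # planted at codon 10 -> stretch of exactly 90 codons
        body = "".join(np.random.default_rng(0).choice(
            [c for c in synthio._SENSE_CODONS if c != "ATG"], size=99))
        seq = "ATG" + body + "TAA"
        seq = seq[:30] + "ATG" + seq[33:]
        cons = TEConsensus(family="f", sequence=seq, status="intact",
                           orfs=(ORFModel(0, len(seq), ((36, 60),)),))
        copy = seq[30:]
        (a,) = repeatio.assess_orf_integrity(copy, cons, 30)
        assert a.fraction_of_canonical_orf == pytest.approx(0.90)
        assert a.status == "complete"

    def test_remnant_not_assessed(self, consensus):
        remnant = TEConsensus(family="r", sequence=consensus.sequence, status="remnant",
                              orfs=consensus.orfs)
        out = repeatio.assess_orf_integrity(consensus.sequence, remnant, 0)
        assert all(a.status == "not_assessed" for a in out)

    def test_full_length_copies_orf_complete_without_disruption(self):
        # no planted disruption and no mutation: every intact-family
        # full-length copy must assess as ORF-complete
        params = synthio.SimParams(
            seed=21, n_families=6, copies_per_family=5, genome_length=500_000,
            waves=((0.0, 0.0, 1.0),), truncation_prob_by_wave=(0.5,),
            orf_disruption_prob=0.0, status_weights=(1.0, 0.0, 0.0),
        )
        library = synthio.gen_library(params)
        genome, truth, hits = synthio.build_genome(params, library)
        from tedyn._util import revcomp
        n_full = 0
        for row in truth[truth["full_length"]].itertuples():
            cons = library[row.family]
            seq = genome[row.contig][row.start : row.end]
            if row.strand == "-":
                seq = revcomp(seq)
            out = repeatio.assess_orf_integrity(seq, cons, row.consensus_start)
            assert all(a.status == "complete" for a in out)
            n_full += 1
        assert n_full > 0
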