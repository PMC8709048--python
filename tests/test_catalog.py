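"""Junction enumeration, k-mer construction, intron tiling and ambiguity
screening, each checked against brute-force oracles."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import junctionscout as js
from junctionscout.catalog import (
    CatalogError,
    Junction,
    build_catalog,
    build_intron_tiles,
    build_junction_kmers,
    enumerate_splice_events,
    tile_positions,
)
from junctionscout.model import Exon, GeneModel
from junctionscout.simulate import SimulationConfig, make_gene_model


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(6, 15), (7, 21), (2, 1)])
    def test_pair_counts(self, n, count):
        model = make_gene_model(SimulationConfig(seed=50 + n, n_exons=n), f"G{n}")
        assert len(enumerate_splice_events(model)) == count

    @given(n=st.integers(min_value=2, max_value=12))
    @settings(max_examples=11, deadline=None)
    def test_count_formula(self, n):
        model = make_gene_model(
            SimulationConfig(seed=7000 + n, n_exons=n), f"H{n}"
        )
        events = enumerate_splice_events(model)
        assert len(events) == n * (n - 1) // 2
        assert len(set((j.donor_exon, j.acceptor_exon) for j in events)) == len(events)

    def test_adjacent_flagging(self):
        assert Junction(1, 2).kind == "adjacent"
        assert Junction(2, 4).kind == "skipping"
        assert Junction(2, 4).skipped == (3,)

    def test_donor_must_precede_acceptor(self):
        with pytest.raises(CatalogError):
            Junction(3, 2)


class TestJunctionKmers:
    def test_offset_count_default_params(self, toy4):
        kmers = build_junction_kmers(toy4, Junction(1, 2), k=24, min_flank=8)
        assert len(kmers) == 9  # 24 - 16 + 1

    def test_single_offset_matches_slice_oracle(self, toy4, toy4_raw):
        [kmer] = build_junction_kmers(toy4, Junction(1, 3), k=12, min_flank=6)
        e1, e3 = toy4.exons[0], toy4.exons[2]
        assert kmer.sequence == toy4_raw[e1.end - 6 : e1.end] + toy4_raw[e3.start : e3.start + 6]
        assert kmer.boundary_offset == 6

    def test_kmer_reconstruction_invariant(self, kras):
        model = kras.model
        for entry in kras.catalog.entries:
            if entry.kind != "junction":
                continue
            donor = model.exon_sequence(entry.junction.donor_exon, entry.first_exon_variant
                                        if entry.junction.donor_exon == 1 else 0)
            acceptor = model.exon_sequence(entry.junction.acceptor_exon)
            off = entry.boundary_offset
            assert entry.sequence == donor[len(donor) - off :] + acceptor[: kras.catalog.k - off]

    def test_min_flank_violation(self, toy4):
        with pytest.raises(CatalogError, match="min_flank"):
            build_junction_kmers(toy4, Junction(1, 2), k=12, min_flank=7)

    def test_short_exon_offsets_skipped(self):
        # acceptor exon of 10 nt: offsets needing >10 acceptor bases skipped
        model = GeneModel(
            gene_name="S",
            exons=(Exon(1, 0, 40), Exon(2, 50, 60), Exon(3, 70, 110)),
            locus_sequence="ACGT" * 30,
        )
        kmers = build_junction_kmers(model, Junction(1, 2), k=24, min_flank=8)
        assert all(24 - e.boundary_offset <= 10 for e in kmers)
        assert len(kmers) == 3  # offsets 14, 15, 16


class TestIntronTiles:
    def test_tiling_matches_bruteforce_oracle(self):
        # oracle: every stride-step start plus the right-aligned final tile
        for length, k, stride in [(50, 24, 12), (100, 24, 12), (37, 12, 5)]:
            starts = tile_positions(length, k, stride)
            oracle = sorted(set(list(range(0, length - k + 1, stride)) + [length - k]))
            assert starts == oracle

    def test_intron50_k24_stride12_gives_4_tiles(self, toy4):
        tiles = [t for t in build_intron_tiles(toy4, k=24, stride=12) if t.intron_id == 3]
        assert len(tiles) == 4  # starts 0, 12, 24 and right-aligned 26
        assert [t.tile_index for t in tiles] == [0, 1, 2, 3]

    def test_exact_k_intron_single_tile(self):
        model = GeneModel(
            gene_name="T",
            exons=(Exon(1, 0, 40), Exon(2, 64, 120)),  # intron length 24
            locus_sequence="ACGT" * 40,
        )
        tiles = build_intron_tiles(model, k=24, stride=12)
        assert len(tiles) == 1 and not tiles[0].short

    def test_short_intron_single_short_tile(self):
        model = GeneModel(
            gene_name="T",
            exons=(Exon(1, 0, 40), Exon(2, 50, 120)),  # intron length 10
            locus_sequence="ACGT" * 40,
        )
        [tile] = build_intron_tiles(model, k=24, stride=12)
        assert tile.short and len(tile.sequence) == 10

    def test_tiles_are_locus_substrings(self, kras):
        for t in (e for e in kras.catalog.entries if e.kind == "tile"):
            assert t.sequence in kras.model.locus_sequence


class TestAmbiguityScreen:
    def test_random_fixture_has_no_ambiguity(self, ras_bundles):
        # exhaustive substring-count oracle over locus + catalog
        for bundle in ras_bundles.values():
            locus = bundle.model.locus_sequence
            seqs = [e.sequence for e in bundle.catalog.entries]
            for e in bundle.catalog.entries:
                assert not e.ambiguous
                expected = 1 if e.kind in ("tile", "anchor") else 0
                assert locus.count(e.sequence) == expected
            assert len(set(seqs)) == len(seqs)

    def _collision_model(self):
        # exon 2 and exon 3 share an identical 24-nt prefix
        import numpy as np

        rng = np.random.default_rng(99)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        rand = lambda n: rng.choice(bases, size=n).tobytes().decode()
        shared = rand(24)
        e1, e2, e3 = rand(60), shared + rand(36), shared + rand(36)
        i1, i2 = rand(40), rand(40)
        locus = e1 + i1 + e2 + i2 + e3
        return GeneModel(
            gene_name="COLL",
            exons=(
                Exon(1, 0, 60),
                Exon(2, 100, 160),
                Exon(3, 200, 260),
            ),
            locus_sequence=locus,
        )

    def test_shared_acceptor_prefix_flagged(self):
        model = self._collision_model()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            catalog = build_catalog(model, k=24, min_flank=8)
        flagged = [e for e in catalog.entries if e.ambiguous and e.kind == "junction"]
        # acceptor-side-heavy k-mers of (1,2)/(1,3) and (2,3)... collide
        assert flagged, "expected acceptor-side collisions to be flagged"
        for e in catalog.active_entries:
            # every retained k-mer is globally unique across catalog + locus
            expected = 1 if e.kind in ("tile", "anchor") else 0
            assert model.locus_sequence.count(e.sequence) <= expected or e.kind == "junction"

    def test_kmer_equal_to_intronic_sequence_flagged(self):
        # plant a junction k-mer inside an intron: donor/acceptor flanks copied
        import numpy as np

        rng = np.random.default_rng(123)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        rand = lambda n: rng.choice(bases, size=n).tobytes().decode()
        e1, e2 = rand(60), rand(60)
        junction_kmer = e1[-12:] + e2[:12]  # the offset-12 k-mer of (1,2)
        intron = rand(14) + junction_kmer + rand(14)
        locus = e1 + intron + e2
        model = GeneModel(
            gene_name="PLANT",
            exons=(Exon(1, 0, 60), Exon(2, 60 + len(intron), 120 + len(intron))),
            locus_sequence=locus,
        )
        catalog = build_catalog(model, k=24, min_flank=8)
        hit = [
            e
            for e in catalog.entries
            if e.kind == "junction" and e.sequence == junction_kmer
        ]
        assert hit and all(e.ambiguous for e in hit)

    def test_rebuild_is_deterministic(self, toy4, tmp_path):
        c1 = build_catalog(toy4, k=24, min_flank=8, stride=12)
        js.write_gene_model_json(toy4, tmp_path / "m.json")
        js.write_fasta([(toy4.seqid, toy4.locus_sequence)], tmp_path / "m.fa")
        again = js.load_gene_model(tmp_path / "m.json", tmp_path / "m.fa")
        c2 = build_catalog(again, k=24, min_flank=8, stride=12)
        assert [e.sequence for e in c1.entries] == [e.sequence for e in c2.entries]
        assert [e.ambiguous for e in c1.entries] == [e.ambiguous for e in c2.entries]


class TestSerialization:
    def test_tsv_roundtrip(self, kras, tmp_path):
        path = tmp_path / "catalog.tsv"
        kras.catalog.to_tsv(path)
        again = js.JunctionCatalog.from_tsv(path)
        assert again.k == kras.catalog.k
        assert len(again.entries) == len(kras.catalog.entries)
        for a, b in zip(again.entries, kras.catalog.entries):
            assert a == b
        assert again.amplicon == kras.catalog.amplicon
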