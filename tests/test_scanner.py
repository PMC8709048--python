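"""Read scanning, hit chaining and per-read structure reconstruction.

The scanner is held to two independent oracles: a sliding-window exact
substring search, and (for the bounded-edit mode) a numpy semi-global
edit-distance DP computed from scratch in this file.
"""

import numpy as np
import pytest

import junctionscout as js
from junctionscout.model import TranscriptStructure, reverse_complement
from junctionscout.scanner import (
    ReadEvidence,
    ScanParams,
    chain_hits,
    evidence_to_structure,
    process_read,
    scan_read,
)


def toy_structure(chain, retained=(), fe=0):
    return TranscriptStructure("TOY4", tuple(chain), frozenset(retained), fe)


@pytest.fixture(scope="module")
def toy4_catalog(toy4):
    primers = js.PrimerPair(
        toy4.exon_sequence(1)[:20],
        reverse_complement(toy4.exon_sequence(4)[-20:]),
    )
    return js.build_catalog(toy4, k=24, min_flank=8, stride=12, primers=primers)


def naive_exact_hits(seq, catalog):
    """Sliding-window oracle: every exact occurrence of every active k-mer."""
    hits = set()
    for idx, entry in enumerate(catalog.active_entries):
        k = len(entry.sequence)
        for pos in range(len(seq) - k + 1):
            if seq[pos : pos + k] == entry.sequence:
                hits.add((idx, pos))
    return hits


def semiglobal_min_edits(pattern, text):
    """Independent DP oracle: minimum edit distance of pattern against any
    substring of text (infix alignment), O(|pattern|*|text|) with numpy."""
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    prev = np.zeros(len(t) + 1, dtype=np.int32)  # free start gap in text
    for i in range(1, len(p) + 1):
        cur = np.empty_like(prev)
        cur[0] = i
        sub = prev[:-1] + (t != p[i - 1])
        dele = prev[1:] + 1
        cur[1:] = np.minimum(sub, dele)
        # insertions need a left-to-right pass
        for j in range(1, len(t) + 1):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev.min())


class TestScanRead:
    def test_exact_cdna_read_hits_expected_junctions(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 3, 4]))
        scanned = scan_read(read, toy4_catalog, read_id="r1")
        assert scanned.orientation == "forward"
        entries = toy4_catalog.active_entries
        junctions = {
            (entries[h.entry_index].junction.donor_exon,
             entries[h.entry_index].junction.acceptor_exon)
            for h in scanned.hits
            if entries[h.entry_index].kind == "junction"
        }
        assert junctions == {(1, 3), (3, 4)}
        # all 9 offsets of each junction present, at consecutive positions
        for dj in [(1, 3), (3, 4)]:
            offs = sorted(
                entries[h.entry_index].boundary_offset
                for h in scanned.hits
                if entries[h.entry_index].kind == "junction"
                and (entries[h.entry_index].junction.donor_exon,
                     entries[h.entry_index].junction.acceptor_exon) == dj
            )
            assert offs == list(range(8, 17))

    def test_hits_match_naive_oracle_positions(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 3, 4]))
        scanned = scan_read(read, toy4_catalog, read_id="r1")
        got = {(h.entry_index, h.position) for h in scanned.hits}
        assert got == naive_exact_hits(read, toy4_catalog)

    def test_revcomp_read_same_junctions(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 3, 4]))
        fwd = scan_read(read, toy4_catalog)
        rev = scan_read(reverse_complement(read), toy4_catalog)
        assert rev.orientation == "reverse-complement"
        key = lambda s: sorted((h.entry_index, h.position) for h in s.hits)
        assert key(fwd) == key(rev)

    def test_read_of_ns_has_no_hits(self, toy4_catalog):
        scanned = scan_read("N" * 300, toy4_catalog)
        assert scanned.hits == []

    def test_empty_read_rejected(self, toy4_catalog):
        with pytest.raises(ValueError):
            scan_read("", toy4_catalog)

    def test_oracle_equality_on_seeded_random_reads(self, kras):
        # 1,000 random reads: exact scanner == sliding-window oracle
        rng = np.random.default_rng(42)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        entries = kras.catalog.active_entries
        cdnas = [js.spliced_sequence(kras.model, ts) for ts in kras.planted]
        n_checked = 0
        for i in range(1000):
            if i % 2:
                read = rng.choice(bases, size=300).tobytes().decode()
            else:  # half the corpus: real cDNA fragments, which carry hits
                src = cdnas[i % len(cdnas)]
                start = int(rng.integers(0, max(1, len(src) - 400)))
                read = src[start : start + 400]
            scanned = scan_read(read, kras.catalog, read_id=f"r{i}")
            if scanned.orientation == "forward":
                got = {(h.entry_index, h.position) for h in scanned.hits}
                oracle = naive_exact_hits(read, kras.catalog)
                rc_oracle = naive_exact_hits(reverse_complement(read), kras.catalog)
                if len(oracle) >= len(rc_oracle):
                    assert got == oracle
                    n_checked += 1
        assert n_checked > 400

    def test_approximate_mode_matches_dp_oracle(self, toy4, toy4_catalog):
        # mutated junction regions: edlib presence/absence == numpy DP oracle
        rng = np.random.default_rng(7)
        read0 = js.spliced_sequence(toy4, toy_structure([1, 3, 4]))
        entries = toy4_catalog.active_entries
        for trial in range(15):
            arr = list(read0)
            for pos in rng.integers(0, len(arr), size=6):
                arr[pos] = "ACGT"[rng.integers(0, 4)]
            read = "".join(arr)
            scanned = scan_read(read, toy4_catalog, max_edits=2)
            if scanned.orientation != "forward":
                continue
            got = {h.entry_index for h in scanned.hits}
            for idx, entry in enumerate(entries):
                expected = semiglobal_min_edits(entry.sequence, read) <= 2
                assert (idx in got) == expected, (trial, entry.sequence)


class TestChaining:
    def test_errorfree_skip_read_is_full_length(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 2, 4]))
        ev = process_read("r", read, toy4_catalog, toy4)
        assert ev.junction_chain == ((1, 2), (2, 4))
        assert ev.has_first_anchor and ev.has_last_anchor and not ev.conflict
        assert ev.structure == toy_structure([1, 2, 4])

    def test_chimeric_read_conflicts(self, toy4, toy4_catalog):
        # a fused read carrying both (1,2) and (1,3) junctions
        a = js.spliced_sequence(toy4, toy_structure([1, 2, 3, 4]))
        b = js.spliced_sequence(toy4, toy_structure([1, 3, 4]))
        ev = process_read("chimera", a + b, toy4_catalog, toy4)
        assert ev.conflict
        assert ev.structure is None

    def test_retention_read_detected(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 2, 3, 4], retained=(3,)))
        ev = process_read("r", read, toy4_catalog, toy4)
        assert ev.retained_intron_calls == {3}
        assert not ev.conflict
        assert ev.structure == toy_structure([1, 2, 3, 4], retained=(3,))

    def test_retention_requires_junction_absence(self, toy4, toy4_catalog):
        # read with both the spliced (3,4) junction AND intron-3 tiles:
        # contradictory -> conflict
        spliced = js.spliced_sequence(toy4, toy_structure([1, 2, 3, 4]))
        retained = js.spliced_sequence(toy4, toy_structure([1, 2, 3, 4], retained=(3,)))
        ev = process_read("r", spliced + retained, toy4_catalog, toy4)
        assert ev.conflict

    def test_truncated_read_not_full_length(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 2, 3, 4]))[40:]
        ev = process_read("r", read, toy4_catalog, toy4)
        assert not ev.has_first_anchor
        assert ev.structure is None


class TestStructureReconstruction:
    def test_interior_filled_only_with_adjacent_evidence(self, kras):
        # junction (2,4) + adjacent (1,2),(4,5),(5,6) -> chain [1,2,4,5,6]
        ts = TranscriptStructure("KRAS", (1, 2, 4, 5, 6))
        read = js.spliced_sequence(kras.model, ts)
        ev = process_read("r", read, kras.catalog, kras.model)
        assert ev.structure is not None
        assert ev.structure.exon_chain == (1, 2, 4, 5, 6)

    def test_annotated_chain_from_all_adjacent_junctions(self, toy4, toy4_catalog):
        read = js.spliced_sequence(toy4, toy_structure([1, 2, 3, 4]))
        ev = process_read("r", read, toy4_catalog, toy4)
        assert ev.structure.exon_chain == (1, 2, 3, 4)

    def test_anchors_without_junctions_unresolvable(self, toy4):
        ev = ReadEvidence(
            read_id="r",
            orientation="forward",
            junction_chain=(),
            first_exon_variant=0,
            retained_intron_calls=frozenset(),
            has_first_anchor=True,
            has_last_anchor=True,
            conflict=False,
        )
        assert evidence_to_structure(ev, toy4) is None

    def test_first_exon_variant_assigned_from_donor_kmers(self, kras):
        for fe in (0, 1):
            ts = TranscriptStructure("KRAS", (1, 2, 3, 4, 5, 6), first_exon_variant=fe)
            read = js.spliced_sequence(kras.model, ts)
            ev = process_read("r", read, kras.catalog, kras.model)
            assert ev.first_exon_variant == fe
            assert ev.structure.first_exon_variant == fe


class TestInvariantProperties:
    def test_orientation_invariance_on_simulated_reads(self, kras):
        from conftest import simulate_bundle

        reads, _ = simulate_bundle(kras, seed=11, coverage=2)
        params = ScanParams()
        n = 0
        for sample, lst in reads.items():
            for rid, seq in lst[:40]:
                ev1 = process_read(rid, seq, kras.catalog, kras.model, params)
                ev2 = process_read(
                    rid, reverse_complement(seq), kras.catalog, kras.model, params
                )
                assert ev1.structure == ev2.structure
                n += 1
        assert n > 0

    def test_substitutions_never_create_structures(self, kras):
        # monotone robustness: each error-free read resolves to its planted
        # structure or (with added errors) to None -- never to a different one
        rng = np.random.default_rng(5)
        for ts in kras.planted[:4]:
            clean = js.spliced_sequence(kras.model, ts)
            truth = process_read("r", clean, kras.catalog, kras.model).structure
            assert truth is not None and truth.key == ts.key
            for trial in range(5):
                arr = list(clean)
                for pos in rng.integers(0, len(arr), size=30):
                    arr[pos] = "ACGT"[rng.integers(0, 4)]
                ev = process_read("r", "".join(arr), kras.catalog, kras.model,
                                  ScanParams(max_edits=0))
                assert ev.structure is None or ev.structure.key == ts.key
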