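"""Detect catalog k-mers in long reads and chain them into read evidence.

Matching is exact (substring) at ``max_edits=0`` and bounded-edit-distance
(edlib, infix mode) otherwise. Nanopore reads carry ~5-7% errors, so the
default allows 2 edits per 24-mer; multiple boundary offsets per junction
then give several nearly independent chances to witness each splicing event
in a read.

A read's junctions must form a single consistent path (collinear along the
read, pairwise chainable); reads carrying contradictory junction evidence —
e.g. PCR chimeras hitting both (1,2) and (1,3) — are flagged ``conflict``
and never contribute to calling. Full-length status requires both
primer-derived anchors.
"""

from __future__ import annotations

import gzip
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .catalog import CatalogEntry, Junction, JunctionCatalog
from .model import GeneModel, TranscriptStructure, reverse_complement

DEFAULT_MAX_EDITS = 2
DEFAULT_MIN_OFFSETS = 2
DEFAULT_RETENTION_FRAC = 0.8


@dataclass(frozen=True)
class ScanParams:
    max_edits: int = DEFAULT_MAX_EDITS
    min_offsets: int = DEFAULT_MIN_OFFSETS
    retention_frac: float = DEFAULT_RETENTION_FRAC

    def __post_init__(self):
        if self.max_edits < 0:
            raise ValueError("max_edits must be >= 0")
        if self.min_offsets < 1:
            raise ValueError("min_offsets must be >= 1")
        if not 0 < self.retention_frac <= 1:
            raise ValueError("retention_frac must be in (0, 1]")


@dataclass(frozen=True)
class ReadHit:
    """One k-mer occurrence in a read (position of the match start)."""

    entry_index: int
    position: int
    edits: int = 0


@dataclass
class ScannedRead:
    read_id: str
    orientation: str  # {forward, reverse-complement}
    hits: List[ReadHit]
    read_length: int


@dataclass
class ReadEvidence:
    """Per-read junction chain, retention calls and anchoring status."""

    read_id: str
    orientation: str
    junction_chain: Tuple[Tuple[int, int], ...]
    first_exon_variant: int
    retained_intron_calls: frozenset
    has_first_anchor: bool
    has_last_anchor: bool
    conflict: bool
    sample: str = ""
    gene_name: str = ""
    structure: Optional[TranscriptStructure] = None

    @property
    def full_length(self) -> bool:
        return self.has_first_anchor and self.has_last_anchor and not self.conflict


# ---------------------------------------------------------------------------
# hit detection
# ---------------------------------------------------------------------------


def _exact_hits(seq: str, entries: Sequence[CatalogEntry]) -> List[ReadHit]:
    hits = []
    for idx, entry in enumerate(entries):
        start = seq.find(entry.sequence)
        while start >= 0:
            hits.append(ReadHit(idx, start, 0))
            start = seq.find(entry.sequence, start + 1)
    return hits


def _approx_hits(
    seq: str,
    entries: Sequence[CatalogEntry],
    max_edits: int,
    skip: frozenset,
) -> List[ReadHit]:
    hits = []
    for idx, entry in enumerate(entries):
        if idx in skip:
            continue
        res = edlib.align(entry.sequence, seq, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            continue
        for start, _end in res["locations"]:
            hits.append(ReadHit(idx, start or 0, res["editDistance"]))
    return hits


def scan_read(
    read: str,
    catalog: JunctionCatalog,
    max_edits: int = 0,
    read_id: str = "",
) -> ScannedRead:
    """All occurrences of unambiguous catalog k-mers in the read.

    Both the read and its reverse complement are scanned; the orientation
    with more hits wins (ties -> forward) and only that orientation's hits
    are returned, with positions on the oriented read.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    entries = catalog.active_entries
    fwd = _exact_hits(read, entries)
    rc_seq = reverse_complement(read)
    rev = _exact_hits(rc_seq, entries)
    if max_edits > 0:
        if len(fwd) == len(rev):  # undecided by exact hits: extend both
            fwd += _approx_hits(read, entries, max_edits,
                                frozenset(h.entry_index for h in fwd))
            rev += _approx_hits(rc_seq, entries, max_edits,
                                frozenset(h.entry_index for h in rev))
        elif len(fwd) > len(rev):
            fwd += _approx_hits(read, entries, max_edits,
                                frozenset(h.entry_index for h in fwd))
        else:
            rev += _approx_hits(rc_seq, entries, max_edits,
                                frozenset(h.entry_index for h in rev))
    if len(fwd) >= len(rev):
        return ScannedRead(read_id, "forward", fwd, len(read))
    return ScannedRead(read_id, "reverse-complement", rev, len(read))


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _compatible(pairs: Sequence[Tuple[int, int]]) -> bool:
    """Adjacency assertions are chainable iff no assertion endpoint falls
    strictly inside another's (donor, acceptor) skipped interval and no exon
    has two different partners on the same side."""
    donors: Dict[int, int] = {}
    acceptors: Dict[int, int] = {}
    for d, a in pairs:
        if donors.setdefault(d, a) != a or acceptors.setdefault(a, d) != d:
            return False
    endpoints = {x for p in pairs for x in p}
    for d, a in pairs:
        for x in endpoints:
            if d < x < a:
                return False
    return True


def chain_hits(
    scanned: ScannedRead,
    catalog: JunctionCatalog,
    params: ScanParams = ScanParams(),
) -> ReadEvidence:
    """Aggregate one read's hits into junction calls, retention calls and
    anchor flags, marking contradictory reads as conflicts."""
    # group junction hits by (junction, exon-1 variant)
    by_junction: Dict[Tuple[Junction, int], Dict[int, int]] = {}
    tile_hits: Dict[int, set] = {}
    has_first = has_last = False
    entries = catalog.active_entries
    for hit in scanned.hits:
        e = entries[hit.entry_index]
        if e.kind == "junction":
            offs = by_junction.setdefault((e.junction, e.first_exon_variant), {})
            prev = offs.get(e.boundary_offset)
            if prev is None or hit.position < prev:
                offs[e.boundary_offset] = hit.position
        elif e.kind == "tile":
            tile_hits.setdefault(e.intron_id, set()).add(e.tile_index)
        elif e.kind == "anchor":
            if e.anchor_side == "first":
                has_first = True
            else:
                has_last = True

    conflict = False
    kept: List[Tuple[Junction, int, float]] = []  # (junction, fe, position)
    for (junction, fe), offs in by_junction.items():
        available = catalog.junction_kmer_count(junction, fe)
        required = min(params.min_offsets, max(available, 1))
        if len(offs) >= required:
            kept.append((junction, fe, statistics.median(offs.values())))

    # a junction witnessed under two exon-1 donor variants is contradictory
    seen_j: Dict[Tuple[int, int], int] = {}
    for junction, fe, _pos in kept:
        key = (junction.donor_exon, junction.acceptor_exon)
        if seen_j.setdefault(key, fe) != fe:
            conflict = True
    fe_variants = {fe for junction, fe, _ in kept if junction.donor_exon == 1}
    if len(fe_variants) > 1:
        conflict = True
    first_exon_variant = fe_variants.pop() if len(fe_variants) == 1 else 0

    # intron retention: enough tiles hit AND the spliced junction absent
    retained = set()
    kept_pairs = {(j.donor_exon, j.acceptor_exon) for j, _fe, _p in kept}
    for intron_id, idxs in tile_hits.items():
        n_active = catalog.intron_tile_count(intron_id)
        if n_active and len(idxs) / n_active >= params.retention_frac:
            if (intron_id, intron_id + 1) in kept_pairs:
                conflict = True  # retention and splicing of the same intron
            else:
                retained.add(intron_id)

    # collinearity: junction order along the read must follow exon order
    ordered = sorted(kept, key=lambda t: (t[0].donor_exon, t[0].acceptor_exon))
    positions = [pos for _j, _fe, pos in ordered]
    if any(b < a - catalog.k for a, b in zip(positions, positions[1:])):
        conflict = True

    assertions = sorted(kept_pairs | {(i, i + 1) for i in retained})
    if not _compatible(assertions):
        conflict = True

    chain = tuple(
        sorted((j.donor_exon, j.acceptor_exon) for j, _fe, _p in kept)
    )
    return ReadEvidence(
        read_id=scanned.read_id,
        orientation=scanned.orientation,
        junction_chain=chain,
        first_exon_variant=first_exon_variant,
        retained_intron_calls=frozenset(retained),
        has_first_anchor=has_first,
        has_last_anchor=has_last,
        conflict=conflict,
        gene_name=catalog.gene_name,
    )


def evidence_to_structure(
    ev: ReadEvidence, model: GeneModel
) -> Optional[TranscriptStructure]:
    """Reconstruct the transcript structure asserted by a full-length read.

    A junction (i, j) asserts i and j adjacent in the mature mRNA (exons
    between them skipped); a retention call asserts i and i+1 adjacent with
    the intron kept. The chain is walked from exon 1 to the last exon; any
    gap the evidence cannot bridge makes the read unresolvable (never invent
    structure).
    """
    if not ev.full_length:
        return None
    nxt: Dict[int, Tuple[int, bool]] = {}
    for d, a in ev.junction_chain:
        if d in nxt:
            return None
        nxt[d] = (a, False)
    for i in ev.retained_intron_calls:
        if i in nxt:
            return None
        nxt[i] = (i + 1, True)
    chain = [1]
    retained = set()
    cur = 1
    while cur != model.n_exons:
        if cur not in nxt:
            return None
        acceptor, is_retained = nxt.pop(cur)
        if is_retained:
            retained.add(cur)
        chain.append(acceptor)
        cur = acceptor
    if nxt:  # leftover assertions outside the walked path
        return None
    return TranscriptStructure(
        gene_name=model.gene_name,
        exon_chain=tuple(chain),
        retained_introns=frozenset(retained),
        first_exon_variant=ev.first_exon_variant,
    )


# ---------------------------------------------------------------------------
# FASTQ-level driver
# ---------------------------------------------------------------------------


def process_read(
    read_id: str,
    seq: str,
    catalog: JunctionCatalog,
    model: GeneModel,
    params: ScanParams = ScanParams(),
    sample: str = "",
) -> ReadEvidence:
    scanned = scan_read(seq, catalog, max_edits=params.max_edits, read_id=read_id)
    ev = chain_hits(scanned, catalog, params)
    ev.sample = sample
    ev.structure = evidence_to_structure(ev, model)
    return ev


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def scan_fastq(
    fastq_by_sample: Dict[str, "str | Path"],
    catalog: JunctionCatalog,
    model: GeneModel,
    params: ScanParams = ScanParams(),
) -> List[ReadEvidence]:
    """Scan one FASTQ (optionally gzipped) per sample."""
    evidence = []
    for sample, path in fastq_by_sample.items():
        with _open_maybe_gzip(path) as fh:
            for read_id, seq, _qual in FastqGeneralIterator(fh):
                evidence.append(
                    process_read(read_id.split()[0], seq, catalog, model,
                                 params, sample=sample)
                )
    return evidence


def evidence_to_dataframe(evidence: Sequence[ReadEvidence]) -> pd.DataFrame:
    rows = []
    for ev in evidence:
        rows.append(
            {
                "read_id": ev.read_id,
                "sample": ev.sample,
                "gene": ev.gene_name,
                "orientation": ev.orientation,
                "junction_chain": ";".join(f"{d}-{a}" for d, a in ev.junction_chain),
                "retained_introns": ",".join(map(str, sorted(ev.retained_intron_calls))),
                "first_exon_variant": ev.first_exon_variant,
                "has_first_anchor": ev.has_first_anchor,
                "has_last_anchor": ev.has_last_anchor,
                "conflict": ev.conflict,
                "full_length": ev.full_length,
                "resolved": ev.structure is not None,
                "structure": ""
                if ev.structure is None
                else _structure_token(ev.structure),
            }
        )
    return pd.DataFrame(rows)


def _structure_token(ts: TranscriptStructure) -> str:
    return "chain:{};ir:{};fe:{}".format(
        ",".join(map(str, ts.exon_chain)),
        ",".join(map(str, sorted(ts.retained_introns))),
        ts.first_exon_variant,
    )


def _parse_structure_token(token: str, gene_name: str) -> TranscriptStructure:
    fields = dict(part.split(":", 1) for part in token.split(";"))
    return TranscriptStructure(
        gene_name=gene_name,
        exon_chain=tuple(int(x) for x in fields["chain"].split(",") if x),
        retained_introns=frozenset(int(x) for x in fields["ir"].split(",") if x),
        first_exon_variant=int(fields["fe"]),
    )


def evidence_from_dataframe(df: pd.DataFrame) -> List[ReadEvidence]:
    """Inverse of :func:`evidence_to_dataframe` (evidence TSV round trip)."""
    out = []
    for _, r in df.iterrows():
        chain = tuple(
            tuple(int(x) for x in pair.split("-"))
            for pair in str(r["junction_chain"]).split(";")
            if pair and pair != "nan"
        )
        retained = frozenset(
            int(x) for x in str(r["retained_introns"]).split(",")
            if x and x != "nan"
        )
        ev = ReadEvidence(
            read_id=str(r["read_id"]),
            orientation=r["orientation"],
            junction_chain=chain,
            first_exon_variant=int(r["first_exon_variant"]),
            retained_intron_calls=retained,
            has_first_anchor=bool(r["has_first_anchor"]),
            has_last_anchor=bool(r["has_last_anchor"]),
            conflict=bool(r["conflict"]),
            sample=str(r["sample"]),
            gene_name=str(r["gene"]),
        )
        token = str(r.get("structure", ""))
        if r.get("resolved", False) and token and token != "nan":
            ev.structure = _parse_structure_token(token, ev.gene_name)
        out.append(ev)
    return out


def read_evidence_tsv(path) -> List[ReadEvidence]:
    return evidence_from_dataframe(pd.read_csv(path, sep="\t", keep_default_na=False))
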