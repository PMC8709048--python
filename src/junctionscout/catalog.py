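"""Enumeration of splicing events and the k-mer detection dictionary.

Every ordered exon pair (i, j), i < j, of the target gene is a potential
splicing event; each is materialized as a set of boundary-spanning k-mers
(one per donor-side offset between ``min_flank`` and ``k - min_flank``).
Introns are tiled with fixed-stride k-mers so intron retention (and, more
generally, unexpected intronic sequence) is detectable with the same exact/
bounded-edit matching machinery. Amplicon anchors (from the primer pair) are
tiled the same way and mark full-length reads.

Junctions whose donor is exon 1 are emitted once per exon-1 donor variant,
because an alternative 5' splice site of exon 1 changes the donor-side
sequence of every junction leaving that exon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import Amplicon, GeneModel, PrimerPair, define_amplicon

DEFAULT_K = 24
DEFAULT_MIN_FLANK = 8
DEFAULT_STRIDE = 12


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class Junction:
    donor_exon: int
    acceptor_exon: int

    def __post_init__(self):
        if not self.donor_exon < self.acceptor_exon:
            raise CatalogError(
                f"junction donor must precede acceptor, got "
                f"({self.donor_exon}, {self.acceptor_exon})"
            )

    @property
    def kind(self) -> str:
        return "adjacent" if self.acceptor_exon == self.donor_exon + 1 else "skipping"

    @property
    def skipped(self) -> Tuple[int, ...]:
        return tuple(range(self.donor_exon + 1, self.acceptor_exon))


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog k-mer: a junction k-mer, an intron tile or an anchor tile."""

    sequence: str
    kind: str  # {junction, tile, anchor}
    junction: Optional[Junction] = None
    first_exon_variant: int = 0
    boundary_offset: Optional[int] = None  # donor-exon bases in the k-mer
    intron_id: Optional[int] = None
    tile_index: Optional[int] = None
    anchor_side: Optional[str] = None  # {first, last}
    short: bool = False
    ambiguous: bool = False


def enumerate_splice_events(model: GeneModel) -> List[Junction]:
    """All ordered exon pairs (i, j) with i < j: n(n-1)/2 junctions."""
    n = model.n_exons
    return [Junction(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]


def build_junction_kmers(
    model: GeneModel,
    junction: Junction,
    k: int = DEFAULT_K,
    min_flank: int = DEFAULT_MIN_FLANK,
    first_exon_variant: int = 0,
) -> List[CatalogEntry]:
    """One k-mer per boundary offset in [min_flank, k - min_flank].

    Offsets whose donor suffix or acceptor prefix would run off the exon are
    skipped; a junction with no realizable offset is an error.
    """
    if min_flank < 1 or 2 * min_flank > k:
        raise CatalogError(
            f"need 1 <= min_flank and 2*min_flank <= k, got k={k}, m={min_flank}"
        )
    donor = model.exon_sequence(junction.donor_exon, first_exon_variant)
    acceptor = model.exon_sequence(junction.acceptor_exon)
    out = []
    for off in range(min_flank, k - min_flank + 1):
        if off > len(donor) or (k - off) > len(acceptor):
            continue
        seq = donor[len(donor) - off :] + acceptor[: k - off]
        out.append(
            CatalogEntry(
                sequence=seq,
                kind="junction",
                junction=junction,
                first_exon_variant=first_exon_variant,
                boundary_offset=off,
            )
        )
    if not out:
        raise CatalogError(
            f"junction ({junction.donor_exon}, {junction.acceptor_exon}): "
            f"exons too short for any offset at k={k}, min_flank={min_flank}"
        )
    return out


def tile_positions(length: int, k: int, stride: int) -> List[int]:
    """Start positions of fixed-stride k-tiles plus a final right-aligned
    tile (brute-force-checkable tiling rule)."""
    if stride < 1:
        raise CatalogError("stride must be >= 1")
    last = length - k
    pos = list(range(0, last + 1, stride))
    if pos[-1] != last:
        pos.append(last)
    return pos


def build_intron_tiles(
    model: GeneModel,
    k: int = DEFAULT_K,
    stride: int = DEFAULT_STRIDE,
) -> List[CatalogEntry]:
    """Tile every intron; introns shorter than k yield one short tile."""
    out = []
    for intron_id in range(1, model.n_introns + 1):
        seq = model.intron_sequence(intron_id)
        if len(seq) < k:
            out.append(
                CatalogEntry(
                    sequence=seq,
                    kind="tile",
                    intron_id=intron_id,
                    tile_index=0,
                    short=True,
                )
            )
            continue
        for idx, p in enumerate(tile_positions(len(seq), k, stride)):
            out.append(
                CatalogEntry(
                    sequence=seq[p : p + k],
                    kind="tile",
                    intron_id=intron_id,
                    tile_index=idx,
                )
            )
    return out


def _anchor_tiles(amplicon: Amplicon, k: int, stride: int) -> List[CatalogEntry]:
    out = []
    for side, seq in (("first", amplicon.first_anchor), ("last", amplicon.last_anchor)):
        if len(seq) < k:
            out.append(
                CatalogEntry(
                    sequence=seq, kind="anchor", anchor_side=side, tile_index=0,
                    short=True,
                )
            )
            continue
        for idx, p in enumerate(tile_positions(len(seq), k, stride)):
            out.append(
                CatalogEntry(
                    sequence=seq[p : p + k],
                    kind="anchor",
                    anchor_side=side,
                    tile_index=idx,
                )
            )
    return out


@dataclass
class JunctionCatalog:
    """The detection dictionary for one gene."""

    gene_name: str
    k: int
    min_flank: int
    stride: int
    entries: List[CatalogEntry]
    amplicon: Optional[Amplicon] = None

    # -- views --------------------------------------------------------------

    @property
    def active_entries(self) -> List[CatalogEntry]:
        return [e for e in self.entries if not e.ambiguous]

    @property
    def junctions(self) -> List[Junction]:
        seen = {}
        for e in self.entries:
            if e.kind == "junction":
                seen.setdefault((e.junction.donor_exon, e.junction.acceptor_exon), e.junction)
        return [seen[key] for key in sorted(seen)]

    def junction_kmer_count(self, junction: Junction, first_exon_variant: int = 0) -> int:
        return sum(
            1
            for e in self.active_entries
            if e.kind == "junction"
            and e.junction == junction
            and e.first_exon_variant == first_exon_variant
        )

    def intron_tile_count(self, intron_id: int) -> int:
        return sum(
            1
            for e in self.active_entries
            if e.kind == "tile" and e.intron_id == intron_id
        )

    # -- serialization -------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "kmer": e.sequence,
                    "type": e.kind,
                    "donor_exon": e.junction.donor_exon if e.junction else "",
                    "acceptor_exon": e.junction.acceptor_exon if e.junction else "",
                    "first_exon_variant": e.first_exon_variant,
                    "boundary_offset": "" if e.boundary_offset is None else e.boundary_offset,
                    "intron_id": "" if e.intron_id is None else e.intron_id,
                    "tile_index": "" if e.tile_index is None else e.tile_index,
                    "anchor_side": e.anchor_side or "",
                    "short": int(e.short),
                    "ambiguous": int(e.ambiguous),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        sidecar = {
            "gene": self.gene_name,
            "k": self.k,
            "min_flank": self.min_flank,
            "stride": self.stride,
            "n_entries": len(self.entries),
            "n_ambiguous": sum(e.ambiguous for e in self.entries),
            "amplicon": None
            if self.amplicon is None
            else {
                "first_anchor": self.amplicon.first_anchor,
                "last_anchor": self.amplicon.last_anchor,
                "forward_start": self.amplicon.forward_start,
                "reverse_end": self.amplicon.reverse_end,
            },
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "JunctionCatalog":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        meta = json.loads(Path(str(path) + ".json").read_text())
        entries = []
        for _, r in df.iterrows():
            junction = None
            if r["type"] == "junction":
                junction = Junction(int(r["donor_exon"]), int(r["acceptor_exon"]))
            entries.append(
                CatalogEntry(
                    sequence=r["kmer"],
                    kind=r["type"],
                    junction=junction,
                    first_exon_variant=int(r["first_exon_variant"]),
                    boundary_offset=int(r["boundary_offset"]) if r["boundary_offset"] != "" else None,
                    intron_id=int(r["intron_id"]) if r["intron_id"] != "" else None,
                    tile_index=int(r["tile_index"]) if r["tile_index"] != "" else None,
                    anchor_side=r["anchor_side"] or None,
                    short=bool(int(r["short"])),
                    ambiguous=bool(int(r["ambiguous"])),
                )
            )
        amp = None
        if meta.get("amplicon"):
            a = meta["amplicon"]
            amp = Amplicon(
                first_anchor=a["first_anchor"],
                last_anchor=a["last_anchor"],
                forward_start=a["forward_start"],
                reverse_end=a["reverse_end"],
            )
        return cls(
            gene_name=meta["gene"],
            k=meta["k"],
            min_flank=meta["min_flank"],
            stride=meta["stride"],
            entries=entries,
            amplicon=amp,
        )


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count."""
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def screen_ambiguity(catalog: JunctionCatalog, model: GeneModel) -> JunctionCatalog:
    """Flag k-mers that cannot be uniquely attributed.

    A k-mer is ambiguous when it occurs more often than its one expected
    origin across (a) the locus sequence and (b) the catalog itself:
    junction k-mers span boundaries absent from the genome, so any locus
    occurrence is a collision; intron tiles and anchor tiles are locus
    substrings, so a *second* locus occurrence is a collision. A sequence
    shared by two catalog entries, or equal to the reverse complement of
    another entry or of a locus occurrence, is flagged on both entries.
    Ambiguous k-mers are excluded from scanning rather than down-weighted.
    """
    from .model import reverse_complement

    locus = model.locus_sequence
    seq_count: Dict[str, int] = {}
    for e in catalog.entries:
        seq_count[e.sequence] = seq_count.get(e.sequence, 0) + 1

    flagged = []
    for e in catalog.entries:
        expected_locus = 1 if e.kind in ("tile", "anchor") else 0
        in_locus = _count_occurrences(locus, e.sequence)
        rc = reverse_complement(e.sequence)
        rc_hits = _count_occurrences(locus, rc) + (rc in seq_count and rc != e.sequence)
        ambiguous = (
            seq_count[e.sequence] > 1
            or in_locus > expected_locus
            or rc_hits > 0
        )
        if ambiguous is not e.ambiguous:
            from dataclasses import replace

            e = replace(e, ambiguous=ambiguous)
        flagged.append(e)

    screened = JunctionCatalog(
        gene_name=catalog.gene_name,
        k=catalog.k,
        min_flank=catalog.min_flank,
        stride=catalog.stride,
        entries=flagged,
        amplicon=catalog.amplicon,
    )
    for junction in screened.junctions:
        n_active = sum(
            1
            for e in screened.active_entries
            if e.kind == "junction" and e.junction == junction
        )
        if n_active == 0:
            warnings.warn(
                f"{catalog.gene_name}: junction "
                f"({junction.donor_exon}, {junction.acceptor_exon}) lost all "
                "k-mers to ambiguity and is undetectable"
            )
    return screened


def build_catalog(
    model: GeneModel,
    k: int = DEFAULT_K,
    min_flank: int = DEFAULT_MIN_FLANK,
    stride: int = DEFAULT_STRIDE,
    primers: Optional[PrimerPair] = None,
    screen: bool = True,
) -> JunctionCatalog:
    """Build (and by default ambiguity-screen) the full catalog for a gene."""
    entries: List[CatalogEntry] = []
    for junction in enumerate_splice_events(model):
        variants = (
            range(model.n_first_exon_variants) if junction.donor_exon == 1 else (0,)
        )
        for fe in variants:
            entries.extend(
                build_junction_kmers(model, junction, k=k, min_flank=min_flank,
                                     first_exon_variant=fe)
            )
    entries.extend(build_intron_tiles(model, k=k, stride=stride))
    amplicon = None
    if primers is not None:
        amplicon = define_amplicon(model, primers)
        entries.extend(_anchor_tiles(amplicon, k=k, stride=stride))
    catalog = JunctionCatalog(
        gene_name=model.gene_name,
        k=k,
        min_flank=min_flank,
        stride=stride,
        entries=entries,
        amplicon=amplicon,
    )
    return screen_ambiguity(catalog, model) if screen else catalog
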