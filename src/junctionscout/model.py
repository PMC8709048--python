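"""Target-gene models, transcript structures and amplicon anchors.

A gene model is a single multi-exon locus: an ordered list of exons on one
strand of a locus sequence. Exon ranks (``exon_id``, 1-based) follow
transcription order, so for a '-' gene exon 1 has the highest genomic
coordinates. All internal coordinates are 0-based half-open on the forward
genomic strand; GFF3 I/O converts to/from the 1-based inclusive convention.

Alternative 5' splice sites (alternative donors) of exon 1 — e.g. the
179-nt vs 166-nt first-exon forms of KRAS — are modeled as 3'-truncation
offsets of exon 1 (``alt_first_exon_ends``), selected per transcript via
``first_exon_variant`` (0 = full exon 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = re.compile(r"^[ACGT]+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ModelValidationError(ValueError):
    """A gene model, transcript structure or primer violates an invariant."""


@dataclass(frozen=True)
class Exon:
    """One exon: genomic interval (0-based half-open, forward strand)."""

    exon_id: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"exon {self.exon_id}: unknown strand {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ModelValidationError(
                f"exon {self.exon_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A validated single-gene model plus its locus sequence.

    ``exons`` are in transcription order; ``alt_first_exon_ends`` lists
    alternative-donor truncations of exon 1 in nucleotides (each > 0 and
    smaller than exon 1); ``annotated_start`` optionally places the
    annotated translation-initiation codon as (exon_id, offset-within-exon,
    in mRNA orientation).
    """

    gene_name: str
    exons: Tuple[Exon, ...]
    locus_sequence: str
    alt_first_exon_ends: Tuple[int, ...] = ()
    annotated_start: Optional[Tuple[int, int]] = None
    seqid: str = "locus"

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(
            self, "alt_first_exon_ends", tuple(self.alt_first_exon_ends)
        )
        object.__setattr__(self, "locus_sequence", self.locus_sequence.upper())
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        if len(self.exons) < 2:
            raise ModelValidationError(
                f"{self.gene_name}: a gene model needs >= 2 exons"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise ModelValidationError(f"{self.gene_name}: mixed exon strands")
        ids = [e.exon_id for e in self.exons]
        if ids != list(range(1, len(self.exons) + 1)):
            raise ModelValidationError(
                f"{self.gene_name}: exon ids must be 1..n in transcription "
                f"order, got {ids}"
            )
        L = len(self.locus_sequence)
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end >= b.start:  # >= : introns must have length >= 1
                raise ModelValidationError(
                    f"{self.gene_name}: exons {a.exon_id} and {b.exon_id} "
                    "overlap or leave no intron"
                )
        for e in self.exons:
            if e.end > L:
                raise ModelValidationError(
                    f"{self.gene_name}: exon {e.exon_id} out of locus bounds "
                    f"(end {e.end} > {L})"
                )
        # transcription order must match strand
        starts = [e.start for e in self.exons]
        if self.strand == "+" and starts != sorted(starts):
            raise ModelValidationError(
                f"{self.gene_name}: '+' gene exons not in ascending order"
            )
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise ModelValidationError(
                f"{self.gene_name}: '-' gene exons not in descending order"
            )
        e1len = self.exons[0].length
        for off in self.alt_first_exon_ends:
            if not (0 < off < e1len):
                raise ModelValidationError(
                    f"{self.gene_name}: alternative exon-1 boundary offset "
                    f"{off} outside exon 1 (length {e1len})"
                )
        if self.annotated_start is not None:
            ex, off = self.annotated_start
            if not 1 <= ex <= len(self.exons):
                raise ModelValidationError(
                    f"{self.gene_name}: annotated start in unknown exon {ex}"
                )
            if not 0 <= off <= self.exons[ex - 1].length - 3:
                raise ModelValidationError(
                    f"{self.gene_name}: annotated start offset {off} outside "
                    f"exon {ex}"
                )

    # -- basic accessors --------------------------------------------------

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def n_first_exon_variants(self) -> int:
        return 1 + len(self.alt_first_exon_ends)

    def first_exon_truncation(self, variant: int) -> int:
        """nt removed from exon 1's 3' end for the given donor variant."""
        if variant == 0:
            return 0
        try:
            return self.alt_first_exon_ends[variant - 1]
        except IndexError:
            raise ModelValidationError(
                f"{self.gene_name}: no first-exon variant {variant}"
            ) from None

    def _oriented(self, start: int, end: int) -> str:
        seq = self.locus_sequence[start:end]
        return reverse_complement(seq) if self.strand == "-" else seq

    def exon_sequence(self, exon_id: int, first_exon_variant: int = 0) -> str:
        """Exon sequence in mRNA (transcription) orientation."""
        e = self.exons[exon_id - 1]
        seq = self._oriented(e.start, e.end)
        if exon_id == 1:
            trunc = self.first_exon_truncation(first_exon_variant)
            if trunc:
                seq = seq[: len(seq) - trunc]
        return seq

    def intron_sequence(self, intron_id: int) -> str:
        """Intron between exon ``intron_id`` and its acceptor, mRNA-oriented."""
        if not 1 <= intron_id <= self.n_introns:
            raise ModelValidationError(
                f"{self.gene_name}: no intron {intron_id}"
            )
        d = self.exons[intron_id - 1]
        a = self.exons[intron_id]
        if self.strand == "+":
            return self._oriented(d.end, a.start)
        return self._oriented(a.end, d.start)

    def intron_length(self, intron_id: int) -> int:
        d = self.exons[intron_id - 1]
        a = self.exons[intron_id]
        return (a.start - d.end) if self.strand == "+" else (d.start - a.end)


@dataclass(frozen=True)
class TranscriptStructure:
    """An exon chain + intron retentions + exon-1 donor variant.

    Full-length convention: the chain starts at exon 1 and ends at the last
    exon of the model (amplicon reads span first to last exon). A retained
    intron is identified by its donor exon id; its donor must be immediately
    followed by its acceptor in the chain.
    """

    gene_name: str
    exon_chain: Tuple[int, ...]
    retained_introns: frozenset = frozenset()
    first_exon_variant: int = 0
    name: str = ""
    status: str = "novel"  # {annotated, novel}

    def __post_init__(self):
        object.__setattr__(self, "exon_chain", tuple(self.exon_chain))
        object.__setattr__(
            self, "retained_introns", frozenset(self.retained_introns)
        )
        chain = self.exon_chain
        if not chain or any(b <= a for a, b in zip(chain, chain[1:])):
            raise ModelValidationError(
                f"{self.name or self.gene_name}: exon chain must be strictly "
                f"increasing, got {chain}"
            )
        if self.status not in ("annotated", "novel"):
            raise ModelValidationError(f"unknown status {self.status!r}")

    @property
    def key(self) -> tuple:
        """Identity key used for grouping/counting."""
        return (
            self.gene_name,
            self.exon_chain,
            tuple(sorted(self.retained_introns)),
            self.first_exon_variant,
        )

    def validate_against(self, model: GeneModel) -> None:
        chain = self.exon_chain
        if chain[0] != 1 or chain[-1] != model.n_exons:
            raise ModelValidationError(
                f"{self.name or self.gene_name}: chain must span exon 1 to "
                f"exon {model.n_exons} (full-length convention), got {chain}"
            )
        model.first_exon_truncation(self.first_exon_variant)
        pos = {e: i for i, e in enumerate(chain)}
        for intr in self.retained_introns:
            if intr not in pos:
                raise ModelValidationError(
                    f"{self.name or self.gene_name}: retained intron {intr} "
                    "has no donor exon in the chain"
                )
            i = pos[intr]
            if i + 1 >= len(chain) or chain[i + 1] != intr + 1:
                raise ModelValidationError(
                    f"{self.name or self.gene_name}: retained intron {intr} "
                    "donor is not immediately followed by its acceptor"
                )


def spliced_sequence(model: GeneModel, ts: TranscriptStructure) -> str:
    """Mature mRNA of ``ts``: exon sequences in chain order, retained
    introns inserted between their flanking exons, exon 1 truncated per the
    donor variant. Already in mRNA orientation for '-' genes."""
    ts.validate_against(model)
    parts = []
    for e in ts.exon_chain:
        parts.append(model.exon_sequence(e, ts.first_exon_variant))
        if e in ts.retained_introns:
            parts.append(model.intron_sequence(e))
    return "".join(parts)


def annotated_full_structure(model: GeneModel, name: str = "") -> TranscriptStructure:
    """The trivially annotated structure using every exon, no retention."""
    return TranscriptStructure(
        gene_name=model.gene_name,
        exon_chain=tuple(range(1, model.n_exons + 1)),
        name=name or f"{model.gene_name} full",
        status="annotated",
    )


@dataclass(frozen=True)
class PrimerPair:
    """Gene-specific PCR primers; the reverse primer is given 5'->3' on the
    antisense strand and is matched as its reverse complement."""

    forward_seq: str
    reverse_seq: str

    def __post_init__(self):
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if not seq or not VALID_BASES.match(seq):
                raise ModelValidationError(
                    f"{label} primer must be non-empty A/C/G/T, got {seq!r}"
                )


@dataclass(frozen=True)
class Amplicon:
    """Full-length anchors derived from a primer pair.

    ``first_anchor``: exon-1 subsequence from the forward-primer site to the
    exon-1 boundary shared by every donor variant. ``last_anchor``: last-exon
    subsequence from the exon boundary through the reverse-primer site.
    """

    first_anchor: str
    last_anchor: str
    forward_start: int
    reverse_end: int


class AmpliconError(ValueError):
    """Primer missing or ambiguous in its target exon."""


def _find_once(haystack: str, needle: str, what: str) -> int:
    first = haystack.find(needle)
    if first < 0:
        raise AmpliconError(f"{what} not found in its target exon")
    if haystack.find(needle, first + 1) >= 0:
        raise AmpliconError(f"{what} found more than once (ambiguous anchoring)")
    return first


def define_amplicon(model: GeneModel, primers: PrimerPair) -> Amplicon:
    """Locate the primer pair on exon 1 / last exon and derive anchors.

    The forward primer must occur exactly once in exon 1; the reverse
    complement of the reverse primer exactly once in the last exon. The
    first anchor stops at the shortest exon-1 donor variant so it is shared
    by all first-exon forms.
    """
    exon1 = model.exon_sequence(1)
    last = model.exon_sequence(model.n_exons)
    fpos = _find_once(exon1, primers.forward_seq, "forward primer")
    rseq = reverse_complement(primers.reverse_seq)
    rpos = _find_once(last, rseq, "reverse primer (reverse complement)")
    max_trunc = max(model.alt_first_exon_ends, default=0)
    common_end = len(exon1) - max_trunc
    if fpos + len(primers.forward_seq) > common_end:
        raise AmpliconError(
            "forward primer extends past the shortest exon-1 donor variant; "
            "anchor would not be shared by all first-exon forms"
        )
    return Amplicon(
        first_anchor=exon1[fpos:common_end],
        last_anchor=last[: rpos + len(rseq)],
        forward_start=fpos,
        reverse_end=rpos + len(rseq),
    )


def mirror_model(model: GeneModel) -> GeneModel:
    """The same gene declared on the opposite strand of the reverse-
    complemented locus (useful for strand-symmetry checks)."""
    L = len(model.locus_sequence)
    flipped = "-" if model.strand == "+" else "+"
    exons = tuple(
        Exon(e.exon_id, L - e.end, L - e.start, flipped) for e in model.exons
    )
    return replace(
        model,
        exons=exons,
        locus_sequence=reverse_complement(model.locus_sequence),
    )
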