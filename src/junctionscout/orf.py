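"""ORF selection, translation and PTC/NMD classification of called transcripts.

Policy: every forward-frame ATG...stop span of at least ``min_len_aa``
residues is a candidate. If any candidate starts at the annotated
translation-initiation codon (mapped through the transcript structure), the
5'-most such ORF is chosen — splice variants that keep the annotated start
use it. Otherwise the longest ORF is chosen (the alternative-initiation-
codon case). A transcript whose chosen stop codon lies more than
``nmd_threshold`` nt (default 50, the standard exon-junction-complex rule)
upstream of the last exon-exon junction carries a premature termination
codon and is reported as an NMD candidate, i.e. effectively non-coding.
Retained introns leave no junction behind — no splicing, no deposited EJC —
so those boundaries never count.

Coding products shorter than 100 aa are flagged as micropeptides (smORFs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

from .model import GeneModel, TranscriptStructure, spliced_sequence

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_LEN_AA = 25
DEFAULT_NMD_THRESHOLD = 50
MICROPEPTIDE_MAX_AA = 99


@dataclass(frozen=True)
class Orf:
    """A candidate ORF on a mature mRNA; ``end`` is the position after the
    stop codon, so (end - start) is a multiple of 3."""

    start: int
    end: int
    peptide: str

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class OrfAnnotation:
    transcript_name: str
    orf_start: Optional[int]
    orf_end: Optional[int]
    peptide: str
    peptide_length: int
    uses_annotated_start: bool
    coding_status: str  # {coding, NMD_candidate, non_coding}
    micropeptide: bool


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def find_orfs(mrna: str, min_len_aa: int = DEFAULT_MIN_LEN_AA) -> List[Orf]:
    """All forward-frame ATG..stop spans with an in-frame stop inside the
    sequence and peptide length >= min_len_aa, longest first (ties: 5'-most)."""
    mrna = mrna.upper()
    # first in-frame stop downstream of each position, per frame
    n = len(mrna)
    next_stop = [None] * 3  # frame -> sorted stop positions
    for frame in range(3):
        next_stop[frame] = [
            i for i in range(frame, n - 2, 3) if mrna[i : i + 3] in STOP_CODONS
        ]
    orfs = []
    import bisect

    for i in range(n - 2):
        if mrna[i : i + 3] != "ATG":
            continue
        stops = next_stop[i % 3]
        j = bisect.bisect_left(stops, i)
        if j == len(stops):
            continue  # no in-frame stop: not a complete ORF
        stop = stops[j]
        if stop == i:
            continue  # cannot happen (ATG is not a stop); defensive
        peptide = translate(mrna[i:stop])
        if len(peptide) >= min_len_aa:
            orfs.append(Orf(start=i, end=stop + 3, peptide=peptide))
    orfs.sort(key=lambda o: (-o.peptide_length, o.start))
    return orfs


def select_orf(
    orfs: Sequence[Orf], annotated_start_positions: Sequence[int] = ()
) -> Optional[Orf]:
    """Prefer the 5'-most ORF starting at an annotated start codon; fall back
    to the longest ORF; None when no candidate exists."""
    if not orfs:
        return None
    starts = set(annotated_start_positions)
    annotated = [o for o in orfs if o.start in starts]
    if annotated:
        return min(annotated, key=lambda o: o.start)
    return orfs[0]


def junction_positions(model: GeneModel, ts: TranscriptStructure) -> List[int]:
    """Positions (on the mature mRNA) of exon-exon junctions of ``ts``.

    The boundaries flanking a retained intron are not junctions: no splicing
    occurred there. The transcript's 3' end is not a junction.
    """
    positions = []
    pos = 0
    chain = ts.exon_chain
    for idx, e in enumerate(chain):
        pos += len(model.exon_sequence(e, ts.first_exon_variant))
        if idx == len(chain) - 1:
            break
        if e in ts.retained_introns:
            pos += len(model.intron_sequence(e))  # retained: junction-free
        else:
            positions.append(pos)
    return positions


def annotated_start_positions(
    model: GeneModel, ts: TranscriptStructure
) -> List[int]:
    """Map the model's annotated start codon onto ``ts``'s mRNA, if the
    carrying exon is in the chain and the codon survives the exon-1 variant."""
    if model.annotated_start is None:
        return []
    ex, off = model.annotated_start
    if ex not in ts.exon_chain:
        return []
    exon_len = len(model.exon_sequence(ex, ts.first_exon_variant if ex == 1 else 0))
    if off + 3 > exon_len:
        return []  # codon lost to the exon-1 donor variant
    pos = 0
    for e in ts.exon_chain:
        if e == ex:
            return [pos + off]
        pos += len(model.exon_sequence(e, ts.first_exon_variant))
        if e in ts.retained_introns:
            pos += len(model.intron_sequence(e))
    return []


def classify_coding(
    orf: Optional[Orf],
    junctions: Sequence[int],
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD,
) -> str:
    if orf is None:
        return "non_coding"
    if not junctions:
        return "coding"  # no junction, no EJC: the NMD rule is vacuous
    distance = junctions[-1] - orf.end
    return "NMD_candidate" if distance > nmd_threshold else "coding"


def annotate_transcript(
    model: GeneModel,
    ts: TranscriptStructure,
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD,
) -> OrfAnnotation:
    mrna = spliced_sequence(model, ts)
    return annotate_mrna(
        mrna,
        name=ts.name,
        annotated_starts=annotated_start_positions(model, ts),
        junctions=junction_positions(model, ts),
        min_len_aa=min_len_aa,
        nmd_threshold=nmd_threshold,
    )


def annotate_mrna(
    mrna: str,
    name: str = "",
    annotated_starts: Sequence[int] = (),
    junctions: Sequence[int] = (),
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD,
) -> OrfAnnotation:
    orfs = find_orfs(mrna, min_len_aa=min_len_aa)
    orf = select_orf(orfs, annotated_starts)
    status = classify_coding(orf, junctions, nmd_threshold)
    if orf is None:
        return OrfAnnotation(
            transcript_name=name,
            orf_start=None,
            orf_end=None,
            peptide="",
            peptide_length=0,
            uses_annotated_start=False,
            coding_status="non_coding",
            micropeptide=False,
        )
    return OrfAnnotation(
        transcript_name=name,
        orf_start=orf.start,
        orf_end=orf.end,
        peptide=orf.peptide,
        peptide_length=orf.peptide_length,
        uses_annotated_start=orf.start in set(annotated_starts),
        coding_status=status,
        micropeptide=status == "coding" and orf.peptide_length <= MICROPEPTIDE_MAX_AA,
    )


def annotate_structures(
    model: GeneModel,
    structures: Sequence[TranscriptStructure],
    min_len_aa: int = DEFAULT_MIN_LEN_AA,
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD,
) -> pd.DataFrame:
    rows = []
    for ts in structures:
        ann = annotate_transcript(model, ts, min_len_aa, nmd_threshold)
        rows.append(
            {
                "name": ann.transcript_name or _fallback_name(ts),
                "coding_status": ann.coding_status,
                "orf_start": ann.orf_start,
                "orf_end": ann.orf_end,
                "peptide_length_aa": ann.peptide_length,
                "uses_annotated_start": ann.uses_annotated_start,
                "micropeptide": ann.micropeptide,
                "peptide": ann.peptide,
            }
        )
    return pd.DataFrame(rows)


def _fallback_name(ts: TranscriptStructure) -> str:
    return f"{ts.gene_name} {'-'.join(map(str, ts.exon_chain))}"
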