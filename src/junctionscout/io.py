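"""Reading and writing gene models, transcript sets and sequences.

Two on-disk model formats are supported:

* GFF3/GTF (1-based inclusive, parsed with gffutils) + locus FASTA;
* a JSON schema that can additionally carry the exon-1 donor variants and
  the annotated start codon::

      {"gene": "KRAS", "strand": "+", "seqid": "KRAS_locus",
       "exons": [{"id": 1, "start": 0, "end": 179}, ...],   # 0-based half-open
       "alt_first_exon_ends": [13],
       "annotated_start": {"exon_id": 2, "offset": 5}}

Transcript sets are written as GFF3 (mRNA features with exon children;
retained introns appear as merged exon blocks, exon-1 donor variants as
shortened first-exon blocks) and re-read losslessly against their model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO

from .model import (
    Exon,
    GeneModel,
    ModelValidationError,
    TranscriptStructure,
    spliced_sequence,
)


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Sequence[Tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def load_gene_model(model_file, fasta) -> GeneModel:
    """Load and validate a gene model (JSON or GFF3/GTF) plus its locus."""
    model_file = Path(model_file)
    seqs = read_fasta(fasta)
    if model_file.suffix.lower() == ".json":
        return _model_from_json(model_file, seqs)
    return _model_from_gff(model_file, seqs)


def _get_locus(seqs: Dict[str, str], seqid: Optional[str], where: str) -> Tuple[str, str]:
    if seqid is None:
        if len(seqs) != 1:
            raise ModelValidationError(
                f"{where}: FASTA has {len(seqs)} sequences; a seqid is required"
            )
        return next(iter(seqs.items()))
    if seqid not in seqs:
        raise ModelValidationError(
            f"{where}: sequence id {seqid!r} not found in FASTA"
        )
    return seqid, seqs[seqid]


def _model_from_json(path: Path, seqs: Dict[str, str]) -> GeneModel:
    data = json.loads(path.read_text())
    seqid, locus = _get_locus(seqs, data.get("seqid"), str(path))
    strand = data.get("strand", "+")
    exons = tuple(
        Exon(int(e["id"]), int(e["start"]), int(e["end"]), strand)
        for e in sorted(data["exons"], key=lambda e: int(e["id"]))
    )
    ann = data.get("annotated_start")
    return GeneModel(
        gene_name=data["gene"],
        exons=exons,
        locus_sequence=locus,
        alt_first_exon_ends=tuple(data.get("alt_first_exon_ends", ())),
        annotated_start=(int(ann["exon_id"]), int(ann["offset"])) if ann else None,
        seqid=seqid,
    )


def _model_from_gff(path: Path, seqs: Dict[str, str]) -> GeneModel:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exon_feats = list(db.features_of_type("exon"))
    if not exon_feats:
        raise ModelValidationError(f"{path}: no exon features found")
    strands = {f.strand for f in exon_feats}
    if len(strands) != 1:
        raise ModelValidationError(f"{path}: mixed exon strands")
    strand = strands.pop()
    if strand not in ("+", "-"):
        raise ModelValidationError(f"{path}: unknown strand {strand!r}")
    seqids = {f.seqid for f in exon_feats}
    if len(seqids) != 1:
        raise ModelValidationError(f"{path}: exons on multiple sequences")
    seqid, locus = _get_locus(seqs, seqids.pop(), str(path))
    genes = list(db.features_of_type("gene"))
    if genes:
        gene_name = genes[0].attributes.get("Name", [genes[0].id])[0]
    else:
        gene_name = exon_feats[0].attributes.get("gene", [path.stem])[0]
    # transcription order: ascending genomic for '+', descending for '-'
    ordered = sorted(
        exon_feats, key=lambda f: f.start, reverse=(strand == "-")
    )
    exons = tuple(
        Exon(i + 1, f.start - 1, f.end, strand) for i, f in enumerate(ordered)
    )
    return GeneModel(
        gene_name=gene_name, exons=exons, locus_sequence=locus, seqid=seqid
    )


def write_gene_model_json(model: GeneModel, path) -> None:
    data = {
        "gene": model.gene_name,
        "strand": model.strand,
        "seqid": model.seqid,
        "exons": [
            {"id": e.exon_id, "start": e.start, "end": e.end} for e in model.exons
        ],
        "alt_first_exon_ends": list(model.alt_first_exon_ends),
    }
    if model.annotated_start is not None:
        data["annotated_start"] = {
            "exon_id": model.annotated_start[0],
            "offset": model.annotated_start[1],
        }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


# ---------------------------------------------------------------------------
# transcript structures <-> GFF3
# ---------------------------------------------------------------------------


def _structure_blocks(model: GeneModel, ts: TranscriptStructure) -> List[Tuple[int, int]]:
    """Genomic blocks (0-based half-open, forward strand) of a structure.

    Consecutive chain exons joined by a retained intron collapse into one
    block; the exon-1 donor variant shortens the exon-1 block at its
    transcription-3' side.
    """
    blocks: List[Tuple[int, int]] = []
    trunc = model.first_exon_truncation(ts.first_exon_variant)
    open_block: Optional[Tuple[int, int]] = None
    for e in ts.exon_chain:
        ex = model.exons[e - 1]
        start, end = ex.start, ex.end
        if e == 1 and trunc:
            if model.strand == "+":
                end -= trunc
            else:
                start += trunc
        if open_block is not None:
            # retained intron: merge with previous block
            open_block = (min(open_block[0], start), max(open_block[1], end))
        else:
            open_block = (start, end)
        if e in ts.retained_introns:
            continue  # keep block open through the intron
        blocks.append(open_block)
        open_block = None
    if open_block is not None:
        blocks.append(open_block)
    return sorted(blocks)


def write_transcripts_gff3(
    structures: Sequence[TranscriptStructure], model: GeneModel, path
) -> None:
    """Write structures as GFF3 (version 3 header, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    g0 = min(e.start for e in model.exons)
    g1 = max(e.end for e in model.exons)
    lines.append(
        "\t".join(
            [
                model.seqid,
                "junctionscout",
                "gene",
                str(g0 + 1),
                str(g1),
                ".",
                model.strand,
                ".",
                f"ID={model.gene_name};Name={model.gene_name}",
            ]
        )
    )
    for i, ts in enumerate(structures, 1):
        tid = f"t{i}"
        blocks = _structure_blocks(model, ts)
        attrs = (
            f"ID={tid};Parent={model.gene_name};Name={ts.name};"
            f"status={ts.status};first_exon_variant={ts.first_exon_variant};"
            f"retained_introns={','.join(map(str, sorted(ts.retained_introns))) or '.'}"
        )
        lines.append(
            "\t".join(
                [
                    model.seqid,
                    "junctionscout",
                    "mRNA",
                    str(blocks[0][0] + 1),
                    str(blocks[-1][1]),
                    ".",
                    model.strand,
                    ".",
                    attrs,
                ]
            )
        )
        for j, (s, e) in enumerate(blocks, 1):
            lines.append(
                "\t".join(
                    [
                        model.seqid,
                        "junctionscout",
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        model.strand,
                        ".",
                        f"ID={tid}.exon{j};Parent={tid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_transcripts_gff3(path, model: GeneModel) -> List[TranscriptStructure]:
    """Re-read a transcript GFF3 written by :func:`write_transcripts_gff3`,
    mapping exon blocks back onto the model (round-trip inverse)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        blocks = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        chain, retained, fe = _blocks_to_structure(model, blocks)
        out.append(
            TranscriptStructure(
                gene_name=model.gene_name,
                exon_chain=chain,
                retained_introns=retained,
                first_exon_variant=fe,
                name=mrna.attributes.get("Name", [mrna.id])[0],
                status=mrna.attributes.get("status", ["novel"])[0],
            )
        )
    return out


def _blocks_to_structure(model, blocks):
    """Invert :func:`_structure_blocks`: genomic blocks -> (chain, retained, fe)."""
    chain: List[int] = []
    retained = set()
    fe = 0
    exons = {e.exon_id: e for e in model.exons}
    for s, e in blocks:
        covered = [
            x.exon_id
            for x in model.exons
            if x.start < e and s < x.end  # overlap
        ]
        if not covered:
            raise ModelValidationError(
                f"exon block [{s}, {e}) matches no model exon"
            )
        covered.sort()
        for a, b in zip(covered, covered[1:]):
            if b != a + 1:
                raise ModelValidationError(
                    f"exon block [{s}, {e}) spans non-adjacent exons {covered}"
                )
            retained.add(a)
        for x in covered:
            ex = exons[x]
            exp_start, exp_end = ex.start, ex.end
            if x == 1:
                # allow a donor-variant-shortened exon 1
                got = (max(s, ex.start), min(e, ex.end))
                trunc = (
                    ex.end - got[1] if model.strand == "+" else got[0] - ex.start
                )
                if trunc:
                    try:
                        fe = 1 + model.alt_first_exon_ends.index(trunc)
                    except ValueError:
                        raise ModelValidationError(
                            f"exon-1 block truncated by {trunc} nt, which is "
                            "not a declared donor variant"
                        ) from None
            chain.append(x)
    chain = sorted(set(chain))
    return tuple(chain), frozenset(retained), fe


def write_spliced_fasta(
    structures: Sequence[TranscriptStructure], model: GeneModel, path
) -> None:
    # FASTA ids must be whitespace-free; "KRAS v.5" -> "KRAS_v.5"
    write_fasta(
        [
            ((ts.name or f"ts{i}").replace(" ", "_"), spliced_sequence(model, ts))
            for i, ts in enumerate(structures, 1)
        ],
        path,
    )
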