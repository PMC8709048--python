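"""Aggregate per-read evidence into supported transcript-variant calls.

Full-length, conflict-free, resolvable reads are grouped by identical
structure (exon chain, retained introns, exon-1 donor variant). Groups that
match an annotated transcript keep its name; the rest become novel variants
when their pooled support reaches ``min_support`` (every newly reported
variant must be validated by multiple reads), and are otherwise preserved in
a low-support table for auditing. Novel names continue the gene's numbering
after the annotated transcripts — a gene with 4 annotated variants gets
novels from v.5, one with a single annotated mRNA from v.2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import GeneModel, TranscriptStructure
from .scanner import ReadEvidence

DEFAULT_MIN_SUPPORT = 3


@dataclass(frozen=True)
class VariantCall:
    structure: TranscriptStructure
    name: str
    status: str  # {annotated, novel}
    support_total: int
    support_by_sample: Tuple[Tuple[str, int], ...]

    def support_in(self, sample: str) -> int:
        return dict(self.support_by_sample).get(sample, 0)


@dataclass
class CallResult:
    calls: List[VariantCall]
    low_support: List[VariantCall]
    n_reads: int
    n_full_length: int
    n_conflict: int
    n_unresolved: int

    @property
    def novel(self) -> List[VariantCall]:
        return [c for c in self.calls if c.status == "novel"]

    @property
    def annotated(self) -> List[VariantCall]:
        return [c for c in self.calls if c.status == "annotated"]


def _naming_key(ts: TranscriptStructure) -> tuple:
    """Deterministic novel-variant ordering: more exons first, then
    lexicographic chain, retention set, exon-1 variant."""
    return (
        -len(ts.exon_chain),
        ts.exon_chain,
        tuple(sorted(ts.retained_introns)),
        ts.first_exon_variant,
    )


def call_variants(
    evidence: Sequence[ReadEvidence],
    model: GeneModel,
    annotated: Sequence[TranscriptStructure],
    min_support: int = DEFAULT_MIN_SUPPORT,
    name_map: Optional[Dict[tuple, str]] = None,
) -> CallResult:
    """Group resolvable full-length reads into variant calls.

    ``name_map`` optionally overrides novel names (structure key -> name),
    e.g. to reproduce an externally published numbering.
    """
    for ts in annotated:
        ts.validate_against(model)
    annotated_by_key = {ts.key: ts for ts in annotated}
    groups: Dict[tuple, Dict[str, int]] = {}
    n_conflict = n_unresolved = n_full = 0
    structures: Dict[tuple, TranscriptStructure] = {}
    for ev in evidence:
        if ev.gene_name and ev.gene_name != model.gene_name:
            continue
        if ev.conflict:
            n_conflict += 1
            continue
        if not ev.full_length:
            continue
        n_full += 1
        if ev.structure is None:
            n_unresolved += 1
            continue
        key = ev.structure.key
        structures.setdefault(key, ev.structure)
        per_sample = groups.setdefault(key, {})
        per_sample[ev.sample] = per_sample.get(ev.sample, 0) + 1

    calls: List[VariantCall] = []
    novel_structs: List[tuple] = []
    for key, per_sample in groups.items():
        total = sum(per_sample.values())
        if key in annotated_by_key:
            ann = annotated_by_key[key]
            calls.append(
                VariantCall(
                    structure=ann,
                    name=ann.name,
                    status="annotated",
                    support_total=total,
                    support_by_sample=tuple(sorted(per_sample.items())),
                )
            )
        else:
            novel_structs.append(key)

    # deterministic naming independent of evidence order
    novel_structs.sort(key=lambda key: _naming_key(structures[key]))
    low_support: List[VariantCall] = []
    next_number = len(annotated) + 1
    for key in novel_structs:
        per_sample = groups[key]
        total = sum(per_sample.values())
        ts = structures[key]
        if total >= min_support:
            name = (name_map or {}).get(key) or f"{model.gene_name} v.{next_number}"
            next_number += 1
            ts = replace(ts, name=name, status="novel")
            calls.append(
                VariantCall(
                    structure=ts,
                    name=name,
                    status="novel",
                    support_total=total,
                    support_by_sample=tuple(sorted(per_sample.items())),
                )
            )
        else:
            ts = replace(ts, name=_fallback_name(ts), status="novel")
            low_support.append(
                VariantCall(
                    structure=ts,
                    name=ts.name,
                    status="novel",
                    support_total=total,
                    support_by_sample=tuple(sorted(per_sample.items())),
                )
            )

    # annotated first (annotated list order), then novels in naming order
    ann_order = {ts.key: i for i, ts in enumerate(annotated)}
    calls.sort(
        key=lambda c: (0, ann_order[c.structure.key], ())
        if c.status == "annotated"
        else (1, 0, _naming_key(c.structure))
    )
    return CallResult(
        calls=calls,
        low_support=low_support,
        n_reads=len(evidence),
        n_full_length=n_full,
        n_conflict=n_conflict,
        n_unresolved=n_unresolved,
    )


def _fallback_name(ts: TranscriptStructure) -> str:
    tag = "-".join(map(str, ts.exon_chain))
    if ts.retained_introns:
        tag += "+ir" + ",".join(map(str, sorted(ts.retained_introns)))
    if ts.first_exon_variant:
        tag += f"+fe{ts.first_exon_variant}"
    return f"{ts.gene_name} [{tag}]"


def calls_to_dataframe(result: CallResult, samples: Sequence[str] = ()) -> pd.DataFrame:
    all_samples = list(samples) or sorted(
        {s for c in result.calls + result.low_support for s, _ in c.support_by_sample}
    )
    rows = []
    for c in result.calls:
        row = {
            "name": c.name,
            "gene": c.structure.gene_name,
            "status": c.status,
            "exon_chain": ",".join(map(str, c.structure.exon_chain)),
            "retained_introns": ",".join(map(str, sorted(c.structure.retained_introns))),
            "first_exon_variant": c.structure.first_exon_variant,
            "support_total": c.support_total,
        }
        for s in all_samples:
            row[f"support_{s}"] = c.support_in(s)
        rows.append(row)
    return pd.DataFrame(rows)


def export_calls(
    result: CallResult,
    model: GeneModel,
    outdir,
    samples: Sequence[str] = (),
) -> Dict[str, Path]:
    """Write calls as GFF3 + spliced-cDNA FASTA + support TSVs."""
    from .io import write_spliced_fasta, write_transcripts_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / f"{model.gene_name}.calls.gff3",
        "fasta": outdir / f"{model.gene_name}.calls.fa",
        "tsv": outdir / f"{model.gene_name}.calls.tsv",
        "low_support": outdir / f"{model.gene_name}.low_support.tsv",
    }
    structures = [c.structure for c in result.calls]
    write_transcripts_gff3(structures, model, paths["gff3"])
    write_spliced_fasta(structures, model, paths["fasta"])
    calls_to_dataframe(result, samples).to_csv(paths["tsv"], sep="\t", index=False)
    low = CallResult(result.low_support, [], 0, 0, 0, 0)
    calls_to_dataframe(low, samples).to_csv(paths["low_support"], sep="\t", index=False)
    return paths
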