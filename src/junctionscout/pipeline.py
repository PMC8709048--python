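"""End-to-end orchestration: catalog -> scan -> call -> orf -> quant.

A run is driven by a flat key-value config (TOML file or keyword arguments)
and writes every intermediate artifact into the output directory together
with a machine-readable manifest (package version, parameters, input
checksums, per-stage record counts) and a human-readable log, so a run can
be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__
from .caller import DEFAULT_MIN_SUPPORT, call_variants, calls_to_dataframe, export_calls
from .catalog import DEFAULT_K, DEFAULT_MIN_FLANK, DEFAULT_STRIDE, build_catalog
from .io import load_gene_model, read_transcripts_gff3, write_fasta
from .model import PrimerPair
from .orf import DEFAULT_MIN_LEN_AA, DEFAULT_NMD_THRESHOLD, annotate_structures
from .quant import DEFAULT_PSEUDOCOUNT, export_heatmap, quantify
from .scanner import ScanParams, evidence_to_dataframe, scan_fastq

log = logging.getLogger("junctionscout")


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run (one gene, many samples)."""

    model: str
    fasta: str
    annotated: str
    fastq: Dict[str, str]  # sample name -> FASTQ path
    outdir: str
    forward_primer: str = ""
    reverse_primer: str = ""
    k: int = DEFAULT_K
    min_flank: int = DEFAULT_MIN_FLANK
    stride: int = DEFAULT_STRIDE
    max_edits: int = 2
    min_offsets: int = 2
    retention_frac: float = 0.8
    min_support: int = DEFAULT_MIN_SUPPORT
    min_len_aa: int = DEFAULT_MIN_LEN_AA
    nmd_threshold: int = DEFAULT_NMD_THRESHOLD
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    denominator: str = "sum"

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data)
        except TypeError as exc:
            raise PipelineConfigError(f"bad config {path}: {exc}") from None

    def validate(self) -> None:
        missing = [
            p
            for p in [self.model, self.fasta, self.annotated, *self.fastq.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineConfigError(f"missing input paths: {missing}")
        if not self.fastq:
            raise PipelineConfigError("at least one sample FASTQ is required")
        if not (self.forward_primer and self.reverse_primer):
            raise PipelineConfigError(
                "forward_primer and reverse_primer are required (full-length "
                "anchoring is primer-defined)"
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory. Raises on any stage
    error (with the stage name), leaving the partial manifest behind."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {
        "tool": "junctionscout",
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if k not in ("fastq",)
        },
        "samples": dict(cfg.fastq),
        "inputs": {
            "model": _sha256(cfg.model),
            "fasta": _sha256(cfg.fasta),
            "annotated": _sha256(cfg.annotated),
            **{f"fastq:{s}": _sha256(p) for s, p in cfg.fastq.items()},
        },
        "stages": [],
    }
    t0 = time.time()

    def stage_done(name: str, **info):
        manifest["stages"].append({"stage": name, "elapsed_s": round(time.time() - t0, 2), **info})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        log.info("stage %s done: %s", name, info)

    try:
        model = load_gene_model(cfg.model, cfg.fasta)
        annotated = read_transcripts_gff3(cfg.annotated, model)
        primers = PrimerPair(cfg.forward_primer, cfg.reverse_primer)
        catalog = build_catalog(
            model, k=cfg.k, min_flank=cfg.min_flank, stride=cfg.stride,
            primers=primers,
        )
        catalog.to_tsv(outdir / "catalog.tsv")
        stage_done(
            "catalog",
            n_entries=len(catalog.entries),
            n_ambiguous=sum(e.ambiguous for e in catalog.entries),
        )
    except Exception as exc:
        raise RuntimeError(f"stage catalog failed: {exc}") from exc

    try:
        params = ScanParams(
            max_edits=cfg.max_edits,
            min_offsets=cfg.min_offsets,
            retention_frac=cfg.retention_frac,
        )
        evidence = scan_fastq(cfg.fastq, catalog, model, params)
        evidence_to_dataframe(evidence).to_csv(
            outdir / "evidence.tsv", sep="\t", index=False
        )
        stage_done(
            "scan",
            n_reads=len(evidence),
            n_full_length=sum(ev.full_length for ev in evidence),
            n_conflict=sum(ev.conflict for ev in evidence),
        )
    except Exception as exc:
        raise RuntimeError(f"stage scan failed: {exc}") from exc

    try:
        result = call_variants(evidence, model, annotated, min_support=cfg.min_support)
        export_calls(result, model, outdir / "calls", samples=list(cfg.fastq))
        stage_done(
            "call",
            n_calls=len(result.calls),
            n_novel=len(result.novel),
            n_low_support=len(result.low_support),
        )
    except Exception as exc:
        raise RuntimeError(f"stage call failed: {exc}") from exc

    try:
        structures = [c.structure for c in result.calls]
        orfs = annotate_structures(
            model, structures, min_len_aa=cfg.min_len_aa,
            nmd_threshold=cfg.nmd_threshold,
        )
        orfs.drop(columns=["peptide"]).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
        write_fasta(
            [
                (row["name"].replace(" ", "_"), row["peptide"])
                for _, row in orfs.iterrows()
                if row["peptide"]
            ],
            outdir / "peptides.fa",
        )
        stage_done(
            "orf",
            n_coding=int((orfs["coding_status"] == "coding").sum()),
            n_nmd=int((orfs["coding_status"] == "NMD_candidate").sum()),
            n_micropeptide=int(orfs["micropeptide"].sum()),
        )
    except Exception as exc:
        raise RuntimeError(f"stage orf failed: {exc}") from exc

    try:
        quantdir = outdir / "quant"
        quantdir.mkdir(exist_ok=True)
        tables = quantify(
            evidence, result, list(cfg.fastq), pseudocount=cfg.pseudocount,
            denominator=cfg.denominator,
        )
        tables["counts"].to_csv(quantdir / "counts.tsv", sep="\t")
        tables["size_factors"].to_csv(quantdir / "size_factors.tsv", sep="\t")
        tables["normalized"].to_csv(quantdir / "normalized.tsv", sep="\t")
        export_heatmap(tables["log2fc"], quantdir / "log2fc")
        stage_done("quant", n_novel_rows=int(tables["log2fc"].shape[0]))
    except Exception as exc:
        raise RuntimeError(f"stage quant failed: {exc}") from exc

    log.removeHandler(handler)
    handler.close()
    return outdir
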