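"""Synthetic gene models, planted transcript variants and nanopore-like reads.

The generator emulates targeted full-length cDNA amplicon sequencing of a
single multi-exon gene: every read is a complete amplicon of one planted
transcript (first to last exon, primer-anchored), emitted in random
orientation with per-base substitution / insertion / deletion errors and
occasional end truncation. Default error rates (1.5% / 2% / 2.5%, ~6%
total) approximate R9.4.1-era nanopore basecalls; qualities are a constant
placeholder because the scanner ignores them. Every read is logged with its
originating variant, orientation and realized edits, and per-sample truth
count matrices are emitted so recovery can be scored exactly.

Gene models are rejection-sampled until the default-k catalog is free of
ambiguous k-mers, so detection failures in tests are attributable to the
planted error process, never to k-mer collisions.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caller import CallResult
from .catalog import DEFAULT_K, DEFAULT_MIN_FLANK, DEFAULT_STRIDE, build_catalog
from .model import (
    Exon,
    GeneModel,
    ModelValidationError,
    PrimerPair,
    TranscriptStructure,
    reverse_complement,
    spliced_sequence,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_SUB_RATE = 0.015
DEFAULT_INS_RATE = 0.02
DEFAULT_DEL_RATE = 0.025
PLACEHOLDER_QUAL = "?"  # constant placeholder; the scanner is quality-blind


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gene/run."""

    seed: int
    n_exons: int = 6
    exon_length_range: Tuple[int, int] = (80, 220)
    intron_length_range: Tuple[int, int] = (60, 120)
    alt_first_exon_ends: Tuple[int, ...] = ()
    annotated_start: Optional[Tuple[int, int]] = None
    sub_rate: float = DEFAULT_SUB_RATE
    ins_rate: float = DEFAULT_INS_RATE
    del_rate: float = DEFAULT_DEL_RATE
    truncation_prob: float = 0.05
    truncation_max: int = 150
    primer_length: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2], got {r}")
        if not 0 <= self.truncation_prob <= 1:
            raise ValueError("truncation_prob must be a probability")

    @property
    def error_free(self) -> bool:
        return (
            self.sub_rate == self.ins_rate == self.del_rate == 0
            and self.truncation_prob == 0
        )


@dataclass
class GroundTruth:
    reads: pd.DataFrame  # read_id, sample, variant, orientation, edits...
    counts: pd.DataFrame  # variant x sample, reads emitted

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.counts.to_csv(outdir / "truth_counts.tsv", sep="\t")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def make_gene_model(
    cfg: SimulationConfig,
    gene_name: str = "SYNTH",
    exon_lengths: Optional[Sequence[int]] = None,
    intron_lengths: Optional[Sequence[int]] = None,
    k: int = DEFAULT_K,
    min_flank: int = DEFAULT_MIN_FLANK,
    stride: int = DEFAULT_STRIDE,
    max_draws: int = 100,
) -> GeneModel:
    """Random-base locus with the requested layout, rejection-sampled until
    the catalog (including primer anchors) has zero ambiguous k-mers."""
    if cfg.n_exons < 2:
        raise ModelValidationError("a gene model needs >= 2 exons")
    rng = np.random.default_rng(cfg.seed)
    for _draw in range(max_draws):
        ex_lens = list(
            exon_lengths
            if exon_lengths is not None
            else rng.integers(*cfg.exon_length_range, size=cfg.n_exons, endpoint=True)
        )
        in_lens = list(
            intron_lengths
            if intron_lengths is not None
            else rng.integers(*cfg.intron_length_range, size=cfg.n_exons - 1, endpoint=True)
        )
        if len(ex_lens) != cfg.n_exons or len(in_lens) != cfg.n_exons - 1:
            raise ValueError("exon/intron length lists do not match n_exons")
        coords, pos = [], 0
        for i, L in enumerate(ex_lens):
            coords.append((pos, pos + int(L)))
            pos += int(L)
            if i < len(in_lens):
                pos += int(in_lens[i])
        locus = _random_sequence(rng, pos)
        if cfg.annotated_start is not None:
            ex, off = cfg.annotated_start
            s = coords[ex - 1][0] + off
            locus = locus[:s] + "ATG" + locus[s + 3 :]
        model = GeneModel(
            gene_name=gene_name,
            exons=tuple(Exon(i + 1, s, e, "+") for i, (s, e) in enumerate(coords)),
            locus_sequence=locus,
            alt_first_exon_ends=cfg.alt_first_exon_ends,
            annotated_start=cfg.annotated_start,
            seqid=f"{gene_name}_locus",
        )
        catalog = build_catalog(
            model, k=k, min_flank=min_flank, stride=stride,
            primers=default_primers(model, cfg.primer_length),
        )
        if not any(e.ambiguous for e in catalog.entries):
            return model
    raise ModelValidationError(
        f"could not draw an ambiguity-free locus in {max_draws} tries; "
        "try longer exons or a larger k"
    )


def default_primers(model: GeneModel, primer_length: int = 20) -> PrimerPair:
    """Primers at the very ends of the amplicon: the first bases of exon 1
    and the reverse complement of the last bases of the final exon."""
    exon1 = model.exon_sequence(1)
    last = model.exon_sequence(model.n_exons)
    return PrimerPair(
        forward_seq=exon1[:primer_length],
        reverse_seq=reverse_complement(last[-primer_length:]),
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _mutate(seq: str, rng: np.random.Generator, cfg: SimulationConfig):
    """Apply per-base substitution/insertion/deletion errors; returns the
    mutated read and the realized (n_sub, n_ins, n_del)."""
    n = len(seq)
    p = (cfg.sub_rate, cfg.ins_rate, cfg.del_rate)
    if sum(p) == 0:
        return seq, 0, 0, 0
    events = rng.choice(
        4, size=n, p=[1 - sum(p), *p]
    )  # 0 none, 1 sub, 2 ins, 3 del
    out = []
    n_sub = n_ins = n_del = 0
    last = 0
    arr = seq
    for i in np.flatnonzero(events):
        ev = events[i]
        out.append(arr[last:i])
        base = arr[i]
        if ev == 1:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
            n_sub += 1
        elif ev == 2:  # insertion before the base
            out.append("ACGT"[rng.integers(0, 4)])
            out.append(base)
            n_ins += 1
        else:
            n_del += 1  # base dropped
        last = i + 1
    out.append(arr[last:])
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(
    model: GeneModel,
    cfg: SimulationConfig,
    planted: Sequence[TranscriptStructure],
    abundances: Dict[str, Dict[str, int]],
    outdir=None,
) -> Tuple[Dict[str, List[Tuple[str, str]]], GroundTruth]:
    """Emit reads per sample/variant with ground truth.

    ``abundances``: sample -> {variant name -> number of reads}. Returns
    in-memory reads (sample -> [(read_id, seq), ...]) and writes FASTQ +
    truth tables when ``outdir`` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    by_name = {ts.name: ts for ts in planted}
    cdna = {name: spliced_sequence(model, ts) for name, ts in by_name.items()}
    samples = list(abundances)
    counts = pd.DataFrame(0, index=list(by_name), columns=samples, dtype=int)
    reads: Dict[str, List[Tuple[str, str]]] = {s: [] for s in samples}
    rows = []
    serial = 0
    for sample in samples:
        for name, n_reads in abundances[sample].items():
            if name not in by_name:
                raise ValueError(f"abundance given for unknown variant {name!r}")
            for _ in range(int(n_reads)):
                serial += 1
                read_id = f"read{serial:06d}"
                seq, n_sub, n_ins, n_del = _mutate(cdna[name], rng, cfg)
                trunc = 0
                trunc_end = ""
                if cfg.truncation_prob and rng.random() < cfg.truncation_prob:
                    trunc = int(rng.integers(1, cfg.truncation_max + 1))
                    trunc = min(trunc, len(seq) - 1)
                    if rng.random() < 0.5:
                        seq, trunc_end = seq[trunc:], "5p"
                    else:
                        seq, trunc_end = seq[:-trunc], "3p"
                orientation = "forward"
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                    orientation = "reverse-complement"
                reads[sample].append((read_id, seq))
                counts.loc[name, sample] += 1
                rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "variant": name,
                        "orientation": orientation,
                        "n_sub": n_sub,
                        "n_ins": n_ins,
                        "n_del": n_del,
                        "truncated_nt": trunc,
                        "truncated_end": trunc_end,
                    }
                )
    truth = GroundTruth(reads=pd.DataFrame(rows), counts=counts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample in samples:
            write_fastq(reads[sample], outdir / f"{sample}.fastq.gz")
        truth.write(outdir)
    return reads, truth


def write_fastq(reads: Sequence[Tuple[str, str]], path) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{PLACEHOLDER_QUAL * len(seq)}\n")


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def score_recovery(
    result: CallResult,
    truth: GroundTruth,
    planted: Sequence[TranscriptStructure],
    count_matrix: Optional[pd.DataFrame] = None,
) -> Dict[str, float]:
    """Structure-level precision/recall of the calls against the planted set,
    plus mean absolute count error when a count matrix is supplied."""
    planted_keys = {ts.key for ts in planted}
    called_keys = {c.structure.key for c in result.calls}
    tp = len(planted_keys & called_keys)
    precision = tp / len(called_keys) if called_keys else float("nan")
    recall = tp / len(planted_keys) if planted_keys else float("nan")
    out = {"precision": precision, "recall": recall}
    if count_matrix is not None:
        name_of = {ts.key: ts.name for ts in planted}
        called_names = {c.structure.key: c.name for c in result.calls}
        errs = []
        for key, true_name in name_of.items():
            for sample in truth.counts.columns:
                true_n = int(truth.counts.loc[true_name, sample])
                called = called_names.get(key)
                got = (
                    int(count_matrix.loc[called, sample])
                    if called is not None and called in count_matrix.index
                    else 0
                )
                errs.append(abs(got - true_n))
        out["count_mae"] = float(np.mean(errs)) if errs else float("nan")
    return out
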