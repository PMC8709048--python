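"""RAS-family reference material and the synthetic RAS-like preset.

Two distinct things live here:

* The published RAS isoform registry — the exon chains, retention flags and
  exon-1 donor variants of the annotated KRAS/NRAS/HRAS transcripts and of
  the deposited novel variants (GenBank MZ068300-MZ068338), plus the Table-1
  amplification primers. KRAS v.19/v.20 chains are reconstructed guesses
  (the published description only calls them distant-exon junctions) and are
  marked as such.

* A synthetic "RAS-like" preset: three rejection-sampled random-sequence
  gene models mirroring the KRAS/NRAS/HRAS exon topology (6/7/7 exons, a
  13-nt exon-1 donor variant for the KRAS-like gene, an intron retention
  between exons 6 and 7 for the HRAS-like gene), with a representative
  subset of the published splicing patterns planted as ground truth. The
  loci are synthetic: only the exon/intron topology and splicing patterns
  mirror the real genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .model import GeneModel, PrimerPair, TranscriptStructure
from .simulate import SimulationConfig, make_gene_model

# Gene-specific touchdown-PCR primers (forward on exon 1; reverse, given
# 5'->3' antisense, on the last exon).
TABLE1_PRIMERS: Dict[str, PrimerPair] = {
    "KRAS": PrimerPair("GCCATTTCGGACTGGGAGC", "CTCGAACTAATGTATAGAAGGCATCATC"),
    "NRAS": PrimerPair("GCTGTGGTCCTAAATCTGTCCA", "CTGTGAGACTGAAGACAGCAAC"),
    "HRAS": PrimerPair("GCAGTCGCGCCTGTGAAC", "GCACCTCCATGTCCTGAGCTT"),
}

PRESET_SAMPLES: Tuple[str, ...] = ("breast", "lung", "noncancer")


@dataclass(frozen=True)
class IsoformRecord:
    name: str
    exon_chain: Tuple[int, ...]
    retained_introns: Tuple[int, ...] = ()
    first_exon_variant: int = 0
    accession: str = ""
    reconstructed: bool = False  # structure inferred, not explicitly published

    def structure(self, gene: str, status: str) -> TranscriptStructure:
        return TranscriptStructure(
            gene_name=gene,
            exon_chain=self.exon_chain,
            retained_introns=frozenset(self.retained_introns),
            first_exon_variant=self.first_exon_variant,
            name=self.name,
            status=status,
        )


def _rec(name, chain, ir=(), fe=0, acc="", recon=False):
    return IsoformRecord(name, tuple(chain), tuple(ir), fe, acc, recon)


# Exon-1 donor variants: fe=0 -> full 179-nt exon 1, fe=1 -> truncated 166 nt.
KRAS_ANNOTATED = [
    _rec("KRAS v.1", (1, 2, 3, 4, 5, 6), fe=0, acc="NM_033360.4"),
    _rec("KRAS v.2", (1, 2, 3, 4, 6), fe=0, acc="NM_004985.5"),
    _rec("KRAS v.3", (1, 2, 3, 4, 5, 6), fe=1, acc="NM_001369786.1"),
    _rec("KRAS v.4", (1, 2, 3, 4, 6), fe=1, acc="NM_001369787.1"),
]
KRAS_NOVEL = [
    _rec("KRAS v.5", (1, 2, 4, 6), fe=0, acc="MZ068300"),
    _rec("KRAS v.6", (1, 2, 4, 6), fe=1, acc="MZ068301"),
    _rec("KRAS v.7", (1, 2, 4, 5, 6), fe=0, acc="MZ068302"),
    _rec("KRAS v.8", (1, 2, 4, 5, 6), fe=1, acc="MZ068303"),
    _rec("KRAS v.9", (1, 2, 5, 6), fe=1, acc="MZ068304"),
    _rec("KRAS v.10", (1, 2, 6), fe=0, acc="MZ068305"),
    _rec("KRAS v.11", (1, 2, 6), fe=1, acc="MZ068306"),
    _rec("KRAS v.12", (1, 3, 4, 6), fe=0, acc="MZ068307"),
    _rec("KRAS v.13", (1, 3, 4, 6), fe=1, acc="MZ068308"),
    _rec("KRAS v.14", (1, 3, 4, 5, 6), fe=0, acc="MZ068309"),
    _rec("KRAS v.15", (1, 3, 4, 5, 6), fe=1, acc="MZ068310"),
    _rec("KRAS v.16", (1, 4, 6), fe=0, acc="MZ068311"),
    _rec("KRAS v.17", (1, 4, 6), fe=1, acc="MZ068312"),
    _rec("KRAS v.18", (1, 4, 5, 6), fe=0, acc="MZ068313"),
    _rec("KRAS v.19", (1, 5, 6), fe=0, acc="MZ068314", recon=True),
    _rec("KRAS v.20", (1, 6), fe=0, acc="MZ068315", recon=True),
]

NRAS_ANNOTATED = [_rec("NRAS v.1", (1, 2, 3, 4, 5, 6, 7), acc="NM_002524.5")]
NRAS_NOVEL = [
    _rec("NRAS v.2", (1, 2, 4, 5, 6, 7), acc="MZ068316"),
    _rec("NRAS v.3", (1, 2, 5, 6, 7), acc="MZ068317"),
    _rec("NRAS v.4", (1, 2, 3, 5, 6, 7), acc="MZ068318"),
    _rec("NRAS v.5", (1, 2, 3, 4, 5, 7), acc="MZ068319"),
    _rec("NRAS v.6", (1, 3, 4, 5, 6, 7), acc="MZ068320"),
    _rec("NRAS v.7", (1, 4, 5, 6, 7), acc="MZ068321"),
    _rec("NRAS v.8", (1, 4, 5, 7), acc="MZ068322"),
    _rec("NRAS v.9", (1, 5, 6, 7), acc="MZ068323"),
    _rec("NRAS v.10", (1, 6, 7), acc="MZ068324", recon=True),
]

HRAS_ANNOTATED = [
    _rec("HRAS v.1", (1, 2, 3, 4, 5, 6, 7), acc="NM_005343.4"),
    _rec("HRAS v.2", (1, 2, 3, 4, 5, 6, 7), ir=(6,), acc="NM_176795.5"),
    _rec("HRAS v.3", (1, 2, 3, 4, 6, 7), ir=(6,), acc="NM_001130442.3", recon=True),
    _rec("HRAS v.4", (1, 2, 3, 4, 6, 7), acc="NM_001318054.2", recon=True),
]
HRAS_NOVEL = [
    _rec("HRAS v.5", (1, 3, 4, 6, 7), acc="MZ068325"),
    _rec("HRAS v.6", (1, 3, 4, 6, 7), ir=(6,), acc="MZ068326"),
    _rec("HRAS v.7", (1, 3, 4, 5, 6, 7), acc="MZ068327"),
    _rec("HRAS v.8", (1, 3, 4, 5, 6, 7), ir=(6,), acc="MZ068328"),
    _rec("HRAS v.9", (1, 4, 6, 7), acc="MZ068329"),
    _rec("HRAS v.10", (1, 4, 6, 7), ir=(6,), acc="MZ068330"),
    _rec("HRAS v.11", (1, 4, 5, 6, 7), acc="MZ068331"),
    _rec("HRAS v.12", (1, 4, 5, 6, 7), ir=(6,), acc="MZ068332"),
    _rec("HRAS v.13", (1, 5, 6, 7), acc="MZ068333"),
    _rec("HRAS v.14", (1, 5, 6, 7), ir=(6,), acc="MZ068334"),
    _rec("HRAS v.15", (1, 6, 7), acc="MZ068335"),
    _rec("HRAS v.16", (1, 6, 7), ir=(6,), acc="MZ068336"),
    _rec("HRAS v.17", (1, 2, 4, 6, 7), acc="MZ068337"),
    _rec("HRAS v.18", (1, 2, 4, 6, 7), ir=(6,), acc="MZ068338"),
]

ISOFORM_REGISTRY: Dict[str, Dict[str, List[IsoformRecord]]] = {
    "KRAS": {"annotated": KRAS_ANNOTATED, "novel": KRAS_NOVEL},
    "NRAS": {"annotated": NRAS_ANNOTATED, "novel": NRAS_NOVEL},
    "HRAS": {"annotated": HRAS_ANNOTATED, "novel": HRAS_NOVEL},
}


# ---------------------------------------------------------------------------
# synthetic RAS-like preset
# ---------------------------------------------------------------------------

# fixed layout + model seed per gene; random loci are rejection-sampled to be
# ambiguity-free at the default k
_PRESET_LAYOUT = {
    "KRAS": dict(
        seed=4202,
        exon_lengths=(179, 122, 179, 160, 118, 290),
        alt_first_exon_ends=(13,),
        annotated_start=(2, 5),
    ),
    "NRAS": dict(
        seed=4203,
        exon_lengths=(172, 128, 179, 88, 146, 70, 210),
        alt_first_exon_ends=(),
        annotated_start=(2, 3),
    ),
    "HRAS": dict(
        seed=4204,
        exon_lengths=(164, 111, 179, 160, 90, 68, 151),
        alt_first_exon_ends=(),
        annotated_start=(2, 10),
    ),
}

# representative subset of the published splicing patterns planted in
# simulations (exon skipping incl. multi-exon skips, exon-1 donor variants,
# intron retention)
_PRESET_PLANTED_NOVEL = {
    "KRAS": ["KRAS v.5", "KRAS v.6", "KRAS v.9", "KRAS v.10", "KRAS v.12", "KRAS v.16"],
    "NRAS": ["NRAS v.2", "NRAS v.3", "NRAS v.7", "NRAS v.9"],
    "HRAS": ["HRAS v.5", "HRAS v.6", "HRAS v.13", "HRAS v.17"],
}

PRESET_GENES = ("KRAS", "NRAS", "HRAS")


def preset_gene(gene: str) -> Tuple[GeneModel, List[TranscriptStructure], List[TranscriptStructure], PrimerPair]:
    """One synthetic RAS-like gene: (model, annotated, planted novels, primers)."""
    if gene not in _PRESET_LAYOUT:
        raise KeyError(f"no preset for {gene!r}; choose from {PRESET_GENES}")
    lay = _PRESET_LAYOUT[gene]
    cfg = SimulationConfig(
        seed=lay["seed"],
        n_exons=len(lay["exon_lengths"]),
        alt_first_exon_ends=lay["alt_first_exon_ends"],
        annotated_start=lay["annotated_start"],
    )
    model = make_gene_model(cfg, gene_name=gene, exon_lengths=lay["exon_lengths"])
    annotated = [r.structure(gene, "annotated") for r in ISOFORM_REGISTRY[gene]["annotated"]]
    by_name = {r.name: r for r in ISOFORM_REGISTRY[gene]["novel"]}
    novels = [
        by_name[n].structure(gene, "novel") for n in _PRESET_PLANTED_NOVEL[gene]
    ]
    from .simulate import default_primers

    return model, annotated, novels, default_primers(model)


def preset_abundances(
    annotated: Sequence[TranscriptStructure],
    novels: Sequence[TranscriptStructure],
    samples: Sequence[str] = PRESET_SAMPLES,
    coverage: Optional[int] = None,
) -> Dict[str, Dict[str, int]]:
    """Per-sample reads per variant.

    ``coverage`` set -> uniform coverage for every planted variant (the
    controlled regime used for recovery scoring). Otherwise an expression-
    profile-like default: abundant annotated transcripts, sparser novel
    variants varying deterministically across samples.
    """
    out: Dict[str, Dict[str, int]] = {}
    for j, sample in enumerate(samples):
        table: Dict[str, int] = {}
        for i, ts in enumerate(annotated):
            table[ts.name] = coverage if coverage is not None else (60 - 12 * i)
        for i, ts in enumerate(novels):
            table[ts.name] = (
                coverage if coverage is not None else 3 + ((2 * i + 3 * j) % 12)
            )
        out[sample] = table
    return out
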