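# junctionscout

Targeted long-read splice-variant discovery for single genes.

Targeted amplicon nanopore sequencing — PCR from the first to the last exon
of a gene, then long-read sequencing of the product — yields enormous
per-gene depth, deep enough to catch rare alternative splicing events that
genome-wide RNA-seq misses. `junctionscout` is the analysis side of that
design: given a gene model (exon coordinates + locus sequence), an annotated
transcript set and one FASTQ per sample, it

1. **enumerates every possible splicing event** between annotated exons —
   all n(n−1)/2 ordered exon pairs — and materializes each junction as a set
   of boundary-spanning k-mers (one per donor-side offset), plus fixed-stride
   k-mer tilings of every intron (for intron-retention detection) and of the
   primer-defined amplicon anchors (for full-length classification);
2. **scans reads** for those k-mers (exact or bounded-edit-distance
   matching), chains the hits into a consistent per-read junction path, and
   reconstructs each full-length, conflict-free read's transcript structure
   — exon chain, retained introns, exon-1 donor variant — without ever
   inventing structure a read does not assert;
3. **calls variants** by grouping identical read structures: groups matching
   an annotated transcript keep its name; new structures with enough
   supporting reads become novel variants (`GENE v.N`, numbering continuing
   after the annotated set); the rest land in a low-support audit table;
4. **classifies coding potential** of every called transcript: ORF selection
   (annotated start codon preferred, longest ORF otherwise), translation,
   premature-termination-codon detection via the 50-nt last-junction rule
   (PTC ⇒ NMD candidate ⇒ effectively non-coding), and a micropeptide flag
   for coding products < 100 aa;
5. **quantifies abundance** as full-length read counts per variant and
   sample, normalized with median-of-ratios (MRN) size factors, and reports
   each novel variant v in sample s as
   `log2FC(v,s) = log2((norm(v,s)+pc) / (Σ_annotated norm(a,s)+pc))`
   with pseudocount pc = 0.5, rendered as a clustered heatmap.

A fully seeded synthetic-data module generates random-locus gene models
(rejection-sampled to be k-mer-collision-free), plants transcript structures
with exon skipping, intron retention and alternative exon-1 donors, and
emits nanopore-like amplicon reads (substitutions/insertions/deletions,
random orientation, occasional end truncation) with exact ground truth — so
the whole pipeline is testable end to end without any downloads. A
"RAS-like" preset mirrors the KRAS/NRAS/HRAS exon topologies (6/7/7 exons,
a 13-nt alternative exon-1 donor, retention of the second-to-last intron)
on synthetic loci.

## Worked example

```python
import junctionscout as js
from junctionscout.presets import preset_gene, preset_abundances
from junctionscout.simulate import SimulationConfig, simulate_reads
from junctionscout.scanner import ScanParams, process_read

model, annotated, novels, primers = preset_gene("KRAS")
catalog = js.build_catalog(model, primers=primers)
# catalog: 15 junctions, 250 k-mers, 0 ambiguous

cfg = SimulationConfig(seed=1)                      # ~6% total error
reads, truth = simulate_reads(model, cfg, annotated + novels,
                              preset_abundances(annotated, novels))
evidence = [process_read(rid, seq, catalog, model, ScanParams(), sample=s)
            for s, lst in reads.items() for rid, seq in lst]
result = js.call_variants(evidence, model, annotated, min_support=3)
tables = js.quantify(evidence, result, list(truth.counts.columns))
```

Output (seed 1): 654 reads, 437 full-length resolvable, 2 conflicts; all
4 annotated and all 6 planted novel structures are recovered —

```
KRAS v.1   annotated  chain=1,2,3,4,5,6  fe=0  support=112
KRAS v.2   annotated  chain=1,2,3,4,6    fe=0  support=95
...
KRAS v.5   novel      chain=1,2,4,6      fe=0  support=14
...
size factors: breast 0.930, lung 0.993, noncancer 1.109
log2FC (novel vs summed annotated), e.g. KRAS v.5: -5.35 / -4.23 / -3.95
```

`support` counts full-length reads whose junction-path exactly matches the
call; `fe` is the exon-1 donor variant (0 = full first exon, 1 = the
truncated form); negative log2FC means the novel variant is rarer than the
annotated transcripts in that sample, as planted.

## Command line

```
junctionscout simulate --gene KRAS --seed 1 -o sim/        # synthetic dataset
junctionscout catalog  --model m.json --fasta locus.fa \
                       --forward-primer ... --reverse-primer ... -o catalog.tsv
junctionscout scan     --catalog catalog.tsv --model m.json --fasta locus.fa \
                       --fastq breast=breast.fastq.gz ... -o evidence.tsv
junctionscout call     --evidence evidence.tsv ... -o calls/
junctionscout orf      --calls calls/GENE.calls.gff3 ... -o orfs.tsv
junctionscout quant    --evidence evidence.tsv ... -o quant/
junctionscout run      --config run.toml                   # all stages + manifest
```

`run.toml` is flat key-value: `model`, `fasta`, `annotated`, `outdir`,
`forward_primer`, `reverse_primer`, a `[fastq]` table of `sample = "path"`
pairs, and optional parameters (`k`, `min_flank`, `stride`, `max_edits`,
`min_offsets`, `retention_frac`, `min_support`, `min_len_aa`,
`nmd_threshold`, `pseudocount`, `denominator`). Every run writes a
`manifest.json` with parameters, input checksums and per-stage counts.

## Gene-model JSON schema

```json
{"gene": "KRAS", "strand": "+", "seqid": "KRAS_locus",
 "exons": [{"id": 1, "start": 0, "end": 179}, ...],
 "alt_first_exon_ends": [13],
 "annotated_start": {"exon_id": 2, "offset": 5}}
```

Coordinates are 0-based half-open on the forward genomic strand; exon ids
are 1-based in transcription order (GFF3 input, 1-based inclusive, is also
accepted). `alt_first_exon_ends` lists alternative exon-1 donor boundaries
as 3′-truncation offsets in nt; `annotated_start` places the annotated
initiation codon.

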