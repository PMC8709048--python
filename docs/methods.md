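# Methods

## The detection model

The pipeline targets a single multi-exon gene amplified as full-length cDNA
(forward primer in exon 1, reverse primer in the last exon) and sequenced
with error-prone long reads. Because every read is expected to span the
whole transcript, transcript discovery reduces to deciding, per read, which
exon-exon junctions it contains and whether each intron was spliced out —
no genome alignment is needed.

**Junction k-mers.** Every ordered exon pair (i, j), i < j, is a candidate
splicing event (n(n−1)/2 events for n exons; adjacent pairs are ordinary
splicing, non-adjacent pairs are exon skipping). Each junction is
represented by k-mers that straddle the boundary with donor-side offset
o ∈ [m, k−m]: sequence = (last o nt of exon i) + (first k−o nt of exon j).
Defaults k = 24, m = 8 give 9 k-mers per junction. Offsets that would run
off a short exon are dropped; a junction with no realizable offset is an
error.

**Alternative exon-1 donors.** An alternative 5′ splice site of exon 1
(e.g. a 179-nt vs a 166-nt first-exon form) changes the donor-side sequence
of every junction leaving exon 1, so those junctions are materialized once
per donor variant. This is also what makes the variant observable at all in
primer-anchored amplicons: the differing sequence lies inside the read. The
variant is modeled as a 3′-truncation offset of exon 1
(`alt_first_exon_ends`), not as a separate exon.

**Intron tiles and anchors.** Introns are tiled with k-mers at stride 12
plus a right-aligned final tile (introns shorter than k yield one short
tile); amplicon anchors — exon-1 sequence from the forward-primer site to
the boundary shared by all donor variants, and last-exon sequence through
the reverse-primer site — are tiled the same way. Anchor hits classify a
read as full-length; tile hits drive intron-retention calls.

**Ambiguity screening.** Exact attribution requires unique k-mers: any
sequence occurring more than its single expected origin across the locus
and the catalog (junction k-mers must not occur in the locus at all; tiles
and anchors exactly once; no sequence shared between entries or equal to
another's reverse complement) is flagged and excluded from scanning, with a
warning if a junction loses all of its k-mers. Exclusion rather than
down-weighting keeps every call explainable.

## Scanning and per-read chaining

Reads are scanned in both orientations; the orientation with more hits wins
(ties → forward). Matching is exact substring search at `max_edits = 0` and
bounded edit-distance (edlib, infix mode) otherwise. The default
`max_edits = 2` per 24-mer is what makes the method work at nanopore error
rates: with ~6% per-base errors an exact 24-mer survives only
≈ 0.94²⁴ ≈ 23% of the time, capping per-junction sensitivity so low that
full-length chains would essentially never assemble, while two allowed
edits raise per-junction detection to ≈ 0.8 and per-read full-chain
recovery to ≈ 0.3–0.7. Exact mode is retained both as an oracle-checkable
reference and for error-free data.

A junction is called within a read when ≥ `min_offsets` (default 2; capped
at the number of available k-mers) distinct offsets hit. An intron is
called retained when ≥ 80% of its tiles hit **and** its spliced junction
(i, i+1) is absent — a read cannot contain both the spliced boundary and
the retained intron, so their co-occurrence marks the read as conflicted.
Conflicts (two acceptors for one donor, colliding exon-1 donor variants,
junction order violating read collinearity, assertions that cannot form one
increasing chain) are data, not errors: conflicted reads are counted and
excluded from calling.

Structure reconstruction walks the adjacency assertions from exon 1 to the
last exon; a junction (i, j) asserts i and j adjacent in the mature mRNA, a
retention call asserts i, i+1 adjacent with the intron kept. Any gap —
e.g. anchors present but an interior junction undetected — makes the read
unresolvable (`None`) rather than guessed. Partial (unanchored) reads never
create variants.

## Calling and naming

Resolvable full-length reads are grouped by identical structure key
(chain, retentions, exon-1 variant). Annotated matches keep their names.
Novel groups need pooled support ≥ `min_support` (default 3 — "multiple
reads" made concrete; support is pooled across samples) and are numbered
continuing after the annotated count, ordered deterministically (more exons
first, then lexicographic chain, retention set, donor variant) so identical
evidence in any order yields identical names. Sub-threshold groups are
preserved in a low-support table for auditing. An optional name map can
impose an externally published numbering.

## ORF and NMD classification

All forward-frame ATG→stop spans with an in-frame stop and ≥ `min_len_aa`
(default 25 aa — comfortably below every published RAS isoform at 76–189 aa
while still catching smORFs) are candidates. If any candidate starts at the
annotated initiation codon mapped through the structure, the 5′-most such
ORF wins; otherwise the longest (alternative-initiation case). The stop is
premature when it lies > `nmd_threshold` (default 50) nt upstream of the
last exon-exon junction — the standard exon-junction-complex rule; the
boundaries of a retained intron are not junctions (no splicing, no EJC), so
retention locally disables the rule. NMD candidates are reported as
effectively non-coding. Coding products < 100 aa are flagged micropeptides.

## Quantification

Counts are raw full-length supporting reads per variant and sample;
unassigned full-length reads go to a diagnostics row excluded from
normalization. Size factors follow the median-of-ratios convention used by
DESeq2 (geometric-mean reference over variants positive in all samples;
factor = median ratio; verified to 1e-9 against an independent DESeq2 run
on a fixed 5×3 matrix). Note that scaling one sample by c rescales the
geometric-mean reference by c^(1/S), so individual factors shift by that
global constant while factor ratios — and hence all relative abundances —
scale exactly. log2FC compares each novel variant to the pooled annotated
transcripts of its gene with pseudocount 0.5 (`denominator="max"` uses the
single most abundant annotated transcript instead). The heatmap uses a
red-high / blue-low diverging scale centered at 0.

## The synthetic generator and what it does (not) show

The generator emulates: full-length amplicon reads of planted structures,
uniform per-base substitution (1.5%), insertion (2%) and deletion (2.5%)
errors — a ~6% total, R9.4.1-like regime — random read orientation, 5%
end-truncation up to 150 nt, constant placeholder qualities, multi-sample
designs with per-variant abundances, and exact per-read/per-sample ground
truth. Loci are uniform-random sequence, rejection-sampled (≤ 100 draws)
until the default-k catalog is collision-free.

It does **not** emulate: realistic coding content (random sequence has a
stop about every 21 codons, so synthetic ORFs are short and NMD labels on
synthetic transcripts are arbitrary — ORF semantics are instead tested on
constructed mRNAs and, where available, the deposited reference cDNAs),
sequence-context-dependent error hotspots (homopolymers), PCR chimeras
beyond what the conflict rule is tested with, quality-score information, or
genomic repeats (real genes may need a larger k than random loci).
Recovery results on the preset therefore demonstrate the detection and
quantification machinery under controlled error rates, not performance on
any particular real locus.

The RAS-like preset fixes three models (6/7/7 exons, exon lengths mirroring
the real gene topologies, a 13-nt exon-1 donor variant on the KRAS-like
gene, retention of intron 6 on the HRAS-like gene) with fixed layout seeds,
and plants a representative subset of the published splicing patterns
(single and multi-exon skips, donor-variant pairs, retention pairs). Study
conditions used by the acceptance checks: error-free at coverage 50× and
nanopore-like at 6% error, coverage 20×, both over 3 samples with support
pooled; the noisy check aggregates 10 seeds.

## Numerical and design notes

- Internal coordinates are 0-based half-open on the forward genomic strand;
  GFF3 I/O converts to/from 1-based inclusive. '-'-strand genes are handled
  by reverse-complementing at sequence-extraction time; exon ranks always
  follow transcription order.
- The reverse primer is stored 5′→3′ on the antisense strand and matched as
  its reverse complement; each primer must occur exactly once in its target
  exon, else anchoring is ambiguous and refused.
- Naming ties, grouping and catalog construction contain no randomness;
  the only RNG in the package is the simulator's, seeded mandatorily.
- log2FC is implemented as the log-ratio of normalized abundances (novel vs
  pooled annotated). The pseudocount (0.5) makes zero counts well-defined:
  a zero-count novel against a normalized annotated sum of 127.5 gives
  log2(0.5/128) = −8 exactly.
- Degenerate inputs: introns shorter than k get one short tile; exons
  shorter than the minimum flank lose only the unrealizable offsets; a
  sample with zero full-length reads yields a zero column and a warning;
  an all-zero count matrix (no variant positive in every sample) makes MRN
  factors undefined and raises rather than guessing.
- KRAS v.19/v.20 and a few annotated HRAS/NRAS structures in the registry
  are marked `reconstructed`: their published descriptions do not pin down
  the exact chains, so plausible structures are encoded and excluded from
  assertions.

## Limitations

- Detection is catalog-bound: events between unannotated boundaries
  (cryptic exons, exon extensions) surface only as intronic tile clusters,
  not as assembled new exons.
- Reads must span first to last exon; degraded or internally primed
  material is counted but never called.
- The retention rule needs most of an intron present; partial retentions
  below the 80% tile threshold are missed.
- Quantification inherits amplicon biases (PCR length/efficiency effects);
  MRN corrects depth, not amplification preference, and no cross-sample
  differential test is provided.
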