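# Methods

## Coordinate model

All internal coordinates are 0-based, half-open, converted only at format
boundaries (GTF and VCF are 1-based inclusive on disk; BedGraph is natively
0-based half-open). A transcript stores its exons as genomic intervals
ordered 5′→3′ in transcript orientation; `cds_start_genomic` /
`cds_stop_genomic` are the genomic positions of the *first base* of the
start / stop codon in transcript orientation (on the minus strand this is
the highest genomic coordinate of the codon). A read's 5′ end is its first
*aligned* base — soft-clipped bases are ignored — and on the minus strand
the rightmost aligned base. Multimapping multiplicity comes from the `NH`
tag (assumed 1 when absent); each alignment of a multimapper counts with
full weight 1. Fractional weighting was considered and rejected: it changes
library-size normalization downstream and real pipelines of this kind count
alignments, not reads; the choice is isolated in `read_alignments` should a
sensitivity analysis want the alternative.

## P-site offsets

Offsets are calibrated per read length by a start-codon metagene:
`d(L) = argmax_{d ∈ [d_min, d_max]} #{reads of length L whose 5′ end lies
exactly d nt 5′ of an annotated start-codon first base}`, ties broken
toward the smaller d, search range 8–18 nt (typical RPF geometry). Lengths
with fewer than `min_support = 50` metagene reads fall back to the default
offset 12 and are flagged. The exact windowing/normalization of published
offset tools varies; this argmax form is deliberately simple, fully
specified here, and pinned by tests. It presumes the initiation pause
visible in real elongating libraries: the start codon must be locally
over-represented relative to any single interior codon, otherwise the
metagene is ambiguous modulo 3. The synthetic generator reproduces that
pause (see below).

## Translated-transcript calling

Exon coverage is mean P-site density (reads/nt); the alternative
(fraction-of-bases-covered) was rejected because P-sites are intrinsically
punctate — one site per 3 nt even at saturation. An exon passes when its
density strictly exceeds `cov_threshold`; a transcript is translated when
≥ 85% of its exons pass. The threshold is not a fixed constant of the
method: it is a required, logged parameter (default 0.1 reads/nt). Strict
`>` at the exon level with `≥` at the 85% level pins the 6-of-7-exon case
(0.857) as translated. Adding counts can only raise densities, so calling
is monotone.

## TIS calling

Candidates are all positions of the spliced transcript whose codon is ATG
or one substitution away (CTG, GTG, TTG, ACG, AGG, AAG, ATA, ATC, ATT),
annotated as aTIS / 5UTR / CDS / 3UTR relative to the annotated CDS, or
ntr on transcripts without one. Three rules, all required:

1. raw initiating-library count `x_LTM ≥ min_count` (default 5);
2. local maximum: no candidate within ±7 nt on the same transcript has a
   higher `x_LTM` (equal counts: the 5′-most wins);
3. normalized excess `r_LTM − r_CHX ≥ min_r_delta` with
   `r = x / library_size × 10⁶` (default 0.01 per million).

Rule 3 is invariant under joint rescaling of both libraries. Calling is
restricted to transcripts already called translated (which includes
covered non-coding transcripts). Without an initiating library the module
is skipped and externally generated databases can be merged in instead.
These rule shapes and defaults are configuration, logged per run — not
empirical claims; they are pinned by tests against planted truth.

## SNV calling

A hand-rolled pileup (CIGAR walk; soft clips excluded; reads with
insertions/deletions skipped with a warning — indels are out of scope) and
two thresholds: depth ≥ 10 and top non-reference allele frequency ≥ 0.3,
one variant per position. Calls are deterministic and independent of read
order; allele ties break alphabetically. No external known-sites filtering
is performed (the pipeline is network-free); the VCF writer makes the calls
available to external annotation if wanted.

## Assembly

Translation uses the standard code with two deviations. (1) The initiator
codon always yields Met, including near-cognate starts. (2) On transcripts
annotated as selenoproteins, in-frame TGA strictly 5′ of the annotated stop
is recoded to U; at or beyond the annotated stop TGA terminates again. ORFs
that run off the transcript end are kept and flagged `no_stop` (they still
yield usable tryptic peptides). Minimum entry length is 6 aa.

Variants are applied **all at once** per transcript — one variant entry per
TIS rather than the 2^k combinatorial enumeration — with per-SNP
protein-space (position, ref, alt) retained for PEFF. Synonymous-only
variant sets produce no extra entry. A stop-gaining SNV yields a shortened
variant entry flagged `stop_shift` (such entries cannot be expressed as
`\VariantSimple` and stay separate in PEFF).

## Export and the code system

Accessions are `generic|<transcript>_<tisIndex>[v]_<mask>|<gene>` with the
source bitmask classic=1, price=2, spectre=4, uniprot_sp=8, uniprot_tr=16;
`parse_accession` inverts the writer exactly. Merging identical sequences
ORs masks and reports Venn cells that partition the distinct sequences.
Redundancy removal has two modes: exact duplicates only, or (default)
duplicate collapse plus suffix absorption within a gene, where the
initiator M is treated as a wildcard at the junction (a truncation starting
at internal codon X translates X→M, so `MAB` is absorbed by `MXXAB`).
Reference fusion counts a sequence as overlapping when identical or
identical after stripping either side's initiator Met. Writers sort their
output and are deterministic. PEFF output follows PEFF 1.0: header block
with `DbName/Prefix/NumberOfEntries/SequenceType`, one entry per base
proteoform, SAVs as `\VariantSimple=(pos|alt)` applied against the entry's
own sequence.

## Classification

The proteoform taxonomy is implemented as a total function via a fixed
cascade (first match wins): non-coding biotype (subcategory pseudogene /
lincRNA / other) → uORF (5′UTR start whose stop precedes the CDS) → dORF
(3′UTR start) → out-of-frame (start offset from the annotated frame) →
terminal comparison against same-gene reference proteins
(extension/truncation by which terminus differs, initiator-M-adjusted,
ungapped) → SAV-only (equal length, 1–5 substitutions) → splice variant
(internal block not reachable by end-trimming plus ≤ 5 substitutions;
subcategory exon_skip for a clean internal deletion, novel_junction for an
insertion, else other). Candidates with no same-gene reference are labeled
from their TIS class alone and flagged low-confidence. Biotype is checked
before geometry before sequence because it is the least ambiguous evidence.

## Share arithmetic

`compute_share` rounds half-up (47/4477 → 1.05%). `redundancy_increase`
truncates to two decimals (119716 vs 76945 → 55.58%): the two published
conventions differ, and each function follows the convention its printed
examples use.

## Synthetic data

The generator emulates: multi-exon gene models on both strands (Ensembl
GTF dialect, including the `seleno` tag); elongating footprints whose
5′ ends sit the planted length-specific offset upstream of uniformly
sampled CDS codons, with a 5× initiation-pause weight on the start codon;
initiating footprints exactly at planted TISs; read lengths 28/29/30 at
0.6/0.3/0.1 with offsets {28:12, 29:12, 30:13} (typical mammalian values);
an optional jitter fraction moving 5′ ends ±1 nt; heterozygous SNVs edited
into read sequences at a target allele frequency (alignments unchanged).
Reads are ungapped genomic alignments — footprints never span introns —
which matches the genomic-linear offset arithmetic of the calibrator.

It does **not** emulate sequencing error, rRNA contamination, codon-level
dwell-time variation, overlapping genes, or mapping ambiguity. Passing
tests therefore demonstrate correctness of the calling rules and the
bookkeeping under the stated signal model, not robustness to real-library
noise; the jitter and allele-frequency parameters probe the first-order
deviations only.

Scenario sizes were chosen to exercise every code path at comfortable
statistical margins: ~10 transcripts × 2,000 elongating reads for the
category scenario, 4 × 5,000 reads at 10% jitter for offset recovery, and
50 planted TISs at 100 initiating reads each. The whole suite runs in a few
seconds.

## Known limitations

- No indel handling anywhere (explicitly out of scope).
- One variant entry per TIS; co-occurring SNVs are never enumerated
  separately.
- Terminal classification is ungapped; a proteoform that is simultaneously
  extended and substituted beyond the junction will fall through to the
  splice-variant branch.
- The offset calibrator requires an initiation pause or an initiating
  library; on perfectly uniform elongating coverage the offset is
  identifiable only modulo 3.
- BedGraph export writes one file per strand; viewers that want a single
  signed track need to combine them.
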