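"""Proteoform assembly: from called TISs and SNPs to amino-acid sequences.

Each passed initiation site yields one candidate translation product from
the spliced transcript sequence.  Near-cognate initiators are translated
as methionine.  On selenoprotein transcripts, in-frame UGA upstream of the
annotated stop is recoded to selenocysteine (U).  Called SNVs are applied
all-at-once per transcript, producing at most one additional variant entry
per TIS with its single-amino-acid variants recorded in protein space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from riboforge.ribo_io import Transcript, AnnotationBoundsError
from riboforge.db_export import make_accession

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard nuclear genetic code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class EmptyOrfError(ValueError):
    pass


class VariantConsistencyError(ValueError):
    pass


@dataclass
class ProteoformEntry:
    """One candidate database record: a sequence with full provenance."""

    accession: str
    sequence: str
    transcript_id: str
    gene_id: str
    tis_gpos: int
    tis_tpos: int
    tis_index: int
    codon: str
    annotation_class: str
    is_variant: bool = False
    variants_applied: list[tuple[int, str, str]] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    source_mask: int = 1
    orf_stop_tpos: int | None = None   # first base of the stop codon, if any

    def __post_init__(self) -> None:
        if not self.sequence or self.sequence[0] != "M":
            raise ValueError("proteoform sequence must be non-empty and start with M")
        if "*" in self.sequence:
            raise ValueError("proteoform sequence must not contain internal stops")


def spliced_sequence(transcript: Transcript, genome: dict[str, str]
                     ) -> tuple[str, list[int]]:
    """Concatenate exon sequences in transcript orientation.

    Returns (sequence, map) with ``map[tpos] == genomic position`` — a
    bijection over spliced positions.  Minus-strand exons are
    reverse-complemented.
    """
    chrom_seq = genome[transcript.chrom]
    parts: list[str] = []
    gmap: list[int] = []
    for (s, e) in transcript.exons:
        if s < 0 or e > len(chrom_seq):
            raise AnnotationBoundsError(
                f"exon [{s},{e}) outside chromosome {transcript.chrom}")
        block = chrom_seq[s:e].upper()
        if transcript.strand == "+":
            parts.append(block)
            gmap.extend(range(s, e))
        else:
            parts.append(block.translate(_COMPLEMENT)[::-1])
            gmap.extend(range(e - 1, s - 1, -1))
    return "".join(parts), gmap


def translate_orf(spliced_seq: str, tis_tpos: int, seleno: bool = False,
                  annotated_stop_tpos: int | None = None
                  ) -> tuple[str, bool, int | None]:
    """Translate from a TIS to the first stop (or sequence end).

    The initiator codon yields M even when near-cognate.  With ``seleno``,
    in-frame TGA 5' of ``annotated_stop_tpos`` is recoded to U; at or past
    the annotated stop, TGA terminates again.  Returns
    (aa sequence, no_stop flag, stop codon tpos or None).
    """
    if tis_tpos < 0 or tis_tpos + 3 > len(spliced_seq):
        raise EmptyOrfError("TIS within 3 nt of the sequence end")
    aas: list[str] = []
    pos = tis_tpos
    while pos + 3 <= len(spliced_seq):
        codon = spliced_seq[pos:pos + 3]
        if pos == tis_tpos:
            aas.append("M")
        elif codon in STOP_CODONS:
            if (codon == "TGA" and seleno and annotated_stop_tpos is not None
                    and pos < annotated_stop_tpos):
                aas.append("U")
            else:
                return "".join(aas), False, pos
        else:
            aas.append(CODON_TABLE.get(codon, "X"))
        pos += 3
    return "".join(aas), True, None


def apply_variants(spliced_seq: str, tvariants: list[tuple[int, str, str]]) -> str:
    """Apply all transcript-space SNVs (tpos, ref, alt) at once."""
    seq = list(spliced_seq)
    for (tp, ref, alt) in tvariants:
        if seq[tp] != ref:
            raise VariantConsistencyError(
                f"variant ref {ref!r} disagrees with transcript base {seq[tp]!r} at {tp}")
        seq[tp] = alt
    return "".join(seq)


def variants_to_transcript_space(transcript: Transcript, variants
                                 ) -> list[tuple[int, str, str]]:
    """Project genomic SNVs onto a transcript; minus strand complements alleles."""
    out = []
    for v in variants:
        if v.chrom != transcript.chrom:
            continue
        tp = transcript.genomic_to_transcript(v.pos)
        if tp is None:
            continue
        ref, alt = v.ref_base, v.alt_base
        if transcript.strand == "-":
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        out.append((tp, ref, alt))
    return sorted(out)


def assemble(tis_calls, variants, transcripts: list[Transcript],
             genome: dict[str, str], min_length: int = 6,
             source_mask: int = 1) -> list[ProteoformEntry]:
    """Build one ProteoformEntry per passed TIS, plus one variant entry per
    TIS whose transcript carries nonsynonymous SNVs inside the ORF.

    Ordering is deterministic: (transcript_id, TIS transcript position,
    variant status).  Entries shorter than ``min_length`` aa are dropped.
    """
    tmap = {t.transcript_id: t for t in transcripts}
    passed = [c for c in tis_calls if c.passed_rules]
    by_t: dict[str, list] = {}
    for c in passed:
        by_t.setdefault(c.transcript_id, []).append(c)

    entries: list[ProteoformEntry] = []
    for tid in sorted(by_t):
        t = tmap[tid]
        seq, _gmap = spliced_sequence(t, genome)
        stop_t = (t.genomic_to_transcript(t.cds_stop_genomic)
                  if t.cds_stop_genomic is not None else None)
        tvars = variants_to_transcript_space(t, variants)
        vseq = apply_variants(seq, tvars) if tvars else None
        for idx, call in enumerate(sorted(by_t[tid], key=lambda c: c.tpos), start=1):
            aa, no_stop, orf_stop = translate_orf(seq, call.tpos, t.seleno, stop_t)
            if len(aa) < min_length:
                continue
            flags = {}
            if no_stop:
                flags["no_stop"] = True
            n_u = aa.count("U")
            if n_u:
                flags["seleno_recoded"] = n_u
            entry = ProteoformEntry(
                accession="", sequence=aa, transcript_id=tid, gene_id=t.gene_id,
                tis_gpos=call.genomic_pos, tis_tpos=call.tpos, tis_index=idx,
                codon=call.codon, annotation_class=call.annotation_class,
                is_variant=False, flags=flags, source_mask=source_mask,
                orf_stop_tpos=orf_stop)
            entry.accession = make_accession(entry)
            entries.append(entry)
            if vseq is None:
                continue
            vaa, v_no_stop, v_stop = translate_orf(vseq, call.tpos, t.seleno, stop_t)
            if vaa == aa or len(vaa) < min_length:
                if vaa == aa and tvars:
                    entry.flags["synonymous_snps"] = len(
                        [tv for tv in tvars if call.tpos <= tv[0]])
                continue
            savs = [(i + 1, aa[i], vaa[i])
                    for i in range(min(len(aa), len(vaa))) if aa[i] != vaa[i]]
            vflags = {}
            if v_no_stop:
                vflags["no_stop"] = True
            if vaa.count("U"):
                vflags["seleno_recoded"] = vaa.count("U")
            if len(vaa) != len(aa):
                vflags["stop_shift"] = True
            ventry = ProteoformEntry(
                accession="", sequence=vaa, transcript_id=tid, gene_id=t.gene_id,
                tis_gpos=call.genomic_pos, tis_tpos=call.tpos, tis_index=idx,
                codon=call.codon, annotation_class=call.annotation_class,
                is_variant=True, variants_applied=savs, flags=vflags,
                source_mask=source_mask, orf_stop_tpos=v_stop)
            ventry.accession = make_accession(ventry)
            entries.append(ventry)
    return entries
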