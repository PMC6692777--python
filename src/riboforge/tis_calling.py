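"""Classic-method translation initiation site (TIS) calling.

Candidate start codons (ATG plus all near-cognates one substitution away)
are scanned over the spliced sequence of each transcript in the calling
set.  A candidate is called initiating when the initiating (LTM) P-site
profile shows a supported local maximum at its first base that clearly
exceeds the elongating (CHX) background after library-size normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from riboforge.ribo_io import PsiteTrack, Transcript
from riboforge.assembly import spliced_sequence

# ATG and every 3-mer one substitution away from it
NEAR_COGNATE_SET = frozenset({
    "ATG", "CTG", "GTG", "TTG", "ACG", "AGG", "AAG", "ATA", "ATC", "ATT"})


class NormalizationError(ValueError):
    pass


@dataclass
class TisParams:
    min_count: int = 5          # rule 1: raw LTM P-site count floor
    local_max_window: int = 7   # rule 2: +/- nt window for the local maximum
    min_r_delta: float = 0.01   # rule 3: normalized LTM - CHX excess (per million)


@dataclass
class Candidate:
    transcript_id: str
    chrom: str
    strand: str
    tpos: int
    genomic_pos: int
    codon: str
    annotation_class: str


@dataclass
class TisCall:
    transcript_id: str
    genomic_pos: int
    tpos: int
    codon: str
    annotation_class: str
    x_ltm: int
    x_chx: int
    r_ltm: float
    r_chx: float
    passed_rules: bool
    failed: list[str] = field(default_factory=list)


def scan_candidates(transcript: Transcript, genome: dict[str, str],
                    codon_set=NEAR_COGNATE_SET) -> list[Candidate]:
    """Return every spliced position whose codon is in ``codon_set``.

    Annotation class: aTIS at the annotated start, 5UTR / CDS / 3UTR
    relative to the annotated CDS, ntr on transcripts without one.
    """
    seq, _gmap = spliced_sequence(transcript, genome)
    cds_t = stop_t = None
    if transcript.cds_start_genomic is not None:
        cds_t = transcript.genomic_to_transcript(transcript.cds_start_genomic)
        if transcript.cds_stop_genomic is not None:
            stop_t = transcript.genomic_to_transcript(transcript.cds_stop_genomic)
    out = []
    for i in range(len(seq) - 2):
        codon = seq[i:i + 3]
        if codon not in codon_set:
            continue
        if cds_t is None:
            cls = "ntr"
        elif i == cds_t:
            cls = "aTIS"
        elif i < cds_t:
            cls = "5UTR"
        elif stop_t is None or i < stop_t:
            cls = "CDS"
        else:
            cls = "3UTR"
        out.append(Candidate(
            transcript_id=transcript.transcript_id, chrom=transcript.chrom,
            strand=transcript.strand, tpos=i,
            genomic_pos=transcript.transcript_to_genomic(i),
            codon=codon, annotation_class=cls))
    return out


def call_tis(candidates: list[Candidate], track_ltm: PsiteTrack,
             track_chx: PsiteTrack, params: TisParams | None = None
             ) -> list[TisCall]:
    """Apply the three classic calling rules to every candidate.

    1. raw LTM count >= min_count;
    2. the candidate is the LTM local maximum among candidates within
       +/- local_max_window nt on the same transcript (ties: 5'-most wins);
    3. normalized excess r_ltm - r_chx >= min_r_delta, with
       r = count / library_size * 1e6.
    """
    params = params or TisParams()
    if track_ltm.library_size == 0 or track_chx.library_size == 0:
        raise NormalizationError("cannot normalize against an empty library")
    by_t: dict[str, list[Candidate]] = {}
    for c in candidates:
        by_t.setdefault(c.transcript_id, []).append(c)

    calls: list[TisCall] = []
    for tid, cands in sorted(by_t.items()):
        cands = sorted(cands, key=lambda c: c.tpos)
        xs = [track_ltm.get(c.chrom, c.strand, c.genomic_pos) for c in cands]
        for i, c in enumerate(cands):
            x_ltm = xs[i]
            x_chx = track_chx.get(c.chrom, c.strand, c.genomic_pos)
            r_ltm = x_ltm / track_ltm.library_size * 1e6
            r_chx = x_chx / track_chx.library_size * 1e6
            failed = []
            if x_ltm < params.min_count:
                failed.append("min_count")
            for j, other in enumerate(cands):
                if j == i or abs(other.tpos - c.tpos) > params.local_max_window:
                    continue
                if xs[j] > x_ltm or (xs[j] == x_ltm and other.tpos < c.tpos):
                    failed.append("local_max")
                    break
            if r_ltm - r_chx < params.min_r_delta:
                failed.append("r_delta")
            calls.append(TisCall(
                transcript_id=tid, genomic_pos=c.genomic_pos, tpos=c.tpos,
                codon=c.codon, annotation_class=c.annotation_class,
                x_ltm=x_ltm, x_chx=x_chx, r_ltm=r_ltm, r_chx=r_chx,
                passed_rules=not failed, failed=failed))
    return calls
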