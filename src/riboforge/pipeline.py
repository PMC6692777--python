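"""End-to-end orchestration: alignments in, proteoform database out.

Stage order mirrors the analysis: offset calibration -> P-site tracks ->
translated-transcript calling -> TIS calling (LTM vs CHX) -> SNP calling ->
proteoform assembly.  All stage parameters are explicit and logged with the
run so every call is reproducible from the results database alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from riboforge import ribo_io
from riboforge.psite import OffsetTable, calibrate_offsets, build_psite_track
from riboforge.transcript_calling import call_translated
from riboforge.tis_calling import NEAR_COGNATE_SET, TisParams, call_tis, scan_candidates
from riboforge.variant_calling import call_snps, pileup
from riboforge.assembly import assemble


@dataclass
class PipelineParams:
    cov_threshold: float = 0.1     # reads/nt per exon for transcript calling
    exon_fraction: float = 0.85
    d_min: int = 8
    d_max: int = 18
    min_support: int = 50
    default_offset: int = 12
    tis: TisParams = field(default_factory=TisParams)
    snp_min_depth: int = 10
    snp_min_af: float = 0.3
    min_orf_length: int = 6
    unique_only: bool = False
    max_hits: int = 16


@dataclass
class PipelineResult:
    offsets: OffsetTable
    track_chx: ribo_io.PsiteTrack
    track_ltm: ribo_io.PsiteTrack
    transcript_calls: list
    tis_calls: list
    variants: list
    entries: list


def run_pipeline(genome: dict[str, str], transcripts, chx_sam: str,
                 ltm_sam: str | None, params: PipelineParams | None = None,
                 store: ribo_io.ResultsStore | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run the full calling chain from SAM files to proteoform entries.

    Without an LTM sample the initiating profile is unavailable and TIS
    calling (hence assembly) is skipped; candidate databases from external
    callers can be merged in downstream instead.
    """
    params = params or PipelineParams()
    chx_reads = ribo_io.read_alignments(chx_sam, params.unique_only, params.max_hits)
    ltm_reads = (ribo_io.read_alignments(ltm_sam, params.unique_only, params.max_hits)
                 if ltm_sam else [])

    offsets = calibrate_offsets(chx_reads + ltm_reads, transcripts,
                                params.d_min, params.d_max,
                                params.min_support, params.default_offset)
    track_chx = build_psite_track(chx_reads, offsets)
    tcalls = call_translated(track_chx, transcripts, params.cov_threshold,
                             params.exon_fraction)
    translated_ids = {c.transcript_id for c in tcalls if c.translated}

    tis_calls, entries, variants = [], [], []
    track_ltm = ribo_io.PsiteTrack()
    if ltm_reads:
        track_ltm = build_psite_track(ltm_reads, offsets)
        candidates = []
        for t in transcripts:
            if t.transcript_id in translated_ids:
                candidates.extend(scan_candidates(t, genome, NEAR_COGNATE_SET))
        tis_calls = call_tis(candidates, track_ltm, track_chx, params.tis)
        counts = pileup(chx_sam, params.max_hits)
        variants = call_snps(counts, genome, params.snp_min_depth, params.snp_min_af)
        entries = assemble(tis_calls, variants, transcripts, genome,
                           params.min_orf_length)

    if store is not None:
        p = asdict(params)
        store.new_run(seed=seed, params=p)
        store.save_transcripts(transcripts)
        store.save_transcript_calls(tcalls)
        store.save_tis_calls(tis_calls)
        store.save_snps(variants)
        store.save_proteoforms(entries)

    return PipelineResult(offsets=offsets, track_chx=track_chx,
                         track_ltm=track_ltm, transcript_calls=tcalls,
                         tis_calls=tis_calls, variants=variants, entries=entries)
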