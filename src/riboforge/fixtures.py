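"""Synthetic ribosome-profiling fixtures with planted, machine-readable ground truth.

Generates a small genome, Ensembl-dialect annotation, CHX (elongating) and
LTM (initiating) alignments, a reference proteome and MaxQuant-style result
tables, entirely in memory and fully determined by a seed.  Every planted
feature — translation initiation sites, SNPs, per-length P-site offsets,
the translated transcript set and the expected proteoform database — is
recorded in a :class:`TruthManifest` so downstream stages can be verified
against construction-time truth.

What the generator emulates: 3-nt periodic elongating footprints whose 5'
ends sit a fixed, length-specific distance upstream of the decoded codon;
initiating footprints piling only at start codons; allele-frequency-driven
mismatches in read sequences.  What it does not emulate: sequencing error,
rRNA contamination, uneven codon dwell times, intron-spanning footprints.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from Bio.Seq import Seq

from riboforge.ribo_io import Transcript, gtf_to_text

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# sense codons used as random CDS filler (no stops, no ATG/near-cognates to
# keep planted start-codon neighbourhoods unambiguous is NOT required, but
# stops must never appear in frame 0)
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_SENSE_CODONS = sorted(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)


class SizingError(ValueError):
    """A chromosome is too short to host its requested transcripts."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExtraTis:
    """A non-annotated initiation site to plant on a transcript.

    kind: one of extension (in-frame 5'UTR start running into the CDS),
    uorf (self-contained ORF inside the 5'UTR), truncation (in-frame CDS
    start), out_of_frame (CDS start shifted +1 nt), dorf (ORF in the
    3'UTR), ntr_orf (ORF on a non-coding transcript).
    """

    kind: str
    codon: str = "ATG"
    upstream_nt: int = 9      # extension: nt 5' of the annotated start (multiple of 3)
    codon_index: int = 10     # truncation / out_of_frame: CDS codon index
    orf_codons: int = 6       # uorf / dorf / ntr_orf: aa after the initiator M
    offset_nt: int = 0        # uorf / dorf / ntr_orf: placement inside its region


@dataclass
class SnpSpec:
    codon_index: int
    target_af: float = 0.5
    synonymous: bool = False


@dataclass
class TranscriptSpec:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str = "+"
    biotype: str = "protein_coding"
    coding: bool = True
    n_exons: int = 3
    n_codons: int = 40        # protein length in aa (incl. initiator M)
    utr5: int = 30
    utr3: int = 30
    seleno: bool = False
    translated: bool = True
    extra_tis: list[ExtraTis] = field(default_factory=list)
    snps: list[SnpSpec] = field(default_factory=list)


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int]
    transcripts: list[TranscriptSpec]
    read_lengths: dict[int, float] = field(default_factory=lambda: {28: 0.6, 29: 0.3, 30: 0.1})
    offsets: dict[int, int] = field(default_factory=lambda: {28: 12, 29: 12, 30: 13})
    jitter: float = 0.0       # fraction of 5' ends displaced +/-1 nt
    init_pause: int = 5       # initiation-pause weight of the start codon in CHX
    intron_length: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["transcripts"] = [
            TranscriptSpec(
                **{**t,
                   "extra_tis": [ExtraTis(**e) for e in t.get("extra_tis", [])],
                   "snps": [SnpSpec(**s) for s in t.get("snps", [])]})
            for t in raw["transcripts"]
        ]
        raw["read_lengths"] = {int(k): v for k, v in raw.get("read_lengths", {28: 0.6, 29: 0.3, 30: 0.1}).items()}
        raw["offsets"] = {int(k): v for k, v in raw.get("offsets", {28: 12, 29: 12, 30: 13}).items()}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    """Construction-time ground truth for one generated scenario."""

    planted_tis: list[dict]          # transcript_id, tpos, genomic_pos, codon, tclass, kind
    planted_snps: list[dict]         # chrom, pos (0-based, fwd), ref, alt, target_af, synonymous
    planted_offsets: dict[int, int]
    planted_translated: list[str]
    expected_proteome: list[dict]    # transcript_id, tis_tpos, tclass, variant, sequence, savs
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        raw["planted_offsets"] = {int(k): v for k, v in raw["planted_offsets"].items()}
        return cls(**raw)


@dataclass
class Scenario:
    """In-memory handle on a generated reference: genome, models and truth."""

    genome: dict[str, str]
    transcripts: list[Transcript]
    manifest: TruthManifest
    config: SimConfig


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _build_spliced(spec: TranscriptSpec, rng: np.random.Generator):
    """Design the spliced transcript sequence and all planted features on it.

    Returns (seq, cds_tpos|None, stop_tpos|None, planted list of
    (tpos, codon, tclass, kind), snp list of (tpos, ref, alt, af, synonymous)).
    """
    planted: list[tuple[int, str, str, str]] = []
    snps: list[tuple[int, str, str, float, bool]] = []

    if spec.coding:
        cds_nt = 3 * spec.n_codons
        body = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(spec.n_codons - 1)]
        if spec.seleno:
            body[spec.n_codons // 2] = "TGA"
        cds = "".join(body) + "TAA"
        utr5 = "".join(rng.choice(list(_BASES), size=spec.utr5))
        utr3 = "".join(rng.choice(list(_BASES), size=spec.utr3))
        seq = list(utr5 + cds + utr3)
        cds_t = spec.utr5
        stop_t = cds_t + cds_nt
        planted.append((cds_t, "ATG", "aTIS", "atis"))
    else:
        total = spec.utr5 + 3 * spec.n_codons + spec.utr3
        seq = list("".join(rng.choice(list(_BASES), size=total)))
        cds_t = stop_t = None

    def put(pos: int, sub: str) -> None:
        seq[pos:pos + len(sub)] = list(sub)

    for et in spec.extra_tis:
        if et.kind == "extension":
            if et.upstream_nt % 3 or et.upstream_nt > spec.utr5:
                raise ValueError("extension upstream_nt must be an in-frame distance within the 5'UTR")
            t = cds_t - et.upstream_nt
            put(t, et.codon)
            for j in range(t + 3, cds_t, 3):     # keep the linking codons sense
                put(j, "GCT")
            planted.append((t, et.codon, "5UTR", "extension"))
        elif et.kind == "uorf":
            t = et.offset_nt
            cassette = et.codon + "GCT" * et.orf_codons + "TAG"
            if t + len(cassette) > spec.utr5:
                raise SizingError("uORF cassette does not fit in the 5'UTR")
            put(t, cassette)
            planted.append((t, et.codon, "5UTR", "uorf"))
        elif et.kind == "truncation":
            t = cds_t + 3 * et.codon_index
            put(t, et.codon)
            planted.append((t, et.codon, "CDS", "truncation"))
        elif et.kind == "out_of_frame":
            # +1 frameshifted start; cassette length 20 ends flush before a
            # frame-0 codon boundary so downstream CDS codons stay intact,
            # and its 'GC' tail reads Ala in the shifted frame
            t = cds_t + 3 * et.codon_index + 1
            put(t, et.codon + "GCT" * 5 + "GC")
            planted.append((t, et.codon, "CDS", "out_of_frame"))
        elif et.kind == "dorf":
            t = stop_t + 3 + et.offset_nt
            cassette = et.codon + "GCT" * et.orf_codons + "TAA"
            if t + len(cassette) > len(seq):
                raise SizingError("dORF cassette does not fit in the 3'UTR")
            put(t, cassette)
            planted.append((t, et.codon, "3UTR", "dorf"))
        elif et.kind == "ntr_orf":
            t = et.offset_nt
            cassette = et.codon + "GCT" * et.orf_codons + "TAA"
            if t + len(cassette) > len(seq):
                raise SizingError("ORF cassette does not fit on the transcript")
            put(t, cassette)
            planted.append((t, et.codon, "ntr", "ntr_orf"))
        else:
            raise ValueError(f"unknown ExtraTis kind {et.kind!r}")

    for sp in spec.snps:
        t0 = cds_t + 3 * sp.codon_index
        put(t0, "GCT")                       # Ala reference codon
        if sp.synonymous:
            tpos, ref, alt = t0 + 2, "T", "A"   # GCT -> GCA (still Ala)
        else:
            tpos, ref, alt = t0 + 1, "C", "T"   # GCT -> GTT (Ala -> Val)
        snps.append((tpos, ref, alt, sp.target_af, sp.synonymous))

    # construction check: no stop may remain inside the CDS interior in frame 0
    if spec.coding:
        for j in range(cds_t, stop_t, 3):
            codon = "".join(seq[j:j + 3])
            if codon in _STOPS and not (spec.seleno and codon == "TGA"):
                raise AssertionError(f"planting broke the CDS of {spec.transcript_id} at {j}")

    return "".join(seq), cds_t, stop_t, planted, snps


def _exonize(length: int, n_exons: int) -> list[int]:
    base, rem = divmod(length, n_exons)
    return [base + (1 if i < rem else 0) for i in range(n_exons)]


def build_scenario(config: SimConfig) -> Scenario:
    """Construct genome, transcript models and the truth manifest in memory."""
    rng = np.random.default_rng(config.seed)
    genomes = {c: bytearray("".join(rng.choice(list(_BASES), size=n)), "ascii")
               for c, n in config.chrom_lengths.items()}
    cursors = {c: 100 for c in config.chrom_lengths}

    transcripts: list[Transcript] = []
    planted_tis: list[dict] = []
    planted_snps: list[dict] = []
    translated: list[str] = []
    spliced_cache: dict[str, tuple] = {}

    for spec in config.transcripts:
        seq, cds_t, stop_t, planted, snps = _build_spliced(spec, rng)
        chunks = _exonize(len(seq), spec.n_exons)
        span = sum(chunks) + config.intron_length * (spec.n_exons - 1)
        start = cursors[spec.chrom]
        if start + span + 100 > config.chrom_lengths[spec.chrom]:
            raise SizingError(
                f"chromosome {spec.chrom} too short for {spec.transcript_id}"
                f" (needs {start + span + 100}, has {config.chrom_lengths[spec.chrom]})")
        cursors[spec.chrom] = start + span + 200

        # genomic exons left-to-right; transcript order depends on strand
        gex: list[tuple[int, int]] = []
        pos = start
        glens = chunks if spec.strand == "+" else chunks[::-1]
        for ln in glens:
            gex.append((pos, pos + ln))
            pos += ln + config.intron_length
        exons_t = gex if spec.strand == "+" else gex[::-1]

        # write the spliced sequence into the genome
        off = 0
        for (s, e) in exons_t:
            chunk = seq[off:off + (e - s)]
            genomes[spec.chrom][s:e] = (
                chunk if spec.strand == "+" else _revcomp(chunk)).encode()
            off += e - s

        t = Transcript(
            transcript_id=spec.transcript_id, gene_id=spec.gene_id,
            chrom=spec.chrom, strand=spec.strand, biotype=spec.biotype,
            exons=exons_t, seleno=spec.seleno)
        if spec.coding:
            t.cds_start_genomic = t.transcript_to_genomic(cds_t)
            t.cds_stop_genomic = t.transcript_to_genomic(stop_t)
        transcripts.append(t)
        spliced_cache[spec.transcript_id] = (seq, cds_t, stop_t, planted, snps, spec)
        if spec.translated:
            translated.append(spec.transcript_id)
            for (tp, codon, tclass, kind) in planted:
                planted_tis.append({
                    "transcript_id": spec.transcript_id, "tpos": tp,
                    "genomic_pos": t.transcript_to_genomic(tp),
                    "codon": codon, "tclass": tclass, "kind": kind})
        for (tp, ref, alt, af, syn) in snps:
            g = t.transcript_to_genomic(tp)
            if spec.strand == "-":
                ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
            planted_snps.append({"chrom": spec.chrom, "pos": g, "ref": ref,
                                 "alt": alt, "target_af": af, "synonymous": syn})

    expected = _expected_proteome(spliced_cache, planted_tis)
    manifest = TruthManifest(
        planted_tis=planted_tis, planted_snps=planted_snps,
        planted_offsets=dict(config.offsets),
        planted_translated=sorted(translated),
        expected_proteome=expected, seed=config.seed)
    return Scenario(genome={c: g.decode() for c, g in genomes.items()},
                    transcripts=transcripts, manifest=manifest, config=config)


def _oracle_translate(seq: str, tis: int, seleno: bool, stop_t: int | None):
    """Independent translation oracle: Biopython per-codon, initiator-M and
    seleno-recoding rules applied explicitly."""
    aas = []
    pos = tis
    while pos + 3 <= len(seq):
        codon = seq[pos:pos + 3]
        if pos == tis:
            aas.append("M")
        elif codon in _STOPS:
            if codon == "TGA" and seleno and stop_t is not None and pos < stop_t:
                aas.append("U")
            else:
                return "".join(aas), False
        else:
            aas.append(str(Seq(codon).translate()))
        pos += 3
    return "".join(aas), True


def _expected_proteome(cache: dict, planted_tis: list[dict], min_len: int = 6) -> list[dict]:
    out: list[dict] = []
    for rec in planted_tis:
        seq, cds_t, stop_t, _pl, snps, spec = cache[rec["transcript_id"]]
        aa, no_stop = _oracle_translate(seq, rec["tpos"], spec.seleno, stop_t)
        if len(aa) < min_len:
            continue
        out.append({"transcript_id": rec["transcript_id"], "tis_tpos": rec["tpos"],
                    "tclass": rec["tclass"], "variant": False, "sequence": aa,
                    "savs": []})
        if snps:
            vseq = list(seq)
            for (tp, ref, alt, _af, _syn) in snps:
                assert vseq[tp] == ref
                vseq[tp] = alt
            vaa, _ = _oracle_translate("".join(vseq), rec["tpos"], spec.seleno, stop_t)
            if vaa != aa:
                savs = [[i + 1, aa[i], vaa[i]]
                        for i in range(min(len(aa), len(vaa))) if aa[i] != vaa[i]]
                out.append({"transcript_id": rec["transcript_id"],
                            "tis_tpos": rec["tpos"], "tclass": rec["tclass"],
                            "variant": True, "sequence": vaa, "savs": savs})
    return out


def generate_reference(config: SimConfig):
    """Generate (genome FASTA text, annotation GTF text, TruthManifest)."""
    sc = build_scenario(config)
    buf = io.StringIO()
    for chrom in sorted(sc.genome):
        buf.write(f">{chrom}\n")
        s = sc.genome[chrom]
        for i in range(0, len(s), 60):
            buf.write(s[i:i + 60] + "\n")
    return buf.getvalue(), gtf_to_text(sc.transcripts), sc.manifest


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

def simulate_alignments(scenario: Scenario, sample_kind: str, depth: int,
                        seed: int) -> str:
    """Simulate CHX- or LTM-stalled footprint alignments; returns SAM text.

    CHX: ``depth`` reads per translated transcript, P-sites uniform over its
    coding codons, 5' ends displaced upstream by the planted per-length
    offset.  LTM: ``depth`` reads per planted TIS, P-sites exactly at the
    initiation codon.  Reads are ungapped genomic alignments; planted SNPs
    appear in read sequences at their target allele frequency.
    """
    if sample_kind not in ("CHX", "LTM"):
        raise ValueError("sample_kind must be CHX or LTM")
    cfg = scenario.config
    rng = np.random.default_rng(seed)
    lengths = sorted(cfg.read_lengths)
    probs = np.array([cfg.read_lengths[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    snps_by_chrom: dict[str, list[dict]] = {}
    for s in scenario.manifest.planted_snps:
        snps_by_chrom.setdefault(s["chrom"], []).append(s)

    tmap = {t.transcript_id: t for t in scenario.transcripts}
    cache = {sp.transcript_id: sp for sp in cfg.transcripts}
    records: list[tuple[str, int, str]] = []  # (chrom, pos, line-without-qname)
    n = 0

    def emit(t: Transcript, p_t: int, L: int, d: int) -> None:
        nonlocal n
        g = t.transcript_to_genomic(p_t)
        if t.strand == "+":
            five = g - d
        else:
            five = g + d
        if cfg.jitter > 0 and rng.random() < cfg.jitter:
            five += int(rng.choice([-1, 1]))
        if t.strand == "+":
            lo, hi = five, five + L
        else:
            lo, hi = five - L + 1, five + 1
        glen = len(scenario.genome[t.chrom])
        if lo < 0 or hi > glen:
            return
        seq = list(scenario.genome[t.chrom][lo:hi])
        for s in snps_by_chrom.get(t.chrom, ()):
            if lo <= s["pos"] < hi and rng.random() < s["target_af"]:
                seq[s["pos"] - lo] = s["alt"]
        flag = 0 if t.strand == "+" else 16
        line = (f"\t{flag}\t{t.chrom}\t{lo + 1}\t255\t{L}M\t*\t0\t0\t"
                f"{''.join(seq)}\t{'I' * L}\tNH:i:1")
        records.append((t.chrom, lo + 1, line))
        n += 1

    if sample_kind == "CHX":
        for tid in scenario.manifest.planted_translated:
            t, spec = tmap[tid], cache[tid]
            if spec.coding:
                cds_t = t.genomic_to_transcript(t.cds_start_genomic)
                codons = [cds_t + 3 * i for i in range(spec.n_codons)]
                # elongating libraries show a strong initiation pause; the
                # over-weighted start codon is what anchors offset calibration
                codons = [cds_t] * (cfg.init_pause - 1) + codons
            else:
                orfs = [p for p in scenario.manifest.planted_tis
                        if p["transcript_id"] == tid]
                codons = []
                for p in orfs:
                    et = next(e for e in spec.extra_tis if e.kind == "ntr_orf")
                    codons += [p["tpos"] + 3 * i for i in range(et.orf_codons + 1)]
            for _ in range(depth):
                p_t = int(rng.choice(codons))
                L = int(rng.choice(lengths, p=probs))
                emit(t, p_t, L, cfg.offsets[L])
    else:
        for p in scenario.manifest.planted_tis:
            t = tmap[p["transcript_id"]]
            for _ in range(depth):
                L = int(rng.choice(lengths, p=probs))
                emit(t, p["tpos"], L, cfg.offsets[L])

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    out = io.StringIO()
    out.write("@HD\tVN:1.6\tSO:coordinate\n")
    for chrom in sorted(scenario.genome):
        out.write(f"@SQ\tSN:{chrom}\tLN:{len(scenario.genome[chrom])}\n")
    for i, (_c, _p, line) in enumerate(records):
        out.write(f"r{i:07d}{line}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Reference proteome & MaxQuant-style fixtures
# ---------------------------------------------------------------------------

def reference_proteome_fasta(scenario: Scenario) -> str:
    """SwissProt-style FASTA of the annotated (aTIS, reference-allele)
    translation products — the 'known proteome' a candidate database is
    compared against."""
    lines = []
    i = 0
    for rec in scenario.manifest.expected_proteome:
        if rec["tclass"] == "aTIS" and not rec["variant"]:
            t = next(x for x in scenario.transcripts
                     if x.transcript_id == rec["transcript_id"])
            i += 1
            lines.append(f">sp|P{i:05d}|{t.gene_id}_SYN synthetic known protein "
                         f"GN={t.gene_id}")
            seq = rec["sequence"]
            lines += [seq[j:j + 60] for j in range(0, len(seq), 60)]
    return "\n".join(lines) + "\n"


def maxquant_table(groups: list[dict]) -> str:
    """Render a minimal MaxQuant proteinGroups.txt-style TSV.

    Each group dict: members (list of accession strings), reverse (bool),
    contaminant (bool), peptides (int).
    """
    rows = ["Protein IDs\tReverse\tPotential contaminant\tPeptide counts (all)"]
    for g in groups:
        rows.append("\t".join([
            ";".join(g["members"]),
            "+" if g.get("reverse") else "",
            "+" if g.get("contaminant") else "",
            str(g.get("peptides", 1)),
        ]))
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Canned scenario configurations
# ---------------------------------------------------------------------------

def classification_config(seed: int = 0) -> SimConfig:
    """One transcript per novel-proteoform category, plus controls.

    Plants an N-terminal extension, an N-terminal truncation, an
    out-of-frame CDS ORF, a SAV via a planted SNP, a uORF, a dORF, a
    pseudogene ORF and a lincRNA ORF, alongside an untranslated control
    transcript and a minus-strand case.
    """
    tx = [
        TranscriptSpec("ENST0001", "GEXT", "chr1",
                       extra_tis=[ExtraTis("extension", codon="ACG", upstream_nt=9)]),
        TranscriptSpec("ENST0002", "GTRU", "chr1", strand="-",
                       extra_tis=[ExtraTis("truncation", codon="CTG", codon_index=10)]),
        TranscriptSpec("ENST0003", "GOOF", "chr1",
                       extra_tis=[ExtraTis("out_of_frame", codon="ATG", codon_index=12)]),
        TranscriptSpec("ENST0004", "GSAV", "chr1", snps=[SnpSpec(codon_index=8)]),
        TranscriptSpec("ENST0005", "GUOR", "chr1",
                       extra_tis=[ExtraTis("uorf", codon="ATG", orf_codons=6, offset_nt=0)]),
        TranscriptSpec("ENST0006", "GDOR", "chr2",
                       extra_tis=[ExtraTis("dorf", codon="ATG", orf_codons=6, offset_nt=3)]),
        TranscriptSpec("ENST0007", "GPSE", "chr2", biotype="processed_pseudogene",
                       coding=False, n_exons=1, n_codons=12,
                       extra_tis=[ExtraTis("ntr_orf", codon="ATG", orf_codons=10, offset_nt=30)]),
        TranscriptSpec("ENST0008", "GLIN", "chr2", biotype="lincRNA",
                       coding=False, n_exons=1, n_codons=12,
                       extra_tis=[ExtraTis("ntr_orf", codon="ATG", orf_codons=10, offset_nt=30)]),
        TranscriptSpec("ENST0009", "GSEL", "chr2", seleno=True),
        TranscriptSpec("ENST0010", "GOFF", "chr2", translated=False),
    ]
    return SimConfig(chrom_lengths={"chr1": 4000, "chr2": 4000},
                     transcripts=tx, seed=seed)


def offsets_config(seed: int = 0, offsets: dict[int, int] | None = None,
                   jitter: float = 0.0) -> SimConfig:
    """A few well-expressed coding transcripts for offset calibration."""
    offsets = offsets or {28: 12, 29: 13}
    frac = 1.0 / len(offsets)
    tx = [TranscriptSpec(f"ENSTC{i:03d}", f"GC{i:03d}", "chr1", n_codons=60)
          for i in range(4)]
    return SimConfig(chrom_lengths={"chr1": 4000}, transcripts=tx,
                     read_lengths={l: frac for l in offsets},
                     offsets=dict(offsets), jitter=jitter, seed=seed)


def tis_config(seed: int = 0, n_tis: int = 50) -> SimConfig:
    """Many planted TISs of mixed annotation classes and start codons."""
    near = ["ACG", "CTG", "GTG", "TTG", "ATG", "ATC", "AAG", "AGG"]
    tx: list[TranscriptSpec] = []
    count = 0
    i = 0
    while count + 3 <= n_tis - 3:
        tx.append(TranscriptSpec(
            f"ENSTT{i:03d}", f"GT{i:03d}", "chr1",
            strand="-" if i % 3 == 2 else "+",
            extra_tis=[
                ExtraTis("extension", codon=near[i % len(near)], upstream_nt=9 + 3 * (i % 3)),
                ExtraTis("truncation", codon=near[(i + 1) % len(near)]
                         if near[(i + 1) % len(near)] != "ATG" else "CTG",
                         codon_index=8 + i % 10),
            ]))
        count += 3
        i += 1
    tx.append(TranscriptSpec("ENSTTP01", "GTPS", "chr2", biotype="processed_pseudogene",
                             coding=False, n_exons=1, n_codons=12,
                             extra_tis=[ExtraTis("ntr_orf", orf_codons=10, offset_nt=30)]))
    tx.append(TranscriptSpec("ENSTTD01", "GTDO", "chr2",
                             extra_tis=[ExtraTis("dorf", orf_codons=6, offset_nt=3)]))
    count += 3  # ntr + (aTIS + dORF)
    while count < n_tis:
        j = len(tx)
        tx.append(TranscriptSpec(f"ENSTX{j:03d}", f"GX{j:03d}", "chr2"))
        count += 1
    n1 = sum(1 for t in tx if t.chrom == "chr1")
    n2 = len(tx) - n1
    return SimConfig(chrom_lengths={"chr1": 700 * n1 + 500, "chr2": 700 * n2 + 500},
                     transcripts=tx, seed=seed)
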