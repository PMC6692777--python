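"""Readers/writers for the standard formats the pipeline touches, plus the results store.

Internal coordinate convention: 0-based, half-open, everywhere.  Conversion
to/from 1-based inclusive happens only at the GTF boundary; BedGraph is
natively 0-based half-open.
"""

from __future__ import annotations

import json
import math
import re
import sqlite3
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pysam


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


class SamFormatError(ValueError):
    pass


class AnnotationBoundsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """An annotated gene model: the coordinate backbone for everything downstream.

    ``exons`` are genomic ``(start, end)`` intervals, 0-based half-open,
    ordered 5'->3' in *transcript* orientation (descending genomic order on
    the minus strand).  ``cds_start_genomic`` / ``cds_stop_genomic`` are the
    genomic positions of the first base of the start / stop codon in
    transcript orientation, or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]]
    cds_start_genomic: int | None = None
    cds_stop_genomic: int | None = None
    seleno: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to its spliced-transcript offset (or None if intronic)."""
        t = 0
        for s, e in self.exons:
            if s <= gpos < e:
                if self.strand == "+":
                    return t + (gpos - s)
                return t + (e - 1 - gpos)
            t += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if tpos < 0 or tpos >= self.spliced_length:
            raise IndexError(f"transcript position {tpos} outside spliced length")
        t = 0
        for s, e in self.exons:
            n = e - s
            if tpos < t + n:
                off = tpos - t
                return s + off if self.strand == "+" else e - 1 - off
            t += n
        raise AssertionError("unreachable")

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None


@dataclass
class AlignedRead:
    """A single ribosome-protected-fragment alignment.

    ``five_prime_pos`` is the 0-based genomic position of the read's 5' end,
    strand-aware: for minus-strand reads this is the rightmost aligned base.
    """

    chrom: str
    strand: str
    five_prime_pos: int
    length: int
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")


@dataclass
class PsiteTrack:
    """Strand-aware per-base P-site count map."""

    counts: dict[tuple[str, str, int], int] = field(default_factory=dict)
    library_size: int = 0

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        key = (chrom, strand, pos)
        self.counts[key] = self.counts.get(key, 0) + n
        self.library_size += n

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand, pos), 0)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_GTF_FEATURES = {"gene", "transcript", "exon", "CDS", "start_codon", "stop_codon"}


def _parse_attrs(attr_field: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for k, v in _ATTR_RE.findall(attr_field):
        out.setdefault(k, []).append(v)
    return out


def read_gtf(path: str, chrom_lengths: dict[str, int] | None = None) -> list[Transcript]:
    """Parse an Ensembl-dialect GTF into Transcript records.

    GTF coordinates (1-based inclusive) are converted to internal 0-based
    half-open.  Exons are reordered into transcript orientation for
    minus-strand transcripts.  Transcripts without a ``start_codon`` line get
    ``cds_start_genomic=None``.  The optional Ensembl ``tag "seleno"``
    attribute marks selenoprotein transcripts.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    starts: dict[str, list[tuple[int, int, str]]] = {}
    stops: dict[str, list[tuple[int, int, str]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in _GTF_FEATURES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"line {lineno}: invalid interval {start1}-{end1}")
            if strand not in "+-":
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            if chrom_lengths is not None and chrom in chrom_lengths and end1 > chrom_lengths[chrom]:
                raise AnnotationBoundsError(
                    f"line {lineno}: feature end {end1} beyond chromosome {chrom} length {chrom_lengths[chrom]}")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attrs(attrs_s)
            if feature == "gene":
                continue
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: {feature} record lacks transcript_id attribute")
            tid = attrs["transcript_id"][0]
            if tid not in meta:
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", ["?"])[0],
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", attrs.get("transcript_biotype", ["protein_coding"]))[0],
                    "seleno": "seleno" in attrs.get("tag", []),
                }
            if "seleno" in attrs.get("tag", []):
                meta[tid]["seleno"] = True
            if feature == "exon":
                exons.setdefault(tid, []).append((start, end))
            elif feature == "start_codon":
                starts.setdefault(tid, []).append((start, end, strand))
            elif feature == "stop_codon":
                stops.setdefault(tid, []).append((start, end, strand))

    out: list[Transcript] = []
    for tid, m in meta.items():
        ex = sorted(exons.get(tid, []))
        if m["strand"] == "-":
            ex = ex[::-1]
        cds_start = _anchor_first_base(starts.get(tid), m["strand"])
        cds_stop = _anchor_first_base(stops.get(tid), m["strand"])
        out.append(Transcript(
            transcript_id=tid, gene_id=m["gene_id"], chrom=m["chrom"],
            strand=m["strand"], biotype=m["biotype"], exons=ex,
            cds_start_genomic=cds_start, cds_stop_genomic=cds_stop,
            seleno=m["seleno"],
        ))
    out.sort(key=lambda t: t.transcript_id)
    return out


def _anchor_first_base(segs: list[tuple[int, int, str]] | None, strand: str) -> int | None:
    """First base (transcript orientation) of a possibly split codon anchor."""
    if not segs:
        return None
    if strand == "+":
        return min(s for s, _e, _ in segs)
    return max(e for _s, e, _ in segs) - 1


def gtf_to_text(transcripts: list[Transcript]) -> str:
    """Render Ensembl-dialect GTF text (1-based inclusive) for the round-trip contract."""
    import io as _io
    fh = _io.StringIO()
    fh.write("#!genome-version riboforge-synthetic\n")
    for t in sorted(transcripts, key=lambda x: (x.chrom, min(s for s, _ in x.exons), x.transcript_id)):
            tag = ' tag "seleno";' if t.seleno else ""
            attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                     f'gene_biotype "{t.biotype}";{tag}')
            gstart = min(s for s, _ in t.exons) + 1
            gend = max(e for _, e in t.exons)
            fh.write(f"{t.chrom}\triboforge\ttranscript\t{gstart}\t{gend}\t.\t{t.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(t.exons, start=1):
                fh.write(f"{t.chrom}\triboforge\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                         f"{attrs} exon_number \"{i}\";\n")
            if t.cds_start_genomic is not None:
                for feat, anchor in (("start_codon", t.cds_start_genomic),
                                     ("stop_codon", t.cds_stop_genomic)):
                    if anchor is None:
                        continue
                    if t.strand == "+":
                        s1, e1 = anchor + 1, anchor + 3
                    else:
                        s1, e1 = anchor - 1, anchor + 1
                    fh.write(f"{t.chrom}\triboforge\t{feat}\t{s1}\t{e1}\t.\t{t.strand}\t0\t{attrs}\n")
    return fh.getvalue()


def write_gtf(transcripts: list[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(gtf_to_text(transcripts))


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str, unique_only: bool = False, max_hits: int = 16) -> list[AlignedRead]:
    """Read SAM/BAM alignments into strand-aware 5'-end records.

    Multimapping multiplicity is taken from the NH tag (assumed 1 if
    absent); each alignment of a multimapper keeps full weight.  Soft-clipped
    bases are excluded from the 5'-end computation: the 5' end is the first
    *aligned* base (for minus-strand reads, the rightmost aligned base).
    """
    out: list[AlignedRead] = []
    try:
        fh = pysam.AlignmentFile(path, "r", check_sq=False)
    except ValueError as exc:
        raise SamFormatError(str(exc)) from exc
    with fh:
        if not fh.header.to_dict().get("SQ"):
            raise SamFormatError(f"{path}: SAM header missing @SQ lines")
        for rec in fh:
            if rec.is_unmapped:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            if nh > max_hits or (unique_only and nh > 1):
                continue
            length = rec.query_alignment_length  # soft clips excluded
            if length == 0:
                continue
            if rec.is_reverse:
                strand, five = "-", rec.reference_end - 1
            else:
                strand, five = "+", rec.reference_start
            out.append(AlignedRead(chrom=rec.reference_name, strand=strand,
                                   five_prime_pos=five, length=length, n_hits=nh))
    return out


# ---------------------------------------------------------------------------
# BedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: PsiteTrack, path_prefix: str, transform: str = "identity") -> dict[str, str]:
    """Write one BedGraph file per strand, merging adjacent equal-value runs.

    ``transform="ln1p"`` writes ln(count+1) per position, the display
    transform used for genome-browser RPF tracks; ``identity`` writes raw
    counts.  Returns {strand: path}.
    """
    if transform not in ("identity", "ln1p"):
        raise ValueError(f"unknown transform {transform!r}")
    paths: dict[str, str] = {}
    for strand, suffix in (("+", "fw"), ("-", "rev")):
        path = f"{path_prefix}.{suffix}.bedgraph"
        paths[strand] = path
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for (chrom, st, pos), n in track.counts.items():
            if st == strand and n > 0:
                per_chrom.setdefault(chrom, []).append((pos, n))
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="riboforge_psites_{suffix}"\n')
            for chrom in sorted(per_chrom):
                run_start = run_end = None
                run_val: float | None = None
                for pos, n in sorted(per_chrom[chrom]):
                    val = round(math.log1p(n), 6) if transform == "ln1p" else n
                    if run_val is not None and pos == run_end and val == run_val:
                        run_end = pos + 1
                        continue
                    if run_val is not None:
                        fh.write(f"{chrom}\t{run_start}\t{run_end}\t{_fmt_val(run_val)}\n")
                    run_start, run_end, run_val = pos, pos + 1, val
                if run_val is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{_fmt_val(run_val)}\n")
    return paths


def _fmt_val(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}".rstrip("0").rstrip(".")


def read_bedgraph(path: str) -> dict[tuple[str, int], float]:
    """Expand a BedGraph file back to per-base values (round-trip checking)."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.split("\t")
            for p in range(int(s), int(e)):
                out[(chrom, p)] = float(v)
    return out


def read_genome_fasta(path: str) -> dict[str, str]:
    """Load a (small) genome FASTA into a chrom -> uppercase sequence dict."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Protein FASTA
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str) -> list[tuple[str, str, str, str]]:
    """Read a protein FASTA; returns (accession, description, sequence, source_db).

    UniProt-style headers ``sp|ACC|NAME`` parse as SwissProt and
    ``tr|ACC|NAME`` as TrEMBL; anything else is ``generic``.  Sequences are
    uppercased and trailing ``*`` stop marks stripped; empty records are
    skipped with a warning.
    """
    out = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper().replace("*", "")
        if not seq:
            warnings.warn(f"skipping empty-sequence record {header!r}")
            return
        parts = header.split(None, 1)
        name, desc = parts[0], parts[1] if len(parts) > 1 else ""
        bits = name.split("|")
        if len(bits) >= 3 and bits[0] == "sp":
            out.append((bits[1], desc, seq, "SwissProt"))
        elif len(bits) >= 3 and bits[0] == "tr":
            out.append((bits[1], desc, seq, "TrEMBL"))
        else:
            out.append((name, desc, seq, "generic"))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                flush()
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    flush()
    return out


# ---------------------------------------------------------------------------
# Results store
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS run_metadata (
    run_id INTEGER PRIMARY KEY AUTOINCREMENT,
    created_utc TEXT NOT NULL,
    schema_version INTEGER NOT NULL,
    seed INTEGER,
    params_json TEXT
);
CREATE TABLE IF NOT EXISTS transcripts (
    transcript_id TEXT PRIMARY KEY,
    gene_id TEXT, chrom TEXT, strand TEXT, biotype TEXT,
    exons_json TEXT, cds_start INTEGER, cds_stop INTEGER, seleno INTEGER
);
CREATE TABLE IF NOT EXISTS transcript_calls (
    transcript_id TEXT PRIMARY KEY REFERENCES transcripts(transcript_id),
    n_exons INTEGER, n_pass INTEGER, pass_fraction REAL, translated INTEGER
);
CREATE TABLE IF NOT EXISTS tis_calls (
    tis_id INTEGER PRIMARY KEY AUTOINCREMENT,
    transcript_id TEXT REFERENCES transcripts(transcript_id),
    genomic_pos INTEGER, codon TEXT, annotation_class TEXT,
    x_ltm INTEGER, x_chx INTEGER, r_ltm REAL, r_chx REAL, passed INTEGER
);
CREATE TABLE IF NOT EXISTS snps (
    chrom TEXT, pos INTEGER, ref TEXT, alt TEXT,
    depth INTEGER, alt_count INTEGER, af REAL,
    PRIMARY KEY (chrom, pos)
);
CREATE TABLE IF NOT EXISTS proteoforms (
    accession TEXT PRIMARY KEY,
    transcript_id TEXT REFERENCES transcripts(transcript_id),
    annotation_class TEXT, sequence TEXT,
    savs_json TEXT, flags_json TEXT, source_mask INTEGER
);
"""


class ResultsStore:
    """Single-file SQLite results database for one pipeline invocation."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)

    def new_run(self, seed: int | None = None, params: dict | None = None) -> int:
        cur = self.conn.execute(
            "INSERT INTO run_metadata (created_utc, schema_version, seed, params_json) VALUES (?,?,?,?)",
            (datetime.now(timezone.utc).isoformat(), SCHEMA_VERSION, seed,
             json.dumps(params or {}, sort_keys=True)))
        self.conn.commit()
        return cur.lastrowid

    def save_transcripts(self, transcripts: list[Transcript]) -> None:
        self.conn.executemany(
            "INSERT OR REPLACE INTO transcripts VALUES (?,?,?,?,?,?,?,?,?)",
            [(t.transcript_id, t.gene_id, t.chrom, t.strand, t.biotype,
              json.dumps(t.exons), t.cds_start_genomic, t.cds_stop_genomic,
              int(t.seleno)) for t in transcripts])
        self.conn.commit()

    def save_transcript_calls(self, calls) -> None:
        self.conn.executemany(
            "INSERT OR REPLACE INTO transcript_calls VALUES (?,?,?,?,?)",
            [(c.transcript_id, len(c.exon_coverages), c.n_pass, c.pass_fraction,
              int(c.translated)) for c in calls])
        self.conn.commit()

    def save_tis_calls(self, calls) -> None:
        self.conn.executemany(
            "INSERT INTO tis_calls (transcript_id, genomic_pos, codon, annotation_class,"
            " x_ltm, x_chx, r_ltm, r_chx, passed) VALUES (?,?,?,?,?,?,?,?,?)",
            [(c.transcript_id, c.genomic_pos, c.codon, c.annotation_class,
              c.x_ltm, c.x_chx, c.r_ltm, c.r_chx, int(c.passed_rules)) for c in calls])
        self.conn.commit()

    def save_snps(self, variants) -> None:
        self.conn.executemany(
            "INSERT OR REPLACE INTO snps VALUES (?,?,?,?,?,?,?)",
            [(v.chrom, v.pos, v.ref_base, v.alt_base, v.depth, v.alt_count, v.af)
             for v in variants])
        self.conn.commit()

    def save_proteoforms(self, entries) -> None:
        self.conn.executemany(
            "INSERT OR REPLACE INTO proteoforms VALUES (?,?,?,?,?,?,?)",
            [(e.accession, e.transcript_id, e.annotation_class, e.sequence,
              json.dumps(e.variants_applied), json.dumps(e.flags, sort_keys=True),
              e.source_mask) for e in entries])
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()
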