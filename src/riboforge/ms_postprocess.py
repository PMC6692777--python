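"""MS post-processing: protein-group parsing, source attribution, share
statistics and novel-proteoform classification.

After an MS/MS search against the combined database, each protein group is
attributed to the calling method(s) and reference database(s) that
contributed its members, via the accession code system.  Groups absent
from the reference are novel-proteoform candidates, and are classified by
the nature of their variation relative to the best same-gene reference
protein: N-/C-terminal extensions and truncations, single-amino-acid
variants, splice variants, upstream/downstream ORFs, out-of-frame ORFs and
products of non-coding transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP

import pandas as pd

from riboforge.db_export import (AccessionError, IntegrityError, SOURCE_BITS,
                                 METHOD_NAMES, parse_accession)

PRIMARY_CATEGORIES = (
    "known", "N_terminal_extension", "N_terminal_truncation",
    "C_terminal_extension", "C_terminal_truncation", "SAV_only",
    "new_splice_variant", "uORF", "dORF", "out_of_frame_ORF", "non_coding")


class FormatError(ValueError):
    pass


@dataclass
class ProteinGroupRecord:
    members: list[str]
    source_union: int
    is_reverse: bool = False
    is_contaminant: bool = False


@dataclass
class ClassificationLabel:
    category: str
    subcategory: str | None = None
    evidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MaxQuant parsing & attribution
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("Protein IDs", "Reverse", "Potential contaminant")


def parse_protein_groups(path: str) -> list[ProteinGroupRecord]:
    """Parse a MaxQuant proteinGroups.txt-style TSV.

    Rows flagged Reverse or Potential contaminant are excluded, as are
    REV__/CON__-prefixed members; remaining member accessions are decoded
    through the accession code system to build each group's source union.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    out: list[ProteinGroupRecord] = []
    for _, row in df.iterrows():
        if row["Reverse"].strip() == "+" or row["Potential contaminant"].strip() == "+":
            continue
        members = [m for m in row["Protein IDs"].split(";") if m
                   and not m.startswith(("REV__", "CON__"))]
        if not members:
            continue
        mask = 0
        kept = []
        for m in members:
            try:
                mask |= parse_accession(m)["mask"]
                kept.append(m)
            except AccessionError:
                warnings.warn(f"unrecognized accession {m!r} skipped")
        if kept:
            out.append(ProteinGroupRecord(members=kept, source_union=mask))
    return out


def attribute_sources(records: list[ProteinGroupRecord]
                      ) -> tuple[dict[tuple[str, ...], int], dict[tuple[str, ...], int]]:
    """Partition groups into Venn cells over the calling methods and over
    {pipeline, swissprot, trembl}.  Each group lands in exactly one
    cell of each partition, so cells sum to the group count."""
    method_cells: dict[tuple[str, ...], int] = {}
    db_cells: dict[tuple[str, ...], int] = {}
    for g in records:
        if g.source_union == 0:
            raise IntegrityError("protein group with empty source mask")
        mkey = tuple(m for m in METHOD_NAMES if g.source_union & SOURCE_BITS[m])
        method_cells[mkey] = method_cells.get(mkey, 0) + 1
        dkey = []
        if g.source_union & (SOURCE_BITS["classic"] | SOURCE_BITS["price"]
                             | SOURCE_BITS["spectre"]):
            dkey.append("pipeline")
        if g.source_union & SOURCE_BITS["uniprot_sp"]:
            dkey.append("swissprot")
        if g.source_union & SOURCE_BITS["uniprot_tr"]:
            dkey.append("trembl")
        db_cells[tuple(dkey)] = db_cells.get(tuple(dkey), 0) + 1
    return method_cells, db_cells


def novel_candidates(records: list[ProteinGroupRecord]) -> list[ProteinGroupRecord]:
    """Groups supported by the pipeline only (no reference member):
    the novel-proteoform candidates forwarded to classification."""
    ref_mask = SOURCE_BITS["uniprot_sp"] | SOURCE_BITS["uniprot_tr"]
    return [g for g in records
            if g.source_union and not (g.source_union & ref_mask)]


# ---------------------------------------------------------------------------
# Share arithmetic
# ---------------------------------------------------------------------------

def compute_share(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage share, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def redundancy_increase(redundant_n: int, nonredundant_n: int) -> float:
    """Percentage size increase of the redundant over the nonredundant
    database, truncated to two decimals (the convention the published size
    ratios follow)."""
    if nonredundant_n <= 0:
        raise ValueError("nonredundant count must be positive")
    q = (Decimal(100) * (Decimal(redundant_n) - Decimal(nonredundant_n))
         / Decimal(nonredundant_n))
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_DOWN))


# ---------------------------------------------------------------------------
# Classification cascade
# ---------------------------------------------------------------------------

def _noncoding_subcategory(biotype: str) -> str:
    if "pseudogene" in biotype:
        return "pseudogene"
    if biotype in ("lincRNA", "lncRNA"):
        return "lincRNA"
    return "other"


def _terminal_relation(cand: str, ref: str) -> str | None:
    """Ungapped anchored relation between candidate and reference with the
    initiator M as wildcard at the N-terminal junction."""
    if len(cand) > len(ref):
        if cand.endswith(ref) or (ref.startswith("M") and cand.endswith(ref[1:])):
            return "N_terminal_extension"
        if cand.startswith(ref):
            return "C_terminal_extension"
    elif len(cand) < len(ref):
        if ref.endswith(cand) or (cand.startswith("M") and ref.endswith(cand[1:])):
            return "N_terminal_truncation"
        if ref.startswith(cand):
            return "C_terminal_truncation"
    return None


def _splice_relation(cand: str, ref: str) -> str:
    p = 0
    while p < min(len(cand), len(ref)) and cand[p] == ref[p]:
        p += 1
    s = 0
    while (s < min(len(cand), len(ref)) - p
           and cand[len(cand) - 1 - s] == ref[len(ref) - 1 - s]):
        s += 1
    if len(cand) < len(ref) and cand == ref[:p] + ref[len(ref) - s:]:
        return "exon_skip"
    if len(cand) > len(ref) and ref == cand[:p] + cand[len(cand) - s:]:
        return "novel_junction"
    return "other"


def classify(candidate, reference_by_gene: dict[str, list[tuple[str, str]]],
             transcripts_by_id: dict, max_substitutions: int = 5
             ) -> ClassificationLabel:
    """Assign exactly one primary category to a novel proteoform.

    Decision cascade, first match wins: non-coding biotype; uORF (5'UTR
    start with a stop before the annotated CDS); dORF (3'UTR start);
    out-of-frame (start not in the annotated reading frame); terminal
    extension/truncation against the best same-gene reference; SAV-only
    (same length, <= ``max_substitutions`` substitutions); splice variant.
    """
    t = transcripts_by_id[candidate.transcript_id]
    seq = candidate.sequence
    cds_t = (t.genomic_to_transcript(t.cds_start_genomic)
             if t.cds_start_genomic is not None else None)

    if t.biotype != "protein_coding" or candidate.annotation_class == "ntr":
        return ClassificationLabel("non_coding", _noncoding_subcategory(t.biotype),
                                   {"biotype": t.biotype})
    if (candidate.annotation_class == "5UTR" and candidate.orf_stop_tpos is not None
            and cds_t is not None and candidate.orf_stop_tpos < cds_t):
        return ClassificationLabel("uORF", None, {"stop_tpos": candidate.orf_stop_tpos})
    if candidate.annotation_class == "3UTR":
        return ClassificationLabel("dORF")
    if cds_t is not None and (candidate.tis_tpos - cds_t) % 3 != 0:
        return ClassificationLabel("out_of_frame_ORF",
                                   None, {"frame": (candidate.tis_tpos - cds_t) % 3})

    refs = reference_by_gene.get(candidate.gene_id, [])
    if not refs:
        fallback = {"5UTR": "N_terminal_extension", "CDS": "N_terminal_truncation",
                    "aTIS": "SAV_only"}.get(candidate.annotation_class, "non_coding")
        return ClassificationLabel(fallback, None, {"low_confidence": True,
                                                    "no_reference": True})
    best: ClassificationLabel | None = None
    for (racc, rseq) in sorted(refs):
        if rseq == seq:
            return ClassificationLabel("known", None, {"reference": racc})
        rel = _terminal_relation(seq, rseq)
        if rel is not None:
            return ClassificationLabel(rel, None, {"reference": racc,
                                                   "delta": len(seq) - len(rseq)})
        if len(rseq) == len(seq):
            nsub = sum(1 for a, b in zip(seq, rseq) if a != b)
            if 1 <= nsub <= max_substitutions:
                return ClassificationLabel("SAV_only", None,
                                           {"reference": racc, "n_substitutions": nsub})
        sub = _splice_relation(seq, rseq)
        lbl = ClassificationLabel("new_splice_variant", sub, {"reference": racc})
        if best is None or (best.subcategory == "other" and sub != "other"):
            best = lbl
    return best
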