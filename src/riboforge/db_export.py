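"""Database export: method merging, redundancy removal, reference fusion,
the accession code system, and FASTA/PEFF writers.

Every sequence in the combined search database carries a source bitmask in
its accession so that, after the MS search, each identification can be
traced back to the calling method(s) and/or reference database(s) that
contributed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# source bitmask: which calling method / reference database contributed a sequence
SOURCE_BITS = {"classic": 1, "price": 2, "spectre": 4,
               "uniprot_sp": 8, "uniprot_tr": 16}
METHOD_NAMES = ("classic", "price", "spectre")


class AccessionError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


def encode_sources(names) -> int:
    mask = 0
    for n in names:
        mask |= SOURCE_BITS[n]
    return mask


def decode_sources(mask: int) -> set[str]:
    return {n for n, b in SOURCE_BITS.items() if mask & b}


@dataclass
class FastaRecord:
    accession: str
    description: str
    sequence: str
    mask: int
    gene: str = ""
    absorbed: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Accession code system
# ---------------------------------------------------------------------------

def format_accession(transcript_id: str, tis_index: int, is_variant: bool,
                     mask: int, gene: str) -> str:
    tok = f"{tis_index}v" if is_variant else str(tis_index)
    return f"generic|{transcript_id}_{tok}_{mask}|{gene}"


def make_accession(entry) -> str:
    """``generic|<transcript_id>_<tis_index>[v]_<mask>|<gene>`` — the middle
    token encodes TIS identity, variant status and the source bitmask."""
    return format_accession(entry.transcript_id, entry.tis_index,
                            entry.is_variant, entry.source_mask, entry.gene_id)


def entry_description(entry) -> str:
    flags = ",".join(sorted(entry.flags)) if entry.flags else "-"
    return (f"class={entry.annotation_class} sav={len(entry.variants_applied)} "
            f"flags={flags}")


def parse_accession(header: str) -> dict:
    """Invert the accession writer; understands generic, sp and tr headers.

    Raises :class:`AccessionError` on malformed input.
    """
    name = header.split(None, 1)[0].lstrip(">")
    bits = name.split("|")
    if len(bits) != 3:
        raise AccessionError(f"malformed accession {name!r}")
    db, core, gene = bits
    if db == "sp":
        return {"source_db": "uniprot_sp", "accession": core, "mask": SOURCE_BITS["uniprot_sp"]}
    if db == "tr":
        return {"source_db": "uniprot_tr", "accession": core, "mask": SOURCE_BITS["uniprot_tr"]}
    if db != "generic":
        raise AccessionError(f"unknown database tag {db!r} in {name!r}")
    parts = core.rsplit("_", 2)
    if len(parts) != 3:
        raise AccessionError(f"malformed generic accession core {core!r}")
    tid, tok, mask_s = parts
    variant = tok.endswith("v")
    idx_s = tok[:-1] if variant else tok
    try:
        idx, mask = int(idx_s), int(mask_s)
    except ValueError:
        raise AccessionError(f"non-numeric tis index/mask in {core!r}") from None
    if mask <= 0:
        raise AccessionError(f"mask must be positive in {core!r}")
    return {"source_db": "generic", "transcript_id": tid, "tis_index": idx,
            "variant": variant, "mask": mask, "gene": gene}


# ---------------------------------------------------------------------------
# Method merging & redundancy
# ---------------------------------------------------------------------------

def entries_to_records(entries, method: str = "classic") -> list[FastaRecord]:
    bit = SOURCE_BITS[method]
    return [FastaRecord(
        accession=format_accession(e.transcript_id, e.tis_index, e.is_variant,
                                   bit, e.gene_id),
        description=entry_description(e), sequence=e.sequence, mask=bit,
        gene=e.gene_id) for e in entries]


def merge_methods(sets: dict[str, list[FastaRecord]], keep_redundant: bool = True
                  ) -> tuple[list[FastaRecord], dict[tuple[str, ...], int]]:
    """Merge per-method databases; identical sequences across methods become
    one record with OR-ed masks.

    Returns (records, venn) where ``venn`` maps each method subset (sorted
    tuple) to the number of distinct sequences found in exactly that subset
    of methods; the cells partition the distinct sequences.
    """
    if not sets:
        raise ValueError("at least one method set required")
    by_seq: dict[str, FastaRecord] = {}
    members: dict[str, set[str]] = {}
    seen_acc: dict[str, str] = {}
    for method in sorted(sets):
        for rec in sets[method]:
            prev = seen_acc.get(rec.accession)
            if prev is not None and prev != rec.sequence:
                raise IntegrityError(
                    f"accession {rec.accession} maps to two different sequences")
            seen_acc[rec.accession] = rec.sequence
            if rec.sequence in by_seq:
                r = by_seq[rec.sequence]
                r.mask |= rec.mask
                if rec.accession != r.accession and rec.accession not in r.absorbed:
                    r.absorbed.append(rec.accession)
            else:
                by_seq[rec.sequence] = FastaRecord(
                    accession=rec.accession, description=rec.description,
                    sequence=rec.sequence, mask=rec.mask, gene=rec.gene,
                    absorbed=list(rec.absorbed))
            members.setdefault(rec.sequence, set()).add(method)
    venn: dict[tuple[str, ...], int] = {}
    for seq, meths in members.items():
        key = tuple(sorted(meths))
        venn[key] = venn.get(key, 0) + 1
    records = sorted(by_seq.values(), key=lambda r: r.accession)
    if not keep_redundant:
        records = remove_redundancy(records)
    return records, venn


def _absorbed_by(shorter: str, longer: str) -> bool:
    """Suffix absorption with the initiator M treated as a wildcard at the
    junction: a truncation starting at internal codon X translates X -> M."""
    if len(longer) <= len(shorter):
        return False
    if longer.endswith(shorter):
        return True
    return shorter.startswith("M") and longer.endswith(shorter[1:])


def remove_redundancy(records: list[FastaRecord], mode: str = "suffix"
                      ) -> list[FastaRecord]:
    """Collapse redundant records; idempotent.

    mode="duplicates": exact duplicate sequences only (masks OR-ed).
    mode="suffix" (default): additionally absorb any sequence that is an
    (initiator-M-adjusted) exact suffix of a longer retained sequence of
    the same gene, so truncations collapse into the longest form.
    """
    if mode not in ("duplicates", "suffix"):
        raise ValueError(f"unknown redundancy mode {mode!r}")
    by_seq: dict[str, FastaRecord] = {}
    for rec in sorted(records, key=lambda r: r.accession):
        if rec.sequence in by_seq:
            r = by_seq[rec.sequence]
            r.mask |= rec.mask
            if rec.accession not in r.absorbed:
                r.absorbed.append(rec.accession)
            r.absorbed.extend(a for a in rec.absorbed if a not in r.absorbed)
        else:
            by_seq[rec.sequence] = FastaRecord(
                accession=rec.accession, description=rec.description,
                sequence=rec.sequence, mask=rec.mask, gene=rec.gene,
                absorbed=list(rec.absorbed))
    uniq = list(by_seq.values())
    if mode == "duplicates":
        return sorted(uniq, key=lambda r: r.accession)

    kept: list[FastaRecord] = []
    by_gene: dict[str, list[FastaRecord]] = {}
    for rec in sorted(uniq, key=lambda r: (-len(r.sequence), r.accession)):
        host = next((k for k in by_gene.get(rec.gene, [])
                     if _absorbed_by(rec.sequence, k.sequence)), None)
        if host is not None:
            host.mask |= rec.mask
            host.absorbed.append(rec.accession)
            host.absorbed.extend(a for a in rec.absorbed if a not in host.absorbed)
        else:
            kept.append(rec)
            by_gene.setdefault(rec.gene, []).append(rec)
    return sorted(kept, key=lambda r: r.accession)


def read_method_fasta(path: str, method: str) -> list[FastaRecord]:
    """Adapter: ingest an external calling method's FASTA (e.g. PRICE or
    SPECtre output) as records carrying that method's source bit."""
    from riboforge.ribo_io import read_protein_fasta
    bit = SOURCE_BITS[method]
    out = []
    for (acc, desc, seq, _db) in read_protein_fasta(path):
        gene = ""
        try:
            gene = parse_accession(acc if "|" in acc else f"generic|{acc}|?").get("gene", "")
        except AccessionError:
            pass
        out.append(FastaRecord(accession=acc if "|" in acc else f"generic|{acc}_{1}_{bit}|{gene or '?'}",
                               description=desc, sequence=seq, mask=bit, gene=gene))
    return out


# ---------------------------------------------------------------------------
# Reference fusion
# ---------------------------------------------------------------------------

def reference_to_records(ref_tuples) -> list[FastaRecord]:
    """Convert read_protein_fasta output into records with UniProt masks."""
    out = []
    for (acc, desc, seq, db) in ref_tuples:
        if db == "SwissProt":
            mask, prefix = SOURCE_BITS["uniprot_sp"], "sp"
        elif db == "TrEMBL":
            mask, prefix = SOURCE_BITS["uniprot_tr"], "tr"
        else:
            mask, prefix = SOURCE_BITS["uniprot_tr"], "generic"
        out.append(FastaRecord(accession=f"{prefix}|{acc}|{acc}",
                               description=desc, sequence=seq, mask=mask))
    return out


def merge_with_reference(pf_records: list[FastaRecord],
                         ref_records: list[FastaRecord]
                         ) -> tuple[list[FastaRecord], dict[str, str], dict[str, int]]:
    """Fuse the pipeline database with a reference proteome.

    Overlap means exact sequence identity, or identity after stripping the
    initiator M of either side.  Returns (combined records, category per
    accession in {pipeline_only, overlap, reference_only}, counts with
    SwissProt/TrEMBL split out).
    """
    ref_keys: dict[str, list[FastaRecord]] = {}
    for r in ref_records:
        ref_keys.setdefault(r.sequence, []).append(r)
        if r.sequence.startswith("M"):
            ref_keys.setdefault(r.sequence[1:], []).append(r)

    combined: dict[str, FastaRecord] = {}
    category: dict[str, str] = {}
    matched_refs: set[str] = set()

    for p in sorted(pf_records, key=lambda r: r.accession):
        hits = list(ref_keys.get(p.sequence, []))
        if p.sequence.startswith("M"):
            hits += ref_keys.get(p.sequence[1:], [])
        rec = combined.setdefault(p.sequence, FastaRecord(
            accession=p.accession, description=p.description,
            sequence=p.sequence, mask=p.mask, gene=p.gene,
            absorbed=list(p.absorbed)))
        rec.mask |= p.mask
        if hits:
            for h in hits:
                rec.mask |= h.mask
                matched_refs.add(h.accession)
            category[p.accession] = "overlap"
        else:
            category[p.accession] = "pipeline_only"

    pf_seqs = set(combined)
    pf_stripped = {s[1:] for s in pf_seqs if s.startswith("M")}
    for r in ref_records:
        matched = r.accession in matched_refs or r.sequence in pf_seqs \
            or r.sequence in pf_stripped \
            or (r.sequence.startswith("M") and r.sequence[1:] in pf_seqs)
        if r.sequence in combined:
            combined[r.sequence].mask |= r.mask
        else:
            combined[r.sequence] = FastaRecord(
                accession=r.accession, description=r.description,
                sequence=r.sequence, mask=r.mask)
        category[r.accession] = "overlap" if matched else "reference_only"

    counts: dict[str, int] = {"pipeline_only": 0, "overlap": 0, "reference_only": 0,
                              "overlap_sp": 0, "overlap_tr": 0,
                              "reference_only_sp": 0, "reference_only_tr": 0}
    for p in pf_records:
        counts[category[p.accession]] += 1 if category[p.accession] != "reference_only" else 0
    for r in ref_records:
        cat = category[r.accession]
        suffix = "sp" if r.mask & SOURCE_BITS["uniprot_sp"] else "tr"
        if cat == "reference_only":
            counts["reference_only"] += 1
            counts[f"reference_only_{suffix}"] += 1
        else:
            counts[f"overlap_{suffix}"] += 1
    records = sorted(combined.values(), key=lambda r: r.accession)
    return records, category, counts


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(records: list[FastaRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda x: x.accession):
            desc = r.description
            if r.absorbed:
                desc = (desc + " " if desc else "") + "absorbed=" + ",".join(sorted(r.absorbed))
            fh.write(f">{r.accession}{' ' + desc if desc else ''}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def write_peff(entries, path: str, db_name: str = "riboforge",
               prefix: str = "rfdb") -> int:
    """Write PEFF 1.0: SAV-only variant entries fold into their base entry
    as ``\\VariantSimple=(pos|alt)`` records; stop-shifting variants stay
    separate entries.  Returns the number of entries written."""
    bases = [e for e in entries if not e.is_variant]
    variants = [e for e in entries if e.is_variant]
    by_key = {(e.transcript_id, e.tis_index): e for e in bases}
    folded: dict[str, list[tuple[int, str, str]]] = {}
    standalone = []
    for v in variants:
        b = by_key.get((v.transcript_id, v.tis_index))
        if b is not None and len(v.sequence) == len(b.sequence):
            if any(p > len(b.sequence) for p, _r, _a in v.variants_applied):
                raise ValueError(f"variant position beyond length in {v.accession}")
            folded[b.accession] = list(v.variants_applied)
        else:
            standalone.append(v)

    out_entries = sorted(bases + standalone,
                         key=lambda e: (e.transcript_id, e.tis_index, e.is_variant))
    lines = ["# PEFF 1.0",
             f"# DbName={db_name}",
             f"# Prefix={prefix}",
             f"# NumberOfEntries={len(out_entries)}",
             "# SequenceType=AA",
             "# //"]
    for e in out_entries:
        core = e.accession.split("|")[1]
        hdr = (f">{prefix}:{core} \\PName={e.transcript_id} proteoform "
               f"{e.annotation_class} \\GName={e.gene_id} \\Length={len(e.sequence)}")
        savs = folded.get(e.accession)
        if savs:
            hdr += " \\VariantSimple=" + "".join(f"({p}|{alt})" for p, _r, alt in savs)
        lines.append(hdr)
        for i in range(0, len(e.sequence), 60):
            lines.append(e.sequence[i:i + 60])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return len(out_entries)
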