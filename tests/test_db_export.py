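"""Database export: accession round-trips, method merging with Venn cells,
redundancy absorption, reference fusion and PEFF variant reapplication."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from riboforge import ribo_io
from riboforge.db_export import (AccessionError, FastaRecord, IntegrityError,
                                 decode_sources, encode_sources,
                                 entries_to_records, format_accession,
                                 merge_methods, merge_with_reference,
                                 parse_accession, reference_to_records,
                                 remove_redundancy, write_fasta, write_peff)


def _rec(seq, acc=None, gene="G1", mask=1):
    return FastaRecord(accession=acc or f"generic|{seq}_1_{mask}|{gene}",
                       description="", sequence=seq, mask=mask, gene=gene)


def test_source_mask_encode_decode_round_trip():
    for subset in ({"classic"}, {"classic", "price"},
                   {"spectre", "uniprot_sp", "uniprot_tr"}):
        assert decode_sources(encode_sources(subset)) == subset


@settings(max_examples=100, derandomize=True)
@given(tid=st.from_regex(r"ENST[0-9]{4,11}", fullmatch=True),
       idx=st.integers(1, 99), variant=st.booleans(),
       mask=st.integers(1, 31),
       gene=st.from_regex(r"[A-Z][A-Z0-9]{1,8}", fullmatch=True))
def test_accession_parse_inverts_format(tid, idx, variant, mask, gene):
    acc = format_accession(tid, idx, variant, mask, gene)
    p = parse_accession(acc)
    assert (p["transcript_id"], p["tis_index"], p["variant"],
            p["mask"], p["gene"]) == (tid, idx, variant, mask, gene)


def test_uniprot_headers_parse_and_malformed_raise():
    assert parse_accession("sp|P12345|X")["mask"] == 8
    assert parse_accession("tr|Q1|X")["mask"] == 16
    for bad in ("nonsense", "generic|no_mask|G", "xx|A|B", "generic|T_a_b|G"):
        with pytest.raises(AccessionError):
            parse_accession(bad)


def test_merge_identical_sequence_ors_masks():
    recs, venn = merge_methods({
        "classic": [_rec("MABC", "generic|T1_1_1|G1", mask=1)],
        "price": [_rec("MABC", "generic|T1_1_2|G1", mask=2)]})
    assert len(recs) == 1 and recs[0].mask == 3
    assert venn == {("classic", "price"): 1}


def test_merge_disjoint_sets_partition_venn():
    sets = {
        "classic": [_rec(f"MC{i}AAA") for i in range(2)],
        "price": [_rec(f"MP{i}AAA") for i in range(3)],
        "spectre": [_rec(f"MS{i}AAA") for i in range(4)],
    }
    recs, venn = merge_methods(sets)
    assert len(recs) == 9
    assert venn == {("classic",): 2, ("price",): 3, ("spectre",): 4}
    assert sum(venn.values()) == len(recs)


def test_merge_duplicate_accession_different_sequence_is_integrity_error():
    with pytest.raises(IntegrityError):
        merge_methods({"classic": [_rec("MAAA", "generic|T1_1_1|G"),
                                   _rec("MCCC", "generic|T1_1_1|G")]})


def test_remove_redundancy_collapses_duplicates_and_suffixes():
    dup = [_rec("MAB", "a1"), _rec("MAB", "a2")]
    out = remove_redundancy(dup, mode="duplicates")
    assert len(out) == 1 and set(out[0].absorbed) == {"a2"}

    ext = _rec("MXXAB", "ext", gene="G")     # N-extension
    atis = _rec("MAB", "atis", gene="G")     # truncation: M replaces internal X
    out = remove_redundancy([atis, ext])
    assert [r.accession for r in out] == ["ext"]
    assert "atis" in out[0].absorbed

    other_gene = _rec("MAB", "og", gene="H")  # different gene: not absorbed
    assert len(remove_redundancy([ext, other_gene])) == 2


def test_remove_redundancy_is_idempotent():
    recs = [_rec("MXXAB", "e", gene="G"), _rec("MAB", "a", gene="G"),
            _rec("MZZZZ", "z", gene="G"), _rec("MZZZZ", "z2", gene="G")]
    once = remove_redundancy(recs)
    twice = remove_redundancy(once)
    assert [(r.accession, r.sequence, r.mask) for r in once] == \
           [(r.accession, r.sequence, r.mask) for r in twice]


def test_merge_with_reference_met_stripping_rules():
    pf = [_rec("MABC", "generic|T1_1_1|G1"), _rec("MXXABC", "generic|T2_1_1|G2"),
          _rec("MDEF", "generic|T3_1_1|G3")]
    refs = reference_to_records([
        ("P1", "d", "MABC", "SwissProt"),     # exact overlap
        ("P2", "d", "DEF", "SwissProt"),      # overlap after stripping pf's M
        ("P3", "d", "MZZZ", "TrEMBL"),        # reference only
    ])
    combined, category, counts = merge_with_reference(pf, refs)
    assert category["generic|T1_1_1|G1"] == "overlap"
    assert category["generic|T3_1_1|G3"] == "overlap"
    assert category["generic|T2_1_1|G2"] == "pipeline_only"
    assert category["tr|P3|P3"] == "reference_only"
    assert counts["pipeline_only"] == 1
    assert counts["overlap_sp"] == 2 and counts["reference_only_tr"] == 1
    mabc = next(r for r in combined if r.sequence == "MABC")
    assert mabc.mask == (1 | 8)


def test_merge_then_reference_counts_partition(class_result, class_files):
    records = entries_to_records(class_result.entries, "classic")
    refs = reference_to_records(ribo_io.read_protein_fasta(class_files.ref_path))
    _combined, category, counts = merge_with_reference(records, refs)
    assert counts["pipeline_only"] + counts["overlap"] == len(records)
    assert (counts["overlap_sp"] + counts["overlap_tr"]
            + counts["reference_only"]) == len(refs)


def test_fasta_write_parse_round_trip(class_result, tmp_path):
    records = entries_to_records(class_result.entries, "classic")
    path = tmp_path / "db.fa"
    write_fasta(records, str(path))
    back = ribo_io.read_protein_fasta(str(path))
    assert len(back) == len(records)
    seqs = {r.sequence for r in records}
    for (acc, _desc, seq, db) in back:
        assert db == "generic" and seq in seqs
        parsed = parse_accession(acc)
        assert parsed["mask"] == 1


def test_peff_header_counts_and_variant_reapplication(class_result, tmp_path):
    """Reapplying each \\VariantSimple record to its base sequence must
    reproduce every SAV-variant proteoform sequence exactly."""
    path = tmp_path / "db.peff"
    n = write_peff(class_result.entries, str(path))
    text = path.read_text()
    assert text.startswith("# PEFF 1.0\n")
    assert f"# NumberOfEntries={n}" in text
    headers = [l for l in text.splitlines() if l.startswith(">")]
    assert len(headers) == n

    # independent reapplication oracle
    entries = {}
    key = None
    for line in text.splitlines():
        if line.startswith(">"):
            key = line.split()[0][1:]
            entries[key] = {"hdr": line, "seq": ""}
        elif key and not line.startswith("#"):
            entries[key]["seq"] += line.strip()

    variant_truth = {(e.transcript_id, e.tis_index): e.sequence
                     for e in class_result.entries
                     if e.is_variant and not e.flags.get("stop_shift")}
    reproduced = 0
    for info in entries.values():
        m = re.search(r"\\VariantSimple=((?:\(\d+\|[A-Z]\))+)", info["hdr"])
        if not m:
            continue
        seq = list(info["seq"])
        for pos, alt in re.findall(r"\((\d+)\|([A-Z])\)", m.group(1)):
            seq[int(pos) - 1] = alt
        core = info["hdr"].split()[0].split(":")[1]
        tid = core.rsplit("_", 2)[0]
        idx = int(core.rsplit("_", 2)[1].rstrip("v"))
        assert "".join(seq) == variant_truth[(tid, idx)]
        reproduced += 1
    assert reproduced == len(variant_truth) >= 1
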