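"""MS post-processing: protein-group parsing, source attribution partitions,
share arithmetic and the novel-proteoform classification cascade."""

import pytest

from riboforge import fixtures
from riboforge.db_export import IntegrityError
from riboforge.ms_postprocess import (ClassificationLabel, FormatError,
                                      ProteinGroupRecord, attribute_sources,
                                      classify, compute_share,
                                      novel_candidates, parse_protein_groups,
                                      redundancy_increase)
from riboforge.ribo_io import Transcript


# ---------------------------------------------------------------------------
# MaxQuant parsing & attribution
# ---------------------------------------------------------------------------

def _mq(tmp_path, groups):
    p = tmp_path / "proteinGroups.txt"
    p.write_text(fixtures.maxquant_table(groups))
    return str(p)


def test_parse_decodes_sources_and_excludes_flagged_rows(tmp_path):
    path = _mq(tmp_path, [
        {"members": ["generic|ENST1_1_1|G1", "sp|P1|X"]},
        {"members": ["generic|ENST2_1_2|G2"], "reverse": True},
        {"members": ["CON__P99", "tr|Q1|Y"], "contaminant": True},
        {"members": ["REV__generic|ENST3_1_1|G3"]},
    ])
    recs = parse_protein_groups(path)
    assert len(recs) == 1
    assert recs[0].source_union == (1 | 8)


def test_missing_column_is_format_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("Protein IDs\tReverse\nx\t\n")
    with pytest.raises(FormatError):
        parse_protein_groups(str(p))


def test_attribution_partitions_sum_to_group_count():
    recs = [ProteinGroupRecord(["a"], 1),          # classic only
            ProteinGroupRecord(["b"], 1 | 2),      # classic & price
            ProteinGroupRecord(["c"], 8)]          # swissprot only
    method_cells, db_cells = attribute_sources(recs)
    assert method_cells[("classic",)] == 1
    assert method_cells[("classic", "price")] == 1
    assert method_cells[()] == 1
    assert sum(method_cells.values()) == sum(db_cells.values()) == 3
    assert db_cells[("pipeline",)] == 2 and db_cells[("swissprot",)] == 1


def test_empty_mask_is_integrity_error():
    with pytest.raises(IntegrityError):
        attribute_sources([ProteinGroupRecord(["x"], 0)])


def test_novel_candidates_are_pipeline_only_groups():
    recs = [ProteinGroupRecord(["a"], 1), ProteinGroupRecord(["b"], 1 | 8),
            ProteinGroupRecord(["c"], 2 | 4)]
    assert [g.members for g in novel_candidates(recs)] == [["a"], ["c"]]


# ---------------------------------------------------------------------------
# Share arithmetic (worked examples)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("num,den,dec,expect", [
    (47, 4477, 2, 1.05),
    (43, 42452, 1, 0.1),
    (0, 100, 2, 0.0),
    (134, 234000, 3, 0.057),
])
def test_compute_share_half_up(num, den, dec, expect):
    assert compute_share(num, den, dec) == expect


def test_compute_share_zero_denominator():
    with pytest.raises(ValueError):
        compute_share(1, 0)


@pytest.mark.parametrize("r,nr,expect", [
    (119716, 76945, 55.58),
    (100, 100, 0.00),
    (150, 100, 50.00),
])
def test_redundancy_increase(r, nr, expect):
    assert redundancy_increase(r, nr) == expect


# ---------------------------------------------------------------------------
# Classification cascade (unit level)
# ---------------------------------------------------------------------------

class _Cand:
    def __init__(self, seq, tclass="CDS", tid="t1", gene="G1",
                 tis_tpos=30, orf_stop_tpos=120, variant=False):
        self.sequence = seq
        self.annotation_class = tclass
        self.transcript_id = tid
        self.gene_id = gene
        self.tis_tpos = tis_tpos
        self.orf_stop_tpos = orf_stop_tpos
        self.is_variant = variant


def _tx(biotype="protein_coding", coding=True):
    t = Transcript("t1", "G1", "chr1", "+", biotype, [(0, 300)])
    if coding:
        t.cds_start_genomic = 30
        t.cds_stop_genomic = 150
    return t


REF = {"G1": [("sp|P1|X", "MABCDEFGH")]}


@pytest.mark.parametrize("cand_kwargs,tx_kwargs,expect,sub", [
    (dict(seq="MZZZZZZ", tclass="ntr"), dict(biotype="processed_pseudogene", coding=False),
     "non_coding", "pseudogene"),
    (dict(seq="MZZZZZZ", tclass="5UTR", tis_tpos=0, orf_stop_tpos=21), {},
     "uORF", None),
    (dict(seq="MZZZZZZ", tclass="3UTR", tis_tpos=160), {}, "dORF", None),
    (dict(seq="MZZZZZZ", tclass="CDS", tis_tpos=31), {}, "out_of_frame_ORF", None),
    (dict(seq="MXXABCDEFGH", tclass="5UTR", tis_tpos=21, orf_stop_tpos=150), {},
     "N_terminal_extension", None),
    (dict(seq="MEFGH", tclass="CDS", tis_tpos=42), {}, "N_terminal_truncation", None),
    (dict(seq="MABCDEFGHQQ", tclass="aTIS"), {}, "C_terminal_extension", None),
    (dict(seq="MABCDE", tclass="aTIS"), {}, "C_terminal_truncation", None),
    (dict(seq="MABCDEFGX", tclass="aTIS", variant=True), {}, "SAV_only", None),
    (dict(seq="MABGH", tclass="aTIS"), {}, "new_splice_variant", "exon_skip"),
    (dict(seq="MABCQQQDEFGH", tclass="aTIS"), {}, "new_splice_variant", "novel_junction"),
    (dict(seq="MABCDEFGH", tclass="aTIS"), {}, "known", None),
])
def test_cascade_categories(cand_kwargs, tx_kwargs, expect, sub):
    label = classify(_Cand(**cand_kwargs), REF, {"t1": _tx(**tx_kwargs)})
    assert label.category == expect
    if sub is not None:
        assert label.subcategory == sub


def test_no_reference_falls_back_low_confidence():
    label = classify(_Cand("MZZZZZZ", tclass="5UTR", tis_tpos=21,
                           orf_stop_tpos=150), {}, {"t1": _tx()})
    assert label.category == "N_terminal_extension"
    assert label.evidence.get("low_confidence")


def test_equal_length_many_mismatches_is_not_sav():
    label = classify(_Cand("MQQQQQQQQ", tclass="aTIS"), REF, {"t1": _tx()})
    assert label.category == "new_splice_variant"


def test_classification_is_total_and_deterministic():
    c = _Cand("MABCDEFGX", tclass="aTIS")
    labels = {classify(c, REF, {"t1": _tx()}).category for _ in range(3)}
    assert labels == {"SAV_only"}
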