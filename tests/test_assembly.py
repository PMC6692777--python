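"""Assembly: spliced coordinates, translation rules (initiator M, seleno
recoding, no-stop), variant application and the fixtures proteome oracle."""

import pytest
from Bio.Seq import Seq

from riboforge.assembly import (EmptyOrfError, VariantConsistencyError,
                                apply_variants, assemble, spliced_sequence,
                                translate_orf)
from riboforge.ribo_io import Transcript


def test_spliced_sequence_plus_strand_concatenates_exons():
    t = Transcript("t", "g", "chr1", "+", "protein_coding", [(0, 3), (6, 9)])
    seq, gmap = spliced_sequence(t, {"chr1": "ATGCCCGGG"})
    assert seq == "ATGGGG"
    assert gmap == [0, 1, 2, 6, 7, 8]


def test_spliced_sequence_minus_strand_reverse_complements():
    t = Transcript("t", "g", "chr1", "-", "protein_coding", [(0, 3)])
    seq, gmap = spliced_sequence(t, {"chr1": "ATG"})
    assert seq == "CAT"
    assert gmap == [2, 1, 0]


def test_coordinate_map_is_a_bijection(class_files):
    t = next(x for x in class_files.scenario.transcripts if x.strand == "-")
    seq, gmap = spliced_sequence(t, class_files.scenario.genome)
    assert len(set(gmap)) == len(gmap) == len(seq)
    for tp, g in enumerate(gmap):
        assert t.genomic_to_transcript(g) == tp
        assert t.transcript_to_genomic(tp) == g


@pytest.mark.parametrize("seq,tis,seleno,stop_t,expect", [
    ("ATGGCCTAA", 0, False, None, ("MA", False)),
    ("ACGGCCTAA", 0, False, None, ("MA", False)),   # near-cognate initiator -> M
    ("ATGTGAGCCTAA", 0, True, 9, ("MUA", False)),   # in-frame TGA recoded to U
    ("ATGGCC", 0, False, None, ("MA", True)),       # runs off the end
])
def test_translation_rules(seq, tis, seleno, stop_t, expect):
    aa, no_stop, _ = translate_orf(seq, tis, seleno, stop_t)
    assert (aa, no_stop) == expect


def test_tga_past_annotated_stop_terminates_even_on_seleno():
    # annotated stop at 6; the TGA at 6 must terminate, not recode
    aa, no_stop, stop = translate_orf("ATGGCCTGA", 0, seleno=True,
                                      annotated_stop_tpos=6)
    assert (aa, no_stop, stop) == ("MA", False, 6)


def test_tis_too_close_to_end_is_error():
    with pytest.raises(EmptyOrfError):
        translate_orf("ATGG", 2)


def test_apply_variants_checks_reference_base():
    assert apply_variants("ATGGCC", [(3, "G", "T")]) == "ATGTCC"
    with pytest.raises(VariantConsistencyError):
        apply_variants("ATGGCC", [(3, "C", "T")])


def test_entries_retranslate_under_independent_codon_table(class_result, class_files):
    """Every emitted entry must re-translate identically under a Biopython
    per-codon oracle applied to the stored transcript coordinates."""
    genome = class_files.scenario.genome
    by_id = {t.transcript_id: t for t in class_files.scenario.transcripts}
    for e in class_result.entries:
        t = by_id[e.transcript_id]
        seq, _ = spliced_sequence(t, genome)
        if e.is_variant:
            vs = [v for v in class_result.variants if v.chrom == t.chrom]
            from riboforge.assembly import variants_to_transcript_space
            seq = apply_variants(seq, variants_to_transcript_space(t, vs))
        stop_t = (t.genomic_to_transcript(t.cds_stop_genomic)
                  if t.cds_stop_genomic is not None else None)
        aas, pos = [], e.tis_tpos
        while pos + 3 <= len(seq):
            codon = seq[pos:pos + 3]
            if pos == e.tis_tpos:
                aas.append("M")
            elif codon in ("TAA", "TAG", "TGA"):
                if codon == "TGA" and t.seleno and stop_t and pos < stop_t:
                    aas.append("U")
                else:
                    break
            else:
                aas.append(str(Seq(codon).translate()))
            pos += 3
        assert "".join(aas) == e.sequence, e.accession


def test_seleno_entries_contain_u_exactly_at_planted_tga(class_result, class_files):
    sel_ids = {t.transcript_id for t in class_files.scenario.transcripts if t.seleno}
    assert sel_ids
    for e in class_result.entries:
        if e.transcript_id in sel_ids and e.annotation_class == "aTIS":
            spec = next(s for s in class_files.scenario.config.transcripts
                        if s.transcript_id == e.transcript_id)
            u_pos = [i for i, a in enumerate(e.sequence) if a == "U"]
            assert u_pos == [spec.n_codons // 2]
            assert e.flags.get("seleno_recoded") == 1
        elif e.transcript_id not in sel_ids:
            assert "U" not in e.sequence


def test_extension_entry_has_atis_entry_as_exact_suffix(class_result):
    by_key = {}
    for e in class_result.entries:
        if not e.is_variant:
            by_key.setdefault(e.transcript_id, {})[e.annotation_class] = e
    found = 0
    for tid, d in by_key.items():
        if "5UTR" in d and "aTIS" in d and d["5UTR"].orf_stop_tpos == d["aTIS"].orf_stop_tpos:
            assert d["5UTR"].sequence.endswith(d["aTIS"].sequence)
            found += 1
    assert found >= 1


def test_assembly_matches_truth_manifest_proteome(class_result, class_files):
    got = sorted((e.transcript_id, e.tis_tpos, e.is_variant, e.sequence)
                 for e in class_result.entries)
    exp = sorted((r["transcript_id"], r["tis_tpos"], r["variant"], r["sequence"])
                 for r in class_files.manifest.expected_proteome)
    assert got == exp


def test_sav_recorded_in_protein_space(class_result, class_files):
    variant_entries = [e for e in class_result.entries if e.is_variant]
    assert variant_entries
    for e in variant_entries:
        for (pos, ref_aa, alt_aa) in e.variants_applied:
            assert 1 <= pos <= len(e.sequence)
            assert e.sequence[pos - 1] == alt_aa and ref_aa != alt_aa


def test_entry_count_monotone_in_passed_tis(class_result, class_files):
    genome = class_files.scenario.genome
    tx = class_files.scenario.transcripts
    full = assemble(class_result.tis_calls, class_result.variants, tx, genome)
    passed = [c for c in class_result.tis_calls if c.passed_rules]
    fewer = assemble(passed[:-2], class_result.variants, tx, genome)
    assert len(full) >= len(fewer)
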