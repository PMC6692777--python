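"""Allele-frequency SNP calling from the profiling alignments themselves.

Proteoforms should carry the sample's own single-amino-acid variants, so
single-nucleotide variants are called directly from the ribosome-profiling
alignments: a per-position base pileup followed by simple depth and allele
frequency thresholds.  Indels are deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pysam


@dataclass
class Variant:
    chrom: str
    pos: int          # 0-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int

    @property
    def af(self) -> float:
        return self.alt_count / self.depth

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        if not (0 < self.alt_count <= self.depth):
            raise ValueError("require 0 < alt_count <= depth")


def pileup(sam_path: str, max_hits: int = 16) -> dict[tuple[str, int], dict[str, int]]:
    """Per-position A/C/G/T counts from aligned read bases.

    Soft-clipped bases are excluded; reads whose CIGAR contains insertions
    or deletions are skipped with a warning (indel-aware calling is out of
    scope).
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            if nh > max_hits:
                continue
            if any(op in (1, 2, 3) for op, _ in rec.cigartuples or ()):
                warnings.warn(
                    f"read {rec.query_name}: indel/skip CIGAR, positions skipped")
                continue
            qpos, rpos = 0, rec.reference_start
            for op, ln in rec.cigartuples:
                if op == 0 or op == 7 or op == 8:      # M / = / X
                    for k in range(ln):
                        base = rec.query_sequence[qpos + k].upper()
                        if base in "ACGT":
                            d = counts.setdefault((rec.reference_name, rpos + k),
                                                  {"A": 0, "C": 0, "G": 0, "T": 0})
                            d[base] += 1
                    qpos += ln
                    rpos += ln
                elif op == 4:                           # S
                    qpos += ln
    return counts


def call_snps(counts: dict[tuple[str, int], dict[str, int]],
              genome: dict[str, str], min_depth: int = 10,
              min_af: float = 0.3) -> list[Variant]:
    """Call one SNV per position where the top non-reference base reaches
    ``min_af`` at ``min_depth`` coverage.  Deterministic in position order;
    base ties break alphabetically."""
    out: list[Variant] = []
    for (chrom, pos) in sorted(counts):
        d = counts[(chrom, pos)]
        depth = sum(d.values())
        if depth < min_depth:
            continue
        ref = genome[chrom][pos].upper()
        alts = [(n, b) for b, n in d.items() if b != ref and n > 0]
        if not alts:
            continue
        alt_count, alt = max(alts, key=lambda x: (x[0], -ord(x[1])))
        if alt_count / depth >= min_af:
            out.append(Variant(chrom=chrom, pos=pos, ref_base=ref,
                               alt_base=alt, depth=depth, alt_count=alt_count))
    return out


def write_vcf(variants: list[Variant], path: str,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Minimal VCF 4.2 writer (1-based positions, DP/AF in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=riboforge\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        for c, n in sorted((chrom_lengths or {}).items()):
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_base}\t{v.alt_base}\t.\tPASS\t"
                     f"DP={v.depth};AF={v.af:.4f}\n")
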