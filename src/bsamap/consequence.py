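"""Codon-level consequence annotation for CDS substitutions.

Maps a 1-based position in a spliced coding sequence to its codon and
residue, applies the standard nuclear genetic code, and classifies the
amino-acid change (synonymous / missense / stop_gained / stop_lost).
Genomic-to-CDS projection (strand, introns) is the caller's responsibility;
input is always the forward-strand spliced CDS.
"""

from __future__ import annotations

from dataclasses import dataclass

# Standard nuclear genetic code; '*' denotes a stop codon.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class CdsVariant:
    """A single-base substitution within a spliced CDS (1-based position)."""

    cds_pos: int
    ref_base: str
    alt_base: str


@dataclass(frozen=True)
class ProteinChange:
    codon_number: int   # 1-based residue index
    codon_offset: int   # 1..3 position within the codon
    ref_aa: str
    alt_aa: str
    consequence: str    # synonymous | missense | stop_gained | stop_lost

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.ref_aa}{self.codon_number}{self.alt_aa}"


def cds_position_to_codon(cds_pos: int) -> tuple[int, int]:
    """Codon number and within-codon offset of a CDS position.

    ``codon_number = ceil(cds_pos / 3)``; ``offset = cds_pos - 3*(codon_number-1)``,
    so position 1427 lands in codon 476 at offset 2.
    """
    if cds_pos < 1:
        raise ValueError("CDS positions are 1-based")
    codon_number = -(-cds_pos // 3)
    return codon_number, cds_pos - 3 * (codon_number - 1)


def annotate(cds_sequence: str, variant: CdsVariant) -> ProteinChange:
    """Annotate one CDS substitution with its protein-level consequence."""
    seq = cds_sequence.upper()
    if len(seq) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    if not 1 <= variant.cds_pos <= len(seq):
        raise ValueError(f"CDS position {variant.cds_pos} outside sequence "
                         f"of length {len(seq)}")
    ref, alt = variant.ref_base.upper(), variant.alt_base.upper()
    for base, what in ((ref, "ref"), (alt, "alt")):
        if base not in "ACGT":
            raise ValueError(f"ambiguous or invalid {what} base {base!r}")
    found = seq[variant.cds_pos - 1]
    if found != ref:
        raise ValueError(
            f"reference mismatch at CDS {variant.cds_pos}: sequence has "
            f"{found}, variant claims {ref}")
    codon_number, offset = cds_position_to_codon(variant.cds_pos)
    start = 3 * (codon_number - 1)
    ref_codon = seq[start:start + 3]
    alt_codon = ref_codon[:offset - 1] + alt + ref_codon[offset:]
    ref_aa, alt_aa = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "missense"
    return ProteinChange(codon_number, offset, ref_aa, alt_aa, consequence)


def hgvs_c(variant: CdsVariant) -> str:
    """HGVS-like coding notation, e.g. ``c.1427C>T``."""
    return f"c.{variant.cds_pos}{variant.ref_base}>{variant.alt_base}"
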