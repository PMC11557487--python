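"""Residue conservation across aligned plant homolog proteins.

Given a multiple alignment containing the focal (wheat) protein and its
homologs, the conservation of the mutated residue is the percentage of
non-focal sequences carrying the same residue at that alignment column.
Homologs gapped at the column are excluded from the denominator: a gap is
absence of evidence, not disagreement (``count_gaps_as_mismatch`` switches
this).
"""

from __future__ import annotations

from dataclasses import dataclass

GAP = "-"


class UndefinedConservation(ValueError):
    """Raised when every non-focal row is gapped at the focal column."""


@dataclass(frozen=True)
class HomologAlignment:
    """Equal-length aligned protein rows with one designated focal sequence.

    ``focal_column`` is the 0-based alignment column of the residue of
    interest; the focal sequence must not be gapped there.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    focal_id: str
    focal_column: int

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.rows:
            raise ValueError("need matching, non-empty id and row lists")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows must all have the same length")
        if self.focal_id not in self.ids:
            raise ValueError(f"focal sequence {self.focal_id!r} not in alignment")
        if not 0 <= self.focal_column < width:
            raise ValueError("focal column outside alignment")
        if self.focal_row[self.focal_column] == GAP:
            raise ValueError("focal sequence is gapped at the focal column")

    @property
    def focal_row(self) -> str:
        return self.rows[self.ids.index(self.focal_id)]


def column_conservation(alignment: HomologAlignment,
                        count_gaps_as_mismatch: bool = False) -> float:
    """Percent of non-focal homologs matching the focal residue at the column.

    Returns 100 x matches / informative rows, where informative rows are the
    non-focal rows without a gap at the column (all rows when
    ``count_gaps_as_mismatch``).
    """
    focal_res = alignment.focal_row[alignment.focal_column].upper()
    focal_index = alignment.ids.index(alignment.focal_id)
    matches = informative = 0
    for i, row in enumerate(alignment.rows):
        if i == focal_index:
            continue
        res = row[alignment.focal_column].upper()
        if res == GAP and not count_gaps_as_mismatch:
            continue
        informative += 1
        if res == focal_res:
            matches += 1
    if informative == 0:
        raise UndefinedConservation(
            "every non-focal homolog is gapped at the focal column")
    return 100.0 * matches / informative


def residue_to_column(aligned_focal: str, residue_pos: int) -> int:
    """0-based alignment column of the focal sequence's 1-based residue."""
    if residue_pos < 1:
        raise ValueError("residue positions are 1-based")
    seen = 0
    for col, ch in enumerate(aligned_focal):
        if ch != GAP:
            seen += 1
            if seen == residue_pos:
                return col
    raise ValueError(f"focal sequence has fewer than {residue_pos} residues")


def extract_flank(protein_sequence: str, residue_pos: int,
                  k: int) -> tuple[str, int]:
    """Window of up to ``2k + 1`` residues around a position, clipped at the ends.

    Returns (subsequence, 1-based offset of the focal residue within it);
    an unclipped window has the focal residue at offset ``k + 1``.
    """
    if not 1 <= residue_pos <= len(protein_sequence):
        raise ValueError(f"residue {residue_pos} outside sequence of length "
                         f"{len(protein_sequence)}")
    lo = max(0, residue_pos - 1 - k)
    hi = min(len(protein_sequence), residue_pos + k)
    return protein_sequence[lo:hi], residue_pos - lo
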