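"""Published reference tables for the wheat *srh1* short-root-hair locus.

Bundles the curated candidate-variant and differential-expression tables of
the *srh1* BC1F3 mapping study (chromosome 3A, cv. Cadenza x Chinese Spring
coordinates) so the prioritization cascade and DEG thresholding can be
re-run on the published values without the raw sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .scan import IntervalCall

#: Mapping intervals of the srh1 locus on chromosome 3A (bp, BED-like frame).
SRH1_WIDER_INTERVAL = IntervalCall("3A", 584_000_000, 647_000_000,
                                   threshold=0.35, max_value=0.66,
                                   peak_pos=606_000_000)
SRH1_PEAK_INTERVAL = IntervalCall("3A", 595_000_000, 617_000_000,
                                  threshold=0.5, max_value=0.66,
                                  peak_pos=606_000_000)

#: Phenotypic class counts of the BC1F2 segregation screen:
#: (wild-type, heterozygous, srh1), expected 1:2:1 for one semi-dominant locus.
SRH1_SEGREGATION_COUNTS = (62, 141, 63)

#: CDS substitutions of the candidate set plus the calreticulin-3 truncation:
#: (cds_pos, ref, alt, residue, ref_aa, alt_aa); alt_aa None where the
#: published residue identity is internally inconsistent and only the codon
#: arithmetic is trusted.
SRH1_CDS_SUBSTITUTIONS = [
    (1166, "G", "A", 389, "G", "E"),
    (1799, "A", "G", 600, "D", None),
    (1427, "C", "T", 476, "A", "V"),
    (187, "G", "A", 63, "E", "K"),
    (1103, "C", "T", 368, "P", "L"),
    (1459, "A", "G", 487, "S", "G"),
    (693, "G", "T", 231, "E", "D"),
    (1077, "G", "A", 359, "W", "*"),
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("bsamap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_candidate_table() -> pd.DataFrame:
    """The seven srh1 candidate variants inside the peak interval.

    Columns: gene_id, chrom, pos, cds_pos, ref, alt, aa_change, consequence,
    annotation, sift, conservation_pct.
    """
    return _load("srh1_candidates.tsv")


def load_deg_table() -> pd.DataFrame:
    """The 29 significant whole-root DEGs (srh1 vs wild-type).

    Genomic positions are filled in only where published (three chromosome-3A
    genes); `pos` is NaN elsewhere.
    """
    return _load("srh1_deg_combined_root.tsv")
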