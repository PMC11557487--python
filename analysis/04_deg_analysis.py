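#!/usr/bin/env python
"""Summarize the root differentially-expressed genes and their colocalization.

Applies the significance thresholds (FDR <= 0.01 and |log2FC| >= 1.5) to the
bundled combined-root DEG table, counts directions, reports the extreme
genes, and labels each gene by position relative to the mapping intervals.

Writes results/deg_labeled.tsv.
"""

from pathlib import Path

from bsamap.deg import (apply_thresholds, colocalize, count_directions,
                        extremes, lfc_to_fold)
from bsamap.reference import (SRH1_PEAK_INTERVAL, SRH1_WIDER_INTERVAL,
                              load_deg_table)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = load_deg_table()
    significant = apply_thresholds(table)
    down, up = count_directions(table, 1.5)
    print(f"{len(significant)} of {len(table)} genes pass FDR <= 0.01 "
          f"and |log2FC| >= 1.5")
    print(f"by magnitude-and-sign: {down} down-regulated, {up} up-regulated "
          f"(fold change at |log2FC| = 1.5: {lfc_to_fold(1.5):.2f})")

    ex = extremes(table)
    print(f"strongest down: {ex['min_log2fc']['gene_id']} "
          f"log2FC {ex['min_log2fc']['log2fc']:.2f}")
    print(f"strongest up:   {ex['max_log2fc']['gene_id']} "
          f"log2FC {ex['max_log2fc']['log2fc']:.2f}")
    print(f"smallest FDR:   {ex['min_fdr']['gene_id']} "
          f"FDR {ex['min_fdr']['fdr']:.2e}")

    labeled = colocalize(table, SRH1_PEAK_INTERVAL, SRH1_WIDER_INTERVAL)
    RESULTS.mkdir(exist_ok=True)
    labeled.to_csv(RESULTS / "deg_labeled.tsv", sep="\t", index=False)
    print(labeled["colocalization"].value_counts().to_string())


if __name__ == "__main__":
    main()
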