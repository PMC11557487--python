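#!/usr/bin/env python
"""Scan the simulated bulks for the causal region.

Reads results/bulks.vcf (from 01_simulate_bulks.py), applies the per-site
filters (SNPs only, both bulks called, per-bulk depth 5-200), computes the
bulk-frequency ratio (BFR = mutant-bulk BAF minus wild-type-bulk BAF) and
scans 27.5 Mb windows jumped by 1.5 Mb. Intervals are called where window
mean BFR >= 0.35 (wider interval) and >= 0.5 (peak interval).

Writes results/windows.tsv, results/intervals.bed, results/peak_intervals.bed.
"""

from pathlib import Path

from bsamap.io import read_vcf_bulks, write_intervals_bed
from bsamap.scan import ScanConfig, add_bfr, call_intervals, site_filter, \
    window_scan

RESULTS = Path(__file__).resolve().parent.parent / "results"
CHROM_SIZES = {f"chr{i}": 100_000_000 for i in range(1, 6)}


def main() -> None:
    records = read_vcf_bulks(RESULTS / "bulks.vcf")
    filtered = add_bfr(site_filter(records))
    print(f"{len(records)} sites read, {len(filtered)} pass site filters")

    windows = window_scan(filtered, ScanConfig(), CHROM_SIZES)
    windows.to_csv(RESULTS / "windows.tsv", sep="\t", index=False)

    wider = call_intervals(windows, threshold=0.35)
    peaks = call_intervals(windows, threshold=0.5)
    write_intervals_bed(wider, RESULTS / "intervals.bed")
    write_intervals_bed(peaks, RESULTS / "peak_intervals.bed")

    for label, calls in (("BFR >= 0.35", wider), ("BFR >= 0.50", peaks)):
        print(f"{label}: {len(calls)} interval(s)")
        for iv in calls:
            print(f"  {iv.chrom}:{iv.start:,}-{iv.end:,}  "
                  f"max {iv.max_value:.3f}  peak at {iv.peak_pos:,}")


if __name__ == "__main__":
    main()
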