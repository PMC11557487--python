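"""Bulked-allele-frequency genome scan.

In bulked segregant analysis (BSA-seq) two pools of phenotypically extreme
individuals from a segregating population are sequenced jointly.  At a site
linked to the causal locus the two bulks diverge in allele frequency, while
unlinked sites stay near the population expectation.  The scan statistic used
here is the bulked frequency ratio

    BAF = AA / RD            (alternate-allele depth over total depth, per bulk)
    BFR = BAF_mut - BAF_wt   (signed difference between the two bulks)

aggregated over an overlapping "jumping" window (fixed width, advanced by a
step smaller than the width), from which mapping intervals are called by
thresholding and merging qualifying windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of a variant-call table as produced by the simulator / VCF reader.
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "qual",
    "aa_mut", "rd_mut", "aa_wt", "rd_wt",
    "is_indel", "is_missing_mut", "is_missing_wt",
]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the jumping-window scan.

    The defaults are the exome-capture BSA settings for hexaploid wheat:
    a 27.5 Mb window advanced in 1.5 Mb jumps (overlapping, since the jump is
    smaller than the width), per-variant BFRs combined by the arithmetic mean.
    """

    window_bp: int = 27_500_000
    jump_bp: int = 1_500_000
    stat: str = "mean"                  # "mean" or "median"
    min_variants_per_window: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.jump_bp <= self.window_bp):
            raise ValueError("require window_bp >= jump_bp > 0")
        if self.stat not in ("mean", "median"):
            raise ValueError(f"unknown window statistic {self.stat!r}")
        if self.min_variants_per_window < 1:
            raise ValueError("min_variants_per_window must be >= 1")


@dataclass(frozen=True)
class IntervalCall:
    """A mapping interval: merged run of windows whose BFR meets a threshold.

    Coordinates are 0-based half-open (BED convention), matching the window
    frame; a 1-based variant position ``p`` lies inside iff ``start < p <= end``.
    """

    chrom: str
    start: int          # half-open [start, end), bp
    end: int
    threshold: float
    max_value: float
    peak_pos: int       # midpoint of the best window (ties -> lowest coordinate)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must precede end")

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos <= self.end


def compute_baf(aa: int, rd: int) -> float:
    """Bulked allele frequency at one site in one bulk: ``aa / rd``.

    ``rd == 0`` is a missing observation, not a zero frequency; such sites
    must be flagged missing upstream rather than passed here.
    """
    if rd <= 0:
        raise ValueError("BAF undefined at zero total depth; flag the site missing")
    if not 0 <= aa <= rd:
        raise ValueError(f"alternate depth {aa} outside [0, {rd}]")
    return aa / rd


def compute_bfr(baf_mut: float, baf_wt: float) -> float:
    """Signed bulked frequency ratio: mutant-bulk BAF minus wild-type-bulk BAF."""
    for v in (baf_mut, baf_wt):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"BAF {v} outside [0, 1]")
    return baf_mut - baf_wt


def site_filter(records: pd.DataFrame, min_depth: int = 5,
                max_depth: int = 200) -> pd.DataFrame:
    """Site-level filters applied before the scan.

    Keeps biallelic SNPs that are non-missing in both bulks and whose total
    depth lies in ``[min_depth, max_depth]`` in each bulk separately.
    """
    keep = (
        ~records["is_indel"].astype(bool)
        & ~records["is_missing_mut"].astype(bool)
        & ~records["is_missing_wt"].astype(bool)
        & records["rd_mut"].between(min_depth, max_depth)
        & records["rd_wt"].between(min_depth, max_depth)
    )
    return records.loc[keep].reset_index(drop=True)


def add_bfr(records: pd.DataFrame, signed: bool = True) -> pd.DataFrame:
    """Append per-site ``baf_mut``, ``baf_wt`` and ``bfr`` columns.

    Records must already have passed :func:`site_filter` (positive depths).
    With ``signed=False`` the absolute BFR is reported, for data where the
    reference polarity of the causal allele is unknown.
    """
    out = records.copy()
    out["baf_mut"] = out["aa_mut"] / out["rd_mut"]
    out["baf_wt"] = out["aa_wt"] / out["rd_wt"]
    bfr = out["baf_mut"] - out["baf_wt"]
    out["bfr"] = bfr if signed else bfr.abs()
    return out


def _window_starts(chrom_len: int, config: ScanConfig) -> np.ndarray:
    return np.arange(0, chrom_len, config.jump_bp, dtype=np.int64)


def window_scan(records: pd.DataFrame, config: ScanConfig | None = None,
                chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Aggregate per-variant BFR over a jumping window.

    Windows are anchored at 0 and advanced by ``jump_bp`` per chromosome,
    each spanning the half-open range ``[start, start + window_bp)`` clipped
    at the chromosome end.  A window supported by fewer than
    ``min_variants_per_window`` variants is reported with ``called=False``
    and a NaN value.

    Parameters
    ----------
    records
        Variant table with a ``bfr`` column (see :func:`add_bfr`), sorted by
        (chrom, pos).
    chrom_sizes
        Chromosome lengths in bp; when omitted, the last variant position per
        chromosome is used.

    Returns
    -------
    DataFrame with columns chrom, start, end, n, value, called.
    """
    config = config or ScanConfig()
    for chrom, group in records.groupby("chrom", sort=False):
        if not group["pos"].is_monotonic_increasing:
            raise ValueError(f"records on {chrom} are not sorted by position")

    agg = np.mean if config.stat == "mean" else np.median
    rows = []
    chroms = list(chrom_sizes) if chrom_sizes else list(dict.fromkeys(records["chrom"]))
    by_chrom = dict(tuple(records.groupby("chrom", sort=False)))
    for chrom in chroms:
        group = by_chrom.get(chrom)
        if chrom_sizes:
            chrom_len = chrom_sizes[chrom]
        elif group is not None:
            chrom_len = int(group["pos"].max())
        else:
            continue
        pos = group["pos"].to_numpy() if group is not None else np.empty(0)
        bfr = group["bfr"].to_numpy() if group is not None else np.empty(0)
        for start in _window_starts(chrom_len, config):
            end = min(start + config.window_bp, chrom_len)
            # VCF positions are 1-based; window [start, end) covers pos in (start, end]
            in_win = (pos > start) & (pos <= end)
            n = int(in_win.sum())
            called = n >= config.min_variants_per_window
            rows.append({
                "chrom": chrom, "start": int(start), "end": int(end),
                "n": n, "value": float(agg(bfr[in_win])) if called else math.nan,
                "called": called,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n", "value", "called"])


def call_intervals(windows: pd.DataFrame, threshold: float) -> list[IntervalCall]:
    """Merge qualifying windows (value >= threshold) into mapping intervals.

    Overlapping or abutting qualifying windows on the same chromosome are
    merged; the interval spans from the first window's start to the last
    window's end, and the peak is the midpoint of the window with the maximal
    value (ties broken toward the lowest coordinate).
    """
    calls: list[IntervalCall] = []
    qual = windows[windows["called"] & (windows["value"] >= threshold)]
    for chrom, group in qual.groupby("chrom", sort=False):
        group = group.sort_values(["start", "end"])
        cluster: list[pd.Series] = []
        for _, win in group.iterrows():
            if cluster and win["start"] > cluster[-1]["end"]:
                calls.append(_finish_cluster(chrom, cluster, threshold))
                cluster = []
            cluster.append(win)
        if cluster:
            calls.append(_finish_cluster(chrom, cluster, threshold))
    return calls


def _finish_cluster(chrom: str, cluster: list[pd.Series],
                    threshold: float) -> IntervalCall:
    best = max(cluster, key=lambda w: (w["value"], -w["start"]))
    return IntervalCall(
        chrom=chrom,
        start=int(min(w["start"] for w in cluster)),
        end=int(max(w["end"] for w in cluster)),
        threshold=threshold,
        max_value=float(best["value"]),
        peak_pos=int((best["start"] + best["end"]) // 2),
    )
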