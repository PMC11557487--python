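"""Differential-expression table filtering and interval colocalization.

Consumes an already-fitted expression contrast (gene, chromosome, position,
Log2 fold change, BH-adjusted FDR) and applies significance / effect-size
thresholds, direction labels, fold-change conversion, extreme extraction and
colocalization of significant genes with the mapped interval.  Model fitting
and shrinkage are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import IntervalCall


@dataclass(frozen=True)
class DegThresholds:
    """Inclusive cutoffs: keep genes with fdr <= fdr_max and |log2fc| >= lfc_abs_min.

    Defaults are the whole-root contrast values (FDR 0.01, |Log2FC| 1.5,
    i.e. a 2.83-fold change); mature-zone contrasts conventionally tighten
    to (0.001, 2).
    """

    fdr_max: float = 0.01
    lfc_abs_min: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.lfc_abs_min < 0:
            raise ValueError("lfc_abs_min must be non-negative")


def apply_thresholds(table: pd.DataFrame,
                     thresholds: DegThresholds | None = None) -> pd.DataFrame:
    """Significant DEGs with a ``direction`` label (down iff log2fc < 0)."""
    thresholds = thresholds or DegThresholds()
    keep = (table["fdr"] <= thresholds.fdr_max) & \
           (table["log2fc"].abs() >= thresholds.lfc_abs_min)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] < 0, "down", "up")
    return out.reset_index(drop=True)


def count_directions(table: pd.DataFrame, lfc_abs_min: float = 1.5) -> tuple[int, int]:
    """(n_down, n_up) by the sign/magnitude rule alone: log2fc <= -c / >= +c."""
    down = int((table["log2fc"] <= -lfc_abs_min).sum())
    up = int((table["log2fc"] >= lfc_abs_min).sum())
    return down, up


def lfc_to_fold(log2fc: float) -> float:
    """Fold change implied by a Log2FC magnitude: ``2 ** |log2fc|``.

    Both signs map to the same fold (a gene halved and a gene doubled are
    both 2-fold changes); direction is carried separately.
    """
    return 2.0 ** abs(log2fc)


def extremes(table: pd.DataFrame) -> dict[str, pd.Series]:
    """Most down-regulated, most up-regulated, and most significant record.

    Ties are broken by lexical gene id so results are reproducible.
    """
    if table.empty:
        raise ValueError("extremes of an empty DEG table are undefined")
    ordered = table.sort_values("gene_id", kind="stable")
    return {
        "min_log2fc": ordered.loc[ordered["log2fc"].idxmin()],
        "max_log2fc": ordered.loc[ordered["log2fc"].idxmax()],
        "min_fdr": ordered.loc[ordered["fdr"].idxmin()],
    }


def colocalize(degs: pd.DataFrame, peak: IntervalCall | tuple[str, int, int],
               wider: IntervalCall | tuple[str, int, int]) -> pd.DataFrame:
    """Label each gene in_peak / in_wider / outside the mapping intervals.

    Membership is inclusive at both ends (the intervals come from Mb-rounded
    window bounds); genes on another chromosome, or without a known position,
    are outside.
    """
    def _bounds(iv):
        if isinstance(iv, IntervalCall):
            return iv.chrom, iv.start, iv.end
        return iv

    pc, ps, pe = _bounds(peak)
    wc, ws, we = _bounds(wider)
    out = degs.copy()
    pos = pd.to_numeric(out["pos"], errors="coerce")
    in_peak = (out["chrom"] == pc) & (pos >= ps) & (pos <= pe)
    in_wider = (out["chrom"] == wc) & (pos >= ws) & (pos <= we)
    out["colocalization"] = np.select(
        [in_peak.fillna(False), in_wider.fillna(False)],
        ["in_peak", "in_wider"], default="outside")
    return out
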