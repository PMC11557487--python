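"""Mendelian segregation goodness-of-fit.

A semi-dominant single-locus trait segregates 1:2:1 in an F2-type
generation; the Pearson chi-square test compares observed phenotypic class
counts against any hypothesized ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SegregationResult:
    statistic: float
    df: int
    p_value: float
    expected: tuple[float, ...]


def chisq_gof(observed: list[int] | tuple[int, ...],
              ratio: list[float] | tuple[float, ...] = (1, 2, 1),
              continuity_correction: bool = False) -> SegregationResult:
    """Pearson goodness-of-fit of class counts against a ratio.

    Expected counts are total x weight / sum(weights); the statistic is
    sum((|O-E| - c)^2 / E) with c = 0.5 under Yates' correction (off by
    default — with three classes and 2 df no correction is conventional).
    """
    obs = np.asarray(observed, dtype=float)
    weights = np.asarray(ratio, dtype=float)
    if obs.shape != weights.shape or obs.size < 2:
        raise ValueError("need matching observed counts and ratio weights "
                         "for at least two classes")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (weights <= 0).any():
        raise ValueError("ratio weights must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total * weights / weights.sum()
    if continuity_correction:
        stat = float((((np.abs(obs - expected) - 0.5) ** 2) / expected).sum())
        df = obs.size - 1
        p = float(stats.chi2.sf(stat, df))
    else:
        stat, p = stats.chisquare(obs, expected)
        stat, p = float(stat), float(p)
        df = obs.size - 1
    return SegregationResult(stat, df, p, tuple(expected))
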