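"""Candidate-gene prioritization cascade.

Variants inside the mapped interval are whittled down through the stages a
mutant-mapping study applies after the genome scan:

1. restrict to the mapping interval;
2. discard low-confidence calls (quality <= 50 OR combined depth <= 20);
3. keep exonic variants only, attaching their gene ids;
4. keep genes expressed in the tissue of interest (root);
5. keep non-synonymous variants predicted deleterious (SIFT <= 0.05);
6. keep variants whose reference residue is conserved (>= 70%) across
   plant homologs.

Each survivor is also classified by EMS mutation spectrum: C→T and G→A (as
written against the reference strand) are the canonical alkylation-induced
transitions; everything else is atypical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .scan import IntervalCall

log = logging.getLogger(__name__)

NONSYNONYMOUS = {"missense", "stop_gained", "stop_lost"}
_CANONICAL_PAIRS = {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the wheat exome-capture values."""

    qual_max_discard: float = 50.0        # discard if qual <= this
    combined_depth_max_discard: int = 20  # discard if rd_mut + rd_wt <= this
    sift_max: float = 0.05                # keep if sift <= this
    conservation_min_pct: float = 70.0    # keep if conservation >= this
    expression_min: float = 0.5           # keep if root expression > this (TPM-like)

    def __post_init__(self) -> None:
        if min(self.qual_max_discard, self.combined_depth_max_discard,
               self.sift_max, self.conservation_min_pct, self.expression_min) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class CandidateReport:
    """Per-stage bookkeeping of the cascade plus the final candidate table."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def record(self, stage: str, df: pd.DataFrame) -> None:
        self.stage_counts.append((stage, len(df)))

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "n_variants"])


def interval_filter(variants: pd.DataFrame, interval: IntervalCall) -> pd.DataFrame:
    # interval is 0-based half-open; pos is 1-based
    keep = ((variants["chrom"] == interval.chrom)
            & (variants["pos"] > interval.start)
            & (variants["pos"] <= interval.end))
    return variants.loc[keep].reset_index(drop=True)


def qual_depth_filter(variants: pd.DataFrame,
                      config: FilterConfig | None = None) -> pd.DataFrame:
    """Discard calls with quality <= 50 or combined sample depth <= 20.

    Either defect alone disqualifies a call: a high-depth variant with a poor
    quality score is as untrustworthy as a confident call with almost no
    supporting reads.
    """
    config = config or FilterConfig()
    combined = variants["rd_mut"] + variants["rd_wt"]
    keep = (variants["qual"] > config.qual_max_discard) & \
           (combined > config.combined_depth_max_discard)
    return variants.loc[keep].reset_index(drop=True)


def exome_filter(variants: pd.DataFrame,
                 exons: pd.DataFrame) -> pd.DataFrame:
    """Keep variants inside annotated exons and attach gene ids.

    ``exons`` columns: gene_id, chrom, start, end (1-based inclusive).  A
    variant inside exons of several overlapping gene models is emitted once
    per gene and flagged ``multi_gene``.
    """
    rows = []
    for _, var in variants.iterrows():
        hits = exons[(exons["chrom"] == var["chrom"])
                     & (exons["start"] <= var["pos"])
                     & (var["pos"] <= exons["end"])]
        genes = sorted(hits["gene_id"].unique())
        for gene in genes:
            row = var.to_dict()
            row["gene_id"] = gene
            row["multi_gene"] = len(genes) > 1
            rows.append(row)
    if not rows:
        out = variants.iloc[0:0].copy()
        out["gene_id"] = pd.Series(dtype=str)
        out["multi_gene"] = pd.Series(dtype=bool)
        return out
    return pd.DataFrame(rows).reset_index(drop=True)


def expression_filter(variants: pd.DataFrame, expression: dict[str, float],
                      config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep variants in genes expressed in root tissue (strictly above cutoff).

    Genes absent from the expression table are treated as not expressed.
    """
    config = config or FilterConfig()
    missing = set(variants["gene_id"]) - set(expression)
    if missing:
        log.warning("no expression value for %d gene(s): %s — treated as "
                    "not expressed", len(missing), sorted(missing)[:5])
    keep = variants["gene_id"].map(
        lambda g: expression.get(g, 0.0) > config.expression_min)
    return variants.loc[keep].reset_index(drop=True)


def sift_filter(variants: pd.DataFrame,
                config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep non-synonymous variants predicted deleterious (SIFT <= 0.05).

    A non-synonymous variant lacking a SIFT prediction is retained with a
    warning (missing evidence is not evidence of tolerance).
    """
    config = config or FilterConfig()
    nonsyn = variants["consequence"].isin(NONSYNONYMOUS)
    sift = pd.to_numeric(variants["sift"], errors="coerce")
    no_score = nonsyn & sift.isna()
    if no_score.any():
        log.warning("%d non-synonymous variant(s) without SIFT score retained",
                    int(no_score.sum()))
    keep = nonsyn & (sift.isna() | (sift <= config.sift_max))
    return variants.loc[keep].reset_index(drop=True)


def ems_classify(ref: str, alt: str) -> str:
    """EMS mutation-spectrum class of a substitution: canonical or atypical.

    EMS alkylates guanine, producing C→T transitions (read G→A on the other
    strand); exactly those two reference-strand substitutions are canonical.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"ems_classify expects single-base SNP, got {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return "canonical" if (ref, alt) in _CANONICAL_PAIRS else "atypical"


def conservation_filter(variants: pd.DataFrame,
                        config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep variants whose reference residue is >= 70% conserved in homologs.

    Variants without a conservation value are removed with a warning.
    """
    config = config or FilterConfig()
    pct = pd.to_numeric(variants["conservation_pct"], errors="coerce")
    if pct.isna().any():
        log.warning("%d variant(s) without conservation value removed",
                    int(pct.isna().sum()))
    keep = pct >= config.conservation_min_pct
    return variants.loc[keep].reset_index(drop=True)


def run_cascade(variants: pd.DataFrame, interval: IntervalCall | None,
                exons: pd.DataFrame | None = None,
                expression: dict[str, float] | None = None,
                config: FilterConfig | None = None) -> CandidateReport:
    """Apply the full prioritization cascade and report per-stage counts.

    Stages needing side tables (exons, expression) are skipped when the table
    is not supplied — the input is then expected to carry ``gene_id`` /
    ``consequence`` / ``sift`` / ``conservation_pct`` columns already, as when
    re-filtering a published candidate table.
    """
    config = config or FilterConfig()
    report = CandidateReport()
    current = variants.reset_index(drop=True)
    report.record("input", current)
    if interval is not None:
        current = interval_filter(current, interval)
        report.record("interval", current)
    if {"qual", "rd_mut", "rd_wt"} <= set(current.columns):
        current = qual_depth_filter(current, config)
        report.record("qual_depth", current)
    if exons is not None:
        current = exome_filter(current, exons)
        report.record("exome", current)
    if expression is not None:
        current = expression_filter(current, expression, config)
        report.record("expression", current)
    current = sift_filter(current, config)
    report.record("sift", current)
    current = conservation_filter(current, config)
    report.record("conservation", current)
    final = current.copy()
    if not final.empty:
        final["ems_class"] = [
            ems_classify(r, a) for r, a in zip(final["ref"], final["alt"])]
    else:
        final["ems_class"] = pd.Series(dtype=str)
    report.table = final
    return report
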