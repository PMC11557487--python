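"""File-format adapters: two-sample VCF, BED intervals, TSV tables, FASTA.

Coordinate conventions: VCF and exon/expression TSVs are 1-based inclusive;
BED output is 0-based half-open (which is also the internal frame of
:class:`~bsamap.scan.IntervalCall`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .scan import VARIANT_COLUMNS, IntervalCall


class VcfFormatError(ValueError):
    pass


def write_vcf_bulks(records: pd.DataFrame, path: str | Path,
                    chrom_sizes: dict[str, int] | None = None,
                    sample_mut: str = "mut_bulk",
                    sample_wt: str = "wt_bulk") -> None:
    """Write a variant-call table as an uncompressed two-sample VCF.

    Per sample the AD (ref,alt depths) and DP FORMAT fields carry the bulk
    read counts; a bulk with zero depth is emitted with a missing genotype.
    """
    path = Path(path)
    if chrom_sizes is None:
        chrom_sizes = {c: int(g["pos"].max())
                       for c, g in records.groupby("chrom", sort=False)}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap\n")
        for chrom, length in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_mut}\t{sample_wt}\n")
        for _, r in records.iterrows():
            fields = []
            for aa, rd, missing in ((r["aa_mut"], r["rd_mut"], r["is_missing_mut"]),
                                    (r["aa_wt"], r["rd_wt"], r["is_missing_wt"])):
                if missing or rd == 0:
                    fields.append("./.:.:.")
                else:
                    gt = "1/1" if aa == rd else ("0/0" if aa == 0 else "0/1")
                    fields.append(f"{gt}:{int(rd) - int(aa)},{int(aa)}:{int(rd)}")
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t"
                     f"{r['qual']}\t.\t.\tGT:AD:DP\t{fields[0]}\t{fields[1]}\n")


def read_vcf_bulks(path: str | Path, sample_mut: str | None = None,
                   sample_wt: str | None = None) -> pd.DataFrame:
    """Parse a two-sample VCF into a variant-call table.

    The first sample is the mutant bulk and the second the wild-type bulk
    unless sample names are given.  Sites with a missing genotype or absent
    depth are flagged, not dropped, so the downstream site filter stays the
    single place where records are discarded.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(samples) != 2:
        raise VcfFormatError(f"expected exactly two samples, found {samples}")
    s_mut = sample_mut or samples[0]
    s_wt = sample_wt or samples[1]
    for s in (s_mut, s_wt):
        if s not in samples:
            raise VcfFormatError(f"sample {s!r} not present in {samples}")
    rows = []
    for line_no, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        alt = alts[0] if alts else ""
        is_indel = bool(alt) and (len(rec.ref) != len(alt))
        row = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt,
            "qual": rec.qual if rec.qual is not None else 0.0,
            "is_indel": is_indel,
        }
        for tag, sample in (("mut", s_mut), ("wt", s_wt)):
            call = rec.samples[sample]
            gt = call.get("GT")
            missing_gt = gt is None or any(a is None for a in gt)
            ad = call.get("AD")
            dp = call.get("DP")
            if ad is not None and not any(a is None for a in ad):
                aa = int(sum(ad[1:]))
                rd = int(dp) if dp is not None else int(sum(ad))
            elif dp is not None:
                raise VcfFormatError(
                    f"sample {sample!r} lacks AD at line {line_no} "
                    f"({rec.chrom}:{rec.pos})")
            else:
                aa, rd = 0, 0
            row[f"aa_{tag}"] = aa
            row[f"rd_{tag}"] = rd
            row[f"is_missing_{tag}"] = missing_gt or rd == 0
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    df = pd.DataFrame(rows)[VARIANT_COLUMNS]
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_intervals_bed(intervals: list[IntervalCall], path: str | Path) -> None:
    """Write interval calls as BED (0-based half-open), one line per interval.

    Columns: chrom, start, end, name (threshold), score (max BFR x 1000,
    capped at 1000), plus the peak position as a seventh column.
    """
    with Path(path).open("w") as fh:
        for iv in intervals:
            score = min(1000, int(round(abs(iv.max_value) * 1000)))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"bfr_ge_{iv.threshold:g}\t{score}\t.\t{iv.peak_pos}\n")


def read_intervals_bed(path: str | Path) -> list[IntervalCall]:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        threshold = float(parts[3].removeprefix("bfr_ge_")) if len(parts) > 3 else 0.0
        score = int(parts[4]) / 1000 if len(parts) > 4 else 0.0
        peak = int(parts[6]) if len(parts) > 6 else (start + end) // 2
        intervals.append(IntervalCall(chrom, start, end, threshold,
                                      max(score, threshold), peak))
    return intervals


def read_exons_tsv(path: str | Path) -> pd.DataFrame:
    """Exon table: gene_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"exon table needs columns {sorted(required)}")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Per-gene root-tissue expression: gene_id, expression columns."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"], df["expression"].astype(float)))


def read_deg_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "log2fc", "fdr"}
    if not required <= set(df.columns):
        raise ValueError(f"DEG table needs columns {sorted(required)}")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered id -> sequence mapping of a (possibly aligned) FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
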