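"""Forward simulation of an EMS backcross mapping population.

Emulates the data-generating process behind an exome-capture BSA experiment
on a mutagenized wheat line:

* EMS mutagenesis lays down mostly C→T / G→A transitions across the genome;
  after four selfing generations (M4) the mutant parent is homozygous for its
  background mutations.
* The mutant is backcrossed to the wild-type progenitor, so the BC1F1 is
  heterozygous at every mutant-line variant, in coupling phase with the
  causal allele.  Two rounds of selfing (two meioses per individual) yield
  BC1F3 individuals.
* Because the causal locus is semi-dominant, homozygous mutant and homozygous
  wild-type BC1F3 individuals can be recognized phenotypically and pooled
  into two bulks.
* Each bulk is sequenced: per site, total depth is Poisson and the
  alternate-allele depth is Binomial in the bulk's true allele frequency,
  perturbed by a symmetric base-miscall rate.

Recombination between loci follows the Haldane map function on physical
distance scaled by a constant cM/Mb rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .scan import VARIANT_COLUMNS

_EMS_CANONICAL = [("C", "T"), ("G", "A")]
_BASES = np.array(list("ACGT"))
# transversions/ non-canonical transitions used for the atypical fraction
_EMS_ATYPICAL = [(r, a) for r in "ACGT" for a in "ACGT"
                 if r != a and (r, a) not in _EMS_CANONICAL]


@dataclass(frozen=True)
class GenomeModel:
    """Coordinate frame of the simulated genome: named chromosome lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @classmethod
    def regular(cls, n_chrom: int = 5, length_bp: int = 100_000_000) -> "GenomeModel":
        return cls(tuple((f"chr{i + 1}", length_bp) for i in range(n_chrom)))


@dataclass(frozen=True)
class CrossDesign:
    """Structure of the mapping population and bulk selection rule.

    Defaults mirror a wheat BC1F3 bulk design: 63 homozygous-mutant and 55
    homozygous-wild-type seedlings selected from a population segregating a
    single semi-dominant locus, with a wheat-like 0.3 cM/Mb map rate.
    """

    causal_chrom: str = "chr1"
    causal_pos: int = 60_000_000
    dominance: str = "semi-dominant"    # recessive | semi-dominant | dominant
    n_bulk_mut: int = 63
    n_bulk_wt: int = 55
    map_rate: float = 0.3               # cM per Mb
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dominance not in ("recessive", "semi-dominant", "dominant"):
            raise ValueError(f"unknown dominance {self.dominance!r}")
        if self.n_bulk_mut <= 0 or self.n_bulk_wt <= 0:
            raise ValueError("bulk sizes must be positive")
        if self.map_rate < 0:
            raise ValueError("map rate must be non-negative")


@dataclass(frozen=True)
class DepthModel:
    """Sequencing depth and error model: Poisson depth, symmetric miscalls."""

    mean_depth: float = 40.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")


def simulate_ems_variants(genome: GenomeModel, density: float = 3.0,
                          canonical_fraction: float = 0.98,
                          seed: int = 0) -> pd.DataFrame:
    """Scatter EMS-induced point mutations over the genome.

    Per chromosome the variant count is Poisson with mean ``density`` (per Mb)
    times the length; positions are uniform and strictly increasing.  Each
    variant is a canonical EMS transition (C→T or G→A, as written against the
    reference strand) with probability ``canonical_fraction``, otherwise a
    uniformly chosen non-canonical substitution.

    Returns a DataFrame with columns chrom, pos, ref, alt.
    """
    if not 0 <= canonical_fraction <= 1:
        raise ValueError("canonical_fraction must lie in [0, 1]")
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in genome.chromosomes:
        n = rng.poisson(density * length / 1e6)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + 1
        canonical = rng.random(len(pos)) < canonical_fraction
        pairs = [_EMS_CANONICAL[i] for i in rng.integers(0, 2, len(pos))]
        atypical_idx = rng.integers(0, len(_EMS_ATYPICAL), len(pos))
        for j, p in enumerate(pos):
            ref, alt = pairs[j] if canonical[j] else _EMS_ATYPICAL[atypical_idx[j]]
            rows.append((chrom, int(p), ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def haldane_r(distance_bp: np.ndarray, map_rate: float) -> np.ndarray:
    """Recombination fraction from physical distance via the Haldane map.

    ``d`` (Morgans) = map_rate [cM/Mb] x distance [Mb] / 100;
    ``r = (1 - exp(-2 d)) / 2``, capped at 0.5 for unlinked loci.
    """
    morgans = map_rate * np.asarray(distance_bp, dtype=float) / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, r_adj: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from a pair of haplotype matrices.

    ``hap_a``/``hap_b``: (n_ind, n_loci) allele matrices; ``r_adj``:
    recombination fractions between adjacent loci (n_loci - 1).  The choice of
    parental haplotype along the chromosome is a two-state Markov chain with
    switch probabilities ``r_adj`` (crossover count parity under Haldane's
    no-interference model).
    """
    n_ind, n_loci = hap_a.shape
    switch = np.empty((n_ind, n_loci), dtype=bool)
    switch[:, 0] = rng.random(n_ind) < 0.5
    if n_loci > 1:
        switch[:, 1:] = rng.random((n_ind, n_loci - 1)) < r_adj
    use_b = np.logical_xor.accumulate(switch, axis=1)
    return np.where(use_b, hap_b, hap_a)


def _bc1f3_dosages(n_ind: int, pos: np.ndarray, map_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Mutant-allele dosage (0/1/2) at each locus for n_ind BC1F3 individuals.

    Each individual descends from its own BC1F2 parent: the BC1F1 (het at all
    loci, causal allele in coupling) is selfed once to make the F2, and the F2
    selfed once to make the F3 — two meioses per generation transition.
    """
    n_loci = len(pos)
    r_adj = haldane_r(np.diff(pos), map_rate)
    ones = np.ones((n_ind, n_loci), dtype=np.int8)
    zeros = np.zeros((n_ind, n_loci), dtype=np.int8)
    # F1 haplotypes: mutant parental chromosome = all 1, wild-type = all 0
    f2_a = _gametes(ones, zeros, r_adj, rng)
    f2_b = _gametes(ones, zeros, r_adj, rng)
    f3_a = _gametes(f2_a, f2_b, r_adj, rng)
    f3_b = _gametes(f2_a, f2_b, r_adj, rng)
    return f3_a + f3_b


def _phenotype_classes(dominance: str) -> tuple[set[int], set[int]]:
    """(mutant-phenotype dosages, wild-type-phenotype dosages) at the causal locus."""
    if dominance == "semi-dominant":
        # heterozygotes show an intermediate phenotype and are left out of both bulks
        return {2}, {0}
    if dominance == "recessive":
        return {2}, {0, 1}
    return {1, 2}, {0}


def simulate_bulks(variants: pd.DataFrame, design: CrossDesign,
                   depth: DepthModel | None = None) -> pd.DataFrame:
    """Simulate bulk sequencing of the two phenotypic pools.

    Individuals are generated (in batches, each with its own F2 parent) until
    both bulks are filled with individuals of the required phenotype class at
    the causal locus.  Sites are then sequenced per bulk: total depth
    ~ Poisson(mean_depth), alternate depth ~ Binomial(depth, f(1-e) + (1-f)e)
    where f is the bulk's true alternate-allele frequency.

    Returns a variant-call table (one row per site) with per-bulk AA/RD
    columns, ready for :func:`bsamap.scan.site_filter`.
    """
    depth = depth or DepthModel()
    rng = np.random.default_rng(design.seed)
    variants = variants.sort_values(["chrom", "pos"]).reset_index(drop=True)
    causal_mask = ((variants["chrom"] == design.causal_chrom)
                   & (variants["pos"] == design.causal_pos))
    if not causal_mask.any():
        raise ValueError(
            f"causal locus {design.causal_chrom}:{design.causal_pos} must be "
            "present in the variant list")

    mut_pheno, wt_pheno = _phenotype_classes(design.dominance)
    chrom_groups = {c: g for c, g in variants.groupby("chrom", sort=False)}
    causal_idx_local = int(
        np.flatnonzero(chrom_groups[design.causal_chrom]["pos"].to_numpy()
                       == design.causal_pos)[0])

    need = design.n_bulk_mut + design.n_bulk_wt
    mut_dosages: list[np.ndarray] = []   # per selected individual: dict chrom->dosage row
    wt_dosages: list[np.ndarray] = []
    n_mut = n_wt = 0
    # P(homozygote at causal in F3) = 3/8 per class; batch generously
    batch = max(64, int(need * 3))
    while n_mut < design.n_bulk_mut or n_wt < design.n_bulk_wt:
        per_chrom = {
            chrom: _bc1f3_dosages(batch, g["pos"].to_numpy(), design.map_rate, rng)
            for chrom, g in chrom_groups.items()
        }
        causal_dose = per_chrom[design.causal_chrom][:, causal_idx_local]
        stacked = np.concatenate(
            [per_chrom[c] for c in chrom_groups], axis=1)  # (batch, n_loci)
        for i in range(batch):
            d = int(causal_dose[i])
            if d in mut_pheno and n_mut < design.n_bulk_mut:
                mut_dosages.append(stacked[i])
                n_mut += 1
            elif d in wt_pheno and n_wt < design.n_bulk_wt:
                wt_dosages.append(stacked[i])
                n_wt += 1

    order = np.concatenate([g.index.to_numpy() for g in chrom_groups.values()])
    freq_mut = np.vstack(mut_dosages).sum(axis=0) / (2 * design.n_bulk_mut)
    freq_wt = np.vstack(wt_dosages).sum(axis=0) / (2 * design.n_bulk_wt)
    # back to the sorted variant order
    f_mut = np.empty(len(variants))
    f_wt = np.empty(len(variants))
    f_mut[order] = freq_mut
    f_wt[order] = freq_wt

    e = depth.error_rate
    rd_mut = rng.poisson(depth.mean_depth, len(variants))
    rd_wt = rng.poisson(depth.mean_depth, len(variants))
    aa_mut = rng.binomial(rd_mut, f_mut * (1 - e) + (1 - f_mut) * e)
    aa_wt = rng.binomial(rd_wt, f_wt * (1 - e) + (1 - f_wt) * e)

    out = variants.copy()
    out["qual"] = np.round(
        np.clip(rng.normal(200, 60, len(variants)), 1, None), 1)
    out["aa_mut"] = aa_mut
    out["rd_mut"] = rd_mut
    out["aa_wt"] = aa_wt
    out["rd_wt"] = rd_wt
    out["is_indel"] = out["alt"].str.len() != out["ref"].str.len()
    out["is_missing_mut"] = rd_mut == 0
    out["is_missing_wt"] = rd_wt == 0
    out["true_freq_mut"] = f_mut
    out["true_freq_wt"] = f_wt
    return out[VARIANT_COLUMNS + ["true_freq_mut", "true_freq_wt"]]


def simulate_mapping_dataset(genome: GenomeModel | None = None,
                             design: CrossDesign | None = None,
                             depth: DepthModel | None = None,
                             density: float = 3.0,
                             canonical_fraction: float = 0.98,
                             seed: int = 0) -> pd.DataFrame:
    """End-to-end convenience: EMS variants + causal site + bulk sequencing.

    The causal site is inserted as a canonical C→T variant if no simulated
    variant falls exactly at the design's causal position.
    """
    genome = genome or GenomeModel.regular()
    design = design or CrossDesign(seed=seed)
    if design.seed != seed:
        design = CrossDesign(**{**design.__dict__, "seed": seed})
    variants = simulate_ems_variants(genome, density, canonical_fraction, seed=seed)
    at_causal = ((variants["chrom"] == design.causal_chrom)
                 & (variants["pos"] == design.causal_pos))
    if not at_causal.any():
        causal = pd.DataFrame(
            [(design.causal_chrom, design.causal_pos, "C", "T")],
            columns=["chrom", "pos", "ref", "alt"])
        variants = pd.concat([variants, causal], ignore_index=True)
        variants = variants.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return simulate_bulks(variants, design, depth)


def simulate_annotation_fixtures(variants: pd.DataFrame, design: CrossDesign,
                                 seed: int = 0,
                                 exonic_fraction: float = 0.4,
                                 expressed_fraction: float = 0.7,
                                 deleterious_fraction: float = 0.15,
                                 conserved_fraction: float = 0.5,
                                 ) -> tuple[pd.DataFrame, dict[str, float], pd.DataFrame]:
    """Gene-model, expression and effect-prediction fixtures for the cascade.

    A random subset of variants is made exonic (one toy single-exon gene
    around each), genes are expressed with probability ``expressed_fraction``,
    and non-synonymous/deleterious/conserved labels are drawn so a known
    subset survives each stage.  The causal variant is always given the full
    surviving profile (exonic, expressed, missense, SIFT 0, 95% conserved),
    matching a deleterious mutation in a conserved domain.

    Returns (exons table, expression dict, annotated variant table with
    consequence/sift/conservation_pct columns).
    """
    rng = np.random.default_rng(seed)
    variants = variants.reset_index(drop=True)
    causal = ((variants["chrom"] == design.causal_chrom)
              & (variants["pos"] == design.causal_pos)).to_numpy()
    exonic = (rng.random(len(variants)) < exonic_fraction) | causal
    exon_rows = []
    gene_ids = np.array([""] * len(variants), dtype=object)
    for i in np.flatnonzero(exonic):
        gene = f"gene_{variants.at[i, 'chrom']}_{variants.at[i, 'pos']}"
        gene_ids[i] = gene
        exon_rows.append((gene, variants.at[i, "chrom"],
                          max(1, int(variants.at[i, "pos"]) - 500),
                          int(variants.at[i, "pos"]) + 500))
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])

    expressed = (rng.random(len(variants)) < expressed_fraction) | causal
    expression = {g: (float(rng.lognormal(2, 1)) if expr else 0.0)
                  for g, expr in zip(gene_ids, expressed) if g}

    consequence = rng.choice(["synonymous", "missense"],
                             p=[0.3, 0.7], size=len(variants))
    sift = np.where(rng.random(len(variants)) < deleterious_fraction,
                    rng.uniform(0, 0.05, len(variants)),
                    rng.uniform(0.06, 1.0, len(variants)))
    conservation = np.where(rng.random(len(variants)) < conserved_fraction,
                            rng.uniform(70, 100, len(variants)),
                            rng.uniform(0, 69.5, len(variants)))
    annotated = variants.copy()
    annotated["gene_id"] = gene_ids
    annotated["consequence"] = consequence
    annotated["sift"] = np.round(sift, 3)
    annotated["conservation_pct"] = np.round(conservation, 1)
    ci = int(np.flatnonzero(causal)[0])
    annotated.loc[ci, ["consequence", "sift", "conservation_pct"]] = \
        ["missense", 0.0, 95.0]
    return exons, expression, annotated


def simulate_deg_table(n_genes: int = 1000, n_true: int = 50,
                       lfc_effect_sd: float = 4.0, seed: int = 0,
                       chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3"),
                       chrom_len: int = 100_000_000) -> pd.DataFrame:
    """Synthetic differential-expression result table with planted signal.

    Null genes get Log2FC ~ Normal(0, 0.2) and uniform p-values; the first
    ``n_true`` genes get Log2FC ~ ±Normal(lfc_effect_sd, 1) and tiny p-values.
    The ``fdr`` column is the Benjamini–Hochberg adjustment of the p-values,
    and ``is_true`` records the planted ground truth.
    """
    if n_true > n_genes:
        raise ValueError("n_true must not exceed n_genes")
    rng = np.random.default_rng(seed)
    lfc = rng.normal(0, 0.2, n_genes)
    pvals = rng.uniform(0, 1, n_genes)
    sign = rng.choice([-1, 1], n_true)
    lfc[:n_true] = sign * np.abs(rng.normal(lfc_effect_sd, 1.0, n_true))
    pvals[:n_true] = 10.0 ** rng.uniform(-60, -8, n_true)
    fdr = false_discovery_control(pvals, method="bh")
    return pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "chrom": rng.choice(chrom_names, n_genes),
        "pos": rng.integers(1, chrom_len, n_genes),
        "log2fc": lfc,
        "fdr": fdr,
        "is_true": np.arange(n_genes) < n_true,
    })


def make_cds_fixture(length_codons: int, substitutions: list[tuple[int, str]],
                     seed: int = 0) -> tuple[str, pd.DataFrame]:
    """Random coding sequence plus substitutions with independently derived truth.

    ``substitutions`` is a list of (cds_pos 1-based, alt_base).  Truth labels
    are produced by translating the full reference and full mutated sequence
    codon-by-codon — deliberately not via the annotation module, so the two
    can be checked against each other.

    Returns (cds string, DataFrame with cds_pos/ref/alt/ref_aa/alt_aa/consequence).
    """
    from Bio.Seq import Seq  # oracle-side translation

    if length_codons < 1:
        raise ValueError("need at least one codon")
    rng = np.random.default_rng(seed)
    n = length_codons * 3
    # build from non-stop codons so the reference has no internal stops
    non_stop = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
                if c not in ("TAA", "TAG", "TGA")]
    cds = "".join(rng.choice(non_stop, length_codons))
    protein = str(Seq(cds).translate())
    rows = []
    for cds_pos, alt in substitutions:
        if not 1 <= cds_pos <= n:
            raise ValueError(f"substitution position {cds_pos} outside CDS")
        ref = cds[cds_pos - 1]
        mutated = cds[:cds_pos - 1] + alt + cds[cds_pos:]
        mut_protein = str(Seq(mutated).translate())
        codon = (cds_pos - 1) // 3
        ref_aa, alt_aa = protein[codon], mut_protein[codon]
        if ref_aa == alt_aa:
            consequence = "synonymous"
        elif alt_aa == "*":
            consequence = "stop_gained"
        elif ref_aa == "*":
            consequence = "stop_lost"
        else:
            consequence = "missense"
        rows.append((cds_pos, ref, alt, ref_aa, alt_aa, consequence))
    truth = pd.DataFrame(
        rows, columns=["cds_pos", "ref", "alt", "ref_aa", "alt_aa", "consequence"])
    return cds, truth
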