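#!/usr/bin/env python
"""Simulate the BC1F3 bulk-sequencing experiment and write a two-sample VCF.

Study conditions: five 100 Mb chromosomes, 3 EMS variants per Mb, a
semi-dominant causal locus at chr3:60,000,000, bulks of 63 mutant-phenotype
and 55 wild-type-phenotype F3 plants, mean exome depth 40x.

Writes results/bulks.vcf and results/variants.tsv.
"""

import argparse
from pathlib import Path

from bsamap.io import write_vcf_bulks
from bsamap.simulate import (CrossDesign, DepthModel, GenomeModel,
                             simulate_mapping_dataset)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    genome = GenomeModel.regular(n_chrom=5, length_bp=100_000_000)
    design = CrossDesign(causal_chrom="chr3", causal_pos=60_000_000,
                         n_bulk_mut=63, n_bulk_wt=55, seed=args.seed)
    records = simulate_mapping_dataset(genome, design, DepthModel(40.0),
                                       density=3.0, seed=args.seed)

    RESULTS.mkdir(exist_ok=True)
    write_vcf_bulks(records, RESULTS / "bulks.vcf", chrom_sizes=genome.sizes)
    records.to_csv(RESULTS / "variants.tsv", sep="\t", index=False)

    causal = records[(records["chrom"] == design.causal_chrom)
                     & (records["pos"] == design.causal_pos)].iloc[0]
    print(f"simulated {len(records)} variant sites on {len(genome.sizes)} "
          f"chromosomes (seed {args.seed})")
    print(f"causal site {design.causal_chrom}:{design.causal_pos} "
          f"{causal['ref']}>{causal['alt']}  "
          f"mut bulk {causal['aa_mut']}/{causal['rd_mut']}  "
          f"wt bulk {causal['aa_wt']}/{causal['rd_wt']}")
    print(f"wrote {RESULTS / 'bulks.vcf'} and {RESULTS / 'variants.tsv'}")


if __name__ == "__main__":
    main()
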