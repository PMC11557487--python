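#!/usr/bin/env python
"""Chi-square goodness of fit of the F2 phenotype counts to a 1:2:1 ratio.

The 266 F2 plants scored 62 short-hair : 141 intermediate : 63 normal,
the pattern expected for a single semi-dominant locus.
"""

from bsamap.reference import SRH1_SEGREGATION_COUNTS
from bsamap.segregation import chisq_gof


def main() -> None:
    counts = SRH1_SEGREGATION_COUNTS
    res = chisq_gof(counts, (1, 2, 1))
    print(f"observed counts: {counts}  (n = {sum(counts)})")
    print(f"expected under 1:2:1: {tuple(round(float(e), 1) for e in res.expected)}")
    print(f"chi-square = {res.statistic:.4f}  df = {res.df}  "
          f"p = {res.p_value:.4f}")
    verdict = "consistent" if res.p_value > 0.05 else "inconsistent"
    print(f"the segregation is {verdict} with a single semi-dominant locus")


if __name__ == "__main__":
    main()
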