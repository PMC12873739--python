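"""Published inputs for the two-variant alcohol-related cirrhosis analysis.

The study cohort (118 Serbian patients with alcohol-related liver cirrhosis,
131 matched controls) released per-variant genotype counts, PGS-Catalog
effect weights (PGS000704) and PCR-RFLP fragment patterns, but no
individual-level data.  These constants are the package defaults for
reconstruction-based analyses and for the bundled examples.
"""

from __future__ import annotations

from alcprs.genotype_io import MarginalCounts, VariantDef
from alcprs.rflp_caller import AllelePattern

PNPLA3 = "rs738409"
TM6SF2 = "rs58542926"

#: PGS000704 effect weights (log odds ratios) for the two scored variants.
VARIANTS = [
    VariantDef(rsid=PNPLA3, gene="PNPLA3", ref_allele="C", effect_allele="G",
               effect_weight=0.19895),
    VariantDef(rsid=TM6SF2, gene="TM6SF2", ref_allele="C", effect_allele="T",
               effect_weight=0.186567),
]

#: Published per-cohort genotype counts (homref, het, homalt).
CASE_COUNTS = MarginalCounts(
    cohort="case", counts={PNPLA3: (40, 49, 29), TM6SF2: (81, 32, 5)}
)
CONTROL_COUNTS = MarginalCounts(
    cohort="control", counts={PNPLA3: (74, 50, 7), TM6SF2: (111, 18, 2)}
)

#: Risk-stratum cutpoint used in the published tertile-style grouping:
#: low = PRS 0, moderate = (0, 0.26], high = > 0.26.
PRS_CUTPOINT = 0.26

#: Cohort demographics used by the synthetic generator.
AGE_MEAN, AGE_SD = 58.5, 10.0
MALE_FRACTION = 0.87

#: PCR-RFLP fragment patterns (bp).  BseGI digest for PNPLA3 rs738409 C>G,
#: Hpy188I digest for TM6SF2 rs58542926 C>T.  The published TM6SF2 C-allele
#: pattern (178+33+85) does not sum to the 429 bp amplicon; it is kept as
#: printed and flagged by `rflp_caller.validate_patterns`.
RFLP_PATTERNS = {
    PNPLA3: (
        AllelePattern(rsid=PNPLA3, allele="C", fragments=(200, 133),
                      product_length=333),
        AllelePattern(rsid=PNPLA3, allele="G", fragments=(333,),
                      product_length=333),
    ),
    TM6SF2: (
        AllelePattern(rsid=TM6SF2, allele="C", fragments=(178, 33, 85),
                      product_length=429),
        AllelePattern(rsid=TM6SF2, allele="T", fragments=(251, 178),
                      product_length=429),
    ),
}
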