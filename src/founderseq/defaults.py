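"""Default study parameters, kept in one place.

These defaults describe the kind of founder cohort the package is designed
for: a small island population descended from a few founding couples, an
incompletely penetrant autosomal risk variant introduced by designated
founders, sex-specific disorder prevalence, and exome read evidence from a
moderately overdispersed depth distribution.
"""

#: probability a risk-variant carrier is affected
PENETRANCE_CARRIER = 0.76

#: disorder prevalence by sex
PREVALENCE_MALE = 0.25
PREVALENCE_FEMALE = 0.27

#: risk allele frequency in the founder-related study population
RISK_ALLELE_FREQ = 0.125

#: fraction of individuals carrying at least one copy of the risk variant
#: (Hardy-Weinberg heterozygote + homozygote fraction at RISK_ALLELE_FREQ),
#: used when calibrating non-carrier baseline risks to the prevalences
CARRIER_FRACTION = 2 * RISK_ALLELE_FREQ * (1 - RISK_ALLELE_FREQ) + RISK_ALLELE_FREQ**2

#: number of designated heterozygous carrier founders
CARRIER_FOUNDERS = 2

#: fraction of unions contracted within the pedigree (consanguinity)
CONSANGUINITY_PROB = 0.14

#: pedigree demography: founding couples, total generations, mean offspring
N_FOUNDING_COUPLES = 8
GENERATIONS = 5
OFFSPRING_MEAN = 2.0

#: exome fixture scale: sequenced affected relatives and shared-variant rule
N_EXOME_SAMPLES = 5
MIN_SHARED = 3

#: read-evidence quality thresholds
MIN_UNIQUE_STARTS = 4
MIN_VAF = 0.15

#: read-depth model: negative binomial mean and shape (smaller = more overdispersed)
MEAN_DEPTH = 56.0
DEPTH_SHAPE = 2.0

#: burden-analysis thresholds
RARE_THRESHOLD = 0.01
VERIFICATION_VAF = 0.05


def baseline_risk(
    prevalence: float,
    carrier_fraction: float = CARRIER_FRACTION,
    penetrance: float = PENETRANCE_CARRIER,
) -> float:
    """Non-carrier baseline risk that reproduces a target overall prevalence.

    Solves prevalence = carrier_fraction * penetrance +
    (1 - carrier_fraction) * baseline for the baseline (floored at 0).
    """
    b = (prevalence - carrier_fraction * penetrance) / (1.0 - carrier_fraction)
    return max(b, 0.0)
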