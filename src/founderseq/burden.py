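"""Rare-variant burden comparisons against reference-panel allele counts.

Case and control chromosomes are compared variant by variant, or aggregated
over a category of variants (a specific list, private variants, or all rare
variants below a control-frequency threshold), with a two-tailed Fisher's
exact test.  The two-sided p-value follows the small-probability convention:
it sums the probabilities of every table with the observed margins whose
point probability does not exceed the observed table's (with a small
relative slack for floating-point ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .filtering import NONSYNONYMOUS_CONSEQUENCES


class BurdenError(ValueError):
    """Raised for inconsistent contingency counts."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 allele-count table: (variant, reference) x (case, control)."""

    case_variant: int
    case_reference: int
    control_variant: int
    control_reference: int

    def __post_init__(self) -> None:
        counts = (
            self.case_variant,
            self.case_reference,
            self.control_variant,
            self.control_reference,
        )
        if any(c < 0 for c in counts):
            raise BurdenError("contingency counts must be non-negative")

    @property
    def case_chromosomes(self) -> int:
        return self.case_variant + self.case_reference

    @property
    def control_chromosomes(self) -> int:
        return self.control_variant + self.control_reference

    @property
    def case_freq(self) -> float:
        n = self.case_chromosomes
        return self.case_variant / n if n else float("nan")

    @property
    def control_freq(self) -> float:
        n = self.control_chromosomes
        return self.control_variant / n if n else float("nan")


@dataclass
class BurdenResult:
    category: str
    table: ContingencyTable
    case_freq: float
    control_freq: float
    p: float


@dataclass
class RarityLabels:
    """Non-exclusive rarity categories for one variant (private implies rare)."""

    private: bool
    rare: bool
    common: bool


@dataclass
class VerificationDecision:
    selected: bool
    reasons: list[str]


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher's exact p for a 2x2 allele-count table.

    Uses the small-probability method (sum of all equally-or-less-probable
    tables with the observed margins).  An all-zero table yields p = 1 with
    a warning.
    """
    if (
        table.case_chromosomes == 0
        and table.control_chromosomes == 0
    ):
        warnings.warn("empty contingency table; returning p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(
        [
            [table.case_variant, table.case_reference],
            [table.control_variant, table.control_reference],
        ],
        alternative="two-sided",
    )
    return min(float(p), 1.0)


def combined_burden(
    case_variant_counts: Sequence[int],
    case_chromosomes: int,
    control_variant_counts: Sequence[int],
    control_chromosomes: int,
    category: str = "combined_listed",
) -> BurdenResult:
    """Aggregate allele counts over a variant category and test the burden.

    Sums the per-variant case and control allele counts, forms the 2x2
    table against the chromosome totals, and computes the two-tailed
    Fisher's exact p.  An empty category gives a null table with p = 1.
    """
    a = int(sum(case_variant_counts))
    c = int(sum(control_variant_counts))
    if a > case_chromosomes:
        raise BurdenError(
            f"case variant alleles ({a}) exceed case chromosomes ({case_chromosomes})"
        )
    if c > control_chromosomes:
        raise BurdenError(
            f"control variant alleles ({c}) exceed control chromosomes ({control_chromosomes})"
        )
    table = ContingencyTable(a, case_chromosomes - a, c, control_chromosomes - c)
    return BurdenResult(
        category=category,
        table=table,
        case_freq=table.case_freq,
        control_freq=table.control_freq,
        p=fisher_exact_two_tailed(table),
    )


def classify_rarity(
    control_freqs: Sequence[float],
    case_carrier_counts: Sequence[int],
    rare_threshold: float = 0.01,
) -> list[RarityLabels]:
    """Label each variant as private / rare / common from panel frequencies.

    Private: carried by exactly one case individual and absent from the
    reference panels.  Rare: control frequency below ``rare_threshold``.
    Common: everything else.  Private variants are by construction also rare.
    """
    if len(control_freqs) != len(case_carrier_counts):
        raise BurdenError("control_freqs and case_carrier_counts differ in length")
    labels = []
    for freq, carriers in zip(control_freqs, case_carrier_counts):
        private = carriers == 1 and freq == 0.0
        rare = freq < rare_threshold
        labels.append(RarityLabels(private=private, rare=rare, common=not rare))
    return labels


def select_for_verification(
    consequences: Sequence[str],
    pooled_vafs: Sequence[float],
    vaf_threshold: float = 0.05,
) -> list[VerificationDecision]:
    """Which pooled-sequencing calls warrant orthogonal verification.

    A variant is selected when it is nonsynonymous (amino-acid-changing or
    splice-disrupting) or its pooled variant-allele-fraction estimate is
    below ``vaf_threshold``; each selection is tagged with its reasons.
    """
    if len(consequences) != len(pooled_vafs):
        raise BurdenError("consequences and pooled_vafs differ in length")
    out = []
    for csq, vaf in zip(consequences, pooled_vafs):
        reasons = []
        if csq in NONSYNONYMOUS_CONSEQUENCES:
            reasons.append("nonsynonymous")
        if vaf < vaf_threshold:
            reasons.append(f"estimated VAF < {vaf_threshold}")
        out.append(VerificationDecision(selected=bool(reasons), reasons=reasons))
    return out
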