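"""Rare-variant burden comparisons against reference-panel allele counts.

Case allele counts (heterozygous carriers, one of two chromosomes each) are
compared with public-panel counts by a two-tailed Fisher's exact test,
singly and aggregated over a category.
"""

from founderseq import (
    ContingencyTable,
    classify_rarity,
    combined_burden,
    fisher_exact_two_tailed,
    select_for_verification,
)

# a private variant: 1 of 234 case chromosomes vs 0 of 9358 control chromosomes
p_private = fisher_exact_two_tailed(ContingencyTable(1, 233, 0, 9358))
print(f"private variant, 1/234 vs 0/9358: p = {p_private:.4f}")

# three rare variants aggregated: 4 case alleles vs 44 control alleles
res = combined_burden([1, 2, 1], 234, [44], 9358, category="combined_listed")
print(f"combined burden: case freq {100 * res.case_freq:.2f}%, "
      f"control freq {100 * res.control_freq:.2f}%, p = {res.p:.3f}")

# category labels from panel frequencies and case carrier multiplicity
labels = classify_rarity(
    control_freqs=[0.0, 0.0047, 0.31], case_carrier_counts=[1, 2, 40]
)
for freq, lab in zip([0.0, 0.0047, 0.31], labels):
    kind = "private" if lab.private else ("rare" if lab.rare else "common")
    print(f"control freq {freq:<7} -> {kind}")

# the verification rule for pooled sequencing calls
for csq, vaf in [("synonymous", 0.064), ("missense", 0.32), ("synonymous", 0.0035)]:
    d = select_for_verification([csq], [vaf])[0]
    verdict = "verify (" + ", ".join(d.reasons) + ")" if d.selected else "skip"
    print(f"{csq:<11} VAF {vaf:<7}: {verdict}")
# Nonsynonymous calls are always verified; synonymous ones only when the
# pooled frequency estimate falls below 5%.
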