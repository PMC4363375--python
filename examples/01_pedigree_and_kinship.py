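"""Build a small pedigree, compute its complexity in bits and its kinship matrix.

The kinship coefficient phi(i, j) is the probability that one allele drawn
at random from i and one from j are identical by descent; the diagonal
carries inbreeding (phi_ii = (1 + h) / 2).
"""

from founderseq import IndividualRecord, Pedigree, kinship_matrix, pedigree_bits

# grandparents -> two sibs who marry out -> first cousins -> their child
ped = Pedigree(
    [
        IndividualRecord("gf", sex="male"),
        IndividualRecord("gm", sex="female"),
        IndividualRecord("s1", "gf", "gm", sex="male"),
        IndividualRecord("s2", "gf", "gm", sex="female"),
        IndividualRecord("w1", sex="female"),
        IndividualRecord("h2", sex="male"),
        IndividualRecord("cousin_a", "s1", "w1", sex="male"),
        IndividualRecord("cousin_b", "h2", "s2", sex="female"),
        IndividualRecord("child", "cousin_a", "cousin_b"),
    ]
)

print(f"individuals: {len(ped)}, founders: {len(ped.founders)}, "
      f"non-founders: {len(ped.nonfounders)}")
print(f"pedigree bits (2*non-founders - founders): {pedigree_bits(ped)}")
print(f"the published island pedigree (203 non-founders, 85 founders) has "
      f"{pedigree_bits((203, 85))} bits")

km = kinship_matrix(ped)
print(f"kinship(sib, sib)       = {km.get('s1', 's2')}   (expected 1/4)")
print(f"kinship(cousin, cousin) = {km.get('cousin_a', 'cousin_b')}  (expected 1/16)")
print(f"inbreeding(child of first cousins) = {km.inbreeding('child')}  (expected 1/16)")
# The child's inbreeding equals the kinship of its parents: alleles at one
# locus have a 1/16 chance of being identical by descent.
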