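"""The worked cleavage example: one site, (11/9) offsets, a 48-bp product.

Builds the 390-bp PCR substrate whose first 48 nt are the mutagenic primer
(single GACCGA at 1-based 34-39), digests it and repairs the ends.  The
upstream product is exactly 48 bp: site end at base 39, bottom-strand
scission 9 nt downstream at 48, and T4 repair resects the 2-nt 3' overhang.
"""

import starcut as sc

enzyme = sc.taqii()
substrate = sc.make_pcr_substrate("single", seed=1)

matches = sc.find_sites(substrate, enzyme)
print(f"substrate: {len(substrate)} bp, matches: "
      f"{[(m.start + 1, m.strand, m.site) for m in matches]} (1-based start)")

cuts = sc.place_cuts(matches, enzyme, substrate)
cut = cuts.cuts[0]
print(f"cut: top strand after base {cut.top}, bottom after base {cut.bottom} "
      f"({cut.overhang}-nt 3' overhang)")

fragments = sc.fragmentize(substrate, cuts, mode="complete")
for frag in fragments:
    repaired = sc.end_repair(frag)
    print(f"fragment top span {frag.top}: pre-repair {frag.top_length} nt top strand, "
          f"repaired blunt duplex {repaired.repaired_length} bp")
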