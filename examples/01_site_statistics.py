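"""Cleavage-frequency statistics: how a relaxed hexamer behaves like a 2.9-bp site.

Builds the canonical TaqII site and a 70-variant relaxed truth enzyme and
prints expected cut spacings and effective recognition-site lengths.
"""

import starcut as sc

canonical = sc.SitePattern.exact("GACCGA")
relaxed = sc.make_truth_enzyme(sc.TruthEnzymeSpec(seed=5))
rgcy = sc.SitePattern.from_iupac("RGCY")

for label, site in [
    ("canonical GACCGA", canonical),
    (f"relaxed set ({len(relaxed.sequences)} hexamers)", relaxed.sites),
    ("CviJI-like RGCY", rgcy),
]:
    spacing = sc.expected_spacing(site)
    eff = sc.effective_site_length(spacing)
    print(f"{label:34s} spacing {spacing:8.1f} bp   effective length {eff:.1f} bp")

print()
print("The spacing counts one orientation only.  With both strands cut, the")
print("expected fragment length is about half of it:")
print(f"  GACCGA both strands : {sc.mean_fragment_length(sc.taqii()):8.1f} bp")
print(f"  relaxed both strands: {sc.mean_fragment_length(relaxed):8.1f} bp")
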