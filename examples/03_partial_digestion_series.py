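"""Partial digestion series: the single knob q stands for dilution or time.

Digests a 200-kb synthetic genome with the relaxed enzyme over twofold
"dilutions" of the per-site cleavage probability q and prints the fragment
length summary per q: fewer retained cuts mean longer fragments.
"""

import starcut as sc

genome = sc.make_genome(sc.GenomeSpec(length=200_000, gc=0.51, seed=1))
enzyme = sc.make_truth_enzyme(sc.TruthEnzymeSpec(seed=5))
series = sc.DigestSeries.twofold_dilutions(q_max=0.8, n=6, seed=3)

fragsets, table = sc.partial_series(genome, enzyme, series)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print("q=0.8 is a near-complete digest; each twofold dilution roughly")
print("doubles the mean fragment length (quasi-random overlapping coverage).")
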