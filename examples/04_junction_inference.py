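"""Recover a relaxed recognition-site set from vector/insert junction reads.

Simulates the full shotgun-library experiment on a 200-kb synthetic genome:
partial digest with a 70-variant truth enzyme, size selection, blunt cloning
of 600 fragments, 1200 junction reads, exact mapping, cut-offset inversion
and variant calling -- then audits the detected set against the truth.
"""

import numpy as np

import starcut as sc

genome = sc.make_genome(sc.GenomeSpec(length=200_000, gc=0.5, seed=11))
truth = sc.make_truth_enzyme(sc.TruthEnzymeSpec(seed=5))

fragments = sc.digest(genome, truth, mode="bernoulli", q=0.2, seed=101)
selected = sc.size_select(fragments, 60, 500)
print(f"{fragments.n_cuts_applied} cuts -> {len(fragments)} fragments, "
      f"{len(selected)} in the 60-500 bp window")

rng = np.random.default_rng(202)
pool = list(selected)
idx = sorted(rng.choice(len(pool), size=600, replace=False))
vector, insertion_site = sc.make_vector(seed=7)
clones, reads = sc.clone_and_read(
    [pool[i] for i in idx], vector, insertion_site, read_len=40, seed=rng
)
print(f"{len(clones)} clones, {len(reads)} junction reads")

ends, reasons = sc.map_ends(reads, genome)
print(f"mapping: {dict(reasons)}")

tally = sc.call_sites(ends, genome, truth, min_support=3)
report = sc.recovery_report(tally, truth.sites)
print(f"true-positive fraction : {report['true_positive_fraction']:.3f} "
      f"({report['n_true_positives']}/{report['n_truth']})")
print(f"false positives        : {report['n_false_positives']}")
print(f"excluded-pair breaches : {report['n_excluded_pair_violations']}")
print()
print(tally.to_frame().head(10).to_string(index=False))
print("...")
print("A TP fraction of 1.0 with zero constraint breaches means the junction")
print("reads alone pin down the entire 71-hexamer recognition set.")
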