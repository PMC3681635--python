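# starcut

In-silico digestion with chemically relaxed ("affinity star") restriction
specificities, and recovery of the relaxed recognition-site set from
shotgun-library junction sequences.

## The problem

TaqII is a *Thermus* sp. family Type IIS/IIG restriction endonuclease that
reads the hexamer 5′-GACCGA-3′ and cuts downstream of it at fixed offsets,
written (11/9): the top strand 11 nt and the bottom strand 9 nt 3′ of the
site, leaving a 2-nt 3′ overhang.  When its SAM cofactor is replaced by the
analogue sinefungin in the presence of DMSO, the enzyme's specificity
relaxes to a family of ~70 variants of the canonical site differing at one
or two positions (with certain position pairs never jointly changed).  A set
of *k* disjoint hexamers is matched once every 4096/*k* bp per orientation
on random DNA, so a 71-member set cuts every 4096/71 ≈ 57.7 bp — the
statistical equivalent of a

```
effective site length = log4(expected spacing) = log4(57.7) ≈ 2.9 bp
```

recognition site.  Such ultra-frequent cutters, used under *partial*
digestion (each site cleaved with probability q < 1), fragment DNA
quasi-randomly and are valuable for representative genomic library
construction.

`starcut` implements that computational chain end to end, for scientists who
want to model, simulate, or re-derive it:

* **site_model** — exact, IUPAC-degenerate and explicit variant-set
  recognition sites; match probabilities, expected spacings (one-orientation
  and both-strand conventions) and effective site lengths.
* **digest_engine** — both-strand scanning, (11/9)-style offset cut
  placement with full overhang geometry, complete/bernoulli/fixed-n
  fragmentation, T4-polymerase end repair, length statistics.
* **library_sim** — partial-digestion series (dilution/time collapsed onto
  the single knob q), size selection, blunt cloning into a vector, and
  error-free junction reads with truth provenance.
* **site_inference** — exact junction mapping, inversion of the cut-offset
  geometry, minimal-distance variant calling, and recovery audits against a
  known truth set.
* **synthetic_data** — seeded i.i.d. genomes of chosen GC (optionally with
  dispersed repeats), constrained truth enzymes, the 390-bp PCR assay
  substrates, and a placeholder vector.

## Worked example

```python
import starcut as sc

enzyme = sc.taqii()                                  # GACCGA (11/9)
substrate = sc.make_pcr_substrate("single", seed=1)  # 390 bp, one site at 34-39

matches = sc.find_sites(substrate, enzyme)
cuts = sc.place_cuts(matches, enzyme, substrate)
fragments = sc.fragmentize(substrate, cuts, mode="complete")
for frag in fragments:
    print(frag.top, sc.end_repair(frag).repaired_length)
```

prints

```
(0, 50) 48
(50, 390) 340
```

The site ends at base 39; the top-strand scission falls after base 50 and
the bottom-strand scission after base 48.  T4 repair resects the 2-nt 3′
overhang, so the upstream product is a 48-bp blunt duplex — the fragment a
gel of this digestion shows.

The `examples/` directory holds one short script per capability
(`01_site_statistics.py` … `05_gc_content_comparison.py`); each builds its
own inputs, runs one stage and explains what the numbers mean.  The
headline recovery experiment (`04_junction_inference.py`) simulates a
200-kb genome, a 70-variant truth enzyme and 1200 junction reads, and
recovers all 71 recognition hexamers with zero false positives and zero
breaches of the positional exclusion rules.

A thin CLI mirrors the library:

```bash
starcut stats --enzyme fixtures/taqii_star_synthetic.yaml
starcut digest fixtures/pcr_single.fasta --enzyme fixtures/taqii_star_synthetic.yaml
starcut make-genome --length 200000 --gc 0.51 --seed 1 --out genome.fasta
starcut simulate-library genome.fasta --enzyme fixtures/taqii_star_synthetic.yaml --q 0.2
starcut infer-sites --reads library.junctions.fasta --ref genome.fasta \
    --enzyme fixtures/taqii_star_synthetic.yaml
```

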