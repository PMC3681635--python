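# Fixtures

All files here are **synthetic** and regenerable from the package (the
generators are deterministic per seed):

- `taqii_star_synthetic.yaml` — a relaxed-specificity truth enzyme: canonical
  GACCGA, 70 variants sampled (seed 5) from the constrained 1–2-mismatch
  neighborhood, cut offsets (11, 9).
  Regenerate: `starcut make-enzyme --variants 70 --seed 5 --out taqii_star_synthetic.yaml`
- `pcr_single.fasta` — 390-bp substrate whose first 48 nt are the mutagenic
  primer carrying a single GACCGA site at 1-based positions 34–39 (seed 1).
  Regenerate: `starcut make-substrate --kind single --seed 1 --out pcr_single.fasta`
- `pcr_wt.fasta` — 390-bp substrate free of any site (seed 1).
  Regenerate: `starcut make-substrate --kind wt --seed 1 --out pcr_wt.fasta`

Genomes are not shipped; generate them at any size with
`starcut make-genome --length 100000 --gc 0.51 --seed 1 --out genome.fasta`.
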