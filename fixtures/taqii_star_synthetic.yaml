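canonical: GACCGA
cut_offset_bottom: 9
cut_offset_top: 11
excluded_pairs:
- - 1
  - 2
- - 2
  - 5
max_departures: 2
name: TaqII_star_synthetic
variants:
- AAACGA
- AACAGA
- AACCAA
- AACCCA
- AACCGA
- AACCGG
- AACCGT
- AACTGA
- AAGCGA
- AATCGA
- CACAGA
- CACCCA
- CACCGT
- CACCTA
- CAGCGA
- CATCGA
- GAACAA
- GAACGA
- GAACGT
- GACAAA
- GACAGA
- GACAGC
- GACAGG
- GACATA
- GACCAC
- GACCAG
- GACCCG
- GACCGT
- GACCTC
- GACCTG
- GACGAA
- GACGCA
- GACGGG
- GACTAA
- GACTCA
- GACTGA
- GACTGC
- GACTGG
- GAGAGA
- GAGCGC
- GAGCGG
- GAGCGT
- GAGTGA
- GATAGA
- GATCCA
- GATCGA
- GATCGT
- GATCTA
- GATGGA
- GCCAGA
- GCCCGT
- GCCGGA
- GCTCGA
- GGCCGT
- GGCGGA
- GGCTGA
- GGGCGA
- GGTCGA
- GTCCGA
- GTCCGG
- GTGCGA
- TAACGA
- TACAGA
- TACCAA
- TACCGC
- TACCGG
- TACCGT
- TACCTA
- TACGGA
- TATCGA
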