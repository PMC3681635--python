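# Methods

## Recognition-site model

A recognition site is one of three things: an exact sequence, an
IUPAC-degenerate pattern (an ordered list of allowed-base sets, e.g. RGCY =
{A,G}×{G}×{C}×{C,T}), or an explicit variant set — a canonical sequence
plus exact-sequence variants constrained to at most `max_departures`
mismatches (default 2) and forbidden from changing both members of any
*excluded position pair* (defaults (1,2) and (2,5), 1-based).  For the
canonical hexamer GACCGA these constraints leave a neighborhood of
18 single + 117 double mutants = 135 sequences; truth enzymes sample 70 of
them without replacement.  Positions are 1-based in configs and reports and
0-based half-open internally.

Under an i.i.d. base composition (parameterised by GC fraction:
P(G)=P(C)=GC/2, P(A)=P(T)=(1−GC)/2, strand-symmetric by construction) the
probability that a fixed window matches a set of exact sequences is the sum
of the member probabilities — exact sequences are disjoint events.  Two
spacing conventions coexist and are both reported:

* **expected_spacing** = 1/p counts one orientation only.  This is the
  convention under which a fully specified hexamer occurs every 4⁶ = 4096 bp
  and a 71-member set every 4096/71 ≈ 57.7 bp.
* **mean_fragment_length** models physical double-strand digestion: with
  per-window single-strand site probabilities q₊ (top) and q₋ (bottom), the
  density of *distinct* cut positions per bp is q₊ + q₋ − q_coincide.  The
  coincidence term matters: for a downstream cutter with offsets (ot, ob),
  a top-strand site together with a bottom-strand site starting ot+ob nt
  after its end put their scissions on identical coordinates and are one
  physical cut (which cut placement deduplicates).  For downstream cutters the two implicated windows are disjoint, so
  q_coincide = q₊·q₋; for palindromic within-site cutters the windows
  coincide and q_coincide is the probability of the self-complementary
  overlap (hence HaeIII's 1/256 density, not 2/256).  For the 71-member set
  on 1 Mb this correction shifts the expectation from the coarse
  1/(2q) = 28.85 bp to 29.10 bp — about 1.7 standard errors, i.e. large
  enough that the exact form is the right test oracle while 1/(2q) remains
  the right headline approximation (the tests assert both, at 3 SE and 2%
  respectively).

**effective_site_length** is log₄ of a spacing, reported to one decimal,
round-half-up (4096/71 → 2.9; 64 → 3.0).

## Cut geometry and end repair

A cut is a coordinate pair (top, bottom), each the index of the first base
right of the scission on that strand, in top-strand coordinates.  A
top-strand site spanning [s, s+L) with offsets (ot, ob) cuts at
(s+L+ot, s+L+ob); a bottom-strand site at [s, s+L) cuts at (s−ob, s−ot).
Offsets are signed: TaqII is (11, 9); blunt comparator enzymes (HaeIII
GG^CC, CviJI RGCY) are modelled as within-site midpoint cuts (−2, −2),
configurable per enzyme document.  top − bottom > 0 means 3′ overhangs on
both products; < 0 means 5′ overhangs; 0 blunt.  Cuts that would overrun a
linear molecule's end are dropped (the enzyme cannot cut past the
molecule), with a logged count; circular molecules are scanned with
wraparound windows and a cut whose two scissions straddle the origin is
likewise dropped.

Fragments between consecutive cuts carry their strand spans and hence their
end chemistry.  T4 repair fills 5′ overhangs to the longer strand and
resects 3′ overhangs to the shorter; both rules leave the repaired duplex
spanning [top_start, bottom_end) — at each end the strand whose 5′ terminus
faces outward survives.  This makes the repaired upstream product of the
single-site 390-bp substrate exactly 48 bp (site at 34–39, bottom scission
after base 48), the package's normative reading of that gel band; the
pre-repair top strand is 50 nt.  Degenerate fragments shorter than 1 bp on
either strand (possible only at dense cut clusters or molecule ends) are
discarded with logged counts, which is why length-conservation is asserted
as top-span sum + discarded bp = molecule length.

Length statistics default to pre-repair top-strand spans (these partition
the molecule, the right quantity for spacing laws); insert-size statistics
use repaired duplex lengths (each repair trims the 2-nt overhang).

## Library simulation

Enzyme dilution and digestion time are collapsed onto one knob: the
per-site cleavage probability q of a Bernoulli thinning of the cut set
(reported wet-lab behaviour justifies this — dilution and duration series
produce the same partial pattern).  A digest series is a monotone list of
q values with one seeded digest each.  Size selection filters on repaired
length.  Cloning inserts each repaired fragment into a synthetic random
vector at a marked blunt site in a seeded random orientation and emits two
error-free junction reads per clone: `vector_flank` vector bases (default
10) followed by insert sequence, the right-end read taken on the opposite
strand.  Reads carry the true source cut coordinate and expected mapping
orientation for auditing.  Sequencing errors, ligation bias, transformation
efficiency and screening are out of scope; an optional empty-clone rate
(default 0) models insert-less clones.

## Junction inference

`map_end` exact-matches a read's insert-side segment (minimum 20 nt,
configurable) against both reference strands; zero or multiple hits discard
the read with a logged reason (ends inside repeats are thus dropped, never
multi-assigned).  A forward hit at p yields boundary p with the insert
rightward ('+'); a reverse hit yields the boundary at the segment's
right edge with the insert leftward ('−').

`infer_cut` makes the blunt-repair ambiguity explicit: a blunt boundary
from an (ot/ob) cutter is consistent with scission offsets anywhere in
[min(ot,ob), max(ot,ob)] — width 3 for TaqII — depending on which strand's
scission the repaired end preserved.

`call_sites` inverts the geometry per end.  Because the error-free repair
model preserves the top-strand scission at '+' boundaries and the
bottom-strand scission at '−' boundaries, each offset in the interval is
compatible with exactly one site placement, giving two candidate windows
per end: a top-strand site `up_offset` nt upstream and a bottom-strand site
`down_offset` nt downstream (up/down offsets are (ot, ob) for '+' ends and
swapped for '−').  An `offset_slack` parameter widens every offset by ±n nt
for sloppier repair models; the default 0 matches the generator.  Candidates
are scored by Hamming distance to the canonical site; per end all
minimal-distance candidates are retained, ties at fractional weight (a
distance-d+1 candidate never outranks a distance-d one), and ends whose
best candidate exceeds 2 mismatches (the cap mirroring the 1–2-bp departure
structure of the relaxed specificity) land in an *unexplained* bucket.
Detection thresholds on accumulated support; the default `min_support` is 1
(real libraries report singleton-supported variants), raised to 3 in the
desk-scale recovery experiment where ~17 ends support each true variant
(Poisson power analysis: P(true variant < 3) ≈ 10⁻⁴, while spurious
near-canonical hexamers accumulate ≈ 0.2 weight each, making both a ≥95%
true-positive fraction and zero excluded-pair violations comfortable).
The inference itself never uses the exclusion constraints; they are only
audited afterwards in `recovery_report`.

The original experiment published only chromatogram software names; this
offset-interval / minimal-distance procedure is a reconstruction and is
labelled as such.

## Synthetic data

Genomes are i.i.d. draws from the GC-parameterised composition (51% and
69.4% are the two study compositions), with optional dispersed exact
repeats: non-overlapping copies of a same-composition unit overwrite seeded
positions, and the unit is recoverable (`genome_repeat_unit`) so tests can
assert that repeat-internal fragment lengths recur once per copy — the
in-silico analogue of discrete bands over a digestion smear.  An i.i.d.
model reproduces only composition, not real k-mer structure; notably, under
i.i.d. sequence the 67%-GC canonical site gets *denser* with rising GC, so
the observed larger fragments of high-GC genomes (which may reflect the
real variant list's composition or impaired binding) are reported by the
GC-comparison example but asserted nowhere.

The 390-bp PCR substrates are built by rejection sampling (cap 10,000
iterations) of uniform filler around a fixed 48-nt primer constant until
exactly one (or zero, for the site-free control) match of the enzyme's site
set survives on either strand.  The truth-enzyme sampler draws uniformly
without replacement from the constrained neighborhood and refuses requests
beyond its 135 members.  All generators are deterministic per seed and all
seeds are explicit in the tests.

## Problem sizes and numerical choices

The test suite and acceptance computations use desk-scale versions of the
study: 1 Mb genomes for the mean-spacing laws (≈490 and ≈34,400 cuts; 3 SE
bands from the delta method SE = mean/√n_expected), 200 kb / 600 clones /
1200 reads for the recovery experiment, 20 × 5 kb sequences for scanner
oracle equivalence, and 100–200 replicates for expectation checks.  These
sizes give sub-second to few-second runs per check while leaving every
statistical margin at 3 SE or wider.  Whole-genome-scale inputs (megabase
to gigabase) are supported by the same code paths; nothing is hard-coded to
the desk scale.

Known limitations: no cleavage-preference weighting across variants (all
equally weighted unless a config supplies weights — reported biased site
preference is not modelled), no enzyme kinetics or steric effects on short
substrates beyond the Bernoulli/fixed-n models, exact matching only (no
mismatch/indel alignment, appropriate for the error-free read model), and
no attempt to reproduce the literal published variant list, which is
figure-only content treated as a configurable input.
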