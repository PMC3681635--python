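"""Double-stranded digestion with downstream offset cuts.

Scans both strands of a sequence for any member of an enzyme's recognition
set, places staggered (11/9)-style cuts, builds fragments with explicit end
chemistry, and models T4-polymerase end repair (fill in 5' overhangs, resect
3' overhangs).

Coordinate conventions (normative for the whole package):

* 0-based, half-open internally; reports are 1-based.
* A cut is a pair ``(top, bottom)`` where each value is the index of the
  first base to the right of the scission on that strand, both expressed in
  top-strand coordinates.
* For a top-strand site occupying ``[s, s+L)`` with offsets ``(ot, ob)``
  the cut is ``(s+L+ot, s+L+ob)``; the mirror image for a bottom-strand
  site is ``(s-ob, s-ot)``.  With TaqII's (11, 9) both cases leave a 2-nt
  3' overhang on the flanking fragments, which is what makes the repaired
  upstream product of the single-site PCR substrate exactly 48 bp.
* Cuts that would overrun a linear molecule's ends are dropped (the enzyme
  cannot cut past the molecule), with a logged count.
* Circular molecules are scanned with wraparound windows; a cut whose two
  scissions would straddle the origin is dropped with a logged count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .site_model import EnzymeSpec, reverse_complement


@dataclass(frozen=True)
class DsSequence:
    """A double-stranded DNA molecule, stored as its top strand 5'->3'."""

    seq: str
    name: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if len(seq) < 1:
            raise ValueError("sequence must have length >= 1")
        if set(seq) - set("ACGT"):
            raise ValueError("sequence alphabet restricted to A/C/G/T")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "DsSequence":
        return DsSequence(
            reverse_complement(self.seq), name=f"{self.name}_rc", circular=self.circular
        )

    def window(self, start: int, length: int) -> str:
        """Top-strand window, wrapping past the origin for circular molecules."""
        if self.circular:
            return (self.seq + self.seq)[start : start + length]
        return self.seq[start : start + length]


@dataclass(frozen=True)
class SiteMatch:
    """One recognition-site occurrence.

    ``start`` is the 0-based top-strand coordinate of the matched window;
    ``site`` is the recognition sequence as the enzyme reads it, 5'->3' on
    the matched strand (so for a '-' match it is the reverse complement of
    the top-strand window).
    """

    start: int
    strand: Literal["+", "-"]
    site: str


def find_sites(seq: DsSequence, enzyme: EnzymeSpec) -> list[SiteMatch]:
    """All recognition-site matches on both strands, sorted by (start, strand).

    Each matching (window, strand) is reported exactly once; a palindromic
    site therefore yields one '+' and one '-' match at the same start.
    """
    members = enzyme.sequences
    L = enzyme.site_length
    n = len(seq)
    if L > n:
        return []
    rc_map = {reverse_complement(m): m for m in members}
    top = seq.seq + seq.seq[: L - 1] if seq.circular else seq.seq
    n_windows = n if seq.circular else n - L + 1
    matches: list[SiteMatch] = []
    for i in range(n_windows):
        w = top[i : i + L]
        if w in members:
            matches.append(SiteMatch(i, "+", w))
        m = rc_map.get(w)
        if m is not None:
            matches.append(SiteMatch(i, "-", m))
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


@dataclass(frozen=True)
class Cut:
    """One double-strand cut; see the module docstring for the convention."""

    top: int
    bottom: int
    source: SiteMatch | None = field(default=None, compare=False)

    @property
    def overhang(self) -> int:
        """top - bottom: positive = 3' overhangs on the products."""
        return self.top - self.bottom


@dataclass
class CutSet:
    """Oriented cut coordinates on one molecule, sorted and deduplicated."""

    cuts: list[Cut]
    dropped_out_of_range: int = 0

    def __len__(self) -> int:
        return len(self.cuts)

    def __iter__(self):
        return iter(self.cuts)


def place_cuts(matches: Iterable[SiteMatch], enzyme: EnzymeSpec, seq: DsSequence) -> CutSet:
    """Translate site matches into cut coordinates.

    Out-of-range cuts on linear molecules (and origin-straddling cuts on
    circular ones) are dropped with a count; cuts with identical coordinates
    from different sites are deduplicated into one physical cut.
    """
    L = len(seq)
    sl = enzyme.site_length
    ot, ob = enzyme.cut_offset_top, enzyme.cut_offset_bottom
    dropped = 0
    seen: dict[tuple[int, int], Cut] = {}
    for m in matches:
        if m.strand == "+":
            end = m.start + sl
            t, b = end + ot, end + ob
        else:
            t, b = m.start - ob, m.start - ot
        if seq.circular:
            t_mod, b_mod = t % L, b % L
            if t_mod - b_mod != t - b:  # scissions straddle the origin
                dropped += 1
                continue
            t, b = t_mod, b_mod
        elif min(t, b) < 0 or max(t, b) > L:
            dropped += 1
            continue
        key = (t, b)
        if key not in seen:
            seen[key] = Cut(t, b, m)
    cuts = sorted(seen.values(), key=lambda c: (c.top, c.bottom))
    return CutSet(cuts, dropped_out_of_range=dropped)


class EndChemistry(NamedTuple):
    kind: Literal["blunt", "5prime", "3prime"]
    length: int


@dataclass(frozen=True)
class Fragment:
    """A digestion product: top and bottom strand spans in source coordinates.

    For circular sources the wrap fragment's spans may extend past the
    sequence length; sequence extraction uses the doubled sequence.
    """

    source: DsSequence = field(repr=False, compare=False)
    top: tuple[int, int]
    bottom: tuple[int, int]

    @property
    def top_length(self) -> int:
        return self.top[1] - self.top[0]

    @property
    def bottom_length(self) -> int:
        return self.bottom[1] - self.bottom[0]

    def _end(self, t: int, b: int, side: str) -> EndChemistry:
        if t == b:
            return EndChemistry("blunt", 0)
        if side == "left":
            # top's left terminus is 5'; bottom's left terminus is 3'
            return (
                EndChemistry("5prime", b - t) if t < b else EndChemistry("3prime", t - b)
            )
        # right end: top's terminus is 3', bottom's is 5'
        return (
            EndChemistry("3prime", t - b) if t > b else EndChemistry("5prime", b - t)
        )

    @property
    def left_end(self) -> EndChemistry:
        return self._end(self.top[0], self.bottom[0], "left")

    @property
    def right_end(self) -> EndChemistry:
        return self._end(self.top[1], self.bottom[1], "right")

    @property
    def is_blunt(self) -> bool:
        return self.top == self.bottom

    @property
    def repaired_length(self) -> int:
        """Duplex length after T4 end repair (see :func:`end_repair`)."""
        return max(0, self.bottom[1] - self.top[0])

    def top_sequence(self) -> str:
        doubled = self.source.seq * 2 if self.source.circular else self.source.seq
        return doubled[self.top[0] : self.top[1]]

    def repaired_sequence(self) -> str:
        doubled = self.source.seq * 2 if self.source.circular else self.source.seq
        return doubled[self.top[0] : max(self.top[0], self.bottom[1])]


def end_repair(fragment: Fragment) -> Fragment:
    """Blunt a fragment the way T4 DNA polymerase + dNTPs does.

    5' overhangs are filled in to the longer strand; 3' overhangs are
    resected to the shorter strand.  Both rules leave the repaired duplex
    spanning ``[top_start, bottom_end)``: at the left end the surviving
    boundary is the top strand's 5' terminus, at the right end the bottom
    strand's 5' terminus.  Idempotent on blunt fragments.
    """
    t0 = fragment.top[0]
    b1 = max(fragment.top[0], fragment.bottom[1])  # guard sub-2-bp degenerates
    span = (t0, b1)
    return Fragment(source=fragment.source, top=span, bottom=span)


@dataclass
class FragmentSet:
    """Digestion products plus bookkeeping for dropped/degenerate pieces."""

    fragments: list[Fragment]
    source: DsSequence
    mode: str
    n_cuts_available: int
    n_cuts_applied: int
    discarded_subduplex: int = 0
    discarded_top_bp: int = 0

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def lengths(self, which: str = "top") -> np.ndarray:
        if which == "top":
            return np.array([f.top_length for f in self.fragments], dtype=int)
        if which == "repaired":
            return np.array([f.repaired_length for f in self.fragments], dtype=int)
        raise ValueError("which must be 'top' or 'repaired'")


def _build_fragments(
    seq: DsSequence, selected: list[Cut]
) -> tuple[list[Fragment], int, int]:
    frags: list[Fragment] = []
    discarded = 0
    discarded_bp = 0
    n = len(seq)
    if seq.circular:
        if not selected:
            return [Fragment(seq, (0, n), (0, n))], 0, 0
        bounds = selected + [Cut(selected[0].top + n, selected[0].bottom + n)]
    else:
        bounds = [Cut(0, 0)] + selected + [Cut(n, n)]
    for c0, c1 in itertools.pairwise(bounds):
        top = (c0.top, c1.top)
        bottom = (c0.bottom, c1.bottom)
        if top[1] - top[0] < 1 or bottom[1] - bottom[0] < 1:
            # single-stranded slivers (e.g. a cut 2 nt from a molecule end)
            discarded += 1
            discarded_bp += max(0, top[1] - top[0])
            continue
        frags.append(Fragment(seq, top, bottom))
    return frags, discarded, discarded_bp


def fragmentize(
    seq: DsSequence,
    cuts: CutSet,
    mode: str = "complete",
    q: float | None = None,
    k: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> FragmentSet:
    """Apply all or a random subset of cuts and return the fragments.

    ``complete`` applies every cut.  ``bernoulli`` retains each cut
    independently with probability ``q`` -- the partial-digestion model, with
    ``q`` standing in for enzyme dilution or reaction time.  ``fixed_n``
    retains a uniform random subset of exactly ``k`` cuts.  Top-strand spans
    of the returned fragments partition the molecule exactly, except for
    logged single-stranded slivers at dense cut clusters or molecule ends.
    """
    ordered = sorted(cuts, key=lambda c: (c.top, c.bottom))
    if mode == "complete":
        selected = ordered
    elif mode == "bernoulli":
        if q is None or not (0.0 <= q <= 1.0):
            raise ValueError("bernoulli mode requires q in [0, 1]")
        rng = np.random.default_rng(seed)
        mask = rng.random(len(ordered)) < q
        selected = [c for c, keep in zip(ordered, mask) if keep]
    elif mode == "fixed_n":
        if k is None or k < 0 or k > len(ordered):
            raise ValueError(
                f"fixed_n mode requires 0 <= k <= {len(ordered)}, got {k}"
            )
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(ordered), size=k, replace=False))
        selected = [ordered[i] for i in idx]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frags, discarded, discarded_bp = _build_fragments(seq, selected)
    return FragmentSet(
        fragments=frags,
        source=seq,
        mode=mode,
        n_cuts_available=len(ordered),
        n_cuts_applied=len(selected),
        discarded_subduplex=discarded,
        discarded_top_bp=discarded_bp,
    )


def digest(
    seq: DsSequence,
    enzyme: EnzymeSpec,
    mode: str = "complete",
    q: float | None = None,
    k: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> FragmentSet:
    """find_sites -> place_cuts -> fragmentize in one call."""
    cuts = place_cuts(find_sites(seq, enzyme), enzyme, seq)
    return fragmentize(seq, cuts, mode=mode, q=q, k=k, seed=seed)


def length_stats(
    fragments: FragmentSet | Sequence[Fragment],
    which: str = "top",
    bins: int = 10,
) -> dict:
    """Count, mean, median, quartiles and a histogram of fragment lengths.

    ``which='top'`` measures the pre-repair top-strand span (the partition of
    the source, the right quantity for mean-spacing laws); ``'repaired'``
    measures the blunt duplex length (the insert size a library would see).
    """
    if isinstance(fragments, FragmentSet):
        lengths = fragments.lengths(which)
    else:
        lengths = np.array(
            [f.top_length if which == "top" else f.repaired_length for f in fragments],
            dtype=int,
        )
    if lengths.size == 0:
        raise ValueError("cannot summarise an empty fragment set")
    counts, edges = np.histogram(lengths, bins=bins)
    return {
        "count": int(lengths.size),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": int(lengths.min()),
        "max": int(lengths.max()),
        "q25": float(np.quantile(lengths, 0.25)),
        "q75": float(np.quantile(lengths, 0.75)),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }
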