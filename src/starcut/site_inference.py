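"""Recover a relaxed recognition-site set from junction reads.

The wet-lab readout is a set of Sanger reads across vector/insert junctions
of a shotgun library.  Each read's insert-side segment is located exactly on
the reference; the mapped boundary is a blunt-repaired cut end, and the
enzyme's downstream cut offsets are inverted to enumerate the recognition
windows that could have produced it.  Candidates are scored by Hamming
distance to the canonical site; per end, all minimal-distance candidates
are retained (ties at fractional weight) and aggregated into a tally whose
thresholded support defines the detected variant set.

The original junction analysis named only chromatogram software, not an
algorithm; the offset-interval / minimal-distance procedure here is a
reconstruction, with the 2-nt repair ambiguity made explicit rather than
guessed away (see :func:`infer_cut` and the ``offset_slack`` knob).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .digest_engine import DsSequence
from .library_sim import JunctionRead
from .site_model import (
    EnzymeSpec,
    SiteVariantSet,
    changed_positions,
    hamming,
    reverse_complement,
)

DEFAULT_MIN_INSERT = 20


@dataclass(frozen=True)
class MappedEnd:
    """A junction read located on the reference.

    ``coordinate`` is the candidate cut position (0-based boundary);
    ``strand`` records which side of it the insert lies on: '+' means the
    insert-side sequence continues rightward on the top strand (the boundary
    is a top-strand scission of the flanking cut), '-' leftward (a
    bottom-strand scission).
    """

    read_id: str
    coordinate: int
    strand: Literal["+", "-"]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def map_end(
    read: JunctionRead, reference: DsSequence, min_insert: int = DEFAULT_MIN_INSERT
) -> tuple[MappedEnd | None, str]:
    """Exact-match the insert-side segment against both reference strands.

    Returns ``(MappedEnd, 'mapped')`` for a unique hit; otherwise
    ``(None, reason)`` with reason one of 'too_short', 'unmapped',
    'ambiguous'.  Multi-hit reads (e.g. ends inside repeat copies) are
    discarded rather than multi-assigned.
    """
    segment = read.insert_segment
    if len(segment) < min_insert:
        return None, "too_short"
    fwd = _find_all(reference.seq, segment)
    rev = _find_all(reference.seq, reverse_complement(segment))
    if len(fwd) + len(rev) == 0:
        return None, "unmapped"
    if len(fwd) + len(rev) > 1:
        return None, "ambiguous"
    if fwd:
        return MappedEnd(read.read_id, fwd[0], "+"), "mapped"
    return MappedEnd(read.read_id, rev[0] + len(segment), "-"), "mapped"


def map_ends(
    reads: Sequence[JunctionRead],
    reference: DsSequence,
    min_insert: int = DEFAULT_MIN_INSERT,
) -> tuple[list[MappedEnd], Counter]:
    """Map many reads; returns the kept ends and a Counter of discard reasons."""
    ends: list[MappedEnd] = []
    reasons: Counter = Counter()
    for read in reads:
        end, reason = map_end(read, reference, min_insert)
        reasons[reason] += 1
        if end is not None:
            ends.append(end)
    return ends, reasons


@dataclass(frozen=True)
class CutAmbiguity:
    """The blunt-repair ambiguity at one mapped end.

    A blunt boundary produced by staggered (ot/ob) cutting plus T4 repair is
    consistent with scission offsets anywhere in [min(ot,ob), max(ot,ob)]
    (width 3 for TaqII's 11/9), depending on which strand's scission the
    repaired end preserved.  ``clipped`` flags ends whose candidate windows
    would run past the reference edge.
    """

    boundary: int
    offsets: tuple[int, ...]
    clipped: bool = False


def infer_cut(
    end: MappedEnd, enzyme: EnzymeSpec, reference_length: int | None = None
) -> CutAmbiguity:
    lo = min(enzyme.cut_offset_top, enzyme.cut_offset_bottom)
    hi = max(enzyme.cut_offset_top, enzyme.cut_offset_bottom)
    offsets = tuple(range(lo, hi + 1))
    clipped = False
    if reference_length is not None:
        L = enzyme.site_length
        clipped = (
            end.coordinate - hi - L < 0 or end.coordinate + hi + L > reference_length
        )
    return CutAmbiguity(end.coordinate, offsets, clipped)


def candidate_sites(
    end: MappedEnd,
    reference: DsSequence,
    enzyme: EnzymeSpec,
    offset_slack: int = 0,
) -> frozenset[str]:
    """Recognition windows compatible with the mapped boundary.

    An end-repaired boundary preserves the top-strand scission at a left
    fragment end (map strand '+') and the bottom-strand scission at a right
    end ('-').  Inverting the cut geometry, the compatible placements are a
    top-strand site ``offset`` nt upstream of the boundary and a
    bottom-strand site ``offset`` nt downstream, where for strand '+' the
    upstream offset is ``cut_offset_top`` and the downstream one
    ``cut_offset_bottom`` (swapped for '-').  ``offset_slack`` widens each
    offset by +/- that many nt for repair models that chew or fill
    imprecisely; candidates are reported as the enzyme reads them, 5'->3' on
    the site's own strand.
    """
    L = enzyme.site_length
    n = len(reference)
    x = end.coordinate
    if end.strand == "+":
        up_off, down_off = enzyme.cut_offset_top, enzyme.cut_offset_bottom
    else:
        up_off, down_off = enzyme.cut_offset_bottom, enzyme.cut_offset_top
    cands: set[str] = set()
    for slack in range(-offset_slack, offset_slack + 1):
        a = x - (up_off + slack) - L
        if 0 <= a and a + L <= n:
            cands.add(reference.seq[a : a + L])
        b = x + (down_off + slack)
        if 0 <= b and b + L <= n:
            cands.add(reverse_complement(reference.seq[b : b + L]))
    return frozenset(cands)


@dataclass
class VariantTally:
    """Aggregated support per inferred recognition sequence.

    ``support`` maps hexamer -> weight (ties contribute fractionally);
    ``unexplained`` counts ends with no candidate within the distance cap,
    ``clipped`` ends with no in-bounds candidate window at all.
    """

    support: dict[str, float]
    n_ends: int
    unexplained: int
    clipped: int
    min_support: float
    canonical: str

    def detected(self) -> frozenset[str]:
        return frozenset(
            h for h, w in self.support.items() if w >= self.min_support
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": h,
                "support": w,
                "distance": hamming(h, self.canonical),
                "positions_changed": ",".join(
                    map(str, changed_positions(h, self.canonical))
                ),
                "detected": w >= self.min_support,
            }
            for h, w in self.support.items()
        ]
        return (
            pd.DataFrame(rows, columns=["site", "support", "distance", "positions_changed", "detected"])
            .sort_values(["support", "site"], ascending=[False, True])
            .reset_index(drop=True)
        )


def _score_end(
    candidates: frozenset[str], canonical: str, distance_cap: int
) -> tuple[list[str], int | None]:
    """Minimal-distance winners among candidates, or none if beyond the cap."""
    if not candidates:
        return [], None
    by_dist = sorted((hamming(c, canonical), c) for c in candidates)
    dmin = by_dist[0][0]
    if dmin > distance_cap:
        return [], dmin
    return [c for d, c in by_dist if d == dmin], dmin


def call_sites(
    ends: Sequence[MappedEnd],
    reference: DsSequence,
    enzyme: EnzymeSpec,
    canonical: str | None = None,
    min_support: float = 1.0,
    distance_cap: int = 2,
    offset_slack: int = 0,
) -> VariantTally:
    """Tally recognition-site candidates over all mapped ends.

    Per end: enumerate compatible windows, keep the candidates closest in
    Hamming distance to the canonical site (never ranking a distance d+1
    candidate above a distance d one), split weight across ties, and send
    ends whose best candidate exceeds ``distance_cap`` mismatches to the
    unexplained bucket.  ``min_support`` (default 1, matching
    singleton-supported variants in small libraries) sets the detection
    threshold.
    """
    if not ends:
        raise ValueError("call_sites requires at least one mapped end")
    canonical = canonical or enzyme.canonical
    if canonical is None:
        raise ValueError("a canonical site is required to score candidates")
    support: dict[str, float] = {}
    unexplained = 0
    clipped = 0
    for end in ends:
        cands = candidate_sites(end, reference, enzyme, offset_slack=offset_slack)
        winners, dmin = _score_end(cands, canonical, distance_cap)
        if not winners:
            if dmin is None:
                clipped += 1
            else:
                unexplained += 1
            continue
        w = 1.0 / len(winners)
        for h in winners:
            support[h] = support.get(h, 0.0) + w
    return VariantTally(
        support=support,
        n_ends=len(ends),
        unexplained=unexplained,
        clipped=clipped,
        min_support=min_support,
        canonical=canonical,
    )


def violates_excluded_pairs(
    seq: str, canonical: str, excluded_pairs: Sequence[tuple[int, int]]
) -> bool:
    changed = set(changed_positions(seq, canonical))
    return any(a in changed and b in changed for a, b in excluded_pairs)


def recovery_report(tally: VariantTally, truth: SiteVariantSet) -> dict:
    """Compare a tally against the known truth set (synthetic runs only).

    Reports the true-positive fraction over the full truth event set
    (variants plus canonical), false positives, per-variant support, and an
    audit of whether any detected sequence breaks the truth's excluded-pair
    rule.
    """
    truth_all = truth.sequences
    detected = tally.detected()
    tp = detected & truth_all
    fp = detected - truth_all
    violations = sorted(
        h
        for h in detected
        if violates_excluded_pairs(h, truth.canonical, sorted(truth.excluded_pairs))
    )
    return {
        "n_truth": len(truth_all),
        "n_detected": len(detected),
        "n_true_positives": len(tp),
        "true_positive_fraction": len(tp) / len(truth_all),
        "false_positives": sorted(fp),
        "n_false_positives": len(fp),
        "excluded_pair_violations": violations,
        "n_excluded_pair_violations": len(violations),
        "per_variant_support": {
            h: tally.support.get(h, 0.0) for h in sorted(truth_all)
        },
    }
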