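"""Quasi-random library construction in silico.

Models the wet-lab chain: partial digestion series (twofold enzyme dilutions
or time points, both collapsed onto a single per-site cleavage probability
``q``), size selection, blunt cloning of repaired fragments into a vector,
and error-free junction reads spanning each vector/insert boundary.  Reads
carry the true source cut coordinate so inference can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .digest_engine import (
    CutSet,
    DsSequence,
    Fragment,
    FragmentSet,
    end_repair,
    find_sites,
    fragmentize,
    place_cuts,
)
from .site_model import EnzymeSpec, reverse_complement


@dataclass(frozen=True)
class DigestSeries:
    """Ordered per-site cleavage probabilities, one per dilution/time point."""

    qs: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        qs = tuple(float(q) for q in self.qs)
        if any(not (0.0 <= q <= 1.0) for q in qs):
            raise ValueError("every q must lie in [0, 1]")
        increasing = all(a <= b for a, b in zip(qs, qs[1:]))
        decreasing = all(a >= b for a, b in zip(qs, qs[1:]))
        if not (increasing or decreasing):
            raise ValueError("q values must be monotone (a dilution/time series)")
        object.__setattr__(self, "qs", qs)

    @classmethod
    def twofold_dilutions(cls, q_max: float, n: int, seed: int = 0) -> "DigestSeries":
        return cls(tuple(q_max / 2**i for i in range(n)), seed=seed)


def partial_series(
    seq: DsSequence, enzyme: EnzymeSpec, series: DigestSeries
) -> tuple[list[FragmentSet], pd.DataFrame]:
    """One seeded bernoulli digest per q, plus a per-q length summary table."""
    cuts: CutSet = place_cuts(find_sites(seq, enzyme), enzyme, seq)
    child_seeds = np.random.SeedSequence(series.seed).spawn(len(series.qs))
    fragsets = [
        fragmentize(seq, cuts, mode="bernoulli", q=q, seed=np.random.default_rng(ss))
        for q, ss in zip(series.qs, child_seeds)
    ]
    rows = []
    for q, fs in zip(series.qs, fragsets):
        lengths = fs.lengths("top")
        rows.append(
            {
                "q": q,
                "n_cuts": fs.n_cuts_applied,
                "n_fragments": len(fs),
                "mean_length": float(lengths.mean()),
                "median_length": float(np.median(lengths)),
            }
        )
    return fragsets, pd.DataFrame(rows)


def size_select(
    fragments: FragmentSet, min_len: int, max_len: int, which: str = "repaired"
) -> FragmentSet:
    """Keep fragments whose (default: repaired duplex) length is in [min, max]."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    kept = [
        f
        for f in fragments
        if min_len
        <= (f.repaired_length if which == "repaired" else f.top_length)
        <= max_len
    ]
    if not kept:
        warnings.warn(
            f"size selection [{min_len}, {max_len}] kept no fragments", stacklevel=2
        )
    return FragmentSet(
        fragments=kept,
        source=fragments.source,
        mode=f"{fragments.mode}+size_select",
        n_cuts_available=fragments.n_cuts_available,
        n_cuts_applied=fragments.n_cuts_applied,
        discarded_subduplex=fragments.discarded_subduplex,
        discarded_top_bp=fragments.discarded_top_bp,
    )


@dataclass(frozen=True)
class Clone:
    """A blunt insert ligated into the vector in a recorded orientation.

    ``left_source``/``right_source`` are the source-genome coordinates of the
    two vector/insert boundaries; for a '+' insert they are the repaired
    fragment's (top_start, bottom_end), swapped for a '-' insert.
    """

    clone_id: str
    insert: Fragment
    orientation: Literal["+", "-"]
    vector_name: str
    insert_sequence: str
    left_source: int | None
    right_source: int | None


@dataclass(frozen=True)
class JunctionRead:
    """An error-free read across one vector/insert boundary.

    The first ``vector_flank`` bases are vector; the rest run into the
    insert.  ``truth_coord`` is the source cut coordinate at this boundary
    and ``truth_strand`` the mapping orientation an exact aligner should
    report ('+': insert continues rightward of the coordinate on the source
    top strand; '-': leftward).
    """

    read_id: str
    clone_id: str
    end: Literal["left", "right"]
    sequence: str
    vector_flank: int
    truth_coord: int | None
    truth_strand: Literal["+", "-"] | None

    @property
    def insert_segment(self) -> str:
        return self.sequence[self.vector_flank :]


def clone_and_read(
    fragments: FragmentSet | Sequence[Fragment],
    vector: DsSequence,
    insertion_site: int,
    read_len: int = 40,
    vector_flank: int = 10,
    seed: int | np.random.Generator | None = None,
    empty_clone_rate: float = 0.0,
) -> tuple[list[Clone], list[JunctionRead]]:
    """Insert each (repaired) fragment in a random orientation; read both junctions.

    Returns two junction reads per clone.  Reads are exact substrings of the
    vector+insert construct (error-free model); for the right junction the
    read is taken on the opposite strand, reading from vector into insert.
    """
    if not (0 <= insertion_site <= len(vector)):
        raise ValueError("insertion site must lie within the vector")
    if vector_flank < 0 or read_len <= vector_flank:
        raise ValueError("need 0 <= vector_flank < read_len")
    rng = np.random.default_rng(seed)
    vec = vector.seq
    clones: list[Clone] = []
    reads: list[JunctionRead] = []
    frag_list = list(fragments)
    for i, frag in enumerate(frag_list):
        clone_id = f"clone{i:05d}"
        blunt = frag if frag.is_blunt else end_repair(frag)
        if empty_clone_rate and rng.random() < empty_clone_rate:
            insert_seq = ""
            orientation: Literal["+", "-"] = "+"
            left_src = right_src = None
            left_strand = right_strand = None
        else:
            t0, b1 = blunt.top[0], blunt.bottom[1]
            insert_seq = blunt.top_sequence()
            orientation = "+" if rng.random() < 0.5 else "-"
            if orientation == "-":
                insert_seq = reverse_complement(insert_seq)
                left_src, right_src = b1, t0
                left_strand, right_strand = "-", "+"
            else:
                left_src, right_src = t0, b1
                left_strand, right_strand = "+", "-"
        construct = vec[:insertion_site] + insert_seq + vec[insertion_site:]
        left_start = insertion_site - vector_flank
        right_stop = insertion_site + len(insert_seq) + vector_flank
        if left_start < 0 or left_start + read_len > len(construct):
            raise ValueError("read length exceeds the construct")
        if right_stop > len(construct) or right_stop - read_len < 0:
            raise ValueError("read length exceeds the construct")
        left_read = construct[left_start : left_start + read_len]
        right_read = reverse_complement(construct[right_stop - read_len : right_stop])
        clones.append(
            Clone(
                clone_id=clone_id,
                insert=blunt,
                orientation=orientation,
                vector_name=vector.name,
                insert_sequence=insert_seq,
                left_source=left_src,
                right_source=right_src,
            )
        )
        reads.append(
            JunctionRead(
                read_id=f"{clone_id}/left",
                clone_id=clone_id,
                end="left",
                sequence=left_read,
                vector_flank=vector_flank,
                truth_coord=left_src,
                truth_strand=left_strand,
            )
        )
        reads.append(
            JunctionRead(
                read_id=f"{clone_id}/right",
                clone_id=clone_id,
                end="right",
                sequence=right_read,
                vector_flank=vector_flank,
                truth_coord=right_src,
                truth_strand=right_strand,
            )
        )
    return clones, reads


def truth_table(reads: Sequence[JunctionRead]) -> pd.DataFrame:
    """Per-read provenance table (clone id, end, source coordinate, strand)."""
    return pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "clone_id": r.clone_id,
                "end": r.end,
                "truth_coord": r.truth_coord,
                "truth_strand": r.truth_strand,
            }
            for r in reads
        ]
    )
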