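"""Recognition-site models and cleavage-frequency statistics.

Restriction endonucleases of the *Thermus* sp. family (TaqII, TspGWI) are
Type IIS/IIG enzymes that cut a fixed distance downstream of a short
recognition sequence; TaqII reads 5'-GACCGA-3' and cuts 11 nt beyond the
site on the top strand and 9 nt on the bottom, written ``(11/9)``.  In the
presence of the cofactor analogue sinefungin plus DMSO the enzyme accepts a
relaxed family of sites: the canonical hexamer plus ~70 variants that differ
from it at one or two positions, subject to positional exclusion rules.

This module represents recognition sites in three forms -- exact sequences,
IUPAC-degenerate patterns (e.g. CviJI's RGCY) and explicit variant sets --
and computes the statistics that summarise how often such an enzyme cuts
random DNA:

* the per-window match probability under a base composition,
* the expected spacing between sites (one orientation, the convention under
  which a fully specified hexamer appears every 4^6 = 4096 bp),
* the expected double-strand fragment length (both orientations cut), and
* the *effective recognition-site length*, log base 4 of the spacing -- a
  71-hexamer set cutting every ~57.7 bp behaves like a 2.9-bp site.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

DNA_BASES = "ACGT"

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def changed_positions(seq: str, canonical: str) -> tuple[int, ...]:
    """1-based positions at which ``seq`` differs from ``canonical``."""
    return tuple(i for i, (x, y) in enumerate(zip(seq, canonical), 1) if x != y)


class InvalidPatternError(ValueError):
    """Raised for recognition patterns with empty or non-ACGT positional sets."""


@dataclass(frozen=True)
class SitePattern:
    """A degenerate recognition pattern: one allowed-base set per position.

    ``SitePattern.from_iupac("RGCY")`` gives the CviJI pattern
    {A,G} x {G} x {C} x {C,T}.
    """

    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        norm = tuple(frozenset(p) for p in self.positions)
        if not norm:
            raise InvalidPatternError("pattern must have at least one position")
        for p in norm:
            if not p or not p <= set(DNA_BASES):
                raise InvalidPatternError(
                    f"positional set {set(p)!r} must be a nonempty subset of ACGT"
                )
        object.__setattr__(self, "positions", norm)

    @classmethod
    def from_iupac(cls, text: str) -> "SitePattern":
        try:
            return cls(tuple(frozenset(IUPAC_CODES[c]) for c in text.upper()))
        except KeyError as exc:
            raise InvalidPatternError(f"unknown IUPAC code {exc.args[0]!r}") from exc

    @classmethod
    def exact(cls, seq: str) -> "SitePattern":
        return cls(tuple(frozenset(c) for c in seq.upper()))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def cardinality(self) -> int:
        return math.prod(len(p) for p in self.positions)

    @property
    def is_exact(self) -> bool:
        return all(len(p) == 1 for p in self.positions)

    def __str__(self) -> str:
        return "".join(_SET_TO_IUPAC[p] for p in self.positions)


def expand_pattern(pattern: SitePattern) -> frozenset[str]:
    """All exact sequences matching a degenerate pattern (Cartesian product)."""
    return frozenset(
        "".join(bases)
        for bases in itertools.product(*(sorted(p) for p in pattern.positions))
    )


def variant_neighborhood(
    canonical: str,
    max_departures: int,
    excluded_pairs: Iterable[tuple[int, int]] = (),
) -> frozenset[str]:
    """All sequences 1..max_departures mismatches from ``canonical``, minus
    those that change both members of any excluded position pair.

    Positions are 1-based, matching how site positions are reported.  For
    GACCGA with ``max_departures=2`` and excluded pairs {(1,2), (2,5)} this
    is the 135-member constrained neighborhood from which the relaxed TaqII
    variant sets are drawn.
    """
    canonical = canonical.upper()
    length = len(canonical)
    if not set(canonical) <= set(DNA_BASES):
        raise ValueError("canonical sequence must be A/C/G/T only")
    if max_departures < 1 or max_departures > length:
        raise ValueError(
            f"max_departures must be in 1..{length}, got {max_departures}"
        )
    pairs = [tuple(sorted(p)) for p in excluded_pairs]
    for a, b in pairs:
        if not (1 <= a <= length and 1 <= b <= length and a != b):
            raise ValueError(f"invalid excluded position pair ({a}, {b})")

    out: set[str] = set()
    for r in range(1, max_departures + 1):
        for combo in itertools.combinations(range(length), r):
            combo_1based = {i + 1 for i in combo}
            if any(a in combo_1based and b in combo_1based for a, b in pairs):
                continue
            alternatives = [
                [b for b in DNA_BASES if b != canonical[i]] for i in combo
            ]
            for subs in itertools.product(*alternatives):
                seq = list(canonical)
                for i, b in zip(combo, subs):
                    seq[i] = b
                out.add("".join(seq))
    return frozenset(out)


@dataclass(frozen=True)
class SiteVariantSet:
    """A canonical site plus an explicit set of relaxed variants.

    The union ``variants | {canonical}`` is the event set used by the
    frequency statistics; its size (71 for the relaxed TaqII set) is the
    divisor in the expected-spacing calculation.
    """

    canonical: str
    variants: frozenset[str] = frozenset()
    max_departures: int = 2
    excluded_pairs: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        canonical = self.canonical.upper()
        if not canonical or not set(canonical) <= set(DNA_BASES):
            raise ValueError("canonical must be a nonempty A/C/G/T sequence")
        variants = frozenset(v.upper() for v in self.variants)
        pairs = frozenset(tuple(sorted(p)) for p in self.excluded_pairs)
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "variants", variants)
        object.__setattr__(self, "excluded_pairs", pairs)
        for v in variants:
            if len(v) != len(canonical):
                raise ValueError(f"variant {v} length differs from canonical")
            if not set(v) <= set(DNA_BASES):
                raise ValueError(f"variant {v} contains non-ACGT characters")
            d = hamming(v, canonical)
            if v == canonical:
                raise ValueError("canonical sequence may not appear in variants")
            if d > self.max_departures:
                raise ValueError(
                    f"variant {v} departs at {d} positions, "
                    f"max allowed is {self.max_departures}"
                )
            changed = set(changed_positions(v, canonical))
            for a, b in pairs:
                if a in changed and b in changed:
                    raise ValueError(
                        f"variant {v} changes both positions of excluded pair ({a},{b})"
                    )

    @property
    def sequences(self) -> frozenset[str]:
        """Variants plus the canonical sequence (the frequency event set)."""
        return self.variants | {self.canonical}

    @property
    def size(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.canonical)


SiteLike = Union[SitePattern, SiteVariantSet, Iterable[str]]


@dataclass(frozen=True)
class BaseComposition:
    """Independent per-base probabilities for i.i.d. random sequence models."""

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = {b: float(self.probs.get(b, 0.0)) for b in DNA_BASES}
        if set(self.probs) - set(DNA_BASES):
            raise ValueError("composition keys must be A/C/G/T")
        for b, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"P({b})={p} outside [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-12:
            raise ValueError("base probabilities must sum to 1 within 1e-12")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls({b: 0.25 for b in DNA_BASES})

    @classmethod
    def from_gc(cls, gc: float) -> "BaseComposition":
        """P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2; e.g. gc=0.694 for a
        Thermus thermophilus-like genome, 0.51 for E. coli-like."""
        if not (0.0 <= gc <= 1.0):
            raise ValueError("GC fraction must lie in [0, 1]")
        at = (1.0 - gc) / 2.0
        return cls({"A": at, "T": at, "G": gc / 2.0, "C": gc / 2.0})

    @property
    def gc(self) -> float:
        return self.probs["G"] + self.probs["C"]

    def p(self, base: str) -> float:
        return self.probs[base]

    def sequence_probability(self, seq: str) -> float:
        return math.prod(self.probs[b] for b in seq)

    def pattern_probability(self, pattern: SitePattern) -> float:
        return math.prod(
            sum(self.probs[b] for b in pos) for pos in pattern.positions
        )

    def as_array(self):
        """Probabilities in A, C, G, T order (for numpy sampling)."""
        return [self.probs[b] for b in DNA_BASES]


def _site_sequences(site: SiteLike) -> frozenset[str]:
    if isinstance(site, SitePattern):
        return expand_pattern(site)
    if isinstance(site, SiteVariantSet):
        return site.sequences
    seqs = frozenset(s.upper() for s in site)
    for s in seqs:
        if not set(s) <= set(DNA_BASES):
            raise ValueError(f"site sequence {s} contains non-ACGT characters")
    return seqs


def site_probability(site: SiteLike, composition: BaseComposition | None = None) -> float:
    """Probability that one fixed top-strand window matches the site.

    Exact member sequences are disjoint events, so a set's probability is the
    sum of its members'.  For a degenerate pattern the per-position product is
    used (identical to summing over the expansion).
    """
    composition = composition or BaseComposition.uniform()
    if isinstance(site, SitePattern):
        return composition.pattern_probability(site)
    return sum(composition.sequence_probability(s) for s in _site_sequences(site))


def expected_spacing(site: SiteLike, composition: BaseComposition | None = None) -> float:
    """Expected distance in bp between site starts, one orientation only.

    This is the convention under which a fully specified hexamer occurs every
    4^6 = 4096 bp and a 71-member hexamer set every 4096/71 ~ 57.7 bp.  The
    physical double-strand cut spacing is roughly half this for
    non-palindromic sites; see :func:`mean_fragment_length`.
    Returns ``math.inf`` when the match probability is zero.
    """
    p = site_probability(site, composition)
    if p == 0.0:
        return math.inf
    return 1.0 / p


def _strand_probabilities(
    site: SiteLike, composition: BaseComposition
) -> tuple[float, float, frozenset[str], frozenset[str]]:
    seqs = _site_sequences(site)
    rc = frozenset(reverse_complement(s) for s in seqs)
    q_top = sum(composition.sequence_probability(s) for s in seqs)
    q_bot = sum(composition.sequence_probability(s) for s in rc)
    return q_top, q_bot, seqs, rc


def mean_fragment_length(
    enzyme_or_site: "EnzymeSpec | SiteLike",
    composition: BaseComposition | None = None,
) -> float:
    """Expected complete-digest fragment length with both strands cut.

    The density of distinct cut positions per bp is
    ``q_top + q_bottom - q_coincide`` where ``q_top``/``q_bottom`` are the
    per-window probabilities of a site on either strand and ``q_coincide``
    accounts for scissions that land on identical coordinates and are
    therefore a single physical cut.  For downstream cutters (offsets past
    the site) the two site windows implicated in a coincident cut are
    disjoint, so ``q_coincide = q_top * q_bottom``; for palindromic
    within-site cutters the windows coincide and ``q_coincide`` is the
    probability of the self-complementary overlap.  Approximately
    ``1/(2p)`` for non-palindromic sets: ~2048 bp for GACCGA alone and
    ~28.8 bp for the 71-member relaxed set, on equiprobable sequence.
    """
    composition = composition or BaseComposition.uniform()
    site = enzyme_or_site.sites if isinstance(enzyme_or_site, EnzymeSpec) else enzyme_or_site
    q_top, q_bot, seqs, rc = _strand_probabilities(site, composition)
    if isinstance(enzyme_or_site, EnzymeSpec) and enzyme_or_site.cut_offset_top < 0:
        # within-site cutter: + and - scissions of a self-complementary window coincide
        coincide = sum(
            composition.sequence_probability(s) for s in (seqs & rc)
        )
    else:
        coincide = q_top * q_bot
    density = q_top + q_bot - coincide
    if density == 0.0:
        return math.inf
    return 1.0 / density


def effective_site_length(spacing: float) -> float:
    """Effective (bp-equivalent) recognition-site length: log4 of the spacing.

    Reported to one decimal, round-half-up: spacing 4096/71 -> 2.9; 64 -> 3.0.
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    raw = math.log(spacing, 4)
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EnzymeSpec:
    """A named enzyme: recognition sites plus dual-strand cut offsets.

    Offsets are measured in nt 3' of the last base of the recognition
    sequence, in top-strand coordinates for a top-strand site; TaqII is
    (11, 9), leaving a 2-nt 3' overhang.  Negative offsets place the cut
    within the site (blunt comparator enzymes such as HaeIII GG^CC are
    (-2, -2), the site midpoint).
    """

    name: str
    sites: SitePattern | SiteVariantSet
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        L = self.site_length
        for off in (self.cut_offset_top, self.cut_offset_bottom):
            if off < -L:
                raise ValueError(
                    f"cut offset {off} places the scission upstream of the site"
                )

    @property
    def site_length(self) -> int:
        return len(self.sites)

    @property
    def sequences(self) -> frozenset[str]:
        """Exact top-strand sequences recognised by the enzyme."""
        return _site_sequences(self.sites)

    @property
    def canonical(self) -> str | None:
        if isinstance(self.sites, SiteVariantSet):
            return self.sites.canonical
        if self.sites.is_exact:
            return str(self.sites)
        return None

    @property
    def overhang(self) -> int:
        """top - bottom offset; positive means 3' overhangs on the products."""
        return self.cut_offset_top - self.cut_offset_bottom


def taqii(variants: Iterable[str] = ()) -> EnzymeSpec:
    """TaqII with offsets (11, 9); pass variants for the relaxed SIN/DMSO form."""
    sites = SiteVariantSet(
        canonical="GACCGA",
        variants=frozenset(variants),
        max_departures=2,
        excluded_pairs=frozenset({(1, 2), (2, 5)}),
    )
    return EnzymeSpec("TaqII", sites, 11, 9)


def cviji() -> EnzymeSpec:
    """CviJI, degenerate RGCY blunt cutter modelled at the site midpoint."""
    return EnzymeSpec("CviJI", SitePattern.from_iupac("RGCY"), -2, -2)


def haeiii() -> EnzymeSpec:
    """HaeIII, GG^CC blunt cutter."""
    return EnzymeSpec("HaeIII", SitePattern.from_iupac("GGCC"), -2, -2)


# -- enzyme definition documents (YAML/JSON-compatible dicts) -----------------

def enzyme_to_dict(enzyme: EnzymeSpec) -> dict:
    doc: dict = {
        "name": enzyme.name,
        "cut_offset_top": enzyme.cut_offset_top,
        "cut_offset_bottom": enzyme.cut_offset_bottom,
    }
    if isinstance(enzyme.sites, SiteVariantSet):
        doc["canonical"] = enzyme.sites.canonical
        doc["variants"] = sorted(enzyme.sites.variants)
        doc["max_departures"] = enzyme.sites.max_departures
        doc["excluded_pairs"] = [list(p) for p in sorted(enzyme.sites.excluded_pairs)]
    else:
        doc["site"] = str(enzyme.sites)
    return doc


def enzyme_from_dict(doc: Mapping) -> EnzymeSpec:
    name = doc["name"]
    if "site" in doc:
        pattern = SitePattern.from_iupac(doc["site"])
        default_cut = len(pattern) // 2 - len(pattern)  # site midpoint
        return EnzymeSpec(
            name,
            pattern,
            int(doc.get("cut_offset_top", default_cut)),
            int(doc.get("cut_offset_bottom", default_cut)),
        )
    sites = SiteVariantSet(
        canonical=doc["canonical"],
        variants=frozenset(doc.get("variants", ())),
        max_departures=int(doc.get("max_departures", 2)),
        excluded_pairs=frozenset(
            tuple(p) for p in doc.get("excluded_pairs", ())
        ),
    )
    return EnzymeSpec(name, sites, int(doc["cut_offset_top"]), int(doc["cut_offset_bottom"]))


def save_enzyme(enzyme: EnzymeSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(enzyme_to_dict(enzyme), sort_keys=True))


def load_enzyme(path: str | Path) -> EnzymeSpec:
    return enzyme_from_dict(yaml.safe_load(Path(path).read_text()))
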