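"""Generators for every input the pipeline needs.

Real experiments of this kind digest phage, bacterial and mammalian DNA and
sequence plasmid libraries.  Everything here is synthetic: i.i.d. random
genomes of chosen length and GC fraction (optionally with injected tandem
repeat copies), truth enzymes whose relaxed variant sets are seeded samples
from the constrained mutational neighborhood of the canonical site, the two
390-bp PCR assay substrates, and a placeholder cloning vector.  All outputs
are deterministic functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .digest_engine import DsSequence, find_sites
from .site_model import (
    BaseComposition,
    EnzymeSpec,
    SiteVariantSet,
    variant_neighborhood,
)

#: 48-nt mutagenic forward primer that introduces a single GACCGA site
#: (1-based positions 34-39) into an otherwise TaqII-free PCR substrate;
#: mutagenic lower-case positions normalised to upper case.
PCR_SINGLE_PRIMER_48NT = "CTCGACCTGAATGGAAGCCGGCGGCACCTCGCTGACCGATTCACCACT"

PCR_SUBSTRATE_LENGTH = 390
_REJECTION_CAP = 10_000


@dataclass(frozen=True)
class RepeatSpec:
    """Dispersed exact repeat copies to inject into a genome."""

    unit_length: int
    copies: int


@dataclass(frozen=True)
class GenomeSpec:
    length: int
    gc: float = 0.5
    repeat: Optional[RepeatSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("GC fraction must lie in [0, 1]")


def _random_bases(rng: np.random.Generator, n: int, composition: BaseComposition) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = rng.choice(4, size=n, p=composition.as_array())
    return alphabet[idx].tobytes().decode("ascii")


def make_genome(spec: GenomeSpec) -> DsSequence:
    """An i.i.d. random genome; repeats, if any, overwrite seeded positions.

    Repeat copies are non-overlapping and placed uniformly at random; the
    unit itself is drawn from the same base composition, so repeats change
    only the genome's repetitiveness, not its expected composition.
    """
    rng = np.random.default_rng(spec.seed)
    comp = BaseComposition.from_gc(spec.gc)
    seq = _random_bases(rng, spec.length, comp)
    if spec.repeat is not None:
        unit_len, copies = spec.repeat.unit_length, spec.repeat.copies
        if unit_len > spec.length:
            raise ValueError("repeat unit longer than genome")
        if copies * unit_len > spec.length:
            raise ValueError("repeat copies do not fit in the genome")
        unit = _random_bases(rng, unit_len, comp)
        starts = _nonoverlapping_starts(rng, spec.length, unit_len, copies)
        chars = list(seq)
        for s in starts:
            chars[s : s + unit_len] = unit
        seq = "".join(chars)
    name = f"synthetic_{spec.length}bp_gc{spec.gc:g}_seed{spec.seed}"
    return DsSequence(seq, name=name)


def genome_repeat_unit(spec: GenomeSpec) -> str:
    """The exact repeat unit :func:`make_genome` injects for this spec.

    Useful for truth-checking repeat recovery: the unit's internal digestion
    fragments recur once per injected copy.
    """
    if spec.repeat is None:
        raise ValueError("spec has no repeat component")
    rng = np.random.default_rng(spec.seed)
    comp = BaseComposition.from_gc(spec.gc)
    _ = _random_bases(rng, spec.length, comp)  # consume the genome draw
    return _random_bases(rng, spec.repeat.unit_length, comp)


def _nonoverlapping_starts(
    rng: np.random.Generator, length: int, unit_len: int, copies: int
) -> list[int]:
    for _ in range(1000):
        starts = sorted(rng.choice(length - unit_len + 1, size=copies, replace=False))
        if all(b - a >= unit_len for a, b in zip(starts, starts[1:])):
            return starts
    raise RuntimeError("could not place non-overlapping repeat copies; genome too dense")


@dataclass(frozen=True)
class TruthEnzymeSpec:
    """A synthetic relaxed enzyme: canonical site plus a seeded variant sample.

    Defaults model the relaxed TaqII conditions: 70 variants drawn without
    replacement from the 135-member neighborhood of GACCGA at 1-2 mismatches
    with position pairs (1,2) and (2,5) never jointly changed, and (11, 9)
    downstream cut offsets.
    """

    canonical: str = "GACCGA"
    n_variants: int = 70
    max_departures: int = 2
    excluded_pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 5))
    cut_offset_top: int = 11
    cut_offset_bottom: int = 9
    seed: int = 0
    name: str = "TaqII_star_synthetic"


def make_truth_enzyme(spec: TruthEnzymeSpec = TruthEnzymeSpec()) -> EnzymeSpec:
    """Sample a truth enzyme; ``n_variants=0`` gives the canonical-only enzyme."""
    neighborhood = sorted(
        variant_neighborhood(spec.canonical, spec.max_departures, spec.excluded_pairs)
    )
    if spec.n_variants > len(neighborhood):
        raise ValueError(
            f"requested {spec.n_variants} variants but the constrained "
            f"neighborhood has only {len(neighborhood)} members"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(neighborhood), size=spec.n_variants, replace=False)
    variants = frozenset(neighborhood[i] for i in sorted(idx))
    sites = SiteVariantSet(
        canonical=spec.canonical,
        variants=variants,
        max_departures=spec.max_departures,
        excluded_pairs=frozenset(spec.excluded_pairs),
    )
    return EnzymeSpec(spec.name, sites, spec.cut_offset_top, spec.cut_offset_bottom)


def make_pcr_substrate(
    kind: str,
    seed: int = 0,
    enzyme: EnzymeSpec | None = None,
    length: int = PCR_SUBSTRATE_LENGTH,
) -> DsSequence:
    """One of the two 390-bp PCR assay substrates.

    ``single`` starts with the 48-nt mutagenic primer (site at 1-based
    34-39) and carries no other match of the enzyme's site set on either
    strand; ``wt`` carries no match at all.  Filler bases are seeded and
    rejection-sampled until the zero/one-site property holds.
    """
    if kind not in ("wt", "single"):
        raise ValueError("kind must be 'wt' or 'single'")
    if enzyme is None:
        from .site_model import taqii

        enzyme = taqii()
    if kind == "single" and length < len(PCR_SINGLE_PRIMER_48NT):
        raise ValueError("substrate shorter than the 48-nt primer")
    rng = np.random.default_rng(seed)
    comp = BaseComposition.uniform()
    for _ in range(_REJECTION_CAP):
        if kind == "single":
            filler = _random_bases(rng, length - len(PCR_SINGLE_PRIMER_48NT), comp)
            candidate = DsSequence(
                PCR_SINGLE_PRIMER_48NT + filler, name=f"pcr_single_{length}bp"
            )
            matches = find_sites(candidate, enzyme)
            if len(matches) == 1 and matches[0].start == 33 and matches[0].strand == "+":
                return candidate
        else:
            candidate = DsSequence(
                _random_bases(rng, length, comp), name=f"pcr_wt_{length}bp"
            )
            if not find_sites(candidate, enzyme):
                return candidate
    raise RuntimeError(
        f"rejection sampling failed to satisfy the {kind!r} site-count "
        f"constraint within {_REJECTION_CAP} iterations"
    )


def make_vector(
    length: int = 2700, seed: int = 0, gc: float = 0.5
) -> tuple[DsSequence, int]:
    """A placeholder blunt cloning vector and its insertion-site coordinate.

    Stands in for a real plasmid opened at a blunt site; the insertion site
    is the midpoint of the random backbone.
    """
    rng = np.random.default_rng(seed)
    seq = _random_bases(rng, length, BaseComposition.from_gc(gc))
    return DsSequence(seq, name=f"vector_synthetic_{length}bp_seed{seed}"), length // 2
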