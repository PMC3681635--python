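"""Double-strand scanning, offset cut placement, fragmentation and repair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import starcut as sc
from starcut.digest_engine import Cut, CutSet, Fragment


class TestFindSites:
    def test_single_site_substrate(self, single_substrate, taqii_canonical):
        matches = sc.find_sites(single_substrate, taqii_canonical)
        assert [(m.start, m.strand, m.site) for m in matches] == [
            (33, "+", "GACCGA")
        ]

    def test_site_free_substrate(self, wt_substrate, taqii_canonical):
        assert sc.find_sites(wt_substrate, taqii_canonical) == []

    def test_bottom_strand_site(self, taqii_canonical):
        seq = sc.DsSequence("A" * 20 + "TCGGTC" + "A" * 20)
        matches = sc.find_sites(seq, taqii_canonical)
        assert [(m.start, m.strand, m.site) for m in matches] == [
            (20, "-", "GACCGA")
        ]

    def test_palindromic_site_reported_on_both_strands(self):
        seq = sc.DsSequence("AAAGGCCAAA")
        matches = sc.find_sites(seq, sc.haeiii())
        assert [(m.start, m.strand) for m in matches] == [(3, "+"), (3, "-")]

    def test_site_longer_than_sequence(self, taqii_canonical):
        assert sc.find_sites(sc.DsSequence("GACC"), taqii_canonical) == []

    def test_circular_site_spanning_origin(self, taqii_canonical):
        # GACCGA assembled from the last 3 and first 3 bases of the circle
        seq = sc.DsSequence("CGA" + "A" * 60 + "GAC", circular=True)
        matches = sc.find_sites(seq, taqii_canonical)
        assert [(m.start, m.strand) for m in matches] == [(63, "+")]


class TestPlaceCuts:
    def test_worked_11_9_geometry(self, single_substrate, taqii_canonical):
        """Site at 1-based 34-39 puts the scissions after bases 50 (top) and 48."""
        cuts = sc.place_cuts(
            sc.find_sites(single_substrate, taqii_canonical),
            taqii_canonical,
            single_substrate,
        )
        assert [(c.top, c.bottom) for c in cuts] == [(50, 48)]
        assert cuts.cuts[0].overhang == 2  # 2-nt 3' overhang

    def test_cut_past_linear_end_dropped(self, taqii_canonical):
        seq = sc.DsSequence("A" * 10 + "GACCGA" + "A" * 5)
        cuts = sc.place_cuts(
            sc.find_sites(seq, taqii_canonical), taqii_canonical, seq
        )
        assert len(cuts) == 0 and cuts.dropped_out_of_range == 1

    def test_coincident_cuts_deduplicated(self, taqii_canonical):
        # + site and - site placed so both scissions coincide exactly
        seq = sc.DsSequence("A" * 4 + "GACCGA" + "A" * 20 + "TCGGTC" + "A" * 10)
        matches = sc.find_sites(seq, taqii_canonical)
        assert len(matches) == 2
        cuts = sc.place_cuts(matches, taqii_canonical, seq)
        assert [(c.top, c.bottom) for c in cuts] == [(21, 19)]

    def test_mirror_geometry_on_bottom_strand(self, taqii_canonical):
        seq = sc.DsSequence("A" * 30 + "TCGGTC" + "A" * 30)
        cuts = sc.place_cuts(
            sc.find_sites(seq, taqii_canonical), taqii_canonical, seq
        )
        # site starts at 30: top scission at 30-9, bottom at 30-11
        assert [(c.top, c.bottom) for c in cuts] == [(21, 19)]


class TestFragmentize:
    def test_single_cut_complete_gives_two_fragments(
        self, single_substrate, taqii_canonical
    ):
        frags = sc.digest(single_substrate, taqii_canonical)
        assert len(frags) == 2
        assert [f.top_length for f in frags] == [50, 340]
        assert sum(f.top_length for f in frags) == 390

    def test_q_zero_returns_intact_molecule(self, single_substrate, taqii_canonical):
        frags = sc.digest(single_substrate, taqii_canonical, mode="bernoulli", q=0.0, seed=1)
        assert len(frags) == 1
        assert frags.fragments[0].top == (0, 390)
        assert frags.fragments[0].is_blunt

    def test_fixed_n_larger_than_cut_count_rejected(
        self, single_substrate, taqii_canonical
    ):
        with pytest.raises(ValueError):
            sc.digest(single_substrate, taqii_canonical, mode="fixed_n", k=5, seed=0)

    def test_bernoulli_expected_fragment_count(self, taqii_canonical):
        """E[fragments] = 1 + s*q by linearity; checked within 3 SE over 200 runs."""
        genome = sc.make_genome(sc.GenomeSpec(length=100_000, gc=0.5, seed=3))
        cuts = sc.place_cuts(
            sc.find_sites(genome, taqii_canonical), taqii_canonical, genome
        )
        s, q = len(cuts), 0.3
        counts = [
            len(sc.fragmentize(genome, cuts, mode="bernoulli", q=q, seed=seed))
            for seed in range(200)
        ]
        se = np.sqrt(s * q * (1 - q) / 200)
        assert abs(np.mean(counts) - (1 + s * q)) <= 3 * se

    def test_circular_single_cut_yields_one_linear_fragment(self, taqii_canonical):
        seq = sc.DsSequence("CGA" + "A" * 60 + "GAC", circular=True)
        frags = sc.digest(seq, taqii_canonical)
        assert len(frags) == 1
        assert frags.fragments[0].top_length == len(seq)


class TestEndRepair:
    def test_three_prime_overhang_resected_to_48(self, single_substrate):
        upstream = Fragment(single_substrate, top=(0, 50), bottom=(0, 48))
        assert upstream.right_end == ("3prime", 2)
        repaired = sc.end_repair(upstream)
        assert repaired.is_blunt and repaired.repaired_length == 48

    def test_blunt_fragment_unchanged(self, single_substrate):
        frag = Fragment(single_substrate, top=(10, 60), bottom=(10, 60))
        assert sc.end_repair(frag) == frag

    def test_five_prime_overhang_filled_in(self, single_substrate):
        # 4-nt 5' overhang at the right end: bottom strand longer
        frag = Fragment(single_substrate, top=(0, 46), bottom=(0, 50))
        assert frag.right_end == ("5prime", 4)
        assert sc.end_repair(frag).repaired_length == 50

    def test_idempotent(self, single_substrate):
        frag = Fragment(single_substrate, top=(0, 50), bottom=(0, 48))
        once = sc.end_repair(frag)
        assert sc.end_repair(once) == once


class TestLengthStats:
    def test_mean_of_two_lengths(self, single_substrate):
        frags = [
            Fragment(single_substrate, (0, 48), (0, 48)),
            Fragment(single_substrate, (48, 390), (48, 390)),
        ]
        stats = sc.length_stats(frags)
        assert stats["count"] == 2 and stats["mean"] == 195.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sc.length_stats([])


class TestDigestionInvariants:
    @given(
        seq=st.text(alphabet="ACGT", min_size=40, max_size=250),
        seed=st.integers(0, 2**31 - 1),
        mode_q=st.sampled_from(
            [("complete", None), ("bernoulli", 0.0), ("bernoulli", 0.35), ("bernoulli", 1.0)]
        ),
    )
    @settings(max_examples=60)
    def test_top_spans_partition_input(self, seq, seed, mode_q, truth_enzyme):
        """Length conservation for every mode and seed (slivers are logged)."""
        mode, q = mode_q
        ds = sc.DsSequence(seq)
        frags = sc.digest(ds, truth_enzyme, mode=mode, q=q, seed=seed)
        spans = sorted(f.top for f in frags)
        assert sum(b - a for a, b in spans) + frags.discarded_top_bp == len(ds)
        for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
            assert b0 <= a1  # no overlap

    def test_complete_digest_idempotent(self, truth_enzyme):
        """Re-digesting complete-digest fragments yields no interior cuts."""
        genome = sc.make_genome(sc.GenomeSpec(length=20_000, gc=0.5, seed=8))
        frags = sc.digest(genome, truth_enzyme)
        assert len(frags) > 100
        for frag in frags:
            piece = sc.DsSequence(frag.top_sequence())
            cuts = sc.place_cuts(
                sc.find_sites(piece, truth_enzyme), truth_enzyme, piece
            )
            for c in cuts:
                interior = 0 < min(c.top, c.bottom) and max(c.top, c.bottom) < len(piece)
                assert not interior

    def test_strand_symmetry(self, truth_enzyme):
        """The reverse complement digests into mirrored fragments."""
        genome = sc.make_genome(sc.GenomeSpec(length=5_000, gc=0.5, seed=4))
        fwd = sc.digest(genome, truth_enzyme)
        rev = sc.digest(genome.reverse_complement(), truth_enzyme)
        assert sorted(f.repaired_length for f in fwd) == sorted(
            f.repaired_length for f in rev
        )
        # top spans of the mirror digest are the bottom spans of the original
        assert sorted(f.top_length for f in rev) == sorted(
            f.bottom_length for f in fwd
        )
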