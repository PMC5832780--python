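"""Window enumeration, filtering, exon exclusion and atlas construction."""

import pytest

from mirhap.core_io import GenomicInterval, HaplotypeSequence, revcomp
from mirhap.scanner import (ScanConfig, ScanStats, build_atlas, count_windows,
                            enumerate_windows, exclude_exons, prescreen,
                            scan_sequence)
from mirhap.simulate import hairpin_with_mfe, plant_hairpin, random_background

from oracles import mask_union


def hap(seq, name="h"):
    return HaplotypeSequence(name, seq)


class TestEnumerateWindows:
    def test_minimal_sequence_gives_one_window_per_strand(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=58))
        wins = list(enumerate_windows(hap(seq), ScanConfig()))
        assert len(wins) == 2
        assert {w[0].strand for w in wins} == {"+", "-"}

    def test_window_count_formula(self, rng):
        # L=60, lengths 58-60: per strand 3+2+1 = 6, both strands 12
        seq = "".join(rng.choice(list("ACGT"), size=60))
        cfg = ScanConfig(min_len=58, max_len=60)
        wins = list(enumerate_windows(hap(seq), cfg))
        assert len(wins) == 12 == count_windows(60, cfg)

    def test_minus_strand_window_is_revcomp_of_forward_slice(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=70))
        wins = list(enumerate_windows(hap(seq), ScanConfig()))
        iv, w = next(
            (iv, w) for iv, w in wins
            if iv.strand == "-" and iv.start == 0 and len(iv) == 58
        )
        assert w == revcomp(seq[0:58])

    def test_short_sequence_yields_nothing(self):
        assert list(enumerate_windows(hap("ACGTACGT"), ScanConfig())) == []


class TestPrescreen:
    def test_poly_a_fails(self):
        assert not prescreen("A" * 60, threshold=9)

    def test_perfect_stem_passes(self):
        seq, _ = plant_hairpin(25, 6, seed=3)
        assert prescreen(seq, threshold=9)

    def test_threshold_zero_disables(self):
        assert prescreen("A" * 60, threshold=0)

    def test_conservative_wrt_final_atlas(self, hap_pair):
        """Disabling the prescreen must not change the scan outcome."""
        hap_a, _, _, _ = hap_pair
        sub = HaplotypeSequence("sub", hap_a.seq[:400])
        with_screen = scan_sequence(sub, ScanConfig(prescreen=True))
        without = scan_sequence(sub, ScanConfig(prescreen=False))
        key = lambda ws: [(w.interval, w.fold.mfe) for w in ws]
        assert key(with_screen) == key(without)


class TestScanSequence:
    def test_planted_hairpin_recovered_background_rejected(self, rng):
        hp, _ = plant_hairpin(20, 6, seed=5)
        bg = random_background(500, 0.41, rng)
        seq = bg[:200] + hp + bg[200:]
        wins = scan_sequence(hap(seq), ScanConfig())
        planted = GenomicInterval("h", 200, 200 + len(hp))
        assert any(w.interval.overlaps(planted) for w in wins)

    def test_mfe_boundary_is_strict(self):
        """A window at exactly -19.1 kcal/mol is excluded at the -20 cutoff."""
        win = hairpin_with_mfe(-19.1, seed=8)
        assert scan_sequence(hap(win), ScanConfig(min_len=len(win),
                                                  max_len=len(win))) == []
        found = scan_sequence(hap(win), ScanConfig(min_len=len(win),
                                                   max_len=len(win),
                                                   mfe_cutoff=-19.0))
        assert any(w.fold.mfe == pytest.approx(-19.1) for w in found)

    def test_empty_input(self):
        assert scan_sequence(hap("ACGT"), ScanConfig()) == []

    def test_stride_one_atlas_superset_of_coarser(self, hap_pair):
        hap_a, _, _, _ = hap_pair
        sub = HaplotypeSequence("sub", hap_a.seq[250:600])
        fine = scan_sequence(sub, ScanConfig(stride=1))
        coarse = scan_sequence(sub, ScanConfig(stride=4))
        fine_keys = {(w.interval.start, w.interval.end, w.interval.strand)
                     for w in fine}
        coarse_keys = {(w.interval.start, w.interval.end, w.interval.strand)
                       for w in coarse}
        assert coarse_keys <= fine_keys

    def test_atlas_invariant_to_input_orientation(self, hap_pair):
        """Scanning the reverse-complemented FASTA gives the mirrored atlas."""
        hap_a, _, _, _ = hap_pair
        sub = hap_a.seq[250:600]
        fwd = build_atlas(scan_sequence(hap(sub), ScanConfig()))
        rev = build_atlas(scan_sequence(hap(revcomp(sub)), ScanConfig()))
        n = len(sub)
        mirrored = sorted((n - l.interval.end, n - l.interval.start)
                          for l in rev)
        assert sorted((l.interval.start, l.interval.end) for l in fwd) == mirrored


class TestExcludeExons:
    def test_one_base_overlap_removes(self):
        locus = GenomicInterval("c", 100, 160)
        assert exclude_exons([locus], [GenomicInterval("c", 159, 200)]) == []

    def test_half_open_abutment_retains(self):
        locus = GenomicInterval("c", 100, 160)
        assert exclude_exons([locus], [GenomicInterval("c", 160, 200)]) == [locus]

    def test_matches_per_base_mask_oracle(self, rng):
        loci = [GenomicInterval("c", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 900, 500),
                                rng.integers(1, 50, 500))]
        exons = [GenomicInterval("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 900, 60),
                                 rng.integers(1, 80, 60))]
        kept = exclude_exons(loci, exons)
        exon_mask = mask_union(exons, 1000)
        expected = [iv for iv in loci
                    if not any(exon_mask[p] for p in range(iv.start, iv.end))]
        assert kept == expected


class TestBuildAtlas:
    def _window(self, start, end, mfe=-25.0):
        from mirhap.folding import FoldResult, classify_topology
        from mirhap.scanner import HairpinWindow

        seq = "A" * (end - start)
        st = "." * (end - start)
        return HairpinWindow(GenomicInterval("c", start, end, "+"), seq,
                             FoldResult(seq, st, mfe, "reference"),
                             classify_topology(st))

    def test_two_overlapping_windows_one_locus(self):
        atlas = build_atlas([self._window(0, 60, -25.0),
                             self._window(30, 90, -30.0)])
        assert len(atlas) == 1
        assert atlas[0].n_windows == 2
        assert atlas[0].best_mfe == -30.0

    def test_empty(self):
        assert build_atlas([]) == []

    def test_atlas_loci_reverify_post_hoc(self, scanned_hapA):
        """Every atlas locus holds >= 1 window below cutoff, passing topology."""
        windows, _ = scanned_hapA
        cfg = ScanConfig()
        atlas = build_atlas(windows)
        for locus in atlas:
            members = [w for w in windows if w.interval.overlaps(locus.interval)]
            assert members
            assert any(cfg.mfe_passes(w.fold.mfe)
                       and cfg.topology_passes(w.topology) for w in members)
            assert locus.best_mfe < cfg.mfe_cutoff
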