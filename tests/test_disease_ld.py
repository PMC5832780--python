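"""LD-block construction, intersection and disease summaries."""

import numpy as np
import pandas as pd
import pytest

from mirhap.core_io import GenomicInterval
from mirhap.disease_ld import (DiseaseSNP, build_ld_blocks, common_snp_overlap,
                               intersect_mirna_ld, summarize_disease)


def proxies_df(rows):
    return pd.DataFrame(rows, columns=["index_rsid", "proxy_rsid", "pos", "r2"])


class TestBuildLdBlocks:
    def test_flanking_proxies_span_block(self):
        snps = [DiseaseSNP("rs1", "c", 100)]
        blocks = build_ld_blocks(
            proxies_df([("rs1", "p1", 50, 0.95), ("rs1", "p2", 150, 0.91)]),
            snps,
        )
        assert (blocks[0].interval.start, blocks[0].interval.end) == (50, 151)
        assert blocks[0].members == {"p1": 0.95, "p2": 0.91}

    def test_sub_threshold_proxies_collapse_block(self):
        snps = [DiseaseSNP("rs1", "c", 100)]
        blocks = build_ld_blocks(
            proxies_df([("rs1", "p1", 50, 0.89), ("rs1", "p2", 150, 0.89)]),
            snps,
        )
        assert (blocks[0].interval.start, blocks[0].interval.end) == (100, 101)

    def test_r2_boundary_inclusive(self):
        snps = [DiseaseSNP("rs1", "c", 100)]
        blocks = build_ld_blocks(proxies_df([("rs1", "p1", 50, 0.9)]), snps)
        assert blocks[0].interval.start == 50

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError, match="rsX"):
            build_ld_blocks(proxies_df([("rsX", "p", 5, 0.95)]),
                            [DiseaseSNP("rs1", "c", 100)])

    def test_matches_filter_then_extent_oracle(self, rng):
        snps = [DiseaseSNP(f"rs{i}", "c", int(rng.integers(0, 10000)))
                for i in range(20)]
        rows = []
        for s in snps:
            for p in range(int(rng.integers(0, 8))):
                rows.append((s.rsid, f"{s.rsid}_p{p}",
                             int(rng.integers(0, 10000)),
                             float(np.round(rng.uniform(0.5, 1.0), 3))))
        df = proxies_df(rows)
        blocks = {b.index_rsid: b for b in build_ld_blocks(df, snps)}
        for s in snps:
            qualifying = [r[2] for r in rows if r[0] == s.rsid and r[3] >= 0.9]
            lo = min([s.pos] + qualifying)
            hi = max([s.pos] + qualifying)
            assert (blocks[s.rsid].interval.start,
                    blocks[s.rsid].interval.end) == (lo, hi + 1)

    def test_raising_r2_min_shrinks_blocks(self, rng):
        snps = [DiseaseSNP(f"rs{i}", "c", int(rng.integers(0, 5000)))
                for i in range(10)]
        rows = [(s.rsid, f"{s.rsid}_p{p}", int(rng.integers(0, 5000)),
                 float(np.round(rng.uniform(0.5, 1.0), 3)))
                for s in snps for p in range(6)]
        df = proxies_df(rows)
        loose = {b.index_rsid: b for b in build_ld_blocks(df, snps, r2_min=0.8)}
        tight = {b.index_rsid: b for b in build_ld_blocks(df, snps, r2_min=0.95)}
        for rsid in loose:
            assert loose[rsid].interval.start <= tight[rsid].interval.start
            assert loose[rsid].interval.end >= tight[rsid].interval.end


class TestIntersect:
    def _blocks(self):
        snps = [DiseaseSNP("rs1", "c", 100, ["asthma"]),
                DiseaseSNP("rs2", "c", 400, ["psoriasis", "Asthma "])]
        df = proxies_df([("rs1", "p1", 50, 0.95), ("rs1", "p2", 200, 0.92),
                         ("rs2", "p3", 350, 0.95), ("rs2", "p4", 230, 0.91)])
        return snps, build_ld_blocks(df, snps)

    def test_mirna_inside_block(self):
        snps, blocks = self._blocks()
        assoc = intersect_mirna_ld([("m1", GenomicInterval("c", 120, 150))],
                                   blocks)
        assert len(assoc) == 1 and assoc.iloc[0]["index_rsid"] == "rs1"

    def test_mirna_spanning_two_blocks_gets_two_rows(self):
        snps, blocks = self._blocks()
        assoc = intersect_mirna_ld([("m1", GenomicInterval("c", 190, 240))],
                                   blocks)
        assert sorted(assoc["index_rsid"]) == ["rs1", "rs2"]

    def test_matches_nested_loop_oracle(self, rng):
        snps = [DiseaseSNP(f"rs{i}", "c", int(rng.integers(0, 3000)))
                for i in range(15)]
        rows = [(s.rsid, f"{s.rsid}_p{p}", int(rng.integers(0, 3000)),
                 float(np.round(rng.uniform(0.7, 1.0), 3)))
                for s in snps for p in range(4)]
        blocks = build_ld_blocks(proxies_df(rows), snps)
        loci = [(f"m{i}", GenomicInterval("c", int(s), int(s) + int(l)))
                for i, (s, l) in enumerate(zip(rng.integers(0, 2900, 100),
                                               rng.integers(20, 120, 100)))]
        assoc = intersect_mirna_ld(loci, blocks)
        got = {(r["mirna_id"], r["index_rsid"]) for _, r in assoc.iterrows()}
        expected = {
            (mid, b.index_rsid)
            for mid, iv in loci for b in blocks
            if iv.start < b.interval.end and b.interval.start < iv.end
        }
        assert got == expected


class TestSummarize:
    def test_one_mirna_one_snp_two_phenotypes(self):
        snps = [DiseaseSNP("rs1", "c", 100, ["asthma", "psoriasis"])]
        blocks = build_ld_blocks(proxies_df([]), snps)
        assoc = intersect_mirna_ld([("m1", GenomicInterval("c", 100, 101))],
                                   blocks)
        assert summarize_disease(assoc, snps) == (1, 1, 2)

    def test_no_associations(self):
        assert summarize_disease(pd.DataFrame(), []) == (0, 0, 0)

    def test_phenotype_labels_normalised(self):
        snps, blocks = TestIntersect()._blocks()
        assoc = intersect_mirna_ld([("m1", GenomicInterval("c", 50, 360))],
                                   blocks)
        # "asthma" and "Asthma " collapse; psoriasis distinct
        assert summarize_disease(assoc, snps) == (1, 2, 2)

    def test_row_order_invariance(self, rng):
        snps, blocks = TestIntersect()._blocks()
        assoc = intersect_mirna_ld(
            [("m1", GenomicInterval("c", 50, 360)),
             ("m2", GenomicInterval("c", 100, 120))], blocks)
        shuffled = assoc.sample(frac=1, random_state=3)
        assert summarize_disease(assoc, snps) == \
            summarize_disease(shuffled, snps)


class TestCommonSnpOverlap:
    def _mirna(self):
        return [("m1", GenomicInterval("c", 100, 121))]

    def test_inclusive_boundaries(self):
        snps = [DiseaseSNP("rs1", "c", 100, maf=0.05)]
        flags, count = common_snp_overlap(self._mirna(), snps, maf_min=0.05)
        assert flags["m1"] and count == 1

    def test_maf_below_cutoff_not_flagged(self):
        snps = [DiseaseSNP("rs1", "c", 100, maf=0.009)]
        flags, count = common_snp_overlap(self._mirna(), snps, maf_min=0.01)
        assert not flags["m1"] and count == 0

    def test_position_outside_interval_not_flagged(self):
        snps = [DiseaseSNP("rs1", "c", 121, maf=0.3)]  # half-open end
        flags, _ = common_snp_overlap(self._mirna(), snps, maf_min=0.01)
        assert not flags["m1"]

    def test_matches_containment_oracle_and_monotone_in_maf(self, rng):
        mirnas = [(f"m{i}", GenomicInterval("c", int(s), int(s) + 21))
                  for i, s in enumerate(rng.integers(0, 2000, 40))]
        snps = [DiseaseSNP(f"rs{i}", "c", int(rng.integers(0, 2000)),
                           maf=float(np.round(rng.uniform(0, 0.5), 3)))
                for i in range(60)]
        counts = []
        for maf_min in (0.01, 0.05, 0.2):
            flags, count = common_snp_overlap(mirnas, snps, maf_min)
            expected = {
                mid: any(s.maf >= maf_min and iv.start <= s.pos < iv.end
                         for s in snps)
                for mid, iv in mirnas
            }
            assert flags == expected
            counts.append(count)
        assert counts[0] >= counts[1] >= counts[2]
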