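"""Ago CLIP read support and Dicer-dependence calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirhap.evidence import (AgoSupport, count_read_support,
                             dicer_dependence_test, flag_supported)
from mirhap.simulate import make_clip_reads, make_qpcr_table, random_background


@pytest.fixture(scope="module")
def clip_fixture(tmp_path_factory):
    """Three CLIP-like datasets with known planted counts."""
    out = tmp_path_factory.mktemp("clip")
    rng = np.random.default_rng(21)
    mirnas = [
        {"id": "mirA", "seq": random_background(21, 0.5, rng)},
        {"id": "mirB", "seq": random_background(21, 0.5, rng)},
        {"id": "mirZero", "seq": random_background(21, 0.5, rng)},
    ]
    counts = {("mirA", 0): 600, ("mirA", 1): 0, ("mirA", 2): 0,
              ("mirB", 0): 300, ("mirB", 1): 300, ("mirB", 2): 0,
              ("mirZero", 0): 0, ("mirZero", 1): 0, ("mirZero", 2): 0}
    truth = make_clip_reads(mirnas, counts, read_len=50, out_dir=out, seed=7,
                            n_decoys=400)
    datasets = {f"d{i}": out / f"clip_{i}.fastq" for i in range(3)}
    return mirnas, truth, datasets


class TestCountReadSupport:
    def test_planted_counts_recovered(self, clip_fixture):
        mirnas, truth, datasets = clip_fixture
        sup = count_read_support("mirA", mirnas[0]["seq"], datasets)
        assert sup.per_dataset == {"d0": 600, "d1": 0, "d2": 0}
        assert sup.total == 600 and sup.supported

    def test_absent_query_counts_zero(self, clip_fixture):
        mirnas, _, datasets = clip_fixture
        sup = count_read_support("mirZero", mirnas[2]["seq"], datasets)
        assert sup.total == 0 and not sup.supported

    def test_matches_naive_per_read_scan(self, clip_fixture):
        mirnas, _, datasets = clip_fixture
        q = mirnas[1]["seq"]
        naive = 0
        for path in datasets.values():
            lines = open(path).read().splitlines()
            naive += sum(1 for i in range(1, len(lines), 4) if q in lines[i])
        sup = count_read_support("mirB", q, datasets)
        assert sup.total == naive == 600

    def test_read_equal_to_mirna_counts(self, tmp_path):
        seq = "ACGTACGTACGTACGTACGT"
        p = tmp_path / "one.fastq"
        p.write_text(f"@r\n{seq}\n+\n{'I' * len(seq)}\n")
        sup = count_read_support("m", seq, {"d": p})
        assert sup.total == 1

    def test_short_query_rejected(self, tmp_path):
        p = tmp_path / "x.fastq"
        p.write_text("@r\nACGTACGTACGTACGTACGT\n+\nIIIIIIIIIIIIIIIIIIII\n")
        with pytest.raises(ValueError, match="16"):
            count_read_support("m", "ACGTACG", {"d": p})

    def test_adding_reads_never_decreases_counts(self, tmp_path, rng):
        seq = random_background(20, 0.5, rng)
        reads = [seq, random_background(30, 0.5, rng)]
        p = tmp_path / "grow.fastq"
        totals = []
        for k in (1, 2):
            p.write_text("".join(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n"
                                 for i, r in enumerate(reads[:k])))
            totals.append(count_read_support("m", seq, {"d": p}).total)
        assert totals[0] <= totals[1]


class TestFlagSupported:
    def test_threshold_boundary(self):
        at = AgoSupport("a", {"d": 500})
        below = AgoSupport("b", {"d": 499})
        flags = flag_supported([at, below], threshold=500)
        assert flags == {"a": True, "b": False}

    def test_empty_dataset_list_unsupported(self):
        assert flag_supported([AgoSupport("a", {})])["a"] is False

    def test_sum_vs_per_dataset_aggregation(self):
        split = {"d0": 300, "d1": 300}
        assert AgoSupport("a", split, mode="sum").supported
        assert not AgoSupport("a", split, mode="per_dataset").supported


class TestDicerDependence:
    @staticmethod
    def table(sil, ctl, target="m1", norm=0.0):
        rows = []
        for i, v in enumerate(ctl):
            rows += [{"sample": f"c{i}", "condition": "control",
                      "target": "ACTB", "ct": norm},
                     {"sample": f"c{i}", "condition": "control",
                      "target": target, "ct": v}]
        for i, v in enumerate(sil):
            rows += [{"sample": f"s{i}", "condition": "silenced",
                      "target": "ACTB", "ct": norm},
                     {"sample": f"s{i}", "condition": "silenced",
                      "target": target, "ct": v}]
        return pd.DataFrame(rows)

    def test_clear_effect_called_dependent(self):
        calls = dicer_dependence_test(self.table([8.0, 8.2], [5.0, 5.1]))
        call = calls[0]
        # independent oracle: pooled t with df = 2
        sil, ctl = np.array([8.0, 8.2]), np.array([5.0, 5.1])
        sp2 = (sil.var(ddof=1) + ctl.var(ddof=1)) / 2
        t = (sil.mean() - ctl.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        p_oracle = 2 * sps.t.sf(abs(t), df=2)
        assert call.p_value == pytest.approx(p_oracle)
        assert call.p_value < 0.05 and call.dependent
        assert call.ddct == pytest.approx(3.05)
        assert call.fold_change == pytest.approx(2 ** -3.05)

    def test_identical_conditions_not_dependent(self):
        calls = dicer_dependence_test(self.table([5.0, 5.1], [5.0, 5.1]))
        assert not calls[0].dependent

    def test_direction_rule_blocks_upregulation(self):
        # expression UP on silencing (lower ΔCt): never dependent
        calls = dicer_dependence_test(self.table([5.0, 5.1], [8.0, 8.2]))
        assert calls[0].p_value < 0.05 and not calls[0].dependent

    def test_missing_normalizer_skips_mirna(self, caplog):
        tbl = self.table([8.0, 8.2], [5.0, 5.1])
        tbl = tbl[~((tbl["sample"] == "s0") & (tbl["target"] == "ACTB"))]
        assert dicer_dependence_test(tbl) == []

    def test_power_on_planted_effect(self):
        """Planted 3-cycle effect at sd 0.1 is recovered in the 2v2 design."""
        hits = 0
        for seed in range(100):
            tbl = make_qpcr_table(["m"], {"m": True}, effect=3.0,
                                  noise_sd=0.1, seed=seed)
            calls = dicer_dependence_test(tbl)
            hits += calls[0].dependent
        assert hits >= 95
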