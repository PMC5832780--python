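"""Shared fixtures: one synthetic study, built once per session.

The expensive artefacts (haplotype pair, full stride-1 scan, trained triage
model) are session-scoped so the planted-truth fixture is generated and
scanned exactly once and reused by scanner, triage, pipeline and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirhap.core_io import GenomicInterval, HaplotypeSequence
from mirhap.scanner import ScanConfig, ScanStats, scan_sequence
from mirhap.simulate import (SimConfig, dinucleotide_shuffle,
                             make_haplotype_pair, make_mature_mirnas,
                             make_triage_training_set)
from mirhap.triage import train_triage


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def hap_pair(sim_config):
    """(haplotype A, haplotype B, truth records, variants) for seed 1."""
    return make_haplotype_pair(sim_config)


@pytest.fixture(scope="session")
def truth_intervals(hap_pair):
    _, _, truth, _ = hap_pair
    return [GenomicInterval("hapA", r["start"], r["end"]) for r in truth]


@pytest.fixture(scope="session")
def mature_mirnas(hap_pair, sim_config):
    hap_a, _, truth, _ = hap_pair
    return make_mature_mirnas(truth, hap_a, sim_config.mature_len)


@pytest.fixture(scope="session")
def scanned_hapA(hap_pair):
    """Full stride-1 default scan of haplotype A (windows, funnel stats)."""
    hap_a, _, _, _ = hap_pair
    stats = ScanStats()
    windows = scan_sequence(hap_a, ScanConfig(), stats=stats)
    return windows, stats


@pytest.fixture(scope="session")
def shuffled_background(hap_pair):
    hap_a, _, _, _ = hap_pair
    return HaplotypeSequence("shuffled", dinucleotide_shuffle(hap_a.seq, 99))


@pytest.fixture(scope="session")
def scanned_background(shuffled_background):
    stats = ScanStats()
    windows = scan_sequence(shuffled_background, ScanConfig(), stats=stats)
    return windows, stats


@pytest.fixture(scope="session")
def triage_training(sim_config):
    return make_triage_training_set(sim_config, n_pos=200, n_neg=200, seed=11)


@pytest.fixture(scope="session")
def triage_model(triage_training):
    pos, neg = triage_training
    return train_triage(pos, neg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
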