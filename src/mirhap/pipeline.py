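"""End-to-end discovery pipeline with a declarative config and run manifest.

Wires the funnel: enumerate windows -> prescreen -> fold -> MFE filter ->
topology filter -> triage classifier -> exon exclusion -> merge into the
candidate-locus atlas.  A manifest records the config snapshot, input
checksums, per-stage counts and timestamps; re-running the same config and
seed reproduces the atlas byte-identically (reference engine).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .core_io import BedRecord, GenomicInterval, read_exons, read_fasta, write_bed
from .scanner import (CandidateLocus, ScanConfig, ScanStats, build_atlas,
                      exclude_exons, scan_sequence)
from .simulate import SimConfig, make_haplotype_pair, make_triage_training_set
from .triage import TriageModel, apply_triage, train_triage


class ConfigError(ValueError):
    """Config schema violation, with the offending field in the message."""


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict
    counts: dict
    timestamps: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


_SCAN_FIELDS = {f.name for f in dataclasses.fields(ScanConfig)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def _build_scan_config(section: dict) -> ScanConfig:
    unknown = set(section) - _SCAN_FIELDS
    if unknown:
        raise ConfigError(f"scan: unknown fields {sorted(unknown)}")
    try:
        return ScanConfig(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"scan: {exc}") from exc


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in cfg:
        if key not in ("seed", "fasta", "exons", "scan", "simulate", "triage",
                       "out_dir"):
            raise ConfigError(f"unknown top-level config field {key!r}")
    return cfg


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, out_dir: str | Path | None = None):
    """Run the full funnel; returns (atlas, manifest, kept windows).

    ``config`` is a YAML path or a dict.  Inputs come either from
    ``fasta`` (+ optional ``exons``) or, when ``fasta`` is absent, from the
    seeded synthetic generator (``simulate`` section = SimConfig fields).
    The triage stage is on by default; without a ``triage.model`` path a
    classifier is trained from synthetic labelled windows derived from the
    run seed.
    """
    t_start = time.strftime("%Y-%m-%dT%H:%M:%S")
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    scan_cfg = _build_scan_config(cfg.get("scan", {}) or {})

    checksums = {}
    if cfg.get("fasta"):
        fasta_path = Path(cfg["fasta"])
        haps = read_fasta(fasta_path)
        checksums[str(fasta_path)] = _md5(fasta_path)
    else:
        sim_section = dict(cfg.get("simulate", {}) or {})
        unknown = set(sim_section) - _SIM_FIELDS
        if unknown:
            raise ConfigError(f"simulate: unknown fields {sorted(unknown)}")
        sim_section.setdefault("seed", seed)
        sim = SimConfig(**sim_section)
        hap_a, _, _, _ = make_haplotype_pair(sim)
        haps = [hap_a]

    exons: list[GenomicInterval] = []
    if cfg.get("exons"):
        exons_path = Path(cfg["exons"])
        exons = read_exons(exons_path)
        checksums[str(exons_path)] = _md5(exons_path)

    triage_cfg = dict(cfg.get("triage", {}) or {})
    triage_enabled = bool(triage_cfg.get("enabled", True))

    stats = ScanStats()
    windows = []
    for hap in haps:
        windows.extend(scan_sequence(hap, scan_cfg, stats=stats))

    counts = {
        "windows_enumerated": stats.windows_enumerated,
        "prescreen_passed": stats.prescreen_passed,
        "folded": stats.folded,
        "mfe_passed": stats.mfe_passed,
        "topology_passed": stats.topology_passed,
    }

    if triage_enabled and windows:
        if triage_cfg.get("model"):
            model = TriageModel.load(triage_cfg["model"])
        else:
            sim_section = dict(cfg.get("simulate", {}) or {})
            sim_section = {k: v for k, v in sim_section.items()
                           if k in _SIM_FIELDS}
            sim_section["seed"] = seed
            sim = SimConfig(**sim_section)
            pos, neg = make_triage_training_set(
                sim,
                n_pos=int(triage_cfg.get("n_pos", 200)),
                n_neg=int(triage_cfg.get("n_neg", 200)),
                seed=seed + 10_007,
            )
            model = train_triage(pos, neg, seed=seed,
                                 threshold=float(triage_cfg.get("threshold",
                                                                0.5)))
        kept = apply_triage(model, windows)
    else:
        kept = list(windows)
    counts["triage_passed"] = len(kept)

    kept = exclude_exons(kept, exons)
    counts["exon_excluded_survivors"] = len(kept)

    atlas = build_atlas(kept)
    counts["loci_merged"] = len(atlas)

    manifest = RunManifest(
        config=cfg,
        version=__version__,
        input_checksums=checksums,
        counts=counts,
        timestamps={"started": t_start,
                    "finished": time.strftime("%Y-%m-%dT%H:%M:%S")},
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_atlas(atlas, out_dir)
        manifest.save(out_dir / "manifest.json")
    return atlas, manifest, kept


def write_atlas(atlas: list[CandidateLocus], out_dir: str | Path) -> None:
    """BED6 atlas plus a TSV sidecar with n_windows and best_mfe."""
    out_dir = Path(out_dir)
    beds = [
        BedRecord(l.interval.chrom, l.interval.start, l.interval.end,
                  f"locus{i}", 0.0, "+")
        for i, l in enumerate(atlas)
    ]
    write_bed(beds, out_dir / "atlas.bed")
    with open(out_dir / "atlas.tsv", "w") as fh:
        fh.write("name\tchrom\tstart\tend\tn_windows\tbest_mfe\n")
        for i, l in enumerate(atlas):
            fh.write(
                f"locus{i}\t{l.interval.chrom}\t{l.interval.start}\t"
                f"{l.interval.end}\t{l.n_windows}\t{l.best_mfe:.1f}\n"
            )
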