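"""Seeded generators for every input the pipeline consumes.

Emulates the statistical structure the analyses assume: hairpin-forming
loci embedded in unstructured background sequence, a divergent haplotype
pair with a protected (verbatim-conserved) fraction of loci, CLIP-like
read sets embedding mature sequences exactly, a two-replicate
silencing/control qPCR design, and an r²-defined SNP/LD/phenotype catalog.
Every generator is deterministic for a fixed seed and records machine-
readable ground truth.

Not modelled (documented limitations): repeat structure and gene
architecture of real MHC sequence, sequencing errors and adapters, qPCR
efficiency differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import HaplotypeSequence, revcomp
from .folding import EnergyParams, fold_mfe
from .folding.params import PAIR_ORDER

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiments (defaults = test fixture).

    Background GC of 0.41 is MHC-like; haplotype length 2,000 bp with five
    planted clean hairpins is the planted-truth scan fixture; substitution/
    indel rates give a divergent-but-alignable haplotype pair with half of
    the hairpin loci protected (conserved verbatim); the qPCR design is two
    biological replicates per condition with a 3-cycle silencing effect.
    """

    seed: int = 0
    hap_length: int = 2000
    background_gc: float = 0.41
    n_hairpins: int = 5
    stem_len_range: tuple[int, int] = (18, 25)
    loop_len_range: tuple[int, int] = (5, 9)
    bulge_prob: float = 0.0
    substitution_rate: float = 0.02
    indel_rate: float = 0.001
    protect_fraction: float = 0.5
    n_mature: int = 5
    mature_len: int = 21
    n_clip_datasets: int = 3
    clip_supported_mean: float = 300.0
    clip_decoy_reads: int = 400
    clip_read_len: int = 50
    qpcr_effect: float = 3.0
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 2
    n_disease_snps: int = 10
    n_proxies_per_snp: int = 5
    r2_low: float = 0.5
    proxy_span: int = 400
    phenotype_pool: tuple[str, ...] = (
        "type 1 diabetes", "rheumatoid arthritis", "psoriasis",
        "multiple sclerosis", "celiac disease", "asthma", "IgA nephropathy",
        "ulcerative colitis", "systemic lupus erythematosus", "narcolepsy",
    )

    def __post_init__(self) -> None:
        for rate in (self.background_gc, self.bulge_prob,
                     self.substitution_rate, self.indel_rate,
                     self.protect_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.hap_length < 10 * (2 * self.stem_len_range[1]
                                   + self.loop_len_range[1]):
            raise ValueError("haplotype too short for the requested hairpins")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def random_background(length: int, gc: float, rng) -> str:
    rng = _rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# hairpin construction
# ---------------------------------------------------------------------------

def plant_hairpin(stem_len: int, loop_len: int, bulges: int = 0,
                  seed=0) -> tuple[str, dict]:
    """A hairpin-forming sequence: arm + loop + revcomp(arm) (+ bulges).

    The arm is drawn GC-biased and redrawn until the perfect stem's summed
    stacking energy is below -30 kcal/mol, so a clean construct always
    clears a -20 kcal/mol cutoff by construction.  ``bulges`` single-base
    insertions into the 3' arm plant bulge loops.
    """
    if stem_len < 15:
        raise ValueError("stem_len must be >= 15")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    rng = _rng(seed)
    params = EnergyParams.default()
    for _ in range(200):
        arm = "".join(rng.choice(_BASES, size=stem_len,
                                 p=[0.22, 0.28, 0.28, 0.22]))
        # summed stacking of the perfect stem
        total = 0.0
        ok = True
        for i in range(stem_len - 1):
            outer = arm[i] + {"A": "U", "C": "G", "G": "C", "T": "A"}[arm[i]]
            inner = arm[i + 1] + {"A": "U", "C": "G", "G": "C", "T": "A"}[arm[i + 1]]
            outer = outer.replace("T", "U")
            inner_rev = inner[::-1].replace("T", "U")
            if outer not in PAIR_ORDER or inner_rev not in PAIR_ORDER:
                ok = False
                break
            total += params.stack[outer][inner_rev]
        # -30 leaves >= 20 kcal/mol headroom over the largest hairpin-loop
        # initiation, so clean constructs always clear a -20 cutoff
        if ok and total < -30.0:
            break
    else:  # pragma: no cover - p(failure) vanishing
        raise RuntimeError("failed to draw a stable stem")
    # loop drawn from {A, C} only: those bases cannot pair with each other,
    # so no spurious pair inside the loop can break the linear topology
    loop = "".join(rng.choice(_BASES[:2], size=loop_len, p=[0.6, 0.4]))
    arm3_clean = revcomp(arm)
    for _ in range(50):
        arm3 = arm3_clean
        for _ in range(bulges):
            pos = int(rng.integers(2, len(arm3) - 2))
            arm3 = arm3[:pos] + str(rng.choice(_BASES)) + arm3[pos:]
        seq = arm + loop + arm3
        if bulges == 0:
            break
        # an inserted base can be absorbed into an internal loop by the
        # folder; verify the construct really folds with a bulge, else redraw
        from .folding import classify_topology as _ct

        topo = _ct(fold_mfe(seq).structure)
        if topo.n_bulges >= bulges:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to plant a bulged hairpin")
    truth = {
        "stem_len": stem_len,
        "loop_len": loop_len,
        "bulges": bulges,
        "length": len(seq),
        "expected_topology": "bulged" if bulges else "linear",
    }
    return seq, truth


def hairpin_with_mfe(target_mfe: float, seed=0, window_len: int = 58,
                     max_trials: int = 20000) -> str:
    """Search for a window whose reference-engine MFE equals ``target_mfe``.

    Builds hairpins of varying stem strength inside an unstructured poly-A
    flank until the folded window hits the target exactly (the model's
    energies are multiples of 0.1 kcal/mol, so exact hits exist densely in
    the relevant range).
    """
    rng = _rng(seed)
    for _ in range(max_trials):
        stem = int(rng.integers(10, 16))
        loop = int(rng.integers(3, 8))
        arm = "".join(rng.choice(_BASES, size=stem,
                                 p=[0.3, 0.2, 0.2, 0.3]))
        hp = arm + "".join(rng.choice(_BASES[:2], size=loop,
                                      p=[0.6, 0.4])) + revcomp(arm)
        if len(hp) > window_len:
            continue
        pad = window_len - len(hp)
        win = "A" * (pad // 2) + hp + "A" * (pad - pad // 2)
        res = fold_mfe(win)
        if abs(res.mfe - target_mfe) < 1e-9:
            from .folding import classify_topology

            topo = classify_topology(res.structure)
            # keep the construct a clean linear hairpin so only the MFE
            # filter decides its fate
            if topo.is_linear_hairpin:
                return win
    raise RuntimeError(f"no window with MFE {target_mfe} found")


# ---------------------------------------------------------------------------
# haplotype pair with planted truth
# ---------------------------------------------------------------------------

def make_haplotype_pair(config: SimConfig):
    """(haplotype A, haplotype B, truth records, variant records).

    A carries ``n_hairpins`` non-overlapping planted hairpins in i.i.d.
    background; B derives from A by seeded substitutions and (background-
    only) indels.  A ``protect_fraction`` of hairpin loci is copied
    verbatim into B; every unprotected hairpin locus receives at least one
    substitution, so mutated copies are guaranteed to differ.
    """
    rng = _rng(config.seed)
    margin = 130  # > max window length so planted loci cannot merge

    hairpins = []
    for h in range(config.n_hairpins):
        stem = int(rng.integers(config.stem_len_range[0],
                                config.stem_len_range[1] + 1))
        loop = int(rng.integers(config.loop_len_range[0],
                                config.loop_len_range[1] + 1))
        bulges = int(rng.random() < config.bulge_prob)
        seq, truth = plant_hairpin(stem, loop, bulges, seed=rng)
        hairpins.append((seq, truth))

    # placement: partition the free space so every locus keeps `margin` bp
    # of clearance (loci can then never merge in the atlas)
    lens = [len(h[0]) for h in hairpins]
    k = len(lens)
    slack = config.hap_length - (sum(lens) + margin * (k + 1))
    if slack < 0:
        raise RuntimeError("could not place non-overlapping hairpins: "
                           f"need {-slack} more bases")
    extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    starts = []
    cur = margin + int(extra[0])
    for i, length in enumerate(lens):
        starts.append(cur)
        cur += length + margin + int(extra[i + 1])

    background = random_background(config.hap_length, config.background_gc, rng)
    seq_a = list(background)
    truth_records = []
    for idx, (start, (hp_seq, hp_truth)) in enumerate(zip(starts, hairpins)):
        seq_a[start : start + len(hp_seq)] = list(hp_seq)
        truth_records.append({
            "name": f"hp{idx}",
            "start": start,
            "end": start + len(hp_seq),
            **hp_truth,
        })
    seq_a = "".join(seq_a)

    n_protect = int(round(config.protect_fraction * len(truth_records)))
    protected_idx = set(
        rng.choice(len(truth_records), size=n_protect, replace=False).tolist()
    )
    for i, rec in enumerate(truth_records):
        rec["protected"] = i in protected_idx

    # derive haplotype B
    in_locus = np.zeros(len(seq_a), dtype=int)  # 0 bg, 1 protected, 2 mutable locus
    for i, rec in enumerate(truth_records):
        in_locus[rec["start"] : rec["end"]] = 1 if rec["protected"] else 2

    variants = []
    out = []
    forced = {rec["name"]: False for rec in truth_records if not rec["protected"]}
    pos_to_locus = {}
    for rec in truth_records:
        for p in range(rec["start"], rec["end"]):
            pos_to_locus[p] = rec["name"]

    for pos, base in enumerate(seq_a):
        zone = in_locus[pos]
        if zone == 1:
            out.append(base)
            continue
        r = rng.random()
        if zone == 0 and r < config.indel_rate:
            if rng.random() < 0.5:
                variants.append({"pos": pos, "ref": base, "alt": "", "type": "del"})
                continue
            ins = str(rng.choice(_BASES))
            out.append(ins + base)
            variants.append({"pos": pos, "ref": "", "alt": ins, "type": "ins"})
            continue
        sub_lo = config.indel_rate if zone == 0 else 0.0
        if sub_lo <= r < sub_lo + config.substitution_rate:
            alt = str(rng.choice(_BASES[_BASES != base]))
            out.append(alt)
            variants.append({"pos": pos, "ref": base, "alt": alt, "type": "sub"})
            if zone == 2:
                forced[pos_to_locus[pos]] = True
        else:
            out.append(base)

    seq_b = list("".join(out))
    # guarantee every unprotected locus differs
    for rec in truth_records:
        if not rec["protected"] and not forced[rec["name"]]:
            pos = int(rng.integers(rec["start"], rec["end"]))
            base = seq_a[pos]
            alt = str(rng.choice(_BASES[_BASES != base]))
            # indels are background-only, so A and B coordinates can drift;
            # apply the forced substitution at the A coordinate mapped via
            # the variant list
            shift = sum(
                (1 if v["type"] == "ins" else -1)
                for v in variants if v["type"] != "sub" and v["pos"] < pos
            )
            seq_b[pos + shift] = alt
            variants.append({"pos": pos, "ref": base, "alt": alt, "type": "sub"})
    seq_b = "".join(seq_b)

    hap_a = HaplotypeSequence("hapA", seq_a)
    hap_b = HaplotypeSequence("hapB", seq_b)
    return hap_a, hap_b, truth_records, variants


def dinucleotide_shuffle(seq: str, seed=0) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    dinucleotide multigraph)."""
    rng = _rng(seed)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for i in range(len(seq) - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    # random walk consuming edges; retry until all edges are used
    for _ in range(200):
        pool = {k: list(v) for k, v in edges.items()}
        for k in pool:
            rng.shuffle(pool[k])
        walk = [seq[0]]
        cur = seq[0]
        ok = True
        while True:
            nxt_list = pool.get(cur)
            if not nxt_list:
                break
            cur = nxt_list.pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    return seq  # pragma: no cover - fallback for pathological inputs


# ---------------------------------------------------------------------------
# mature miRNAs, CLIP reads, qPCR, SNP/LD catalog
# ---------------------------------------------------------------------------

def make_mature_mirnas(truth_records, hap: HaplotypeSequence,
                       mature_len: int = 21) -> list[dict]:
    """Mature sequences excised from the 5' arm of each planted hairpin."""
    out = []
    for rec in truth_records:
        start = rec["start"] + 1
        end = start + mature_len
        out.append({
            "id": f"mir-{rec['name']}",
            "seq": hap.seq[start:end],
            "chrom": hap.name,
            "start": start,
            "end": end,
            "pre_name": rec["name"],
        })
    return out


def make_clip_reads(mirnas: list[dict], counts: dict, read_len: int,
                    out_dir: str | Path, seed=0, n_decoys: int = 400,
                    gc: float = 0.41) -> dict:
    """Write one FASTQ per dataset; supporting reads embed the mature
    sequence exactly, decoys verifiably contain no planted sequence.

    ``counts`` maps (mirna_id, dataset index) -> planted read count.
    Returns the truth counts actually written.
    """
    rng = _rng(seed)
    if mirnas and read_len < max(len(m["seq"]) for m in mirnas):
        raise ValueError("read_len must be >= the longest mature sequence")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets = sorted({d for (_, d) in counts})
    planted = {m["id"]: m["seq"] for m in mirnas}
    truth: dict = {}
    for d in datasets:
        reads = []
        for m in mirnas:
            c = counts.get((m["id"], d), 0)
            truth[(m["id"], d)] = c
            for r in range(c):
                flank = read_len - len(m["seq"])
                off = int(rng.integers(0, flank + 1))
                left = random_background(off, gc, rng)
                right = random_background(flank - off, gc, rng)
                reads.append(left + m["seq"] + right)
        for _ in range(n_decoys):
            while True:
                decoy = random_background(read_len, gc, rng)
                if not any(s in decoy or revcomp(s) in decoy
                           for s in planted.values()):
                    break
            reads.append(decoy)
        order = rng.permutation(len(reads))
        path = out_dir / f"clip_{d}.fastq"
        with open(path, "w") as fh:
            for i, idx in enumerate(order):
                fh.write(f"@read{i}\n{reads[idx]}\n+\n{'I' * read_len}\n")
    return truth


def make_qpcr_table(mirna_ids: list[str], dependent: dict[str, bool],
                    effect: float = 3.0, noise_sd: float = 0.1,
                    replicates: int = 2, seed=0,
                    normalizer: str = "ACTB") -> pd.DataFrame:
    """Two-condition Ct table with a planted silencing effect.

    Dicer-dependent targets gain ``effect`` cycles on the target Ct under
    silencing (lower expression = later amplification); the normalizer is
    unaffected.  Columns: sample, condition, target, ct.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = _rng(seed)
    rows = []
    base_norm = 15.0
    for cond in ("control", "silenced"):
        for rep in range(1, replicates + 1):
            sample = f"{cond}_{rep}"
            rows.append({
                "sample": sample, "condition": cond, "target": normalizer,
                "ct": base_norm + rng.normal(0.0, noise_sd),
            })
            for mid in mirna_ids:
                base = 22.0 + (sum(ord(c) for c in mid) % 5) * 0.5
                ct = base + rng.normal(0.0, noise_sd)
                if cond == "silenced" and dependent.get(mid, False):
                    ct += effect
                rows.append({"sample": sample, "condition": cond,
                             "target": mid, "ct": ct})
    return pd.DataFrame(rows)


def make_snp_ld_catalog(mirnas: list[dict], hap_length: int,
                        n_disease_snps: int = 10, n_proxies: int = 5,
                        r2_low: float = 0.5, proxy_span: int = 400,
                        phenotype_pool=SimConfig.phenotype_pool, seed=0,
                        chrom: str = "hapA"):
    """Disease-SNP and proxy tables with recorded truth block extents.

    Half of the disease SNPs are anchored near planted miRNA loci so their
    r² >= 0.9 blocks overlap them; the rest land in background.  Returns
    (snp table, proxy table, truth dict).
    """
    rng = _rng(seed)
    snp_rows, proxy_rows = [], []
    truth = {"blocks": {}, "snps_near_mirna": []}
    for s in range(n_disease_snps):
        rsid = f"rs{1000 + s}"
        if mirnas and s % 2 == 0:
            m = mirnas[(s // 2) % len(mirnas)]
            pos = int(rng.integers(max(0, m["start"] - 50), m["end"] + 50))
            truth["snps_near_mirna"].append(rsid)
        else:
            pos = int(rng.integers(0, hap_length))
        maf = float(rng.uniform(0.001, 0.5))
        n_phen = int(rng.integers(1, 4))
        phens = rng.choice(len(phenotype_pool), size=n_phen, replace=False)
        snp_rows.append({
            "rsid": rsid, "chrom": chrom, "pos": pos,
            "maf": round(maf, 4),
            "phenotypes": ";".join(phenotype_pool[i] for i in sorted(phens)),
        })
        positions = [pos]
        for p in range(n_proxies):
            ppos = int(np.clip(pos + rng.integers(-proxy_span, proxy_span + 1),
                               0, hap_length - 1))
            r2 = round(float(rng.uniform(r2_low, 1.0)), 3)
            proxy_rows.append({
                "index_rsid": rsid, "proxy_rsid": f"rs{9000 + s * 100 + p}",
                "pos": ppos, "r2": r2,
            })
            if r2 >= 0.9:
                positions.append(ppos)
        truth["blocks"][rsid] = (min(positions), max(positions) + 1)
    return pd.DataFrame(snp_rows), pd.DataFrame(proxy_rows), truth


# ---------------------------------------------------------------------------
# triage training material
# ---------------------------------------------------------------------------

def make_triage_training_set(config: SimConfig, n_pos: int = 200,
                             n_neg: int = 200, seed=None):
    """Labelled windows for the candidate classifier.

    Positives: clean planted hairpins padded with background flanks to
    window size, kept when they pass the scan filters.  Negatives: hard
    negatives — filter-passing windows harvested from dinucleotide-shuffled
    background sequence (the synthetic analogue of a curated negative
    training set).
    """
    from .scanner import ScanConfig, scan_sequence

    rng = _rng(config.seed if seed is None else seed)
    scan_cfg = ScanConfig()
    pos = []
    while len(pos) < n_pos:
        stem = int(rng.integers(config.stem_len_range[0],
                                config.stem_len_range[1] + 1))
        loop = int(rng.integers(config.loop_len_range[0],
                                config.loop_len_range[1] + 1))
        hp, _ = plant_hairpin(stem, loop, 0, seed=rng)
        w_len = int(rng.integers(max(scan_cfg.min_len, len(hp)),
                                 scan_cfg.max_len + 1))
        pad = w_len - len(hp)
        off = int(rng.integers(0, pad + 1))
        win = (random_background(off, config.background_gc, rng) + hp
               + random_background(pad - off, config.background_gc, rng))
        hits = scan_sequence(
            HaplotypeSequence("train", win),
            ScanConfig(min_len=w_len, max_len=w_len, both_strands=False),
        )
        pos.extend(hits[:1])

    neg = []
    while len(neg) < n_neg:
        bg = random_background(1200, config.background_gc, rng)
        bg = dinucleotide_shuffle(bg, rng)
        hits = scan_sequence(HaplotypeSequence("bg", bg), scan_cfg)
        order = rng.permutation(len(hits))
        neg.extend([hits[i] for i in order[: n_neg - len(neg)]])
    return pos, neg


def write_truth_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
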