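# mirhap

Haplotype-aware discovery of putative pre-miRNA hairpin loci, with the
downstream analyses that turn a locus atlas into biological claims:
cross-haplotype conservation, homology to annotated miRNAs, functional
evidence (Ago CLIP read support, Dicer-silencing qPCR), and intersection
with disease-SNP linkage-disequilibrium blocks.

## Who this is for

Researchers studying non-coding RNA in highly polymorphic regions such as
the MHC, where mature miRNAs transcribed from one haplotype may be absent
or sequence-divergent on another.  Reference-based discovery from RNA-seq
only finds miRNAs expressed in the assayed tissue; `mirhap` instead scans
the haplotype *sequence* exhaustively for every locus with the propensity
to form a stable pre-miRNA hairpin, then evaluates conservation and
disease context per haplotype.

## The method

**Scan (the discovery funnel).**  Every window of 58–110 nt (1 bp stride,
both strands, reported 5'→3') is folded to its minimum-free-energy (MFE)
secondary structure.  A window survives when

1. `MFE < −20 kcal/mol` (58/110 nt and −20 kcal/mol are the 5th/95th
   percentiles of annotated human pre-miRNA length and MFE distributions),
2. its structure is a *linear hairpin*: exactly one hairpin loop, no
   multiloop, no bulge loop (internal loops permitted; configurable),
3. a trainable hairpin classifier (the triage stage, standing in for a
   boosting classifier, trained on labelled hairpin windows) scores it
   above threshold.

Surviving windows are stripped of exon overlaps and merged into an atlas
of candidate pre-miRNA loci (BED + TSV).

Folding uses a self-contained Zuker-style nearest-neighbour dynamic
program over an explicit, swappable energy table (`EnergyParams`), exact
by construction: the reported MFE equals the minimum over all nested
structures under the same table (verified against exhaustive enumeration).
Because the pairing matrices depend only on the subsequence, one banded
table fill per strand serves *every* window, which makes stride-1 scans of
kilobase haplotypes take seconds.  An adapter for the external `RNAfold`
executable is provided for reproducing published MFE values.

**Downstream.**

* *Conservation*: a sequence is conserved in a haplotype iff it occurs
  with 100% identity over its full length on either strand (exact
  substring search — equivalent to BLAST filtered to perfect full-length
  hits).  Locus-level conservation uses the containment rule: the shorter
  sequence must occur exactly within the longer.
* *Homology*: semi-global (free terminal gaps) Needleman–Wunsch of each
  novel mature miRNA against an annotated catalog (+5/−4, gap 8); all
  maximal-score matches are reported, ties included.
* *Ago support*: reads containing the exact, ungapped mature sequence are
  counted per CLIP-seq dataset; ≥ 500 reads in total ⇒ supported.
* *Dicer dependence*: ΔCt = Ct(target) − Ct(β-actin) per sample; pooled
  two-sample t-test between silencing and control; dependent iff p ≤ 0.05
  and expression falls on silencing.
* *Disease LD*: the LD block of a disease SNP spans the SNP and all
  proxies with r² ≥ 0.9; loci overlapping a block by ≥ 1 bp are in LD;
  mature miRNAs containing a SNP with MAF ≥ 0.01 (or 0.05) are flagged as
  polymorphic.

A seeded synthetic-data module generates every input with planted ground
truth (hairpins in unstructured background, a divergent haplotype pair
with a protected conserved fraction, CLIP-like reads, two-replicate qPCR
tables, SNP/LD catalogs), so the whole pipeline is testable end to end
without downloads.

## Worked example

```bash
mirhap sim haplotypes --seed 1 --out-dir demo       # 2 kb pair, 5 planted hairpins
mirhap triage train --seed 1 --out demo/model.joblib
mirhap scan --fasta demo/hapA.fasta --triage-model demo/model.joblib --out-dir demo/scan
```

prints

```
trained model (cv accuracy 1.000) -> demo/model.joblib
windows 203202 -> prescreen 203202 -> MFE 64377 -> topology 23861 -> kept 10149 -> loci 5
```

Of the 203,202 windows enumerated on both strands, 64,377 fold below
−20 kcal/mol and 23,861 of those are clean linear hairpins.  The MFE and
topology filters alone are not specific — random sequence folds below
−20 kcal/mol far too often, so without triage those windows merge into
2 near-continuous spans.  The classifier keeps 10,149 windows, which merge
into exactly 5 disjoint loci, one per planted hairpin (`demo/scan/
atlas.tsv`, compare `demo/truth.bed`):

```
name    chrom  start  end   n_windows  best_mfe
locus0  hapA   228    372   2812       -56.2
locus1  hapA   583    729   2988       -56.5
locus2  hapA   944    1070  2039       -53.7
locus3  hapA   1291   1385  335        -39.3
locus4  hapA   1618   1757  1975       -60.5
```

The same gated funnel drives a dinucleotide-shuffled copy of the sequence
to an *empty* atlas.  The full configured pipeline (scan + triage + exon
exclusion + merge, with a manifest of per-stage counts) runs as
`mirhap run --config cfg.yaml --out-dir out`.

## Layout

```
src/mirhap/
  core_io.py        FASTA/BED/GFF readers, intervals, reverse complement
  folding/          energy model, reference DP engine, RNAfold adapter,
                    dot-bracket topology, standalone re-scoring
  scanner.py        window enumeration, prescreen, filters, atlas
  triage.py         feature extraction + trainable candidate classifier
  conservation.py   exact-match presence/conservation
  homology.py       semi-global alignment vs catalog
  evidence.py       Ago CLIP counting, Dicer ΔCt t-tests
  disease_ld.py     LD blocks, intersection, MAF overlap
  simulate.py       seeded generators with planted truth
  pipeline.py/cli.py  orchestration, config, manifest, CLI
```

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
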