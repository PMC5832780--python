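# Methods

## The discovery model

The scan treats pre-miRNA discovery as a sequence-propensity problem:
every genomic window of pre-miRNA size is asked whether it could fold into
a stable, canonical hairpin.  The assumptions are (i) a pre-miRNA is
58–110 nt (5th–95th percentiles of annotated human precursors), (ii) its
fold is thermodynamically stable, MFE below −20 kcal/mol (5th percentile
of annotated precursor MFE), and (iii) its shape is a single stem-loop —
"linear hairpin" — rather than a branched structure.  Both strands are
scanned because a hairpin on one strand folds differently from its
reverse complement; windows are emitted 5'→3' on their strand.

### Folding engine

The reference engine is a Zuker-style energy-minimisation DP over the
loop-decomposition model: structure energy = Σ over closing pairs of the
loop each pair closes (stack / hairpin / bulge / internal / multiloop).
Parameters (`mirhap.folding.params`):

| component | default | units |
|---|---|---|
| stacking table | published nearest-neighbour values, −3.4 … +1.3 | kcal/mol |
| hairpin initiation | 5.4–6.4 by loop size (≥ 3), Jacobson–Stockmayer extrapolated | kcal/mol |
| bulge initiation | 2.8–4.4 by size | kcal/mol |
| internal-loop initiation | 1.5–2.0 by total unpaired | kcal/mol |
| multiloop | a=3.4, b=0.4/branch, c=0.0/unpaired | kcal/mol |
| allowed pairs | AU, UA, GC, CG, GU, UG; N never pairs | — |
| interior-loop cap | 30 unpaired total | nt |

Energies are integers in 0.1 kcal/mol internally, so the DP is exact, and
the reported MFE equals the minimum over all nested structures (min loop
3) under the same table — verified against exhaustive enumeration at
n ≤ 14.  Simplifications relative to full Turner rules: no dangles,
terminal-AU penalties, special tetraloops, or internal-loop asymmetry
terms.  The engine therefore makes no claim of matching any external
folder's energies; an `RNAfold` adapter (tool defaults, 37 °C — the tool
does not document a temperature in its output, so defaults are assumed)
is provided for reproducing published numbers.

Tie-breaking: the DP minimises the lexicographic objective (energy,
−pair count); remaining ties resolve through a fixed traceback case
order (hairpin, interior loops by increasing unpaired counts, multiloop
splits left-to-right; exterior prefers unpaired).  This yields a
deterministic structure for fixed sequence and parameters, which is what
regression tests need.  Lonely (isolated) pairs are permitted; a switch to
forbid them is not implemented (it would require doubled DP tables for a
cosmetic restriction).

The banded tables V/M/M1 depend only on the subsequence [i..j], so the
scanner fills them once per strand (span ≤ 110) and prices all window
lengths at each start with one exterior pass — a stride-1 scan of a 2 kb
haplotype costs ~10 s on one CPU, and memory is linear in sequence length
times the span cap.

### Filters and their semantics

* MFE boundary: strictly `mfe < −20` (windows at ≥ −20 are removed; the
  comparator is configurable).  A hairpin window constructed to fold at
  exactly −19.1 kcal/mol is excluded — the documented behaviour for one
  annotated MHC precursor whose energy sits just above the cutoff.
* Topology: default rejects bulge loops and multiloops and requires
  exactly one hairpin loop; internal (two-sided) loops are permitted, as
  only bulges and multi-stem structures are named by the filter this
  reproduces.  `--reject-internal-loops` tightens this.
* Prescreen: a maximum-pairing (Nussinov) bound converts the MFE cutoff
  into a minimum possible pair count (every loop energy ≥ the strongest
  stack −3.4; any paired structure carries one hairpin initiation ≥ +5.4;
  hence E < −20 requires ≥ 9 pairs).  Windows under the bound can never
  pass and are never folded.  The screen is provably conservative, so
  disabling it cannot change the atlas.
* Exon exclusion removes entries sharing ≥ 1 base with an exon,
  strand-blind, before merging.
* Merging is strand-blind (the atlas answers "which genomic spans can
  encode a hairpin", and overlapping entries are collapsed without strand
  qualification); `--stranded` interval merging exists in the library.

### Triage (the classifier stage)

MFE + topology alone are not specific: measured on dinucleotide-shuffled
background, ~10% of windows fold below −20 kcal/mol into internal-loop-
laden single hairpins (this holds under the external folder as well, at a
lower but still substantial rate — see the scan example in the README).
The funnel therefore ends in a trainable classifier before merging, as in
the boosting-classifier stage it stands in for.  Features (documented
order in `triage.FEATURE_NAMES`): length, GC, mfe, mfe/nt, pair count,
pairing fraction, longest helix, terminal-loop size, arm asymmetry, and
16 dinucleotide frequencies.  The default model is gradient boosting
(`random_state` = seed, fully reproducible); threshold 0.5 (the stage it
replaces publishes no threshold; 0.5 is the natural probability cut and is
config-exposed).  Training data for synthetic studies: positives are
clean planted hairpins padded into windows and passed through the same
filters; negatives are *hard* negatives — filter-passing windows harvested
from shuffled background.  On this separable-by-construction set the
cross-validated accuracy is ≈ 1, and the trained gate empties the
shuffled background while keeping every planted locus.  An adapter seam
(`export_candidates`/`import_scores`) lets an external classifier replace
the built-in model for full-scale reproductions.

## Downstream analyses

Conservation is exact matching (100% identity over the full query, either
strand); locus-level conservation uses the shorter-in-longer containment
rule.  Absence may reflect incomplete haplotype assemblies; no
completeness correction is attempted.  Semi-global alignment uses
+5/−4/gap 8 (linear); the algorithm is fixed but its published parameters
are not, so all three are config-exposed; U ≡ T in scoring.  Ago support
counts sense-strand exact substrings; the "≥ 500 reads within all
datasets" rule is ambiguous between summing across datasets and requiring
the count in each, so the sum is the default and `--per-dataset`
implements the strict reading.  The Dicer test is a two-sided pooled
t-test on β-actin-normalised ΔCt with df = 2 at the two-replicate design;
"dependent" additionally requires the effect direction (expression down
on silencing).  With a 3-cycle planted effect and 0.1-cycle noise the
test's power exceeds 95%, and at zero effect the flag rate is ~2.5%
(half the nominal 5% two-sided rate, because of the direction
requirement).  LD blocks take the filter-then-extent rule (r² ≥ 0.9,
inclusive); phenotype uniqueness is by case-folded, whitespace-normalised
label; a SNP lies "within" a mature miRNA when its position is in
[start, end).

## Synthetic data: what it emulates and what it does not

Backgrounds are i.i.d. nucleotides at GC 0.41 (MHC-like); planted
hairpins are perfect stems (18–25 bp, loop 5–9 from {A,C} so the loop
cannot pair) whose summed stack energy is forced below −30 kcal/mol, so
every clean construct clears the cutoff by construction.  Haplotype B
derives from A by seeded substitutions (2%) and background-only indels
(0.1%); a configurable fraction (default 0.5) of hairpin loci is copied
verbatim and every unprotected locus receives ≥ 1 substitution, making
locus-level conservation truth exact.  CLIP reads embed mature sequences
exactly inside random flanks; decoys are verified planted-sequence-free.
qPCR tables follow the 2-replicate silencing/control design with a
+3-cycle effect on dependent targets.  Half of the disease SNPs are
anchored near planted miRNAs so r² ≥ 0.9 blocks overlap them.

Passing tests on these fixtures demonstrates the *semantics* of every
stage (recovery of planted truth, exactness of filters and counts), not
performance on real genomic sequence: real MHC haplotypes contain
repeats, gene structure, and base composition heterogeneity that i.i.d.
background does not model, and real pre-miRNAs contain bulges and
internal loops that clean planted stems do not.  Full-scale reproduction
of published MHC locus counts additionally requires the original
multi-megabase haplotype sequences, annotation releases, and the original
boosting classifier's decision boundary, none of which ship here.

## Numerical / design choices

* Coordinates are 0-based half-open everywhere; assembly labels are
  opaque metadata (upstream sources mix assembly statements, which the
  artifact does not resolve).
* DNA-side storage uses T; RNA-facing display uses U; queries given as
  RNA are normalised on input.
* The window band is 58 ≤ length ≤ 110 (the printed "58 ≤ Length ≥ 110"
  is a typo for the closed interval).
* Degenerate inputs: N folds as unpairable; identical qPCR conditions
  give p = 1 (never "dependent"); an LD index with no qualifying proxy
  yields a 1-bp block; empty inputs yield empty outputs rather than
  errors wherever a downstream stage can proceed.
* Determinism: every stochastic component takes a seed; identical
  seed + config reproduce byte-identical outputs (atlas files, FASTQ,
  tables).  Thread count never affects results.

## Problem sizes used in the shipped checks

Folding exactness at n ≤ 14 over 50 sequences (exhaustive enumeration is
feasible there); topology agreement on 200 random structures; the planted
scan fixture is 2,000 bp with 5 hairpins (≈ 203k windows, both strands);
conservation uses 20 hairpins on an 8,000 bp pair; Dicer calibration uses
1,000 null and 200 alternative simulations.  These sizes were chosen so
the whole verification suite runs in minutes on a laptop while every
check remains exhaustive or planted-truth-exact at its scale.
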