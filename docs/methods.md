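# Methods

This note documents the models, conventions and numerical choices behind
`luxrbgc`, and what its synthetic benchmark does and does not demonstrate.

## The screen

A cluster record is a *hit* when at least one of its proteins carries
qualifying matches to both Pfam domains that define LuxR-family
quorum-sensing regulators: PF00196 (helix-turn-helix DNA-binding) and
PF03472 (autoinducer/signal-binding). Both domains must sit on the **same
protein**; a cluster whose DNA-binding and signal-binding domains occur on
two different genes does not qualify. This is the stricter of the two
possible readings of "genes encoding both domains" and matches how a
single-protein regulator is actually built.

A *qualifying* domain hit has conditional E-value ≤ `evalue_max` (default
10⁻⁵) and model coverage ≥ `coverage_min` (default 0.35, i.e. the aligned
model span covers at least 35% of the HMM). These two thresholds are this
package's assumptions — the original hmmsearch cutoffs behind the screen
are not published — so they are configurable, echoed into every run
manifest under `assumptions`, and chosen to be permissive for full-length
domains while rejecting fragments.

**luxI-only exclusion.** Cluster predictors treat the AHL synthase (LuxI,
PF00765) itself as a biosynthetic gene, so a lone *luxR–luxI* pair gets
called a "cluster" with no pathway to regulate. A hit is therefore removed
when the set of its biosynthetic-role genes is exactly its (non-empty) set
of LuxI genes. Gene roles come from antiSMASH-style `gene_kind` qualifiers
(`biosynthetic`, `biosynthetic-additional` → biosynthetic; absent →
unknown); the filter never fires on a record with any other
biosynthetic-role gene, and unknown-role genes never count as biosynthetic.

## Dereplication

Redundant hits (the same regulator sequenced in many strains) are collapsed
by greedy incremental clustering of the LuxR protein sequences, CD-HIT
style: sequences are processed in order of decreasing length (ties broken
lexicographically by id); each joins the first existing cluster whose
*representative* it matches at identity ≥ `identity_cutoff` (0.9), else it
founds a new cluster. The representative is therefore always the longest
member, and the representative's BGC is the one retained for downstream
stages.

Identity is **identical aligned residue pairs / length of the shorter
sequence** (CD-HIT's denominator), computed from an exact global alignment:
BLOSUM62, gap open 10, gap extend 0.5 (Biopython's `PairwiseAligner`). No
k-mer pre-filter is used — exact DP identity is the reference behavior, and
at the scales this package targets (up to a few hundred sequences of
~250 aa) the quadratic cost is irrelevant. "Mutual identity ≥ 0.9" with the
shorter-sequence denominator is an interpretation; with substitution-only
variation (as in the synthetic benchmark) every common convention
coincides.

## Classification

Proportions (cluster type, habitat, taxonomic class, LuxI co-occurrence)
are computed over the dereplicated representative list. Raw fractions are
always retained; display rounding follows mixed precision — one decimal at
≥ 1%, two decimals below 1% (so 1/2,000 prints as 0.05%). Per-type
association frequency is `100 · hits(type)/total(type)` over the *input*
population; types absent from the input are omitted. Hybrid records
annotated with both NRPS and PKS products are binned `NRPS-PKS`; an
`AHL-` presentation prefix can be derived from `has_luxi` but is not a
distinct type. Habitat is consumed as curated metadata, never inferred
from sequence.

**Diagnostic-residue subfamily call.** Two alignment columns of the
signal-binding domain separate plant-responsive regulators (M at the first,
W at the second) from canonical AHL responders. Because the literature
marks these positions on an alignment figure rather than by residue
number, the package anchors them as columns of its reference panel. A
query is globally aligned to its highest-scoring ingroup reference, the
query residues mapped to the two reference columns are read off, and the
rule is: W at the second column → `plant_responsive_like` (M at the first
strengthens the call but is not required — one characterized
plant-responsive regulator lacks the M); both residues equal to the AHL
references' consensus → `AHL_type`; anything else, including gaps at both
columns, → `atypical`.

**Reference panel.** The package cannot bundle the real reference proteins,
so `references.py` *generates* a synthetic panel (clearly labelled as such)
reproducing the structural facts the classifier and the tree need: 12
AHL-type and 2 plant-responsive references on a shared scaffold that align
gaplessly, the diagnostic residues pinned per subfamily, and a GerE-like
outgroup far more divergent (~35% identity) than any ingroup pair. The
panel is a package constant (fixed internal seed), not part of a dataset's
randomness. Substituting a real reference alignment is supported wherever a
`ReferencePanel` or aligned FASTA is accepted.

## GC anomaly

`gc_content` is (G+C)/(A+C+G+T) with N excluded from numerator and
denominator (an all-N stretch is NaN, never an error). Windows are
half-open `[i, i+window)` at stride `step` (defaults 500/250 bp — the
windowing is an artifact choice, no published value exists); a trailing
partial window is kept only when *longer* than half a window, so an
exactly-half tail (already covered at step = window/2) is not
double-counted.

The anomaly statistic treats background window GCs as i.i.d.:
`z = (x̄_region − μ̂_genome)/(σ̂_genome/√n_region)` with a two-sided normal
p-value, flagged at `alpha` (0.05). The published observation asserts
significance without naming a test; this z-test is the package's own,
clearly labelled choice. Two calibration caveats are deliberate design
points: (i) overlapping windows are positively correlated and would make
the test anticonservative, so the pipeline computes the statistic on
non-overlapping windows even when the displayed track overlaps; (ii) when
only a scalar genome GC is known, background windows are modelled as
binomial — mean `gc`, sd `√(gc(1−gc)/window)` — via a deterministic
quantile sample. A zero-variance background is degenerate and reported as
such rather than tested. Under the null (region and background drawn from
the same composition) the measured type-I error sits within Monte-Carlo
error of alpha (the acceptance suite verifies this with 1,000 simulations;
with ~100 background windows the normal approximation to the implicit
t-statistic costs well under a percentage point).

## Phylogeny

The tree path is the classic distance workflow:

- **Alignment.** The built-in progressive aligner exists so the pipeline
  has no external aligner dependency: fractional common 3-mer distances →
  UPGMA guide tree (scipy) → profile-profile global alignment (Gotoh
  affine DP; column score = frequency-weighted mean BLOSUM62 pair score,
  gap pairs scoring zero; gap open 10 / extend 0.5; two sequences reduce
  to the exact pairwise alignment). It is deliberately simple — no
  iterative refinement — and externally computed alignments (e.g. MUSCLE)
  are accepted as aligned FASTA anywhere an MSA is. Reproducing any
  specific aligner's output bit-exactly is a non-goal.
- **Complete deletion.** Every column containing a gap or X in *any* row
  is removed before distances; removing all columns is an error, not a
  silent empty matrix.
- **p-distance.** Fraction of differing positions per pair.
- **Neighbor joining.** Saitou–Nei: `Q(i,j) = (n−2)d(i,j) − r_i − r_j`,
  minimal pair joined first with ties broken by the smallest index pair
  (deterministic); limb lengths by the standard formulas; a negative limb
  is clamped to zero with the deficit moved to its sister (MEGA-like), so
  written branch lengths are never negative while the joined pair's summed
  limb length is preserved. On additive matrices no clamping occurs and
  the generating tree is recovered exactly (fuzz-tested, 4–12 leaves).
- **Bootstrap.** Columns resampled with replacement to the original
  length; p-distance + NJ per replicate; support = percent of replicates
  containing each original-tree bipartition (bipartitions keyed as
  leaf-name sets, canonicalized against the lexicographically smallest
  leaf). Seeded and reproducible. Supports below `support_display_min`
  (50%) are *retained in the data* and suppressed only at rendering.
  Note that when distances tie exactly, the index tie-break makes
  replicate topologies depend on taxon input order — inherent to NJ
  tie-breaking, and visible only for weakly supported splits.
- **Rooting.** The root is placed at the midpoint of the outgroup's
  pendant edge; ingroup bipartitions and all leaf-to-leaf path lengths are
  unchanged (tested). The outgroup is a GerE-like regulator: DNA-binding
  domain present, signal-binding domain absent.

Newick output carries branch lengths to 6 decimals and integer bootstrap
percentages as internal-node labels.

## The synthetic benchmark

`synthetic.generate_dataset` produces records + hit table + ground truth
with one RNG stream per record (spawned from the dataset seed, so output
is order-independent and byte-reproducible).

What it emulates, and the defaults (the benchmark's fixed study
conditions):

- **K = 3 LuxR families of (4, 3, 2) members.** Family founders are
  independent mutants of a common root at identity `1 − (1−b)/2` each
  (`b = 0.70` between-family target); members substitute
  `round(L(1−w)/2)` positions from disjoint per-member position sets
  (`w = 0.95` within-family target, L = 250), so within-family pairwise
  identities are exactly `1 − 2d/L ≈ 0.952` — above the 0.9 cutoff with
  zero sampling noise — and between-family identities fall near 0.66,
  safely below it. Substitution-only mutation trades indel realism for
  exact identity control.
- **2 luxI-only decoys** (a LuxR regulator whose record's only
  biosynthetic-role gene is the synthase — the cases the exclusion filter
  must remove), **5 negatives** (no LuxR; one negative carries a lone
  PF00196 hit to exercise the dual-domain rule), and a **47% LuxI
  fraction** among true positives, matching the co-occurrence rate the
  screen reports at full scale.
- **Type/habitat/class mixtures** patterned on the published composition
  (NRPS 26%, PKS 10%, NRPS-PKS 11%, long tail; plant-associated >
  environmental > human-associated > other; Gamma 41% / Alpha 31% /
  Beta 26% / Delta 2%).
- **Region GC 0.60 vs genome GC 0.67** — a detectable anomaly, emulating
  the horizontally acquired look of several real LuxR-linked clusters.
  Regions are ≥ 10 kb of i.i.d. bases at the target composition.
- **Domain evidence as hit-table rows** (E-values drawn ≤ 10⁻⁸, coverage
  0.8–1.0), not as sequence motifs: detection in the real screen is
  hmmsearch-annotation-driven, and the generator mirrors that contract.

What it does **not** emulate — and hence what passing tests do not show
about real data: indels and alignment ambiguity in the LuxR families
(identities are exact by construction, so the 0.9 cutoff is never
borderline); realistic domain-score distributions near the thresholds;
codon structure, operons or compositional autocorrelation in region
sequences (GC windows are i.i.d., making the anomaly z-test better
calibrated here than on real genomes); curation noise in habitat/taxonomy
metadata; and paralogy (each record carries at most one LuxR gene).
Full-scale survey figures (219,499 clusters screened, 2,081 hits, 137
representatives) depend on a specific historical sequence corpus and are
treated as reference arithmetic, not as desk-reproducible targets.

## Determinism

All randomness flows from explicit seeds (`numpy.random.default_rng` /
`SeedSequence.spawn`). A pipeline run writes no timestamps into artifacts,
so identical config + seed reproduce every artifact byte-for-byte (the
run manifest records config, input digests, the stage-count funnel and the
seed; wall-clock information goes to the log stream only).

## Problem sizes in the shipped checks

The test and acceptance suites run the screen and dereplication on the
default 16-record dataset (plus a 500-hit dataset for distributional
checks and K ∈ {2, 5, 10} family sweeps), NJ fuzzing on 100 random 4–12
leaf trees, bootstrap demonstrations at 25–1,000 replicates on 8–18 taxa,
and 1,000 null simulations for the GC test — sizes chosen so the full
suite documents every claim while staying interactive-fast.
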