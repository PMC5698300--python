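# Methods

`lbdkit` characterizes a plant LBD (LATERAL ORGAN BOUNDARIES domain)
transcription-factor gene family end to end: domain grammar and class
calls, catalog statistics and duplication structure, distance phylogeny
with bootstrap-gated subclass assignment, cross-species orthology with
Ka/Ks, promoter cis-element enrichment, and expression/co-expression
analysis. Every stage has a seeded synthetic generator that plants a known
signal, so the whole pipeline is testable without external data. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not show.

## Domain grammar and classification

The LOB domain is modelled as three ordered blocks:

* **C-block** (zinc-finger-like): `C X2 C X6 C X3 C`. Four invariant
  cysteines with fixed spacing; the scanner reports every (possibly
  overlapping) 15-residue frame. `X` in a sequence never matches a
  cysteine anchor.
* **GAS block**: anchor 1 `F X2 [VA] H`, then downstream anchor 2
  `D P [VI] Y G`. In the family the F/H of anchor 1 and the P/G of
  anchor 2 are invariant; *relaxed* mode (`gas_strict=False`) requires
  only those four residues and reports per-anchor strictness.
* **Leucine-zipper-like motif**: `[LVI] X6 [LVI] X3 [LVI] X6 [LVI]`.
  The anchor alphabet is the hydrophobic trio L/V/I, not leucine alone —
  documented family members carry V or I at anchor positions, and a
  strict-L grammar (available via `zipper_alphabet="L"`) would
  misclassify them. The printed four-anchor pattern is the default;
  anchor count follows `zipper_spacings` and is configurable.

**Class call**: Class I = C-block plus a *complete* zipper downstream
within the gap limits; Class II = C-block with a broken zipper (≥ 2 but
not all anchors hydrophobic, or no frame at all); no C-block = not a
family member. The earliest C-block that admits a complete downstream
match anchors the annotation. Two deliberate choices:

* When a partial zipper frame precedes a complete one, the complete frame
  wins (`prefer_complete=True`); otherwise a leading broken frame would
  shadow a genuine Class-I signature.
* A partial frame must start on a hydrophobic residue, so that broken
  frames are anchored rather than free-floating over arbitrary residues.

Gap limits default to 120 residues (C-block → GAS) and 80 (GAS →
zipper). No published bound exists; these comfortably contain the
family's alignment layout and are exposed in `MotifGrammar`.

Conserved-block finding in alignments uses per-column majority-residue
fraction with gaps counted in the denominator (stricter, deterministic);
blocks are maximal runs of ≥ 10 columns at ≥ 50% conservation, both
configurable.

## Catalog statistics

The bundled locus table (`data/table1_vvilbd.tsv`) transcribes the
published 50-gene grapevine catalog verbatim. **Locus length is
`end − start`**, not the 1-based-inclusive `end − start + 1`: the
published locus sizes (603 nt for LBDId4 at 1022072–1022675; 6437 nt for
LBDIf3) follow the former convention, and the package reproduces it
exactly. Note two source-data quirks carried over verbatim rather than
silently corrected: LBDIf10 spans 10,904 bp, exceeding the stated 6,437 bp
family maximum, and chromosome 11 carries LBDIi8 although the source
prose lists chr11 among gene-free chromosomes.

Tandem arrays are maximal same-chromosome, same-(class, subclass) runs
whose consecutive start-to-start gaps are ≤ `max_gap` (default 100 kb,
inclusive) with ≥ `min_size` members (default 2). "Tandem" has no
canonical gap; 100 kb encloses the chromosome-13 subclass-If cluster
(11 genes over 225 kb with individual gaps ≤ 31 kb) while excluding
cross-arm pairs. Exon summaries come from GFF3 via gffutils: exon count
from the first mRNA, non-coding = no CDS overlap. "Nonsense" exons are
an input annotation flag (`nonsense=true`), not computed — no coordinate
rule can decide them.

## Phylogeny and subclass assignment

Distances are p-distances with pairwise deletion of gap sites, optionally
Poisson-corrected (`d = −ln(1 − p)`); saturation (p = 1) is an error.
Columns with < 95% site coverage are removed first. The tree estimator is
neighbor joining (Saitou–Nei) written in-repo so tie-breaking is fully
deterministic: equal Q minima resolve toward the lexicographically
smallest pair of subtree labels. On additive matrices NJ recovers the
generating topology and branch lengths exactly (tested, including
against scikit-bio's independent NJ). Full maximum-likelihood search is
intentionally out of scope — NJ is the classical seed for such searches,
and an external ML tree in Newick (supports as internal labels) can be
ingested via `SupportTree.from_newick`.

Bootstrap: columns resampled with replacement, NJ rebuilt per replicate
(default 100), support = percent of replicates containing each internal
bipartition *of the full-data tree* (not a majority-rule consensus —
this matches how per-clade support values are read off a single tree).
Edges below the collapse threshold (default 30%) contract to polytomies,
but pre-collapse supports remain in `SupportTree.supports` so low
supports stay reportable after collapsing.

Subclass assignment: a query is assigned subclass *s* iff it lies in a
clade with support ≥ 70 containing ≥ 1 reference gene of *s* and none of
any other subclass; the smallest such clade decides. Clades are the two
sides of internal edges only — the complement of a single leaf is
maximally uninformative and would otherwise hijack assignments. A clean
clade below threshold yields `motif_needed` (phylogeny must be
complemented by motif evidence; the two evidence streams are never
silently merged); only mixed-reference neighbourhoods yield
`unassigned`. Raising the threshold never gains assignments.

## Orthology and Ka/Ks

Similarity search: best local alignment per ordered pair
(BLOSUM62, gap open −11 / extend −1, Biopython's PairwiseAligner) with
Karlin–Altschul e-values `E = K·m·n·exp(−λS)` at fixed gapped-BLOSUM62
parameters λ = 0.267, K = 0.041. Parity with any specific BLAST release
is a non-goal; the behaviour of the retention filter at its thresholds
is the contract. Retention is strict as printed: e-value **<** 1e-20 and
identity **>** 40% (identity = identical residues over aligned columns;
"similarity" readings are not implemented). An e-value prefilter skips
alignment traceback for pairs that could never pass retention.

Reciprocal best hits: (A, B) is a pair iff B is A's best retained hit
and A is B's. Score ties break by higher identity, then lexicographic
subject id, and are logged. The presence matrix then categorizes each
gene × species cell: `one_to_one` requires the RBH *and* a unique
retained homolog in that species — a duplicated counterpart is a
one-to-many relationship and scores `homolog_only`, as does any retained
homology without an accepted pair; no retained hit at all is
`no_match`. This uniqueness condition is the package's reading of
"one-to-one": a reciprocal best pair drawn from two interchangeable
duplicates does not identify the ortholog.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions with
changes to stop codons excluded from each position's denominator (so
S + N = 3 per codon exactly), substitution counts averaged over all
stop-free mutation pathways between codon pairs (all orderings
enumerated; if every pathway crosses a stop, all orderings are used with
stop steps counted nonsynonymous), and Jukes–Cantor correction
`d = −3/4 ln(1 − 4p/3)`. Proportions ≥ 3/4 are saturated and raise
rather than returning a number. Trailing stop codons are trimmed;
internal stops are errors. The ratio is undefined (None) at Ks = 0.

## Promoters and enrichment

Promoters are the `window` bp upstream of the translation start on the
coding strand (minus-strand genes: reverse complement of the downstream
flank); window presets `plantcare` (1.5 kb), `plantpan` (3 kb) and
`homer` (2.5 kb) mirror the common database analyses, all ATG-anchored.
With `noorf` the window truncates at the nearest upstream annotated gene
boundary; contig edges shorten silently but are flagged. Internally
coordinates are 0-based half-open; reported scan offsets are promoter-
local and convertible to ATG-relative positions (−1 = first bp
upstream).

IUPAC scanning matches every position on both strands (minus-strand hits
reported at plus-strand coordinates, overlaps included). Enrichment is
per-promoter presence/absence — robust to promoter-length differences —
scored with the one-sided hypergeometric upper tail of target presence
within targets ∪ background. Raw p < 0.01 flags enrichment by default,
as such promoter scans are conventionally reported; Benjamini–Hochberg
is available (`correction="bh"`). A count-based test is deliberately not
the default. De-novo discovery is an exhaustive k-mer scan (k = 6..12):
every observed k-mer's presence counts and hypergeometric p, reverse-
complement pairs merged under the lexicographically smaller
representative, ranked ascending by p. The bundled ~40-entry motif
dictionary carries IUPAC patterns from the public PLACE/PlantCARE
literature; it is data, user-replaceable, and pattern correctness is not
a tested contract.

## Expression analysis

Input is a genes × samples matrix of RMA-scale log2 intensities with
per-sample tissue metadata. Tissue assignment: a gene is called in a
tissue when its **mean** over that tissue's replicates is ≥ log2(256) = 8
(inclusive; the atlas convention averages 3–4 replicates, and `max` is
available where a single-replicate spike should count). Relative
expression is row-mean centering (idempotent). Co-expression uses
d = 1 − PCC with average linkage; the tree is cut so merged groups sit
at linkage distance strictly **below** 0.2 (i.e. PCC > 0.8 —
the "distance lower than 0.2" reading; a PCC-threshold-0.2 reading would
be d < 0.8 and is treated as shorthand for the same cut). Zero-variance
rows are excluded with a warning (PCC undefined), genes are sorted by
label before clustering for deterministic ties, and singletons are
dropped. Condition contrasts are descriptive per-gene log2 mean
differences only — no moderated tests, by design.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of `SimConfig` (seed included):
identical configs give byte-identical outputs, via per-generator
substreams of one seeded PCG64 generator.

* **Proteome** — background residues uniform over the 20 amino acids
  (simplest null, conservative for pattern scanning). Class I/II built
  from the grammar directly; Class II breaks 1–2 zipper anchors keeping
  the first anchor and ≥ 2 anchors intact. Decoys are rejection-sampled
  until they contain none of the three blocks; class constructs are
  validated against the classifier at build time (this is what makes the
  zero-mutation closed loop exact).
* **Gene models** — planted tandem arrays with per-array gap bounds at
  chromosome heads; background genes get unique subclasses per
  chromosome and ≥ 300 kb spacing, so planted arrays are exactly the
  detectable ones. Exon structures (1–3 exons, 30% chance of a
  non-coding first exon) are emitted as GFF3 with recorded truth.
  Packing that exceeds the chromosome length is an error.
* **Ortholog families** — i.i.d. point substitutions at
  `mutation_rate = 0.05` per site, no indels (keeps identity
  unambiguous for RBH tests). Losses (`loss_prob`) produce true
  no-match; duplications (`dup_prob`, loss takes precedence) produce
  two diverged copies, true homolog-only. Family size 20, 3 species by
  default — the closed-loop study condition.
* **Promoters** — uniform random DNA with the motif planted per
  sequence at the configured per-set frequencies (default 20 + 20
  promoters of 500 bp). Chance occurrences of the motif elsewhere are
  possible and are part of the null.
* **Expression** — module genes follow `baseline + a(√r·z + √(1−r)·e)`
  with a shared per-sample latent `z`, so expected pairwise PCC equals
  `module_pcc` exactly (variance ratio solved from the target).
  Tissue-specific genes sit near log2 9.5 in their tissue and 5.0
  elsewhere. Default 12 tissues × 3 replicates.

What passing closed loops shows: the operations recover exactly the
signal they define, at the stated settings, under clean backgrounds.
What it does not show: robustness to real-data structure — indels and
rate heterogeneity in sequences, compositional bias in promoters,
probe-level microarray noise, batch effects, or correlated backgrounds
in expression. Those are out of scope by design.

## Problem sizes and determinism

The test and acceptance workloads use the study-condition sizes: 400
proteins for the classification loop; 10 seeds × 20 genes × 3 species
for orthology recovery; 200 replicate seeds for the enrichment null
(false-enrichment rate ≤ 3% at α = 0.01); 20 seeds × 2 modules for
co-expression recovery; 100 bootstrap replicates. All randomness flows
from explicit seeds; reruns are byte-identical.

## Known limitations

* No maximum-likelihood tree search, no rate heterogeneity, no model
  selection; midpoint rooting only for display.
* E-values are calibrated for the default scoring only; custom matrices
  would need their own Karlin–Altschul parameters.
* NG86 only (no codon-model ML Ka/Ks); standard genetic code only.
* No PWM scanning or Homer-style motif optimization; the k-mer scan is
  exhaustive, not heuristic, and carries no multiple-testing control by
  default.
* Cross-platform expression merging is metadata-only; no probe-to-gene
  re-mapping.
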