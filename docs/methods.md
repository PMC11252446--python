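# Methods

## Reporter scale and calling rules

Colony reporter readout is discretized to an ordinal scale 0 (none), 1
(weak), 2 (moderate), 3 (strong).  "No or only weak" means level ≤ 1 and
"moderate or strong" means level ≥ 2; this is the minimal scale on which the
pair-screen criteria can be stated exactly.  Each strain × bait test is a
quadruplicate of colonies.

**Quad consensus.**  A quad is *uniform* when its modal level occurs in ≥ 3
of 4 colonies; only then is a consensus level defined.  A 2–2 tie is treated
as non-uniform (no call rather than a guessed consensus).  For bookkeeping
the modal level is still recorded, with the higher level winning ties — it is
used only as a conservative background estimate, never as a consensus.

**Single-TF (eY1H) call.**  A colony *displays activity* iff its level is
≥ 1 **and** strictly exceeds the empty-control background consensus on the
same bait; an interaction is positive iff ≥ 3 of 4 colonies are active.
Requiring activity above background makes calls on autoactive baits
conservative instead of impossible.  A strain that failed mating is
*unscorable*, which is distinct from negative and excluded from denominators.

**TF-pair (pY1H) call.**  A pair × bait test is unscorable if any of the
three strains (pair, monomer 1, monomer 2) failed mating or lacks a uniform
quad, or if the empty–empty control itself shows moderate/strong signal (the
criteria compare signal *relative to* that control, so an autoactive bait
cannot be scored; this gate is consistent with the autoactivity pre-filter
below).  Otherwise, with L the consensus levels:

- cooperative iff L(pair) ≥ 2 and L(tf1) ≤ 1 and L(tf2) ≤ 1;
- antagonistic iff L(pair) ≤ 1 and max(L(tf1), L(tf2)) ≥ 2, the monomers
  with L ≥ 2 being the antagonized TFs;
- independent iff L(pair) ≥ 2 and max(L(tf1), L(tf2)) ≥ 2;
- none otherwise.

Cooperative and antagonistic are mutually exclusive by construction (the
pair level cannot be both ≥ 2 and ≤ 1); over the 64 possible consensus
triples exactly 8 are cooperative and 24 antagonistic.

**Ranking indices.**  `cooperativity = L(pair) − max(L(tf1), L(tf2))`,
`antagonism_1 = L(tf1) − L(pair)`, `antagonism_2 = L(tf2) − L(pair)`.  The
upstream plate-analysis software sorts candidate strains by such indices for
manual review but does not publish the formulas; these explicit difference
surrogates are declared here and are used **only** to order candidates in
reports — verdicts never depend on them.

**Multi-day imaging.**  Readout plates may be imaged on several days; an
interaction is counted once per (strain, bait) and the latest imaging day's
levels are used.  How multi-day signals should be combined is genuinely open;
"latest day" was chosen as the most inclusive single-plate rule and is a
declared convention, not an inference.

**Autoactivity filter.**  Baits eligible for the pair screen are those whose
empty-control consensus is strictly below moderate (level 2).  Baits without
a control are excluded with a warning.

## Network, evidence, degrees

One edge per distinct (TF, promoter) positive call; a detection by both the
single-TF screen and a pair-screen monomer strain collapses to a single edge
recording both assays.  Cooperative pair verdicts contribute heterodimer
edges (`"tf1|tf2"` binder ids).  Gene-level edges collapse the promoters of a
gene, so gene-degree ≤ promoter-degree always.

Coordinates are 0-based half-open everywhere (BED and narrowPeak are consumed
natively).  A ChIP peak supports an edge iff `floor((start+end)/2)` lies in
`[promoter.start, promoter.end)` — a center exactly at the end coordinate is
a non-hit.  Literature evidence is a curated (TF, gene) flag table; curation
itself is out of scope.  The four classes (ChIP-only, literature-only, both,
novel) partition the edges; classification is idempotent.

Promoters default to the 2 kb immediately upstream of the TSS (end = TSS on
the + strand, start = TSS on the − strand); deviating lengths warn rather
than fail, since real clone resources contain minor length variation.  The
genome build is irrelevant to the analysis: coordinates are treated as
abstract intervals.

Degree statistics (fraction of TFs with degree 1, hubs at degree ≥ 10, both
configurable) are reported on promoter-degree by default; prognosis scoring
uses gene-level targets because prognosis labels attach to genes.

**Power-law fit.**  The degree histogram is fit by least squares of
log10(count) on log10(degree) over nonzero bins, weighted by sqrt(count).
Under Poisson bin counts the variance of log10(count) is ≈ 1/count, so this
is inverse-variance weighting; it leaves exact power laws and flat histograms
untouched but stops the sparse tail (bins with expected count < 1) from
flattening the slope, which an unweighted fit does by several tenths at
realistic sample sizes.  Fewer than 3 nonzero bins → fit-not-possible.

## Prognosis score, permutation null, nomination

`score(TF) = (n_poor − n_good) / n_targets` over the TF's gene-level
targets.  The denominator counts **all** targets — cancer-dependent and
unlabeled genes dilute the score but cannot flip its sign; a labeled-only
denominator is available behind a config flag (off by default).

The null shuffles the gene → label assignment (label multiset preserved,
edges and hence every TF's degree untouched), 1,000 replicates by default,
seeded.  Empirical two-sided p-values use add-one smoothing,
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`, so p ∈ (0, 1] always.  The
source screens compare per-degree null and observed distributions
graphically; the p-value definition is this package's own and documented as
such.  Note these p-values are *conservative* on coarse score distributions:
ties at |null| = |obs| are counted in the numerator, and a TF with few
targets has a score supported on few values.  The calibration check in the
test suite therefore uses a dense null world (200 TFs, 8,000 genes, degrees
300–700, labels independent of edges) where scores are nearly continuous and
TF target overlap is weak; there the p-value distribution is uniform to
Kolmogorov–Smirnov distance < 0.1 at 1,000 permutations.  At study scale the
conservativeness is in the safe direction.

Nomination: for each oncogene in the network, its promoter-binding TFs with
effector class activator or bifunctional and prognosis score **strictly**
greater than 0.33 (threshold configurable).  TFs without effector annotation
(including heterodimer binders) never qualify.

## Association statistics

Family representation in the network versus the screened array is compared
per family with the pooled two-proportion z-test; whenever any expected cell
of the 2×2 table is below 5 the z approximation is invalid and Fisher's exact
test is used instead.  Both counting units are supported — per TF and per
interaction — because "representation" is ambiguous between them; both are
reported.  Raw p < 0.05 sets the direction flag (no FDR here, matching how
such screens report family effects); BH step-up q-values are available for
user-requested batches via `bh_fdr`.

Pair-event preferences: a cooperative verdict contributes one *cooperative*
event per pair member; an antagonistic verdict one *antagonized* event per
antagonized TF and one *antagonist* event per partner.  Per family ×
event-type, a 2×2 Fisher exact test against all other families; fractions
sum to 1 within a family.

Mutation frequency is `(mutated − synonymous) / total` cases; zero total
cases is an error, not a zero.

## SWIM-seq strain confirmation

A promoter strain is confirmed iff ≥ 25% (inclusive) of its pMW3-vector reads
match the expected promoter sequence.  pMW2 summaries are carried but never
gate the decision.  Zero total reads is "unconfirmable", distinct from a
failed confirmation.  Confirmation is monotone in matching reads.

## Synthetic worlds

`WorldParams` defaults define the study conditions: 300 TFs × 150 promoters
(136 genes, ~10% with an alternative promoter, mirroring a 136-gene /
152-promoter screen), 50 TF pairs, TF out-degrees from a truncated power law
with exponent −1.8 capped at 54, 18% autoactive baits (so 123 of 150 survive
the pair-screen filter), per-colony dropout 0.1 and false activation 0.001,
ChIP coverage 0.45 and literature flagging 0.06 of true edges, and
categorical family/effector/prognosis/role distributions loosely shaped on
published annotation tallies.  Prognosis labels are drawn independently of
the edges, so the generator doubles as a null world for permutation checks.

Noise is injected per colony, not per interaction, so the ≥ 3/4 rule's
robustness is actually exercised: a true edge survives one colony dropout.
A single quad recovers a true edge with probability 0.9477 at dropout 0.1;
TFs in the pair array get an independent second quad from the monomer
strains on the pair-screen plates (as in the real screen design), and the
network deduplicates across assays, which lifts overall edge recall to
≈ 0.96 at default scale.  Precision is ≈ 1 because a false positive needs
three simultaneous false-activations (probability ~4 × 10⁻⁹ per non-edge).

Pair relations are sampled conditional on the monomer truth: where neither
monomer binds, cooperative with probability 0.015 (else none); where a
monomer binds, antagonistic with probability 0.5 (else independent).  At
default scale this yields on the order of 90 cooperative and 120–140
antagonistic calls, matching the scale of the real pair screen.  At zero
noise the calling stages reproduce the truth network and every planted pair
relation exactly, and the same seed reproduces the emitted file set byte for
byte.

What the generator does **not** emulate: real TF binding-site sequence
specificity (targets are attached uniformly), correlated plate/batch
effects, inter-day signal development, biased label–degree dependence, and
genome-scale peak background.  Passing tests therefore demonstrate the
correctness of the calling/annotation/statistics machinery under the stated
noise model, not screen performance on real plates.

`make_planted_study` is a synthetic stand-in for the study's supplementary
call tables: it *constructs* (rather than samples) tables whose summary
counts are planted — 1,350 interactions between 265 binders and 108 of 136
genes; 117 degree-1 TFs and 36 hubs with maximum degree 54; evidence classes
543/21/61/725 with one degree-36 TF split 19 ChIP / 2 literature / 15 novel;
and 90 cooperative + 136 antagonistic calls over 67 TF pairs and 66
promoters — so the counting machinery can be validated against known totals
without any external download.  `make_planted_nomination` plants a world
where exactly 25 of 51 oncogenes have a qualifying TF.

## Problem sizes and determinism

Default test and acceptance runs use the 300 × 150 world (~45,000 quads),
500 TFs for exponent recovery, and 200 TFs × 1,000 permutations for null
calibration; the full suite runs in well under a minute.  Every stochastic
stage takes an explicit seed, and stage outputs are pure functions of
(inputs, config, seed).

## Known limitations

- The ranking indices are declared surrogates for unpublished software
  internals; only their ordering role is meaningful.
- Empirical p-values are conservative for low-degree TFs (see above); they
  are not corrected for the multiplicity of TFs.
- Literature evidence quality is whatever the input flag table encodes.
- Survival modelling, differential expression, GO enrichment and plate-image
  segmentation are out of scope; their outputs enter only as labels.
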