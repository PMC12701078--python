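# Methods

## Data model and limit-of-detection semantics

A qPCR miRNA array reports one cycle-threshold (CT) value per assay per
sample; an assay that never crosses the fluorescence threshold is
exported as the token `undetermined`.  The pipeline treats the ceiling
(default 40 cycles) as a hard limit of detection: `undetermined`, empty,
and numeric values ≥ the ceiling are all imputed *at* the ceiling and
flagged not-detected.  Treating numeric CTs ≥ 40 identically to
`undetermined` is a deliberate choice — a CT at the ceiling carries the
same information ("below quantifiable abundance") regardless of how the
instrument happened to render it.  The ceiling is a parameter, not a
constant, so the policy itself is testable.

Imputed cells are *kept* in downstream statistics for retained miRNAs.
A miRNA switched off by the intervention shows exactly this pattern
(detected pre, ceiling post), and discarding imputed cells would blind
the analysis to the strongest biology.  The cost is that imputation
compresses true fold changes toward zero (a 7-cycle shift from a
baseline of 36 cannot express more than 4 cycles of change) and can
produce zero-variance difference vectors; both effects are handled
explicitly (see degenerate records below).

## Filtering

A candidate miRNA is retained iff detected in ≥ `min_detected` (default
2) samples of either timepoint group.  The "either group" disjunction is
essential: a miRNA fully repressed post-intervention is detected only in
the pre group and must survive.  The exogenous spike-in is never a
candidate and its absence in any sample is fatal, because normalization
is undefined without it.  The filter report carries the three-stage
cascade (total candidates → detected in ≥1 sample → retained), with the
spike-in excluded from all three counts.

## Normalization

Expression is −ΔCT = −(CT_miRNA − CT_spike) per cell, i.e. log2 relative
abundance under the assumption of perfect doubling per cycle
(amplification efficiency exactly 2).  Any technical effect that shifts
all assays of a sample by a common additive offset cancels exactly in
the subtraction.  Note this is an IEEE-exact identity only when the
additions themselves are exact; the property tests therefore draw CT
values and offsets on a dyadic grid (multiples of 1/64 cycle), where
`(a + c) − (b + c) == a − b` holds bit-for-bit.

## Paired differential expression

Per miRNA, with per-patient differences d = post − pre:
t = mean(d) / (sd(d)/√n), sample sd (n−1 denominator), two-tailed p from
Student's t with n−1 df.  log2FC = mean(post) − mean(pre) = mean(d).

Zero-variance difference vectors (typically all cells at the ceiling)
make t undefined.  Such records are flagged *degenerate*: p and q are
NaN, they are excluded from the BH adjustment, and they can never be
significant.  Assigning them p = 0 (or 1) would fabricate evidence in
either direction; exclusion is the only defensible policy and is
documented as this package's choice.

BH is the standard step-up over the m defined p-values: sort ascending,
q(i) = min over j ≥ i of p(j)·m/j, capped at 1.  Significance uses
strict inequalities throughout (q < 0.2, and nominal p < 0.05 where the
network is concerned), matching the "less than" convention of the
thresholds' definitions.

Consistency: a miRNA is consistently down (up) when ≥ `consistency_min`
(default 3) of the patients moved in that direction; zero differences
count toward neither side.  With `consistency_min` > n/2 both calls
cannot fire at once.

PCA treats samples as observations and miRNAs as features, centers
features without scaling (all features already share the −ΔCT log2
scale), and computes scores by SVD.  Each component's sign is fixed so
its largest-|loading| feature loads positively, making score files
reproducible across runs and platforms.

## Target ranking

Assay labels are normalized by trimming whitespace and assay-suffix
decorations (tokens after whitespace/underscore), lowercasing, and
prepending the species prefix (`hsa` by default) when missing.  Each
gene targeted by at least one selected miRNA receives the metric
−log2FC of its *most strongly regulated* targeting miRNA.  "Most
strongly regulated" is interpreted as largest |log2FC|, with smaller p
then lexicographic key as tie-breaks (a `strength="significance"` switch
prefers the smallest p instead, since the phrase admits either reading).
By default all retained miRNAs feed the ranking — preranked enrichment
needs a dense background, and restricting to nominally significant
miRNAs (available via `selection="nominal_p"`) would leave a handful of
genes.  The resulting list is totally ordered (metric descending, gene
id ascending on ties) so every downstream permutation result is
reproducible from a seed.

## Preranked GSEA

The enrichment score is the weighted Kolmogorov–Smirnov running sum:
walking the ranked list, a set member increments the sum by
|metric|^w / Σ_hits |metric|^w (w = 1 by default; if every hit metric is
0 the increments fall back to uniform 1/n_hits), a non-member decrements
by 1/(N − n_hits).  ES is the signed value at the maximum absolute
deviation; the sum starts and ends at zero by construction.  Leading
edge: hits at or before the peak for ES > 0, at or after it for ES < 0.

Significance uses gene-label permutation — same-size uniform draws from
the ranked universe — which is the only null available for an
externally ranked list.  Null distributions are shared between sets of
equal intersection size (the null depends only on size), drawn from one
seeded generator.  Nominal p is the matching-sign tail frequency with
add-one smoothing, (b+1)/(B_side+1), so p is never exactly 0.
NES = ES / mean(|null ES| of the matching sign); null ES values are
normalized the same way to build the pooled null-NES distribution.  The
FDR for a set with NES* is the ratio of the null tail fraction to the
observed tail fraction at NES*, computed separately for the positive and
negative tails, capped at 1; reported q-values are monotonized as
q-values must be — each set receives the minimum estimated FDR over
thresholds no more extreme than its own NES.

Defaults n_perm = 1000, min_size = 15, max_size = 500 and w = 1 follow
the conventions of the standard preranked GSEA tooling; all are
configurable, and the validation fixtures set min_size low enough that
the bounds are not binding.

## Network

Strict thresholds: miRNA nodes need nominal p < 0.05, pathway nodes
permutation q < 0.2.  Gene nodes need *both* to be a validated target of
some included miRNA *and* a leading-edge member of some included pathway
— an independent conjunction; the two conditions need not involve the
same miRNA/pathway pair.  Included miRNAs or pathways that end up with
no qualifying gene are dropped rather than drawn as isolated nodes: a
tripartite interaction map is about relations, and an entity with no
edges asserts none.  Exports (GraphML with statistic attributes,
edge-list TSV) rebuild the graph in (node-kind, label) order so two
exports of the same network are byte-identical.  Layout is presentation
and deliberately outside the contract.

## Synthetic data

The generator emulates the paired five-patient, ~384-assay design:

| parameter | default | meaning (units) |
|---|---|---|
| n_patients | 5 | paired pre/post samples per patient |
| n_assays | 384 | candidate miRNA assays (plus one spike-in) |
| spike_in_mean / sd | 22.0 / 0.3 | spike-in CT per sample (cycles) |
| baseline_ct_mean / sd | 30.0 / 4.0 | between-miRNA baseline CT (cycles) |
| fraction_near_lod | 0.4 | miRNAs drawn from a high-CT regime (mean 38, sd 1.5) |
| noise_sd_within_patient | 1.0 | technical noise per measurement (cycles) |
| patient_offset_sd | 1.5 | patient offset shared by both timepoints (cycles) |
| ceiling | 40.0 | limit of detection (cycles) |
| planted_effects | {} | assay index → ΔΔCT shift on post samples (cycles) |
| baseline_ct_max | None | optional right-truncation of the baseline (cycles) |

CT = baseline + patient offset + noise (+ shift on post); any value ≥
the ceiling is censored to `undetermined`.  The shared patient offset is
what the paired test exploits; censoring is hard truncation, not a
probabilistic dropout curve, keeping calibration checks analytic.  A
positive planted shift means later CT after the intervention, i.e.
downregulation, and maps to an expected log2FC of exactly −shift.
Planted magnitudes of 3–7 cycles mirror the effect sizes this kind of
study reports.  `baseline_ct_max` draws baselines from a right-truncated
normal; this emulates an already-filtered, retained subset, whose
defining property is detectability (the selection the real detection
filter induces).  The retained-set validation experiments use
`baseline_ct_max = 37` — three cycles of headroom, about two standard
deviations of the per-sample CT spread √(1.5² + 1²).

The companion generator builds a random miRNA→target map (20 targets
per miRNA from a 500-gene universe by default) and a gene-set collection
in which one designated set draws a controllable fraction (default 0.8)
of its members from the union of planted-down-miRNA targets; the rest,
and all other sets, are uniform draws.  The designated set is therefore
the only true enrichment signal, with known identity.

What the simulation does *not* model: plate/batch effects, amplification
-efficiency variation between assays, miRNA-correlated co-regulation,
realistic miRNA sequence identity, and target-map biases (hub genes,
literature coverage).  Passing recovery tests therefore demonstrate that
the statistical machinery is correct and calibrated under the design's
assumed noise structure — not that the pipeline is robust to every
artefact of real array data.

## Validation design and problem sizes

The packaged validation uses: exhaustive ES equivalence against a
brute-force running sum (all 385 subsets of sizes 1–4 of a 10-gene
list); BH equivalence on 1,000 random vectors of length 1–200 at 1e-12;
paired-t agreement with an independent reference at 1e-10 on 1,000
fixtures; 100-fixture bitwise shift invariance; a deterministic
filter-cascade toy; 100-cohort planted-effect recovery plus pooled null
calibration at the retained-set scale (134 miRNAs); 20-cohort GSEA
recovery (500-gene universe, 21 sets, 1,000 permutations); 100-fixture
network threshold monotonicity against a set-algebra oracle; and a
byte-level end-to-end determinism check.  These sizes keep the full
suite in the tens of seconds while leaving every statistical check at
the scale the design targets.

Under the recovery conditions the per-seed probability that all four
planted miRNAs simultaneously clear nominal p < 0.05 is close to 0.9 by
the noncentral-t power of the weakest (3-cycle) effect, so the ≥ 90%
recovery requirement sits near the design's own power boundary; the
reported recovery rate should be read with that in mind.

## End-to-end reproducibility

All randomness flows from a single root seed through
`numpy.random.SeedSequence` children (simulation, target/set generation,
permutations), so a fixed config + seed reproduces every output file
byte for byte; the manifest records a SHA-256 checksum per artifact.

## Known limitations

- The paired t-test at n = 5 has limited power and no variance
  moderation; nonparametric or empirical-Bayes alternatives are
  deliberately out of scope.
- Imputation-at-ceiling biases log2FC toward zero for near-LOD miRNAs;
  effect sizes for partially detected species are lower bounds.
- The identifier normalizer handles array-style decorations, not full
  miRBase version migration (e.g. renamed mature accessions).
- Gene-label permutation tests a competitive null over the supplied
  ranked universe; conclusions are relative to that universe.
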