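# Methods

This note documents the models and procedures implemented in
`riboscreen`, the conventions and tunable parameters they expose, what
the synthetic-data generators do and do not emulate, and the design
choices made where the design was genuinely open.

## Sequence ingestion and preprocessing

All sequences are stored uppercase RNA.  Ingestion maps T→U first, then
collapses every IUPAC ambiguity code to the first matching base in the
order A, C, G, U (R→A, Y→C, S→G, W→A, K→G, M→A, B→C, D→A, H→A, V→A,
N→A).  This is a deterministic, length-preserving substitution — not an
attempt to guess the true base — chosen so that downstream k-mer and
folding steps see a fixed four-letter alphabet.  Non-IUPAC characters
are a hard error naming the 1-based position.  Records shorter than
25 NT are dropped with a warning (25 NT is the smallest record the
screen is meant to handle, matching the shortest sequence in the
reference corpora).  Internally all coordinates are 0-based half-open;
user-facing positions are 1-based.

Ligand annotations pass through a canonicalizer: synonyms of one
molecule merge (mn/manganese → Mn2+), cobalamin subtypes merge under
"cobalamin", protein-specific ligands become "protein", tRNA variants
"tRNA", and speculative/synthetic classes (nhA-I motif, duf1646, raiA,
synthetic, sul1, blank) become "unknown".  Unrecognized names pass
through verbatim so no record is silently dropped; the map is idempotent.

5'UTR preprocessing appends the first 25 NT of the coding sequence (the
AUG start codon plus 22 downstream NT) and, when the result exceeds
300 NT, keeps only the last 300 NT.  The trim is 3'-anchored so the
start-codon context always survives: output length is exactly
min(L_UTR + 25, 300).  The coding context is supplied by the caller per
record; records without one are dropped.  A CDS that does not begin
with AUG is flagged (`cds_no_aug`), not rejected.  Deduplication removes
exact sequence duplicates within a corpus (first occurrence kept, order
stable); duplicates *across* the positive and unlabeled corpora are
retained, since the same string can legitimately be both a known
riboswitch and a 5'UTR candidate.

## Secondary structure

Folding is a backend contract: anything deterministic that maps a
sequence to a balanced dot-bracket string plus an MFE in kcal/mol.
Three backends ship:

* **TableBackend** — returns precomputed structures keyed by record id
  or sequence; bit-exact, used by the test suite.
* **SuffixTableBackend** — additionally serves any 3'-anchored suffix of
  a stored entry by cutting the stored structure at the same point,
  unpairing bases whose partner fell in the removed prefix, and scaling
  the MFE by the fraction of pairs retained.  This makes truncation
  scans deterministic whenever full-length structures are known.
* **ViennaBackend** — single-strand MFE folding through ViennaRNA
  (Python bindings, falling back to the `RNAfold` executable), default
  Turner model at 37 °C.

The single-strand MFE structure stands in for a multi-strand tube-mode
consensus; for non-complexed structures the two coincide, and the
deterministic single-strand fold is what makes results reproducible.
Pseudoknots are out of scope throughout: dot strings are required to be
balanced and non-crossing.

### Dot-bracket decomposition

Reading 5'→3': a *helix* is a maximal run of stacked pairs
(i, j), (i+1, j−1), …; a *stem* chains helices whose interruptions
contain no paired bases.  Each interruption contributes, independently
per strand, a *bulge* (exactly one unpaired NT) or an *internal loop*
(two or more) — *left* when the gap sits on the opening strand, *right*
on the closing strand, so one interruption can contribute one left and
one right element.  The unpaired run closed by a leaf stem's innermost
pair is its *hairpin*.  A stem whose innermost pair encloses two or more
child stems is *branched*.  Every position receives exactly one
category: paired, hairpin, bulge L/R, loop L/R, or unpaired — the last
covering exterior NTs *and* multiloop-junction NTs.  Junction NTs could
arguably form their own class; counting them as unpaired keeps the
seven-way partition exhaustive and matches the published accounting of
the two-stem worked example (9 unpaired NT with the 8 hairpin NT
excluded).  Hairpin counts are loop counts, not NT counts; the hairpin
NT total is exposed separately.  The decomposition is unique given the
pair list, so no tie-breaking arises.

## The 74-feature encoding

S1..S64 are 3-mer frequencies in strict lexicographic order over
A<C<G<U, each count divided by the number of windows (L−2); the block
sums to 1 for any sequence of length ≥ 3.  The ordering is fixed and
documented in `FEATURE_NAMES`; any consistent order works as long as
training and prediction share it.  S65 is GC content.  S66..S74 are the
structural features [MFE, N_unbranched, N_branched, N_loops_L,
N_loops_R, N_hairpins, N_bulges_L, N_bulges_R, unpaired fraction].

Normalization is corpus-wide and persisted with any trained model:
counts divide by their maxima over the corpus the normalizer was fitted
on (positives and unlabeled jointly), and S66 = mfe/min_mfe with
min_mfe the most negative MFE observed — the simplest map taking
(−∞, 0] onto [0, 1].  Positive MFEs are clipped to 0 before
normalization.  The unpaired fraction S74 uses the featurized
(post-trim) sequence length as denominator.  Feature-distribution
comparisons between corpora use the two-sample Kolmogorov–Smirnov
statistic per feature (`scipy.stats.ks_2samp`).

## Elkan–Noto PU classification

Training data carry a flag s per example (1 = labeled positive,
0 = unlabeled).  Under the selected-completely-at-random assumption
— positives are labeled with a probability c = p(s=1 | y=1) independent
of x — a calibrated classifier g(x) ≈ p(s=1 | x) satisfies
p(y=1 | x) = g(x)/c.  The implementation is the unweighted variant:

1. hold out a fraction (default 0.1) of the labeled positives;
2. fit the base learner on the rest versus all unlabeled examples;
3. estimate ĉ as the mean of g over the held-out positives;
4. predict p(y=1 | x) = min(1, g(x)/ĉ).

The holdout estimate is only unbiased where the class posterior on
positives is ≈ 1, i.e. when the classes are well separated — this is an
assumption of the method, not of the implementation.  Predictions are
monotone in g, so rankings are exactly preserved.  ĉ ≤ 0 (a degenerate
holdout) and single-class inputs are hard errors.  All randomness
(holdout split, calibration folds) flows from one recorded seed.

The default base learner is the RBF support-vector classifier with
C = 10, γ = 0.4 and probability calibration, the reference
configuration for the 74-feature screening task.  The base learner is a
contract, and the choice matters for ĉ: a Platt/logistic sigmoid cannot
represent the plateau p(s=1|x) = c < 1, so for the Gaussian tabular
benchmark the isotonically-calibrated logistic learner is used — its
step-function calibration can sit exactly at c.  Feature importance is
plain permutation importance: each column shuffled independently
(default 10 repeats, seeded), loss = baseline accuracy − mean shuffled
accuracy, with accuracy thresholding the PU output at 0.5 against known
evaluation labels.

## The leave-ligand-out ensemble

Splits are built from the positive corpus' canonical ligand labels: one
single-holdout per class at or above 2 % representation (most frequent
first), one per listed ligand pair whose members are present (the nine
reference pairs: FMN+glycine, FMN+SAM, FMN+TPP, FMN+cobalamin,
TPP+cobalamin, TPP+glycine, TPP+SAM, cobalamin+SAM, cobalamin+TPP —
kept verbatim, including the set-duplicate TPP/cobalamin entry, which
simply yields two independently-seeded members with the same withheld
set), and one "other" split withholding all sub-2 % classes jointly.
On the reference-shaped distribution this gives 10 + 9 + 1 = 20 splits;
with fewer classes the scheme degrades gracefully with warnings.  The
rare classes withheld by the "other" split remain in the training sets
of the 19 other members.

Member i trains on (positives minus its withheld classes) versus the
full unlabeled corpus, with per-member seed = base seed + i so
sequential and parallel execution agree.  The validation report gives,
per member, the fraction of training positives and of withheld
positives with raw output ≥ 0.5 (the decision threshold for accuracy
figures; a config key).  Scoring computes

J_Ensemble(x) = mean_i clip(PU_i(x)/max_i, 0, 1),

where max_i is member i's maximum raw output over *all* positives,
including its own withheld class.  A *hit* requires every member's raw
(non-normalized) output ≥ 0.95 (config key); `n_calling` counts members
reaching that threshold, so hit sets are nested and monotone in the
agreement level.

### Truncation scan

For a preprocessed UTR of length L (start codon at L−25), cut sites are
the 20 evenly spaced integer positions in [30, L−25) starting exactly
at 30; the start codon + 22 NT anchor is never truncated.  Each suffix
is refolded with the configured backend, refeaturized with the training
normalizer, and scored.  Sequences that are not full-length hits but
reach J_Ensemble ≥ 0.95 in at least 5 bins are flagged as candidates
rescued by truncation.  Sequences too short for 20 distinct cuts get
fewer bins with a warning; too short to place any cut past the offset
is an error.

## UTR-to-riboswitch similarity

D_L = |L_UTR − L_RS|; D_Lev = Levenshtein distance between dot strings
(computed by edlib's exact dynamic programming, equal to the recursive
textbook definition, empty strings included); D_struct = Σ over
S66..S74 of squared differences (both vectors from the same
normalizer).  The composite score is

J_Sim = 1 − ⅓ (D_L/max D_L + D_Lev/max D_Lev + D_struct/max D_struct),

clipped to [0, 1].  The normalizers follow corpus conventions rather
than hard-coded constants: max D_L = (longest RS) − (shortest sequence
in the combined corpora) — 476 − 25 = 451 in the reference data;
max D_Lev = max((max D_L) − L_UTR, L_UTR), an asymmetric convention
retained as given; max D_struct is recomputed per query as its maximum
structural distance over the whole reference set, so the weakest match
anchors that term at 1.  Ranked retrieval breaks J_Sim ties by
riboswitch id, making output order deterministic and independent of
reference-corpus order; the ligand tally over the top 20 matches is a
first ligand hypothesis, not a prediction.

## Synthetic corpora

The generators are pure functions of (spec, seed) and emulate the
*shape* of the real training data:

* **Structured positives** — lengths from a clipped normal (mean 150,
  sd 75, range 25–476 NT); stems planted as complementary arm pairs
  (4–10 bp, loops 4–8 NT, occasional 1-NT bulges and branched units),
  about one stem per 70 NT at unit intensity.  Ligand classes follow a
  skewed distribution shaped like the reference corpus (ten classes
  ≥ 2 %, cobalamin ≈ 23 % at the top, a long sub-2 % tail) and each
  class writes a fixed 6-mer motif into its first hairpin loop so
  classes are statistically distinguishable.  Planted structures are
  emitted as the sequences' dot strings with a pseudo-MFE of ≈ −1.8
  kcal/mol per planted pair (jittered, seeded).
* **Unlabeled** — lengths capped at 300 NT; a configurable fraction
  (default 0.3) mildly structured, the rest unstructured.
* **Random controls** — i.i.d. uniform nucleotides, length-matched to
  the positive distribution, fully unpaired toy structures.
* **Exon-like controls** — a codon-periodic Markov chain (frame-
  dependent composition tuned to a target GC, default 0.52, with mild
  repeat avoidance): sequence-level structure without planted pairing.
* **Anchored candidates** — an unstructured 5' pad, a strong structured
  core, and the AUG + 22 NT anchor, within the 300-NT cap; the shape
  the truncation scanner consumes.
* **PU tabular data** — two spherical Gaussian clusters; `separation`
  is each mean's offset from the inter-cluster midpoint in σ units
  (means 2·separation·σ apart), so separation 3 puts the class
  posterior at ≈ 0/1 everywhere — the regime in which the labeling
  propensity is identifiable.  Exactly a c_true fraction of positives,
  chosen uniformly, receive s = 1.

What the generators do **not** emulate: thermodynamic folding (random
controls would in reality fold somewhat; here their toy structures are
fully unpaired, which widens the structure gap between positives and
controls), sequence homology within ligand families, RNAcentral-scale
corpus sizes, or biological base composition beyond GC and codon
periodicity.  Tests passing on these fixtures therefore demonstrate the
pipeline's mechanics — encoding, propensity estimation, holdout
construction, scoring, scanning, ranking — under favorable separation,
not screening performance on real genomes.  Count defaults in
`FixtureSpec` mirror the reference corpus scale (67,683 / 48,031 /
60,000 / 5,946); tests and examples pass explicit small `n` (a few
hundred sequences, 5-member mini ensembles), which keeps the full suite
under half a minute on one core.

## Numerical and degenerate-input conventions

MFE 0 normalizes to S66 = 0; an all-unpaired structure has unpaired
fraction 1 and zero counts.  Count features never observed nonzero stay
0 rather than dividing by zero.  Hit thresholds compare with ≥.
Empty FASTA files yield empty record lists with a warning; malformed
headers are errors naming the line.  J_Sim normalizer denominators are
floored at 1 (lengths) or the observed maximum (structural), so a
reference set of identical sequences cannot divide by zero.  Ensemble
member maxima of 0 are replaced by 1 in the J_Ensemble denominator
(a member that scores every positive at 0 contributes 0, not NaN).

## Known limitations

The screen inherits the Elkan–Noto assumptions: labeled positives
selected completely at random and near-separable classes; when the
unlabeled pool contains positives whose features differ systematically
from labeled ones, ĉ and the ranking are biased.  Single-strand MFE
structures ignore conformational ensembles and pseudoknots.  The 2 %
representation threshold, the 0.5/0.95 thresholds, the 10 % holdout and
the 20-bin scan are conventions carried as configuration, not fitted
quantities.  The similarity score's max D_Lev convention is asymmetric
in UTR length and is kept for compatibility rather than by argument.
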