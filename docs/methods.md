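# Methods

## Tag geometry and digestion

BcgI recognises CGA-N6-TGC and cleaves both strands on both sides of the
site, releasing an iso-length fragment. We model the fragment as exactly
32 bp: 10 bp upstream flank, the 12-bp recognition core, 10 bp downstream
flank (core at 1-based positions 11–22). Both strands are scanned — the
reverse-strand core reads GCA-N6-TCG on the forward strand — and every tag
is stored in canonical orientation, the lexicographically smaller of the
sequence and its reverse complement, so strand is irrelevant everywhere
downstream. Site occurrences whose window would run past a sequence end
are skipped, as are windows containing N (they can never be matched
exactly). Within one genome, duplicate tags count once: the database
tallies distinct markers, not copies. Reads are modelled as the bare
32-bp insert with Phred+33 qualities; adaptor handling is out of scope.

## Read QC

Raw reads are reduced to *enzyme reads* — exact-length reads carrying the
core in either orientation (an N inside a core triplet matches nothing) —
and then to *clean reads* by removing reads with more than 8% N bases and
reads with more than 20% of bases at Q ≤ 20. Both fraction thresholds are
strict inequalities and Q = 20 itself counts as low quality; a 32-bp read
with two Ns (6.25%) survives, three Ns (9.375%) does not. The two filters
commute and the pass is idempotent.

## Two-pass profiling

Pass 1 assigns each clean read by exact canonical 32-mer lookup in the
primary species-specific tag database, accumulating S (read hits,
including repeated hits to one tag) and t (distinct tags observed) per
species. Candidates are those with G = √(S·t) ≥ 10; the boundary is
inclusive, reading the threshold as the smallest admissible value. Pass 2
rebuilds tag specificity among the candidates of that sample only,
remaps all clean reads, and normalises S_i/T_i to the final profile.
Unmatched reads are tallied as a diagnostic and enter no normalisation.
With all species as candidates the secondary database equals the primary
one, so the two passes agree exactly — a property the tests assert to
1e-9.

The estimator is consistent because the generator draws a read from
species *i* with probability proportional to abundance_i × (tag count of
*i*): dividing read counts by T_i removes the tag-count factor. On
30-species communities with 10⁵ error-free reads the L1 recovery error is
≈0.01 and scales as expected with read depth (≈×0.5 when reads ×4).

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
cohort:

- **Taxonomy**: a random tree over requested phylum/genus/species counts,
  every parent guaranteed at least one child.
- **Genomes**: random sequences (default 100 kb ± 5%) with
  clade-correlated GC (phylum-level GC uniform in the configured range,
  genus/species jitter SD 0.03/0.015); recognition sites are planted as
  complete 32-bp tags at uniform random non-overlapping positions, with a
  per-species count drawn uniformly from 20–200 so every species carries
  markers.
- **Paired design**: per-species community log-means ~ N(0, σ) with
  σ = 1.5 by default (a standard log-normal rank-abundance curve); each
  subject adds a species-wise N(0, subject_sd) effect shared by both
  sides, so the two sides of a subject are identical up to the planted
  stone-side fold changes, which are applied multiplicatively before
  renormalisation. An optional `sample_sd` (default 0) adds independent
  side-level log-normal noise; simulations that need realistic within-pair
  variation (marker-model and detection studies, the pipeline demo) set it
  to 0.5. Defaults mirror the study scale: 30 subjects × 2 sides.
- **Reads**: 32-bp tags drawn ∝ abundance × tag count, random
  orientation. Base qualities are two-level (Q40/Q13) mixed so the
  marginal substitution rate equals `error_rate`, and each base is
  substituted with the probability its own Phred value implies — quality
  strings are therefore consistent with the realised error process. N
  substitutions occur at `n_rate` with Q2. Error-bearing reads simply fail
  exact matching; no mismatch tolerance is attempted.

What the generator does *not* model: PCR/amplification bias, indels,
host-DNA contamination, adaptor read-through, within-species strain
variation, or compositional correlation between species beyond the
log-normal draws. Passing tests therefore demonstrate correctness of the
computation under the stated sampling model, not robustness to every
artefact of real libraries.

## Ecology

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) on integer
pass-2 read counts (it needs singletons/doubletons; it is undefined on
proportions), while Shannon (natural log) and Gini–Simpson (1 − Σp²) use
relative abundances. Beta diversity offers Bray–Curtis on abundances,
Jaccard on presence/absence and Euclidean distance; PCoA double-centres
−D²/2 and reports negative eigenvalues without correction, with
proportion explained taken over the positive spectrum. PERMANOVA uses the
standard pseudo-F from within-group sums of squared distances with the
(1 + exceedances)/(1 + permutations) p-value convention; the default
permutes labels freely (matching the study's analysis), and a `strata`
option restricts permutations to within-subject swaps for paired designs.
Species are "detected" in a group, for the Venn partition, when their
abundance is positive in at least one sample of the group.

## Differential abundance

Paired Wilcoxon signed-rank tests (zero differences dropped; exact null
for untied samples up to n = 50, tie- and continuity-corrected normal
approximation otherwise, via scipy) produce a per-rank table of mean
relative abundances (%), statistics and raw two-sided p-values — no
multiple-testing correction, matching how such tables are conventionally
reported; the calibration suite verifies the raw type-I error instead. A
taxon whose paired differences are all zero is reported with p = NaN and
never flagged.

The LDA effect size follows the published LEfSe recipe in spirit:
Kruskal–Wallis screen at α = 0.05; per-sample rescale to a 10⁶ total; 30
class-balanced two-thirds subsamples, each fitted with a single linear
discriminant; per-feature effect = mean of the raw between-class mean
difference and the feature's share (normalised |coefficient|) of the
projected class separation; score = signed log10(1 + |effect|), reported
at |score| ≥ 2.0. Exact numerical parity with the original LEfSe
implementation is a non-goal; the contracts are the threshold semantics,
monotonicity in the threshold, and that non-overlapping class supports of
ecological magnitude (10⁻⁵ vs 10⁻¹) always clear 2.0. Degenerate
discriminant fits in a subsample fall back to the raw mean difference for
that subsample.

Spearman correlations (tie-corrected, via scipy) are computed among the
top-30 taxa by mean abundance; pairs involving a constant taxon are
emitted as NaN.

## Marker model

Features are the top 30 species by overall mean abundance. A 500-tree
random forest (Gini importance, √p features per split) provides a single
global ranking; nested top-k panels are evaluated by stratified 10-fold
CV repeated 10 times, pooling folds within a repeat and taking mean/SD
across repeats. The cut-off value is min error + SD at the minimising k;
the optimal panel is the smallest k with error below the cut-off, with
the minimising k itself always eligible (covering SD = 0). The rule is
scale-free in the error units.

POD is defined as the *fraction* of trees voting the stone-side class
(the raw stone/non-stone vote ratio is unbounded and undefined under
unanimity); training samples are scored by their out-of-bag trees to
avoid resubstitution optimism — fully grown trees cast effectively hard
votes, so the OOB decision function is the vote fraction — and samples
with no OOB trees fall back to the full-ensemble vote and are flagged.
AUC uses the mid-rank Mann–Whitney formulation (ties count 1/2), checked
in the tests against brute-force concordant-pair enumeration and
scikit-learn's implementation.

## Numerical and design choices

- All randomness flows from one seed through named `SeedSequence`
  substreams; reruns are byte-identical, and every simulation function is
  deterministic given its seed.
- Profiles must sum to 1 within 1e-9; rank aggregation conserves
  per-sample mass exactly.
- The CV curve uses fewer trees per fit (default 100) than the final
  500-tree forest; the curve's role is ranking panel sizes, not producing
  the deployed classifier, and the error bars are taken across repeats
  either way. Tests and the acceptance script use 30-tree CV fits and
  30-subject designs — the study's scale — to keep full runs in the
  minutes range.
- Where a pipeline sample yields no G-score candidates the profile is
  empty and a warning is logged rather than raising: an uncolonised or
  failed sample is data, not a crash.

## Known limitations

- Exact matching only: substitution errors shrink S and t rather than
  being recovered; abundance estimates are effectively restricted to
  reads that survive error-free.
- Single enzyme, single 32-bp geometry; other type IIB enzymes are out of
  scope.
- The LEfSe-style scorer and the PERMANOVA are two-group procedures;
  multi-class designs are not supported.
- Chao1 on deeply sequenced tag data saturates quickly because singleton
  counts shrink with depth; comparisons across samples of very different
  depth should rarefy first, which the package deliberately does not do.
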