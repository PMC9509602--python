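# urotag

Species-level microbiome profiling from iso-length type IIB restriction
tags, plus the paired comparison stack used for stone-side versus
non-stone-side renal-pelvis urine samples in kidney stone disease.

Low-biomass samples such as renal-pelvis urine carry too little microbial
DNA for deep shotgun sequencing to be economical. Tag-based profiling
digests genomic DNA with a type IIB enzyme (BcgI, recognition core
CGA-N6-TGC) that releases iso-length ~32-bp fragments, sequences those
fragments, and assigns them to species through a database of
*species-specific* tags. `urotag` implements this quantification and every
downstream analysis of a paired two-side study design, along with a
synthetic-data generator that makes the whole pipeline testable with known
ground truth and no external downloads.

## The model

For species *i* in one sample, let

- `T_i` — number of species-specific tags of *i* in the database in force,
- `S_i` — reads assigned to any tag of *i*,
- `t_i` — distinct tags of *i* observed at least once.

Candidate species are screened by the **G score**,

    G_i = sqrt(S_i * t_i),   kept when G_i >= 10,

which suppresses false positives created by a few stray reads (3 reads
spread over 3 tags give G = 3 and are discarded). A **secondary database**
is then rebuilt over the candidates only — tag specificity is recomputed
among candidates, so each candidate's `T_i` can only grow — all reads are
remapped, and relative abundance is estimated as

    p_i = (S_i / T_i) / sum_j (S_j / T_j),

which removes the genome-size (tag-count) bias.

Downstream, per-sample profiles feed: Chao1 / Shannon / Simpson alpha
diversity; Bray-Curtis, binary Jaccard and Euclidean beta diversity with
PCoA and PERMANOVA; a Venn partition of detected species; paired Wilcoxon
differential-abundance tables at phylum/genus/species rank; LEfSe-style
LDA effect sizes (threshold 2.0); Spearman correlation networks; and a
random-forest marker panel chosen by the minimum-CV-error-plus-SD
smallest-set rule, scored per sample with the POD (probability of disease)
index — the fraction of trees voting for the stone side — and summarised
by ROC/AUC.

## Worked example

```python
import numpy as np, pandas as pd
from urotag import synthdata, tagdb, readqc, profiler

tax     = synthdata.make_taxonomy(n_phyla=3, n_genera=8, n_species=30, seed=1)
genomes = synthdata.make_genomes(tax, length_mean=60_000, seed=2)
db      = tagdb.build_tagdb(genomes, tax)

design = synthdata.make_paired_design(list(tax.species_id), n_subjects=4, seed=3)
truth  = design.abundances.iloc[:, 0]           # one sample's ground truth

reads       = synthdata.simulate_reads(genomes, truth.to_dict(), 100_000, seed=4)
clean, rep  = readqc.run_qc(reads)
profile     = profiler.profile_sample(clean, db, genomes)

est = profile.abundances.reindex(truth.index).fillna(0)
print(len(db), rep.n_clean, round(float(np.abs(est - truth).sum()), 4))
```

prints

```
4143 100000 0.0092
```

i.e. the database holds 4,143 species-specific tags, all 100,000 simulated
error-free reads survive QC (every read is a genuine enzyme fragment), and
the profiled abundances differ from the planted community by a total
L1 error of ~0.009 across 30 species.

The full pipeline runs from a single config:

```bash
urotag run --config config.yaml --out results/
```

with a `simulate:` block (or `inputs:` paths to FASTA/FASTQ/TSV), and
writes per-stage outputs plus `report.json`. Reruns with the same config
and seed are byte-identical. A fully synthetic demo lives at
`examples/demo_config.yaml` and finishes in about a minute on one CPU.

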