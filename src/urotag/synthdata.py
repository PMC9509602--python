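"""Synthetic taxonomies, genomes, paired community designs and reads.

The generator emulates the statistical structure of a paired renal-pelvis
urobiome study: ~30 subjects each contributing a stone-side and a
non-stone-side sample, a few hundred detectable species across ~10 phyla,
log-normal community abundances, a handful of planted side-specific
fold-change effects, and single-end iso-length (32 bp) restriction-tag
reads with substitution errors, N bases and Phred+33 qualities.  Every
sample carries a known ground truth, which is what makes the profiler and
the downstream statistics testable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from ._seq import Read, phred_char
from .tagdb import digest_genome

__all__ = [
    "PairedDesign",
    "make_taxonomy",
    "make_genomes",
    "make_paired_design",
    "simulate_reads",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMPLEMENT_U8 = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_U8[_x] = _y


def make_taxonomy(
    n_phyla: int, n_genera: int, n_species: int, seed: int
) -> pd.DataFrame:
    """Random lineage tree: each species in one genus, each genus in one phylum.

    Requires ``n_phyla <= n_genera <= n_species``; every phylum receives at
    least one genus and every genus at least one species.
    """
    if not (1 <= n_phyla <= n_genera <= n_species):
        raise ValueError("need 1 <= n_phyla <= n_genera <= n_species")
    rng = np.random.default_rng(seed)
    # First len(parent) children pin one child per parent, the rest land randomly.
    genus_phylum = np.concatenate(
        [np.arange(n_phyla), rng.integers(0, n_phyla, n_genera - n_phyla)]
    )
    species_genus = np.concatenate(
        [np.arange(n_genera), rng.integers(0, n_genera, n_species - n_genera)]
    )
    width = len(str(n_species))
    return pd.DataFrame(
        {
            "species_id": [f"s{i + 1:0{width}d}" for i in range(n_species)],
            "genus": [f"g{species_genus[i] + 1:03d}" for i in range(n_species)],
            "phylum": [
                f"p{genus_phylum[species_genus[i]] + 1:02d}" for i in range(n_species)
            ],
        }
    )


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def make_genomes(
    taxonomy: pd.DataFrame,
    length_mean: int = 100_000,
    gc_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    planted_sites: tuple[int, int] = (20, 200),
) -> dict[str, str]:
    """One random genome per species with clade-correlated GC content.

    Recognition sites (full 32-bp tags with the CGA-N6-TGC core) are planted
    at uniform random non-overlapping positions, ``planted_sites`` drawn
    uniformly per species, which guarantees every species carries tags.
    GC is drawn per phylum and jittered per genus and species so related
    species share base composition.
    """
    lo, hi = gc_range
    if not (0 < lo < hi < 1):
        raise ValueError("gc_range must satisfy 0 < lo < hi < 1")
    if len(taxonomy) == 0:
        raise ValueError("taxonomy must be nonempty")
    rng = np.random.default_rng(seed)
    phylum_gc = {p: rng.uniform(lo, hi) for p in sorted(taxonomy["phylum"].unique())}
    genus_gc = {
        g: np.clip(phylum_gc[ph] + rng.normal(0, 0.03), lo, hi)
        for g, ph in sorted(
            taxonomy[["genus", "phylum"]].drop_duplicates().itertuples(index=False)
        )
    }
    genomes: dict[str, str] = {}
    for row in taxonomy.sort_values("species_id").itertuples(index=False):
        gc = float(np.clip(genus_gc[row.genus] + rng.normal(0, 0.015), lo, hi))
        length = int(rng.normal(length_mean, 0.05 * length_mean))
        length = max(length, 2000)
        seq = _random_dna(rng, length, gc)
        k = int(rng.integers(planted_sites[0], planted_sites[1] + 1))
        # Sorted draws plus a 32-bp stride give non-overlapping start positions.
        starts = np.sort(rng.integers(0, length - 32 * k + 1, size=k)) + 32 * np.arange(k)
        for s in starts:
            site = _random_dna(rng, 32, gc)
            site[10:13] = _BASES[[1, 2, 0]]  # CGA
            site[19:22] = _BASES[[3, 2, 1]]  # TGC
            seq[s : s + 32] = site
        genomes[row.species_id] = seq.tobytes().decode()
    return genomes


@dataclass
class PairedDesign:
    """Paired two-side community design with a ground-truth effect registry.

    ``samples`` has one row per sample (sample_id, subject_id, side);
    ``abundances`` is a species x sample matrix of relative abundances, each
    column summing to 1; ``effects`` maps species to the stone-side fold
    change planted into the design.
    """

    samples: pd.DataFrame
    abundances: pd.DataFrame
    effects: dict[str, float] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.samples["subject_id"].unique())

    def sample_ids(self, side: str | None = None) -> list[str]:
        df = self.samples if side is None else self.samples[self.samples["side"] == side]
        return list(df["sample_id"])

    def labels(self) -> pd.Series:
        return self.samples.set_index("sample_id")["side"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / "design.tsv", sep="\t", index=False)
        io.write_profile_matrix(self.abundances, outdir / "true_abundances.tsv")
        (outdir / "effects.json").write_text(json.dumps(self.effects, sort_keys=True))


def make_paired_design(
    species: Sequence[str],
    n_subjects: int = 30,
    sigma_lognormal: float = 1.5,
    effects: Mapping[str, float] | None = None,
    subject_sd: float = 0.5,
    seed: int = 0,
    sample_sd: float = 0.0,
) -> PairedDesign:
    """Log-normal paired community design with planted stone-side effects.

    Per-species community log-means are drawn N(0, ``sigma_lognormal``)
    (the rank-abundance curve); each subject adds a species-wise random
    effect N(0, ``subject_sd``) shared by both sides, so the two sides of a
    subject are identical before the planted fold changes are applied.
    ``sample_sd`` > 0 additionally adds independent side-level log-normal
    noise, for simulations that need within-pair variation.  Stone-side
    abundances are multiplied by their fold change, then every sample is
    renormalised to sum to 1.
    """
    effects = dict(effects or {})
    species = list(species)
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    unknown = sorted(set(effects) - set(species))
    if unknown:
        raise ValueError(f"effect species not in community: {unknown}")
    if any(f <= 0 for f in effects.values()):
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    n_sp = len(species)
    mu = rng.normal(0.0, sigma_lognormal, n_sp)
    fold = np.array([effects.get(sp, 1.0) for sp in species])
    rows, cols = [], {}
    width = len(str(n_subjects))
    for j in range(n_subjects):
        subject = f"subj{j + 1:0{width}d}"
        u = rng.normal(0.0, subject_sd, n_sp)
        base = mu + u
        for side in ("stone", "non_stone"):
            x = np.exp(base + (rng.normal(0.0, sample_sd, n_sp) if sample_sd > 0 else 0.0))
            if side == "stone":
                x = x * fold
            sample_id = f"{subject}_{side}"
            rows.append({"sample_id": sample_id, "subject_id": subject, "side": side})
            cols[sample_id] = x / x.sum()
    abundances = pd.DataFrame(cols, index=pd.Index(species, name="species_id"))
    return PairedDesign(pd.DataFrame(rows), abundances, effects)


def simulate_reads(
    genomes: Mapping[str, str],
    abundance: Mapping[str, float],
    n_reads: int,
    error_rate: float = 0.0,
    n_rate: float = 0.0,
    seed: int = 0,
    tag_sets: Mapping[str, Sequence[str]] | None = None,
) -> list[Read]:
    """Draw iso-length tag reads from a community.

    A read originates from species *i* with probability proportional to
    ``abundance_i`` times the number of distinct tags of *i*, and copies one
    of those tags uniformly in a random orientation.  This is exactly the
    sampling structure under which the profiler's per-tag normalisation
    ``S_i/T_i`` is proportional to the input abundance.

    Errors follow a quality-driven model: each base is either high quality
    (Q=40) or low quality (Q=13), mixed so that the marginal substitution
    rate equals ``error_rate``, and is substituted (to a different base)
    with the probability its own Phred value implies — so quality strings
    are consistent with the error process.  N substitutions additionally
    hit each base at ``n_rate`` and carry Q=2.
    """
    if not (0 <= error_rate < 1 and 0 <= n_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    bad = [sp for sp, a in abundance.items() if a < 0]
    if bad:
        raise ValueError(f"negative abundances: {bad}")
    unknown = sorted(set(abundance) - set(genomes))
    if unknown:
        raise ValueError(f"abundance species without genomes: {unknown}")
    species = sorted(sp for sp, a in abundance.items() if a > 0)
    if tag_sets is None:
        tag_sets = {sp: sorted(set(digest_genome(genomes[sp]))) for sp in species}
    else:
        tag_sets = {sp: sorted(set(tag_sets[sp])) for sp in species}
    weights = np.array(
        [abundance[sp] * len(tag_sets[sp]) for sp in species], dtype=float
    )
    if weights.sum() == 0:
        raise ValueError("no species has positive abundance and at least one tag")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    chunks: list[str] = []
    origins: list[str] = []
    for sp, c in zip(species, counts):
        if c == 0:
            continue
        idx = rng.integers(0, len(tag_sets[sp]), size=c)
        chunks.extend(tag_sets[sp][i] for i in idx)
        origins.extend([sp] * c)
    arr = np.frombuffer("".join(chunks).encode(), dtype=np.uint8).reshape(-1, 32).copy()
    order = rng.permutation(n_reads)
    arr = arr[order]
    origins = [origins[i] for i in order]

    flip = rng.random(n_reads) < 0.5
    arr[flip] = _COMPLEMENT_U8[arr[flip]][:, ::-1]
    q_hi, q_lo = 40, 13
    e_hi, e_lo = 10 ** (-q_hi / 10), 10 ** (-q_lo / 10)
    if error_rate == 0:
        q = np.full(arr.shape, q_hi)
        err = np.zeros(arr.shape, bool)
    elif error_rate < e_lo:
        frac_lo = (error_rate - e_hi) / (e_lo - e_hi)
        q = np.where(rng.random(arr.shape) < frac_lo, q_lo, q_hi)
        err = rng.random(arr.shape) < 10.0 ** (-q / 10)
    else:  # uniformly poor run: one quality level matching the rate
        q = np.full(arr.shape, int(round(-10 * np.log10(error_rate))))
        err = rng.random(arr.shape) < error_rate
    if err.any():
        shift = rng.integers(1, 4, size=arr.shape)
        idx = _BASE_INDEX[arr]
        arr[err] = _BASES[(idx[err] + shift[err]) % 4]
    n_mask = (
        rng.random(arr.shape) < n_rate if n_rate > 0 else np.zeros(arr.shape, bool)
    )
    arr[n_mask] = ord("N")

    qual_arr = (33 + np.clip(q, 0, 41)).astype(np.uint8)
    qual_arr[n_mask] = ord(phred_char(2))

    reads = []
    for i in range(n_reads):
        reads.append(
            Read(
                f"r{i:07d}|{origins[i]}",
                arr[i].tobytes().decode(),
                qual_arr[i].tobytes().decode(),
            )
        )
    return reads


def simulate_study(
    outdir: str | Path,
    n_phyla: int = 10,
    n_genera: int = 60,
    n_species: int = 300,
    n_subjects: int = 30,
    sigma_lognormal: float = 1.5,
    subject_sd: float = 0.5,
    sample_sd: float = 0.0,
    effects: Mapping[str, float] | None = None,
    n_reads_per_sample: int = 50_000,
    error_rate: float = 0.001,
    n_rate: float = 0.0005,
    length_mean: int = 100_000,
    gc_range: tuple[float, float] = (0.3, 0.7),
    planted_sites: tuple[int, int] = (20, 200),
    seed: int = 0,
) -> PairedDesign:
    """Generate a full synthetic study on disk: taxonomy, genomes, design, reads.

    Writes ``taxonomy.tsv``, ``genomes.fasta``, the design ground truth
    (``design.tsv``, ``true_abundances.tsv``, ``effects.json``), one FASTQ
    per sample under ``reads/`` and a JSON manifest beside it.  All
    randomness derives from ``seed``; identical seeds reproduce
    byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_tax, s_gen, s_design, s_reads = (int(s.generate_state(1)[0] % 2**31)
                                       for s in root.spawn(4))
    taxonomy = make_taxonomy(n_phyla, n_genera, n_species, seed=s_tax)
    genomes = make_genomes(
        taxonomy, length_mean=length_mean, gc_range=gc_range, seed=s_gen,
        planted_sites=planted_sites,
    )
    design = make_paired_design(
        list(taxonomy["species_id"]),
        n_subjects=n_subjects,
        sigma_lognormal=sigma_lognormal,
        effects=effects,
        subject_sd=subject_sd,
        sample_sd=sample_sd,
        seed=s_design,
    )
    io.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
    io.write_fasta(genomes, outdir / "genomes.fasta")
    design.write(outdir)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    tag_sets = {sp: sorted(set(digest_genome(seq))) for sp, seq in genomes.items()}
    manifest: dict[str, dict] = {}
    read_rng = np.random.default_rng(s_reads)
    for sample_id in design.sample_ids():
        sample_seed = int(read_rng.integers(0, 2**31))
        reads = simulate_reads(
            genomes,
            design.abundances[sample_id].to_dict(),
            n_reads_per_sample,
            error_rate=error_rate,
            n_rate=n_rate,
            seed=sample_seed,
            tag_sets=tag_sets,
        )
        io.write_fastq(reads, reads_dir / f"{sample_id}.fastq")
        manifest[sample_id] = {
            "n_reads": n_reads_per_sample,
            "error_rate": error_rate,
            "n_rate": n_rate,
            "seed": sample_seed,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return design
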