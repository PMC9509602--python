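"""Two-pass taxonomic profiling from iso-length tag reads.

Pass 1 maps clean reads against the primary species-specific tag database
and screens candidate species with the G score, G = sqrt(S * t), where S is
the number of reads assigned to any tag of a species and t the number of
its distinct tags observed.  Low-level signals (few reads over few tags)
have small G and are discarded as likely false positives; the screening
threshold is 10.

Pass 2 rebuilds a sample-specific secondary database over the candidates
only — which enlarges each candidate's specific tag complement — remaps all
clean reads against it, and estimates relative abundance as

    abundance_i = (S_i / T_i) / sum_j (S_j / T_j)

with T_i the candidate's total specific tag count in the secondary
database.  Dividing by T_i removes the genome-size (tag-count) bias, so the
estimate tracks the underlying community proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import Read, canonical
from .tagdb import TagDatabase, build_secondary_db

__all__ = [
    "SampleTagCounts",
    "SpeciesProfile",
    "EmptyProfileError",
    "assign_reads",
    "g_score",
    "screen_candidates",
    "relative_abundance",
    "profile_sample",
    "aggregate_ranks",
    "G_SCORE_THRESHOLD",
]

logger = logging.getLogger(__name__)

G_SCORE_THRESHOLD = 10.0


class EmptyProfileError(ValueError):
    """No species carries any assignable signal."""


@dataclass
class SampleTagCounts:
    """Per-species read (S) and distinct-tag (t) tallies for one sample."""

    S: dict[str, int] = field(default_factory=dict)
    t: dict[str, int] = field(default_factory=dict)
    n_unmatched: int = 0

    def g_scores(self) -> dict[str, float]:
        return {sp: g_score(self.S[sp], self.t[sp]) for sp in self.S}

    def to_frame(self) -> pd.DataFrame:
        g = self.g_scores()
        return pd.DataFrame(
            {
                "S": pd.Series(self.S, dtype=int),
                "t": pd.Series(self.t, dtype=int),
                "G": pd.Series(g, dtype=float),
            }
        ).rename_axis("species_id").sort_index()


@dataclass
class SpeciesProfile:
    """Per-sample relative abundances over detected species (sum to 1)."""

    sample_id: str
    abundances: pd.Series
    provenance: str = "pass2"

    def __post_init__(self) -> None:
        a = self.abundances
        if len(a) and (a < 0).any():
            raise ValueError("negative abundance")
        if len(a) and abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


def assign_reads(clean: Sequence[Read], db: TagDatabase) -> SampleTagCounts:
    """Exact-match read assignment: a read hits iff its canonical 32-mer is a tag."""
    if len(db) == 0:
        raise ValueError("tag database is empty")
    counts = SampleTagCounts()
    seen: dict[str, set[str]] = {}
    lookup = db.tag_to_species
    for r in clean:
        tag = canonical(r.sequence)
        sp = lookup.get(tag)
        if sp is None:
            counts.n_unmatched += 1
            continue
        counts.S[sp] = counts.S.get(sp, 0) + 1
        seen.setdefault(sp, set()).add(tag)
    counts.t = {sp: len(tags) for sp, tags in seen.items()}
    return counts


def g_score(S: int, t: int) -> float:
    """G = sqrt(S * t); the false-positive control statistic."""
    if S < 0 or t < 0:
        raise ValueError("S and t must be non-negative")
    return math.sqrt(S * t)


def screen_candidates(
    counts: SampleTagCounts, threshold: float = G_SCORE_THRESHOLD
) -> list[str]:
    """Species with G >= threshold (the minimum admissible G is the threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return sorted(sp for sp, g in counts.g_scores().items() if g >= threshold)


def relative_abundance(
    counts: SampleTagCounts, db: TagDatabase, sample_id: str = "sample",
    provenance: str = "pass1",
) -> SpeciesProfile:
    """Normalised S_i/T_i ratios over species with S_i > 0."""
    ratios = {}
    for sp, s in counts.S.items():
        if s == 0:
            continue
        if sp not in db.tag_counts:
            raise ValueError(f"database supplies no T for species {sp!r}")
        ratios[sp] = s / db.tag_counts[sp]
    total = sum(ratios.values())
    if total == 0:
        raise EmptyProfileError("sum of S_i/T_i is zero")
    ab = pd.Series({sp: v / total for sp, v in sorted(ratios.items())}, dtype=float)
    ab.index.name = "species_id"
    return SpeciesProfile(sample_id, ab, provenance)


def profile_sample(
    clean: Sequence[Read],
    primary: TagDatabase,
    genomes: Mapping[str, str],
    sample_id: str = "sample",
    g_threshold: float = G_SCORE_THRESHOLD,
    with_counts: bool = False,
):
    """Full two-pass profile of one sample.

    Returns an empty profile (with a warning) when no species survives the
    G-score screen.  With ``with_counts=True`` returns
    ``(profile, pass1_counts, pass2_counts)`` so callers can reuse the
    pass-2 read tallies (e.g. for Chao1).
    """
    pass1 = assign_reads(clean, primary)
    candidates = screen_candidates(pass1, threshold=g_threshold)
    if not candidates:
        logger.warning("sample %s: no candidate passed the G-score screen", sample_id)
        empty = pd.Series(dtype=float)
        empty.index.name = "species_id"
        profile = SpeciesProfile(sample_id, empty, "pass2")
        return (profile, pass1, SampleTagCounts()) if with_counts else profile
    secondary = build_secondary_db(genomes, candidates, digests=primary.species_tags)
    pass2 = assign_reads(clean, secondary)
    profile = relative_abundance(pass2, secondary, sample_id, provenance="pass2")
    return (profile, pass1, pass2) if with_counts else profile


def profiles_to_matrix(profiles: Iterable[SpeciesProfile]) -> pd.DataFrame:
    """Taxa x samples matrix; species absent from a sample get 0."""
    cols = {p.sample_id: p.abundances for p in profiles}
    df = pd.DataFrame(cols).fillna(0.0).sort_index()
    df.index.name = "species_id"
    return df


def aggregate_ranks(
    profiles: pd.DataFrame | Iterable[SpeciesProfile],
    taxonomy: pd.DataFrame,
    rank: str,
) -> pd.DataFrame:
    """Sum species abundances by lineage at the requested rank.

    Aggregation conserves per-sample mass: column sums equal the species
    level sums.  ``rank`` is one of phylum, genus, species.
    """
    if rank not in ("phylum", "genus", "species"):
        raise ValueError(f"unknown rank {rank!r}")
    if not isinstance(profiles, pd.DataFrame):
        profiles = profiles_to_matrix(profiles)
    if rank == "species":
        out = profiles.copy()
        out.index.name = "species_id"
        return out
    lineage = taxonomy.set_index("species_id")[rank]
    missing = sorted(set(profiles.index) - set(lineage.index))
    if missing:
        raise ValueError(f"species without lineage: {missing}")
    out = profiles.groupby(lineage.reindex(profiles.index)).sum()
    out.index.name = rank
    return out.sort_index()
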