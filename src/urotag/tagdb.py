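"""In-silico BcgI digestion and species-specific tag databases.

BcgI is a type IIB restriction enzyme: it recognises CGA-N6-TGC and cleaves
both strands on both sides of the site, releasing an iso-length fragment.
Here a fragment ("tag") is modelled as 32 bp: 10 bp upstream flank, the
12-bp recognition core, 10 bp downstream flank.  Tags are stored in
canonical orientation (the lexicographically smaller of the sequence and
its reverse complement), so a site found on either strand yields the same
tag.

The primary tag database keeps only tags occurring in exactly one species;
``T_i`` is the number of such species-specific tags of species *i* and is
the denominator of the profiler's abundance estimator.  A secondary
database recomputes specificity among a candidate subset only, which can
only grow each candidate's ``T_i``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._seq import TAG_LENGTH, canonical

__all__ = [
    "TagDatabase",
    "digest_genome",
    "build_tagdb",
    "build_secondary_db",
]

# Overlapping occurrences matter, hence the lookahead. N in the 6-bp spacer is
# tolerated by the motif but the resulting tag is dropped below.
_SITE_FWD = re.compile(r"(?=CGA[ACGTN]{6}TGC)")
_SITE_REV = re.compile(r"(?=GCA[ACGTN]{6}TCG)")

_FLANK = 10  # bp on each side of the 12-bp core


def digest_genome(sequence: str) -> list[str]:
    """Return one canonical 32-bp tag per recognition-site occurrence.

    Both strands are scanned (the reverse-strand core appears on the forward
    strand as GCA-N6-TCG).  Occurrences whose 32-bp window would run past a
    sequence end are skipped, as are windows containing N.  A sequence
    shorter than 32 bp yields an empty list.
    """
    sequence = sequence.upper()
    if not set(sequence) <= set("ACGTN"):
        raise ValueError("sequence alphabet must be {A,C,G,T,N}")
    tags: list[str] = []
    n = len(sequence)
    for pattern in (_SITE_FWD, _SITE_REV):
        for m in pattern.finditer(sequence):
            start = m.start() - _FLANK
            end = m.start() + TAG_LENGTH - _FLANK
            if start < 0 or end > n:
                continue
            window = sequence[start:end]
            if "N" in window:
                continue
            tags.append(canonical(window))
    return tags


@dataclass
class TagDatabase:
    """Species-specific tag database (primary or secondary scope).

    Attributes
    ----------
    tag_to_species:
        Mapping from canonical tag to the single species carrying it.
    tag_counts:
        ``T_i``: the number of distinct species-specific tags per species.
    scope:
        ``"primary"`` (specificity judged among all species) or
        ``"secondary"`` (among a candidate subset only).
    candidate_species:
        The candidate subset, for secondary databases.
    no_marker_species:
        Species left without any specific tag (listed, but carrying no
        ``T_i``); reads cannot be assigned to them.
    """

    tag_to_species: dict[str, str]
    tag_counts: dict[str, int]
    scope: str = "primary"
    candidate_species: tuple[str, ...] | None = None
    no_marker_species: tuple[str, ...] = ()
    # Full per-species digest (distinct canonical tags, before the
    # specificity filter); retained so secondary databases can be built by
    # set arithmetic without re-digesting genomes.
    species_tags: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for species, count in self.tag_counts.items():
            if count < 1:
                raise ValueError(f"T must be >= 1 for listed species ({species})")

    @property
    def species(self) -> list[str]:
        return sorted(self.tag_counts)

    def __len__(self) -> int:
        return len(self.tag_to_species)

    def write(self, outdir: str | Path) -> None:
        """Serialise as a sorted TSV (tag, species_id) plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = sorted(self.tag_to_species.items())
        pd.DataFrame(rows, columns=["tag", "species_id"]).to_csv(
            outdir / "tags.tsv", sep="\t", index=False
        )
        meta = {
            "scope": self.scope,
            "tag_counts": dict(sorted(self.tag_counts.items())),
            "candidate_species": sorted(self.candidate_species)
            if self.candidate_species is not None
            else None,
            "no_marker_species": sorted(self.no_marker_species),
        }
        (outdir / "db.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def read(cls, indir: str | Path) -> "TagDatabase":
        indir = Path(indir)
        tags = pd.read_csv(indir / "tags.tsv", sep="\t", dtype=str)
        meta = json.loads((indir / "db.json").read_text())
        return cls(
            tag_to_species=dict(zip(tags["tag"], tags["species_id"])),
            tag_counts={k: int(v) for k, v in meta["tag_counts"].items()},
            scope=meta["scope"],
            candidate_species=tuple(meta["candidate_species"])
            if meta["candidate_species"] is not None
            else None,
            no_marker_species=tuple(meta["no_marker_species"]),
        )


def _digest_all(genomes: Mapping[str, str]) -> dict[str, frozenset[str]]:
    """Distinct canonical tags per species (duplicates within a genome count once)."""
    return {sp: frozenset(digest_genome(seq)) for sp, seq in genomes.items()}


def _specific_db(
    digests: Mapping[str, frozenset[str]],
    scope: str,
    candidates: tuple[str, ...] | None,
) -> TagDatabase:
    owners: dict[str, str | None] = {}
    for sp in sorted(digests):
        for tag in digests[sp]:
            owners[tag] = sp if tag not in owners else None
    tag_to_species = {t: sp for t, sp in owners.items() if sp is not None}
    counts: dict[str, int] = {}
    for sp in tag_to_species.values():
        counts[sp] = counts.get(sp, 0) + 1
    flagged = tuple(sorted(set(digests) - set(counts)))
    return TagDatabase(
        tag_to_species=tag_to_species,
        tag_counts=counts,
        scope=scope,
        candidate_species=candidates,
        no_marker_species=flagged,
        species_tags=dict(digests),
    )


def build_tagdb(genomes: Mapping[str, str], taxonomy: pd.DataFrame) -> TagDatabase:
    """Digest all genomes and keep tags occurring in exactly one species.

    Species with no specific tag are flagged in ``no_marker_species``.
    Every species in ``genomes`` must appear in the taxonomy table.
    """
    if not genomes:
        raise ValueError("genomes must be nonempty")
    known = set(taxonomy["species_id"])
    missing = sorted(set(genomes) - known)
    if missing:
        raise ValueError(f"species absent from taxonomy: {missing}")
    return _specific_db(_digest_all(genomes), "primary", None)


def build_secondary_db(
    genomes: Mapping[str, str],
    candidates: Iterable[str],
    *,
    digests: Mapping[str, frozenset[str]] | None = None,
) -> TagDatabase:
    """Rebuild the database with specificity judged among candidates only.

    For every candidate the secondary ``T_i`` is at least its primary
    ``T_i``, because tags blocked only by non-candidate species become
    specific again.  ``digests`` may carry precomputed per-species tag sets
    (e.g. from a primary database) to avoid re-digesting genomes.
    """
    candidates = tuple(sorted(set(candidates)))
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    pool = digests if digests is not None else {}
    unknown = [sp for sp in candidates if sp not in pool and sp not in genomes]
    if unknown:
        raise ValueError(f"candidates absent from genomes: {unknown}")
    sub = {
        sp: pool[sp] if sp in pool else frozenset(digest_genome(genomes[sp]))
        for sp in candidates
    }
    return _specific_db(sub, "secondary", candidates)
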