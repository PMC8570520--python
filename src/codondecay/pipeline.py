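"""Orchestration helpers: intergenic extraction, triplet selection, config.

These operations sit upstream of the counting stage when working from
annotated chloroplast genome records: noncoding regions are the gaps between
annotated features on the forward strand (the model's complementation
machinery keeps counting strand-consistent), and genomes are grouped into
closely related triplets family by family so that no evolutionary branch is
sampled twice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("codondecay")

DEFAULT_FEATURE_TYPES = ("gene", "CDS", "tRNA", "rRNA")


def extract_intergenic(
    record, feature_types: tuple[str, ...] = DEFAULT_FEATURE_TYPES
) -> list[tuple[str, str]]:
    """Forward-strand gaps between consecutive annotated features.

    Coordinates are 0-based half-open internally (Biopython's convention).
    Zero-length gaps between abutting features are omitted; overlapping
    features produce no region and a warning.  A record without features
    yields an empty list.
    """
    spans = sorted(
        (int(f.location.start), int(f.location.end))
        for f in getattr(record, "features", [])
        if f.type in feature_types and f.location is not None
    )
    regions: list[tuple[str, str]] = []
    prev_end = None
    n = 0
    for start, end in spans:
        if prev_end is not None:
            if start < prev_end:
                logger.warning(
                    "%s: features overlap near position %d; no region emitted",
                    record.id, start,
                )
            elif start > prev_end:
                n += 1
                regions.append(
                    (f"{record.id}|ig{n:04d}", str(record.seq[prev_end:start]))
                )
        prev_end = end if prev_end is None else max(prev_end, end)
    return regions


@dataclass(frozen=True)
class TaxonRecord:
    accession: str
    family: str
    genus: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.family or not self.genus:
            raise ValueError(f"{self.accession}: family and genus are required")


def read_taxa_table(path) -> list[TaxonRecord]:
    """TSV with columns accession, family, genus[, species]."""
    taxa = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("accession\t"):
                continue
            parts = line.split("\t")
            taxa.append(TaxonRecord(*parts[:4]))
    return taxa


def select_triplets(
    taxa: list[TaxonRecord], rng: np.random.Generator
) -> list[tuple[str, str, str]]:
    """Group genomes into (ingroup1, ingroup2, outgroup) accession triplets.

    Within each family: every genus with at least two unused genomes
    contributes one random pair; one further pair is then drawn from the
    remaining genomes and the rest discarded.  Each pair receives an outgroup
    drawn at random from the family's other genomes.  No accession appears in
    more than one ingroup pair; families with fewer than three genomes
    contribute nothing.
    """
    by_family: dict[str, list[TaxonRecord]] = {}
    for t in taxa:
        by_family.setdefault(t.family, []).append(t)

    triplets: list[tuple[str, str, str]] = []
    for family in sorted(by_family):
        members = sorted(by_family[family], key=lambda t: t.accession)
        if len(members) < 3:
            logger.info("family %s has <3 genomes; skipped", family)
            continue
        used: set[str] = set()
        pairs: list[tuple[str, str]] = []

        by_genus: dict[str, list[TaxonRecord]] = {}
        for t in members:
            by_genus.setdefault(t.genus, []).append(t)
        for genus in sorted(by_genus):
            pool = [t for t in by_genus[genus] if t.accession not in used]
            if len(pool) >= 2:
                pick = rng.choice(len(pool), size=2, replace=False)
                pair = (pool[int(pick[0])].accession, pool[int(pick[1])].accession)
                pairs.append(pair)
                used.update(pair)

        remaining = [t for t in members if t.accession not in used]
        if len(remaining) >= 2:
            pick = rng.choice(len(remaining), size=2, replace=False)
            pair = (
                remaining[int(pick[0])].accession,
                remaining[int(pick[1])].accession,
            )
            pairs.append(pair)
            used.update(pair)

        for in1, in2 in pairs:
            outgroup_pool = [
                t.accession for t in members if t.accession not in (in1, in2)
            ]
            if not outgroup_pool:
                continue
            outg = outgroup_pool[int(rng.integers(len(outgroup_pool)))]
            triplets.append((in1, in2, outg))
    return triplets


@dataclass
class PipelineConfig:
    """File paths, simulation settings and per-gene dN/dS for a full run."""

    seed: int = 0
    mode: str = "syn_only"
    n_mutations: int = 500
    record_every: int = 5
    replicates: int = 1000
    dnds: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    aligner: str | None = None
    min_region_len: int = 70
    target_max_rate: float = 1.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
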