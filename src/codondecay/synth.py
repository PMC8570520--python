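"""Synthetic inputs: triplet alignments under a known model, biased genes.

Every input class the pipeline consumes can be generated here under
controlled conditions, so counting, model building, simulation and the
overlay are all testable end to end without any external data.  Triplet
regions are evolved forward from a stationary-composition root along three
independent branches with the same proposal kernel the decay simulator uses
(uniform site, context-dependent row draw, self-mutations discarded), at
branch lengths small enough that multiple hits are rare — matching the
sub-percent divergence regime real triplets are selected for.  Coding
sequences are drawn with a tunable bias strength beta: within each
synonymous family a codon is picked with probability proportional to
w(codon)^beta, so beta = 0 gives uniform synonymous usage and large beta
gives a maximally adapted gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cai import FAMILIES, CodingSequence, FitnessTable
from .counting import BASES, CANONICAL_CONTEXTS, TripletAlignment
from .models import MutationModel, stationary_vector
from .simulate import _cumulative_rows


@dataclass
class SyntheticTripletSpec:
    """Conditions for generating noncoding triplet alignments.

    Branch expectations default to the sub-percent regime of real chloroplast
    triplets (ingroup pair divergence around 0.6%), where multiple hits per
    site are essentially absent.
    """

    n_regions: int = 50
    region_length: int = 2000
    ingroup_subs_per_site: float = 0.003
    outgroup_subs_per_site: float = 0.006
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.ingroup_subs_per_site, self.outgroup_subs_per_site):
            if not 0 <= rate <= 0.01:
                raise ValueError(
                    "branch expectations above 0.01 subs/site leave the "
                    "low-divergence regime this generator emulates"
                )


@dataclass
class SyntheticGeneSpec:
    """Conditions for generating a coding sequence with controlled bias."""

    n_codons: int = 300
    beta: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("bias strength beta must be >= 0")
        if self.n_codons < 2:
            raise ValueError("need at least 2 codons")


def evolve_neutral(
    seq: str,
    model: MutationModel,
    expected_subs_per_site: float,
    rng: np.random.Generator,
) -> str:
    """Mutate a copy of ``seq`` with the simulator's proposal kernel.

    The accepted-change target is Poisson with mean expectation x mutable
    sites; proposals draw a uniform site (terminal bases excluded, as they
    have no two-sided context), sample the context-dependent row, and discard
    self-mutations.  Every real change is accepted — no coding constraints.
    """
    if expected_subs_per_site < 0:
        raise ValueError("expectation must be non-negative")
    ints = [BASES.index(b) for b in seq.upper()]
    n_mutable = len(ints) - 2
    if n_mutable <= 0 or expected_subs_per_site == 0:
        return seq
    target = int(rng.poisson(expected_subs_per_site * n_mutable))
    cum = _cumulative_rows(model)
    length = len(ints)
    accepted = 0
    batch = 4096
    idx = batch
    sites: list[int] = []
    us: list[float] = []
    while accepted < target:
        if idx >= batch:
            sites = rng.integers(1, length - 1, size=batch).tolist()
            us = rng.random(batch).tolist()
            idx = 0
        site = sites[idx]
        u = us[idx]
        idx += 1
        c = ints[site]
        row = cum[ints[site - 1]][ints[site + 1]][c]
        if u < row[1]:
            d = 0 if u < row[0] else 1
        else:
            d = 2 if u < row[2] else 3
        if d == c:
            continue
        ints[site] = d
        accepted += 1
    return "".join(BASES[i] for i in ints)


def mean_stationary_composition(model: MutationModel) -> np.ndarray:
    """Stationary base frequencies averaged over all 16 contexts."""
    total = np.zeros(4)
    for ctx in CANONICAL_CONTEXTS:
        pi = stationary_vector(model.matrices[ctx])
        total += pi
        total += pi[::-1]  # the complementary context's stationary vector
    total /= total.sum()
    return total


def generate_triplets(
    spec: SyntheticTripletSpec, model: MutationModel
) -> list[TripletAlignment]:
    """Evolve triplet regions on a star: root -> in1, in2, outgroup.

    No indels are introduced, so the three sequences are trivially aligned.
    """
    rng = np.random.default_rng(spec.seed)
    comp = mean_stationary_composition(model)
    triplets = []
    for r in range(spec.n_regions):
        root = "".join(
            BASES[i] for i in rng.choice(4, size=spec.region_length, p=comp)
        )
        triplets.append(
            TripletAlignment(
                region_id=f"region{r + 1:04d}",
                in1=evolve_neutral(root, model, spec.ingroup_subs_per_site, rng),
                in2=evolve_neutral(root, model, spec.ingroup_subs_per_site, rng),
                outg=evolve_neutral(root, model, spec.outgroup_subs_per_site, rng),
            )
        )
    return triplets


def generate_coding(
    spec: SyntheticGeneSpec, table: FitnessTable, gene_id: str = "synthetic"
) -> CodingSequence:
    """Draw a random protein, then codons within families with weight w^beta."""
    rng = np.random.default_rng(spec.seed)
    amino_acids = sorted(FAMILIES)
    residues = rng.choice(len(amino_acids), size=spec.n_codons)
    codons = []
    for r in residues:
        family = FAMILIES[amino_acids[int(r)]]
        if len(family) == 1:
            codons.append(family[0])
            continue
        w = np.array([table.w.get(c, 1.0) for c in family])
        weights = (w / w.max()) ** spec.beta
        weights /= weights.sum()
        codons.append(family[int(rng.choice(len(family), p=weights))])
    return CodingSequence(gene_id, "".join(codons))


def random_context_model(
    rng: np.random.Generator, min_rate: float = 0.3, max_rate: float = 1.0
) -> MutationModel:
    """A random but well-behaved 10-matrix context-dependent model.

    Each row's off-diagonal spectrum is Dirichlet-distributed and its total
    off-diagonal mass uniform on [min_rate, max_rate]; all rates strictly
    positive, so every matrix is irreducible.  Intended for parameter-recovery
    and property tests where the ground truth must be known.
    """
    matrices = {}
    for ctx in CANONICAL_CONTEXTS:
        m = np.zeros((4, 4))
        for i in range(4):
            rate = rng.uniform(min_rate, max_rate)
            spectrum = rng.dirichlet([2.0, 2.0, 2.0])
            cols = [j for j in range(4) if j != i]
            m[i, cols] = rate * spectrum
            m[i, i] = 1.0 - rate
        matrices[ctx] = m
    return MutationModel(matrices, kind="synthetic")


def example_fitness_table() -> FitnessTable:
    """A deterministic fitness table with one major codon per family.

    Within each family (codons in alphabetical order) w falls geometrically
    from 1, floored at 0.08 — a caricature of strong codon adaptation useful
    as a fixed reference in tests and demonstrations.
    """
    w = {}
    for codons in FAMILIES.values():
        scored = [c for c in codons if c not in ("ATG", "TGG")]
        for rank, codon in enumerate(sorted(scored)):
            w[codon] = max(0.08, 0.5**rank)
    return FitnessTable(w, pseudocount=0.5)
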