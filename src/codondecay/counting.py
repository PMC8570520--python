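"""Context-dependent substitution counting from noncoding triplet alignments.

Mutation dynamics in plant chloroplast DNA depend strongly on the identity of
the two bases flanking a site.  To estimate those dynamics without assuming a
model, aligned noncoding regions from triplets of closely related genomes (two
ingroup taxa plus an outgroup) are scored column by column: at every site whose
immediate 5' and 3' neighbours are identical across all three sequences, a
conserved ingroup pair adds one count to the diagonal of the 4x4 count matrix
for that flanking context, while an ingroup difference polarised by the
outgroup adds one ancestral->derived count off the diagonal.  Complementary
contexts are then merged, leaving 10 canonical matrices that serve all 16
contexts in a strand-specific analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 10 contexts kept after merging each context with its reverse complement
CANONICAL_CONTEXTS = (
    "A_A", "A_T", "T_A", "A_C", "A_G", "C_A", "G_A", "C_C", "C_G", "G_C",
)
ALL_CONTEXTS = tuple(f"{f}_{t}" for f in BASES for t in BASES)
SELF_COMPLEMENTARY = frozenset(("A_T", "T_A", "C_G", "G_C"))

# char -> base index; anything outside ACGT (gaps, IUPAC ambiguity) maps to -1
_CHAR2INT = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CHAR2INT[ord(_b)] = _i
    _CHAR2INT[ord(_b.lower())] = _i


def complement_context(context: str) -> str:
    """Reverse-complement a context key: comp(N5_N3) = comp(N3)_comp(N5)."""
    five, three = context.split("_")
    return f"{COMPLEMENT[three]}_{COMPLEMENT[five]}"


def canonical_context(context: str) -> str:
    """Map any of the 16 contexts onto its canonical representative."""
    return context if context in CANONICAL_CONTEXTS else complement_context(context)


def complement_transform(matrix: np.ndarray) -> np.ndarray:
    """Relabel a 4x4 base-change matrix by complementing rows and columns.

    With the A,C,G,T index order, complementation is index reversal, so the
    transform is ``M[::-1, ::-1]``.  It is an involution.
    """
    return np.asarray(matrix)[::-1, ::-1].copy()


@dataclass
class TripletAlignment:
    """One aligned noncoding region: two ingroup sequences plus an outgroup."""

    region_id: str
    in1: str
    in2: str
    outg: str

    def __post_init__(self) -> None:
        if not (len(self.in1) == len(self.in2) == len(self.outg)):
            raise ValueError(
                f"region {self.region_id!r}: aligned lengths differ "
                f"({len(self.in1)}, {len(self.in2)}, {len(self.outg)})"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.in1)

    @property
    def ungapped_length(self) -> int:
        """Ungapped length of the shortest member (the region's source length)."""
        return min(
            sum(c != "-" for c in seq) for seq in (self.in1, self.in2, self.outg)
        )


def triplet_from_fasta(path, region_id: str | None = None) -> TripletAlignment:
    """Read a three-record aligned FASTA (order: ingroup1, ingroup2, outgroup)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise ValueError(f"{path}: expected exactly 3 records, found {len(records)}")
    rid = region_id if region_id is not None else records[0].id
    return TripletAlignment(rid, *(str(r.seq) for r in records))


def _empty_raw() -> dict[str, np.ndarray]:
    return {ctx: np.zeros((4, 4), dtype=np.int64) for ctx in ALL_CONTEXTS}


def score_triplet(
    aln: TripletAlignment, min_region_len: int = 70
) -> dict[str, np.ndarray]:
    """Score one triplet alignment into 16 context-keyed 4x4 count matrices.

    Only regions whose ungapped length exceeds ``min_region_len`` are scored
    (strict inequality).  A column contributes only when its two flanking
    columns are identical A/C/G/T bases across all three sequences and the
    focal column itself is A/C/G/T in all three.  Conserved ingroup pairs are
    tallied on the diagonal; an ingroup difference is polarised by the
    outgroup (counted ancestral->derived when the outgroup matches one ingroup
    base, ignored when all three differ).
    """
    raw = _empty_raw()
    if aln.ungapped_length <= min_region_len or aln.aligned_length < 3:
        return raw

    a = _CHAR2INT[np.frombuffer(aln.in1.encode("ascii"), dtype=np.uint8)]
    b = _CHAR2INT[np.frombuffer(aln.in2.encode("ascii"), dtype=np.uint8)]
    o = _CHAR2INT[np.frombuffer(aln.outg.encode("ascii"), dtype=np.uint8)]

    aL, bL, oL = a[:-2], b[:-2], o[:-2]
    aM, bM, oM = a[1:-1], b[1:-1], o[1:-1]
    aR, bR, oR = a[2:], b[2:], o[2:]

    context_ok = (
        (aL >= 0) & (aL == bL) & (aL == oL)
        & (aR >= 0) & (aR == bR) & (aR == oR)
    )
    focal_ok = (aM >= 0) & (bM >= 0) & (oM >= 0)
    usable = context_ok & focal_ok

    conserved = usable & (aM == bM)
    differs = usable & (aM != bM)
    anc_is_a = differs & (oM == aM)
    anc_is_b = differs & (oM == bM)

    tensor = np.zeros((4, 4, 4, 4), dtype=np.int64)  # (five, three, anc, der)
    np.add.at(tensor, (aL[conserved], aR[conserved], aM[conserved], aM[conserved]), 1)
    np.add.at(tensor, (aL[anc_is_a], aR[anc_is_a], aM[anc_is_a], bM[anc_is_a]), 1)
    np.add.at(tensor, (aL[anc_is_b], aR[anc_is_b], bM[anc_is_b], aM[anc_is_b]), 1)

    for fi, five in enumerate(BASES):
        for ti, three in enumerate(BASES):
            raw[f"{five}_{three}"] = tensor[fi, ti].copy()
    return raw


def score_triplets(
    alns: Iterable[TripletAlignment], min_region_len: int = 70
) -> dict[str, np.ndarray]:
    """Sum raw context count matrices over many triplet alignments."""
    total = _empty_raw()
    for aln in alns:
        for ctx, m in score_triplet(aln, min_region_len).items():
            total[ctx] += m
    return total


@dataclass
class SubstitutionCounts:
    """The 10 canonical context-dependent substitution count matrices."""

    matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ctx in CANONICAL_CONTEXTS:
            self.matrices.setdefault(ctx, np.zeros((4, 4), dtype=np.int64))
        extra = set(self.matrices) - set(CANONICAL_CONTEXTS)
        if extra:
            raise ValueError(f"non-canonical contexts present: {sorted(extra)}")

    @property
    def total_sites(self) -> int:
        return int(sum(m.sum() for m in self.matrices.values()))

    @property
    def total_substitutions(self) -> int:
        return int(
            sum(m.sum() - np.trace(m) for m in self.matrices.values())
        )

    @property
    def substitution_fraction(self) -> float:
        return self.total_substitutions / self.total_sites if self.total_sites else 0.0

    def to_json(self) -> str:
        payload = {
            "contexts": {
                ctx: self.matrices[ctx].tolist() for ctx in CANONICAL_CONTEXTS
            },
            "total_sites": self.total_sites,
            "total_substitutions": self.total_substitutions,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SubstitutionCounts":
        payload = json.loads(text)
        matrices = {
            ctx: np.asarray(grid, dtype=np.int64)
            for ctx, grid in payload["contexts"].items()
        }
        return cls(matrices)

    def to_tsv(self) -> str:
        lines = []
        for ctx in CANONICAL_CONTEXTS:
            lines.append(f"#context\t{ctx}")
            lines.append("\t" + "\t".join(BASES))
            for i, base in enumerate(BASES):
                row = "\t".join(str(int(v)) for v in self.matrices[ctx][i])
                lines.append(f"{base}\t{row}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "SubstitutionCounts":
        matrices: dict[str, np.ndarray] = {}
        ctx = None
        rows: list[list[int]] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#context"):
                if ctx is not None:
                    matrices[ctx] = np.asarray(rows, dtype=np.int64)
                ctx = line.split("\t")[1]
                rows = []
            elif not line.startswith("\t"):
                rows.append([int(v) for v in line.split("\t")[1:]])
        if ctx is not None:
            matrices[ctx] = np.asarray(rows, dtype=np.int64)
        return cls(matrices)


def merge_complements(raw: Mapping[str, np.ndarray]) -> SubstitutionCounts:
    """Merge the 16 raw context matrices into the 10 canonical ones.

    Each non-self-complementary canonical matrix receives the complement
    transform of its partner context's matrix; the four self-complementary
    contexts pass through unchanged.  Total counts are conserved.
    """
    merged: dict[str, np.ndarray] = {}
    for ctx in CANONICAL_CONTEXTS:
        m = np.asarray(
            raw.get(ctx, np.zeros((4, 4), dtype=np.int64)), dtype=np.int64
        ).copy()
        if ctx not in SELF_COMPLEMENTARY:
            partner = raw.get(complement_context(ctx))
            if partner is not None:
                m += complement_transform(np.asarray(partner, dtype=np.int64))
        merged[ctx] = m
    return SubstitutionCounts(merged)


def read_manifest(path) -> list[TripletAlignment]:
    """Read a TSV manifest (region_id <tab> fasta_path) of triplet alignments."""
    alns = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            region_id, fasta_path = line.split("\t")[:2]
            alns.append(triplet_from_fasta(fasta_path, region_id))
    return alns
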