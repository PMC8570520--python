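"""Codon Adaptation Index, fitness tables, and ambiguity resolution.

Relative adaptiveness (w) of each codon is estimated from reference genes
believed to be under strong selection for translational efficiency: within
each synonymous family, w is the codon's count relative to the most-used
synonym, with a pseudocount guarding unobserved codons.  The CAI of a gene is
then the geometric mean of w over its codons, excluding the single-codon
families (Met, Trp) and stops, so CAI = 1 means every codon is the major
codon of its family.

The same fitness values drive the resolution of IUPAC ambiguities in
parsimony-reconstructed ancestral sequences to the lowest- or highest-fitness
synonymous codon (MP-Low / MP-High), bracketing the ancestral level of codon
adaptation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable

from Bio.Data import CodonTable, IUPACData

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for stops
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
#: single-codon families plus stops: never scored by CAI
EXCLUDED_CODONS = frozenset({"ATG", "TGG"}) | STOP_CODONS

#: amino acid -> codons, sixfold families (Leu/Ser/Arg) kept whole
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        FAMILIES.setdefault(_aa, ())
        FAMILIES[_aa] += (_codon,)

_AMBIG = {
    code: tuple(sorted(bases))
    for code, bases in IUPACData.ambiguous_dna_values.items()
}


@dataclass
class CodingSequence:
    """An in-frame nucleotide sequence (no internal stops)."""

    id: str
    nt: str

    def __post_init__(self) -> None:
        self.nt = self.nt.upper()
        if len(self.nt) % 3:
            raise ValueError(f"{self.id}: length {len(self.nt)} not divisible by 3")
        bad = set(self.nt) - set("ACGT")
        if bad:
            raise ValueError(f"{self.id}: non-ACGT symbols {sorted(bad)}")
        for aa in self.translation[:-1]:
            if aa == "*":
                raise ValueError(f"{self.id}: internal stop codon")

    @property
    def length(self) -> int:
        return len(self.nt)

    @property
    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]

    @property
    def translation(self) -> str:
        return "".join(CODON_TO_AA[c] for c in self.codons)


@dataclass
class AmbiguousSequence:
    """In-frame sequence over IUPAC codes, e.g. a parsimony ancestral state."""

    id: str
    nt: str

    def __post_init__(self) -> None:
        self.nt = self.nt.upper()
        if len(self.nt) % 3:
            raise ValueError(f"{self.id}: length {len(self.nt)} not divisible by 3")
        bad = set(self.nt) - set(_AMBIG)
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC symbols {sorted(bad)}")


@dataclass
class FitnessTable:
    """Per-codon relative adaptiveness w in (0, 1]."""

    w: dict[str, float]
    pseudocount: float = 0.5
    excluded: frozenset = field(default=EXCLUDED_CODONS)

    def __post_init__(self) -> None:
        for codon, value in self.w.items():
            if not 0 < value <= 1:
                raise ValueError(f"w({codon}) = {value} outside (0, 1]")
            if codon in self.excluded:
                raise ValueError(f"excluded codon {codon} present in table")

    def log_w(self, codon: str) -> float | None:
        value = self.w.get(codon)
        return math.log(value) if value is not None else None

    def to_tsv(self) -> str:
        lines = [f"{codon}\t{self.w[codon]!r}" for codon in sorted(self.w)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, pseudocount: float = 0.5) -> "FitnessTable":
        w = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            codon, value = line.split("\t")[:2]
            w[codon] = float(value)
        return cls(w, pseudocount=pseudocount)

    def to_json(self) -> str:
        return json.dumps({"pseudocount": self.pseudocount, "w": self.w}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FitnessTable":
        payload = json.loads(text)
        return cls(payload["w"], pseudocount=payload.get("pseudocount", 0.5))


def fitness_from_reference(
    refs: Iterable[CodingSequence], pseudocount: float = 0.5
) -> FitnessTable:
    """Estimate w from pooled codon counts of highly adapted reference genes.

    Within each synonymous family, w(c) = (count(c) + pseudocount) /
    (max family count + pseudocount), so the majority codon has w = 1 and
    unobserved codons get a small positive value.  Met, Trp and stop codons
    are omitted.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("at least one reference sequence is required")
    counts: dict[str, int] = {}
    for ref in refs:
        for codon in ref.codons:
            counts[codon] = counts.get(codon, 0) + 1

    w: dict[str, float] = {}
    for codons in FAMILIES.values():
        scored = [c for c in codons if c not in EXCLUDED_CODONS]
        if not scored:
            continue
        family_counts = {c: counts.get(c, 0) for c in scored}
        top = max(family_counts.values())
        if top == 0:
            continue  # family absent from the references: no w estimable
        for codon, n in family_counts.items():
            w[codon] = (n + pseudocount) / (top + pseudocount)
    return FitnessTable(w, pseudocount=pseudocount)


def cai(seq: CodingSequence, table: FitnessTable) -> float:
    """Geometric mean of w over the sequence's scorable codons."""
    if not table.w:
        raise ValueError("empty fitness table")
    total = 0.0
    n = 0
    for codon in seq.codons:
        lw = table.log_w(codon)
        if lw is not None:
            total += lw
            n += 1
    if n == 0:
        raise ValueError(f"{seq.id}: no scorable codons")
    return math.exp(total / n)


def _resolution_w(codon_pattern: str, table: FitnessTable, mode: str) -> float | None:
    """Extreme w over full expansions of a possibly-ambiguous codon pattern.

    Stops are disallowed; excluded non-stop codons (ATG, TGG) count as w = 1,
    being the only codon of their family.  Returns None if every expansion is
    a stop.
    """
    values = []
    for bases in product(*(_AMBIG[c] for c in codon_pattern)):
        codon = "".join(bases)
        if codon in STOP_CODONS:
            continue
        values.append(table.w.get(codon, 1.0))
    if not values:
        return None
    return max(values) if mode == "high" else min(values)


def resolve_ambiguities(
    seq: AmbiguousSequence, table: FitnessTable, mode: str
) -> CodingSequence:
    """Resolve IUPAC codes to the lowest- or highest-fitness codon per site.

    Sites are visited left to right.  Each candidate base at a site is scored
    by the w of the codon it produces — taking the mode-extreme w over
    expansions of any ambiguities remaining later in the same codon — and the
    best (mode='high') or worst (mode='low') candidate wins, excluding
    candidates whose every completion is a stop.  Ties go to the
    alphabetically earlier base.
    """
    if mode not in ("high", "low"):
        raise ValueError(f"mode must be 'high' or 'low', got {mode!r}")
    resolved = list(seq.nt)
    for pos, code in enumerate(resolved):
        if code in "ACGT":
            continue
        start = 3 * (pos // 3)
        offset = pos - start
        best_base, best_w = None, None
        for base in _AMBIG[code]:  # alphabetical: first win is the tie-break
            pattern = resolved[start : start + 3]
            pattern[offset] = base
            value = _resolution_w("".join(pattern), table, mode)
            if value is None:
                continue  # every completion stops: base disallowed
            better = (
                best_w is None
                or (mode == "high" and value > best_w)
                or (mode == "low" and value < best_w)
            )
            if better:
                best_base, best_w = base, value
        if best_base is None:
            raise ValueError(
                f"{seq.id}: position {pos + 1}: all expansions produce stop codons"
            )
        resolved[pos] = best_base
    return CodingSequence(f"{seq.id}|MP-{mode}", "".join(resolved))
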