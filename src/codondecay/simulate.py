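"""Neutral decay simulation of codon adaptation.

Starting from a reconstructed ancestral coding sequence, mutations are
introduced one at a time by a two-step kernel.  Step one proposes: a site is
drawn uniformly over the mutable positions, the context-dependent probability
row for its current base (given its two flanking bases) is sampled, and a
draw landing on the diagonal — a "mutation" from a base to itself — is
discarded, which is what converts the non-zero diagonals into per-base and
per-context rate variation.  Step two selects: synonymous changes are always
accepted; nonsynonymous changes are discarded outright in synonymous-only
mode, while in the nonsynonymous mode they must be to an amino acid observed
at that site in an alignment of extant taxa ("acceptable" replacements) and
then pass a coin flip with probability dN/dS.  Stop-creating changes are
never accepted.  CAI is recorded every ``record_every`` accepted mutations,
and trajectories are averaged over replicates.

Because selection here acts only through the accept/reject rules — never on
synonymous codon choice — the recorded decay is the neutral expectation
against which extant genes are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .cai import CODON_TO_AA, CodingSequence, FitnessTable, cai
from .counting import BASES
from .models import MutationModel

_AA_LIST = sorted({aa for aa in CODON_TO_AA.values() if aa != "*"})
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_LIST)}

#: codon rank (16*b0 + 4*b1 + b2) -> amino-acid index, -1 for stops
AA64 = [
    _AA_INDEX.get(CODON_TO_AA["".join(c)], -1)
    for c in product(BASES, repeat=3)
]


@dataclass
class AcceptableReplacements:
    """Per amino-acid site, the residues observed across extant taxa."""

    sites: list[frozenset[str]]

    def __post_init__(self) -> None:
        if any(not s for s in self.sites):
            raise ValueError("every site must have a non-empty residue set")

    def __len__(self) -> int:
        return len(self.sites)

    def __getitem__(self, i: int) -> frozenset:
        return self.sites[i]

    @classmethod
    def everything(cls, n_sites: int) -> "AcceptableReplacements":
        """Permissive set: any residue acceptable at any site."""
        all_aa = frozenset(_AA_LIST)
        return cls([all_aa] * n_sites)


def acceptable_from_alignment(
    aa_alignment: Sequence[str],
) -> AcceptableReplacements:
    """Column-wise sets of non-gap residues from an amino-acid alignment."""
    rows = [r.upper() for r in aa_alignment]
    if not rows:
        raise ValueError("empty amino-acid alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    sites = []
    for col in range(width):
        residues = frozenset(r[col] for r in rows) - {"-", "X", "*"}
        if not residues:
            raise ValueError(f"column {col + 1} contains no residues")
        sites.append(residues)
    return AcceptableReplacements(sites)


@dataclass
class SimulationConfig:
    """Everything a decay run needs besides the sequences themselves."""

    model: MutationModel
    mode: str = "syn_only"
    dnds: float | None = None
    n_mutations: int = 500
    record_every: int = 5
    replicates: int = 1000
    seed: int = 0
    proposal_cap: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("syn_only", "with_nonsyn"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "with_nonsyn":
            if self.dnds is None or not 0 <= self.dnds <= 1:
                raise ValueError("with_nonsyn mode requires dnds in [0, 1]")
        elif self.dnds is not None:
            raise ValueError("dnds is only meaningful in with_nonsyn mode")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be non-negative")
        if self.n_mutations and self.n_mutations % self.record_every:
            raise ValueError("record_every must divide n_mutations")

    @property
    def checkpoints(self) -> np.ndarray:
        if self.n_mutations == 0:
            return np.array([0])
        return np.arange(0, self.n_mutations + 1, self.record_every)

    @property
    def effective_cap(self) -> int:
        if self.proposal_cap is not None:
            return self.proposal_cap
        return 10_000 * max(self.n_mutations, 1) + 100_000


@dataclass
class Trajectory:
    """Mean and SD of CAI at accepted-mutation checkpoints over replicates."""

    checkpoints: np.ndarray
    mean_cai: np.ndarray
    sd_cai: np.ndarray
    replicates: int
    stats: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = [f"#replicates\t{self.replicates}", "checkpoint\tmean_cai\tsd_cai"]
        for k, m, s in zip(self.checkpoints, self.mean_cai, self.sd_cai):
            lines.append(f"{int(k)}\t{float(m)!r}\t{float(s)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Trajectory":
        replicates = 0
        rows = []
        for line in text.splitlines():
            if line.startswith("#replicates"):
                replicates = int(line.split("\t")[1])
            elif line and not line.startswith(("#", "checkpoint")):
                k, m, s = line.split("\t")
                rows.append((int(k), float(m), float(s)))
        ck, mean, sd = (np.array(v) for v in zip(*rows))
        return cls(ck.astype(int), mean, sd, replicates)


def _cumulative_rows(model: MutationModel) -> list:
    """dense() as nested lists of cumulative 4-tuples for fast inner-loop use."""
    dense = model.dense()
    cum = np.cumsum(dense, axis=3)
    cum[..., 3] = 1.0 + 1e-12  # guard against u landing beyond fp round-off
    return [
        [[tuple(cum[f, t, c]) for c in range(4)] for t in range(4)]
        for f in range(4)
    ]


def _prepare(ancestor: CodingSequence, table: FitnessTable):
    seq = [BASES.index(b) for b in ancestor.nt]
    logw64: list[float | None] = [None] * 64
    for codon, value in table.w.items():
        k = 16 * BASES.index(codon[0]) + 4 * BASES.index(codon[1]) + BASES.index(codon[2])
        logw64[k] = math.log(value)
    return seq, logw64


def simulate_replicate(
    ancestor: CodingSequence,
    table: FitnessTable,
    acc: AcceptableReplacements | None,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    collect_stats: bool = False,
    return_final: bool = False,
):
    """One replicate: CAI at each checkpoint.

    With ``collect_stats`` the acceptance counters are appended to the return
    tuple; with ``return_final`` the replicate's final sequence is appended.
    """
    seq, logw64 = _prepare(ancestor, table)
    cum = _cumulative_rows(cfg.model)
    acc_sets = _acceptance_sets(ancestor, acc, cfg)
    values, stats = _run(seq, logw64, cum, acc_sets, cfg, rng)
    out = [np.asarray(values)]
    if collect_stats:
        out.append(stats)
    if return_final:
        final = "".join(BASES[i] for i in seq)
        out.append(CodingSequence(f"{ancestor.id}|final", final))
    return out[0] if len(out) == 1 else tuple(out)


def _acceptance_sets(ancestor, acc, cfg):
    if cfg.mode == "syn_only":
        return None
    n_codons = ancestor.length // 3
    if acc is None:
        raise ValueError("with_nonsyn mode requires acceptable replacements")
    if len(acc) != n_codons:
        raise ValueError(
            f"acceptable-replacement list covers {len(acc)} sites, "
            f"gene has {n_codons} codons"
        )
    protein = ancestor.translation
    sets = []
    for i in range(n_codons):
        aa = protein[i]
        if aa != "*" and aa not in acc[i]:
            raise ValueError(
                f"site {i + 1}: ancestral residue {aa} missing from its "
                "acceptable set"
            )
        sets.append(frozenset(_AA_INDEX[r] for r in acc[i] if r in _AA_INDEX))
    return sets


_POW = (16, 4, 1)


def _run(seq, logw64, cum, acc_sets, cfg, rng):
    length = len(seq)
    if length < 6:
        raise ValueError("sequence too short to simulate (need >= 2 codons)")
    syn_only = cfg.mode == "syn_only"
    dnds = cfg.dnds or 0.0
    record_every = cfg.record_every
    cap = cfg.effective_cap
    aa64 = AA64

    sum_logw = 0.0
    n_scored = 0
    for i in range(0, length, 3):
        lw = logw64[16 * seq[i] + 4 * seq[i + 1] + seq[i + 2]]
        if lw is not None:
            sum_logw += lw
            n_scored += 1
    if n_scored == 0:
        raise ValueError("ancestor has no scorable codons")

    values = [math.exp(sum_logw / n_scored)]
    n_acc = 0
    proposals = 0
    stats = {
        "proposals": 0,
        "self_discards": 0,
        "syn_accepted": 0,
        "stop_discards": 0,
        "nonsyn_blocked": 0,
        "nonsyn_offered": 0,
        "nonsyn_accepted": 0,
    }

    batch = 8192
    sites: list[int] = []
    us: list[float] = []
    idx = batch

    while n_acc < cfg.n_mutations:
        if idx >= batch:
            sites = rng.integers(1, length - 1, size=batch).tolist()
            us = rng.random(batch).tolist()
            idx = 0
        site = sites[idx]
        u = us[idx]
        idx += 1
        proposals += 1
        if proposals > cap:
            raise RuntimeError(
                f"proposal cap {cap} reached after {n_acc} accepted mutations; "
                "the sequence may admit no further acceptable change"
            )

        c = seq[site]
        row = cum[seq[site - 1]][seq[site + 1]][c]
        if u < row[1]:
            d = 0 if u < row[0] else 1
        else:
            d = 2 if u < row[2] else 3
        if d == c:
            stats["self_discards"] += 1
            continue

        start = site - site % 3
        k0 = 16 * seq[start] + 4 * seq[start + 1] + seq[start + 2]
        k1 = k0 + (d - c) * _POW[site - start]
        aa0 = aa64[k0]
        aa1 = aa64[k1]
        if aa1 < 0:  # stop codon: never acceptable
            stats["stop_discards"] += 1
            continue
        if aa1 != aa0:
            if syn_only:
                stats["nonsyn_blocked"] += 1
                continue
            if aa1 not in acc_sets[start // 3]:
                stats["nonsyn_blocked"] += 1
                continue
            stats["nonsyn_offered"] += 1
            if rng.random() >= dnds:
                continue
            stats["nonsyn_accepted"] += 1
        else:
            stats["syn_accepted"] += 1

        seq[site] = d
        lw0 = logw64[k0]
        lw1 = logw64[k1]
        if lw0 is not None:
            sum_logw -= lw0
            n_scored -= 1
        if lw1 is not None:
            sum_logw += lw1
            n_scored += 1
        n_acc += 1
        if n_acc % record_every == 0:
            values.append(math.exp(sum_logw / n_scored))

    stats["proposals"] = proposals
    return values, stats


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Counter-based per-replicate stream: independent and reproducible."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def simulate(
    ancestor: CodingSequence,
    table: FitnessTable,
    acc: AcceptableReplacements | None,
    cfg: SimulationConfig,
    return_replicates: bool = False,
):
    """Run all replicates and aggregate CAI mean and SD per checkpoint.

    Checkpoint 0 is the ancestor's CAI exactly with SD 0; SDs are sample
    standard deviations (ddof=1) across replicates.
    """
    checkpoints = cfg.checkpoints
    matrix = np.empty((cfg.replicates, len(checkpoints)))
    totals: dict[str, int] = {}
    for rep in range(cfg.replicates):
        values, stats = simulate_replicate(
            ancestor, table, acc, cfg, replicate_rng(cfg.seed, rep),
            collect_stats=True,
        )
        matrix[rep] = values
        for key, val in stats.items():
            totals[key] = totals.get(key, 0) + val

    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if cfg.replicates > 1 else np.zeros_like(mean)
    ancestral_cai = cai(ancestor, table)
    mean[0] = ancestral_cai  # exact by construction; enforce against fp noise
    sd[0] = 0.0
    traj = Trajectory(checkpoints, mean, sd, cfg.replicates, stats=totals)
    if return_replicates:
        return traj, matrix
    return traj
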