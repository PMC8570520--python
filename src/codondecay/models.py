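"""Context-dependent probability matrices, stationary vectors and summaries.

A substitution count matrix becomes a probability matrix by dividing each row
by its total: off-diagonal entries give the relative probability of each
base change, while the non-zero diagonal (the probability of proposing "no
change") encodes per-base rate variation.  A single global rescaling then
makes the fastest row's off-diagonal mass equal to ``target_max_rate`` while
preserving every relative rate, which minimises rejected self-mutations in
the decay simulator without altering the process being simulated.

Each probability matrix is a Markov transition matrix; its stationary vector
pi (pi P = pi), found by raising P to growing powers until the rows agree,
is the equilibrium base composition a neutrally evolving site would reach in
that flanking context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import (
    BASES,
    CANONICAL_CONTEXTS,
    SubstitutionCounts,
    canonical_context,
)

TRANSITION_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T


@dataclass
class MutationModel:
    """Canonical context -> 4x4 row-stochastic matrix, plus model metadata.

    ``matrices`` holds the 10 canonical contexts; lookups for the other six
    go through complementation.  Context-independent models (e.g. K2P) store
    the same matrix under every canonical key.
    """

    matrices: dict[str, np.ndarray]
    kind: str = "MC2020"
    normalization_scale: float = 1.0

    def __post_init__(self) -> None:
        missing = set(CANONICAL_CONTEXTS) - set(self.matrices)
        if missing:
            raise ValueError(f"missing canonical contexts: {sorted(missing)}")
        for ctx, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (4, 4):
                raise ValueError(f"{ctx}: matrix must be 4x4")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{ctx}: rows must sum to 1")
            self.matrices[ctx] = m

    def row(self, five_prime: str, three_prime: str, current: str) -> np.ndarray:
        """Probability row for ``current`` in context five_prime_three_prime.

        Non-canonical contexts resolve through the complement: the canonical
        matrix of comp(3')_comp(5') is read at row comp(current) and its
        entries relabelled derived-base -> complement.
        """
        return lookup_row(self, five_prime, three_prime, current)

    def dense(self) -> np.ndarray:
        """All 16 contexts as an array indexed (five, three, current, derived)."""
        out = np.empty((4, 4, 4, 4))
        for fi, five in enumerate(BASES):
            for ti, three in enumerate(BASES):
                ctx = f"{five}_{three}"
                canon = canonical_context(ctx)
                if ctx == canon:
                    out[fi, ti] = self.matrices[ctx]
                else:
                    out[fi, ti] = self.matrices[canon][::-1, ::-1]
        return out

    def stationary_vectors(self, tol: float = 1e-10) -> dict[str, np.ndarray]:
        return {
            ctx: stationary_vector(self.matrices[ctx], tol=tol)
            for ctx in CANONICAL_CONTEXTS
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "normalization_scale": self.normalization_scale,
                "contexts": {
                    ctx: self.matrices[ctx].tolist() for ctx in CANONICAL_CONTEXTS
                },
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MutationModel":
        payload = json.loads(text)
        matrices = {
            ctx: np.asarray(grid, dtype=float)
            for ctx, grid in payload["contexts"].items()
        }
        return cls(
            matrices,
            kind=payload.get("kind", "MC"),
            normalization_scale=payload.get("normalization_scale", 1.0),
        )

    def to_tsv(self) -> str:
        lines = [f"#kind\t{self.kind}", f"#scale\t{self.normalization_scale!r}"]
        for ctx in CANONICAL_CONTEXTS:
            lines.append(f"#context\t{ctx}")
            lines.append("\t" + "\t".join(BASES))
            for i, base in enumerate(BASES):
                row = "\t".join(repr(float(v)) for v in self.matrices[ctx][i])
                lines.append(f"{base}\t{row}")
        return "\n".join(lines) + "\n"


def lookup_row(
    model: MutationModel, five_prime: str, three_prime: str, current: str
) -> np.ndarray:
    ctx = f"{five_prime}_{three_prime}"
    cur = BASES.index(current)
    if ctx in model.matrices and ctx in CANONICAL_CONTEXTS:
        return model.matrices[ctx][cur].copy()
    canon = canonical_context(ctx)
    # comp(current) row of the complemented context, entries relabelled j->comp(j)
    return model.matrices[canon][3 - cur, ::-1].copy()


def build_probability_model(
    counts: SubstitutionCounts, target_max_rate: float = 1.0, kind: str = "MC2020"
) -> MutationModel:
    """Row-normalize count matrices and apply the global rate rescaling.

    Step 1 divides each count row by its total (zero rows are an error).
    Step 2 finds the maximum off-diagonal row sum r_max over all matrices.
    Step 3 scales every off-diagonal entry by c = target_max_rate / r_max and
    resets each diagonal to keep rows stochastic, so within-row and
    across-matrix relative rates are both preserved.
    """
    probs: dict[str, np.ndarray] = {}
    for ctx in CANONICAL_CONTEXTS:
        m = np.asarray(counts.matrices[ctx], dtype=float)
        row_totals = m.sum(axis=1)
        for i, total in enumerate(row_totals):
            if total <= 0:
                raise ValueError(
                    f"context {ctx}, ancestral base {BASES[i]}: "
                    "no observations (zero row total)"
                )
        probs[ctx] = m / row_totals[:, None]

    r_max = max(
        float((p[i].sum() - p[i, i])) for p in probs.values() for i in range(4)
    )
    if r_max <= 0:
        raise ValueError("no substitutions observed in any context")
    c = target_max_rate / r_max

    rescaled: dict[str, np.ndarray] = {}
    for ctx, p in probs.items():
        q = p * c
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, 1.0 - q.sum(axis=1))
        rescaled[ctx] = q
    return MutationModel(rescaled, kind=kind, normalization_scale=c)


def k2p_model(rate: float = 1.0) -> MutationModel:
    """Kimura two-parameter comparison model with a 3:1 Ts:Tv ratio.

    Every row carries the same off-diagonal mass ``rate``; the transition gets
    3/5 of it and each transversion 1/5, giving transitions three times the
    rate of each transversion.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    m = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            m[i, j] = rate * (3 / 5 if TRANSITION_PARTNER[i] == j else 1 / 5)
        m[i, i] = 1.0 - rate
    return MutationModel(
        {ctx: m.copy() for ctx in CANONICAL_CONTEXTS},
        kind="K2P",
        normalization_scale=rate,
    )


def stationary_vector(
    matrix: np.ndarray, tol: float = 1e-10, max_doublings: int = 64
) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by repeated squaring.

    P is squared until all rows agree componentwise within ``tol``; the common
    row is pi.  Reducible or periodic matrices fail to converge and raise.
    """
    q = np.asarray(matrix, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1] or not np.allclose(
        q.sum(axis=1), 1.0, atol=1e-9
    ):
        raise ValueError("stationary_vector requires a square row-stochastic matrix")
    for _ in range(max_doublings):
        if float(np.max(q.max(axis=0) - q.min(axis=0))) < tol:
            pi = q.mean(axis=0)
            return pi / pi.sum()
        q = q @ q
        q /= q.sum(axis=1, keepdims=True)  # curb floating-point drift
    raise RuntimeError(
        f"matrix powers did not converge after {max_doublings} doublings "
        "(reducible or periodic matrix?)"
    )


def _ts_tv(counts: np.ndarray, ancestral_rows: tuple[int, ...]) -> float:
    ts = sum(
        counts[i, TRANSITION_PARTNER[i]] for i in ancestral_rows
    )
    tv = sum(
        counts[i, j]
        for i in ancestral_rows
        for j in range(4)
        if j != i and j != TRANSITION_PARTNER[i]
    )
    return float(ts) / float(tv) if tv > 0 else float("nan")


def summarize_model(
    counts: SubstitutionCounts, model: MutationModel
) -> pd.DataFrame:
    """Per-context summary: Ts:Tv by ancestral base class, rates and equilibria.

    Columns mirror the standard presentation of context-dependent chloroplast
    mutation properties: transition:transversion ratios among substitutions
    from G/C and from A/T ancestral bases, substitutions per site x 100, the
    ratio of per-site rates from ancestral G/C vs A/T, and the equilibrium
    G+C content and C-G / T-A skews of the stationary vector.  Undefined
    ratios (zero denominators) are reported as NaN.
    """
    rows = []
    for ctx in CANONICAL_CONTEXTS:
        m = np.asarray(counts.matrices[ctx], dtype=float)
        off = m.sum() - np.trace(m)
        total = m.sum()

        gc_rows, at_rows = (1, 2), (0, 3)
        gc_sites = m[gc_rows, :].sum()
        at_sites = m[at_rows, :].sum()
        gc_subs = m[gc_rows, :].sum() - m[1, 1] - m[2, 2]
        at_subs = m[at_rows, :].sum() - m[0, 0] - m[3, 3]
        gc_rate = gc_subs / gc_sites if gc_sites > 0 else float("nan")
        at_rate = at_subs / at_sites if at_sites > 0 else float("nan")

        try:
            pi = stationary_vector(model.matrices[ctx])
        except RuntimeError:  # reducible/periodic matrix: no unique equilibrium
            pi = np.full(4, np.nan)
        pa, pc, pg, pt = pi
        cg = 100.0 * (pc - pg) / (pc + pg) if (pc + pg) > 0 else float("nan")
        ta = 100.0 * (pt - pa) / (pt + pa) if (pt + pa) > 0 else float("nan")

        rows.append(
            {
                "context": ctx,
                "ts_tv_gc": _ts_tv(m, gc_rows),
                "ts_tv_at": _ts_tv(m, at_rows),
                "sub_rate_per100": 100.0 * off / total if total > 0 else float("nan"),
                "gc_at_rate_ratio": (
                    gc_rate / at_rate if at_rate and at_rate > 0 else float("nan")
                ),
                "equil_gc": 100.0 * (pc + pg),
                "equil_cg_skew": cg,
                "equil_ta_skew": ta,
            }
        )
    return pd.DataFrame(rows).set_index("context")
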