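"""K2P distances, inferred mutation counts, and the extant-vs-simulation overlay.

Extant genes are placed on the simulated decay trajectories by estimating how
many mutations separate them from each reconstructed ancestor.  At the very
low divergences involved the Kimura two-parameter estimate is appropriate:
from the transition proportion P and transversion proportion Q of an aligned
pair, k = 1/2 ln(1/(1-2P-Q)) + 1/4 ln(1/(1-2Q)) substitutions per site, with
Kimura's delta-method variance.  Multiplying k by the number of compared
sites gives the inferred mutation count; the minimum and maximum over the
four ancestors bracket each gene's position on the mutation axis, and its
CAI is classified against the envelope of the simulated trajectories
(mean +/- 1 SD at the nearest checkpoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cai import CodingSequence
from .simulate import Trajectory

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class DistanceEstimate:
    p_transition: float
    q_transversion: float
    k: float
    variance: float
    n_sites: int

    @property
    def mutation_count(self) -> float:
        """Inferred mutations: k times the number of compared sites."""
        return self.k * self.n_sites


def k2p_from_proportions(
    p_transition: float, q_transversion: float, n_sites: int
) -> DistanceEstimate:
    """K2P estimate from observed transition/transversion proportions.

    k = 1/2 ln(1/(1-2P-Q)) + 1/4 ln(1/(1-2Q)); the variance is the
    delta-method form (a^2 P + b^2 Q - (aP + bQ)^2)/n with a = 1/(1-2P-Q)
    and b = (a + 1/(1-2Q))/2.  Raises on saturation (2P+Q >= 1 or 2Q >= 1).
    """
    if n_sites <= 0:
        raise ValueError("no comparable columns")
    p, q = p_transition, q_transversion
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(
            f"saturated divergence (P={p:.4f}, Q={q:.4f}): k undefined"
        )
    k = 0.5 * math.log(1.0 / w1) + 0.25 * math.log(1.0 / w2)
    a_coef = 1.0 / w1
    b_coef = 0.5 * (1.0 / w1 + 1.0 / w2)
    variance = (
        a_coef**2 * p + b_coef**2 * q - (a_coef * p + b_coef * q) ** 2
    ) / n_sites
    return DistanceEstimate(p, q, k, variance, n_sites)


def k2p_distance(seq1: str, seq2: str) -> DistanceEstimate:
    """Kimura two-parameter distance between two aligned sequences.

    Columns with gaps or non-ACGT symbols in either sequence are skipped and
    do not count toward n.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    return k2p_from_proportions(ts / n, tv / n, n)


def mutation_range(
    extant: CodingSequence,
    ancestors: Sequence[CodingSequence],
    aligner=None,
) -> tuple[float, float]:
    """Min and max inferred mutation counts of a gene over its ancestors.

    Sequences of equal length are compared position-wise; unequal lengths
    require an ``aligner`` hook, a callable mapping (seq1, seq2) to a pair of
    aligned strings (e.g. wrapping an external pairwise aligner).
    """
    if not ancestors:
        raise ValueError("at least one ancestor is required")
    counts = []
    for anc in ancestors:
        s1, s2 = extant.nt, anc.nt
        if len(s1) != len(s2):
            if aligner is None:
                raise ValueError(
                    f"{extant.id} vs {anc.id}: unequal lengths and no aligner hook"
                )
            s1, s2 = aligner(s1, s2)
        counts.append(k2p_distance(s1, s2).mutation_count)
    return min(counts), max(counts)


def _classify(
    cai_value: float, trajectories: Sequence[Trajectory], mutations: float
) -> tuple[str, int, bool]:
    """Position a CAI value against the trajectory envelope at one checkpoint.

    The envelope spans [min(mean - sd), max(mean + sd)] over all trajectories
    at each one's checkpoint nearest to ``mutations``.  Returns the class
    ('above', 'within' or 'below'), the nearest checkpoint of the first
    trajectory, and an out-of-range flag when ``mutations`` exceeds every
    trajectory's last checkpoint.
    """
    lows, highs, nearest = [], [], []
    out_of_range = True
    for traj in trajectories:
        i = int(np.argmin(np.abs(traj.checkpoints - mutations)))
        lows.append(traj.mean_cai[i] - traj.sd_cai[i])
        highs.append(traj.mean_cai[i] + traj.sd_cai[i])
        nearest.append(int(traj.checkpoints[i]))
        if mutations <= traj.checkpoints[-1]:
            out_of_range = False
    if cai_value > max(highs):
        cls = "above"
    elif cai_value < min(lows):
        cls = "below"
    else:
        cls = "within"
    return cls, nearest[0], out_of_range


def build_overlay(
    trajectories: Sequence[Trajectory],
    extants: Iterable[tuple[str, float, float, float]],
) -> pd.DataFrame:
    """Join extant genes onto the simulated envelope for both mutation counts.

    ``extants`` yields (id, cai, min_mutations, max_mutations) per gene; min
    and max come from the spread over the reconstructed ancestors.  The
    result has one row per gene with its envelope class at the minimum- and
    maximum-mutation placements; an empty extant list yields an empty table
    (the trajectories alone are the plot).
    """
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    rows = []
    for gene_id, cai_value, mut_min, mut_max in extants:
        if mut_min > mut_max:
            raise ValueError(f"{gene_id}: min mutation count exceeds max")
        cls_min, ck_min, oor_min = _classify(cai_value, trajectories, mut_min)
        cls_max, ck_max, oor_max = _classify(cai_value, trajectories, mut_max)
        rows.append(
            {
                "id": gene_id,
                "cai": cai_value,
                "mutations_min": mut_min,
                "mutations_max": mut_max,
                "checkpoint_min": ck_min,
                "class_min": cls_min,
                "out_of_range_min": oor_min,
                "checkpoint_max": ck_max,
                "class_max": cls_max,
                "out_of_range_max": oor_max,
            }
        )
    columns = [
        "id", "cai", "mutations_min", "mutations_max",
        "checkpoint_min", "class_min", "out_of_range_min",
        "checkpoint_max", "class_max", "out_of_range_max",
    ]
    return pd.DataFrame(rows, columns=columns)


def plot_overlay(
    trajectories: Sequence[Trajectory],
    overlay: pd.DataFrame,
    path=None,
    labels: Sequence[str] | None = None,
):
    """Two-panel plot: trajectories +/- SD with extant points at min/max counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for panel, ax, col in zip(
        ("minimum mutations", "maximum mutations"),
        axes,
        ("mutations_min", "mutations_max"),
    ):
        for j, traj in enumerate(trajectories):
            label = labels[j] if labels else f"ancestor {j + 1}"
            ax.fill_between(
                traj.checkpoints,
                traj.mean_cai - traj.sd_cai,
                traj.mean_cai + traj.sd_cai,
                alpha=0.2,
            )
            ax.plot(traj.checkpoints, traj.mean_cai, label=label)
        if len(overlay):
            ax.scatter(overlay[col], overlay["cai"], s=12, c="tab:blue", zorder=3)
        ax.set_xlabel(f"mutations ({panel})")
        ax.set_title(panel)
    axes[0].set_ylabel("CAI")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
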