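"""Summary statistics of time-calibrated trees.

Branching times, lineage-through-time (LTT) curves with replicate
averaging, the gamma statistic of Pybus & Harvey (2000), extinct-tip
counts, and median / 95-percentile summaries.

The gamma statistic standardizes the positions of a reconstructed
ultrametric tree's internal nodes against the pure-birth (Yule)
expectation: gamma < 0 means internodes lengthen toward the present
(nodes cluster at the root), gamma > 0 means they shorten (nodes cluster
at the tips); under the Yule model gamma is asymptotically standard
normal.  With g_k the duration during which the reconstructed tree has
exactly k lineages and T_k = sum_{j=2..k} j * g_j,

    gamma = [ (1/(n-2)) * sum_{i=2..n-1} T_i  -  T_n / 2 ]
            / ( T_n * sqrt(1 / (12 (n-2))) ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timetree import TIME_TOL, TimeTree, TreeError

__all__ = [
    "LTTCurve",
    "GammaResult",
    "SummaryRow",
    "branching_times",
    "ltt",
    "average_ltt",
    "gamma_stat",
    "count_extinct",
    "summarize",
]


@dataclass(frozen=True)
class LTTCurve:
    """Right-continuous step function of lineage count against age.

    ``times`` are event ages in decreasing order (past -> present);
    ``counts[i]`` is the number of lineages alive just after (i.e. more
    recently than) ``times[i]``.
    """

    times: np.ndarray
    counts: np.ndarray

    def count_at(self, t: float) -> float:
        """Number of lineages alive at age ``t``."""
        if t > self.times[0]:
            return 1.0
        # last event with age >= t determines the count at t
        idx = np.searchsorted(-self.times, -t, side="right") - 1
        return float(self.counts[idx])

    @property
    def origin(self) -> float:
        return float(self.times[0])


def branching_times(tree: TimeTree) -> np.ndarray:
    """Ages of the n-1 internal nodes of a reconstructed tree, descending.

    The first entry is the crown age.  Refuses complete trees: prune
    extinct tips first.
    """
    if not tree.is_reconstructed:
        raise TreeError("branching_times requires a reconstructed tree")
    ages = sorted((n.end for n in tree.internal_nodes()), reverse=True)
    return np.asarray(ages)


def ltt(tree: TimeTree) -> LTTCurve:
    """Lineage-through-time curve of a (complete or reconstructed) tree.

    Counts every lineage while it is alive, so extinct side branches of a
    complete tree contribute until their extinction.
    """
    events: list[tuple[float, int]] = []
    for node in tree.preorder():
        if node.is_tip:
            if not node.is_extant:
                events.append((node.end, -1))
        else:
            events.append((node.end, +1))
    events.sort(key=lambda e: -e[0])
    times, counts = [], []
    count = 1
    for t, delta in events:
        count += delta
        if times and abs(times[-1] - t) <= TIME_TOL:
            counts[-1] = count
        else:
            times.append(t)
            counts.append(count)
    return LTTCurve(np.asarray(times), np.asarray(counts))


def average_ltt(
    curves: list[LTTCurve], grid: np.ndarray | None = None, n_points: int = 200
) -> LTTCurve:
    """Pointwise mean of replicate LTT curves aligned at the present.

    On each grid age the mean runs over the replicates whose origin covers
    that age (older replicates only); replicates do not contribute zeros
    beyond their own root.
    """
    if not curves:
        raise ValueError("no curves to average")
    if grid is None:
        oldest = max(c.origin for c in curves)
        grid = np.linspace(oldest, 0.0, n_points)
    means = np.empty_like(grid, dtype=float)
    for i, t in enumerate(grid):
        vals = [c.count_at(t) for c in curves if c.origin >= t - TIME_TOL]
        means[i] = float(np.mean(vals)) if vals else np.nan
    return LTTCurve(np.asarray(grid, dtype=float), means)


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    n_tips: int
    internode_intervals: np.ndarray  # g_2 .. g_n


def gamma_stat(tree: TimeTree) -> GammaResult:
    """Gamma statistic of a reconstructed ultrametric tree (n >= 3 tips)."""
    x = branching_times(tree)  # descending ages, x[0] = crown
    n = len(x) + 1
    if n < 3:
        raise TreeError("gamma statistic undefined for fewer than 3 tips")
    ages = np.concatenate([x, [0.0]])
    g = -np.diff(ages)  # g[k-2] = duration with exactly k lineages
    k = np.arange(2, n + 1)
    T = np.cumsum(k * g)  # T[k-2] = T_k
    Tn = T[-1]
    if Tn <= 0:
        raise TreeError("tree has zero total depth")
    num = T[:-1].mean() - Tn / 2.0
    den = Tn * np.sqrt(1.0 / (12.0 * (n - 2)))
    return GammaResult(float(num / den), n, g)


def count_extinct(tree: TimeTree) -> int:
    """Number of tips that do not survive to the present."""
    return len(tree.extinct_tips())


@dataclass(frozen=True)
class SummaryRow:
    """Replicate summary: median, 2.5-97.5 percentile interval, mean, SD."""

    model: str
    sampling: str
    median: float
    lo: float
    hi: float
    mean: float
    sd: float
    n: int


def summarize(values, model: str = "", sampling: str = "") -> SummaryRow:
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values to summarize")
    return SummaryRow(
        model=model,
        sampling=sampling,
        median=float(np.median(v)),
        lo=float(np.percentile(v, 2.5)),
        hi=float(np.percentile(v, 97.5)),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        n=v.size,
    )
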