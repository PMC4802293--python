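"""Birth-death tree simulation conditioned on the number of extant tips.

Five diversification scenarios are supported, all conditioned on exactly
``N`` extant tips at the present:

* constant-rate birth-death (BD) and its high-background-extinction
  variant (HE), via the generalized sampling approach (GSA): simulate the
  forward process from a crown pair until extinction or a lineage cap, and
  draw the "present" duration-weighted among the periods during which
  exactly N lineages are alive;
* diversity-dependent cladogenesis (DDC), a discrete grid of exponentially
  decaying speciation rates, either anchored at the crown (plain GSA) or
  anchored at the present (episodic machinery below);
* episodic scenarios in which the recent history is a fixed sequence of
  epochs measured back from the present -- a mass extinction (ME) that
  instantaneously thins the standing diversity by a survival fraction
  ``rho``, or a stasis/rate-shift (SRD) scenario.  Here the crown-to-shift
  duration is drawn uniformly (the GSA improper prior on tree age), the
  epoch program is run forward, and the draw is accepted iff exactly N
  lineages survive to the present.

Trees are returned as complete :class:`~extsig.timetree.TimeTree` objects
(extinct side branches included); combine with :func:`drop_extinct` and
:func:`sample_tips` for reconstructed and subsampled trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .timetree import (
    Node,
    TimeTree,
    drop_extinct,
    read_newick,
    sample_tips,
    write_newick,
)

__all__ = [
    "SimulationError",
    "GridDecay",
    "lambda_on_grid",
    "Epoch",
    "BDRegime",
    "SimConfig",
    "ddc_regime",
    "me_regime",
    "srd_regime",
    "ConditionedSimulator",
    "simulate_bd_conditional",
    "simulate_me",
    "simulate_trees",
    "drop_extinct",
    "sample_tips",
    "read_newick",
    "write_newick",
]


class SimulationError(RuntimeError):
    """Conditioning on N extant tips failed within the retry budget."""


# ---------------------------------------------------------------------------
# rate schedules and regimes
# ---------------------------------------------------------------------------

def lambda_on_grid(t: float, lam0: float, K: float, dt: float) -> float:
    """Speciation rate of the discrete exponential-decay schedule.

    The rate is held constant within grid cells of width ``dt`` at the value
    ``lam0 * exp(-K * t_cell)``, where ``t_cell`` is the cell's anchor (its
    older boundary, measured from the start of the schedule).
    """
    if dt <= 0:
        raise ValueError(f"grid step must be positive, got {dt}")
    if lam0 <= 0 or K <= 0:
        raise ValueError("lam0 and K must be positive")
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    cell = math.floor(t / dt + 1e-9)
    return lam0 * math.exp(-K * cell * dt)


@dataclass(frozen=True)
class GridDecay:
    """Piecewise-constant exponentially decaying speciation schedule."""

    lam0: float
    K: float
    dt: float

    def rate(self, t: float) -> float:
        return lambda_on_grid(t, self.lam0, self.K, self.dt)

    def next_boundary(self, t: float) -> float:
        return (math.floor(t / self.dt + 1e-9) + 1) * self.dt


@dataclass(frozen=True)
class Epoch:
    """A recent-history interval of fixed duration, run forward in time.

    ``survival`` is the fraction of lineages surviving an instantaneous
    thinning applied at the epoch's (older) start boundary; 1.0 means no
    thinning (a pure rate shift).
    """

    lam: float
    mu: float
    duration: float
    survival: float = 1.0

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if not 0.0 < self.survival <= 1.0:
            raise ValueError(f"survival fraction must be in (0, 1], got {self.survival}")


@dataclass(frozen=True)
class BDRegime:
    """Diversification regime: an open-ended oldest phase plus optional
    fixed-duration recent epochs (ordered past -> present).

    ``lam`` may be a constant rate or a :class:`GridDecay` schedule (the
    latter measured forward from the crown).  Derived quantities ``r``
    (net diversification) and ``a`` (extinction fraction) refer to the
    oldest phase and require a constant ``lam``.
    """

    lam: float | GridDecay
    mu: float
    epochs: tuple[Epoch, ...] = ()

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if isinstance(self.lam, (int, float)) and self.lam <= 0:
            raise ValueError("lam must be positive")

    @property
    def r(self) -> float:
        return float(self.lam) - self.mu

    @property
    def a(self) -> float:
        return self.mu / float(self.lam)

    @property
    def recent_span(self) -> float:
        """Total duration of the fixed recent epochs (= oldest shift age)."""
        return sum(e.duration for e in self.epochs)

    @property
    def has_mass_extinction(self) -> bool:
        return any(e.survival < 1.0 for e in self.epochs)


@dataclass(frozen=True)
class SimConfig:
    """Conditioning configuration for the simulators."""

    n_extant: int = 20
    cap_factor: int = 10
    max_retries: int = 400_000
    pilot_runs: int = 300
    clip_factor: float = 1.5
    t_max: float = 5000.0

    def __post_init__(self):
        if self.n_extant < 2:
            raise ValueError("n_extant must be >= 2")


def ddc_regime(
    lam0: float = 6.0,
    K: float = 5.0,
    dt: float = 0.2,
    mu: float = 0.01,
    depth: float = 1.0,
    anchor: str = "present",
) -> BDRegime:
    """Diversity-dependent cladogenesis: grid of decaying speciation rates.

    ``anchor="present"`` places the grid against the present: the oldest
    phase (ages > ``depth``) runs at ``lam0`` and the rate decays cell by
    cell toward the present, reaching ``lam0 * exp(-K * depth)`` in the most
    recent cell.  ``anchor="crown"`` measures the grid forward from the
    crown instead.
    """
    if anchor == "crown":
        return BDRegime(lam=GridDecay(lam0, K, dt), mu=mu)
    if anchor != "present":
        raise ValueError(f"anchor must be 'crown' or 'present', got {anchor!r}")
    n_cells = round(depth / dt)
    if abs(n_cells * dt - depth) > 1e-9:
        raise ValueError("depth must be a multiple of dt")
    epochs = tuple(
        Epoch(lam=lam0 * math.exp(-K * (j + 1) * dt), mu=mu, duration=dt)
        for j in range(n_cells)
    )
    return BDRegime(lam=lam0, mu=mu, epochs=epochs)


def me_regime(
    lam1: float = 2.0,
    mu1: float = 0.3,
    lam2: float = 2.0,
    mu2: float = 1.0,
    t_me: float = 1.0,
    survival: float = 0.1,
) -> BDRegime:
    """Mass-extinction scenario: growth, instantaneous thinning at age
    ``t_me`` with survival fraction ``survival``, then recovery."""
    if not 0.0 < survival <= 1.0:
        raise ValueError(f"survival fraction must be in (0, 1], got {survival}")
    return BDRegime(
        lam=lam1, mu=mu1, epochs=(Epoch(lam2, mu2, t_me, survival=survival),)
    )


def srd_regime(
    lam1: float = 0.2,
    mu1: float = 0.1,
    lam2: float = 2.0,
    mu2: float = 0.01,
    t_shift: float = 3.0,
) -> BDRegime:
    """Stasis and rate-shift diversification: a slow phase followed by a
    rate acceleration at age ``t_shift`` before the present."""
    return BDRegime(lam=lam1, mu=mu1, epochs=(Epoch(lam2, mu2, t_shift),))


# ---------------------------------------------------------------------------
# forward Gillespie engine
# ---------------------------------------------------------------------------

class _Run:
    """Mutable state of one forward simulation (lineage bookkeeping)."""

    __slots__ = ("parent", "born", "died", "alive", "t")

    def __init__(self):
        # two crown lineages; parent -1 denotes the crown node
        self.parent = [-1, -1]
        self.born = [0.0, 0.0]
        self.died = [math.inf, math.inf]
        self.alive = [0, 1]
        self.t = 0.0

    @property
    def n(self) -> int:
        return len(self.alive)

    def thin(self, survival: float, rng: np.random.Generator) -> None:
        """Instantaneous mass extinction: each lineage survives w.p. ``survival``."""
        if survival >= 1.0:
            return
        keep = rng.random(len(self.alive)) < survival
        survivors = []
        for i, k in zip(self.alive, keep):
            if k:
                survivors.append(i)
            else:
                self.died[i] = self.t
        self.alive = survivors


def _advance(
    run: _Run,
    lam: float | GridDecay,
    mu: float,
    t_end: float,
    rng: np.random.Generator,
    cap: int | None = None,
    abort_over: int | None = None,
    intervals: list | None = None,
    n_target: int | None = None,
) -> str:
    """Advance a run to ``t_end`` under rates (lam, mu).

    Returns one of ``"ok"`` (reached t_end), ``"extinct"``, ``"capped"``
    (lineage count reached ``cap``), or ``"aborted"`` (count exceeded
    ``abort_over``, used when a later return to the target count has
    negligible probability).  When ``intervals``/``n_target`` are given,
    time spans during which exactly ``n_target`` lineages are alive are
    appended as (start, stop) pairs.
    """
    grid = lam if isinstance(lam, GridDecay) else None
    parent, born, died, alive = run.parent, run.born, run.died, run.alive
    expovariate = rng.exponential
    uniform = rng.random
    t = run.t
    open_start = t if (n_target is not None and len(alive) == n_target) else None

    def close_interval(stop: float) -> None:
        nonlocal open_start
        if open_start is not None and stop > open_start:
            intervals.append((open_start, stop))
        open_start = None

    while alive:
        n = len(alive)
        if cap is not None and n >= cap:
            close_interval(t)
            run.t = t
            run.alive = alive
            return "capped"
        if abort_over is not None and n > abort_over:
            run.t = t
            run.alive = alive
            return "aborted"
        lam_t = grid.rate(t) if grid is not None else lam
        boundary = grid.next_boundary(t) if grid is not None else math.inf
        stop = min(boundary, t_end)
        total = n * (lam_t + mu)
        if total <= 0.0:
            t_next = math.inf
        else:
            t_next = t + expovariate(1.0 / total)
        if t_next >= stop:
            if stop >= t_end:
                close_interval(t_end)
                run.t = t_end
                run.alive = alive
                return "ok"
            t = stop  # cross a grid boundary, redraw the waiting time
            continue
        t = t_next
        j = int(uniform() * n)
        i = alive[j]
        if uniform() * (lam_t + mu) < lam_t:
            # speciation: lineage i continues, a new lineage is born
            if n_target is not None and n == n_target:
                close_interval(t)
            child = len(parent)
            parent.append(i)
            born.append(t)
            died.append(math.inf)
            alive.append(child)
            if n_target is not None and n + 1 == n_target:
                open_start = t
        else:
            # extinction of lineage i
            if n_target is not None and n == n_target:
                close_interval(t)
            died[i] = t
            alive[j] = alive[-1]
            alive.pop()
            if n_target is not None and n - 1 == n_target:
                open_start = t
    run.t = t
    run.alive = alive
    return "extinct"


def _build_tree(run: _Run, t_present: float) -> TimeTree:
    """Truncate a run at forward time ``t_present`` and build the complete
    TimeTree (ages measured back from that present)."""
    parent, born, died = run.parent, run.born, run.died
    n_lin = len(parent)
    # children of each lineage, in birth order (append order is time order)
    kids: list[list[int]] = [[] for _ in range(n_lin)]
    keep = [False] * n_lin
    for i in range(n_lin):
        if born[i] < t_present:
            keep[i] = True
    for i in range(n_lin):
        if keep[i] and parent[i] >= 0:
            kids[parent[i]].append(i)

    def age(t: float) -> float:
        a = t_present - t
        return 0.0 if a < 1e-12 else a

    root = Node(t_present, t_present)
    # iterative construction: stack of (lineage, segment_start, parent_node)
    stack = [(1, 0.0, root), (0, 0.0, root)]
    while stack:
        lin, seg_start, pnode = stack.pop()
        events = kids[lin]
        # find the first birth event after seg_start
        nxt = None
        for b_idx, child in enumerate(events):
            if born[child] > seg_start:
                nxt = (b_idx, child)
                break
        if nxt is None:
            end = died[lin] if died[lin] <= t_present else t_present
            pnode.add_child(Node(age(seg_start), age(end)))
        else:
            _, child = nxt
            t_split = born[child]
            node = pnode.add_child(Node(age(seg_start), age(t_split)))
            stack.append((child, t_split, node))
            stack.append((lin, t_split, node))
    tree = TimeTree(root, validate=False)
    tree.relabel_tips()
    return tree


# ---------------------------------------------------------------------------
# conditioned samplers
# ---------------------------------------------------------------------------

class ConditionedSimulator:
    """Draws complete trees with exactly ``n_extant`` tips at the present.

    One instance holds the pilot calibration for a regime (the rejection
    constant for GSA regimes, or the uniform-age span for episodic
    regimes), so drawing many replicates amortizes the pilot cost.
    """

    def __init__(self, regime: BDRegime, config: SimConfig = SimConfig()):
        self.regime = regime
        self.config = config
        self._clip: float | None = None  # GSA rejection constant C
        self._t_span: float | None = None  # episodic uniform-age span
        self._pool: list[tuple[_Run, list, float]] = []

    # -- GSA path (no fixed recent epochs) --------------------------------
    def _gsa_run(self, rng: np.random.Generator):
        cfg, regime = self.config, self.regime
        cap: int | None = cfg.cap_factor * cfg.n_extant
        if isinstance(regime.lam, GridDecay):
            # eventually-subcritical schedule: run to extinction instead
            cap = None
        run = _Run()
        intervals: list = []
        _advance(
            run,
            regime.lam,
            regime.mu,
            cfg.t_max,
            rng,
            cap=cap,
            intervals=intervals,
            n_target=cfg.n_extant,
        )
        weight = sum(b - a for a, b in intervals)
        return run, intervals, weight

    def _pilot_gsa(self, rng: np.random.Generator) -> None:
        cfg = self.config
        weights = []
        trials = 0
        while len(weights) < cfg.pilot_runs and trials < cfg.max_retries:
            trials += 1
            run, intervals, w = self._gsa_run(rng)
            if w > 0:
                weights.append(w)
                self._pool.append((run, intervals, w))
        if not weights:
            raise SimulationError(
                f"no run reached {cfg.n_extant} lineages in {trials} pilot trials"
            )
        self._clip = cfg.clip_factor * max(weights)

    def _sample_gsa(self, rng: np.random.Generator) -> TimeTree:
        cfg = self.config
        if self._clip is None:
            self._pilot_gsa(rng)
        for _ in range(cfg.max_retries):
            if self._pool:
                run, intervals, w = self._pool.pop()
            else:
                run, intervals, w = self._gsa_run(rng)
            if w <= 0 or rng.random() >= min(1.0, w / self._clip):
                continue
            # duration-weighted uniform position among the N-intervals
            u = rng.random() * w
            for a, b in intervals:
                if u <= b - a:
                    return _build_tree(run, a + u)
                u -= b - a
            return _build_tree(run, intervals[-1][1])
        raise SimulationError("GSA retry budget exhausted")

    # -- episodic path (fixed recent epochs) ------------------------------
    def _phase1_abort(self) -> int | None:
        """Abort threshold for the oldest phase.

        When no later epoch thins the standing diversity, a lineage count
        far above N can never come back down to N by the present; the
        threshold is set so that the neglected return probability is below
        ~1e-12.  With a thinning event downstream large counts remain
        viable, so only the hard cap applies.
        """
        cfg, regime = self.config, self.regime
        cap = cfg.cap_factor * cfg.n_extant
        if any(e.survival < 1.0 for e in regime.epochs):
            return cap
        worst = 0.0
        rates = [(float(regime.lam), regime.mu)] if not isinstance(
            regime.lam, GridDecay
        ) else []
        rates += [(e.lam, e.mu) for e in regime.epochs]
        for lam, mu in rates:
            if lam > 0:
                worst = max(worst, mu / lam)
        if worst >= 1.0 or worst <= 0.0:
            return cap
        margin = math.ceil(-12.0 / math.log10(worst))
        return min(cap, cfg.n_extant + max(1, margin))

    def _pilot_episodic(self, rng: np.random.Generator) -> None:
        """Set the uniform-age span: time for the oldest phase to reach its
        abort threshold (or go extinct), maximized over pilot runs."""
        cfg, regime = self.config, self.regime
        abort = self._phase1_abort()
        t_best = 0.0
        for _ in range(25):
            run = _Run()
            status = _advance(
                run, regime.lam, regime.mu, cfg.t_max, rng, cap=abort
            )
            if status in ("capped", "extinct", "ok"):
                t_best = max(t_best, run.t)
        if t_best <= 0.0:
            raise SimulationError("pilot runs for episodic regime all failed")
        self._t_span = 1.2 * t_best

    @staticmethod
    def _abort_threshold(n_target: int, epochs: Sequence[Epoch], cap: int) -> int:
        """Lineage count above which a return to ``n_target`` at the present
        has probability < ~1e-12 under the remaining epochs."""
        worst = 0.0
        for e in epochs:
            if e.lam <= 0:
                continue
            worst = max(worst, e.mu / e.lam)
        if worst >= 1.0:
            return cap
        if worst <= 0.0:
            return n_target
        margin = math.ceil(-12.0 / math.log10(worst))
        return min(cap, n_target + max(1, margin))

    def _sample_episodic(self, rng: np.random.Generator) -> TimeTree:
        cfg, regime = self.config, self.regime
        if self._t_span is None:
            self._pilot_episodic(rng)
        cap = cfg.cap_factor * cfg.n_extant
        abort1 = self._phase1_abort()
        for _ in range(cfg.max_retries):
            tau1 = rng.random() * self._t_span
            run = _Run()
            status = _advance(run, regime.lam, regime.mu, tau1, rng, cap=abort1)
            if status != "ok" or not run.alive:
                continue
            ok = True
            for k, epoch in enumerate(regime.epochs):
                run.thin(epoch.survival, rng)
                if not run.alive:
                    ok = False
                    break
                abort = self._abort_threshold(
                    cfg.n_extant, regime.epochs[k:], cap
                )
                status = _advance(
                    run,
                    epoch.lam,
                    epoch.mu,
                    run.t + epoch.duration,
                    rng,
                    cap=cap,
                    abort_over=abort,
                )
                if status != "ok":
                    ok = False
                    break
            if ok and len(run.alive) == cfg.n_extant:
                return _build_tree(run, run.t)
        raise SimulationError(
            f"episodic conditioning on N={cfg.n_extant} failed after "
            f"{cfg.max_retries} retries"
        )

    def sample(self, rng: np.random.Generator) -> TimeTree:
        if self.regime.epochs:
            return self._sample_episodic(rng)
        return self._sample_gsa(rng)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def simulate_bd_conditional(
    regime: BDRegime, config: SimConfig, rng: np.random.Generator
) -> TimeTree:
    """One complete tree with exactly ``config.n_extant`` extant tips under
    a constant-rate or grid-rate regime (no mass extinction)."""
    if regime.has_mass_extinction:
        raise ValueError("use simulate_me for regimes with a mass extinction")
    return ConditionedSimulator(regime, config).sample(rng)


def simulate_me(
    regime: BDRegime, config: SimConfig, rng: np.random.Generator
) -> TimeTree:
    """One complete tree under an episodic regime with a mass-extinction
    event, jointly conditioned on N extant tips and the event's age."""
    if not regime.epochs:
        raise ValueError("regime has no mass-extinction epoch")
    return ConditionedSimulator(regime, config).sample(rng)


def simulate_trees(
    regime: BDRegime,
    n_reps: int,
    rng: np.random.Generator,
    config: SimConfig = SimConfig(),
) -> list[TimeTree]:
    """Replicate complete trees sharing one pilot calibration."""
    sim = ConditionedSimulator(regime, config)
    return [sim.sample(rng) for _ in range(n_reps)]
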