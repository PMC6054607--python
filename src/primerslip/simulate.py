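"""Cycle-by-cycle stochastic PCR model with primer slippage.

Each cycle, every molecule is copied with probability ``efficiency``.  A copy
normally inherits its parent's cumulative slip offset, but when shifted
primer binding is feasible it slips with probability ``slip_prob``, drawing a
signed offset from the feasible set.  Forward slips are irreversible: a
primer incorporated s nt into the homopolymer continuation shortens that
run in every descendant, so a lineage's remaining forward-slip capacity only
decreases.  The same shortening removes the room a primer needs to anchor
one base early, so with capacity coupling enabled backward (insertion) slips
are only available to molecules whose run is still intact.  The pool's
offset distribution after c cycles is the quantity of interest; an optional
multinomial resampling cap keeps the exponentially growing pool tractable
without biasing offset fractions.

For the forward-only, unlimited-capacity special case the unslipped
fraction obeys the recursion ``u' = u * (1 + e*(1-q)) / (1 + e)``, giving
the closed form implemented in :func:`expected_unslipped_fraction`; the
Monte-Carlo model is validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .primers import (
    DEFAULT_ANCHOR_LEN,
    DEFAULT_WINDOW,
    BindingSite,
    DegeneratePrimer,
    SlipAssessment,
    feasible_slips,
)

__all__ = [
    "SimConfig",
    "AmpliconPool",
    "step_cycle",
    "simulate",
    "simulate_assessment",
    "expected_unslipped_fraction",
    "backward_suppression_ratio",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the branching PCR model.

    Attributes
    ----------
    cycles : int
        Number of PCR cycles.
    efficiency : float
        Per-molecule, per-cycle copy probability ``e`` in (0, 1].
    slip_prob : float
        Probability ``q`` that a copy event uses a shifted offset, given at
        least one nonzero offset is currently feasible for the parent.
    offset_weights : dict[int, float] or None
        Relative weights over feasible nonzero offsets; ``None`` = uniform.
        This is the hook for homopolymer-length-dependent slip preferences.
    pool_cap : int
        Pool size above which the pool is multinomially resampled down.
    initial_molecules : int
        Founding template copies at cycle 0.
    seed : int
        RNG seed; identical seed + config replays the trajectory exactly.
    backward_coupling : bool
        If True (default), backward slips require an unshortened
        homopolymer (remaining capacity equal to the initial capacity).
        Disable for the uncoupled control experiment.
    """

    cycles: int = 25
    efficiency: float = 1.0
    slip_prob: float = 0.0
    offset_weights: dict[int, float] | None = None
    pool_cap: int = 10_000
    initial_molecules: int = 1000
    seed: int = 0
    backward_coupling: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if not 0 <= self.slip_prob <= 1:
            raise ValueError("slip_prob must be in [0, 1]")
        if self.pool_cap < 100:
            raise ValueError("pool_cap must be >= 100")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.initial_molecules < 1:
            raise ValueError("initial_molecules must be >= 1")


@dataclass
class AmpliconPool:
    """Molecules tracked by (cumulative slip offset, remaining forward capacity).

    ``states`` maps ``(offset, capacity)`` to a molecule count; two molecules
    with the same net offset but different slip histories can differ in how
    much forward room they have left, so capacity is part of the class key.
    ``scale`` accumulates the total down-sampling factor applied so far, so
    absolute yields can be recovered from capped counts.
    """

    cycle: int = 0
    states: dict[tuple[int, int], int] = field(default_factory=dict)
    initial_capacity: int = 0
    scale: float = 1.0

    @property
    def total(self) -> int:
        return sum(self.states.values())

    @property
    def counts(self) -> dict[int, int]:
        """Molecule counts aggregated by cumulative offset."""
        out: dict[int, int] = {}
        for (k, _cap), n in self.states.items():
            out[k] = out.get(k, 0) + n
        return dict(sorted(out.items()))

    @property
    def capacity(self) -> dict[int, int]:
        """Largest remaining forward-slip capacity among molecules at each offset."""
        out: dict[int, int] = {}
        for (k, cap), n in self.states.items():
            if n > 0:
                out[k] = max(out.get(k, -1), cap)
        return dict(sorted(out.items()))

    @property
    def fractions(self) -> dict[int, float]:
        tot = self.total
        return {k: n / tot for k, n in self.counts.items()} if tot else {}

    def fraction_at(self, offset: int = 0) -> float:
        tot = self.total
        return self.counts.get(offset, 0) / tot if tot else 0.0

    def length_distribution(self, expected_len: int) -> dict[int, float]:
        """Apparent footprint length -> fraction (expected length minus offset)."""
        return {expected_len - k: f for k, f in self.fractions.items()}


def expected_unslipped_fraction(q: float, e: float, c: int) -> float:
    """Closed-form unslipped pool fraction after ``c`` cycles.

    Forward-only, unlimited capacity: the pool grows by factor ``1 + e``
    per cycle while the unslipped class grows by ``1 + e*(1-q)``, so the
    fraction is ``((1 + e*(1-q)) / (1 + e)) ** c``.
    """
    if not 0 <= q <= 1 or not 0 < e <= 1 or c < 0:
        raise ValueError("parameters out of range")
    return ((1.0 + e * (1.0 - q)) / (1.0 + e)) ** c


def _feasible_for_state(
    cap: int,
    assessment: SlipAssessment,
    cfg: SimConfig,
    offset: int,
) -> list[int]:
    """Nonzero offsets currently available to a molecule of the given class."""
    out = []
    min_feasible = min(assessment.feasible)
    for s in assessment.feasible:
        if s > 0:
            if s <= cap:
                out.append(s)
        elif s < 0:
            if cfg.backward_coupling and cap != assessment.max_forward_slip:
                continue  # shortened run: no room to anchor early
            if offset + s < min_feasible:
                continue  # cumulative insertions capped at the window bound
            out.append(s)
    return out


def step_cycle(
    pool: AmpliconPool,
    cfg: SimConfig,
    assessment: SlipAssessment,
    rng: np.random.Generator | None = None,
) -> AmpliconPool:
    """Advance the pool by one PCR cycle.

    Originals persist unchanged; each is copied with probability
    ``efficiency``, and a copy slips with probability ``slip_prob`` when any
    nonzero offset is feasible for its parent class.  If the pool then
    exceeds ``pool_cap`` it is multinomially resampled down to the cap.
    """
    if pool.total == 0:
        raise ValueError("cannot step an empty pool")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    new_states: dict[tuple[int, int], int] = dict(pool.states)

    def add(state: tuple[int, int], n: int) -> None:
        if n:
            new_states[state] = new_states.get(state, 0) + n

    for (k, cap), n in pool.states.items():
        copies = int(rng.binomial(n, cfg.efficiency))
        if copies == 0:
            continue
        options = _feasible_for_state(cap, assessment, cfg, k)
        if not options:
            add((k, cap), copies)
            continue
        slipped = int(rng.binomial(copies, cfg.slip_prob))
        add((k, cap), copies - slipped)
        if slipped:
            if cfg.offset_weights:
                w = np.array([cfg.offset_weights.get(s, 0.0) for s in options], float)
                if w.sum() <= 0:
                    add((k, cap), slipped)
                    continue
                w /= w.sum()
            else:
                w = np.full(len(options), 1.0 / len(options))
            draws = rng.multinomial(slipped, w)
            for s, m in zip(options, draws):
                if m:
                    child_cap = cap - s if s > 0 else cap
                    add((k + s, child_cap), int(m))

    out = AmpliconPool(
        cycle=pool.cycle + 1,
        states=new_states,
        initial_capacity=pool.initial_capacity,
        scale=pool.scale,
    )
    if out.total > cfg.pool_cap:
        keys = list(out.states)
        counts = np.array([out.states[s] for s in keys], dtype=float)
        tot = counts.sum()
        draws = rng.multinomial(cfg.pool_cap, counts / tot)
        out.states = {s: int(m) for s, m in zip(keys, draws) if m}
        out.scale = pool.scale * (tot / cfg.pool_cap)
    return out


def simulate_assessment(
    assessment: SlipAssessment, cfg: SimConfig
) -> list[AmpliconPool]:
    """Run the full trajectory from a precomputed slip assessment.

    Returns ``cycles + 1`` pools (cycle 0 = founding templates).
    """
    rng = np.random.default_rng(cfg.seed)
    init_cap = assessment.max_forward_slip
    pool = AmpliconPool(
        cycle=0,
        states={(0, init_cap): cfg.initial_molecules},
        initial_capacity=init_cap,
    )
    trajectory = [pool]
    for _ in range(cfg.cycles):
        pool = step_cycle(pool, cfg, assessment, rng)
        trajectory.append(pool)
    return trajectory


def simulate(
    template: str,
    primer: DegeneratePrimer,
    site: BindingSite,
    cfg: SimConfig,
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> list[AmpliconPool]:
    """Assess the site, then run the cycle-by-cycle slippage simulation.

    Raises if slip-0 binding is infeasible (invalid site).  The final
    pool's :meth:`AmpliconPool.length_distribution` gives the apparent
    primer-footprint length distribution of the amplicons.
    """
    assessment = feasible_slips(primer, template, site, window=window, anchor_len=anchor_len)
    return simulate_assessment(assessment, cfg)


def backward_suppression_ratio(trajectory: list[AmpliconPool]) -> float | None:
    """Insertion-to-deletion molecule fraction ratio on the final pool.

    ``None`` (undefined) when no deletion molecules exist.  With capacity
    coupling enabled this ratio is at most the ratio of an otherwise
    identical uncoupled run: forward slips consume the room backward slips
    need.
    """
    final = trajectory[-1]
    tot = final.total
    if tot == 0:
        return None
    ins = sum(n for k, n in final.counts.items() if k < 0) / tot
    dele = sum(n for k, n in final.counts.items() if k > 0) / tot
    if dele == 0:
        return None
    return ins / dele
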