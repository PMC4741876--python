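"""Discrete-time multi-type branching simulation with lineage tracking.

The population carries three size classes (S, M, G).  Each step of length
``step`` days (default one 70-hour observation window) applies, per cell:

* death — the cell is removed;
* resting — the cell persists unchanged;
* bipolar division — two daughters of the parent's class;
* multi-daughter (depolyploidizing) division — three or four daughters of the
  small class, plus a Poisson number of budded small daughters;
* sibling fusion — immediately after cytokinesis each daughter may fuse with a
  sibling; a fused pair merges into one cell promoted one class (S→M, M→G, G→G).

Rates are piecewise-constant over the measurement epochs (day14 governs
[14, 30), day30 governs [30, 49), day49plus thereafter) unless linear
interpolation between epoch anchors is requested.  Steps shorter than the
70-hour window rescale the categorical fate probabilities by a competing-risk
(proportional-hazard) conversion that composes exactly under step halving.

A deterministic mean-field companion propagates expected class counts by the
per-step expectation matrix and serves as an oracle for the stochastic mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import SIZE_CLASSES
from .errors import ConfigurationError, InputError
from .rates import ClassEpochRates, RateTable

WINDOW_DAYS: float = 70.0 / 24.0  # the 70-hour observation window, in days

_EPOCH_ANCHORS: tuple[tuple[float, str], ...] = (
    (14.0, "day14"), (30.0, "day30"), (49.0, "day49plus"),
)

_PROMOTE = {"S": "M", "M": "G", "G": "G"}
_IDX = {c: i for i, c in enumerate(SIZE_CLASSES)}


def epoch_for_time(t: float) -> str:
    """Epoch whose rates govern a step starting at day ``t`` (piecewise constant)."""
    if t < 30.0:
        return "day14"
    if t < 49.0:
        return "day30"
    return "day49plus"


def step_fate_probs(cer: ClassEpochRates, f: float) -> tuple[float, float, float]:
    """Per-step (death, divide, rest) for a step of ``f`` windows.

    Competing-risk conversion: the no-event probability scales as
    ``p_rest ** f`` and the event mass splits proportionally to the per-window
    death/division probabilities, which leaves the first-event distribution
    over a full window invariant under step subdivision.
    """
    if f == 1.0:
        p = (cer.p_death, cer.p_divide, cer.p_rest)
    else:
        rest = cer.p_rest ** f if cer.p_rest > 0 else 0.0
        event = 1.0 - rest
        w = cer.p_death + cer.p_divide
        if w <= 0:
            return 0.0, 0.0, 1.0
        p = (event * cer.p_death / w, event * cer.p_divide / w, rest)
    total = sum(p)  # guard sampling routines against last-ulp drift
    return p[0] / total, p[1] / total, p[2] / total


def _interpolated(rates: RateTable, sc: str, t: float) -> ClassEpochRates:
    """Linear interpolation of fate parameters between epoch anchor times."""
    times = [a for a, _ in _EPOCH_ANCHORS]
    if t <= times[0]:
        return rates.get(sc, _EPOCH_ANCHORS[0][1])
    if t >= times[-1]:
        return rates.get(sc, _EPOCH_ANCHORS[-1][1])
    for (t0, e0), (t1, e1) in zip(_EPOCH_ANCHORS, _EPOCH_ANCHORS[1:]):
        if t0 <= t < t1:
            lo, hi = rates.get(sc, e0), rates.get(sc, e1)
            u = (t - t0) / (t1 - t0)

            def lerp(a: float | None, b: float | None) -> float | None:
                if a is None or b is None:
                    return a if b is None else b
                return (1 - u) * a + u * b

            dist = None
            if lo.multi_daughter_dist or hi.multi_daughter_dist:
                keys = set(lo.multi_daughter_dist or {}) | set(hi.multi_daughter_dist or {})
                raw = {
                    k: (1 - u) * (lo.multi_daughter_dist or {}).get(k, 0.0)
                    + u * (hi.multi_daughter_dist or {}).get(k, 0.0)
                    for k in keys
                }
                z = sum(raw.values())
                dist = {k: v / z for k, v in raw.items()} if z > 0 else None
            return ClassEpochRates(
                p_death=lerp(lo.p_death, hi.p_death),
                p_divide=lerp(lo.p_divide, hi.p_divide),
                p_rest=lerp(lo.p_rest, hi.p_rest),
                p_multi=lerp(lo.p_multi, hi.p_multi),
                multi_daughter_dist=dist,
                p_fusion_per_daughter=lerp(lo.p_fusion_per_daughter, hi.p_fusion_per_daughter),
                bud_rate=lerp(lo.bud_rate, hi.bud_rate),
            )
    raise AssertionError("unreachable")


def effective_rates(
    rates: RateTable,
    sc: str,
    t: float,
    *,
    interpolate: bool = False,
    fusion_enabled: bool = True,
    medium_depolyploidization: bool = False,
) -> ClassEpochRates:
    """Rates governing class ``sc`` at day ``t`` after applying the model flags."""
    cer = _interpolated(rates, sc, t) if interpolate else rates.get(sc, epoch_for_time(t))
    if sc == "M" and medium_depolyploidization and not (cer.p_multi or 0.0) > 0:
        late = rates.get("M", "day49plus")
        cer = ClassEpochRates(
            p_death=cer.p_death, p_divide=cer.p_divide, p_rest=cer.p_rest,
            p_multi=late.p_multi, multi_daughter_dist=late.multi_daughter_dist,
            p_fusion_per_daughter=cer.p_fusion_per_daughter, bud_rate=cer.bud_rate,
        )
    if not fusion_enabled and (cer.p_fusion_per_daughter or 0.0) > 0:
        cer = ClassEpochRates(
            p_death=cer.p_death, p_divide=cer.p_divide, p_rest=cer.p_rest,
            p_multi=cer.p_multi, multi_daughter_dist=cer.multi_daughter_dist,
            p_fusion_per_daughter=0.0, bud_rate=cer.bud_rate,
        )
    return cer


# ---------------------------------------------------------------------------
# containers


@dataclass
class PopulationState:
    """Class counts at one time; counts are floats in mean-field mode."""

    time: float
    counts: dict[str, float]

    def total(self) -> float:
        return sum(self.counts.values())


class LineageForest:
    """Cells as nodes with birth/end times, parent links and event labels.

    Nodes are created in chronological order, so every parent id is smaller
    than its children's ids.  Fusion products carry two parents; all other
    non-founder nodes carry one.
    """

    def __init__(self) -> None:
        self.birth: list[float] = []
        self.end: list[float | None] = []
        self.klass: list[str] = []
        self.parents: list[tuple[int, ...]] = []
        self.event: list[str | None] = []  # how the node's lifetime ended

    def __len__(self) -> int:
        return len(self.birth)

    def new_node(self, klass: str, birth: float, parents: tuple[int, ...] = ()) -> int:
        self.birth.append(birth)
        self.end.append(None)
        self.klass.append(klass)
        self.parents.append(parents)
        self.event.append(None)
        return len(self.birth) - 1

    def close(self, node: int, t: float, event: str) -> None:
        self.end[node] = t
        self.event[node] = event

    def alive_at(self, t: float) -> list[int]:
        return [
            i
            for i in range(len(self.birth))
            if self.birth[i] <= t and (self.end[i] is None or self.end[i] > t)
        ]

    def to_edgelist_frame(self) -> pd.DataFrame:
        rows = [
            (p, c) for c, parents in enumerate(self.parents) for p in parents
        ]
        return pd.DataFrame(rows, columns=["parent", "child"])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i in range(len(self.birth)):
            g.add_node(
                i, klass=self.klass[i], birth=self.birth[i],
                end=self.end[i], event=self.event[i],
            )
        for child, parents in enumerate(self.parents):
            for p in parents:
                g.add_edge(p, child)
        return g


@dataclass
class StepEvents:
    """Per-step bookkeeping tallies (used by the conservation invariant)."""

    deaths: int = 0
    dividers: int = 0
    daughters: int = 0
    fused_pairs: int = 0
    buds: int = 0


@dataclass
class SimulationResult:
    states: list[PopulationState]
    forest: LineageForest | None = None
    events: list[StepEvents] = field(default_factory=list)

    def trajectory_frame(self) -> pd.DataFrame:
        rows = [
            (st.time, c, st.counts[c]) for st in self.states for c in SIZE_CLASSES
        ]
        return pd.DataFrame(rows, columns=["time", "class", "count"])


# ---------------------------------------------------------------------------
# stochastic stepping


def _multi_fusion_pairs(
    rng: np.random.Generator, counts_by_k: dict[int, int], p_fusion: float
) -> int:
    """Total fused pairs among multi-daughter broods, odd counts rescaled so the
    per-daughter fusion marginal equals ``p_fusion`` for every brood size."""
    total = 0
    for k, m in counts_by_k.items():
        n_pairs = k // 2
        if m == 0 or n_pairs == 0 or p_fusion == 0.0:
            continue
        p_pair = min(1.0, p_fusion * k / (2 * n_pairs))
        total += int(rng.binomial(m * n_pairs, p_pair))
    return total


def _count_step(
    counts: dict[str, float],
    t: float,
    f: float,
    rng: np.random.Generator,
    get_rates,
    multi_daughter_class: str,
) -> tuple[dict[str, float], StepEvents]:
    new = {c: 0 for c in SIZE_CLASSES}
    ev = StepEvents()
    mc = multi_daughter_class
    for sc in SIZE_CLASSES:
        n = int(counts[sc])
        if n == 0:
            continue
        cer = get_rates(sc, t)
        p_d, p_v, p_r = step_fate_probs(cer, f)
        d, v, s = rng.multinomial(n, [p_d, p_v, p_r])
        ev.deaths += int(d)
        ev.dividers += int(v)
        new[sc] += int(s)
        if v == 0:
            continue
        p_multi = cer.p_multi or 0.0
        p_fus = cer.p_fusion_per_daughter or 0.0
        m = int(rng.binomial(v, p_multi)) if p_multi > 0 else 0
        b = int(v) - m
        # bipolar: two same-class daughters, pair may fuse into promote(sc)
        fb = int(rng.binomial(b, p_fus)) if (b and p_fus > 0) else 0
        new[sc] += 2 * (b - fb)
        new[_PROMOTE[sc]] += fb
        ev.daughters += 2 * b
        ev.fused_pairs += fb
        if m:
            dist = cer.multi_daughter_dist or {3: 2 / 3, 4: 1 / 3}
            ks = sorted(dist)
            counts_k = rng.multinomial(m, [dist[k] for k in ks])
            by_k = {k: int(c) for k, c in zip(ks, counts_k)}
            daughters = sum(k * c for k, c in by_k.items())
            fm = _multi_fusion_pairs(rng, by_k, p_fus)
            buds = int(rng.poisson(m * (cer.bud_rate or 0.0)))
            new[mc] += daughters - 2 * fm + buds
            new[_PROMOTE[mc]] += fm
            ev.daughters += daughters
            ev.fused_pairs += fm
            ev.buds += buds
    return new, ev


def _agent_step(
    forest: LineageForest,
    live: dict[str, list[int]],
    t: float,
    t_next: float,
    f: float,
    rng: np.random.Generator,
    get_rates,
    multi_daughter_class: str,
) -> tuple[dict[str, list[int]], StepEvents]:
    new_live: dict[str, list[int]] = {c: [] for c in SIZE_CLASSES}
    ev = StepEvents()
    mc = multi_daughter_class
    for sc in SIZE_CLASSES:
        ids = live[sc]
        if not ids:
            continue
        cer = get_rates(sc, t)
        p_d, p_v, p_r = step_fate_probs(cer, f)
        outcome = rng.choice(3, size=len(ids), p=[p_d, p_v, p_r])
        for node, oc in zip(ids, outcome):
            if oc == 0:  # death
                forest.close(node, t_next, "death")
                ev.deaths += 1
                continue
            if oc == 2:  # resting
                new_live[sc].append(node)
                continue
            ev.dividers += 1
            p_multi = cer.p_multi or 0.0
            is_multi = p_multi > 0 and rng.random() < p_multi
            if is_multi:
                dist = cer.multi_daughter_dist or {3: 2 / 3, 4: 1 / 3}
                ks = sorted(dist)
                k = int(rng.choice(ks, p=[dist[kk] for kk in ks]))
                d_class = mc
                forest.close(node, t_next, "multi_division")
            else:
                k = 2
                d_class = sc
                forest.close(node, t_next, "bipolar_division")
            daughters = [forest.new_node(d_class, t_next, (node,)) for _ in range(k)]
            ev.daughters += k
            p_fus = cer.p_fusion_per_daughter or 0.0
            n_pairs = k // 2
            fused: set[int] = set()
            if p_fus > 0 and n_pairs:
                p_pair = min(1.0, p_fus * k / (2 * n_pairs))
                for j in range(n_pairs):
                    a, b = daughters[2 * j], daughters[2 * j + 1]
                    if rng.random() < p_pair:
                        forest.close(a, t_next, "fused")
                        forest.close(b, t_next, "fused")
                        merged = forest.new_node(_PROMOTE[d_class], t_next, (a, b))
                        new_live[_PROMOTE[d_class]].append(merged)
                        fused.update((a, b))
                        ev.fused_pairs += 1
            for dn in daughters:
                if dn not in fused:
                    new_live[d_class].append(dn)
            if is_multi and (cer.bud_rate or 0.0) > 0:
                for _ in range(int(rng.poisson(cer.bud_rate))):
                    bud = forest.new_node(mc, t_next, (node,))
                    new_live[mc].append(bud)
                    ev.buds += 1
    return new_live, ev


def meanfield_matrix(
    rates: RateTable,
    t: float,
    f: float = 1.0,
    *,
    interpolate: bool = False,
    fusion_enabled: bool = True,
    medium_depolyploidization: bool = False,
    multi_daughter_class: str = "S",
) -> np.ndarray:
    """Per-step expectation matrix ``A`` with ``E[counts(t+step)] = A @ counts(t)``."""
    a = np.zeros((3, 3))
    mc = multi_daughter_class
    for sc in SIZE_CLASSES:
        cer = effective_rates(
            rates, sc, t, interpolate=interpolate, fusion_enabled=fusion_enabled,
            medium_depolyploidization=medium_depolyploidization,
        )
        p_d, p_v, p_r = step_fate_probs(cer, f)
        j = _IDX[sc]
        p_multi = cer.p_multi or 0.0
        p_fus = cer.p_fusion_per_daughter or 0.0
        a[j, j] += p_r + p_v * (1 - p_multi) * 2 * (1 - p_fus)
        a[_IDX[_PROMOTE[sc]], j] += p_v * (1 - p_multi) * p_fus
        if p_multi > 0:
            ek = cer.mean_multi_daughters() if cer.multi_daughter_dist else 10 / 3
            bud = cer.bud_rate or 0.0
            a[_IDX[mc], j] += p_v * p_multi * (ek * (1 - p_fus) + bud)
            a[_IDX[_PROMOTE[mc]], j] += p_v * p_multi * ek * p_fus / 2
    return a


def simulate(
    initial: PopulationState,
    rates: RateTable,
    horizon: float,
    step: float = WINDOW_DAYS,
    seed: int = 0,
    mode: str = "stochastic",
    *,
    track_lineage: bool = False,
    interpolate: bool = False,
    fusion_enabled: bool = True,
    medium_depolyploidization: bool = False,
    multi_daughter_class: str = "S",
) -> SimulationResult:
    """Propagate the population from ``initial.time`` to (at most) day ``horizon``.

    ``mode="stochastic"`` samples every event; with ``track_lineage=True`` a
    :class:`LineageForest` records every cell.  ``mode="meanfield"`` propagates
    expected counts through the per-step expectation matrices.  The trajectory
    ends at the last step boundary not exceeding ``horizon``.
    """
    if step <= 0:
        raise ConfigurationError(f"step must be positive, got {step}")
    if horizon < initial.time:
        raise ConfigurationError(
            f"horizon {horizon} precedes the initial time {initial.time}"
        )
    if mode not in ("stochastic", "meanfield"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if multi_daughter_class not in SIZE_CLASSES:
        raise ConfigurationError(f"unknown multi_daughter_class {multi_daughter_class!r}")
    rates.validate()
    f = step / WINDOW_DAYS
    n_steps = int(math.floor((horizon - initial.time) / step + 1e-9))

    def get_rates(sc: str, t: float) -> ClassEpochRates:
        return effective_rates(
            rates, sc, t, interpolate=interpolate, fusion_enabled=fusion_enabled,
            medium_depolyploidization=medium_depolyploidization,
        )

    # eager check: every (class, epoch) the horizon will touch must be present,
    # even for classes that happen to go extinct mid-run
    for i in range(n_steps):
        for sc in SIZE_CLASSES:
            get_rates(sc, initial.time + i * step)

    if mode == "meanfield":
        counts = np.array([float(initial.counts.get(c, 0.0)) for c in SIZE_CLASSES])
        states = [PopulationState(initial.time, dict(zip(SIZE_CLASSES, counts)))]
        t = initial.time
        for _ in range(n_steps):
            a = meanfield_matrix(
                rates, t, f, interpolate=interpolate, fusion_enabled=fusion_enabled,
                medium_depolyploidization=medium_depolyploidization,
                multi_daughter_class=multi_daughter_class,
            )
            counts = a @ counts
            t += step
            states.append(PopulationState(t, dict(zip(SIZE_CLASSES, counts))))
        return SimulationResult(states=states)

    rng = np.random.default_rng(seed)
    if track_lineage:
        forest = LineageForest()
        live: dict[str, list[int]] = {c: [] for c in SIZE_CLASSES}
        for c in SIZE_CLASSES:
            for _ in range(int(initial.counts.get(c, 0))):
                live[c].append(forest.new_node(c, initial.time))
        states = [
            PopulationState(initial.time, {c: len(live[c]) for c in SIZE_CLASSES})
        ]
        events: list[StepEvents] = []
        t = initial.time
        for _ in range(n_steps):
            t_next = t + step
            live, ev = _agent_step(
                forest, live, t, t_next, f, rng, get_rates, multi_daughter_class
            )
            events.append(ev)
            t = t_next
            states.append(PopulationState(t, {c: len(live[c]) for c in SIZE_CLASSES}))
        return SimulationResult(states=states, forest=forest, events=events)

    counts = {c: int(initial.counts.get(c, 0)) for c in SIZE_CLASSES}
    states = [PopulationState(initial.time, dict(counts))]
    events = []
    t = initial.time
    for _ in range(n_steps):
        counts, ev = _count_step(counts, t, f, rng, get_rates, multi_daughter_class)
        events.append(ev)
        t += step
        states.append(PopulationState(t, dict(counts)))
    return SimulationResult(states=states, events=events)


# ---------------------------------------------------------------------------
# ancestry attribution


@dataclass
class AncestryReport:
    """Fractions of a final-time class attributable to each founder class."""

    final_time: float
    final_class: str
    founder_time: float
    fractions: dict[str, float]
    n_final: int
    empty: bool = False


def attribute_ancestry(
    forest: LineageForest,
    final_time: float,
    final_class: str,
    founder_time: float,
) -> AncestryReport:
    """Split each final cell's unit weight equally along parent links back to the
    founder generation (cells alive at ``founder_time``), halving at fusion
    nodes, and aggregate by founder class."""
    if final_time < founder_time:
        raise InputError(
            f"final_time {final_time} precedes founder_time {founder_time}"
        )
    n = len(forest)
    weights = np.zeros((n, len(SIZE_CLASSES)))
    for i in range(n):  # chronological: parents precede children
        alive_at_founder = forest.birth[i] <= founder_time and (
            forest.end[i] is None or forest.end[i] > founder_time
        )
        if alive_at_founder:
            weights[i, _IDX[forest.klass[i]]] = 1.0
        elif forest.parents[i]:
            ps = forest.parents[i]
            weights[i] = weights[list(ps), :].mean(axis=0)
        # nodes born after founder_time without parents keep zero weight
    finals = [
        i
        for i in forest.alive_at(final_time)
        if forest.klass[i] == final_class
    ]
    if not finals:
        return AncestryReport(
            final_time, final_class, founder_time,
            {c: float("nan") for c in SIZE_CLASSES}, 0, empty=True,
        )
    agg = weights[finals, :].mean(axis=0)
    total = agg.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise InputError(
            "ancestry weights do not sum to 1; the forest is incomplete "
            f"(got {total!r})"
        )
    return AncestryReport(
        final_time, final_class, founder_time,
        {c: float(agg[_IDX[c]]) for c in SIZE_CLASSES}, len(finals),
    )
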