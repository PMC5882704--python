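"""Synthetic data generators.

Three pieces:

* :func:`simulate_fossil_tree` — a birth--death tree grown forward from an
  origin time, with Poisson fossil occurrences along terminal lineages;
  sampled taxa get FAD/LAD from their occurrence extremes and unsampled
  lineages are pruned, yielding a time tree whose leaves sit at their FADs.
* :func:`simulate_ranges` — forward simulation of the stratified
  anagenetic/cladogenetic range-evolution process along a given time tree,
  with a complete event log in the same taxonomy the stochastic mapper
  counts, so the two can be cross-validated.
* :func:`pleurodira_fixture` — the 10-area / 3-stratum / 7-bin study design
  of the side-necked-turtle analyses, with illustrative round-number
  distance matrices (NOT the original supplementary distances, which are
  not reproduced here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bsm import AnageneticEvent, CladogeneticEvent, History
from .data import AgeTable, GeographyTable
from .model import (CladogenesisEvents, EVENT_KINDS, ModelParams, ModelSpec,
                    StateSpace, Stratum, build_q, validate_strata)
from .diversification import TimeBin
from .trees import Node, TimeTree

__all__ = [
    "SimConfig",
    "SimulationError",
    "simulate_fossil_tree",
    "simulate_ranges",
    "pleurodira_fixture",
    "PLEURODIRA_AREAS",
]


class SimulationError(RuntimeError):
    """Raised when a simulated clade yields too few sampled taxa.

    Carries ``n_sampled`` so replicate studies can still account for the
    refused draws.
    """

    def __init__(self, message: str, n_sampled: int = 0):
        super().__init__(message)
        self.n_sampled = n_sampled


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    birth, death : speciation and extinction rates (/Myr)
    psi          : fossil-occurrence (preservation) rate (/Myr)
    origin       : origin time of the clade (Ma)
    seed         : mandatory RNG seed
    """

    birth: float
    death: float
    psi: float
    origin: float
    seed: int

    def __post_init__(self):
        if min(self.birth, self.death, self.psi) < 0:
            raise ValueError("rates must be >= 0")
        if self.birth <= 0:
            raise ValueError("speciation rate must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Fossilized birth-death trees
# ---------------------------------------------------------------------------

@dataclass
class _Lineage:
    birth: float                  # Ma
    node: Node
    death: float | None = None    # Ma; None while alive


_MAX_LINEAGES = 200_000


def simulate_fossil_tree(cfg: SimConfig) -> tuple[TimeTree, AgeTable]:
    """Simulate a fossil-sampled birth--death tree.

    Returns the pruned time tree of sampled taxa (leaves at FADs) and the
    matching FAD/LAD table.  Raises when fewer than two taxa are sampled.
    """
    rng = np.random.default_rng(cfg.seed)
    total_rate = cfg.birth + cfg.death

    root = Node(label=None)
    # stack of (node, start_time); each entry is a live lineage
    stack = [(root, cfg.origin)]
    tips: list[_Lineage] = []
    n_lineages = 1
    while stack:
        node, t = stack.pop()
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = np.inf
        t_event = t - wait
        if t_event <= 0:
            tips.append(_Lineage(birth=t, node=node, death=0.0))
            continue
        if rng.random() < cfg.birth / total_rate:
            node.age = t_event
            n_lineages += 1
            if n_lineages > _MAX_LINEAGES:
                raise RuntimeError("birth-death simulation exploded; lower "
                                   "the speciation rate or origin time")
            for _ in range(2):
                stack.append((node.add_child(Node()), t_event))
        else:
            tips.append(_Lineage(birth=t, node=node, death=t_event))

    # fossil sampling along terminal lineages
    fad, lad = {}, {}
    counter = 0
    sampled: set[int] = set()
    for lin in tips:
        span = lin.birth - lin.death
        n_occ = rng.poisson(cfg.psi * span) if span > 0 else 0
        if n_occ == 0:
            continue
        occ = rng.uniform(lin.death, lin.birth, size=n_occ)
        counter += 1
        name = f"t{counter}"
        lin.node.label = name
        fad[name] = float(occ.max())
        lad[name] = float(occ.min())
        sampled.add(id(lin.node))

    if len(fad) < 2:
        raise SimulationError(
            f"only {len(fad)} taxa sampled; increase psi, the speciation "
            f"rate or the origin time", n_sampled=len(fad)
        )

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if id(node) not in sampled:
                return None
            return Node(label=node.label, age=fad[node.label])
        kids = [build(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = Node(age=node.age)
        for k in kids:
            new.add_child(k)
        return new

    newroot = build(root)
    while newroot is not None and len(newroot.children) == 1:
        newroot = newroot.children[0]
        newroot.parent = None
    if newroot is None or newroot.is_leaf:
        raise RuntimeError("fewer than two sampled taxa survive pruning")
    tree = TimeTree(newroot)
    taxa = tree.leaf_labels
    return tree, AgeTable({t: fad[t] for t in taxa}, {t: lad[t] for t in taxa})


# ---------------------------------------------------------------------------
# Forward range evolution
# ---------------------------------------------------------------------------

def _stratum_at(strata: Sequence[Stratum], t: float) -> int:
    for k, s in enumerate(strata):
        if s.older >= t > s.younger:
            return k
    if t <= strata[-1].younger:
        return len(strata) - 1
    raise ValueError(f"time {t} outside strata")


class _NullRange(Exception):
    pass


def simulate_ranges(tree: TimeTree, spec: ModelSpec, params: ModelParams,
                    strata: Sequence[Stratum], root_range: int,
                    areas: Sequence[str], seed: int = 0,
                    max_rejections: int = 1000
                    ) -> tuple[GeographyTable, History]:
    """Forward-simulate range evolution along a time tree.

    Anagenesis is a Gillespie simulation of the per-stratum rate matrices;
    cladogenesis draws from the model's event table at every node.  A
    replicate in which any lineage hits the null (extinct) range is
    rejected and redrawn, so returned datasets live in the same conditioned
    space the likelihood assumes.  Returns the tip geography and the true
    event history (same event taxonomy as the stochastic mapper).
    """
    if root_range == 0:
        raise ValueError("root range must be non-null")
    strata = validate_strata(strata)
    space = StateSpace(areas, spec.max_range_size)
    if root_range not in space.index:
        raise ValueError("root range outside the state space")
    events = CladogenesisEvents(spec, space)
    p_event = events.probabilities(params)
    ev_lo = np.searchsorted(events.parent_idx, np.arange(space.nstates))
    ev_hi = np.searchsorted(events.parent_idx, np.arange(space.nstates),
                            side="right")
    Qs = [build_q(space, params, s) for s in strata]
    rng = np.random.default_rng(seed)

    from .likelihood import _node_label

    def run_branch(si: int, parent_age: float, child_age: float,
                   label: str, log: list[AnageneticEvent]) -> int:
        a = parent_age
        while a > child_age + 1e-12:
            k = _stratum_at(strata, a)
            boundary = max(child_age, strata[k].younger)
            Q = Qs[k]
            rate = -Q[si, si]
            if rate <= 0:
                a = boundary
                continue
            t_next = a - rng.exponential(1.0 / rate)
            if t_next <= boundary:
                a = boundary
                continue
            p = Q[si, :].clip(min=0.0)
            p[si] = 0.0
            target = int(rng.choice(space.nstates, p=p / p.sum()))
            log.append(AnageneticEvent(
                branch=label, time=float(t_next),
                from_mask=space.states[si], to_mask=space.states[target]))
            si = target
            if si == 0:
                raise _NullRange
            a = t_next
        return si

    root_idx = space.index[root_range]
    for _ in range(max_rejections):
        try:
            anagenetic: list[AnageneticEvent] = []
            cladogenetic: list[CladogeneticEvent] = []
            node_states: dict[str, int] = {}
            ranges: dict[str, int] = {}
            stack = [(tree.root, root_idx)]
            while stack:
                node, si = stack.pop()
                label = _node_label(node)
                node_states[label] = space.states[si]
                if node.is_leaf:
                    ranges[node.label] = space.states[si]
                    continue
                lo, hi = ev_lo[si], ev_hi[si]
                pick = lo + int(rng.choice(hi - lo, p=p_event[lo:hi]))
                kind = EVENT_KINDS[events.kinds[pick]]
                l_idx = int(events.left_idx[pick])
                r_idx = int(events.right_idx[pick])
                cladogenetic.append(CladogeneticEvent(
                    node=label, kind=kind, parent_mask=space.states[si],
                    left_mask=space.states[l_idx],
                    right_mask=space.states[r_idx]))
                for child, ci in zip(node.children, (l_idx, r_idx)):
                    end = run_branch(ci, node.age, child.age,
                                     _node_label(child), anagenetic)
                    stack.append((child, end))
            geo = GeographyTable(list(areas), ranges)
            history = History(node_states=node_states,
                              anagenetic=anagenetic,
                              cladogenetic=cladogenetic)
            return geo, history
        except _NullRange:
            continue
    raise RuntimeError(
        f"range simulation rejected {max_rejections} times (null range "
        f"reached); lower the range-loss rate e"
    )


# ---------------------------------------------------------------------------
# The side-necked-turtle study design
# ---------------------------------------------------------------------------

#: The ten areas, in study order: South America, Africa, North America,
#: Madagascar, Australia, Europe, India, Arabia/Middle East, East Asia,
#: Antarctica.
PLEURODIRA_AREAS = ["SA", "AF", "NAm", "MD", "AU", "EU", "IN", "AR", "EA",
                    "AN"]

PLEURODIRA_AREA_NAMES = {
    "SA": "South America", "AF": "Africa", "NAm": "North America",
    "MD": "Madagascar", "AU": "Australia", "EU": "Europe", "IN": "India",
    "AR": "Arabia/Middle East", "EA": "East Asia", "AN": "Antarctica",
}

_BIN_BOUNDS = [
    ("Early Cretaceous", 145.0, 100.5),
    ("Late Cretaceous", 100.5, 66.0),
    ("Paleocene", 66.0, 56.0),
    ("Eocene", 56.0, 33.9),
    ("Oligocene", 33.9, 23.03),
    ("Miocene", 23.03, 5.333),
    ("Pliocene-Recent", 5.333, 0.0),
]


def _toy_distances(scale: float) -> np.ndarray:
    """Symmetric round-number distances; continents drift apart with scale."""
    n = len(PLEURODIRA_AREAS)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 1.0 + scale * abs(i - j)
    return d


def pleurodira_fixture() -> tuple[list[str], list[Stratum], list[TimeBin]]:
    """Study design: 10 areas, three strata (170-91.1-55.5-0 Ma) with
    illustrative distance matrices, and the seven named time bins.

    The distance matrices are synthetic round numbers for exercising the
    distance-exponent machinery; they are not the original study's values.
    """
    strata = [
        Stratum(170.0, 91.1, _toy_distances(0.5)),
        Stratum(91.1, 55.5, _toy_distances(1.0)),
        Stratum(55.5, 0.0, _toy_distances(1.5)),
    ]
    bins = [TimeBin(name, older, younger)
            for name, older, younger in _BIN_BOUNDS]
    return list(PLEURODIRA_AREAS), strata, bins
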