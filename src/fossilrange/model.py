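"""Range state space, stratified anagenetic rates and cladogenesis tables.

The state space is the set of all non-empty subsets ("ranges") of a fixed
ordered area list up to a maximum range size ``m``, plus the empty (null)
range.  States are indexed deterministically by (size, bitmask value) with
the null range at index 0.

Three model families are supported, differing only in which cladogenetic
events they allow:

* ``DEC``       — narrow sympatry (single-area copy), subset sympatry, and
                  vicariance with one singleton daughter;
* ``DIVALIKE``  — narrow sympatry and unrestricted vicariance;
* ``BAYAREA``   — identity copy only (no range subdivision at nodes).

Two optional free parameters extend each family: ``x`` scales per-pair
dispersal rates by (distance / mean distance)^x, and ``j`` adds
founder-event ("jump") speciation during cladogenesis.  With ``j`` free the
non-jump event weights become (3 - j)/3 and every jump event has weight
``j``, so j = 0 reduces exactly to the standard model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Stratum",
    "ModelSpec",
    "ModelParams",
    "StateSpace",
    "enumerate_states",
    "dispersal_multipliers",
    "build_q",
    "cladogenesis_table",
    "CladogenesisEvents",
    "EVENT_KINDS",
]

Family = Literal["DEC", "DIVALIKE", "BAYAREA"]
Tier = Literal["M0", "M1", "M2"]

#: Cladogenetic event kinds, in the order used throughout the package.
EVENT_KINDS = ("sympatry", "subset", "vicariance", "jump")
_K_SYMPATRY, _K_SUBSET, _K_VICARIANCE, _K_JUMP = range(4)


@dataclass(frozen=True)
class Stratum:
    """A time slice [older, younger) Ma with its inter-area distance matrix."""

    older: float
    younger: float
    distances: np.ndarray | None = None  # square, symmetric, positive off-diag

    def __post_init__(self):
        if not self.older > self.younger:
            raise ValueError(f"stratum bounds not ordered: {self.older} <= "
                             f"{self.younger}")
        if self.distances is not None:
            d = np.asarray(self.distances, dtype=float)
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("distance matrix must be square")
            if not np.allclose(d, d.T):
                raise ValueError("distance matrix must be symmetric")
            off = d[~np.eye(d.shape[0], dtype=bool)]
            if off.size and (off <= 0).any():
                raise ValueError("off-diagonal distances must be positive")
            object.__setattr__(self, "distances", d)

    @property
    def duration(self) -> float:
        return self.older - self.younger

    def contains(self, t: float) -> bool:
        return self.older >= t >= self.younger


def validate_strata(strata: Sequence[Stratum]) -> list[Stratum]:
    """Check strata are ordered oldest-first and contiguous."""
    strata = list(strata)
    if not strata:
        raise ValueError("no strata")
    for a, b in zip(strata, strata[1:]):
        if a.younger != b.older:
            raise ValueError(
                f"strata not contiguous: {a.older}-{a.younger} then "
                f"{b.older}-{b.younger}"
            )
    return strata


@dataclass(frozen=True)
class ModelSpec:
    """Model family + tier (which of x, j are free) + range-size cap."""

    family: Family = "DEC"
    tier: Tier = "M0"
    max_range_size: int | None = None  # default: number of areas
    distance_scaled_jumps: bool = False

    def __post_init__(self):
        if self.family not in ("DEC", "DIVALIKE", "BAYAREA"):
            raise ValueError(f"unknown family {self.family}")
        if self.tier not in ("M0", "M1", "M2"):
            raise ValueError(f"unknown tier {self.tier}")

    @property
    def x_free(self) -> bool:
        return self.tier in ("M1", "M2")

    @property
    def j_free(self) -> bool:
        return self.tier == "M2"

    @property
    def k(self) -> int:
        """Number of free parameters: d, e (+x) (+j)."""
        return 2 + self.x_free + self.j_free

    @property
    def name(self) -> str:
        return f"{self.family}-{self.tier}"


@dataclass(frozen=True)
class ModelParams:
    """Rates of the range-evolution process.

    d : dispersal (area-gain) rate per source-area pair, /Myr
    e : range-loss (local extinction) rate per occupied area, /Myr
    x : distance exponent (<= 0 sensible: farther = slower)
    j : founder-event weight, 0 <= j < 3
    """

    d: float
    e: float
    x: float = 0.0
    j: float = 0.0

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be >= 0")
        if not (0 <= self.j < 3):
            raise ValueError("j must satisfy 0 <= j < 3")

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.e, self.x, self.j])


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------

def enumerate_states(nareas: int, m: int | None = None,
                     include_null: bool = True) -> list[int]:
    """All range bitmasks with 1..m set bits, ordered by (size, mask value).

    Index 0 is the null range when included.
    """
    m = nareas if m is None else m
    if m < 1 or m > nareas:
        raise ValueError(f"max range size m={m} out of range 1..{nareas}")
    states = [0] if include_null else []
    for size in range(1, m + 1):
        masks = sorted(sum(1 << i for i in combo)
                       for combo in combinations(range(nareas), size))
        states.extend(masks)
    return states


class StateSpace:
    """Indexed range state space shared by all model components."""

    def __init__(self, areas: Sequence[str], m: int | None = None):
        self.areas = list(areas)
        self.nareas = len(self.areas)
        self.m = self.nareas if m is None else m
        self.states = enumerate_states(self.nareas, self.m, include_null=True)
        self.index = {mask: i for i, mask in enumerate(self.states)}
        self.sizes = np.array([bin(s).count("1") for s in self.states])
        self.nstates = len(self.states)

    def state_label(self, mask: int) -> str:
        if mask == 0:
            return "-"
        return "+".join(a for i, a in enumerate(self.areas) if mask >> i & 1)

    def labels(self) -> list[str]:
        return [self.state_label(s) for s in self.states]

    def __len__(self) -> int:
        return self.nstates


# ---------------------------------------------------------------------------
# Anagenetic part
# ---------------------------------------------------------------------------

def dispersal_multipliers(stratum: Stratum, x: float,
                          nareas: int | None = None) -> np.ndarray:
    """Per-area-pair dispersal multipliers (distance / mean distance)^x.

    Distances are normalised by the stratum's mean off-diagonal distance so
    that x = 0 is exactly a no-op and the dispersal rate d stays comparable
    across strata.  A stratum without a distance matrix gets all-ones.
    """
    if stratum.distances is None:
        if nareas is None:
            raise ValueError("nareas required when the stratum has no "
                             "distance matrix")
        return np.ones((nareas, nareas))
    d = stratum.distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    mean = d[off].mean()
    w = np.ones_like(d)
    w[off] = (d[off] / mean) ** x
    return w


def build_q(space: StateSpace, params: ModelParams,
            stratum: Stratum) -> np.ndarray:
    """Dense anagenetic rate matrix over the state space for one stratum.

    Gains: rate(R -> R+{b}) = d * sum_{a in R} w[a, b] (capped at range size
    m); losses: rate(R -> R-{a}) = e per occupied area, taking single-area
    ranges to the absorbing null state.  Identical for all three families.
    """
    w = dispersal_multipliers(stratum, params.x, space.nareas)
    n = space.nstates
    Q = np.zeros((n, n))
    for i, R in enumerate(space.states):
        if R == 0:
            continue  # null range is absorbing
        members = [a for a in range(space.nareas) if R >> a & 1]
        # gains
        if len(members) < space.m:
            for b in range(space.nareas):
                if R >> b & 1:
                    continue
                rate = params.d * sum(w[a, b] for a in members)
                if rate > 0:
                    Q[i, space.index[R | (1 << b)]] += rate
        # losses
        for a in members:
            Q[i, space.index[R & ~(1 << a)]] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# Cladogenesis
# ---------------------------------------------------------------------------

def _ordered_events(family: Family, parent: int, nareas: int) -> list[tuple[int, int, int]]:
    """Enumerate ordered (left, right, kind) cladogenetic events.

    Jumps are always enumerated; they only acquire weight when j > 0.
    """
    members = [a for a in range(nareas) if parent >> a & 1]
    size = len(members)
    events: list[tuple[int, int, int]] = []

    if family == "BAYAREA":
        events.append((parent, parent, _K_SYMPATRY))
    else:
        if size == 1:
            events.append((parent, parent, _K_SYMPATRY))
        if family == "DEC" and size >= 2:
            for a in members:
                s = 1 << a
                events.append((parent, s, _K_SUBSET))
                events.append((s, parent, _K_SUBSET))
        if family in ("DEC", "DIVALIKE") and size >= 2:
            # ordered disjoint bipartitions; DEC restricts one daughter to a
            # single area
            for ksub in range(1, size):
                for combo in combinations(members, ksub):
                    left = sum(1 << a for a in combo)
                    right = parent & ~left
                    if family == "DEC" and min(ksub, size - ksub) != 1:
                        continue
                    events.append((left, right, _K_VICARIANCE))
    # founder events: one daughter jumps to a single new area
    for b in range(nareas):
        if parent >> b & 1:
            continue
        s = 1 << b
        events.append((parent, s, _K_JUMP))
        events.append((s, parent, _K_JUMP))
    return events


def _event_weights(kinds: np.ndarray, spec: ModelSpec, params: ModelParams,
                   jump_mult: np.ndarray | None = None) -> np.ndarray:
    j = params.j if spec.j_free else 0.0
    base = (3.0 - j) / 3.0 if spec.j_free else 1.0
    w = np.where(kinds == _K_JUMP, j, base)
    if jump_mult is not None:
        w = np.where(kinds == _K_JUMP, w * jump_mult, w)
    return w


def cladogenesis_table(spec: ModelSpec, parent: int, space: StateSpace,
                       params: ModelParams,
                       stratum: Stratum | None = None
                       ) -> list[tuple[int, int, float]]:
    """Ordered daughter pairs with probabilities for one parent range.

    Probabilities are event weights normalised per parent; zero-probability
    events are dropped, so an M2 table at j = 0 is identical to the M0 one.
    """
    if parent == 0:
        raise ValueError("null parent range has no cladogenesis")
    events = _ordered_events(spec.family, parent, space.nareas)
    kinds = np.array([k for _, _, k in events])
    jump_mult = None
    if spec.distance_scaled_jumps and stratum is not None:
        w = dispersal_multipliers(stratum, params.x, space.nareas)
        members = [a for a in range(space.nareas) if parent >> a & 1]
        jump_mult = np.ones(len(events))
        for idx, (l, r, k) in enumerate(events):
            if k == _K_JUMP:
                target = l if bin(l).count("1") == 1 and not l & parent else r
                b = target.bit_length() - 1
                jump_mult[idx] = np.mean([w[a, b] for a in members])
    weights = _event_weights(kinds, spec, params, jump_mult)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"no allowed cladogenetic event for parent "
                         f"{space.state_label(parent)}")
    return [(l, r, wt / total)
            for (l, r, _), wt in zip(events, weights) if wt > 0]


class CladogenesisEvents:
    """Flat, vectorised cladogenesis tables for a whole state space.

    Precomputes ordered event lists for every parent state once; per-call,
    probabilities are re-weighted for the current j.  Used by the likelihood,
    the stochastic mapper and the forward simulator.
    """

    def __init__(self, spec: ModelSpec, space: StateSpace):
        self.spec = spec
        self.space = space
        parent_idx, left_idx, right_idx, kinds = [], [], [], []
        for i, R in enumerate(space.states):
            if R == 0:
                continue
            for l, r, k in _ordered_events(spec.family, R, space.nareas):
                # daughters outside the state space (size cap) cannot occur:
                # subset/vicariance daughters are subsets of R and jumps are
                # singletons, so all daughters are always in-space.
                parent_idx.append(i)
                left_idx.append(space.index[l])
                right_idx.append(space.index[r])
                kinds.append(k)
        self.parent_idx = np.array(parent_idx)
        self.left_idx = np.array(left_idx)
        self.right_idx = np.array(right_idx)
        self.kinds = np.array(kinds)

    def probabilities(self, params: ModelParams) -> np.ndarray:
        """Per-event probability, normalised within each parent state."""
        w = _event_weights(self.kinds, self.spec, params)
        denom = np.bincount(self.parent_idx, weights=w,
                            minlength=self.space.nstates)
        return w / denom[self.parent_idx]

    def combine(self, params: ModelParams, below_left: np.ndarray,
                below_right: np.ndarray) -> np.ndarray:
        """Conditional likelihood at a node from its daughters' vectors.

        L[R] = sum over events of p(event | R) * L_left(daughterL) *
        L_right(daughterR); the null state keeps likelihood 0.
        """
        p = self.probabilities(params)
        contrib = p * below_left[self.left_idx] * below_right[self.right_idx]
        return np.bincount(self.parent_idx, weights=contrib,
                           minlength=self.space.nstates)
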