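"""Biogeographical stochastic mapping (BSM).

Draws joint biogeographic histories exactly consistent with the tip ranges
and a fitted range-evolution model, then tallies events:

* anagenetic — range expansions (area gains) and contractions (losses)
  along branches, sampled by endpoint-conditioned uniformization of the
  stratified rate matrices;
* cladogenetic — sympatry (range copy), subset speciation, vicariance and
  founder (jump) events at nodes, sampled from the cladogenesis table
  conditioned on the daughters' data.

Every map of a tree with T tips contains exactly T - 1 cladogenetic events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import EVENT_KINDS, ModelParams
from .likelihood import RangeEvolutionModel, _node_label

__all__ = [
    "AnageneticEvent",
    "CladogeneticEvent",
    "History",
    "EventCounts",
    "CATEGORIES",
    "sample_history",
    "sample_histories",
    "count_events",
    "summarize_bsm",
    "dispersal_directions",
]

#: Event categories in reporting order.
CATEGORIES = (
    "range_expansion",
    "range_contraction",
    "founder",
    "sympatry",
    "subset_speciation",
    "vicariance",
)

_KIND_TO_CATEGORY = {
    "sympatry": "sympatry",
    "subset": "subset_speciation",
    "vicariance": "vicariance",
    "jump": "founder",
}


@dataclass
class AnageneticEvent:
    branch: str          # label of the node below the branch
    time: float          # Ma
    from_mask: int
    to_mask: int

    @property
    def category(self) -> str:
        gain = bin(self.to_mask).count("1") > bin(self.from_mask).count("1")
        return "range_expansion" if gain else "range_contraction"


@dataclass
class CladogeneticEvent:
    node: str
    kind: str            # sympatry | subset | vicariance | jump
    parent_mask: int
    left_mask: int
    right_mask: int

    @property
    def category(self) -> str:
        return _KIND_TO_CATEGORY[self.kind]


@dataclass
class History:
    """One sampled biogeographic history."""

    node_states: dict[str, int]
    anagenetic: list[AnageneticEvent]
    cladogenetic: list[CladogeneticEvent]


@dataclass
class EventCounts:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        tot = self.total
        return {c: (100.0 * v / tot if tot else 0.0)
                for c, v in self.counts.items()}


def count_events(history: History) -> EventCounts:
    """Tally a history into the six event categories."""
    counts = {c: 0 for c in CATEGORIES}
    for ev in history.anagenetic:
        counts[ev.category] += 1
    for ev in history.cladogenetic:
        counts[ev.category] += 1
    return EventCounts(counts)


# ---------------------------------------------------------------------------
# Endpoint-conditioned path sampling (uniformization)
# ---------------------------------------------------------------------------

class _Uniformizer:
    """Shared uniformization machinery for one parameter set.

    A single rate bound Lambda = max exit rate over all strata is used, so
    the jump matrices B_s = I + Q_s / Lambda and their powers can be cached
    across branches; any Lambda at least the per-branch maximum yields the
    same path distribution.
    """

    MAX_JUMPS = 100_000

    def __init__(self, Qs: Sequence[np.ndarray]):
        self.Qs = Qs
        self.lam = max(float(np.max(-Q.diagonal())) for Q in Qs)
        self.Bs = [np.eye(Q.shape[0]) + Q / self.lam if self.lam > 0 else
                   np.eye(Q.shape[0]) for Q in Qs]
        self._powers: list[list[np.ndarray]] = [[np.eye(Q.shape[0]), B]
                                                for Q, B in zip(Qs, self.Bs)]

    def power(self, k: int, n: int) -> np.ndarray:
        pw = self._powers[k]
        while len(pw) <= n:
            pw.append(pw[-1] @ self.Bs[k])
        return pw[n]

    def sample_path(self, k: int, a: int, b: int, t: float, rng) -> list[int]:
        """Jump-chain states (incl. virtual self-jumps) from a to b over t."""
        if self.lam == 0 or t == 0:
            if a != b:
                raise RuntimeError("impossible endpoint pair at zero rate")
            return [a]
        lt = self.lam * t
        # weights for the number of uniformized jumps
        logterm = -lt
        weights = []
        n = 0
        tail_guard = lt + 10.0 * np.sqrt(lt) + 20.0
        while True:
            weights.append(np.exp(logterm) * self.power(k, n)[a, b])
            if n > tail_guard and weights[-1] < 1e-14 * (sum(weights) or 1.0):
                break
            n += 1
            if n > self.MAX_JUMPS:
                raise RuntimeError("uniformization failed to converge")
            logterm += np.log(lt) - np.log(n)
        weights = np.array(weights)
        total = weights.sum()
        if total <= 0:
            raise RuntimeError(
                f"endpoint pair ({a}->{b}) has zero probability"
            )
        N = rng.choice(len(weights), p=weights / total)
        B = self.Bs[k]
        states = [a]
        for i in range(1, N + 1):
            prev = states[-1]
            back = self.power(k, N - i)[:, b]
            p = B[prev, :] * back
            s = p.sum()
            p = p / s
            states.append(int(rng.choice(len(p), p=p)))
        assert states[-1] == b
        return states


def _segment_events(uni: _Uniformizer, k: int, a: int, b: int,
                    older: float, younger: float, branch_label: str,
                    space, rng) -> list[AnageneticEvent]:
    states = uni.sample_path(k, a, b, older - younger, rng)
    real = [(i, s0, s1) for i, (s0, s1) in
            enumerate(zip(states, states[1:])) if s0 != s1]
    n_jumps = len(states) - 1
    if not real:
        return []
    times = np.sort(rng.uniform(younger, older, size=n_jumps))[::-1]  # old->young
    events = []
    for i, s0, s1 in real:
        events.append(AnageneticEvent(
            branch=branch_label, time=float(times[i]),
            from_mask=space.states[s0], to_mask=space.states[s1],
        ))
    return events


# ---------------------------------------------------------------------------
# History sampling
# ---------------------------------------------------------------------------

class _Sampler:
    def __init__(self, model: RangeEvolutionModel, params: ModelParams):
        self.model = model
        self.params = params
        ll, cache = model._pruning(params, keep=True)
        if ll is None:
            raise ValueError("data have zero likelihood under these "
                             "parameters; cannot map")
        self.cache = cache
        self.uni = _Uniformizer(cache.propagators.Qs)
        self.p_event = model.events.probabilities(params)
        # per-parent event slices (parent_idx is grouped by construction)
        ev = model.events
        self._ev_lo = np.searchsorted(ev.parent_idx,
                                      np.arange(model.space.nstates))
        self._ev_hi = np.searchsorted(ev.parent_idx,
                                      np.arange(model.space.nstates),
                                      side="right")
        self._branch_P: dict[int, np.ndarray] = {}

    def branch_P(self, node_index: int) -> np.ndarray:
        P = self._branch_P.get(node_index)
        if P is None:
            nd = self.model._nodes[node_index]
            P = self.cache.propagators.branch_matrix(nd.segments)
            self._branch_P[node_index] = P
        return P

    def sample(self, rng) -> History:
        model, cache = self.model, self.cache
        space, ev = model.space, model.events
        node_states: dict[str, int] = {}
        anagenetic: list[AnageneticEvent] = []
        cladogenetic: list[CladogeneticEvent] = []

        root = model._nodes[model._root_index]
        w = np.clip(model.root_prior * cache.L[model._root_index], 0.0,
                    None)
        w = w / w.sum()
        state = {root.index: int(rng.choice(len(w), p=w))}

        for nd in reversed(model._nodes):  # preorder
            si = state[nd.index]
            label = _node_label(nd.node)
            node_states[label] = space.states[si]
            if nd.tip_state is not None:
                continue
            # cladogenetic event, conditioned on data below both daughters
            lo, hi = self._ev_lo[si], self._ev_hi[si]
            li, ri = nd.child_indices
            Dl, Dr = cache.D[li], cache.D[ri]
            pw = np.clip(self.p_event[lo:hi]
                         * Dl[ev.left_idx[lo:hi]]
                         * Dr[ev.right_idx[lo:hi]], 0.0, None)
            tot = pw.sum()
            pick = lo + int(rng.choice(hi - lo, p=pw / tot))
            kind = EVENT_KINDS[ev.kinds[pick]]
            l_state = int(ev.left_idx[pick])
            r_state = int(ev.right_idx[pick])
            cladogenetic.append(CladogeneticEvent(
                node=label, kind=kind, parent_mask=space.states[si],
                left_mask=space.states[l_state],
                right_mask=space.states[r_state],
            ))
            # branch paths down to each child
            for ci, top_state in ((li, l_state), (ri, r_state)):
                child = model._nodes[ci]
                P = self.branch_P(ci)
                pz = np.clip(P[top_state, :] * cache.L[ci], 0.0, None)
                z = int(rng.choice(len(pz), p=pz / pz.sum()))
                state[ci] = z
                anagenetic.extend(
                    self._branch_events(ci, top_state, z, rng))
        return History(node_states=node_states, anagenetic=anagenetic,
                       cladogenetic=cladogenetic)

    def _branch_events(self, node_index: int, x: int, z: int, rng):
        nd = self.model._nodes[node_index]
        label = _node_label(nd.node)
        segs_old_first = list(reversed(nd.segments))
        parent_age = nd.node.parent.age
        # sample states at stratum boundaries, conditioning on the endpoint
        events: list[AnageneticEvent] = []
        cur = x
        age = parent_age
        for i, (k, dt) in enumerate(segs_old_first):
            remaining = segs_old_first[i + 1:]
            if remaining:
                S = self.cache.propagators.branch_matrix(
                    list(reversed(remaining)))
                Pseg = self.cache.propagators.P(k, dt)
                p = np.clip(Pseg[cur, :], 0.0, None) * np.clip(S[:, z], 0.0,
                                                               None)
                tot = p.sum()
                y = int(rng.choice(len(p), p=p / tot))
            else:
                y = z
            events.extend(_segment_events(
                self.uni, k, cur, y, age, age - dt, label,
                self.model.space, rng))
            cur = y
            age -= dt
        return events


def sample_history(model: RangeEvolutionModel, params: ModelParams,
                   seed: int = 0) -> History:
    """Draw one history consistent with the tip data under ``params``."""
    sampler = _Sampler(model, params)
    return sampler.sample(np.random.default_rng(seed))


def sample_histories(model: RangeEvolutionModel, params: ModelParams,
                     n_maps: int, seed: int = 0) -> list[History]:
    sampler = _Sampler(model, params)
    rng = np.random.default_rng(seed)
    return [sampler.sample(rng) for _ in range(n_maps)]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_MODE = {
    "range_expansion": "dispersal",
    "range_contraction": "dispersal",
    "founder": "dispersal",
    "sympatry": "within-area speciation",
    "subset_speciation": "within-area speciation",
    "vicariance": "vicariance",
}


def summarize_bsm(model: RangeEvolutionModel, params: ModelParams,
                  n_maps: int = 50, seed: int = 0) -> pd.DataFrame:
    """Mean, s.d. and percentage of each event category over ``n_maps``.

    The percentage denominator is the grand-total mean event count
    (anagenetic + cladogenetic), so percentages sum to 100.
    """
    if n_maps < 2:
        raise ValueError("n_maps must be >= 2")
    histories = sample_histories(model, params, n_maps, seed)
    return summarize_counts([count_events(h) for h in histories])


def summarize_counts(counts: Sequence[EventCounts]) -> pd.DataFrame:
    arr = np.array([[c.counts[cat] for cat in CATEGORIES] for c in counts],
                   dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    grand = means.sum()
    pct = 100.0 * means / grand if grand > 0 else np.zeros_like(means)
    return pd.DataFrame({
        "mode": [_MODE[c] for c in CATEGORIES],
        "type": CATEGORIES,
        "mean": means,
        "sd": sds,
        "percent": pct,
    })


def percentage_from_means(means: dict[str, float]) -> dict[str, float]:
    """Percentages implied by per-category mean counts (same convention)."""
    grand = sum(means.values())
    return {c: 100.0 * v / grand for c, v in means.items()}


def history_to_frame(history: History, space) -> pd.DataFrame:
    """Tidy per-event log: branch/node, time (Ma), type, from- and to-range.

    Cladogenetic events carry no time of their own beyond their node; the
    two daughter ranges are reported in the from/to columns.
    """
    rows = []
    for ev in history.anagenetic:
        rows.append((ev.branch, ev.time, ev.category,
                     space.state_label(ev.from_mask),
                     space.state_label(ev.to_mask)))
    for ev in history.cladogenetic:
        rows.append((ev.node, np.nan, ev.category,
                     space.state_label(ev.parent_mask),
                     space.state_label(ev.left_mask) + " / "
                     + space.state_label(ev.right_mask)))
    return pd.DataFrame(rows, columns=["branch", "time_ma", "type",
                                       "from_range", "to_range"])


def dispersal_directions(histories: Sequence[History],
                         areas: Sequence[str]) -> pd.DataFrame:
    """Source -> sink area-pair counts for expansions and founder events.

    For a range expansion the source is every area of the pre-event range;
    for a founder event, every area of the parent range.  Counts are means
    per history.
    """
    n = len(areas)
    mat = np.zeros((n, n))
    for h in histories:
        for ev in h.anagenetic:
            gained = ev.to_mask & ~ev.from_mask
            if not gained:
                continue
            b = gained.bit_length() - 1
            for a in range(n):
                if ev.from_mask >> a & 1:
                    mat[a, b] += 1
        for ev in h.cladogenetic:
            if ev.kind != "jump":
                continue
            target = (ev.left_mask if not ev.left_mask & ev.parent_mask
                      else ev.right_mask)
            b = target.bit_length() - 1
            for a in range(n):
                if ev.parent_mask >> a & 1:
                    mat[a, b] += 1
    mat /= max(len(histories), 1)
    return pd.DataFrame(mat, index=list(areas), columns=list(areas))
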