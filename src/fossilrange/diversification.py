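"""Time-sliced diversification-shift detection and diversity curves.

Shift detection works on *time-sliced trees*: for a slice time t, the tree
of all taxa with FAD >= t keeps its original topology, and every branch
crossing t whose entire descendant clade is younger is collapsed into a
single "ghost" terminal.  Per internal node of a sliced tree the imbalance
of the split is scored with an equal-rates-Markov (ERM) tail probability —
under ERM the ordered daughter size of an n-terminal node is uniform on
1..n-1, so P(larger daughter >= L) = 2(n - L)/(n - 1) for L > n/2.
Family-wise calibration simulates the null distribution of the tree-wide
minimum tail over ERM trees of the same size.

Detected shifts are cross-examined against the fossil ages: a shift whose
clade is dominated by taxa already extinct before the focal bin, or whose
balance did not change since the previous bin, is flagged as a possible
artefact of extinction rather than diversification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AgeTable
from .trees import Node, TimeTree

__all__ = [
    "TimeBin",
    "validate_bins",
    "SliceNode",
    "time_slice",
    "erm_split_tail",
    "simulate_erm_min_tails",
    "detect_shifts",
    "flag_artefacts",
    "ShiftReport",
    "taxic_curve",
    "phyletic_curve",
    "diversity_curves",
    "plot_diversity_curves",
]


@dataclass(frozen=True)
class TimeBin:
    name: str
    older: float
    younger: float

    def __post_init__(self):
        if not self.older > self.younger:
            raise ValueError(f"bin {self.name}: bounds not ordered")


def validate_bins(bins: Sequence[TimeBin]) -> list[TimeBin]:
    bins = list(bins)
    for a, b in zip(bins, bins[1:]):
        if a.younger != b.older:
            raise ValueError(f"bins {a.name} and {b.name} not contiguous")
    return bins


# ---------------------------------------------------------------------------
# Time-sliced trees
# ---------------------------------------------------------------------------

@dataclass
class SliceNode:
    """Node of a time-sliced tree; terminals may be sampled taxa or ghosts."""

    original: Node
    children: list["SliceNode"] = field(default_factory=list)
    ghost: bool = False

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def label(self) -> str:
        node = self.original
        if node.is_leaf:
            return node.label
        leaves = sorted(l.label for l in node.leaves())
        return leaves[0] + f"+{len(leaves) - 1}more" if len(leaves) > 1 else leaves[0]

    def terminals(self) -> list["SliceNode"]:
        if self.is_terminal:
            return [self]
        return [t for c in self.children for t in c.terminals()]

    def n_terminals(self) -> int:
        return len(self.terminals())

    def internal(self) -> list["SliceNode"]:
        if self.is_terminal:
            return []
        return [self] + [n for c in self.children for n in c.internal()]


def time_slice(tree: TimeTree, t: float,
               ages: AgeTable | Mapping[str, float] | None = None) -> SliceNode:
    """Slice a time tree at t Ma.

    Terminals are the taxa with FAD >= t (keeping their topology) plus one
    ghost terminal per crossing branch whose clade contains no such taxon.
    ``ages`` defaults to the leaf ages of the tree (leaf age = FAD).
    At t = 0 the slice is the identity with no ghosts.
    """
    if not (0 <= t < tree.root_age):
        raise ValueError(f"slice time {t} outside [0, root age "
                         f"{tree.root_age})")
    if ages is None:
        fad = {l.label: l.age for l in tree.leaves()}
    else:
        fad = ages.fad if hasattr(ages, "fad") else dict(ages)

    def build(node: Node) -> SliceNode:
        if node.is_leaf:
            return SliceNode(node, ghost=fad[node.label] < t)
        if node.age <= t:
            # the whole clade post-dates the slice: one ghost terminal for
            # the crossing branch
            return SliceNode(node, ghost=True)
        return SliceNode(node, children=[build(c) for c in node.children])

    return build(tree.root)


# ---------------------------------------------------------------------------
# ERM imbalance statistic
# ---------------------------------------------------------------------------

def erm_split_tail(n: int, L: int) -> float:
    """P(larger daughter >= L) at an n-terminal node under ERM.

    Under the equal-rates-Markov null the ordered daughter size is uniform
    on 1..n-1, so for n/2 < L <= n-1 the tail is 2(n - L)/(n - 1).
    """
    if n < 4:
        raise ValueError("tail statistic needs n >= 4")
    if not (n / 2 < L <= n - 1):
        raise ValueError(f"L={L} out of range ({n / 2}, {n - 1}] for n={n}")
    return 2.0 * (n - L) / (n - 1)


def _split_tail(a: int, b: int) -> float:
    """Tail of an observed (a, b) split; 1.0 when uninformative/balanced."""
    n = a + b
    L = max(a, b)
    if n < 4 or L <= n / 2:
        return 1.0
    return 2.0 * (n - L) / (n - 1)


def _erm_min_tail(n: int, rng: np.random.Generator) -> float:
    """Minimum split tail over one simulated n-terminal ERM tree."""
    best = 1.0
    stack = [n]
    while stack:
        m = stack.pop()
        if m < 2:
            continue
        a = int(rng.integers(1, m))
        b = m - a
        tail = _split_tail(a, b)
        if tail < best:
            best = tail
        stack.append(a)
        stack.append(b)
    return best


def simulate_erm_min_tails(n: int, n_null: int,
                           rng: np.random.Generator) -> np.ndarray:
    return np.array([_erm_min_tail(n, rng) for _ in range(n_null)])


# ---------------------------------------------------------------------------
# Shift detection
# ---------------------------------------------------------------------------

@dataclass
class ShiftReport:
    frame: pd.DataFrame                      # one row per flagged node
    thresholds: dict[str, float]             # per bin
    splits: dict[str, dict[str, tuple[int, int]]]  # bin -> node -> split
    skipped: list[str] = field(default_factory=list)
    alpha: float = 0.05


def detect_shifts(tree: TimeTree, bins: Sequence[TimeBin], alpha: float = 0.05,
                  n_null: int = 1999, seed: int = 0,
                  ages: AgeTable | None = None) -> ShiftReport:
    """Per-bin ERM shift detection with Monte-Carlo family-wise calibration.

    Each bin is sliced at its younger bound; nodes whose split tail falls
    at or below the empirical alpha-quantile of the null minimum-tail
    distribution (over ``n_null`` simulated ERM trees of the same size) are
    flagged.  Bins whose sliced tree has fewer than 4 terminals are skipped
    with a notice.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    bins = validate_bins(bins)
    rng = np.random.default_rng(seed)
    rows = []
    thresholds: dict[str, float] = {}
    splits: dict[str, dict[str, tuple[int, int]]] = {}
    skipped: list[str] = []
    null_cache: dict[int, np.ndarray] = {}

    for tb in bins:
        t = max(tb.younger, 0.0)
        if t >= tree.root_age:
            skipped.append(f"{tb.name}: slice time {t} at/above root age")
            continue
        sliced = time_slice(tree, t, ages)
        nterm = sliced.n_terminals()
        splits[tb.name] = {}
        if nterm < 4:
            skipped.append(f"{tb.name}: sliced tree has only {nterm} "
                           f"terminals")
            continue
        if nterm not in null_cache:
            null_cache[nterm] = np.sort(
                simulate_erm_min_tails(nterm, n_null, rng))
        null = null_cache[nterm]
        k = int(np.floor(alpha * (n_null + 1)))
        thr = null[k - 1] if k >= 1 else -np.inf
        thresholds[tb.name] = thr
        for node in sliced.internal():
            a = node.children[0].n_terminals()
            b = node.children[1].n_terminals()
            label = _clade_label(node.original)
            splits[tb.name][label] = (a, b)
            tail = _split_tail(a, b)
            if tail <= thr:
                rows.append({
                    "bin": tb.name, "node": label,
                    "n_terminals": a + b, "split": f"{max(a, b)}:{min(a, b)}",
                    "tail": tail, "threshold": thr,
                    "artefact": False, "reason": "",
                })
    frame = pd.DataFrame(
        rows, columns=["bin", "node", "n_terminals", "split", "tail",
                       "threshold", "artefact", "reason"])
    return ShiftReport(frame=frame, thresholds=thresholds, splits=splits,
                       skipped=skipped, alpha=alpha)


def _clade_label(node: Node) -> str:
    if node.is_leaf:
        return node.label
    return "|".join(sorted(c.leaves()[0].label for c in node.children))


def flag_artefacts(report: ShiftReport, tree: TimeTree, ages: AgeTable,
                   bins: Sequence[TimeBin], theta: float = 0.5) -> ShiftReport:
    """Mark detected shifts that are plausibly extinction artefacts.

    A shift at clade C in a bin is a possible artefact when (a) more than
    ``theta`` of C's taxa have a LAD older than the bin's older bound
    (the clade is dominated by lineages already extinct before the bin), or
    (b) C shows the identical split in the preceding bin's slice (no balance
    change).
    """
    bins = validate_bins(bins)
    order = {tb.name: i for i, tb in enumerate(bins)}
    by_name = {tb.name: tb for tb in bins}
    frame = report.frame.copy()
    clade_cache: dict[str, list[str]] = {}

    for idx, row in frame.iterrows():
        tb = by_name[row["bin"]]
        label = row["node"]
        if label not in clade_cache:
            node = _find_clade(tree, label)
            clade_cache[label] = [l.label for l in node.leaves()]
        taxa = [t for t in clade_cache[label] if t in ages.fad]
        reasons = []
        if taxa:
            extinct_before = sum(1 for t in taxa if ages.lad[t] > tb.older)
            if extinct_before / len(taxa) > theta:
                reasons.append(
                    f"{extinct_before}/{len(taxa)} taxa extinct before the "
                    f"bin"
                )
        i = order[tb.name]
        if i > 0:
            prev = bins[i - 1].name
            prev_splits = report.splits.get(prev, {})
            if label in prev_splits:
                cur = tuple(sorted(report.splits[tb.name][label]))
                if tuple(sorted(prev_splits[label])) == cur:
                    reasons.append("no balance change from preceding bin")
        if reasons:
            frame.at[idx, "artefact"] = True
            frame.at[idx, "reason"] = "; ".join(reasons)
    return ShiftReport(frame=frame, thresholds=report.thresholds,
                       splits=report.splits, skipped=report.skipped,
                       alpha=report.alpha)


def _find_clade(tree: TimeTree, label: str) -> Node:
    for node in tree.preorder():
        if _clade_label(node) == label:
            return node
    raise KeyError(f"clade {label} not found")


# ---------------------------------------------------------------------------
# Diversity curves
# ---------------------------------------------------------------------------

def taxic_curve(ages: AgeTable, bins: Sequence[TimeBin]) -> list[int]:
    """Number of taxa whose [LAD, FAD] range intersects each bin (closed)."""
    bins = validate_bins(bins)
    out = []
    for tb in bins:
        out.append(sum(1 for t in ages.taxa
                       if ages.fad[t] >= tb.younger
                       and ages.lad[t] <= tb.older))
    return out


def phyletic_curve(tree: TimeTree, ages: AgeTable,
                   bins: Sequence[TimeBin]) -> list[int]:
    """Lineages (tree edges, including ghost time) alive in each bin.

    A terminal edge unioned with its taxon's observed [LAD, FAD] range
    counts as one lineage; an internal edge spans parent age to child age.
    Closed-interval intersection.
    """
    bins = validate_bins(bins)
    spans = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        older = node.parent.age
        younger = node.age
        if node.is_leaf and node.label in ages.fad:
            older = max(older, ages.fad[node.label])
            younger = min(younger, ages.lad[node.label])
        spans.append((older, younger))
    out = []
    for tb in bins:
        out.append(sum(1 for older, younger in spans
                       if older >= tb.younger and younger <= tb.older))
    return out


def diversity_curves(tree: TimeTree, ages: AgeTable,
                     bins: Sequence[TimeBin]) -> pd.DataFrame:
    bins = validate_bins(bins)
    return pd.DataFrame({
        "bin": [tb.name for tb in bins],
        "older": [tb.older for tb in bins],
        "younger": [tb.younger for tb in bins],
        "taxic": taxic_curve(ages, bins),
        "phyletic": phyletic_curve(tree, ages, bins),
    })


def plot_diversity_curves(curves: pd.DataFrame, ax=None):
    """Taxic (squares) and phyletic (circles) counts against bin midpoints."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    mid = (curves["older"] + curves["younger"]) / 2.0
    ax.plot(mid, curves["phyletic"], "o-", label="phyletic")
    ax.plot(mid, curves["taxic"], "s--", label="taxic")
    ax.set_xlabel("time (Ma)")
    ax.set_ylabel("lineages")
    ax.invert_xaxis()
    ax.legend()
    return ax
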