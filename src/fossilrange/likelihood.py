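"""Time-stratified likelihood, ML fitting and ancestral-range estimation.

The model is exposed statsmodels-style: :class:`RangeEvolutionModel` is
built from a time tree plus a geography table and a :class:`ModelSpec`;
``fit()`` returns a :class:`RangeEvolutionResults` carrying the MLE, its
log-likelihood, AICc and convergence diagnostics, from which ancestral
marginals and stochastic maps are computed.

Likelihood: Felsenstein pruning over the range state space.  Along a branch
the conditional-likelihood vector is propagated through exp(Q_s * t_s) for
each time stratum the branch crosses, chained oldest to youngest; at an
internal node daughter vectors are mixed through the cladogenetic event
table.  The root is summed against a prior that is uniform over the
non-null states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2

from .data import GeographyTable
from .model import (CladogenesisEvents, ModelParams, ModelSpec, StateSpace,
                    Stratum, build_q, validate_strata)
from .trees import Node, TimeTree

__all__ = [
    "RangeEvolutionModel",
    "RangeEvolutionResults",
    "branch_likelihood",
    "tree_loglik",
    "ancestral_marginals",
    "lrt",
    "aicc",
]

_LOG10_RATE_LO, _LOG10_RATE_HI = -12.0, np.log10(5.0)
_X_LO, _X_HI = -5.0, 0.0
_J_LO, _J_HI = 0.0, 2.99999


# ---------------------------------------------------------------------------
# Branch segmentation and propagators
# ---------------------------------------------------------------------------

def branch_segments(child_age: float, parent_age: float,
                    strata: Sequence[Stratum]) -> list[tuple[int, float]]:
    """Split a branch at stratum boundaries.

    Returns (stratum index, segment duration) pairs ordered youngest first,
    which is the order in which per-segment propagators are applied to the
    tipward conditional vector.
    """
    if not parent_age > child_age:
        raise ValueError("branch must have positive duration")
    if parent_age > strata[0].older + 1e-9 or child_age < strata[-1].younger - 1e-9:
        raise ValueError(
            f"branch [{parent_age}, {child_age}] Ma lies outside the "
            f"declared strata [{strata[0].older}, {strata[-1].younger}]"
        )
    segs: list[tuple[int, float]] = []
    for k in range(len(strata) - 1, -1, -1):  # youngest stratum first
        s = strata[k]
        lo = max(child_age, s.younger)
        hi = min(parent_age, s.older)
        if hi > lo + 1e-12:
            segs.append((k, hi - lo))
    return segs


class Propagators:
    """exp(Q_s t) factory with eigendecomposition fast path.

    One rate matrix per stratum; each Q is eigendecomposed once and P(t)
    reconstructed per duration, falling back to scipy's expm when the
    decomposition is ill-conditioned.  Results are cached by (stratum, t).
    """

    def __init__(self, space: StateSpace, params: ModelParams,
                 strata: Sequence[Stratum]):
        self.space = space
        self.strata = list(strata)
        self.Qs = [build_q(space, params, s) for s in self.strata]
        self._eig = []
        for Q in self.Qs:
            self._eig.append(self._try_eig(Q))
        self._cache: dict[tuple[int, float], np.ndarray] = {}

    @staticmethod
    def _try_eig(Q: np.ndarray):
        try:
            w, V = scipy.linalg.eig(Q)
            if np.linalg.cond(V) > 1e12:
                return None
            Vinv = scipy.linalg.inv(V)
        except (scipy.linalg.LinAlgError, ValueError):
            return None
        resid = np.max(np.abs((V * w) @ Vinv - Q))
        scale = max(1.0, np.max(np.abs(Q)))
        if resid > 1e-9 * scale:
            return None
        return w, V, Vinv

    def P(self, stratum_idx: int, t: float) -> np.ndarray:
        key = (stratum_idx, round(t, 12))
        out = self._cache.get(key)
        if out is None:
            eig = self._eig[stratum_idx]
            if eig is not None:
                w, V, Vinv = eig
                out = np.real((V * np.exp(w * t)) @ Vinv)
            else:
                out = scipy.linalg.expm(self.Qs[stratum_idx] * t)
            self._cache[key] = out
        return out

    def branch_matrix(self, segs: Sequence[tuple[int, float]]) -> np.ndarray:
        """Total transition matrix over a branch, rows = older endpoint."""
        out = None
        for k, dt in reversed(list(segs)):  # oldest first
            P = self.P(k, dt)
            out = P if out is None else out @ P
        return out


def branch_likelihood(L_top: np.ndarray, child_age: float, parent_age: float,
                      strata: Sequence[Stratum],
                      propagators: Propagators) -> np.ndarray:
    """Propagate a tipward conditional vector to the rootward branch end.

    L_bottom(i) = sum_j P(i -> j over the branch) L_top(j), with the branch
    split at stratum boundaries.  A zero-duration branch is the identity.
    """
    if parent_age == child_age:
        return np.array(L_top, dtype=float)
    L = np.asarray(L_top, dtype=float)
    for k, dt in branch_segments(child_age, parent_age, strata):
        L = propagators.P(k, dt) @ L
    return L


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------

@dataclass
class _NodeData:
    node: Node
    index: int
    parent_index: int | None
    child_indices: list[int]
    segments: list[tuple[int, float]] | None  # None for the root
    tip_state: int | None = None


class PruningCache:
    """Per-node conditional vectors and propagators for one parameter set."""

    def __init__(self, L: list[np.ndarray], D: list[np.ndarray | None],
                 loglik: float, propagators: Propagators):
        self.L = L          # scaled tipward conditional vector per node
        self.D = D          # vector propagated to the top of the branch
        self.loglik = loglik
        self.propagators = propagators


class RangeEvolutionModel:
    """Likelihood model of geographic-range evolution on a time tree.

    Parameters
    ----------
    tree : TimeTree
        Time-scaled rooted binary tree, ages in Ma.
    geography : GeographyTable
        Observed presence/absence ranges for every leaf.
    spec : ModelSpec
        Family (DEC / DIVALIKE / BAYAREA), tier (M0/M1/M2) and range cap.
    strata : sequence of Stratum
        Contiguous time slices (oldest first) covering the whole tree, each
        optionally with its own inter-area distance matrix.
    """

    def __init__(self, tree: TimeTree, geography: GeographyTable,
                 spec: ModelSpec, strata: Sequence[Stratum],
                 root_prior: int | None = None):
        self.tree = tree
        self.geography = geography
        self.spec = spec
        self.strata = validate_strata(strata)
        if tree.root_age > self.strata[0].older + 1e-9:
            raise ValueError(
                f"root age {tree.root_age} exceeds the oldest stratum bound "
                f"{self.strata[0].older}"
            )
        self.space = StateSpace(geography.areas, spec.max_range_size)
        self.events = CladogenesisEvents(spec, self.space)
        self.nobs = len(tree.leaf_labels)

        missing = [l for l in tree.leaf_labels if l not in geography.ranges]
        if missing:
            raise ValueError(f"leaves without geography: {missing}")

        # flatten the tree into postorder arrays
        self._nodes: list[_NodeData] = []
        order = list(tree.postorder())
        idx = {id(n): i for i, n in enumerate(order)}
        for node in order:
            parent_index = idx[id(node.parent)] if node.parent else None
            segs = None
            if node.parent is not None:
                segs = branch_segments(node.age, node.parent.age, self.strata)
            nd = _NodeData(node=node, index=idx[id(node)],
                           parent_index=parent_index,
                           child_indices=[idx[id(c)] for c in node.children],
                           segments=segs)
            if node.is_leaf:
                mask = geography.ranges[node.label]
                if mask not in self.space.index:
                    raise ValueError(
                        f"tip {node.label} range {geography.bits(node.label)} "
                        f"wider than the max range size m={self.space.m}"
                    )
                nd.tip_state = self.space.index[mask]
            self._nodes.append(nd)
        self._root_index = idx[id(tree.root)]

        # root prior: uniform over non-null states by default, or a point
        # mass on a known root range (useful when cross-validating against
        # forward simulations started from a fixed range)
        pi = np.zeros(self.space.nstates)
        if root_prior is None:
            pi[1:] = 1.0 / (self.space.nstates - 1)
        else:
            if root_prior not in self.space.index or root_prior == 0:
                raise ValueError("root_prior must be a non-null range mask")
            pi[self.space.index[root_prior]] = 1.0
        self.root_prior = pi

    # -- likelihood ---------------------------------------------------------

    def _pruning(self, params: ModelParams, keep: bool = False):
        prop = Propagators(self.space, params, self.strata)
        n = self.space.nstates
        L: list[np.ndarray | None] = [None] * len(self._nodes)
        D: list[np.ndarray | None] = [None] * len(self._nodes)
        logscale = 0.0
        for nd in self._nodes:
            if nd.tip_state is not None:
                vec = np.zeros(n)
                vec[nd.tip_state] = 1.0
            else:
                kids = []
                for ci in nd.child_indices:
                    child = self._nodes[ci]
                    Dc = L[ci]
                    for k, dt in child.segments:
                        Dc = prop.P(k, dt) @ Dc
                    D[ci] = Dc
                    kids.append(Dc)
                vec = self.events.combine(params, kids[0], kids[1])
            s = vec.sum()
            if not np.isfinite(s) or s <= 0:
                return None if not keep else (None, None)
            vec = vec / s
            logscale += np.log(s)
            L[nd.index] = vec
        loglik = float(np.log(self.root_prior @ L[self._root_index]) + logscale)
        if not keep:
            return loglik
        return loglik, PruningCache(L, D, loglik, prop)

    def loglike(self, params: ModelParams) -> float:
        """Log-likelihood of the tip ranges under the given parameters."""
        ll = self._pruning(params)
        return -np.inf if ll is None else ll

    # -- fitting ------------------------------------------------------------

    def _pack_bounds(self):
        bounds = [(_LOG10_RATE_LO, _LOG10_RATE_HI),
                  (_LOG10_RATE_LO, _LOG10_RATE_HI)]
        if self.spec.x_free:
            bounds.append((_X_LO, _X_HI))
        if self.spec.j_free:
            bounds.append((_J_LO, _J_HI))
        return bounds

    def _unpack(self, theta: np.ndarray) -> ModelParams:
        d = 10.0 ** theta[0]
        e = 10.0 ** theta[1]
        pos = 2
        x = 0.0
        if self.spec.x_free:
            x = float(theta[pos]); pos += 1
        j = 0.0
        if self.spec.j_free:
            j = float(theta[pos])
        return ModelParams(d=d, e=e, x=x, j=j)

    def fit(self, n_starts: int = 5, seed: int = 0,
            start: ModelParams | None = None,
            maxiter: int = 500) -> "RangeEvolutionResults":
        """Maximise the likelihood with a bounded quasi-Newton optimiser.

        ``n_starts`` L-BFGS-B runs are launched from a deterministic,
        seed-derived list of starting points (the first start is d = e =
        0.01 /Myr, x = 0, j = 0.1 where free, unless ``start`` is given);
        the best converged optimum is reported.  Refitting with the same
        seed reproduces the result bit-for-bit.
        """
        bounds = self._pack_bounds()
        rng = np.random.default_rng(seed)

        starts = []
        if start is not None:
            theta0 = [np.log10(max(start.d, 1e-12)),
                      np.log10(max(start.e, 1e-12))]
            if self.spec.x_free:
                theta0.append(start.x)
            if self.spec.j_free:
                theta0.append(start.j)
            starts.append(np.array(theta0))
        else:
            theta0 = [-2.0, -2.0]
            if self.spec.x_free:
                theta0.append(0.0)
            if self.spec.j_free:
                theta0.append(0.1)
            starts.append(np.array(theta0))
        while len(starts) < n_starts:
            theta = [rng.uniform(-4.0, 0.5), rng.uniform(-4.0, 0.5)]
            if self.spec.x_free:
                theta.append(rng.uniform(-2.0, 0.0))
            if self.spec.j_free:
                theta.append(rng.uniform(0.0, 2.0))
            starts.append(np.array(theta))

        def nll(theta):
            ll = self.loglike(self._unpack(theta))
            return 1e12 if not np.isfinite(ll) else -ll

        best = None
        diagnostics = []
        for theta0 in starts:
            res = scipy.optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8},
            )
            diagnostics.append({
                "start": theta0.tolist(), "fun": float(res.fun),
                "success": bool(res.success), "nit": int(res.nit),
                "message": str(res.message),
            })
            if best is None or res.fun < best.fun:
                best = res
        params = self._unpack(best.x)
        converged = any(d["success"] for d in diagnostics)
        return RangeEvolutionResults(
            model=self, params=params, llf=float(-best.fun),
            converged=converged, diagnostics=diagnostics, fit_seed=seed,
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class RangeEvolutionResults:
    """MLE of a :class:`RangeEvolutionModel` with model-selection scores."""

    model: RangeEvolutionModel
    params: ModelParams
    llf: float
    converged: bool = True
    diagnostics: list = field(default_factory=list)
    fit_seed: int | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.nobs)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Range-evolution model {self.spec.name}",
            f"  tips: {self.nobs}   areas: {self.model.space.nareas}   "
            f"states: {self.model.space.nstates} (m={self.model.space.m})",
            f"  LnL:  {self.llf:.4f}   k: {self.k}   AICc: {self.aicc:.4f}",
            f"  d: {p.d:.6g} /Myr   e: {p.e:.6g} /Myr",
        ]
        if self.spec.x_free:
            lines.append(f"  x: {p.x:.6g}")
        if self.spec.j_free:
            lines.append(f"  j: {p.j:.6g}")
        lines.append(f"  converged: {self.converged}")
        return "\n".join(lines)

    def ancestral_marginals(self) -> pd.DataFrame:
        """Marginal posterior state probabilities for every internal node."""
        return ancestral_marginals(self.model, self.params)

    def annotated_tree(self) -> str:
        """Newick with internal nodes labelled by their modal range."""
        from .trees import _copy_subtree, TimeTree, write_tree
        marg = self.ancestral_marginals()
        best = marg.loc[marg.groupby("node")["probability"].idxmax()]
        modal = dict(zip(best["node"], best["state"]))
        root = _copy_subtree(self.model.tree.root)
        for node in root.preorder():
            if not node.is_leaf:
                node.label = modal.get(_node_label(node), "")
        return write_tree(TimeTree(root))

    def stochastic_maps(self, n_maps: int = 50, seed: int = 0):
        from .bsm import sample_histories
        return sample_histories(self.model, self.params, n_maps, seed)

    def summarize_bsm(self, n_maps: int = 50, seed: int = 0) -> pd.DataFrame:
        from .bsm import summarize_bsm
        return summarize_bsm(self.model, self.params, n_maps=n_maps,
                             seed=seed)


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------

def tree_loglik(tree: TimeTree, geo: GeographyTable, spec: ModelSpec,
                params: ModelParams, strata: Sequence[Stratum]) -> float:
    """Convenience wrapper: log-likelihood without building a model object."""
    return RangeEvolutionModel(tree, geo, spec, strata).loglike(params)


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion; n is the number of tips."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def lrt(fit_null, fit_alt, tol: float = 1e-6):
    """Likelihood-ratio test between nested fits.

    Accepts results objects or (LnL, k) tuples.  G slightly below zero
    (within ``tol``) is clamped to 0 to absorb optimiser noise.
    Returns (G, df, p).
    """
    def _get(f):
        if hasattr(f, "llf"):
            return f.llf, f.k, getattr(f, "spec", None)
        lnl, k = f
        return lnl, k, None

    lnl0, k0, spec0 = _get(fit_null)
    lnl1, k1, spec1 = _get(fit_alt)
    if spec0 is not None and spec1 is not None:
        if spec0.family != spec1.family:
            raise ValueError("LRT requires models of the same family")
    df = k1 - k0
    if df <= 0:
        raise ValueError("alternative model must have more free parameters")
    G = 2.0 * (lnl1 - lnl0)
    if G < 0:
        if G < -tol:
            raise ValueError(
                f"alternative LnL below null by {-G / 2:.3g}: models not "
                f"nested or optimiser failed"
            )
        G = 0.0
    return G, df, float(chi2.sf(G, df))


def ancestral_marginals(model: RangeEvolutionModel,
                        params: ModelParams) -> pd.DataFrame:
    """Marginal ancestral-range probabilities by up-pass/down-pass.

    The state of a node is its range immediately before its own cladogenetic
    event.  Returns a tidy frame (node, state, probability) where nodes are
    labelled by the sorted pair of first leaves of their daughter clades.
    """
    out = model._pruning(params, keep=True)
    if out[0] is None:
        raise ValueError("zero likelihood under these parameters")
    _, cache = out
    space, events = model.space, model.events
    p_event = events.probabilities(params)

    O: list[np.ndarray | None] = [None] * len(model._nodes)
    O[model._root_index] = model.root_prior.copy()
    rows = []
    # preorder = reversed postorder
    for nd in reversed(model._nodes):
        if nd.tip_state is not None:
            continue
        Ov = O[nd.index]
        li, ri = nd.child_indices
        Dl, Dr = cache.D[li], cache.D[ri]
        marg = Ov * cache.L[nd.index]
        total = marg.sum()
        marg = marg / total
        label = _node_label(nd.node)
        for s, prob in zip(space.states, marg):
            if prob > 1e-12:
                rows.append((label, space.state_label(s), float(prob)))
        # outside vectors for the children
        contrib = p_event * Ov[events.parent_idx]
        H_left = np.bincount(events.left_idx,
                             weights=contrib * Dr[events.right_idx],
                             minlength=space.nstates)
        H_right = np.bincount(events.right_idx,
                              weights=contrib * Dl[events.left_idx],
                              minlength=space.nstates)
        for ci, H in ((li, H_left), (ri, H_right)):
            child = model._nodes[ci]
            Oc = H
            for k, dt in reversed(child.segments):  # oldest segment first
                Oc = cache.propagators.P(k, dt).T @ Oc
            s = Oc.sum()
            O[ci] = Oc / s if s > 0 else Oc
    df = pd.DataFrame(rows, columns=["node", "state", "probability"])
    return df


def _node_label(node: Node) -> str:
    if node.is_leaf:
        return node.label
    firsts = sorted(c.leaves()[0].label for c in node.children)
    return "|".join(firsts)
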