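"""Felsenstein pruning engine with edge-local updates.

The engine stores a rooted view of an unrooted tree (trifurcating seed
node).  Partial likelihoods are cached per node and per discrete-gamma
category; per-pattern log scalers guard against underflow.  Branch-length
proposals and optimization use an exact Euler-tour sweep: on entry to a
node the "outside" partial for its parent edge is assembled from cached
messages, the edge is re-evaluated/updated locally, and on exit the
downward message is refreshed — so every evaluation is exact while costing
only O(1) matrix products per edge.

Ascertainment conditioning for the binary restriction model (characters
that are absent everywhere are unobservable) is implemented by carrying
the all-absent pattern as an extra zero-weight column and subtracting
``N * log(1 - P(all absent))`` from the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from .models import AA_ORDER, RateModel, SubstitutionModel, covarion_matrix
from . import treeutil

MIN_BLEN = 1e-8
MAX_BLEN = 20.0

_AA_CODE = {a: i for i, a in enumerate(AA_ORDER)}
_BIN_CODE = {"0": 0, "1": 1}


def encode_sequence(seq: str, alphabet: str) -> np.ndarray:
    table = _AA_CODE if alphabet == "aa" else _BIN_CODE
    return np.array([table.get(c, -1) for c in seq.upper()], dtype=np.int16)


class PatternTable:
    """Distinct site patterns with multiplicities."""

    def __init__(
        self,
        taxa: list[str],
        codes: np.ndarray,
        weights: np.ndarray,
        site_to_pattern: np.ndarray,
        n_states: int,
    ):
        self.taxa = list(taxa)
        self.codes = codes  # (n_taxa, n_patterns), -1 = missing
        self.weights = weights.astype(float)
        self.site_to_pattern = site_to_pattern
        self.n_states = n_states
        if not np.isclose(self.weights.sum(), len(site_to_pattern)):
            raise ValueError("pattern weights must sum to the alignment length")

    @property
    def n_sites(self) -> int:
        return len(self.site_to_pattern)

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, seqs: dict[str, str], alphabet: str = "aa") -> "PatternTable":
        taxa = list(seqs)
        mat = np.stack([encode_sequence(seqs[t], alphabet) for t in taxa])
        uniq, inv, counts = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True
        )
        return cls(
            taxa,
            uniq.T.copy(),
            counts.astype(float),
            inv.astype(np.int64),
            20 if alphabet == "aa" else 2,
        )


class ArrayTree:
    """Index-based rooted representation of an unrooted tree."""

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        tree = treeutil.as_trifurcating(treeutil.clone(tree))
        self.taxa = list(taxa)
        tax_idx = {t: i for i, t in enumerate(taxa)}
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.blen = np.zeros(self.n_nodes)
        self.leaf_taxon = np.full(self.n_nodes, -1, dtype=np.int64)
        self.postorder = list(range(self.n_nodes))  # nodes already postorder
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = idx[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.blen[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                if nd.taxon.label not in tax_idx:
                    raise ValueError(f"taxon {nd.taxon.label!r} not in pattern table")
                self.leaf_taxon[i] = tax_idx[nd.taxon.label]
        self.root = self.n_nodes - 1
        self._dendropy_ref = tree
        self._node_objs = nodes

    def edge_nodes(self) -> list[int]:
        """All non-root nodes (each owns its parent edge)."""
        return [v for v in self.postorder if v != self.root]

    def edge_ids(self) -> dict[int, frozenset]:
        """node index -> canonical bipartition id of its parent edge."""
        labels = [
            set()
            if self.leaf_taxon[v] < 0
            else {self.taxa[self.leaf_taxon[v]]}
            for v in range(self.n_nodes)
        ]
        for v in self.postorder:
            for c in self.children[v]:
                labels[v] |= labels[c]
        full = frozenset(labels[self.root])
        ref = min(full)
        out = {}
        for v in self.edge_nodes():
            below = frozenset(labels[v])
            out[v] = below if ref not in below else full - below
        return out

    def to_dendropy(self) -> dendropy.Tree:
        for i, nd in enumerate(self._node_objs):
            if nd.parent_node is not None:
                nd.edge.length = float(self.blen[i])
        return treeutil.clone(self._dendropy_ref)


@dataclass
class _EdgeHandle:
    """Callback handle passed to sweep visitors for one edge."""

    engine: "TreeLikelihood"
    node: int

    @property
    def length(self) -> float:
        return float(self.engine.atree.blen[self.node])

    def candidate_loglik(self, t: float) -> float:
        return self.engine._edge_loglik(self.node, t)

    def commit(self, t: float) -> None:
        self.engine._commit_length(self.node, t)


class TreeLikelihood:
    """Likelihood of a pattern table on a fixed topology."""

    def __init__(
        self,
        tree: dendropy.Tree | ArrayTree,
        patterns: PatternTable,
        model: SubstitutionModel,
        rates: RateModel,
        condition_observable: bool = False,
        root_freq: np.ndarray | None = None,
        dtype=np.float64,
    ):
        self.patterns = patterns
        self.model = model
        self.rates = rates
        self.condition_observable = condition_observable
        self.dtype = dtype
        if isinstance(tree, ArrayTree):
            self.atree = tree
        else:
            self.atree = ArrayTree(tree, patterns.taxa)
        if condition_observable and model.kind != "binary-restriction":
            raise ValueError("observability conditioning is for the binary model")
        codes = patterns.codes
        weights = patterns.weights
        if condition_observable:
            codes = np.concatenate(
                [codes, np.zeros((codes.shape[0], 1), dtype=codes.dtype)], axis=1
            )
            weights = np.concatenate([weights, [0.0]])
            self._cond_idx = codes.shape[1] - 1
        else:
            self._cond_idx = None
        self._codes = codes
        self._weights = weights
        self._n_data = float(patterns.weights.sum())
        self._root_override = root_freq
        self._build_model(root_freq)
        self._alloc()
        self._stale = True

    # -- model spectral setup -------------------------------------------------

    def _build_model(self, root_freq):
        m, r = self.model, self.rates
        ncat = r.n_categories
        if r.covarion is not None:
            s_on, s_off = r.covarion
            if s_on <= 0 or s_off <= 0:
                raise ValueError("covarion switch rates must be > 0 when enabled")
            mats = [covarion_matrix(m, rate, s_on, s_off) for rate in r.rates]
            self.ns = 2 * m.n_states
            self._obs_states = m.n_states
        else:
            mats = [(rate * m.rate_matrix, m.freqs) for rate in r.rates]
            self.ns = m.n_states
            self._obs_states = m.n_states
        self._U = np.empty((ncat, self.ns, self.ns))
        self._V = np.empty((ncat, self.ns, self.ns))
        self._w = np.empty((ncat, self.ns))
        for c, (Q, pi) in enumerate(mats):
            d = np.sqrt(pi)
            B = (Q * d[:, None]) / d[None, :]
            B = 0.5 * (B + B.T)  # symmetric for reversible Q; guards roundoff
            w, E = eigh(B)
            self._U[c] = E / d[:, None]
            self._V[c] = E.T * d[None, :]
            self._w[c] = w
        pi_full = mats[0][1]
        if root_freq is None:
            self._root_freq = pi_full.astype(self.dtype)
        else:
            root_freq = np.asarray(root_freq, dtype=self.dtype)
            if root_freq.shape != (self.ns,):
                raise ValueError("root frequency vector has wrong length")
            self._root_freq = root_freq
        self._cat_w = np.full(ncat, 1.0 / ncat)

    def _pmats(self, t: float) -> np.ndarray:
        """(ncat, ns, ns) transition matrices for branch length t."""
        e = np.exp(self._w * t)  # (ncat, ns)
        P = np.matmul(self._U * e[:, None, :], self._V)
        np.maximum(P, 0.0, out=P)
        return P.astype(self.dtype, copy=False)

    # -- partials -------------------------------------------------------------

    def _alloc(self):
        at = self.atree
        ncat, npat, ns = self.rates.n_categories, self._codes.shape[1], self.ns
        self._tipcond = {}
        n_obs = self._obs_states
        for v in range(at.n_nodes):
            ti = at.leaf_taxon[v]
            if ti >= 0:
                cond = np.zeros((npat, ns), dtype=self.dtype)
                cd = self._codes[ti]
                miss = cd < 0
                cond[miss, :] = 1.0
                ok = ~miss
                cond[np.nonzero(ok)[0], cd[ok]] = 1.0
                if ns != n_obs:  # covarion: observable state maps to ON and OFF
                    cond[np.nonzero(ok)[0], cd[ok] + n_obs] = 1.0
                self._tipcond[v] = cond
        self._down = [None] * at.n_nodes  # (ncat, npat, ns)
        self._tdown = [None] * at.n_nodes  # message to parent
        self._dlog = [None] * at.n_nodes  # (npat,)
        self._P = [None] * at.n_nodes
        self._PT = [None] * at.n_nodes

    def _refresh_edge_mats(self, v):
        P = self._pmats(self.atree.blen[v])
        self._P[v] = P
        self._PT[v] = np.ascontiguousarray(P.transpose(0, 2, 1))

    def _tip_message(self, v, P) -> np.ndarray:
        """Message from tip v to its parent for transition matrices P."""
        cd = self._codes[self.atree.leaf_taxon[v]]
        safe = np.clip(cd, 0, None)
        M = P[:, :, safe]  # (ncat, ns, npat)
        if self.ns != self._obs_states:
            M = M + P[:, :, safe + self._obs_states]
        M = np.ascontiguousarray(M.transpose(0, 2, 1))
        if (cd < 0).any():
            M[:, cd < 0, :] = 1.0
        return M

    def _node_down(self, v):
        """Recompute down[v] from children messages (or tip condition)."""
        at = self.atree
        if at.leaf_taxon[v] >= 0:
            self._down[v] = np.broadcast_to(
                self._tipcond[v], (self.rates.n_categories, *self._tipcond[v].shape)
            )
            self._dlog[v] = np.zeros(self._codes.shape[1])
            return
        prod = None
        dlog = np.zeros(self._codes.shape[1])
        for c in at.children[v]:
            prod = self._tdown[c].copy() if prod is None else prod * self._tdown[c]
            dlog += self._dlog[c]
        mx = prod.max(axis=(0, 2))
        mx[mx == 0.0] = 1.0
        prod /= mx[None, :, None]
        self._down[v] = prod
        self._dlog[v] = dlog + np.log(mx)

    def _node_tdown(self, v):
        if self.atree.leaf_taxon[v] >= 0:
            self._tdown[v] = self._tip_message(v, self._P[v])
        else:
            self._tdown[v] = np.matmul(self._down[v], self._PT[v])

    def full_recompute(self):
        at = self.atree
        for v in at.postorder:
            self._node_down(v)
            if v != at.root:
                self._refresh_edge_mats(v)
                self._node_tdown(v)
        self._dirty = np.zeros(at.n_nodes, dtype=bool)
        self._stale = False

    # -- likelihood -----------------------------------------------------------

    def _pattern_loglik(self) -> np.ndarray:
        root = self.atree.root
        like = np.einsum(
            "c,s,cps->p", self._cat_w, self._root_freq, self._down[root]
        )
        like = np.maximum(like, 1e-300)
        return np.log(like) + self._dlog[root]

    def loglik(self) -> float:
        if self._stale:
            self.full_recompute()
        lnl = self._pattern_loglik()
        return self._combine(lnl)

    def _combine(self, pattern_lnl: np.ndarray) -> float:
        total = float(np.dot(self._weights, pattern_lnl))
        if self._cond_idx is not None:
            p0 = np.exp(pattern_lnl[self._cond_idx])
            if p0 >= 1.0:
                raise FloatingPointError("all-absent probability reached 1")
            total -= self._n_data * np.log1p(-p0)
        return total

    def site_logliks(self) -> np.ndarray:
        """Per-site log-likelihoods (conditioned if applicable)."""
        if self._stale:
            self.full_recompute()
        lnl = self._pattern_loglik()
        if self._cond_idx is not None:
            p0 = np.exp(lnl[self._cond_idx])
            lnl = lnl - np.log1p(-p0)
            lnl = lnl[: self._cond_idx]
        return lnl[self.patterns.site_to_pattern]

    def pattern_logliks(self) -> np.ndarray:
        if self._stale:
            self.full_recompute()
        lnl = self._pattern_loglik()
        return lnl[: self._cond_idx] if self._cond_idx is not None else lnl

    # -- edge-local machinery -------------------------------------------------

    def _edge_loglik_from(self, F, flog, v, t) -> float:
        P = self._pmats(t)
        if self.atree.leaf_taxon[v] >= 0:
            M = self._tip_message(v, P)
        else:
            M = np.matmul(self._down[v], np.ascontiguousarray(P.transpose(0, 2, 1)))
        like = np.einsum("c,cps->p", self._cat_w, F * M)
        like = np.maximum(like, 1e-300)
        lnl = np.log(like) + flog + self._dlog[v]
        return self._combine(lnl)

    def _edge_loglik(self, v, t) -> float:
        return self._edge_loglik_from(self._F, self._flog, v, t)

    def _commit_length(self, v, t) -> None:
        self.atree.blen[v] = t
        self._refresh_edge_mats(v)
        self._dirty[v] = True

    def sweep(self, visitor) -> float:
        """Euler-tour over all edges; ``visitor(handle)`` per edge.

        Returns the total log-likelihood after the sweep.  The visitor may
        evaluate candidate lengths and commit a new length for the edge it
        is handed; all evaluations are exact for the current state.
        """
        at = self.atree
        if self._stale:
            self.full_recompute()
        npat = self._codes.shape[1]
        upnode = [None] * at.n_nodes
        ulog = [None] * at.n_nodes
        upnode[at.root] = np.broadcast_to(
            self._root_freq[None, None, :],
            (self.rates.n_categories, 1, self.ns),
        )
        ulog[at.root] = np.zeros(npat)

        def rec(v):
            p = at.parent[v]
            F = None
            flog = ulog[p].copy()
            for s in at.children[p]:
                if s == v:
                    continue
                F = self._tdown[s].copy() if F is None else F * self._tdown[s]
                flog += self._dlog[s]
            F = upnode[p] * F
            mx = F.max(axis=(0, 2))
            mx[mx == 0.0] = 1.0
            F = F / mx[None, :, None]
            flog = flog + np.log(mx)
            self._F, self._flog = F, flog
            self._dirty[v] = False
            visitor(_EdgeHandle(self, v))
            committed = self._dirty[v]
            kids = at.children[v]
            child_changed = False
            if kids:
                upnode[v] = np.matmul(F, self._P[v])
                ulog[v] = flog
                for w in kids:
                    rec(w)
                child_changed = any(self._dirty[w] for w in kids)
                if child_changed:
                    self._node_down(v)
                for w in kids:
                    self._dirty[w] = False
            if committed or child_changed:
                self._node_tdown(v)
            self._dirty[v] = committed or child_changed

        for v in at.children[at.root]:
            rec(v)
        if any(self._dirty[w] for w in at.children[at.root]):
            self._node_down(at.root)
        for w in at.children[at.root]:
            self._dirty[w] = False
        return self._combine(self._pattern_loglik())

    # -- optimization ---------------------------------------------------------

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_sweeps: int = 100
    ) -> tuple[float, bool]:
        """Coordinate ascent over branches; returns (lnL, converged)."""
        last = self.loglik()
        for _ in range(max_sweeps):
            def visit(h: _EdgeHandle):
                res = minimize_scalar(
                    lambda t: -h.candidate_loglik(t),
                    bounds=(MIN_BLEN, MAX_BLEN),
                    method="bounded",
                    options={"xatol": 1e-7},
                )
                if -res.fun > h.candidate_loglik(h.length):
                    h.commit(float(res.x))

            cur = self.sweep(visit)
            if cur < last - 1e-9:
                # ascent should never decrease; numerical guard
                cur = max(cur, last)
            if abs(cur - last) < tol:
                return cur, True
            last = cur
        return last, False

    def set_shape(self, shape: float) -> None:
        self.rates = self.rates.with_shape(shape)
        self._build_model(self._root_override)
        self._stale = True

    def optimize_shape_and_lengths(
        self, shape_bounds=(0.05, 20.0), tol: float = 1e-4, max_outer: int = 20
    ) -> tuple[float, float]:
        """Alternate gamma-shape and branch-length optimization."""
        best, _ = self.optimize_branch_lengths()
        for _ in range(max_outer):
            def neg(shape):
                self.set_shape(float(shape))
                return -self.loglik()

            res = minimize_scalar(
                neg, bounds=shape_bounds, method="bounded", options={"xatol": 1e-3}
            )
            self.set_shape(float(res.x))
            cur, _ = self.optimize_branch_lengths()
            if abs(cur - best) < tol:
                return cur, float(res.x)
            best = cur
        return best, float(self.rates.shape)
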