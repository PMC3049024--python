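"""Likelihood-based inference: pruning likelihoods, branch-length
optimization, Bayesian MCMC (fixed or free topology, optionally
Metropolis-coupled), majority-rule consensus and ML tree search.

The binary "restriction" model conditions every site likelihood on the
character being observable (not absent in every taxon), matching how
detection/non-detection characters arise: a family absent everywhere is
never detected, so all-absent patterns cannot occur in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import treeutil
from ._engine import (
    MAX_BLEN,
    MIN_BLEN,
    ArrayTree,
    PatternTable,
    TreeLikelihood,
)
from .models import (
    RateModel,
    SubstitutionModel,
    binary_restriction_model,
    discretize_gamma,
    empirical_aa_model,
)

__all__ = [
    "PatternTable",
    "RateModel",
    "SubstitutionModel",
    "binary_restriction_model",
    "empirical_aa_model",
    "discretize_gamma",
    "log_likelihood",
    "optimize_branch_lengths",
    "MCMCConfig",
    "ChainTrace",
    "mcmc_sample",
    "consensus_tree",
    "ml_search",
    "logdet_distance_matrix",
    "neighbor_joining_tree",
]


def log_likelihood(
    tree: dendropy.Tree,
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    condition_observable: bool = False,
    root_freq: np.ndarray | None = None,
) -> float:
    """Felsenstein pruning log-likelihood of ``patterns`` on ``tree``."""
    eng = TreeLikelihood(
        tree, patterns, model, rates, condition_observable, root_freq
    )
    lnl = eng.loglik()
    if not np.isfinite(lnl):
        per = eng.pattern_logliks()
        bad = int(np.nonzero(~np.isfinite(per))[0][0])
        raise FloatingPointError(f"non-finite likelihood at pattern {bad}")
    return lnl


def optimize_branch_lengths(
    tree: dendropy.Tree,
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    condition_observable: bool = False,
    optimize_shape: bool = False,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> tuple[dendropy.Tree, float, dict]:
    """Coordinate-ascent ML branch lengths (optionally also gamma shape).

    Returns (tree with optimized lengths, lnL, info).  ``info`` carries a
    ``converged`` flag and, when requested, the fitted ``shape``.
    """
    eng = TreeLikelihood(tree, patterns, model, rates, condition_observable)
    info: dict = {}
    if optimize_shape:
        lnl, shape = eng.optimize_shape_and_lengths(tol=max(tol, 1e-4))
        info["shape"] = shape
        info["converged"] = True
    else:
        lnl, converged = eng.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)
        info["converged"] = converged
    return eng.atree.to_dendropy(), lnl, info


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class MCMCConfig:
    """Metropolis(-coupled) MCMC settings.

    ``temperature`` follows the incremental-heating convention: chain i has
    heat 1 / (1 + temperature * i), chain 0 being the cold chain.
    """

    n_generations: int = 300_000
    sample_interval: int = 500
    burn_in: int = 0
    n_chains: int = 4
    temperature: float = 0.2
    blen_multiplier: float = 1.4  # half-width of log-multiplier window
    shape_window: float = 0.6
    estimate_shape: bool = True
    proposals_per_edge: int = 1  # consecutive proposals per edge visit
    shape_every: int = 1  # propose shape once per this many sweeps
    blen_prior_rate: float = 10.0
    shape_bounds: tuple[float, float] = (0.01, 100.0)
    seed: int = 0
    dtype: str = "float64"
    power: float = 1.0  # likelihood tempering for power posteriors

    def __post_init__(self):
        if self.burn_in >= self.n_generations:
            raise ValueError("burn_in must be < n_generations")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class ChainTrace:
    """Cold-chain samples: generation indices, log-likelihoods, parameters."""

    generations: np.ndarray
    logliks: np.ndarray
    shapes: np.ndarray
    tree_lengths: np.ndarray
    trees: list[str] | None = None
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.generations) > 1 and not np.all(np.diff(self.generations) > 0):
            raise ValueError("generation indices must be strictly increasing")

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("Gen\tLnL\tShape\tTreeLength\n")
            for g, l, s, tl in zip(
                self.generations, self.logliks, self.shapes, self.tree_lengths
            ):
                fh.write(f"{g}\t{l:.6f}\t{s:.6f}\t{tl:.6f}\n")


class _Chain:
    def __init__(self, engine: TreeLikelihood, heat: float, cfg: MCMCConfig, rng):
        self.eng = engine
        self.heat = heat
        self.cfg = cfg
        self.rng = rng
        self.lnl = engine.loglik()
        self.n_acc = {"blen": 0, "shape": 0, "topo": 0}
        self.n_try = {"blen": 0, "shape": 0, "topo": 0}

    def log_prior(self) -> float:
        lam = self.cfg.blen_prior_rate
        bl = self.eng.atree.blen[self.eng.atree.edge_nodes()]
        lp = len(bl) * math.log(lam) - lam * float(np.sum(bl))
        return lp

    def posterior(self) -> float:
        return self.lnl + self.log_prior()

    def sweep_branch_lengths(self, gen_cb) -> None:
        cfg, rng = self.cfg, self.rng
        lam_prior = cfg.blen_prior_rate

        def visit(h):
            for _ in range(max(cfg.proposals_per_edge, 1)):
                self.n_try["blen"] += 1
                t = h.length
                mult = math.exp(cfg.blen_multiplier * (rng.random() - 0.5))
                tn = t * mult
                if MIN_BLEN <= tn <= MAX_BLEN:
                    cand = h.candidate_loglik(tn)
                    dlp = cfg.power * (cand - self.lnl) - lam_prior * (tn - t)
                    ln_r = self.heat * dlp + math.log(mult)
                    if math.log(rng.random() + 1e-300) < ln_r:
                        h.commit(tn)
                        self.lnl = cand
                        self.n_acc["blen"] += 1
                gen_cb(self)

        self.eng.sweep(visit)

    def propose_shape(self) -> None:
        cfg, rng = self.cfg, self.rng
        self.n_try["shape"] += 1
        eng = self.eng
        old = eng.rates.shape
        lo, hi = cfg.shape_bounds
        new = old + cfg.shape_window * (rng.random() - 0.5)
        while new < lo or new > hi:  # reflect
            if new < lo:
                new = 2 * lo - new
            if new > hi:
                new = 2 * hi - new
        # snapshot cached state so a rejection restores instead of recomputing
        saved = (eng.rates, eng._U, eng._V, eng._w,
                 list(eng._down), list(eng._tdown), list(eng._dlog),
                 list(eng._P), list(eng._PT))
        eng.set_shape(new)
        cand = eng.loglik()
        if math.log(rng.random() + 1e-300) < self.heat * cfg.power * (cand - self.lnl):
            self.lnl = cand
            self.n_acc["shape"] += 1
        else:
            (eng.rates, eng._U, eng._V, eng._w,
             down, tdown, dlog, P, PT) = saved
            eng._down[:] = down
            eng._tdown[:] = tdown
            eng._dlog[:] = dlog
            eng._P[:] = P
            eng._PT[:] = PT
            eng._stale = False

    def propose_nni(self, patterns, model, cond) -> None:
        rng = self.rng
        self.n_try["topo"] += 1
        cur_tree = self.eng.atree.to_dendropy()
        nbrs = treeutil.nni_neighbors(cur_tree)
        if not nbrs:
            return
        new_tree = nbrs[rng.integers(len(nbrs))]
        new_eng = TreeLikelihood(
            new_tree,
            patterns,
            model,
            self.eng.rates,
            cond,
            dtype=self.eng.dtype,
        )
        cand = new_eng.loglik()
        if math.log(rng.random() + 1e-300) < self.heat * self.cfg.power * (cand - self.lnl):
            self.eng = new_eng
            self.lnl = cand
            self.n_acc["topo"] += 1


def mcmc_sample(
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    config: MCMCConfig,
    topology: dendropy.Tree | str = "free",
    condition_observable: bool = False,
) -> ChainTrace:
    """Sample branch lengths (and optionally topology/shape) by MCMC.

    ``topology`` is either a fixed tree (branch lengths are re-drawn from
    the Exp(blen_prior_rate) prior when absent) or the string ``"free"``
    for joint topology sampling via NNI moves.  Samples are taken from the
    cold chain every ``sample_interval`` generations after ``burn_in``.
    One generation is one elementary proposal.
    """
    rng = np.random.default_rng(config.seed)
    free_topology = isinstance(topology, str)
    dtype = np.float32 if config.dtype == "float32" else np.float64

    def start_tree() -> dendropy.Tree:
        if free_topology:
            t = treeutil.random_topology(
                patterns.taxa, rng, 1.0 / config.blen_prior_rate
            )
        else:
            t = treeutil.clone(topology)
            for e in t.preorder_edge_iter():
                if e.tail_node is not None and (e.length is None or e.length <= 0):
                    e.length = float(rng.exponential(1.0 / config.blen_prior_rate))
        return t

    chains = []
    for i in range(config.n_chains):
        eng = TreeLikelihood(
            start_tree(), patterns, model, rates, condition_observable, dtype=dtype
        )
        heat = 1.0 / (1.0 + config.temperature * i)
        chains.append(
            _Chain(eng, heat, config, np.random.default_rng(rng.integers(2**31)))
        )

    gens, lnls, shapes, tlens = [], [], [], []
    newicks: list[str] | None = [] if free_topology else None
    gen = [0]

    def record_if_due():
        g = gen[0]
        cold = chains[0]
        if g > config.burn_in and (g % config.sample_interval == 0):
            gens.append(g)
            lnls.append(cold.lnl)
            shapes.append(cold.eng.rates.shape)
            tlens.append(float(cold.eng.atree.blen.sum()))
            if newicks is not None:
                newicks.append(
                    treeutil.write_newick(cold.eng.atree.to_dendropy()).strip()
                )

    def gen_cb(_chain):
        if _chain is chains[0]:
            gen[0] += 1
            record_if_due()

    n_swap_acc = 0
    n_swap = 0
    sweep_no = 0
    while gen[0] < config.n_generations:
        for ch in chains:
            ch.sweep_branch_lengths(gen_cb if ch is chains[0] else lambda c: None)
        sweep_no += 1
        if (
            config.estimate_shape
            and rates.n_categories > 1
            and sweep_no % max(config.shape_every, 1) == 0
        ):
            for ch in chains:
                ch.propose_shape()
            gen[0] += 1
            record_if_due()
        if free_topology:
            for ch in chains:
                ch.propose_nni(patterns, model, condition_observable)
            gen[0] += 1
            record_if_due()
        if len(chains) > 1:
            i = int(rng.integers(len(chains) - 1))
            a, b = chains[i], chains[i + 1]
            ln_r = (a.heat - b.heat) * (b.posterior() - a.posterior())
            n_swap += 1
            if math.log(rng.random() + 1e-300) < ln_r:
                a.heat, b.heat = b.heat, a.heat
                chains[i], chains[i + 1] = b, a
                n_swap_acc += 1

    cold = chains[0]
    acc = {
        k: (cold.n_acc[k] / cold.n_try[k] if cold.n_try[k] else float("nan"))
        for k in cold.n_acc
    }
    if n_swap:
        acc["swap"] = n_swap_acc / n_swap
    return ChainTrace(
        np.array(gens),
        np.array(lnls),
        np.array(shapes),
        np.array(tlens),
        trees=newicks,
        acceptance=acc,
    )


def plot_trace(trace: ChainTrace, path: str) -> None:
    """Log-likelihood and parameter traces for manual burn-in inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    axes[0].plot(trace.generations, trace.logliks, lw=0.7)
    axes[0].set_ylabel("lnL")
    axes[1].plot(trace.generations, trace.shapes, lw=0.7, color="tab:orange")
    axes[1].set_ylabel("gamma shape")
    axes[2].plot(trace.generations, trace.tree_lengths, lw=0.7,
                 color="tab:green")
    axes[2].set_ylabel("tree length")
    axes[2].set_xlabel("generation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Consensus


def consensus_tree(trees: list[dendropy.Tree | str]) -> tuple[dendropy.Tree, dict]:
    """Majority-rule consensus with bipartition posterior frequencies.

    Returns (consensus tree, {bipartition id: frequency in [0, 1]}).  The
    consensus tree's internal edges carry their frequency as node labels.
    """
    parsed = [treeutil.read_newick(t) if isinstance(t, str) else t for t in trees]
    if not parsed:
        raise ValueError("need at least one tree")
    taxa = set(treeutil.taxon_labels(parsed[0]))
    counts: dict[frozenset, int] = {}
    for t in parsed:
        if set(treeutil.taxon_labels(t)) != taxa:
            raise ValueError("trees must share one taxon set")
        for bp in treeutil.bipartition_set(t):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(parsed)
    freqs = {bp: c / n for bp, c in counts.items()}
    tl = dendropy.TreeList()
    ns = dendropy.TaxonNamespace(sorted(taxa))
    for t in parsed:
        tl.append(
            dendropy.Tree.get(
                data=treeutil.write_newick(t), schema="newick", taxon_namespace=ns
            )
        )
    cons = tl.consensus(min_freq=0.5)
    cons = treeutil.as_trifurcating(cons)
    for nd in cons.preorder_node_iter():
        if nd.parent_node is not None and not nd.is_leaf():
            bp = treeutil.edge_id(cons, nd.edge)
            if bp in freqs:
                nd.label = f"{freqs[bp]:.4f}"
    return cons, freqs


# ---------------------------------------------------------------------------
# Distances and ML search


def logdet_distance_matrix(patterns: PatternTable) -> np.ndarray:
    """Pairwise LogDet distances over mutually non-missing sites.

    Falls back to a Jukes-Cantor-style corrected p-distance when the joint
    frequency matrix is singular (short or sparse alignments).
    """
    nt = len(patterns.taxa)
    ns = patterns.n_states
    D = np.zeros((nt, nt))
    codes, w = patterns.codes, patterns.weights
    for i in range(nt):
        for j in range(i + 1, nt):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            if not ok.any():
                D[i, j] = D[j, i] = 5.0
                continue
            J = np.zeros((ns, ns))
            np.add.at(J, (codes[i][ok], codes[j][ok]), w[ok])
            total = J.sum()
            J = J / total
            p = 1.0 - np.trace(J)
            sign, logdet = np.linalg.slogdet(J)
            if sign > 0:
                fi, fj = J.sum(axis=1), J.sum(axis=0)
                with np.errstate(divide="ignore"):
                    corr = 0.5 * (np.log(fi + 1e-12).sum() + np.log(fj + 1e-12).sum())
                d = -(logdet - corr) / ns
            else:
                b = (ns - 1) / ns
                p = min(p, b * 0.999)
                d = -b * math.log(1.0 - p / b)
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


def neighbor_joining_tree(patterns: PatternTable) -> dendropy.Tree:
    """Deterministic neighbour joining on LogDet distances.

    Ties in the Q criterion break by lowest pair index, so the start tree
    is a pure function of the pattern table.
    """
    D = logdet_distance_matrix(patterns)
    nodes = [f"{t}" for t in patterns.taxa]  # newick fragments
    idx = list(range(len(nodes)))
    D = D.copy()
    while len(idx) > 3:
        n = len(idx)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        a, b = idx[i], idx[j]
        d_ab = sub[i, j]
        la = 0.5 * d_ab + (r[i] - r[j]) / (2 * (n - 2))
        lb = d_ab - la
        la, lb = max(la, MIN_BLEN), max(lb, MIN_BLEN)
        new = len(nodes)
        nodes.append(f"({nodes[a]}:{la:.10f},{nodes[b]}:{lb:.10f})")
        # distances from the new node
        newcol = np.zeros(len(nodes))
        for k_pos, k in enumerate(idx):
            if k in (a, b):
                continue
            newcol[k] = 0.5 * (D[a, k] + D[b, k] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, : new] = newcol[:new]
        D[: new, new] = newcol[:new]
        idx = [k for k in idx if k not in (a, b)] + [new]
    (x, y, z) = idx
    dx = max(0.5 * (D[x, y] + D[x, z] - D[y, z]), MIN_BLEN)
    dy = max(0.5 * (D[x, y] + D[y, z] - D[x, z]), MIN_BLEN)
    dz = max(0.5 * (D[x, z] + D[y, z] - D[x, y]), MIN_BLEN)
    nwk = (
        f"({nodes[x]}:{dx:.10f},{nodes[y]}:{dy:.10f},{nodes[z]}:{dz:.10f});"
    )
    return treeutil.as_trifurcating(treeutil.read_newick(nwk))


def ml_search(
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    n_bootstrap: int = 0,
    condition_observable: bool = False,
    seed: int = 0,
    opt_tol: float = 1e-4,
) -> tuple[dendropy.Tree, float, dict[frozenset, float]]:
    """NNI hill-climbing ML search from a neighbour-joining start tree.

    Returns (ML tree, lnL, bootstrap supports per bipartition id).  The
    search stops when no NNI neighbour improves the optimized lnL; the
    bootstrap resamples sites and repeats the full search per replicate.
    """
    if len(patterns.taxa) < 4:
        raise ValueError("ML search needs at least 4 taxa")

    def search(pt: PatternTable) -> tuple[dendropy.Tree, float]:
        tree = neighbor_joining_tree(pt)
        tree, best, _ = optimize_branch_lengths(
            tree, pt, model, rates, condition_observable, tol=opt_tol, max_sweeps=20
        )
        improved = True
        while improved:
            improved = False
            for nbr in treeutil.nni_neighbors(tree):
                cand_tree, cand, _ = optimize_branch_lengths(
                    nbr, pt, model, rates, condition_observable,
                    tol=opt_tol, max_sweeps=20,
                )
                if cand > best + 1e-6:
                    tree, best = cand_tree, cand
                    improved = True
                    break
        return tree, best

    tree, lnl = search(patterns)
    supports: dict[frozenset, float] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        for _ in range(n_bootstrap):
            w = rng.multinomial(patterns.n_sites, patterns.weights / patterns.n_sites)
            keep = w > 0
            pt = PatternTable(
                patterns.taxa,
                patterns.codes[:, keep],
                w[keep].astype(float),
                np.repeat(np.arange(keep.sum()), w[keep]),
                patterns.n_states,
            )
            btree, _ = search(pt)
            for bp in treeutil.bipartition_set(btree):
                counts[bp] = counts.get(bp, 0) + 1
        supports = {bp: c / n_bootstrap for bp, c in counts.items()}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and not nd.is_leaf():
                bp = treeutil.edge_id(tree, nd.edge)
                nd.label = f"{supports.get(bp, 0.0):.2f}"
    return tree, lnl, supports
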