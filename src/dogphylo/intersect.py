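"""Constrained-intersection tests: where does a monophyletic outgroup
attach on a fixed host topology?

One attachment hypothesis is generated per internal host edge (plus any
explicitly listed terminal edges, e.g. unusually long tip branches).  The
host and outgroup branching orders stay fixed; only branch lengths are
sampled.  Per hypothesis and substitution model, the log marginal
likelihood is estimated from a fixed-topology MCMC trace; log10 Bayes
factors are taken against the best hypothesis under each model, and their
across-model average ranks the candidate attachment points.

The default marginal-likelihood estimator is the stabilized harmonic mean
of the sampled log-likelihoods (computed entirely in log space, standard
error by moving-block bootstrap); stepping-stone sampling over a ladder of
power posteriors is available as an independent cross-check.  Ranking, not
absolute marginal likelihood, drives every downstream quantity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from . import treeutil
from ._engine import PatternTable
from .models import RateModel, SubstitutionModel, empirical_aa_model
from .phylocore import ChainTrace, MCMCConfig, mcmc_sample

LN10 = math.log(10.0)
P_FLOOR = 1e-5  # reported p-value floor


@dataclass
class AttachmentHypothesis:
    hyp_id: str
    edge: frozenset
    joint_tree: dendropy.Tree
    is_terminal: bool = False


@dataclass
class BayesFactorTable:
    """Per hypothesis x model log marginal likelihoods and Bayes factors."""

    table: pd.DataFrame  # hypothesis, edge, model, logml, se, log10_bf

    def per_model(self, model: str) -> pd.DataFrame:
        return self.table[self.table["model"] == model].reset_index(drop=True)

    @property
    def models(self) -> list[str]:
        return sorted(self.table["model"].unique())

    @property
    def hypotheses(self) -> list[str]:
        return sorted(self.table["hypothesis"].unique())

    def average(self) -> pd.DataFrame:
        """Across-model average log10 BF per hypothesis, with flags."""
        avg = (
            self.table.groupby("hypothesis", sort=True)
            .agg(edge=("edge", "first"), avg_log10_bf=("log10_bf", "mean"))
            .reset_index()
        )
        avg["extreme"] = avg["avg_log10_bf"] > 1000.0
        avg = avg.sort_values("avg_log10_bf", kind="stable").reset_index(drop=True)
        avg["rank"] = np.arange(1, len(avg) + 1)
        return avg

    def best_hypothesis(self) -> str:
        return str(self.average().iloc[0]["hypothesis"])

    def write_tsv(self, path: str) -> None:
        out = self.table.copy()
        out["edge"] = out["edge"].map(lambda e: ",".join(sorted(e)))
        out.to_csv(path, sep="\t", index=False)


def enumerate_attachments(
    host_tree: dendropy.Tree,
    outgroup_tree: dendropy.Tree,
    extra_terminal_taxa: list[str] | None = None,
    stem_length: float = 0.2,
) -> list[AttachmentHypothesis]:
    """One constrained joint topology per candidate host attachment edge.

    Candidates are every internal edge of the (unrooted binary) host tree
    plus the terminal edges of the taxa in ``extra_terminal_taxa``; order
    is deterministic (postorder edge index).  Pruning the outgroup taxa
    from any hypothesis returns the host topology exactly.
    """
    internal = treeutil.internal_edge_ids(host_tree)
    edges: list[tuple[frozenset, bool]] = [(e, False) for e in internal]
    for lab in extra_terminal_taxa or []:
        edges.append((treeutil.terminal_edge_id(host_tree, lab), True))
    seen = set()
    for e, _ in edges:
        if e in seen:
            raise ValueError(f"duplicate attachment edge {sorted(e)}")
        seen.add(e)
    out = []
    for i, (edge, term) in enumerate(edges, start=1):
        joint = treeutil.graft_subtree(host_tree, outgroup_tree, edge, stem_length)
        out.append(AttachmentHypothesis(f"H{i:02d}", edge, joint, term))
    return out


# ---------------------------------------------------------------------------
# Marginal-likelihood estimators


def estimate_log_marginal(
    trace: ChainTrace | np.ndarray,
    method: str = "stabilized-harmonic-mean",
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_samples: int = 100,
) -> tuple[float, float]:
    """Log marginal likelihood (and SE) from post-burn-in sampled lnLs.

    The harmonic-mean estimator is computed in log space:
    ``logML = log(n) - logsumexp(-lnL)``; its standard error comes from a
    moving-block bootstrap of the lnL series (block length ~ sqrt(n)).
    """
    lnl = trace.logliks if isinstance(trace, ChainTrace) else np.asarray(trace, float)
    n = len(lnl)
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} post-burn-in samples, got {n}")
    if method not in ("stabilized-harmonic-mean", "harmonic-mean"):
        raise ValueError(f"unknown estimator {method!r}")

    def hm(x):
        return math.log(len(x)) - logsumexp(-x)

    est = hm(lnl)
    if np.ptp(lnl) == 0.0:
        return est, 0.0
    rng = np.random.default_rng(seed)
    block = max(int(round(math.sqrt(n))), 1)
    n_blocks = int(math.ceil(n / block))
    starts = np.arange(0, n - block + 1)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        picks = rng.integers(0, len(starts), size=n_blocks)
        series = np.concatenate([lnl[s : s + block] for s in starts[picks]])[:n]
        reps[b] = hm(series)
    return est, float(reps.std(ddof=1))


def stepping_stone_log_marginal(
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    tree: dendropy.Tree,
    config: MCMCConfig,
    n_steps: int = 8,
    alpha: float = 0.3,
    condition_observable: bool = False,
) -> float:
    """Stepping-stone estimate over a Beta(alpha, 1)-spaced power ladder.

    Runs one power-posterior MCMC per beta in the ladder (beta = (k/K)^(1/alpha),
    k = 0..K-1) and accumulates the ratio estimates; independent of the
    harmonic-mean route.
    """
    betas = [(k / n_steps) ** (1.0 / alpha) for k in range(n_steps)] + [1.0]
    total = 0.0
    for k in range(n_steps):
        b_lo, b_hi = betas[k], betas[k + 1]
        cfg = dataclasses.replace(
            config, n_chains=1, seed=config.seed + 1000 + k, power=b_lo
        )
        tr = mcmc_sample(
            patterns, model, rates, cfg, topology=tree,
            condition_observable=condition_observable,
        )
        d = (b_hi - b_lo) * tr.logliks
        total += float(logsumexp(d) - math.log(len(d)))
    return total


def log10_bayes_factors(logmls: dict[str, float]) -> dict[str, float]:
    """log10 BF of each hypothesis against the best (best = 0, others >= 0)."""
    if len(logmls) < 2:
        raise ValueError("need at least two hypotheses")
    best = max(logmls.values())
    return {h: (best - v) / LN10 for h, v in logmls.items()}


# ---------------------------------------------------------------------------
# Scan driver


def _stable_seed(*parts: str) -> int:
    import hashlib

    h = hashlib.sha1("|".join(str(p) for p in parts).encode()).hexdigest()
    return int(h[:6], 16)


def run_intersection_scan(
    host_tree: dendropy.Tree,
    outgroup_tree: dendropy.Tree,
    sequences: dict[str, str],
    models: list[str] = ("WAG", "DAYHOFF"),
    mcmc: MCMCConfig | None = None,
    extra_terminal_taxa: list[str] | None = None,
    stem_length: float = 0.2,
    rates: RateModel | None = None,
    keep_traces: bool = False,
    min_marginal_samples: int = 100,
) -> tuple[BayesFactorTable, list[AttachmentHypothesis], dict]:
    """Full fixed-topology Bayes-factor scan over attachment hypotheses."""
    mcmc = mcmc or MCMCConfig(
        n_generations=50_000, sample_interval=500, burn_in=20_000, n_chains=1
    )
    rates = rates or RateModel(1.0, 4)
    hyps = enumerate_attachments(
        host_tree, outgroup_tree, extra_terminal_taxa, stem_length
    )
    patterns = PatternTable.from_sequences(sequences, "aa")
    rows = []
    traces = {}
    for mname in models:
        model = empirical_aa_model(mname)
        logmls, ses = {}, {}
        for hyp in hyps:
            cfg = dataclasses.replace(
                mcmc, seed=mcmc.seed + _stable_seed(mname, hyp.hyp_id)
            )
            trace = mcmc_sample(patterns, model, rates, cfg, topology=hyp.joint_tree)
            logml, se = estimate_log_marginal(
                trace, seed=cfg.seed, min_samples=min_marginal_samples
            )
            logmls[hyp.hyp_id] = logml
            ses[hyp.hyp_id] = se
            if keep_traces:
                traces[(mname, hyp.hyp_id)] = trace
        bfs = log10_bayes_factors(logmls)
        for hyp in hyps:
            rows.append(
                {
                    "hypothesis": hyp.hyp_id,
                    "edge": hyp.edge,
                    "model": mname.upper(),
                    "logml": logmls[hyp.hyp_id],
                    "se": ses[hyp.hyp_id],
                    "log10_bf": bfs[hyp.hyp_id],
                }
            )
    return BayesFactorTable(pd.DataFrame(rows)), hyps, traces


def average_and_map(
    table: BayesFactorTable, host_tree: dendropy.Tree
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Annotate host edges with across-model average log10 BFs.

    Returns (annotated tree, rank report).  Edge labels carry the average
    BF; values above 1000 are flagged with an asterisk, echoing heat-map
    conventions for decisively rejected placements.
    """
    models = table.models
    per_hyp_sets = {
        m: set(table.per_model(m)["hypothesis"]) for m in models
    }
    ref = per_hyp_sets[models[0]]
    for m, s in per_hyp_sets.items():
        if s != ref:
            raise ValueError(f"hypothesis sets differ between models ({m})")
    avg = table.average()
    tree = treeutil.clone(host_tree)
    by_edge = {row["edge"]: row for _, row in avg.iterrows()}
    for eid, edge in treeutil.edges_with_ids(tree):
        row = by_edge.get(eid)
        if row is not None:
            star = "*" if row["extreme"] else ""
            edge.head_node.label = f"{row['avg_log10_bf']:.2f}{star}"
    return tree, avg


def model_independence(table: BayesFactorTable) -> pd.DataFrame:
    """Pairwise OLS r^2 between per-model log10 BF vectors.

    The p-value uses the t transform of the Pearson correlation and is
    floored at 1e-5 for reporting.
    """
    models = table.models
    if len(models) < 2:
        raise ValueError("need at least two models")
    hyps = table.hypotheses
    if len(hyps) < 3:
        raise ValueError("r^2 undefined with fewer than 3 hypotheses")
    vecs = {}
    for m in models:
        sub = table.per_model(m).set_index("hypothesis")
        vecs[m] = sub.loc[hyps, "log10_bf"].to_numpy()
    rows = []
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            res = stats.linregress(vecs[a], vecs[b])
            r2 = res.rvalue**2
            rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "r2": r2,
                    "slope": res.slope,
                    "p": max(res.pvalue, P_FLOOR),
                }
            )
    return pd.DataFrame(rows)


def filter_shared_dogs(
    membership: pd.DataFrame,
    focal_clade_taxa: set[str],
    outgroup_detected: set[str],
    host_taxa: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Drop families confined to a focal host clade *and* detected in the
    outgroup (candidate lateral transfers); returns (kept, removed) ids."""
    focal = set(focal_clade_taxa)
    if host_taxa is not None and not focal.issubset(host_taxa):
        raise ValueError("focal clade taxa must be a subset of the host taxa")
    kept, removed = [], []
    for fam, grp in membership.groupby("family_id", sort=True):
        taxa = set(grp["taxon"])
        if taxa.issubset(focal) and fam in outgroup_detected:
            removed.append(fam)
        else:
            kept.append(fam)
    return kept, removed
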