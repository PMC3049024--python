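"""Shared fixtures and independent oracles.

The likelihood oracle enumerates every internal-node state assignment
explicitly (no pruning) and uses scipy's matrix exponential for branch
transition probabilities, so it shares no code path with the engine it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from dogphylo import treeutil
from dogphylo.models import covarion_matrix


def enumeration_loglik(engine, root_freq=None) -> float:
    """Exhaustive-state log-likelihood for a TreeLikelihood's tree/data.

    Sums over all joint internal-node state assignments per site pattern;
    applies the same observability conditioning as the engine when active.
    """
    at = engine.atree
    model, rates = engine.model, engine.rates
    cov = rates.covarion
    mats = []
    for r in rates.rates:
        if cov is None:
            Q, pi = r * model.rate_matrix, model.freqs
        else:
            Q, pi = covarion_matrix(model, r, *cov)
        mats.append((Q, pi))
    ns = mats[0][0].shape[0]
    n_obs = model.n_states
    if root_freq is None:
        root_freq = engine._root_freq

    def site_like(site_codes) -> float:
        tot = 0.0
        internals = [v for v in range(at.n_nodes) if at.leaf_taxon[v] < 0]
        for Q, pi in mats:
            P = {
                v: expm(Q * at.blen[v])
                for v in range(at.n_nodes)
                if v != at.root
            }
            like = 0.0
            for assign in itertools.product(range(ns), repeat=len(internals)):
                st = dict(zip(internals, assign))
                contrib = root_freq[st[at.root]]
                for v in range(at.n_nodes):
                    if v == at.root:
                        continue
                    ps = st[at.parent[v]]
                    ti = at.leaf_taxon[v]
                    if ti >= 0:
                        c = site_codes[ti]
                        if c < 0:
                            contrib *= P[v][ps].sum()
                        else:
                            states = [c] if ns == n_obs else [c, c + n_obs]
                            contrib *= sum(P[v][ps, s] for s in states)
                    else:
                        contrib *= P[v][ps, st[v]]
                like += contrib
            tot += like / len(mats)
        return tot

    pt = engine.patterns
    if engine.condition_observable:
        p0 = site_like(np.zeros(len(pt.taxa), dtype=int))
    else:
        p0 = 0.0
    total = 0.0
    for j in range(pt.n_patterns):
        total += pt.weights[j] * np.log(site_like(pt.codes[:, j]) / (1.0 - p0))
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def tree4():
    return treeutil.read_newick("(A:0.31,B:0.006,(C:0.17,D:0.49):0.08);")


@pytest.fixture(scope="session")
def tree5():
    return treeutil.read_newick(
        "(A:0.22,(B:0.10,C:0.35):0.07,(D:0.18,E:0.05):0.12);"
    )
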