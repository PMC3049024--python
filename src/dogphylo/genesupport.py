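"""Per-gene corroboration of a reference phylogeny and compositional
heterogeneity diagnostics.

Quartet support: every gene tree is decomposed into all four-taxon
subsets; each subset induces one resolved quartet in the gene tree and
one in the reference.  A quartet is informative for a reference edge when
that edge splits its four taxa two against two, and it supports the edge
when the induced topologies agree.  Per-edge support is the percentage of
informative quartets that agree.

Composition: pooled amino-acid frequency profiles per taxon group, with a
correlation test between profile distance to a target composition and the
average log10 Bayes factor of the corresponding attachment hypotheses --
a check that attachment preferences are not compositional artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from . import phylocore, treeutil
from ._engine import PatternTable
from .models import AA_INDEX, AA_ORDER
from .seqs import GAP_CHARS, Alignment


# ---------------------------------------------------------------------------
# Per-gene trees


def per_gene_trees(
    dog_alignments: dict[str, Alignment],
    model,
    rates,
    min_taxa: int = 4,
    log: list | None = None,
) -> dict[str, dendropy.Tree]:
    """ML tree per family alignment; families with < ``min_taxa`` skipped."""
    out = {}
    for fam in sorted(dog_alignments):
        aln = dog_alignments[fam]
        if len(aln) < min_taxa:
            if log is not None:
                log.append((fam, "skipped", len(aln)))
            continue
        pt = PatternTable.from_sequences(aln.to_dict(), "aa")
        tree, _, _ = phylocore.ml_search(pt, model, rates)
        out[fam] = tree
    return out


# ---------------------------------------------------------------------------
# Quartet support


def _topo_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Pairwise path lengths in edge counts between leaves."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    labels = [lf.taxon.label for lf in leaves]
    idx = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))
    # distances via root paths
    depth: dict[int, int] = {}
    parent: dict[int, object] = {}
    for nd in tree.preorder_node_iter():
        p = nd.parent_node
        depth[id(nd)] = 0 if p is None else depth[id(p)] + 1
        parent[id(nd)] = p
    for a, b in combinations(leaves, 2):
        x, y = a, b
        dx, dy = depth[id(x)], depth[id(y)]
        d = 0
        while dx > dy:
            x = parent[id(x)]
            dx -= 1
            d += 1
        while dy > dx:
            y = parent[id(y)]
            dy -= 1
            d += 1
        while x is not y:
            x = parent[id(x)]
            y = parent[id(y)]
            d += 2
        D[idx[id(a)], idx[id(b)]] = D[idx[id(b)], idx[id(a)]] = d
    return labels, D


def induced_quartet(D: np.ndarray, i, j, k, l) -> frozenset | None:
    """Resolved quartet split from a tree metric; None when star-like.

    Returns the pair that groups with i (as a frozenset of two indices of
    the input order 0..3), e.g. {0,1} for ij|kl.
    """
    s_ij = D[i, j] + D[k, l]
    s_ik = D[i, k] + D[j, l]
    s_il = D[i, l] + D[j, k]
    m = min(s_ij, s_ik, s_il)
    if [s_ij, s_ik, s_il].count(m) > 1:
        return None
    if m == s_ij:
        return frozenset([0, 1])
    if m == s_ik:
        return frozenset([0, 2])
    return frozenset([0, 3])


@dataclass
class QuartetSupportTable:
    table: pd.DataFrame  # edge id, n_informative, n_agree, support_pct

    def support_of(self, edge: frozenset) -> float:
        row = self.table[self.table["edge"] == edge]
        return float(row["support_pct"].iloc[0]) if len(row) else float("nan")


def quartet_support(
    reference_tree: dendropy.Tree, gene_trees: list[dendropy.Tree]
) -> QuartetSupportTable:
    """Percentage of informative gene quartets agreeing with each internal
    reference edge."""
    ref_labels = treeutil.taxon_labels(reference_tree)
    ref_edges = treeutil.internal_edge_ids(reference_tree)
    counts = {e: [0, 0] for e in ref_edges}  # informative, agree
    for gt in gene_trees:
        labels, D = _topo_distances(gt)
        extra = set(labels) - set(ref_labels)
        if extra:
            raise ValueError(f"gene-tree taxa {sorted(extra)} not in reference")
        gi = {t: i for i, t in enumerate(labels)}
        for quad in combinations(sorted(labels), 4):
            gq = induced_quartet(D, *(gi[t] for t in quad))
            if gq is None:
                continue
            for e in ref_edges:
                side = [t in e for t in quad]
                if sum(side) != 2:
                    continue
                # reference-induced split at this edge
                in_e = [x for x, s in enumerate(side) if s]
                if 0 in in_e:
                    ref_pair = frozenset(in_e)
                else:
                    ref_pair = frozenset(x for x in range(4) if x not in in_e)
                counts[e][0] += 1
                if gq == ref_pair:
                    counts[e][1] += 1
    rows = []
    for e in ref_edges:
        inf, agr = counts[e]
        rows.append(
            {
                "edge": e,
                "n_informative": inf,
                "n_agree": agr,
                "support_pct": 100.0 * agr / inf if inf else float("nan"),
            }
        )
    return QuartetSupportTable(pd.DataFrame(rows))


def annotate_supports(
    reference_tree: dendropy.Tree, table: QuartetSupportTable
) -> dendropy.Tree:
    tree = treeutil.clone(reference_tree)
    by_edge = {row["edge"]: row["support_pct"] for _, row in table.table.iterrows()}
    for eid, edge in treeutil.edges_with_ids(tree):
        if eid in by_edge and not edge.head_node.is_leaf():
            edge.head_node.label = f"{by_edge[eid]:.0f}"
    return tree


# ---------------------------------------------------------------------------
# Composition


@dataclass
class CompositionProfile:
    label: str
    freqs: np.ndarray  # 20-vector, sums to 1
    n_residues: int

    def __post_init__(self):
        if self.n_residues <= 0:
            raise ValueError("profile needs at least one residue")
        if not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")


def composition_profile(sequences, label: str = "") -> CompositionProfile:
    """Pooled amino-acid frequencies over sequences; gaps excluded."""
    counts = np.zeros(20)
    for s in sequences:
        for c in s.upper():
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no residues in input sequences")
    return CompositionProfile(label, counts / total, int(total))


def profile_distance(
    a: CompositionProfile, b: CompositionProfile, metric: str = "euclidean"
) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(a.freqs - b.freqs))
    if metric == "chi-square":
        denom = a.freqs + b.freqs
        ok = denom > 0
        return float(np.sum((a.freqs[ok] - b.freqs[ok]) ** 2 / denom[ok]))
    raise ValueError(f"unknown metric {metric!r}")


def composition_correlation(
    node_profiles: dict[str, CompositionProfile],
    target_profile: CompositionProfile,
    avg_bf: dict[str, float],
    metric: str = "euclidean",
) -> tuple[float, float, pd.DataFrame]:
    """OLS r^2 / p between composition distance to target and average BF."""
    common = sorted(set(node_profiles) & set(avg_bf))
    if len(common) < 3:
        raise ValueError("need at least 3 nodes")
    d = np.array(
        [profile_distance(node_profiles[h], target_profile, metric) for h in common]
    )
    b = np.array([avg_bf[h] for h in common])
    if np.ptp(b) == 0 or np.ptp(d) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    res = stats.linregress(d, b)
    df = pd.DataFrame({"hypothesis": common, "distance": d, "avg_log10_bf": b})
    return float(res.rvalue**2), float(res.pvalue), df
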