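"""Light helpers around :mod:`dendropy` trees.

All trees in this package are :class:`dendropy.Tree` objects.  Unrooted
binary trees are represented with a trifurcating seed node (three children
at the "root", two elsewhere), which makes the number of parent edges equal
to the number of edges of the unrooted tree.

Edges are identified across functions by their *bipartition id*: the frozen
set of taxon labels on the side of the edge that does not contain the
lexicographically smallest label of the tree.  This id is stable under
re-reading, re-rooting and taxon reordering.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np
from dendropy.model import birthdeath


# ---------------------------------------------------------------------------
# I/O


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick tree from a string or a file path."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick", suppress_rooting=True),
        schema="newick",
    )


def taxon_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Construction


def as_trifurcating(tree: dendropy.Tree) -> dendropy.Tree:
    """Normalize to the unrooted convention (trifurcating seed node)."""
    tree.is_rooted = False
    seed = tree.seed_node
    if len(seed.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()
    seed.edge.length = None  # an unrooted tree has no root edge
    return tree


def random_topology(
    labels: Sequence[str], rng: np.random.Generator, mean_blen: float = 0.1
) -> dendropy.Tree:
    """Uniform random unrooted binary topology via sequential addition.

    Branch lengths are i.i.d. exponential with mean ``mean_blen``.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    first = labels[:3]
    for lab in first:
        ch = tree.seed_node.new_child()
        ch.taxon = ns.get_taxon(lab)
    for lab in labels[3:]:
        edges = [
            e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        ]
        e = edges[rng.integers(len(edges))]
        head, tail = e.head_node, e.tail_node
        mid = tail.new_child()
        tail.remove_child(head)
        mid.add_child(head)
        tip = mid.new_child()
        tip.taxon = ns.get_taxon(lab)
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length = float(rng.exponential(mean_blen))
    return tree


def birth_death_tree(
    n_taxa: int,
    birth_rate: float,
    death_rate: float,
    rng: np.random.Generator,
    label_fmt: str = "T{:02d}",
) -> dendropy.Tree:
    """Simulate a birth--death species tree with ``n_taxa`` extant tips."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0 or death_rate < 0:
        raise ValueError("birth rate must be > 0 and death rate >= 0")
    import random as _random

    pyrng = _random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = birthdeath.birth_death_tree(
        birth_rate,
        death_rate,
        num_extant_tips=n_taxa,
        rng=pyrng,
        repeat_until_success=True,
    )
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)):
        leaf.taxon.label = label_fmt.format(i + 1)
    # guard against zero-length branches from simultaneous events
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None and (e.length is None or e.length <= 0):
            e.length = 1e-6
    return as_trifurcating(tree)


# ---------------------------------------------------------------------------
# Bipartitions and edge ids


def _leafset_below(edge: dendropy.Edge) -> frozenset[str]:
    return frozenset(
        lf.taxon.label for lf in edge.head_node.leaf_iter()
    )


def edge_id(tree: dendropy.Tree, edge: dendropy.Edge) -> frozenset[str]:
    """Canonical bipartition id of an edge (side without the smallest label)."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    below = _leafset_below(edge)
    ref = min(all_labels)
    return below if ref not in below else all_labels - below


def edges_with_ids(tree: dendropy.Tree) -> list[tuple[frozenset[str], dendropy.Edge]]:
    """(edge_id, edge) for every parent edge, in postorder; deterministic."""
    out = []
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        out.append((edge_id(tree, nd.edge), nd.edge))
    return out


def internal_edge_ids(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Ids of internal (non-terminal) edges, postorder."""
    return [
        eid
        for eid, e in edges_with_ids(tree)
        if not e.head_node.is_leaf()
    ]


def terminal_edge_id(tree: dendropy.Tree, taxon_label: str) -> frozenset[str]:
    for eid, e in edges_with_ids(tree):
        if e.head_node.is_leaf() and e.head_node.taxon.label == taxon_label:
            return eid
    raise KeyError(taxon_label)


def bipartition_set(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets."""
    n = len(taxon_labels(tree))
    out = set()
    for eid, e in edges_with_ids(tree):
        if 2 <= len(eid) <= n - 2:
            out.add(eid)
    return out


def same_unrooted_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    if set(taxon_labels(t1)) != set(taxon_labels(t2)):
        return False
    return bipartition_set(t1) == bipartition_set(t2)


def find_edge(tree: dendropy.Tree, eid: frozenset[str]) -> dendropy.Edge:
    for cand_id, e in edges_with_ids(tree):
        if cand_id == eid:
            return e
    raise KeyError(f"edge {sorted(eid)} not in tree")


# ---------------------------------------------------------------------------
# Surgery


def graft_subtree(
    host: dendropy.Tree,
    subtree: dendropy.Tree,
    attach_edge: frozenset[str],
    stem_length: float,
    position: float = 0.5,
) -> dendropy.Tree:
    """Attach ``subtree`` to edge ``attach_edge`` of ``host`` via a stem.

    The attachment point splits the host edge at ``position`` (fraction of
    its length measured from the tail/parent side).  The subtree keeps its
    own internal branch lengths; its seed node becomes the far end of the
    stem.  Taxon sets must be disjoint.
    """
    host_labels = set(taxon_labels(host))
    sub_labels = set(taxon_labels(subtree))
    if host_labels & sub_labels:
        raise ValueError("host and subtree taxa must be disjoint")
    joint = clone(host)
    edge = find_edge(joint, attach_edge)
    head, tail = edge.head_node, edge.tail_node
    elen = edge.length if edge.length is not None else 0.0
    mid = dendropy.Node()
    tail.remove_child(head)
    tail.add_child(mid)
    mid.edge.length = elen * position
    mid.add_child(head)
    head.edge.length = elen * (1.0 - position)

    sub = clone(subtree)
    sub_root = sub.seed_node
    if len(sub_root.child_nodes()) == 0:  # single-taxon subtree
        attach_node = sub_root
    else:
        attach_node = sub_root
    mid.add_child(attach_node)
    attach_node.edge.length = stem_length
    # merge taxon namespaces by re-reading
    joint.update_taxon_namespace()
    out = read_newick(write_newick(joint))
    return as_trifurcating(out)


def prune_to(tree: dendropy.Tree, keep_labels: Iterable[str]) -> dendropy.Tree:
    """Restriction of the (unrooted) tree to a label subset."""
    keep = set(keep_labels)
    t = clone(tree)
    t.retain_taxa_with_labels(sorted(keep))
    t.purge_taxon_namespace()
    t.suppress_unifurcations()
    return as_trifurcating(t)


def nni_neighbors(tree: dendropy.Tree) -> list[dendropy.Tree]:
    """All nearest-neighbour-interchange neighbours of an unrooted tree."""
    out = []
    # enumerate internal parent edges by index, regenerate a fresh clone per move
    t0 = clone(tree)
    internal = [
        i
        for i, nd in enumerate(t0.preorder_node_iter())
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    for idx in internal:
        for which in (0, 1):
            t = clone(tree)
            nds = list(t.preorder_node_iter())
            v = nds[idx]
            u = v.parent_node
            sibs = [c for c in u.child_nodes() if c is not v]
            if not sibs or len(v.child_nodes()) != 2:
                continue
            s = sibs[0]
            c = v.child_nodes()[which]
            u.remove_child(s)
            v.remove_child(c)
            u.add_child(c)
            v.add_child(s)
            out.append(as_trifurcating(t))
    # deduplicate by bipartition set
    seen, uniq = set(), []
    for t in out:
        key = frozenset(bipartition_set(t))
        if key not in seen and key != frozenset(bipartition_set(tree)):
            seen.add(key)
            uniq.append(t)
    return uniq
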