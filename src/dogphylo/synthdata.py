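"""Synthetic data with known ground truth.

Everything downstream of genome acquisition can be exercised on data
generated here: species trees, gene-content (detection/non-detection)
matrices evolved by a two-state gain/loss process, amino-acid alignments
under empirical substitution models with discrete-gamma rates and an
optional covarion process, per-taxon proteome FASTA files, and
"intersection" datasets in which a monophyletic outgroup clade is grafted
onto a known branch of a host tree.

Gene gain/loss is modelled as a reversible two-state Markov chain per
family (not an innovation-only process) so that the generating process
matches the binary restriction model used for inference.  Families absent
in every taxon are unobservable; they are discarded and replaced until the
requested number of observable families is reached.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import treeutil
from .models import AA_ORDER, RateModel, covarion_matrix, empirical_aa_model
from .seqs import Alignment, write_fasta_dict


@dataclass
class GeneContentParams:
    """Gain/loss process settings (rates per family per unit branch length)."""

    gain_rate: float = 0.5
    loss_rate: float = 1.0
    root_presence: float = 0.6
    n_families: int = 500
    lgt_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gain_rate < 0 or self.loss_rate < 0 or self.lgt_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.root_presence <= 1.0:
            raise ValueError("root presence probability must be in [0, 1]")


@dataclass
class SeqEvolParams:
    """Amino-acid sequence evolution settings."""

    model: str = "WAG"
    gamma_shape: float = 1.0
    n_categories: int = 4
    length: int = 1000
    covarion: tuple[float, float] | None = None
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")


@dataclass
class FamilySpec:
    """One gene family for proteome simulation."""

    family_id: str
    length: int = 100
    presence: list[str] | None = None  # None = all taxa
    rate: float = 1.0  # branch-length multiplier for this family
    paralogs: dict[str, int] = field(default_factory=dict)  # taxon -> copies
    paralog_divergence: float = 0.4


@dataclass
class TruthRecord:
    """Ground truth emitted next to each synthetic dataset."""

    membership: dict[str, str] = field(default_factory=dict)  # seq id -> family
    attach_edge: frozenset | None = None
    site_categories: np.ndarray | None = None
    presence: dict[str, set[str]] | None = None  # family -> taxa

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tfamily\n")
            for sid in sorted(self.membership):
                fh.write(f"{sid}\t{self.membership[sid]}\n")


# ---------------------------------------------------------------------------
# Species trees


def simulate_species_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    target_height: float | None = None,
) -> dendropy.Tree:
    """Birth--death species tree with ``n_taxa`` extant tips.

    When ``target_height`` is given, branch lengths are rescaled so the
    maximum root-to-tip path equals it (units then being expected
    substitutions per site for an average-rate gene).
    """
    rng = np.random.default_rng(seed)
    tree = treeutil.birth_death_tree(n_taxa, birth_rate, death_rate, rng)
    if target_height is not None:
        height = max(
            lf.distance_from_root() for lf in tree.leaf_node_iter()
        )
        f = target_height / height
        for e in tree.preorder_edge_iter():
            if e.tail_node is not None:
                e.length = e.length * f
    return tree


# ---------------------------------------------------------------------------
# Gene content


def _two_state_p(gain: float, loss: float, t: float) -> np.ndarray:
    """Transition matrix of the gain/loss chain over time t."""
    tot = gain + loss
    if tot == 0.0:
        return np.eye(2)
    e = np.exp(-tot * t)
    p1 = gain / tot  # stationary presence
    return np.array(
        [
            [1 - p1 * (1 - e), p1 * (1 - e)],
            [(1 - p1) * (1 - e), 1 - (1 - p1) * (1 - e)],
        ]
    )


def simulate_gene_content(tree: dendropy.Tree, params: GeneContentParams):
    """Evolve presence/absence characters along the tree.

    Returns (taxa, matrix, truth): ``matrix`` is (n_families, n_taxa) with
    one observable (not all-zero) row per family.
    """
    from .charmatrix import PresenceMatrix

    if params.gain_rate == 0.0 and params.root_presence == 0.0:
        raise ValueError(
            "gain rate 0 with root presence 0 can never produce an observable family"
        )
    rng = np.random.default_rng(params.seed)
    t = treeutil.clone(tree)
    nodes = list(t.postorder_node_iter())
    order = list(reversed(nodes))  # preorder
    leaves = sorted(
        (nd for nd in nodes if nd.is_leaf()), key=lambda nd: nd.taxon.label
    )
    taxa = [lf.taxon.label for lf in leaves]

    rows = []
    guard = 0
    while len(rows) < params.n_families:
        guard += 1
        if guard > 1000 * params.n_families + 1000:
            raise RuntimeError("observable-family rejection loop did not terminate")
        state: dict[int, int] = {}
        for nd in order:
            if nd.parent_node is None:
                state[id(nd)] = int(rng.random() < params.root_presence)
            else:
                P = _two_state_p(
                    params.gain_rate, params.loss_rate, float(nd.edge.length or 0.0)
                )
                s = state[id(nd.parent_node)]
                state[id(nd)] = int(rng.random() < P[s, 1])
        row = np.array([state[id(lf)] for lf in leaves], dtype=np.int8)
        if params.lgt_rate > 0 and rng.random() < params.lgt_rate and row.any():
            absent = np.nonzero(row == 0)[0]
            if len(absent):
                row[absent[rng.integers(len(absent))]] = 1
        if row.any():
            rows.append(row)
    mat = np.stack(rows)
    fam_ids = [f"fam{i + 1:05d}" for i in range(params.n_families)]
    pm = PresenceMatrix(taxa, fam_ids, mat.T.copy())
    truth = TruthRecord(
        presence={
            fid: {taxa[j] for j in np.nonzero(mat[i])[0]}
            for i, fid in enumerate(fam_ids)
        }
    )
    return pm, truth


# ---------------------------------------------------------------------------
# Sequence evolution


class _SiteEvolver:
    """Evolves i.i.d. sites down a tree under an AA model + rates."""

    def __init__(self, params: SeqEvolParams, rng: np.random.Generator):
        self.model = empirical_aa_model(params.model)
        self.rates = RateModel(params.gamma_shape, params.n_categories, params.covarion)
        self.params = params
        self.rng = rng
        self.n_obs = self.model.n_states

    def _branch_pmats(self, t: float) -> list[np.ndarray]:
        from scipy.linalg import expm

        out = []
        for r in self.rates.rates:
            if self.params.covarion is not None:
                Q, _ = covarion_matrix(self.model, r, *self.params.covarion)
            else:
                Q = r * self.model.rate_matrix
            out.append(expm(Q * t))
        return out

    def run(self, tree: dendropy.Tree, length: int):
        rng = self.rng
        cats = rng.integers(0, self.rates.n_categories, size=length)
        if self.params.covarion is not None:
            _, pi = covarion_matrix(self.model, 1.0, *self.params.covarion)
        else:
            pi = self.model.freqs
        ns = len(pi)
        nodes = list(reversed(list(tree.postorder_node_iter())))  # preorder
        states: dict[int, np.ndarray] = {}
        states[id(nodes[0])] = rng.choice(ns, size=length, p=pi)
        for nd in nodes[1:]:
            Ps = self._branch_pmats(float(nd.edge.length or 0.0))
            parent = states[id(nd.parent_node)]
            child = np.empty(length, dtype=np.int64)
            u = rng.random(length)
            for c, P in enumerate(Ps):
                sel = cats == c
                cum = P.cumsum(axis=1)
                child[sel] = (u[sel, None] > cum[parent[sel]]).sum(axis=1)
            states[id(nd)] = child
        leaves = {
            nd.taxon.label: states[id(nd)] % self.n_obs
            for nd in tree.leaf_node_iter()
        }
        return leaves, cats


def simulate_alignment(
    tree: dendropy.Tree, params: SeqEvolParams
) -> tuple[Alignment, TruthRecord]:
    """Simulate an amino-acid alignment on ``tree``; gap-free by default."""
    rng = np.random.default_rng(params.seed)
    ev = _SiteEvolver(params, rng)
    leaf_states, cats = ev.run(tree, params.length)
    ids = sorted(leaf_states)
    seq_chars = {i: np.array(list(AA_ORDER))[leaf_states[i]] for i in ids}
    if params.indel_rate > 0:
        t = treeutil.clone(tree)
        edges = [
            e for e in t.preorder_edge_iter() if e.tail_node is not None
        ]
        hit = np.nonzero(rng.random(params.length) < params.indel_rate)[0]
        for j in hit:
            e = edges[rng.integers(len(edges))]
            for lf in e.head_node.leaf_iter():
                seq_chars[lf.taxon.label][j] = "-"
    aln = Alignment(ids, ["".join(seq_chars[i]) for i in ids])
    return aln, TruthRecord(site_categories=cats)


# ---------------------------------------------------------------------------
# Proteomes


def simulate_proteomes(
    tree: dendropy.Tree,
    families: list[FamilySpec],
    seed: int = 0,
    seq_params: SeqEvolParams | None = None,
    out_dir: str | None = None,
):
    """Per-taxon protein sets implied by family presence and paralogy.

    Returns (proteomes, truth): ``proteomes`` maps taxon -> {seq id: seq}.
    Sequence ids are ``<taxon>_g<serial>``; the truth table maps each id to
    its family.  When ``out_dir`` is given, one FASTA per taxon plus a
    truth TSV and manifest are written there.
    """
    base = seq_params or SeqEvolParams()
    rng = np.random.default_rng(seed)
    taxa = treeutil.taxon_labels(tree)
    proteomes: dict[str, dict[str, str]] = {t: {} for t in taxa}
    truth = TruthRecord(presence={})
    serial = {t: 0 for t in taxa}
    for fam in families:
        present = list(fam.presence) if fam.presence is not None else list(taxa)
        missing = set(present) - set(taxa)
        if missing:
            raise ValueError(f"{fam.family_id}: unknown taxa {sorted(missing)}")
        sub = treeutil.prune_to(tree, present) if len(present) < len(taxa) else tree
        if len(present) == 1:
            seq = "".join(
                np.random.default_rng(rng.integers(2**31)).choice(
                    list(AA_ORDER), fam.length
                )
            )
            fam_seqs = {present[0]: seq}
        else:
            scaled = treeutil.clone(sub)
            for e in scaled.preorder_edge_iter():
                if e.tail_node is not None:
                    e.length = (e.length or 0.0) * fam.rate
            p = SeqEvolParams(
                base.model,
                base.gamma_shape,
                base.n_categories,
                fam.length,
                base.covarion,
                0.0,
                seed=int(rng.integers(2**31)),
            )
            aln, _ = simulate_alignment(scaled, p)
            fam_seqs = aln.to_dict()
        truth.presence[fam.family_id] = set(present)
        for taxon in present:
            copies = fam.paralogs.get(taxon, 1)
            for k in range(copies):
                serial[taxon] += 1
                sid = f"{taxon}_g{serial[taxon]:04d}"
                if sid in truth.membership:
                    raise ValueError(f"duplicate sequence id {sid}")
                seq = fam_seqs[taxon]
                if k > 0:  # diverged paralogous copy
                    tiny = dendropy.Tree.get(
                        data=f"(A:{fam.paralog_divergence},B:0.0,C:0.0);",
                        schema="newick",
                    )
                    p = SeqEvolParams(
                        base.model, base.gamma_shape, base.n_categories,
                        fam.length, seed=int(rng.integers(2**31)),
                    )
                    ev = _SiteEvolver(p, np.random.default_rng(p.seed))
                    P = ev._branch_pmats(fam.paralog_divergence)
                    codes = np.array([AA_ORDER.index(c) for c in seq])
                    cats = np.random.default_rng(p.seed + 1).integers(
                        0, p.n_categories, len(seq)
                    )
                    u = np.random.default_rng(p.seed + 2).random(len(seq))
                    new = codes.copy()
                    for c, Pm in enumerate(P):
                        sel = cats == c
                        cum = Pm.cumsum(axis=1)
                        new[sel] = (u[sel, None] > cum[codes[sel]]).sum(axis=1)
                    seq = "".join(AA_ORDER[i] for i in new)
                proteomes[taxon][sid] = seq
                truth.membership[sid] = fam.family_id
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = []
        for taxon in taxa:
            path = os.path.join(out_dir, f"{taxon}.fasta")
            write_fasta_dict(proteomes[taxon], path)
            manifest.append(path)
        truth.write_tsv(os.path.join(out_dir, "truth.tsv"))
        with open(os.path.join(out_dir, "MANIFEST.tsv"), "w") as fh:
            fh.write("file\tsha256\n")
            for path in manifest + [os.path.join(out_dir, "truth.tsv")]:
                h = hashlib.sha256(open(path, "rb").read()).hexdigest()
                fh.write(f"{os.path.basename(path)}\t{h}\n")
    return proteomes, truth


# ---------------------------------------------------------------------------
# Intersection datasets


def simulate_intersection_dataset(
    host_tree: dendropy.Tree,
    outgroup_tree: dendropy.Tree,
    attach_edge: frozenset,
    stem_length: float,
    params: SeqEvolParams,
):
    """Graft a monophyletic outgroup onto a host edge and simulate sequence.

    Returns (joint_tree, alignment, truth); ``truth.attach_edge`` records
    the host bipartition the outgroup was attached to.
    """
    host_ids = {eid for eid, _ in treeutil.edges_with_ids(host_tree)}
    if attach_edge not in host_ids:
        raise ValueError(f"attach edge {sorted(attach_edge)} is not an edge of the host tree")
    joint = treeutil.graft_subtree(host_tree, outgroup_tree, attach_edge, stem_length)
    aln, truth = simulate_alignment(joint, params)
    truth.attach_edge = attach_edge
    return joint, aln, truth
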