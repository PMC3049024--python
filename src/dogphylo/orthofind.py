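"""Iterative profile search and discrete orthologous group (DOG) calling.

The search protocol, per seed sequence: build a profile from the current
hit set, search every proteome, keep hits at or below the E-value
threshold, re-align, strip gappy columns and near-identical sequences,
rebuild the profile, and repeat until the hit set stops changing.  Results
fall into three categories: (1) nothing but the seed, (2) at most one
sequence per taxon, (3) paralogues in at least one taxon.  Category-2
groups are accepted as DOGs only when every member's own search recovers
exactly the same set.

The profile is a calibrated log-odds position-specific scoring matrix with
per-column affine gap penalties; E-values come from a maximum-likelihood
Gumbel fit to shuffled-decoy scores, refreshed at every iteration.  The
search interface (aligner, profile scorer) is pluggable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gumbel_r

from ._aligner import align_sequences
from ._dp import batch_local_scores
from ._engine import encode_sequence
from .models import AA_INDEX
from .seqs import GAP_CHARS, Alignment


@dataclass
class SearchConfig:
    evalue_threshold: float = 1e-5
    max_gap_fraction: float = 0.5  # strictly-more-than-this columns removed
    max_identity: float = 0.95  # strictly-greater pairs pruned
    max_iterations: int = 30
    n_decoys: int = 500
    band: int = 12
    pseudocount: float = 1.0
    background: np.ndarray | None = None  # amino-acid frequencies
    seed: int = 0
    aligner: object = None  # callable {id: seq} -> Alignment

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("E-value threshold must be > 0")
        for frac in (self.max_gap_fraction, self.max_identity):
            if not 0.0 < frac <= 1.0:
                raise ValueError("fractions must be in (0, 1]")
        if self.background is None:
            from .models import empirical_aa_model

            self.background = empirical_aa_model("BLOSUM62").freqs
        if self.aligner is None:
            self.aligner = align_sequences


@dataclass
class ProfileModel:
    """Calibrated log-odds PSSM with affine per-column gap penalties."""

    scores: np.ndarray  # (L, 20)
    gap_open: np.ndarray
    gap_extend: np.ndarray
    gumbel_loc: float
    gumbel_scale: float
    source_hash: str

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("profile must have at least one column")
        if self.gumbel_scale <= 0:
            raise ValueError("calibration scale must be > 0")

    def evalue(self, score: float, db_size: int) -> float:
        p = gumbel_r.sf(score, loc=self.gumbel_loc, scale=self.gumbel_scale)
        return float(db_size * p)


@dataclass
class SearchHit:
    seq_id: str
    taxon: str
    score: float
    evalue: float
    span: tuple[int, int]  # 1-based inclusive on the target

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass
class SearchResult:
    seed_id: str
    hits: list[SearchHit]
    iterations: int
    converged: bool
    category: int = 0

    @property
    def hit_ids(self) -> frozenset[str]:
        return frozenset(h.seq_id for h in self.hits)


@dataclass
class DiscreteOrthologueGroup:
    family_id: str
    members: dict[str, str]  # taxon -> seq id
    profile: ProfileModel | None = None
    alignment: Alignment | None = None

    def __post_init__(self):
        if len(set(self.members.values())) != len(self.members):
            raise ValueError("duplicate sequence id in DOG")


# ---------------------------------------------------------------------------
# Alignment parsing


def remove_gappy_columns(
    aln: Alignment, max_gap_fraction: float = 0.5
) -> tuple[Alignment, list[int]]:
    """Drop columns with strictly more than ``max_gap_fraction`` gaps.

    Returns the parsed alignment and the retained original indices
    (0-based), preserving column order.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    kept = [
        j for j in range(aln.n_sites) if aln.gap_fraction(j) <= max_gap_fraction
    ]
    if not kept:
        raise ValueError("every column exceeded the gap threshold")
    return aln.take_columns(kept), kept


def pairwise_identity(s1: str, s2: str) -> float:
    """Matches over mutually ungapped columns (0 when none exist)."""
    both = [
        (a, b)
        for a, b in zip(s1, s2)
        if a not in GAP_CHARS and b not in GAP_CHARS
    ]
    if not both:
        return 0.0
    return sum(a == b for a, b in both) / len(both)


def remove_redundant_sequences(aln: Alignment, max_identity: float = 0.95) -> Alignment:
    """Greedy first-kept removal of sequences > ``max_identity`` identical
    to an already-retained sequence (input order)."""
    keep_ids: list[str] = []
    keep_seqs: list[str] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        if any(pairwise_identity(seq, k) > max_identity for k in keep_seqs):
            continue
        keep_ids.append(sid)
        keep_seqs.append(seq)
    return Alignment(keep_ids, keep_seqs)


# ---------------------------------------------------------------------------
# Profiles


def _decoy_codes(
    db: "ProteomeDB", n_decoys: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    pool = db.codes_cat[db.codes_cat >= 0]
    if pool.size == 0:
        raise ValueError("cannot calibrate against an empty database")
    length = max(int(np.median(np.diff(db.offsets))), 10)
    draws = rng.integers(0, pool.size, size=n_decoys * length)
    codes = pool[draws]
    offsets = np.arange(n_decoys + 1, dtype=np.int64) * length
    return codes.astype(np.int16), offsets


def build_profile(
    aln: Alignment,
    config: SearchConfig,
    db: "ProteomeDB",
    rng: np.random.Generator | None = None,
) -> ProfileModel:
    """Log-odds PSSM from a parsed alignment, Gumbel-calibrated on decoys."""
    if len(aln) == 0:
        raise ValueError("empty alignment")
    rng = rng or np.random.default_rng(config.seed)
    bg = config.background
    L = aln.n_sites
    counts = np.zeros((L, 20))
    gapfrac = np.zeros(L)
    for s in aln.seqs:
        for j, c in enumerate(s):
            idx = AA_INDEX.get(c)
            if idx is None:
                gapfrac[j] += 1
            else:
                counts[j, idx] += 1
    gapfrac /= len(aln)
    tau = config.pseudocount
    eff = counts.sum(axis=1, keepdims=True)
    freqs = (counts + tau * bg[None, :]) / (eff + tau)
    scores = np.log(freqs / bg[None, :])
    gap_open = (1.0 - gapfrac) * 4.0 + 0.5
    gap_extend = (1.0 - gapfrac) * 0.4 + 0.1
    h = hashlib.sha1("".join(aln.seqs).encode()).hexdigest()[:12]
    codes, offsets = _decoy_codes(db, config.n_decoys, rng)
    decoy_scores, _, _ = batch_local_scores(
        scores, gap_open, gap_extend, codes, offsets, config.band
    )
    loc, scale = gumbel_r.fit(decoy_scores)
    return ProfileModel(scores, gap_open, gap_extend, float(loc), float(scale), h)


# ---------------------------------------------------------------------------
# Databases and search


class ProteomeDB:
    """Pre-encoded concatenation of per-taxon protein sets."""

    def __init__(self, proteomes: dict[str, dict[str, str]]):
        ids, taxa, chunks = [], [], []
        offsets = [0]
        for taxon in sorted(proteomes):
            for sid in sorted(proteomes[taxon]):
                seq = proteomes[taxon][sid]
                ids.append(sid)
                taxa.append(taxon)
                chunks.append(encode_sequence(seq, "aa"))
                offsets.append(offsets[-1] + len(seq))
        self.ids = ids
        self.taxa = taxa
        self.seqs = {
            sid: proteomes[tx][sid] for sid, tx in zip(ids, taxa)
        }
        self.taxon_of = dict(zip(ids, taxa))
        self.codes_cat = (
            np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int16)
        )
        self.offsets = np.array(offsets, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)


def search_profile(
    profile: ProfileModel, db: ProteomeDB | dict, config: SearchConfig
) -> list[SearchHit]:
    """Score every database sequence; return hits with E <= threshold,
    sorted by score descending then sequence id."""
    if not isinstance(db, ProteomeDB):
        db = ProteomeDB(db)
    if len(db) == 0:
        return []
    scores, starts, ends = batch_local_scores(
        profile.scores,
        profile.gap_open,
        profile.gap_extend,
        db.codes_cat,
        db.offsets,
        config.band,
    )
    ev = len(db) * gumbel_r.sf(
        scores, loc=profile.gumbel_loc, scale=profile.gumbel_scale
    )
    hits = [
        SearchHit(db.ids[i], db.taxa[i], float(scores[i]), float(ev[i]),
                  (int(starts[i]), int(ends[i])))
        for i in np.nonzero(ev <= config.evalue_threshold)[0]
    ]
    hits.sort(key=lambda h: (-h.score, h.seq_id))
    return hits


def classify_result(result: SearchResult, taxon_of: dict[str, str]) -> int:
    """Three-way category: (1) seed only, (2) one per taxon, (3) paralogy."""
    ids = result.hit_ids
    if ids == {result.seed_id}:
        return 1
    taxa = [taxon_of[i] for i in ids]
    return 2 if len(set(taxa)) == len(taxa) else 3


def iterate_search(
    seed_id: str,
    db: ProteomeDB | dict,
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SearchResult:
    """Run the iterative profile search from one seed sequence."""
    config = config or SearchConfig()
    if not isinstance(db, ProteomeDB):
        db = ProteomeDB(db)
    if seed_id not in db.seqs:
        raise KeyError(f"seed sequence {seed_id!r} not in the database")
    rng = rng or np.random.default_rng(config.seed)
    current = frozenset([seed_id])
    hits: list[SearchHit] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        ordered = [seed_id] + sorted(current - {seed_id})
        aln = config.aligner({sid: db.seqs[sid] for sid in ordered})
        aln, _ = remove_gappy_columns(aln, config.max_gap_fraction)
        aln = remove_redundant_sequences(aln, config.max_identity)
        profile = build_profile(aln, config, db, rng)
        hits = search_profile(profile, db, config)
        ids = frozenset(h.seq_id for h in hits)
        if seed_id not in ids:
            # a profile always recognizes its own seed; keep the invariant
            # explicit even if the threshold was missed
            s, a, b = (0.0, 1, len(db.seqs[seed_id]))
            hits.append(SearchHit(seed_id, db.taxon_of[seed_id], s, 0.0, (a, b)))
            ids = ids | {seed_id}
        if ids == current:
            converged = True
            break
        current = ids
    result = SearchResult(seed_id, hits, it, converged)
    result.category = classify_result(result, db.taxon_of)
    return result


def run_all_searches(
    db: ProteomeDB | dict,
    config: SearchConfig | None = None,
    seeds: list[str] | None = None,
    progress: bool = False,
) -> list[SearchResult]:
    """Iterative search from every sequence (or a chosen seed list)."""
    config = config or SearchConfig()
    if not isinstance(db, ProteomeDB):
        db = ProteomeDB(db)
    seeds = list(seeds) if seeds is not None else list(db.ids)
    out = []
    for i, sid in enumerate(seeds):
        # independent child stream per seed: results do not depend on the
        # order in which seeds are processed
        rng = np.random.default_rng([config.seed, i])
        out.append(iterate_search(sid, db, config, rng))
        if progress and (i + 1) % 200 == 0:
            print(f"  searched {i + 1}/{len(seeds)} seeds")
    return out


# ---------------------------------------------------------------------------
# Reconciliation and outgroup scanning


def _family_id(ids: frozenset[str]) -> str:
    h = hashlib.sha1("|".join(sorted(ids)).encode()).hexdigest()[:10]
    return f"DOG_{h}"


def reconcile_dogs(
    results: list[SearchResult],
    db: ProteomeDB,
    config: SearchConfig | None = None,
    log: list | None = None,
) -> list[DiscreteOrthologueGroup]:
    """Accept a candidate group iff every member's search recovers exactly
    the same sequence set (set equality); disagreeing groups are discarded."""
    config = config or SearchConfig()
    by_seed = {r.seed_id: r for r in results}
    accepted: dict[frozenset, DiscreteOrthologueGroup] = {}
    for r in results:
        if r.category != 2:
            continue
        ids = r.hit_ids
        if ids in accepted:
            continue
        ok = True
        for m in sorted(ids):
            other = by_seed.get(m)
            if other is None:
                if log is not None:
                    log.append(("missing-search", m, sorted(ids)))
                ok = False
                break
            if other.hit_ids != ids:
                ok = False
                break
        if not ok:
            continue
        members = {db.taxon_of[m]: m for m in sorted(ids)}
        rep = min(ids)
        rng = np.random.default_rng(config.seed)
        aln = config.aligner({sid: db.seqs[sid] for sid in sorted(ids)})
        aln, _ = remove_gappy_columns(aln, config.max_gap_fraction)
        parsed = remove_redundant_sequences(aln, config.max_identity)
        profile = build_profile(parsed, config, db, rng)
        accepted[ids] = DiscreteOrthologueGroup(
            _family_id(ids), members, profile, aln
        )
    return sorted(accepted.values(), key=lambda d: d.family_id)


def scan_outgroups(
    dogs: list[DiscreteOrthologueGroup],
    outgroup_proteomes: dict[str, dict[str, str]],
    config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Best homologue per DOG per outgroup genome (highest score wins;
    ties broken by sequence id)."""
    config = config or SearchConfig()
    rows = []
    genome_dbs = {g: ProteomeDB({g: seqs}) for g, seqs in outgroup_proteomes.items()}
    for dog in dogs:
        for genome, gdb in sorted(genome_dbs.items()):
            hits = search_profile(dog.profile, gdb, config)
            if not hits:
                continue
            best = min(hits, key=lambda h: (-h.score, h.seq_id))
            rows.append(
                {
                    "family_id": dog.family_id,
                    "genome": genome,
                    "seq_id": best.seq_id,
                    "score": best.score,
                    "evalue": best.evalue,
                }
            )
    return pd.DataFrame(rows, columns=["family_id", "genome", "seq_id", "score", "evalue"])


def membership_table(dogs: list[DiscreteOrthologueGroup]) -> pd.DataFrame:
    rows = [
        {"family_id": d.family_id, "taxon": t, "seq_id": s}
        for d in dogs
        for t, s in sorted(d.members.items())
    ]
    return pd.DataFrame(rows, columns=["family_id", "taxon", "seq_id"])


def category_census(results: list[SearchResult]) -> pd.DataFrame:
    counts = {1: 0, 2: 0, 3: 0}
    for r in results:
        counts[r.category] += 1
    return pd.DataFrame(
        [{"category": k, "n": v} for k, v in sorted(counts.items())]
    )
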