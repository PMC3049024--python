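import numpy as np
import pytest

from dogphylo import orthofind, synthdata, treeutil
from dogphylo.orthofind import (
    ProteomeDB,
    SearchConfig,
    SearchResult,
    SearchHit,
    build_profile,
    classify_result,
    iterate_search,
    pairwise_identity,
    reconcile_dogs,
    remove_gappy_columns,
    remove_redundant_sequences,
    run_all_searches,
    scan_outgroups,
    search_profile,
)
from dogphylo.seqs import Alignment


@pytest.fixture(scope="module")
def family_world():
    """12 clean families + one 2-copy paralogous family over 6 taxa."""
    tree = synthdata.simulate_species_tree(6, 1.0, 0.0, seed=2, target_height=0.4)
    taxa = treeutil.taxon_labels(tree)
    fams = [synthdata.FamilySpec(f"F{i:03d}", length=50) for i in range(12)]
    fams.append(
        synthdata.FamilySpec("PARA", length=50, paralogs={taxa[0]: 2})
    )
    prot, truth = synthdata.simulate_proteomes(tree, fams, seed=7)
    db = ProteomeDB(prot)
    cfg = SearchConfig(seed=1, n_decoys=200)
    results = run_all_searches(db, cfg)
    return dict(tree=tree, taxa=taxa, prot=prot, truth=truth, db=db,
                cfg=cfg, results=results)


class TestGappyColumns:
    def test_strictly_more_than_half_gaps_removed(self):
        aln = Alignment(["a", "b", "c", "d"], ["A-C", "A-C", "A-C", "-AC"])
        # col0: 1/4 gaps keep; col1: 3/4 gaps drop; col2: no gaps keep
        out, kept = remove_gappy_columns(aln, 0.5)
        assert kept == [0, 2]
        assert out.seqs == ["AC", "AC", "AC", "-C"]

    def test_exactly_half_gaps_retained(self):
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "-", "-"])
        out, kept = remove_gappy_columns(aln, 0.5)
        assert kept == [0]

    def test_gap_free_unchanged_and_idempotent(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDF"])
        out, kept = remove_gappy_columns(aln, 0.5)
        assert out.seqs == aln.seqs and kept == [0, 1, 2, 3]
        out2, _ = remove_gappy_columns(out, 0.5)
        assert out2.seqs == out.seqs

    def test_everything_removed_raises(self):
        aln = Alignment(["a", "b"], ["--", "A-"])
        with pytest.raises(ValueError, match="gap threshold"):
            remove_gappy_columns(aln, 0.4)


class TestRedundancy:
    def test_identical_second_removed_keep_first(self):
        aln = Alignment(["x", "y", "z"], ["ACDE", "ACDE", "ACDF"])
        out = remove_redundant_sequences(aln, 0.95)
        assert out.ids == ["x", "z"]

    def test_exactly_at_threshold_both_kept(self):
        # 19/20 matches = 0.95 identity, strictly-greater rule keeps both
        s1 = "A" * 20
        s2 = "A" * 19 + "C"
        out = remove_redundant_sequences(Alignment(["x", "y"], [s1, s2]), 0.95)
        assert out.ids == ["x", "y"]

    def test_identity_over_mutually_ungapped_columns_only(self):
        assert pairwise_identity("AC-E", "ACD-") == 1.0
        assert pairwise_identity("--", "AA") == 0.0

    def test_below_threshold_unchanged(self):
        aln = Alignment(["x", "y"], ["ACDEFGHIKL", "ACDEFWWWWW"])
        out = remove_redundant_sequences(aln, 0.95)
        assert out.ids == ["x", "y"]


class TestProfile:
    def test_single_sequence_profile_ranks_its_source_first(self, family_world):
        db, cfg = family_world["db"], family_world["cfg"]
        sid = db.ids[0]
        aln = Alignment([sid], [db.seqs[sid]])
        prof = build_profile(aln, cfg, db, np.random.default_rng(0))
        scores, _, _ = orthofind.batch_local_scores(
            prof.scores, prof.gap_open, prof.gap_extend,
            db.codes_cat, db.offsets, cfg.band,
        )
        # best-scoring database sequence is the source itself
        assert db.ids[int(np.argmax(scores))] == sid

    def test_calibration_moments_match_decoy_sample(self, family_world):
        # Gumbel(loc, scale) mean = loc + gamma*scale; compare to decoys
        db, cfg = family_world["db"], family_world["cfg"]
        sid = db.ids[3]
        aln = Alignment([sid], [db.seqs[sid]])
        rng = np.random.default_rng(5)
        prof = build_profile(aln, cfg, db, rng)
        from dogphylo.orthofind import _decoy_codes
        codes, offsets = _decoy_codes(db, cfg.n_decoys, np.random.default_rng(5))
        dscores, _, _ = orthofind.batch_local_scores(
            prof.scores, prof.gap_open, prof.gap_extend, codes, offsets, cfg.band
        )
        gumbel_mean = prof.gumbel_loc + np.euler_gamma * prof.gumbel_scale
        assert gumbel_mean == pytest.approx(
            dscores.mean(), abs=4 * dscores.std() / np.sqrt(len(dscores))
        )

    def test_duplicate_sequence_changes_scores_only_via_pseudocounts(
        self, family_world
    ):
        db, cfg = family_world["db"], family_world["cfg"]
        sid = db.ids[0]
        seq = db.seqs[sid]
        a1 = Alignment([sid], [seq])
        a2 = Alignment([sid, sid + "_dup"], [seq, seq])
        p1 = build_profile(a1, cfg, db, np.random.default_rng(1))
        p2 = build_profile(a2, cfg, db, np.random.default_rng(1))
        # doubling identical evidence sharpens frequencies toward the
        # observed residue; column argmax is unchanged
        assert (p1.scores.argmax(axis=1) == p2.scores.argmax(axis=1)).all()


class TestSearch:
    def test_profile_recovers_own_family_with_tiny_evalues(self, family_world):
        db, cfg, truth = (
            family_world["db"], family_world["cfg"], family_world["truth"],
        )
        fam_members = sorted(
            sid for sid, f in truth.membership.items() if f == "F000"
        )
        aln = orthofind.align_sequences({s: db.seqs[s] for s in fam_members})
        prof = build_profile(aln, cfg, db, np.random.default_rng(2))
        hits = search_profile(prof, db, cfg)
        got = {h.seq_id for h in hits}
        assert set(fam_members) <= got
        assert all(h.evalue < 1e-10 for h in hits if h.seq_id in fam_members)

    def test_expected_decoy_hits_scale_with_threshold(self, family_world):
        """E-value semantics: on pure decoy databases the expected hit
        count at threshold E0 is about E0 (checked at a liberal E0)."""
        db, cfg = family_world["db"], family_world["cfg"]
        sid = db.ids[0]
        aln = Alignment([sid], [db.seqs[sid]])
        prof = build_profile(aln, cfg, db, np.random.default_rng(3))
        from dogphylo.orthofind import _decoy_codes

        E0 = 5.0
        counts = []
        rng = np.random.default_rng(77)
        for _ in range(40):
            codes, offsets = _decoy_codes(db, 100, rng)
            scores, _, _ = orthofind.batch_local_scores(
                prof.scores, prof.gap_open, prof.gap_extend,
                codes, offsets, cfg.band,
            )
            from scipy.stats import gumbel_r
            ev = 100 * gumbel_r.sf(
                scores, loc=prof.gumbel_loc, scale=prof.gumbel_scale
            )
            counts.append(int((ev <= E0).sum()))
        mean = np.mean(counts)
        assert 0.2 * E0 <= mean <= 3.0 * E0

    def test_empty_database_returns_empty(self, family_world):
        cfg = family_world["cfg"]
        db, _ = family_world["db"], None
        sid = db.ids[0]
        prof = build_profile(
            Alignment([sid], [db.seqs[sid]]), cfg, db, np.random.default_rng(1)
        )
        assert search_profile(prof, ProteomeDB({}), cfg) == []


class TestIterateAndClassify:
    def test_singleton_family_is_category_1(self):
        tree = synthdata.simulate_species_tree(4, 1.0, 0.0, seed=3)
        taxa = treeutil.taxon_labels(tree)
        fams = [synthdata.FamilySpec(f"F{i}", length=50) for i in range(4)]
        fams.append(
            synthdata.FamilySpec("LONER", length=50, presence=[taxa[0]])
        )
        prot, truth = synthdata.simulate_proteomes(tree, fams, seed=9)
        db = ProteomeDB(prot)
        cfg = SearchConfig(seed=2, n_decoys=150)
        loner = [s for s, f in truth.membership.items() if f == "LONER"][0]
        res = iterate_search(loner, db, cfg)
        assert res.category == 1
        assert res.hit_ids == {loner}
        assert res.converged

    def test_clean_family_recovered_and_converged(self, family_world):
        db, cfg, truth = (
            family_world["db"], family_world["cfg"], family_world["truth"],
        )
        members = {s for s, f in truth.membership.items() if f == "F001"}
        seed = sorted(members)[0]
        res = iterate_search(seed, db, cfg)
        assert res.converged
        assert res.hit_ids == members
        assert res.category == 2

    def test_classification_rules(self):
        taxon_of = {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "d1": "D", "e1": "E"}
        mk = lambda ids: SearchResult(
            "a1", [SearchHit(i, taxon_of[i], 1.0, 0.0, (1, 1)) for i in ids], 1, True
        )
        assert classify_result(mk(["a1"]), taxon_of) == 1
        assert classify_result(mk(["a1", "b1", "c1", "d1", "e1"]), taxon_of) == 2
        assert classify_result(mk(["a1", "a2", "b1", "c1", "d1"]), taxon_of) == 3

    def test_nonconvergent_search_flagged_at_cap(self, family_world):
        db = family_world["db"]
        cfg = SearchConfig(seed=1, n_decoys=100, max_iterations=1)
        # max_iterations=1 cannot reach a fixpoint check for a multi-member
        # family (first iteration grows the hit set), so the cap applies
        truth = family_world["truth"]
        members = sorted(s for s, f in truth.membership.items() if f == "F002")
        res = iterate_search(members[0], db, cfg)
        assert res.iterations == 1
        assert not res.converged


class TestReconcile:
    def test_agreeing_trio_accepted(self, family_world):
        db, cfg = family_world["db"], family_world["cfg"]
        taxon_of = {"x1": "X", "y1": "Y", "z1": "Z"}
        trio = frozenset(["x1", "y1", "z1"])
        # synthetic agreeing results; members present in db are irrelevant
        results = []
        for m in sorted(trio):
            hits = [SearchHit(i, taxon_of[i], 5.0, 1e-9, (1, 10)) for i in sorted(trio)]
            r = SearchResult(m, hits, 2, True)
            r.category = 2
            results.append(r)
        tiny = ProteomeDB(
            {"X": {"x1": "ACDEFGHIKLMNPQRSTVWY"},
             "Y": {"y1": "ACDEFGHIKLMNPQRSTVWY"},
             "Z": {"z1": "ACDEFGHIKLMNPQRSTVWY"}}
        )
        dogs = reconcile_dogs(results, tiny, cfg)
        assert len(dogs) == 1
        assert set(dogs[0].members.values()) == set(trio)

    def test_superset_disagreement_discards_group(self):
        taxon_of = {"x1": "X", "y1": "Y", "z1": "Z", "w1": "W"}
        trio = ["x1", "y1", "z1"]
        results = []
        for m in trio:
            ids = trio if m != "z1" else trio + ["w1"]
            hits = [SearchHit(i, taxon_of[i], 5.0, 1e-9, (1, 10)) for i in ids]
            r = SearchResult(m, hits, 2, True)
            r.category = 2
            results.append(r)
        tiny = ProteomeDB(
            {t: {i: "ACDEFGHIKLMNPQRSTVWY"} for i, t in taxon_of.items()}
        )
        dogs = reconcile_dogs(results, tiny, SearchConfig(n_decoys=100))
        assert dogs == []

    def test_end_to_end_truth_recovery_and_paralogy_demotion(self, family_world):
        db, cfg, truth, results = (
            family_world["db"], family_world["cfg"],
            family_world["truth"], family_world["results"],
        )
        dogs = reconcile_dogs(results, db, cfg)
        truth_sets = {}
        for sid, fam in truth.membership.items():
            truth_sets.setdefault(fam, set()).add(sid)
        clean = {frozenset(v) for f, v in truth_sets.items() if f != "PARA"}
        got = {frozenset(d.members.values()) for d in dogs}
        assert got == clean  # precision = recall = 1
        # every seed of the paralogous family is category 3
        para_ids = truth_sets["PARA"]
        for r in results:
            if r.seed_id in para_ids:
                assert r.category == 3
        # invariants: no sequence in two DOGs, no taxon twice within a DOG
        seen = set()
        for d in dogs:
            ids = set(d.members.values())
            assert not (ids & seen)
            seen |= ids
            assert len(d.members) == len(set(d.members))


class TestScanOutgroups:
    def test_best_hit_selected_per_genome(self, family_world):
        db, cfg, truth, results = (
            family_world["db"], family_world["cfg"],
            family_world["truth"], family_world["results"],
        )
        dogs = reconcile_dogs(results, db, cfg)[:4]
        # outgroup with the same families (diverged) plus a paralogue copy
        tree = synthdata.simulate_species_tree(3, 1.0, 0.0, seed=11,
                                               target_height=0.3)
        for lf in tree.leaf_node_iter():
            lf.taxon.label = "OG" + lf.taxon.label
        og_taxa = treeutil.taxon_labels(tree)
        fams = [
            synthdata.FamilySpec(f"F{i:03d}", length=50,
                                 paralogs={og_taxa[0]: 2} if i == 0 else {})
            for i in range(12)
        ]
        oprot, otruth = synthdata.simulate_proteomes(tree, fams, seed=12)
        table = scan_outgroups(dogs, oprot, cfg)
        # at most one row per DOG x genome
        assert not table.duplicated(["family_id", "genome"]).any()
        assert (table["evalue"] <= cfg.evalue_threshold).all()

    def test_no_hits_leaves_cell_empty(self, family_world):
        db, cfg, results = (
            family_world["db"], family_world["cfg"], family_world["results"],
        )
        dogs = reconcile_dogs(results, db, cfg)[:2]
        rng = np.random.default_rng(5)
        junk = {
            "JUNK": {
                f"j{i}": "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 50))
                for i in range(30)
            }
        }
        table = scan_outgroups(dogs, junk, cfg)
        assert len(table) == 0
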