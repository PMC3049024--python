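import numpy as np
import pandas as pd
import pytest

from dogphylo import intersect, synthdata, treeutil
from dogphylo._engine import PatternTable
from dogphylo.intersect import (
    BayesFactorTable,
    enumerate_attachments,
    estimate_log_marginal,
    filter_shared_dogs,
    log10_bayes_factors,
    model_independence,
    stepping_stone_log_marginal,
)
from dogphylo.models import RateModel, binary_restriction_model
from dogphylo.phylocore import MCMCConfig, mcmc_sample


@pytest.fixture(scope="module")
def outgroup3():
    t = synthdata.simulate_species_tree(3, 1.0, 0.0, seed=6, target_height=0.3)
    for lf in t.leaf_node_iter():
        lf.taxon.label = "O" + lf.taxon.label
    return t


class TestEnumerate:
    def test_internal_edge_count_rule(self, outgroup3):
        for n in (6, 10, 14):
            host = synthdata.simulate_species_tree(n, 1.0, 0.0, seed=n)
            hyps = enumerate_attachments(host, outgroup3)
            assert len(hyps) == n - 3

    def test_forty_eight_tip_host_with_two_long_tips_gives_47(self, outgroup3):
        host = treeutil.random_topology(
            [f"T{i:02d}" for i in range(48)], np.random.default_rng(1)
        )
        tips = treeutil.taxon_labels(host)[:2]
        hyps = enumerate_attachments(host, outgroup3, extra_terminal_taxa=tips)
        assert len(hyps) == 47  # 45 internal + 2 designated terminal edges

    def test_pruning_returns_host_topology(self, outgroup3):
        host = synthdata.simulate_species_tree(8, 1.0, 0.0, seed=2)
        for hyp in enumerate_attachments(host, outgroup3):
            back = treeutil.prune_to(hyp.joint_tree, treeutil.taxon_labels(host))
            assert treeutil.same_unrooted_topology(back, host)

    def test_duplicate_terminal_edge_rejected(self, outgroup3):
        host = synthdata.simulate_species_tree(6, 1.0, 0.0, seed=2)
        tip = treeutil.taxon_labels(host)[0]
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_attachments(host, outgroup3,
                                  extra_terminal_taxa=[tip, tip])


class TestMarginalEstimators:
    def test_constant_trace_returns_value_with_zero_se(self):
        lnl = np.full(200, -123.456)
        est, se = estimate_log_marginal(lnl)
        assert est == pytest.approx(-123.456)
        assert se == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            estimate_log_marginal(np.zeros(50))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown estimator"):
            estimate_log_marginal(np.zeros(200), method="bridge")

    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_binary():
        t = treeutil.read_newick("(A:0.2,B:0.2,C:0.2);")
        counts = {"111": 25, "110": 8, "101": 5, "011": 7, "100": 5,
                  "010": 4, "001": 4}
        seqs = {i: "" for i in "ABC"}
        for pat, n in counts.items():
            for i, taxon in enumerate("ABC"):
                seqs[taxon] += pat[i] * n
        pt = PatternTable.from_sequences(seqs, "binary")
        return t, pt, counts

    @staticmethod
    def _quadrature_logml(counts):
        """Grid integration of the marginal likelihood over 3 branch
        lengths with the Exp(10) prior (independent oracle)."""
        from itertools import product

        grid = np.linspace(1e-4, 1.5, 80)
        dg = grid[1] - grid[0]

        def pmat(tt):
            e = np.exp(-2.0 * tt)
            return np.array([[0.5 + 0.5 * e, 0.5 - 0.5 * e],
                             [0.5 - 0.5 * e, 0.5 + 0.5 * e]])

        Ps = [pmat(g) for g in grid]
        vals = np.empty((80, 80, 80))
        for i, j, k in product(range(80), repeat=3):
            P = (Ps[i], Ps[j], Ps[k])

            def site_like(pat):
                tot = 0.0
                for s in (0, 1):
                    pr = 0.5
                    for b, Pb in zip(pat, P):
                        pr *= Pb[s, int(b)]
                    tot += pr
                return tot

            p0 = site_like("000")
            ll = sum(n * np.log(site_like(p) / (1 - p0))
                     for p, n in counts.items())
            prior = (3 * np.log(10.0)
                     - 10.0 * (grid[i] + grid[j] + grid[k]))
            vals[i, j, k] = ll + prior
        m = vals.max()
        return float(m + np.log(np.exp(vals - m).sum() * dg**3))

    def test_estimators_bracket_quadrature_marginal(self, tiny_binary):
        t, pt, counts = tiny_binary
        truth = self._quadrature_logml(counts)
        model = binary_restriction_model(0.5)
        cfg = MCMCConfig(n_generations=30000, sample_interval=10,
                         burn_in=5000, n_chains=1, estimate_shape=False,
                         seed=5)
        trace = mcmc_sample(pt, model, RateModel(1.0, 1), cfg, topology=t,
                            condition_observable=True)
        hm, hm_se = estimate_log_marginal(trace)
        ss = stepping_stone_log_marginal(
            pt, model, RateModel(1.0, 1), t,
            MCMCConfig(n_generations=4000, sample_interval=10, burn_in=1000,
                       n_chains=1, estimate_shape=False, seed=7),
            condition_observable=True,
        )
        # harmonic mean is upward-biased, stepping stone nearly unbiased
        assert abs(ss - truth) < 0.5
        assert abs(hm - truth) < 2.0
        assert min(hm, ss) - 1.0 < truth < max(hm, ss) + 1.0

    def test_stepping_stone_no_systematic_drift_with_longer_chains(
        self, tiny_binary
    ):
        t, pt, counts = tiny_binary
        model = binary_restriction_model(0.5)
        diffs = []
        for seed in (1, 2):
            short = stepping_stone_log_marginal(
                pt, model, RateModel(1.0, 1), t,
                MCMCConfig(n_generations=1500, sample_interval=10,
                           burn_in=400, n_chains=1, estimate_shape=False,
                           seed=seed),
                condition_observable=True,
            )
            long = stepping_stone_log_marginal(
                pt, model, RateModel(1.0, 1), t,
                MCMCConfig(n_generations=3000, sample_interval=10,
                           burn_in=800, n_chains=1, estimate_shape=False,
                           seed=seed + 100),
                condition_observable=True,
            )
            diffs.append(long - short)
        assert abs(np.mean(diffs)) < 1.0


class TestBayesFactors:
    def test_ln10_conversion(self):
        bf = log10_bayes_factors({"a": -100.0, "b": -102.302585092994046})
        assert bf["a"] == 0.0
        assert bf["b"] == pytest.approx(1.0)

    def test_all_equal_all_zero(self):
        bf = log10_bayes_factors({"a": -5.0, "b": -5.0, "c": -5.0})
        assert set(bf.values()) == {0.0}

    def test_ordering_reversed_from_logml(self):
        logml = {"a": -10.0, "b": -30.0, "c": -20.0}
        bf = log10_bayes_factors(logml)
        order_ml = sorted(logml, key=logml.get, reverse=True)
        order_bf = sorted(bf, key=bf.get)
        assert order_ml == order_bf

    def _table(self, per_model):
        rows = []
        for m, logmls in per_model.items():
            bf = log10_bayes_factors(logmls)
            for h in logmls:
                rows.append({"hypothesis": h, "edge": frozenset([h]),
                             "model": m, "logml": logmls[h], "se": 0.0,
                             "log10_bf": bf[h]})
        return BayesFactorTable(pd.DataFrame(rows))

    def test_single_model_average_equals_model_bfs(self):
        tbl = self._table({"WAG": {"a": -10.0, "b": -20.0, "c": -15.0}})
        avg = tbl.average().set_index("hypothesis")
        bf = log10_bayes_factors({"a": -10.0, "b": -20.0, "c": -15.0})
        for h, v in bf.items():
            assert avg.loc[h, "avg_log10_bf"] == pytest.approx(v)

    def test_average_order_invariant_to_hypothesis_order(self):
        logml = {"a": -10.0, "b": -20.0, "c": -15.0}
        t1 = self._table({"WAG": logml})
        t2 = self._table({"WAG": dict(reversed(list(logml.items())))})
        a1 = t1.average().set_index("hypothesis")["avg_log10_bf"]
        a2 = t2.average().set_index("hypothesis")["avg_log10_bf"]
        assert (a1.sort_index() == a2.sort_index()).all()

    def test_extreme_flag_above_1000(self):
        tbl = self._table({"WAG": {"a": 0.0, "b": -1000.5 * np.log(10.0)}})
        avg = tbl.average().set_index("hypothesis")
        assert bool(avg.loc["b", "extreme"])
        assert not bool(avg.loc["a", "extreme"])

    def test_best_hypothesis_is_argmin_of_average(self):
        tbl = self._table({
            "WAG": {"a": -10.0, "b": -20.0, "c": -15.0},
            "DAYHOFF": {"a": -12.0, "b": -25.0, "c": -14.0},
        })
        assert tbl.best_hypothesis() == "a"

    def test_average_and_map_annotates_host(self):
        host = synthdata.simulate_species_tree(6, 1.0, 0.0, seed=3)
        internal = treeutil.internal_edge_ids(host)
        rows = []
        for i, e in enumerate(internal):
            rows.append({"hypothesis": f"H{i}", "edge": e, "model": "WAG",
                         "logml": -10.0 * i, "se": 0.0,
                         "log10_bf": i * 10.0})
        tbl = BayesFactorTable(pd.DataFrame(rows))
        tree, avg = intersect.average_and_map(tbl, host)
        assert avg.iloc[0]["hypothesis"] == "H0"

    def test_model_mismatch_rejected(self):
        rows = [
            {"hypothesis": "a", "edge": frozenset("a"), "model": "WAG",
             "logml": -1.0, "se": 0.0, "log10_bf": 0.0},
            {"hypothesis": "b", "edge": frozenset("b"), "model": "DAYHOFF",
             "logml": -1.0, "se": 0.0, "log10_bf": 0.0},
        ]
        tbl = BayesFactorTable(pd.DataFrame(rows))
        host = synthdata.simulate_species_tree(5, 1.0, 0.0, seed=3)
        with pytest.raises(ValueError, match="differ"):
            intersect.average_and_map(tbl, host)


class TestModelIndependence:
    def _table(self, vec_a, vec_b):
        rows = []
        for m, vec in (("WAG", vec_a), ("DAYHOFF", vec_b)):
            for i, v in enumerate(vec):
                rows.append({"hypothesis": f"h{i}", "edge": frozenset([str(i)]),
                             "model": m, "logml": 0.0, "se": 0.0,
                             "log10_bf": v})
        return BayesFactorTable(pd.DataFrame(rows))

    def test_identical_vectors_r2_one(self):
        v = [0.0, 3.0, 7.0, 1.0]
        out = model_independence(self._table(v, v))
        assert out.iloc[0]["r2"] == pytest.approx(1.0)

    def test_affine_transform_invariance(self):
        v = np.array([0.0, 3.0, 7.0, 1.0])
        out = model_independence(self._table(list(v), list(2.5 * v + 1.0)))
        assert out.iloc[0]["r2"] == pytest.approx(1.0)

    def test_too_few_hypotheses_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            model_independence(self._table([0.0, 1.0], [0.0, 1.0]))


class TestFilterSharedDogs:
    @pytest.fixture
    def table(self):
        rows = []
        for fam, taxa in [
            ("focal_only_shared", ["M1", "M2"]),
            ("focal_only_private", ["M1"]),
            ("broad_shared", ["M1", "X1"]),
            ("outside_only", ["X1", "X2"]),
        ]:
            rows += [{"family_id": fam, "taxon": t, "seq_id": f"{t}_{fam}"}
                     for t in taxa]
        return pd.DataFrame(rows)

    def test_rules(self, table):
        focal = {"M1", "M2"}
        detected = {"focal_only_shared", "broad_shared"}
        kept, removed = filter_shared_dogs(table, focal, detected)
        assert removed == ["focal_only_shared"]
        assert "broad_shared" in kept  # present outside focal clade
        assert "focal_only_private" in kept  # not detected in outgroup
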