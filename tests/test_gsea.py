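"""Enrichment scoring against a brute-force oracle, permutation null, sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ontarget.gsea import (
    GeneSetCollection,
    classify_pathways,
    enrichment_score,
    gsea_run,
    signal_to_noise,
    significant,
)


def oracle_es(metric_sorted, members, weight_p):
    """Plain-python running-sum oracle for the weighted KS statistic."""
    members = set(members)
    n = len(metric_sorted)
    hits = [g in members for g in metric_sorted.index]
    n_hit = sum(hits)
    denom = sum(abs(m) ** weight_p for m, h in zip(metric_sorted.to_numpy(), hits) if h)
    if denom == 0:
        denom = n_hit
        weights = [1.0 if h else 0.0 for h in hits]
    else:
        weights = [abs(m) ** weight_p if h else 0.0 for m, h in zip(metric_sorted.to_numpy(), hits)]
    running, best = 0.0, 0.0
    for w, h in zip(weights, hits):
        running += w / denom if h else -1.0 / (n - n_hit)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


class TestSignalToNoise:
    def _expr(self, a_vals, b_vals):
        a, b = np.atleast_2d(np.asarray(a_vals)), np.atleast_2d(np.asarray(b_vals))
        data = np.hstack([a, b])  # rows = genes, columns = samples
        cols = [f"a{i}" for i in range(a.shape[1])] + [f"b{i}" for i in range(b.shape[1])]
        return pd.DataFrame(data, index=[f"g{i}" for i in range(data.shape[0])], columns=cols)

    def test_direct_formula(self):
        # mu_a=2, mu_b=1, sd floored at 0.5 each -> metric 1.0
        expr = self._expr([[1.5, 2.0, 2.5]], [[0.5, 1.0, 1.5]])
        m = signal_to_noise(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert m["g0"] == pytest.approx((2 - 1) / (0.5 + 0.5))

    def test_identical_groups_zero(self):
        expr = self._expr([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        m = signal_to_noise(expr, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert m["g0"] == 0.0

    def test_swap_negates(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))
        a, b = ["a0", "a1", "a2"], ["b0", "b1", "b2"]
        m1 = signal_to_noise(expr, a, b).sort_index()
        m2 = signal_to_noise(expr, b, a).sort_index()
        np.testing.assert_allclose(m1.to_numpy(), -m2.to_numpy())

    def test_small_group_rejected(self):
        expr = self._expr([[1.0, 2.0]], [[1.0]])
        with pytest.raises(ValueError):
            signal_to_noise(expr, ["a0", "a1"], ["b0"])


class TestEnrichmentScore:
    def test_top_gene_singleton(self):
        ranked = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        es, running = enrichment_score(ranked, {"a"}, weight_p=0)
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_whole_list_degenerate(self):
        ranked = pd.Series([2.0, 1.0], index=list("ab"))
        with pytest.warns(UserWarning):
            es, _ = enrichment_score(ranked, {"a", "b"})
        assert es == 1.0

    def test_ten_gene_example_matches_oracle(self):
        ranked = pd.Series(
            [5, 4, 3, 2, 1, -1, -2, -3, -4, -5], index=[f"g{i}" for i in range(10)], dtype=float
        )
        members = {"g0", "g1"}
        es, _ = enrichment_score(ranked, members, weight_p=1)
        assert es == pytest.approx(oracle_es(ranked, members, 1), abs=1e-12)

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_random_instances_match_oracle(self, weight_p):
        """100 random (list, set) instances agree with the oracle to 1e-12."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            metric = np.sort(rng.normal(size=n))[::-1]
            ranked = pd.Series(metric, index=[f"g{i}" for i in range(n)])
            k = int(rng.integers(1, n))
            members = set(rng.choice(ranked.index, size=k, replace=False))
            es, _ = enrichment_score(ranked, members, weight_p=weight_p)
            assert es == pytest.approx(oracle_es(ranked, members, weight_p), abs=1e-12)

    def test_p0_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        metric = np.sort(rng.normal(size=50))[::-1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(50)])
        members = set(rng.choice(ranked.index, size=8, replace=False))
        es1, _ = enrichment_score(ranked, members, weight_p=0)
        transformed = pd.Series(np.exp(metric / 3), index=ranked.index)  # strictly monotone
        es2, _ = enrichment_score(transformed, members, weight_p=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_increment_normalization(self):
        rng = np.random.default_rng(6)
        ranked = pd.Series(np.sort(rng.normal(size=40))[::-1], index=[f"g{i}" for i in range(40)])
        members = set(rng.choice(ranked.index, size=6, replace=False))
        _, running = enrichment_score(ranked, members, weight_p=1)
        inc = np.diff(np.concatenate([[0.0], running]))
        assert inc[inc > 0].sum() == pytest.approx(1.0)
        assert -inc[inc < 0].sum() == pytest.approx(1.0)

    def test_empty_intersection_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=list("ab"))
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"zz"})


@pytest.fixture(scope="module")
def ranked200():
    rng = np.random.default_rng(17)
    metric = np.sort(rng.normal(size=200))[::-1]
    return pd.Series(metric, index=[f"g{i:03d}" for i in range(200)])


class TestGseaRun:
    def test_size_filter_retains_168_of_187(self, ranked200):
        """187 sets sized so 19 fall outside [5, 500] leave 168."""
        rng = np.random.default_rng(55)
        sets = {}
        for i in range(168):
            k = int(rng.integers(5, 31))
            sets[f"ok{i}"] = list(rng.choice(ranked200.index, size=k, replace=False))
        for i in range(10):
            sets[f"small{i}"] = list(rng.choice(ranked200.index, size=4, replace=False))
        for i in range(9):
            sets[f"big{i}"] = [f"x{i}_{j}" for j in range(501)]
        coll = GeneSetCollection(sets)
        assert len(coll) == 187
        retained = coll.restrict_size(5, 500)
        assert len(retained) == 168
        res = gsea_run(ranked200, coll, n_perm=100, seed=3)
        assert len(res) == 168

    def test_top_set_maximal_enrichment(self, ranked200):
        coll = GeneSetCollection({"top": list(ranked200.index[:10])})
        res = gsea_run(ranked200, coll, n_perm=1000, seed=5)
        # at the permutation floor: no same-signed null ES is as extreme
        assert res.loc[0, "p"] <= 3 / 1000
        assert res.loc[0, "es"] > 0.9

    def test_determinism_and_seed_required(self, ranked200):
        coll = GeneSetCollection({"s": list(ranked200.index[5:20])})
        r1 = gsea_run(ranked200, coll, n_perm=200, seed=11)
        r2 = gsea_run(ranked200, coll, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(r1, r2)
        with pytest.raises(ValueError):
            gsea_run(ranked200, coll, n_perm=200, seed=None)

    def test_nominal_p_uniform_under_null(self, ranked200):
        """Random sets give approximately uniform nominal p (KS test)."""
        rng = np.random.default_rng(21)
        sets = {
            f"r{i}": list(rng.choice(ranked200.index, size=15, replace=False))
            for i in range(200)
        }
        res = gsea_run(ranked200, GeneSetCollection(sets), n_perm=1000, seed=8)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_nes_max_mode_bounded_by_one(self, ranked200):
        rng = np.random.default_rng(33)
        sets = {
            f"r{i}": list(rng.choice(ranked200.index, size=12, replace=False)) for i in range(10)
        }
        res = gsea_run(ranked200, GeneSetCollection(sets), n_perm=100, seed=2, nes_mode="max")
        assert (res["nes"].abs() <= 1.0 + 1e-12).all()


class TestClassifyPathways:
    def _res(self, nes, p):
        return pd.DataFrame({"set": ["pw"], "size": [10], "es": [np.sign(nes)], "nes": [nes], "p": [p], "fdr": [p]})

    def test_on_up_pattern(self):
        results = {k: self._res(1.5, 0.01) for k in ("kd1", "kd2", "6h", "48h")}
        calls = classify_pathways(results)
        assert calls.loc[0, "label"] == "on_up"

    def test_drug_only_off(self):
        results = {
            "kd1": self._res(0.2, 0.9),
            "kd2": self._res(0.1, 0.8),
            "6h": self._res(1.8, 0.01),
            "48h": self._res(1.9, 0.01),
        }
        assert classify_pathways(results).loc[0, "label"] == "off_up"

    def test_nothing_significant_null(self):
        results = {k: self._res(1.0, 0.9) for k in ("kd1", "kd2", "6h", "48h")}
        assert classify_pathways(results).loc[0, "label"] == "null"

    def test_missing_contrast_rejected(self):
        results = {k: self._res(1.0, 0.5) for k in ("kd1", "kd2", "6h")}
        with pytest.raises(ValueError, match="48h"):
            classify_pathways(results)

    def test_significance_rule_inclusive(self):
        res = self._res(2.0, 0.05)
        res["fdr"] = [0.5]
        assert significant(res).iloc[0]  # p == 0.05 inclusive
        res2 = self._res(2.0, 0.5)
        res2["fdr"] = [0.20]
        assert significant(res2).iloc[0]  # fdr == 0.20 inclusive


def test_planted_pathway_detected(small_experiment):
    """The planted on-target pathway is significant in every contrast."""
    from ontarget import ingest
    from ontarget.gsea import signal_to_noise
    from ontarget.simulate import standard_contrasts

    cfg, (counts, sites, sets, gmap, truth) = small_experiment
    sf = ingest.rle_normalize(counts)
    filtered = ingest.cpm_filter(counts, sf)
    gene_cpm = ingest.collapse_to_genes(ingest.cpm(filtered, sf), gmap)
    gene_expr = np.log2(gene_cpm + 1.0)
    meta = counts.metadata
    ctrl = list(meta.index[meta.treatment == "control"])
    drug48 = list(meta.index[(meta.treatment == "drug") & (meta.timepoint == "48h")])
    ranked = signal_to_noise(gene_expr, drug48, ctrl)
    res = gsea_run(ranked, sets, n_perm=500, seed=13).set_index("set")
    assert significant(res.loc[["PW_ON_UP"]].reset_index()).iloc[0]
    assert res.loc["PW_ON_UP", "nes"] > 0
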