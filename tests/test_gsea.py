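"""Gene ranking, running-sum enrichment score and the permutation engine."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from renin_gsx import (
    ConfigError,
    GeneSetCollection,
    GseaParams,
    enrichment_score,
    gsea_run,
    rank_genes,
    running_sum_table,
    simulate_experiment,
)
from renin_gsx.gsea import _es_from_indices
from renin_gsx.simulate import null_config

from .conftest import make_matrix


def brute_force_es(scores, member_flags, weight_p):
    """Independent oracle: literal walk down the ranked list."""
    n = len(scores)
    hits = [i for i in range(n) if member_flags[i]]
    n_r = sum(abs(scores[i]) ** weight_p for i in hits)
    run, best, cur = [], 0.0, 0.0
    for i in range(n):
        if member_flags[i]:
            cur += abs(scores[i]) ** weight_p / n_r
        else:
            cur -= 1.0 / (n - len(hits))
        run.append(cur)
        if abs(cur) > abs(best) + 1e-12:  # earliest extremum wins on ties
            best = cur
    return best, run


class TestRankGenes:
    def test_equal_group_means_score_zero(self):
        vals = np.array([[1.0, 3.0, 3.0, 1.0]])
        assert rank_genes(make_matrix(vals))["score"][0] == 0.0

    def test_hand_set_means_and_sds(self):
        # group means 1 and 2, sample sds 0.5 each (above every floor):
        # signal2noise = (2 - 1) / (0.5 + 0.5) = 1.0
        s = 0.5 / np.sqrt(2)
        vals = np.array([[1 + s, 1 - s, 2 + s, 2 - s]])
        score = rank_genes(make_matrix(vals))["score"][0]
        assert np.isclose(score, 1.0, rtol=1e-12)

    def test_sd_floor_applies_to_tight_genes(self):
        # sample sd ~ 0 but |mean| = 10 -> floor 0.2 * 10 = 2 per group
        vals = np.array([[10.0, 10.0, 11.0, 11.0]])
        score = rank_genes(make_matrix(vals))["score"][0]
        assert np.isclose(score, 1.0 / (2.0 + 2.2))

    def test_constant_shift_preserves_ordering(self, rng):
        # group means stay inside [-1, 1] so the sd floor is the constant 0.2
        # before and after the shift and the difference is shift-invariant
        base = rng.uniform(-0.5, 0.5, (30, 1))
        vals = base + rng.normal(0, 0.05, (30, 8))
        a = rank_genes(make_matrix(vals))
        b = rank_genes(make_matrix(vals + 0.3))
        assert list(a["gene"]) == list(b["gene"])
        np.testing.assert_allclose(a["score"], b["score"], atol=1e-12)

    def test_duplicate_symbols_rejected(self, rng):
        mat = make_matrix(rng.normal(8, 1, (4, 8)))
        dup = mat.values.copy()
        dup.index = ["A", "A", "B", "C"]
        with pytest.raises(ConfigError, match="unique"):
            rank_genes(mat.with_values(dup))

    def test_t_reg_metric_ranks_by_regularized_t(self, rng):
        vals = rng.normal(8, 0.3, (30, 8))
        vals[0, 4:] += 3.0
        from renin_gsx import CybertParams

        ranking = rank_genes(make_matrix(vals), metric="t_reg",
                             cybert_params=CybertParams(window_w=5))
        assert ranking["gene"][0] == "G0000"


class TestEnrichmentScore:
    def test_top_packed_set_reaches_plus_one_unweighted(self):
        scores = np.linspace(3, -3, 12)
        flags = np.zeros(12, bool)
        flags[:4] = True
        assert np.isclose(enrichment_score(scores, flags, 0.0).es, 1.0)

    def test_bottom_packed_set_reaches_minus_one_unweighted(self):
        scores = np.linspace(3, -3, 12)
        flags = np.zeros(12, bool)
        flags[-4:] = True
        assert np.isclose(enrichment_score(scores, flags, 0.0).es, -1.0)

    def test_hand_enumerated_five_gene_example(self):
        scores = np.array([2.0, 1.0, 0.5, -1.0, -2.0])
        flags = np.array([True, False, False, True, False])
        res = enrichment_score(scores, flags, 1.0)
        assert np.isclose(res.es, 2.0 / 3.0)
        np.testing.assert_allclose(
            res.running_sum, [2 / 3, 1 / 3, 0.0, 1 / 3, 0.0], atol=1e-12
        )
        assert list(res.leading_edge_idx) == [0]

    def test_running_sum_ends_at_zero(self, rng):
        scores = np.sort(rng.normal(0, 1, 50))[::-1]
        flags = np.zeros(50, bool)
        flags[rng.choice(50, 8, replace=False)] = True
        res = enrichment_score(scores, flags, 1.0)
        assert abs(res.running_sum[-1]) < 1e-12

    def test_all_zero_member_scores_rejected(self):
        scores = np.array([1.0, 0.0, 0.0, -1.0])
        flags = np.array([False, True, True, False])
        with pytest.raises(ConfigError, match="zero"):
            enrichment_score(scores, flags, 1.0)

    def test_leading_edge_for_negative_es_is_tail(self):
        scores = np.linspace(2, -2, 10)
        flags = np.zeros(10, bool)
        flags[-3:] = True
        res = enrichment_score(scores, flags, 1.0)
        assert res.es < 0
        assert (res.leading_edge_idx >= int(np.argmin(res.running_sum))).all()

    def test_exhaustive_enumeration_small_instances(self, rng):
        """Fast index-based ES agrees with the full walk and with a literal
        oracle over all member placements (N <= 8 here; the acceptance suite
        extends to N = 10)."""
        for n in (5, 8):
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            for k in (1, 2, 3):
                for idx in combinations(range(n), k):
                    flags = np.zeros(n, bool)
                    flags[list(idx)] = True
                    for p in (0.0, 1.0):
                        expect, run = brute_force_es(scores, flags, p)
                        got = enrichment_score(scores, flags, p)
                        assert np.isclose(got.es, expect, atol=1e-12)
                        np.testing.assert_allclose(got.running_sum, run, atol=1e-12)
                        w = np.abs(scores[list(idx)]) ** p
                        fast = _es_from_indices(
                            np.array(idx), w, n
                        )
                        assert np.isclose(fast[0], expect, atol=1e-12)

    def test_complement_running_sum_is_negated_when_unweighted(self, rng):
        scores = np.sort(rng.normal(0, 1, 20))[::-1]
        flags = np.zeros(20, bool)
        flags[rng.choice(20, 6, replace=False)] = True
        a = enrichment_score(scores, flags, 0.0).running_sum
        b = enrichment_score(scores, ~flags, 0.0).running_sum
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_agrees_with_independent_gsea_implementation(self, rng):
        """Cross-check the weighted ES against gseapy's prerank scorer."""
        gseapy = pytest.importorskip("gseapy")
        n = 300
        names = [f"G{i:04d}" for i in range(n)]
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        sets = {
            "RANDOM": sorted(rng.choice(names, 25, replace=False)),
            "TOP": names[:20],
            "BOTTOM": names[-20:],
        }
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": names, "score": scores}).set_index("gene"),
            gene_sets=sets, permutation_num=2, min_size=3, max_size=100,
            weight=1.0, seed=1, threads=1, no_plot=True, outdir=None,
        ).res2d.set_index("Term")
        for name, members in sets.items():
            flags = np.isin(names, members)
            ours = enrichment_score(scores, flags, 1.0).es
            assert np.isclose(ours, float(res.loc[name, "ES"]), atol=1e-6)


def gene_level(mat, truth):
    from renin_gsx import collapse_probes

    return collapse_probes(mat, truth.probe_map)


def small_planted_run(n_perm=300, seed=5):
    cfg = null_config(
        n_genes=1500, probes_per_gene=1, n_tf_sets=8, n_pathway_sets=12,
        set_size_range=(15, 40), gene_sd_range=(0.25, 0.25),
        active_sets={"TF0001": 2.0}, seed=2,
    )
    mat, catalog, truth = simulate_experiment(cfg)
    genes = gene_level(mat, truth)
    params = GseaParams(n_perm=n_perm, seed=seed)
    return genes, catalog, truth, gsea_run(genes, catalog, params)


class TestGseaRun:
    def test_planted_set_attains_top_positive_nes(self):
        _, _, _, res = small_planted_run()
        assert res["set_name"][0] == "TF0001"
        assert res["nes"][0] > 0 and res["q_fdr"][0] <= 0.01
        assert res["es"].between(-1, 1).all()
        sign_ok = np.sign(res["nes"]) == np.sign(res["es"])
        assert (sign_ok | (res["es"] == 0)).all()

    def test_same_seed_reproduces_results(self):
        _, _, _, a = small_planted_run()
        _, _, _, b = small_planted_run()
        pd.testing.assert_frame_equal(a, b)

    def test_leading_edge_members_belong_to_the_set(self):
        _, catalog, _, res = small_planted_run()
        row = res.set_index("set_name").loc["TF0001"]
        leading = set(row["leading_edge"].split(","))
        assert leading <= set(catalog["TF0001"].members)
        assert len(leading) >= 1

    def test_invariant_to_bijective_gene_relabeling(self):
        cfg = null_config(
            n_genes=400, probes_per_gene=1, n_tf_sets=4, n_pathway_sets=4,
            set_size_range=(15, 25), seed=11,
        )
        mat, catalog, truth = simulate_experiment(cfg)
        mat = gene_level(mat, truth)
        params = GseaParams(n_perm=100, seed=3)
        a = gsea_run(mat, catalog, params)
        # order-preserving rename keeps ranks and drawn indices identical
        rename = {g: g.replace("G", "H") for g in mat.row_ids}
        vals = mat.values.rename(index=rename)
        mat2 = mat.with_values(vals)
        catalog2 = GeneSetCollection.from_dict(
            {s.name: [rename[m] for m in s.members] for s in catalog}, "OTHER"
        )
        b = gsea_run(mat2, catalog2, params)
        np.testing.assert_allclose(a["nes"], b["nes"], atol=1e-12)
        np.testing.assert_allclose(a["q_fdr"], b["q_fdr"], atol=1e-12)

    def test_null_nes_magnitudes_center_near_one(self):
        cfg = null_config(
            n_genes=2000, probes_per_gene=1, n_tf_sets=30, n_pathway_sets=30,
            set_size_range=(15, 60), seed=21,
        )
        mat, catalog, truth = simulate_experiment(cfg)
        res = gsea_run(gene_level(mat, truth), catalog, GseaParams(n_perm=150, seed=9))
        pos = res.loc[res["nes"] > 0, "nes"]
        neg = res.loc[res["nes"] < 0, "nes"]
        assert 0.7 < pos.mean() < 1.3
        assert -1.3 < neg.mean() < -0.7

    def test_size_filter_and_error_when_nothing_survives(self):
        cfg = null_config(n_genes=200, probes_per_gene=1, n_tf_sets=3,
                          n_pathway_sets=3, set_size_range=(5, 8), seed=2)
        mat, catalog, truth = simulate_experiment(cfg)
        genes = gene_level(mat, truth)
        with pytest.raises(ConfigError, match="size bounds"):
            gsea_run(genes, catalog, GseaParams(n_perm=10, min_size=50, max_size=60))
        res = gsea_run(genes, catalog, GseaParams(n_perm=10, min_size=5, max_size=8))
        assert len(res) == 6

    def test_running_sum_table_shape(self):
        cfg = null_config(n_genes=300, probes_per_gene=1, n_tf_sets=2,
                          n_pathway_sets=2, set_size_range=(10, 20),
                          active_sets={"TF0001": 1.0}, seed=2)
        mat, catalog, truth = simulate_experiment(cfg)
        ranking = rank_genes(gene_level(mat, truth))
        tab = running_sum_table(ranking, catalog["TF0001"].members)
        assert len(tab) == 300
        assert abs(tab["running_sum"].iloc[-1]) < 1e-9
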