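import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats
from sklearn.metrics import silhouette_score

from apmskit.interactors import (ControlGroupAssignment, _pooled_t,
                                 bait_vs_complement_test,
                                 build_control_groups, call_bait,
                                 call_interactors, permutation_fdr,
                                 whole_proteome_diff)
from apmskit.io_maxquant import SampleAnnotation
from apmskit.simulate import SimulationConfig, generate_apms_dataset
from apmskit.preprocess import log2_transform

from conftest import make_matrix


def two_group_annotation(n1=4, n2=4):
    rows = ([{"sample_id": f"a{r}", "bait_id": "A", "condition": "u",
              "time_min": 0.0, "replicate": r} for r in range(1, n1 + 1)]
            + [{"sample_id": f"b{r}", "bait_id": "B", "condition": "u",
                "time_min": 0.0, "replicate": r} for r in range(1, n2 + 1)])
    return SampleAnnotation(pd.DataFrame(rows))


def one_group(annotation):
    return ControlGroupAssignment({"group1": annotation.sample_ids})


class TestPooledT:
    def test_matches_textbook_formula_and_scipy(self):
        # bait {26,26,27,27} vs complement {20,20,21,21}
        x = np.array([26.0, 26.0, 27.0, 27.0])
        y = np.array([20.0, 20.0, 21.0, 21.0])
        values = np.concatenate([x, y])[None, :]
        diff, t, p = _pooled_t(values, np.arange(8) < 4)
        assert diff[0] == pytest.approx(6.0)
        # independent closed-form pooled-variance oracle
        sp2 = (3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6
        t_oracle = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_oracle = 2 * sstats.t.sf(abs(t_oracle), 6)
        assert t[0] == pytest.approx(t_oracle)
        assert p[0] == pytest.approx(p_oracle)
        res = sstats.ttest_ind(x, y, equal_var=True)
        assert t[0] == pytest.approx(res.statistic)
        assert p[0] == pytest.approx(res.pvalue)

    def test_identical_groups_give_zero_difference_p_one(self):
        values = np.full((1, 8), 23.0)
        diff, t, p = _pooled_t(values, np.arange(8) < 4)
        assert diff[0] == 0.0 and t[0] == 0.0 and p[0] == 1.0

    def test_swapping_groups_negates_difference_and_t(self):
        rng = np.random.default_rng(0)
        values = rng.normal(24, 2, (50, 9))
        lab = np.arange(9) < 4
        d1, t1, p1 = _pooled_t(values, lab)
        d2, t2, p2 = _pooled_t(values, ~lab)
        np.testing.assert_allclose(d1, -d2)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)


class TestBaitVsComplement:
    def test_untestable_below_min_valid_observed(self):
        ann = two_group_annotation(8, 8)
        rng = np.random.default_rng(1)
        vals = rng.normal(24, 1, (2, 16))
        observed = np.ones((2, 16), dtype=bool)
        observed[0, :4] = False  # P1 observed in only 4 of 8 bait samples
        m = make_matrix(vals, ann.sample_ids, observed_mask=observed)
        res = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=5)
        res = res.set_index("protein_id")
        assert not res.loc["P1", "testable"]
        assert res.loc["P2", "testable"]
        assert res.loc["P1", "n_valid_bait"] == 4

    def test_unknown_bait_and_empty_complement_rejected(self):
        ann = two_group_annotation()
        m = make_matrix(np.full((1, 8), 24.0), ann.sample_ids)
        with pytest.raises(ValueError, match="not present"):
            bait_vs_complement_test(m, ann, "Z", one_group(ann))
        lonely = ControlGroupAssignment({"g": ann.samples_for_bait("A")})
        with pytest.raises(ValueError, match="complement"):
            bait_vs_complement_test(m, ann, "A", lonely)

    def test_feature_wise_independence(self):
        # adding another protein row never changes an existing protein's p
        ann = two_group_annotation()
        rng = np.random.default_rng(2)
        vals = rng.normal(24, 1, (5, 8))
        m1 = make_matrix(vals, ann.sample_ids)
        m2 = make_matrix(np.vstack([vals, rng.normal(20, 1, (1, 8))]),
                         ann.sample_ids)
        r1 = bait_vs_complement_test(m1, ann, "A", one_group(ann), min_valid=2)
        r2 = bait_vs_complement_test(m2, ann, "A", one_group(ann), min_valid=2)
        np.testing.assert_array_equal(r1["p_value"],
                                      r2["p_value"].to_numpy()[:5])


class TestPermutationFdr:
    def exhaustive_q(self, values, n1):
        """Brute-force oracle: enumerate all null relabelings, SAM-style q.

        The observed partition (the first n1 columns, or the complementary
        set when group sizes are equal) is not a null relabeling and is
        skipped.
        """
        n = values.shape[1]
        obs_abs = np.abs(_pooled_t(values, np.arange(n) < n1)[1])
        observed_partitions = [frozenset(range(n1))]
        if 2 * n1 == n:
            observed_partitions.append(frozenset(range(n1, n)))
        perm_abs = []
        for combo in itertools.combinations(range(n), n1):
            if frozenset(combo) in observed_partitions:
                continue
            lab = np.zeros(n, dtype=bool)
            lab[list(combo)] = True
            perm_abs.append(np.abs(_pooled_t(values, lab)[1]))
        perm_abs = np.array(perm_abs)
        q = np.empty_like(obs_abs)
        for i, c in enumerate(obs_abs):
            exceed_perm = (perm_abs >= c).sum() / perm_abs.shape[0]
            exceed_obs = (obs_abs >= c).sum()
            q[i] = min(1.0, exceed_perm / exceed_obs)
        # step-up enforcement: running min from least toward most significant
        order = np.argsort(obs_abs)
        q_sorted = np.minimum.accumulate(q[order])
        out = np.empty_like(q)
        out[order] = q_sorted
        return out

    def test_three_vs_three_equals_exhaustive_enumeration(self):
        ann = two_group_annotation(3, 3)
        rng = np.random.default_rng(5)
        vals = rng.normal(24, 1, (12, 6))
        vals[0, :3] += 5  # one strong interactor
        m = make_matrix(vals, ann.sample_ids)
        stats = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=0)
        # C(6,3) = 20 distinct relabelings <= budget -> exhaustive inside
        res = permutation_fdr(stats, m, ann.samples_for_bait("A"),
                              ann.sample_ids, n_permutations=250, seed=1)
        np.testing.assert_allclose(res["q_value"].to_numpy(),
                                   self.exhaustive_q(vals, 3))

    def test_top_statistic_with_no_permuted_exceedance_gets_q_zero(self):
        ann = two_group_annotation(4, 4)
        rng = np.random.default_rng(6)
        vals = rng.normal(24, 0.2, (30, 8))
        vals[0, :4] += 10
        m = make_matrix(vals, ann.sample_ids)
        stats = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=0)
        res = permutation_fdr(stats, m, ann.samples_for_bait("A"),
                              ann.sample_ids, n_permutations=40, seed=2)
        top = res.loc[res["t_statistic"].abs().idxmax()]
        assert top["protein_id"] == "P1"
        assert top["q_value"] == 0.0

    def test_q_monotone_in_abs_t_and_in_unit_interval(self):
        ann = two_group_annotation(4, 4)
        rng = np.random.default_rng(7)
        vals = rng.normal(24, 1, (60, 8))
        m = make_matrix(vals, ann.sample_ids)
        stats = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=0)
        res = permutation_fdr(stats, m, ann.samples_for_bait("A"),
                              ann.sample_ids, n_permutations=100, seed=3)
        res = res.sort_values("t_statistic", key=lambda s: s.abs())
        q = res["q_value"].to_numpy()
        assert ((q >= 0) & (q <= 1)).all()
        assert (np.diff(q) <= 1e-12).all()

    def test_seed_reproducibility(self):
        ann = two_group_annotation(4, 4)
        rng = np.random.default_rng(8)
        vals = rng.normal(24, 1, (20, 8))
        m = make_matrix(vals, ann.sample_ids)
        stats = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=0)
        q1 = permutation_fdr(stats, m, ann.samples_for_bait("A"),
                             ann.sample_ids, n_permutations=99, seed=4)
        q2 = permutation_fdr(stats, m, ann.samples_for_bait("A"),
                             ann.sample_ids, n_permutations=99, seed=4)
        pd.testing.assert_frame_equal(q1, q2)

    def test_rejects_zero_permutations(self):
        ann = two_group_annotation()
        m = make_matrix(np.full((1, 8), 24.0), ann.sample_ids)
        stats = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=0)
        with pytest.raises(ValueError):
            permutation_fdr(stats, m, ann.samples_for_bait("A"),
                            ann.sample_ids, n_permutations=0, seed=0)


class TestCallInteractors:
    def base_stats(self):
        return pd.DataFrame({
            "bait_id": "A",
            "protein_id": ["P1", "P2", "P3"],
            "log2_difference": [0.585, 2.0, 3.0],  # folds 1.5, 4, 8
            "t_statistic": [8.0, 7.0, 6.0],
            "p_value": [1e-5, 1e-4, 1e-3],
            "n_valid_bait": [10, 10, 4],
            "n_valid_complement": [20, 20, 20],
            "testable": [True, True, False],
            "q_value": [0.005, 0.005, 0.0],
        })

    def test_enrichment_condition_is_conjunctive(self):
        out = call_interactors(self.base_stats(), fdr=0.01, enrichment=2.0)
        out = out.set_index("protein_id")
        assert not out.loc["P1", "significant"]  # q ok, fold 1.5 < 2
        assert out.loc["P2", "significant"]      # q ok, fold 4 > 2
        assert not out.loc["P3", "significant"]  # untestable despite q = 0

    def test_fold_enrichment_exactly_two_to_the_difference(self):
        out = call_interactors(self.base_stats())
        np.testing.assert_array_equal(
            out["fold_enrichment"],
            np.power(2.0, out["log2_difference"]))

    def test_ranking_by_q_then_difference(self):
        out = call_interactors(self.base_stats())
        assert out["rank"].tolist() == [1, 2, 3]
        assert out["protein_id"].tolist() == ["P3", "P2", "P1"]


class TestControlGroups:
    def block_matrix(self, seed=0):
        """Two blocks of baits whose samples share a block-level latent
        profile (within-block r ~ 0.95, between ~ 0.3)."""
        rng = np.random.default_rng(seed)
        n_feat = 300
        shared = rng.normal(24, 1.0, n_feat)      # common backbone
        blockA = shared + rng.normal(0, 1.6, n_feat)
        blockB = shared + rng.normal(0, 1.6, n_feat)
        cols, rows = {}, []
        for bait, block in zip("ABCD", [blockA, blockA, blockB, blockB]):
            for r in (1, 2):
                sid = f"{bait}{r}"
                cols[sid] = block + rng.normal(0, 0.3, n_feat)
                rows.append({"sample_id": sid, "bait_id": bait,
                             "condition": "u", "time_min": 0.0, "replicate": r})
        ann = SampleAnnotation(pd.DataFrame(rows))
        m = make_matrix(np.column_stack([cols[s] for s in ann.sample_ids]),
                        ann.sample_ids)
        return m, ann

    def test_two_latent_blocks_recovered_exactly(self):
        m, ann = self.block_matrix()
        groups = build_control_groups(m, ann, n_groups=2)
        assignment = {s: g for g, ms in groups.groups.items() for s in ms}
        assert assignment["A1"] == assignment["A2"] == assignment["B1"]
        assert assignment["C1"] == assignment["C2"] == assignment["D1"]
        assert assignment["A1"] != assignment["C1"]

    def test_identical_samples_single_group(self):
        ann = two_group_annotation()
        vals = np.tile(np.linspace(20, 28, 50)[:, None], (1, 8))
        m = make_matrix(vals, ann.sample_ids)
        groups = build_control_groups(m, ann, n_groups=1)
        assert groups.n_groups == 1

    def test_auto_matches_brute_force_silhouette(self):
        m, ann = self.block_matrix(seed=3)
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform
        vals = m.values.to_numpy()
        dist = np.clip(1 - np.corrcoef(vals.T), 0, 2)
        np.fill_diagonal(dist, 0)
        link = hierarchy.average(squareform(dist, checks=False))
        scores = {k: silhouette_score(
            dist, hierarchy.fcluster(link, t=k, criterion="maxclust"),
            metric="precomputed") for k in range(2, 4)}  # 2..min(6, 4-1)
        best = max(scores, key=scores.get)
        groups = build_control_groups(m, ann, n_groups="auto")
        assert groups.n_groups == best == 2

    def test_too_many_groups_rejected(self):
        m, ann = self.block_matrix()
        with pytest.raises(ValueError, match="n_groups"):
            build_control_groups(m, ann, n_groups=5)

    def test_sparse_overlap_suggests_imputation(self):
        ann = two_group_annotation()
        vals = np.full((12, 8), np.nan)
        vals[:6, :4] = 24.0
        vals[6:, 4:] = 24.0  # disjoint observation patterns
        m = make_matrix(vals, ann.sample_ids)
        with pytest.raises(ValueError, match="imput"):
            build_control_groups(m, ann, n_groups=2)


class TestWholeProteome:
    def test_identical_proteomes_yield_no_calls(self):
        ann = two_group_annotation(3, 3)
        rng = np.random.default_rng(11)
        vals = np.tile(rng.normal(24, 2, 40)[:, None], (1, 6))
        vals += rng.normal(0, 0.1, vals.shape)
        m = make_matrix(vals, ann.sample_ids)
        out = whole_proteome_diff(m, ann, ann.samples_for_bait("A"),
                                  ann.samples_for_bait("B"), seed=1)
        assert not out["significant"].any()

    def test_single_shifted_protein_alone_significant(self):
        ann = two_group_annotation(3, 3)
        rng = np.random.default_rng(12)
        vals = np.tile(rng.normal(24, 2, 40)[:, None], (1, 6))
        vals += rng.normal(0, 0.1, vals.shape)
        vals[0, :3] += 3.0
        m = make_matrix(vals, ann.sample_ids)
        out = whole_proteome_diff(m, ann, ann.samples_for_bait("A"),
                                  ann.samples_for_bait("B"), seed=1)
        assert set(out.loc[out["significant"], "protein_id"]) == {"P1"}

    def test_min_valid_two_admits_doubly_observed_proteins(self):
        ann = two_group_annotation(3, 3)
        rng = np.random.default_rng(13)
        vals = rng.normal(24, 0.2, (5, 6))
        vals[0, :3] += 3.0
        observed = np.ones((5, 6), dtype=bool)
        observed[0, 2] = False  # P1 observed twice in group A
        m = make_matrix(vals, ann.sample_ids, observed_mask=observed)
        out = whole_proteome_diff(m, ann, ann.samples_for_bait("A"),
                                  ann.samples_for_bait("B"), seed=1)
        assert out.set_index("protein_id").loc["P1", "testable"]


def test_null_data_false_positive_rate_controlled():
    """On exchangeable null data the q < 0.01 call rate stays ~<= 1%."""
    fractions = []
    for seed in range(6):
        ann = two_group_annotation(4, 12)
        rng = np.random.default_rng(100 + seed)
        vals = np.tile(rng.normal(24, 2, 150)[:, None], (1, 16))
        vals += rng.normal(0, 0.3, vals.shape)
        m = make_matrix(vals, ann.sample_ids)
        stats = bait_vs_complement_test(m, ann, "A", one_group(ann), min_valid=0)
        res = permutation_fdr(stats, m, ann.samples_for_bait("A"),
                              ann.sample_ids, n_permutations=250, seed=seed)
        fractions.append((res["q_value"] < 0.01).mean())
    assert np.mean(fractions) <= 0.02
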