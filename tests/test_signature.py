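"""Moderated t statistics, candidate selection, fusion ranking, redundancy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import msmimic as mm


def _toy_matrix():
    """3 loci × 6 samples (3 in-group, 3 out-group) with distinct variances."""
    values = np.array(
        [
            [0.80, 0.70, 0.90, 0.20, 0.30, 0.25],
            [0.55, 0.50, 0.60, 0.45, 0.40, 0.50],
            [0.10, 0.15, 0.05, 0.85, 0.95, 0.90],
        ]
    ).T
    beta = mm.BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(6)],
            columns=["cgA", "cgB", "cgC"],
        )
    )
    labels = pd.Series(["g", "g", "g", "o", "o", "o"], index=beta.sample_ids)
    return beta, labels


def _brute_force_moderated_t(values, in_mask):
    """Independent scalar re-implementation of the shrunken t statistics."""
    n1 = in_mask.sum()
    n2 = (~in_mask).sum()
    d = n1 + n2 - 2
    diffs, s2s = [], []
    for j in range(values.shape[1]):
        a = values[in_mask, j]
        b = values[~in_mask, j]
        va = sum((x - a.mean()) ** 2 for x in a) / (n1 - 1)
        vb = sum((x - b.mean()) ** 2 for x in b) / (n2 - 1)
        diffs.append(a.mean() - b.mean())
        s2s.append(((n1 - 1) * va + (n2 - 1) * vb) / d)
    m1 = float(np.mean(s2s))
    v = float(np.var(s2s, ddof=1))
    r = v / m1**2
    if r * d <= 2:
        d0, s0 = np.inf, m1
    else:
        d0 = (4 * r * d + 2 * d - 4) / (r * d - 2)
        if d0 <= 4:
            d0 = 4 + 1e-6
        s0 = m1 * (d0 - 2) / d0
    out = []
    for diff, s2 in zip(diffs, s2s):
        s2_mod = s0 if np.isinf(d0) else (d0 * s0 + d * s2) / (d0 + d)
        out.append(diff / np.sqrt(s2_mod * (1 / n1 + 1 / n2)))
    return np.array(out)


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self, small_cohort):
        beta = small_cohort.beta.fill_median()
        labels = small_cohort.true_labels
        table = mm.moderated_t_stats(beta, labels, "WNT", prior_df=0)
        in_g = (labels == "WNT").to_numpy()
        X = beta.to_numpy()
        expected = stats.ttest_ind(X[in_g], X[~in_g], axis=0).statistic
        np.testing.assert_allclose(table["moderated_t"].to_numpy(), expected, rtol=1e-10)

    def test_infinite_prior_df_gives_complete_shrinkage(self, small_cohort):
        beta = small_cohort.beta.fill_median()
        table = mm.moderated_t_stats(
            beta, small_cohort.true_labels, "SHH", prior_df=np.inf
        )
        assert (table["moderated_s2"] == table["prior_var"]).all()

    def test_toy_matrix_matches_brute_force_oracle(self):
        beta, labels = _toy_matrix()
        table = mm.moderated_t_stats(beta, labels, "g")
        expected = _brute_force_moderated_t(beta.to_numpy(), (labels == "g").to_numpy())
        np.testing.assert_allclose(
            table["moderated_t"].to_numpy(), expected, atol=1e-10
        )

    def test_moderated_s2_between_ordinary_and_prior(self, small_cohort):
        table = mm.moderated_t_stats(
            small_cohort.beta.fill_median(), small_cohort.true_labels, "Grp3"
        )
        lo = np.minimum(table["ordinary_s2"], table["prior_var"])
        hi = np.maximum(table["ordinary_s2"], table["prior_var"])
        assert ((table["moderated_s2"] >= lo - 1e-12) & (table["moderated_s2"] <= hi + 1e-12)).all()
        assert (table["adjusted_p"] >= table["p_value"] - 1e-12).all()

    def test_equal_variance_preserves_ordinary_ordering(self):
        """With a common sample variance, shrinkage cannot reorder loci."""
        base = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        shifts = [0.0, 0.05, 0.1, 0.2, 0.3]
        cols = {}
        for j, s in enumerate(shifts):
            cols[f"cg{j}"] = np.concatenate([0.5 + base + s, 0.5 + base])
        beta = mm.BetaMatrix(
            pd.DataFrame(cols, index=[f"s{i}" for i in range(10)]).clip(0, 1)
        )
        labels = pd.Series(["g"] * 5 + ["o"] * 5, index=beta.sample_ids)
        mod = mm.moderated_t_stats(beta, labels, "g")
        ord_ = mm.moderated_t_stats(beta, labels, "g", prior_df=0)
        assert list(mod.sort_values("moderated_t")["locus_id"]) == list(
            ord_.sort_values("moderated_t")["locus_id"]
        )

    def test_too_small_group_rejected(self):
        beta, labels = _toy_matrix()
        labels = labels.copy()
        labels.iloc[:] = ["g", "o", "o", "o", "o", "o"]
        with pytest.raises(ValueError):
            mm.moderated_t_stats(beta, labels, "g")


class TestSelectCandidates:
    def test_per_group_one_pools_distinct_tops(self, pipeline):
        picked = mm.select_candidates(pipeline["stats"], per_group_k=1)
        assert 1 <= len(picked.pooled) <= 4
        assert len(set(picked.pooled)) == len(picked.pooled)

    def test_pooled_list_unique_and_sized(self, pipeline):
        cand = pipeline["candidates"]
        assert len(cand.pooled) == len(set(cand.pooled))
        assert len(cand.pooled) == 80  # 4 subgroups x 20, disjoint planting

    def test_design_filter_replaces_rejected_top_locus(self, pipeline):
        unfiltered = mm.select_candidates(pipeline["stats"], per_group_k=10)
        top_wnt = unfiltered.per_subgroup["WNT"][0]

        def reject_top(locus):
            return (locus != top_wnt, "assay design failure" if locus == top_wnt else "")

        filtered = mm.select_candidates(
            pipeline["stats"], per_group_k=10, design_filter=reject_top
        )
        assert top_wnt not in filtered.per_subgroup["WNT"]
        # the displaced slot is filled by the next-ranked locus of the contrast
        assert filtered.per_subgroup["WNT"][:9] == unfiltered.per_subgroup["WNT"][1:10]
        assert (filtered.rejected["locus_id"] == top_wnt).any()

    def test_insufficient_eligible_loci_rejected(self, pipeline):
        with pytest.raises(ValueError):
            mm.select_candidates(
                pipeline["stats"],
                per_group_k=10,
                design_filter=lambda locus: (False, "nothing passes"),
            )


class TestFusionRank:
    @staticmethod
    def _perfect_locus_matrix(rng):
        """One perfectly separating locus among pure-noise loci."""
        n = 60
        labels = pd.Series(
            ["a"] * 30 + ["b"] * 30, index=[f"s{i}" for i in range(n)]
        )
        X = rng.uniform(0.3, 0.7, size=(n, 8))
        X[:30, 0] = rng.uniform(0.86, 0.95, size=30)
        X[30:, 0] = rng.uniform(0.05, 0.14, size=30)
        beta = mm.BetaMatrix(
            pd.DataFrame(X, index=labels.index, columns=[f"cg{j}" for j in range(8)])
        )
        return beta, labels

    def test_perfect_separator_ranks_first_everywhere(self, rng):
        beta, labels = self._perfect_locus_matrix(rng)
        ranking = mm.fusion_rank(beta, labels, n_folds=5, seed=0)
        table = ranking.table
        assert ranking.ordered_loci()[0] == "cg0"
        for col in table.columns:
            if col.startswith("rank_"):
                assert table.loc["cg0", col] == 1.0

    def test_constant_locus_ranks_behind_informative(self, rng):
        beta, labels = self._perfect_locus_matrix(rng)
        vals = beta.values.copy()
        vals["cg7"] = 0.5  # constant
        beta = mm.BetaMatrix(vals)
        ranking = mm.fusion_rank(beta, labels, n_folds=5, seed=0)
        assert (
            ranking.table.loc["cg7", "fused_rank"]
            > ranking.table.loc["cg0", "fused_rank"]
        )

    def test_ranking_invariant_to_locus_order(self, rng):
        beta, labels = self._perfect_locus_matrix(rng)
        shuffled_cols = list(rng.permutation(beta.locus_ids))
        beta_shuffled = mm.BetaMatrix(beta.values.loc[:, shuffled_cols])
        a = mm.fusion_rank(beta, labels, n_folds=5, seed=0)
        b = mm.fusion_rank(beta_shuffled, labels, n_folds=5, seed=0)
        assert a.ordered_loci() == b.ordered_loci()

    def test_missing_class_in_fold_rejected(self, rng):
        beta, labels = self._perfect_locus_matrix(rng)
        labels = labels.copy()
        labels.iloc[0] = "c"  # a singleton class cannot be stratified
        with pytest.raises(ValueError):
            mm.fusion_rank(beta, labels, n_folds=5, seed=0)


class TestRedundancyOptimize:
    def test_disabled_search_returns_top_ranked(self, pipeline):
        sig = mm.redundancy_optimize(
            pipeline["ranking"],
            pipeline["cohort"].beta.subset_loci(pipeline["candidates"].pooled),
            pipeline["labels"],
            target_size=17,
            n_iter=0,
        )
        assert sig.locus_ids == pipeline["ranking"].ordered_loci()[:17]

    def test_signature_has_target_size(self, pipeline):
        assert len(pipeline["signature"]) == 17

    def test_signature_loci_come_from_candidates(self, pipeline):
        assert set(pipeline["signature"].locus_ids) <= set(pipeline["candidates"].pooled)

    def test_redundant_candidates_survive_masking(self, rng):
        """Five redundant strong loci per class keep masked CV accuracy high."""
        n_per, n_classes = 20, 4
        n = n_per * n_classes
        labels = pd.Series(
            np.repeat([f"c{i}" for i in range(n_classes)], n_per),
            index=[f"s{i}" for i in range(n)],
        )
        cols = {}
        for c in range(n_classes):
            for j in range(5):
                col = rng.uniform(0.05, 0.2, size=n)
                col[c * n_per : (c + 1) * n_per] = rng.uniform(0.8, 0.95, size=n_per)
                cols[f"cg_c{c}_{j}"] = col
        for j in range(8):
            cols[f"cg_noise{j}"] = rng.uniform(0.3, 0.7, size=n)
        beta = mm.BetaMatrix(pd.DataFrame(cols, index=labels.index))
        ranking = mm.fusion_rank(
            beta, labels, stages=[("flat", {g: g for g in labels.unique()})],
            n_folds=5, seed=1,
        )
        sig = mm.redundancy_optimize(
            ranking, beta, labels, target_size=16, max_remove=6, n_iter=15, seed=1
        )
        from msmimic.signature import _masked_cv_accuracy

        cols_idx = np.asarray([beta.locus_ids.index(l) for l in sig.locus_ids])
        acc = _masked_cv_accuracy(
            beta.to_numpy(), labels.to_numpy(), cols_idx,
            n_iter=40, max_remove=6, rng=np.random.default_rng(5), n_folds=5,
        )
        assert acc >= 0.95

    def test_insufficient_candidates_rejected(self, pipeline):
        with pytest.raises(ValueError):
            mm.redundancy_optimize(
                pipeline["ranking"],
                pipeline["cohort"].beta,
                pipeline["labels"],
                target_size=1000,
            )
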