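"""DAPC fit, classification, contributions and panel-selection rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from aimsel import (
    DAPC,
    Grouping,
    MeanPlusSd,
    TopCount,
    TopFraction,
    accuracy,
    select_informative,
)
from aimsel.dapc import ContributionProfile, MembershipTable
from aimsel.decompose import impute_and_center

from conftest import toy_matrix


def grouped_matrix(calls, labels):
    gm = toy_matrix(np.asarray(calls, dtype=float))
    grouping = Grouping("g", pd.Series(list(labels), index=gm.sample_ids))
    return gm, grouping


@pytest.fixture(scope="module")
def toy_fit():
    """12 samples, 3 well-separated groups, 6 markers, full-rank retention."""
    rng = np.random.default_rng(14)
    base = {
        "a": [0, 0, 2, 2, 1, 0],
        "b": [2, 2, 0, 0, 1, 2],
        "c": [1, 2, 2, 0, 0, 0],
    }
    calls, labels = [], []
    for g, profile in base.items():
        for _ in range(4):
            row = np.array(profile, dtype=float)
            j = int(rng.integers(0, 6))
            row[j] = float(rng.integers(0, 3))
            calls.append(row)
            labels.append(g)
    gm, grouping = grouped_matrix(calls, labels)
    res = DAPC(gm, grouping, n_pca=6).fit()
    return gm, grouping, res


class TestFit:
    def test_two_separable_groups_fully_reassigned(self):
        calls = [[0, 0, 2]] * 5 + [[2, 2, 0]] * 5
        gm, grouping = grouped_matrix(calls, "aaaaabbbbb")
        res = DAPC(gm, grouping, n_pca=2, n_disc=1).fit()
        assert res.n_disc == 1
        proj_a = res.group_centroids.loc["a", "LD1"]
        proj_b = res.group_centroids.loc["b", "LD1"]
        assert abs(proj_a - proj_b) > 1.0
        assert res.accuracy() == 100.0

    def test_full_rank_matches_direct_generalized_eigensolve(self, toy_fit):
        """With all PCs retained, the discriminant directions back-projected
        to marker space span the same subspace as a generalized eigensolve
        on the imputed, centered dosages (angle < 1e-8 rad)."""
        gm, grouping, res = toy_fit
        x, _, _ = impute_and_center(gm.calls)
        n, k = len(x), grouping.k
        within = np.zeros((6, 6))
        between = np.zeros((6, 6))
        mu = x.mean(axis=0)
        for g, rows in grouping.indices_for(gm.sample_ids).items():
            xg = x[rows]
            mg = xg.mean(axis=0)
            within += (xg - mg).T @ (xg - mg)
            between += len(rows) * np.outer(mg - mu, mg - mu)
        within /= n - k
        between /= k - 1
        evals, evecs = scipy.linalg.eigh(between, within)
        direct = evecs[:, np.argsort(evals)[::-1][: res.n_disc]]
        angles = scipy.linalg.subspace_angles(res.var_coeff.to_numpy(), direct)
        assert float(np.max(angles)) < 1e-8

    def test_ridge_applied_when_within_singular(self):
        # more retained PCs than within-group degrees of freedom
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(6, 10)).astype(float)
        gm, grouping = grouped_matrix(calls, "aaabbb")
        with pytest.warns(UserWarning, match="ridge"):
            res = DAPC(gm, grouping, n_pca=5, n_disc=1).fit()
        assert res.ridge > 0

    def test_invalid_dimensions_rejected(self, toy_fit):
        gm, grouping, _ = toy_fit
        with pytest.raises(ValueError, match="n_disc"):
            DAPC(gm, grouping, n_pca=6, n_disc=5).fit()
        with pytest.raises(ValueError, match="n_pca"):
            DAPC(gm, grouping, n_pca=0).fit()

    def test_summary_mentions_key_dimensions(self, toy_fit):
        _, _, res = toy_fit
        text = res.summary()
        assert "Retained PCs" in text and "Discriminant functions" in text


class TestMembership:
    def test_rows_sum_to_one(self, toy_fit):
        _, _, res = toy_fit
        post = res.predict().posteriors
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert ((post.to_numpy() >= 0) & (post.to_numpy() <= 1)).all()

    def test_sample_at_centroid_gets_high_posterior(self):
        calls = [[0, 0, 2]] * 5 + [[2, 2, 0]] * 5
        gm, grouping = grouped_matrix(calls, "aaaaabbbbb")
        res = DAPC(gm, grouping, n_pca=2, n_disc=1).fit()
        post = res.predict().posteriors
        assert post.loc["s0", "a"] > 0.99

    def test_equidistant_sample_splits_posterior(self):
        calls = [[0.0], [0.0], [2.0], [2.0], [1.0]]
        gm, grouping = grouped_matrix(calls, "aabba")
        # fit on the 4 extreme samples, classify the middle one
        train = gm.take_samples(np.array([True, True, True, True, False]))
        grouping_train = Grouping("g", pd.Series(["a", "a", "b", "b"], index=train.sample_ids))
        res = DAPC(train, grouping_train, n_pca=1, n_disc=1).fit()
        post = res.predict(gm.take_samples(np.array([False] * 4 + [True]))).posteriors
        assert post.iloc[0]["a"] == pytest.approx(0.5, abs=1e-9)

    def test_marker_mismatch_raises(self, toy_fit):
        gm, _, res = toy_fit
        with pytest.raises(ValueError, match="lacks model markers"):
            res.predict(gm.take_snps(gm.marker_ids[:3]))

    def test_accuracy_arithmetic(self):
        """47 of 50 correct -> exactly 94.0%."""
        ids = [f"s{i}" for i in range(50)]
        assigned = pd.Series(["x"] * 47 + ["y"] * 3, index=ids)
        post = pd.DataFrame({"x": 0.5, "y": 0.5}, index=ids)
        truth = Grouping("t", pd.Series(["x"] * 50, index=ids))
        membership = MembershipTable(posteriors=post, assigned=assigned)
        assert accuracy(membership, truth) == 94.0

    def test_accuracy_invariant_under_label_renaming(self, toy_fit):
        gm, grouping, res = toy_fit
        renamed = Grouping(
            "renamed",
            grouping.assignment.map({"a": "North", "b": "South", "c": "East"}),
        )
        res2 = DAPC(gm, renamed, n_pca=6).fit()
        assert res2.accuracy() == res.accuracy()

    def test_random_assignment_accuracy_near_chance(self):
        """Assignments independent of truth with k equal groups: ~100/k %."""
        rng = np.random.default_rng(10)
        k, n, reps = 5, 50, 400
        ids = [f"s{i}" for i in range(n)]
        truth = Grouping("t", pd.Series(np.repeat([f"g{j}" for j in range(k)], n // k), index=ids))
        accs = []
        post = pd.DataFrame(np.full((n, k), 1 / k), index=ids, columns=[f"g{j}" for j in range(k)])
        for _ in range(reps):
            assigned = pd.Series(rng.choice([f"g{j}" for j in range(k)], size=n), index=ids)
            accs.append(accuracy(MembershipTable(post, assigned), truth))
        assert np.mean(accs) == pytest.approx(100 / k, abs=1.5)


class TestContributions:
    def test_sum_to_one_and_zero_loading_marker(self, toy_fit):
        gm, grouping, _ = toy_fit
        calls = np.hstack([gm.calls, np.full((gm.n_samples, 1), 1.0)])  # constant marker
        gm2, grouping2 = grouped_matrix(calls, grouping.assignment.to_list())
        res = DAPC(gm2, grouping2, n_pca=3).fit()
        for f in range(1, res.n_disc + 1):
            profile = res.contributions(f)
            assert profile.contributions.sum() == pytest.approx(1.0, abs=1e-9)
            assert profile.contributions.iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_five_marker_toy_matches_hand_computation(self, toy_fit):
        """contribution_j = (loadings @ eigvec)_j^2, column-normalized —
        recomputed here with explicit dense products."""
        _, _, res = toy_fit
        expect = res.pca.loadings[:, : res.n_pca] @ res.disc_eigvec
        expect = expect**2
        expect = expect / expect.sum(axis=0)
        for f in range(res.n_disc):
            got = res.contributions(f + 1).contributions.to_numpy()
            np.testing.assert_allclose(got, expect[:, f], atol=1e-12)

    def test_combined_profile_sums_to_one(self, toy_fit):
        _, _, res = toy_fit
        combined = res.contributions(None).contributions
        assert combined.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_eigvec_rescaling(self, toy_fit):
        _, _, res = toy_fit
        before = res.contributions(1).contributions.copy()
        res.var_coeff.iloc[:, 0] *= 3.7  # rescale one discriminant column
        after = res.contributions(1).contributions
        np.testing.assert_allclose(after.to_numpy(), before.to_numpy(), atol=1e-12)
        res.var_coeff.iloc[:, 0] /= 3.7


class TestSelectionRules:
    def profile(self, values):
        s = pd.Series(values, index=[f"m{i}" for i in range(len(values))])
        return ContributionProfile(function_index=1, contributions=s / s.sum())

    def test_top_fraction_ceil_and_ties(self):
        p = self.profile([1.0] * 5 + [10.0] * 5)
        sel = select_informative(p, TopFraction(0.2))
        assert len(sel.members) == 5  # ceil(0.2*10)=2 but 5-way tie at the cut

    def test_top_fraction_on_435_markers_selects_at_least_nine(self):
        rng = np.random.default_rng(0)
        p = self.profile(list(rng.random(435)))
        sel = select_informative(p, TopFraction(0.02))
        assert len(sel.members) >= 9

    def test_top_count(self):
        p = self.profile([5.0, 4.0, 3.0, 2.0, 1.0])
        sel = select_informative(p, TopCount(2))
        assert sel.members == {"m0", "m1"}

    def test_mean_plus_sd_flat_profile_selects_none(self):
        p = self.profile([1.0] * 10)
        with pytest.warns(UserWarning, match="selected no markers"):
            sel = select_informative(p, MeanPlusSd(1.0))
        assert sel.members == set()

    def test_selection_invariant_to_marker_order(self):
        rng = np.random.default_rng(6)
        vals = list(rng.random(50))
        p = self.profile(vals)
        perm = rng.permutation(50)
        shuffled = ContributionProfile(1, p.contributions.iloc[perm])
        assert (
            select_informative(p, TopFraction(0.1)).members
            == select_informative(shuffled, TopFraction(0.1)).members
        )

    def test_provenance_records_rule_and_threshold(self):
        p = self.profile([3.0, 2.0, 1.0])
        sel = select_informative(p, TopCount(1))
        assert "top_count(1)" in sel.provenance and "realized_threshold" in sel.provenance
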