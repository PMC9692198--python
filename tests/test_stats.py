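"""Group statistics: rank tests, BH-FDR, network density, regions, trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from cortnet.fidelity import EdgeMask
from cortnet.sourcemodel import make_identity_bundle
from cortnet.stats import (
    add_trajectory,
    bh_reject,
    edgewise_comparison,
    effect_size,
    global_mean_connectivity,
    rank_sum_one_tailed,
    region_summaries,
    spindle_removal_contrast,
    trajectory_analysis,
)
from cortnet.synth import simulate_cohort_matrices


def _bh_oracle(p, alpha=0.05):
    """Textbook step-up: largest k with p_(k) <= k/m * alpha; reject 1..k."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * alpha:
            k_max = rank
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestEffectSize:
    def test_complete_separation_is_one(self):
        assert effect_size([5, 6, 7], [1, 2, 3]) == 1.0
        assert effect_size([1, 2], [5, 6]) == -1.0

    def test_identical_distributions_near_zero(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        assert abs(effect_size(x, y)) < 0.1

    def test_bruteforce_pair_enumeration(self):
        """A=(1,2,3), B=(2,3,4): sign sum over all 9 pairs gives -5/9."""
        a, b = [1, 2, 3], [2, 3, 4]
        wins = sum(1 for x in a for y in b if x > y)
        losses = sum(1 for x in a for y in b if x < y)
        expected = (wins - losses) / 9
        assert effect_size(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(-5 / 9)


class TestRankSum:
    def test_matches_scipy_exact_small_n(self, rng):
        a = rng.standard_normal((6, 20))
        b = rng.standard_normal((8, 20)) - 0.5
        p, _ = rank_sum_one_tailed(a, b)
        for k in range(20):
            ref = sst.mannwhitneyu(a[:, k], b[:, k], alternative="greater", method="exact").pvalue
            assert p[k] == pytest.approx(ref, rel=1e-10)

    def test_matches_scipy_asymptotic_large_n(self, rng):
        a = rng.standard_normal((15, 30))
        b = rng.standard_normal((15, 30))
        p, _ = rank_sum_one_tailed(a, b)
        for k in range(30):
            ref = sst.mannwhitneyu(
                a[:, k], b[:, k], alternative="greater", method="asymptotic"
            ).pvalue
            assert p[k] == pytest.approx(ref, rel=1e-8)

    def test_handles_ties_and_constant_columns(self):
        a = np.array([[1.0, 2.0], [1.0, 2.0], [2.0, 2.0], [3.0, 2.0],
                      [1.0, 2.0], [2.0, 2.0], [3.0, 2.0], [1.0, 2.0],
                      [2.0, 2.0], [3.0, 2.0], [1.0, 2.0], [2.0, 2.0]])
        b = a.copy()
        p, es = rank_sum_one_tailed(a, b)
        assert p[1] == 1.0  # constant edge
        np.testing.assert_allclose(es, 0.0, atol=1e-12)


class TestBH:
    def test_hand_computed_stepup(self):
        """Step-up thresholds k/m*alpha = (0.0125, 0.025, 0.0375, 0.05):
        p_(3) = 0.04 > 0.0375, so exactly the two smallest are rejected."""
        p = np.array([0.01, 0.02, 0.04, 0.8])
        reject = bh_reject(p, alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, False, False])
        # 0.04 is rejected as soon as the threshold allows it
        np.testing.assert_array_equal(
            bh_reject(p, alpha=0.054), [True, True, True, False]
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_textbook_oracle(self, pvals):
        p = np.array(pvals)
        np.testing.assert_array_equal(bh_reject(p), _bh_oracle(p))


class TestGlobalConnectivity:
    def _inputs(self, n_per_group=(6, 6), offset=0.0, seed=0, n_parcels=8):
        labels = ["A"] * n_per_group[0] + ["B"] * n_per_group[1]
        manifest = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(len(labels))], "neuro_2y": labels}
        )
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n_parcels, k=1)
        mats = []
        for lab in labels:
            m = np.full((n_parcels, n_parcels), np.nan)
            vals = 0.2 + 0.05 * rng.standard_normal(iu[0].size)
            if lab == "B":
                vals += offset
            m[iu] = vals
            m.T[iu] = vals
            mats.append(m)
        return {10.0: np.array(mats)}, manifest

    def test_identical_matrices_give_h_zero_p_one(self):
        mats, manifest = self._inputs()
        mats[10.0][:] = np.where(np.isnan(mats[10.0][0]), np.nan, 0.3)
        res = global_mean_connectivity(mats, manifest)
        assert res.tests.loc[0, "H"] == 0.0
        assert res.tests.loc[0, "p"] == 1.0

    def test_strong_offset_detected(self):
        mats, manifest = self._inputs(offset=0.3)
        res = global_mean_connectivity(mats, manifest)
        assert res.tests.loc[0, "p"] < 0.01
        means = res.means.set_index("group")["mean"]
        assert means["B"] > means["A"]

    def test_kw_p_matches_permutation_oracle(self):
        """Three groups of four: the KW chi-square p agrees with the
        exhaustive label-permutation p to within 0.02."""
        vals = np.array(
            [0.1, 0.2, 0.15, 0.3, 0.35, 0.45, 0.5, 0.25, 0.6, 0.7, 0.55, 0.8]
        )
        labels = np.array([0] * 4 + [1] * 4 + [2] * 4)
        n = vals.size
        ranks = sst.rankdata(vals)

        def h_of(assign_matrix):
            # H = 12/(N(N+1)) * sum_g R_g^2/n_g - 3(N+1); no ties here
            h = np.zeros(assign_matrix.shape[0])
            for g in range(3):
                r_g = (ranks[None, :] * (assign_matrix == g)).sum(axis=1)
                h += r_g**2 / 4.0
            return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)

        from itertools import combinations

        idx = set(range(n))
        perms = []
        for g0 in combinations(sorted(idx), 4):
            rest = sorted(idx - set(g0))
            for g1 in combinations(rest, 4):
                assign = np.full(n, 2)
                assign[list(g0)] = 0
                assign[list(g1)] = 1
                perms.append(assign)
        perms = np.array(perms)
        h_all = h_of(perms)
        h_obs = h_of(labels[None, :])[0]
        assert h_obs == pytest.approx(
            sst.kruskal(*(vals[labels == g] for g in range(3))).statistic
        )
        p_perm = np.mean(h_all >= h_obs - 1e-12)
        p_kw = sst.kruskal(*(vals[labels == g] for g in range(3))).pvalue
        assert p_kw == pytest.approx(p_perm, abs=0.02)

    def test_group_requirements_enforced(self):
        mats, manifest = self._inputs(n_per_group=(6, 1))
        with pytest.raises(ValueError):
            global_mean_connectivity(mats, manifest)


class TestEdgewise:
    def test_identical_groups_zero_density(self, rng):
        mats = rng.uniform(0.1, 0.5, (6, 8, 8))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        for m in mats:
            np.fill_diagonal(m, np.nan)
        comp = edgewise_comparison(mats, mats.copy())
        assert comp.k == 0.0

    def test_bh_family_is_unmasked_edges_only(self):
        groups, _ = simulate_cohort_matrices({"A": 6, "B": 6}, n_parcels=10, effect_edges=0, seed=3)
        a, b = groups["A"], groups["B"]
        a[:, 0, 1] = a[:, 1, 0] = np.nan  # masked edge in one subject set
        comp = edgewise_comparison(a, b)
        assert comp.n_edges == 45 - 1
        assert np.isnan(comp.p[0, 1])

    def test_implanted_effect_recovered_with_fdr_control(self):
        """100 implanted edges at n=15/group: sensitivity >= 0.8, FDP <= 0.05
        on average (single-seed smoke; the multi-seed version runs in the
        acceptance suite)."""
        sens, fdp = [], []
        for seed in range(5):
            groups, edges = simulate_cohort_matrices(
                {"A": 15, "B": 15}, n_parcels=58, effect_edges=100,
                effect=0.3, effect_group="B", seed=seed,
            )
            comp = edgewise_comparison(groups["B"], groups["A"], group_a="B", group_b="A")
            sig = {(i, j) for i, j in zip(*np.where(np.triu(comp.significant, k=1)))}
            truth = {tuple(sorted(e)) for e in edges}
            sens.append(len(sig & truth) / len(truth))
            fdp.append(len(sig - truth) / max(len(sig), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdp) <= 0.05

    def test_direction_reversal_disjoint(self, rng):
        a = rng.standard_normal((8, 10, 10))
        b = rng.standard_normal((8, 10, 10))
        for arr in (a, b):
            sym = (arr + arr.transpose(0, 2, 1)) / 2
            arr[:] = sym
            for m in arr:
                np.fill_diagonal(m, np.nan)
        fwd = edgewise_comparison(a, b).significant
        rev = edgewise_comparison(b, a).significant
        assert not (fwd & rev).any()

    def test_k_invariant_under_monotone_transform(self):
        groups, _ = simulate_cohort_matrices(
            {"A": 8, "B": 8}, n_parcels=20, effect_edges=30, effect=0.4, seed=9
        )
        a, b = groups["A"], groups["B"]
        k1 = edgewise_comparison(b, a).k
        k2 = edgewise_comparison(np.exp(3 * b), np.exp(3 * a)).k
        assert k1 == pytest.approx(k2)

    def test_minimum_group_size(self, rng):
        a = rng.standard_normal((2, 5, 5))
        with pytest.raises(ValueError, match="n >= 3"):
            edgewise_comparison(a, a)


class TestRegionSummaries:
    def _comp(self, n=12, sig_edges=()):
        p = np.full((n, n), 0.5)
        np.fill_diagonal(p, np.nan)
        sig = np.zeros((n, n), bool)
        for i, j in sig_edges:
            sig[i, j] = sig[j, i] = True
        from cortnet.stats import GroupComparison

        return GroupComparison(
            group_a="A", group_b="B", n_a=5, n_b=5, p=p,
            significant=sig, effect=np.zeros((n, n)),
            k=len(sig_edges) / (n * (n - 1) / 2),
        )

    def test_empty_significant_set(self, identity_bundle):
        out = region_summaries(self._comp(), identity_bundle)
        assert all(v == 0.0 for v in out["involvement"].values())
        assert out["edge_lengths"].size == 0

    def test_all_edges_significant(self, identity_bundle):
        n = identity_bundle.n_parcels
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        out = region_summaries(self._comp(n=n, sig_edges=edges), identity_bundle)
        assert all(v == pytest.approx(1.0) for v in out["region_pairs"].values())
        assert out["interhemispheric_fraction"] == 1.0

    def test_one_hemisphere_network_has_no_interhemispheric_edges(self, identity_bundle):
        labels = identity_bundle.region_labels
        left = [i for i, lab in enumerate(labels) if lab.endswith("left")]
        edges = [(left[0], left[1]), (left[1], left[2])]
        out = region_summaries(self._comp(n=len(labels), sig_edges=edges), identity_bundle)
        assert out["interhemispheric_fraction"] == 0.0
        assert out["intrahemispheric_fraction"] > 0.0


class TestSpindleContrast:
    def _comp(self, k, band=13.0):
        from cortnet.stats import GroupComparison

        n = 6
        return GroupComparison(
            group_a="A", group_b="B", n_a=5, n_b=5,
            p=np.full((n, n), 0.5), significant=np.zeros((n, n), bool),
            effect=np.zeros((n, n)), k=k, band_fc=band, mode="AAC",
        )

    def test_delta_k_sign(self):
        full = {(13.0, "AAC"): self._comp(0.4)}
        removed = {(13.0, "AAC"): self._comp(0.1)}
        df = spindle_removal_contrast(full, removed)
        assert df.loc[0, "delta_k"] == pytest.approx(-0.3)

    def test_identical_variants_give_zero_delta(self):
        full = {(13.0, "AAC"): self._comp(0.25)}
        df = spindle_removal_contrast(full, dict(full))
        assert df.loc[0, "delta_k"] == 0.0

    def test_subject_mismatch_rejected(self):
        full = {(13.0, "AAC"): self._comp(0.4)}
        other = self._comp(0.1)
        other.n_a = 7
        with pytest.raises(ValueError, match="mismatch"):
            spindle_removal_contrast(full, {(13.0, "AAC"): other})


class TestTrajectories:
    def _manifest(self, trajectories):
        rows = []
        for k, (t1, t2) in enumerate(trajectories):
            rows.append(
                {"subject_id": f"S{k}", "syndrome": "West", "neuro_1y": t1, "neuro_2y": t2}
            )
        return pd.DataFrame(rows)

    def _matrices(self, n_subj, offset_idx=(), offset=0.0, seed=0, n_parcels=6):
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n_parcels, k=1)
        mats = []
        for s in range(n_subj):
            m = np.full((n_parcels, n_parcels), np.nan)
            vals = 0.2 + 0.05 * rng.standard_normal(iu[0].size)
            if s in offset_idx:
                vals += offset
            m[iu] = vals
            m.T[iu] = vals
            mats.append(m)
        return np.array(mats)

    def test_trajectory_labels_and_exclusion(self):
        man = add_trajectory(
            self._manifest([("Typical", "Typical"), ("Typical", "Severe"), ("Mild", "Severe")])
        )
        assert list(man["trajectory"]) == ["Typical-Typical", "Typical-Severe", "Mild-Severe"]
        assert list(man["trajectory_excluded"]) == [False, True, False]

    def test_single_subject_group_dropped(self):
        trajs = [("Typical", "Typical")] * 4 + [("Mild", "Mild")]
        man = self._manifest(trajs)
        res = trajectory_analysis({1.5: self._matrices(5)}, man)
        assert "Mild-Mild" not in res["groups"]

    def test_implanted_offset_flagged_with_direction(self):
        trajs = [("Typical", "Typical")] * 6 + [("Typical", "Mild")] * 6
        man = self._manifest(trajs)
        mats = {
            1.5: self._matrices(12, offset_idx=range(6, 12), offset=0.4, seed=1),
            10.0: self._matrices(12, seed=2),
        }
        res = trajectory_analysis(mats, man)
        tests = res["tests"]
        hit = tests[(tests.band_fc == 1.5)]
        assert hit["p_significant"].iloc[0]
        assert hit["direction"].iloc[0] == "Typical-Mild>Typical-Typical"
        miss = tests[(tests.band_fc == 10.0)]
        assert not miss["p_significant"].iloc[0]

    def test_null_rarely_significant(self):
        trajs = [("Mild", "Mild")] * 5 + [("Mild", "Severe")] * 5
        man = self._manifest(trajs)
        n_sig = 0
        for seed in range(20):
            mats = {1.0: self._matrices(10, seed=seed)}
            res = trajectory_analysis(mats, man)
            n_sig += int(res["tests"]["p_significant"].any())
        assert n_sig <= 2  # >= 95% of null simulations stay clean


def test_manifest_roundtrip(tmp_path):
    from cortnet.io import load_manifest

    df = pd.DataFrame(
        {
            "subject_id": ["S0", "S1"],
            "syndrome": ["West", "self-limited"],
            "neuro_1y": ["Typical", "Mild"],
            "neuro_2y": ["Mild", "Severe"],
        }
    )
    path = tmp_path / "manifest.csv"
    df.to_csv(path, index=False)
    out = load_manifest(path)
    pd.testing.assert_frame_equal(out, df)
    df_bad = df.assign(syndrome=["West", "unknown"])
    df_bad.to_csv(path, index=False)
    with pytest.raises(ValueError, match="syndrome"):
        load_manifest(path)
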