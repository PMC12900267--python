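import numpy as np
import pytest

import pnp_workbench as w

from conftest import make_profile


def _members():
    """3 profiles over 6 features: features 0-2 consistently positive,
    features 3-5 mixed signs across members."""
    z = np.array(
        [
            [2.0, 3.0, 1.5, 1.0, -2.0, 0.5],
            [2.5, 2.0, 1.2, -1.0, 2.0, -0.5],
            [3.0, 2.8, 1.8, 2.0, -1.0, 0.7],
        ]
    )
    return [make_profile(row, f"m{i}") for i, row in enumerate(z)]


def test_subprofile_selects_consistent_features_with_medians():
    with pytest.warns(UserWarning):  # members are not all pairwise biosimilar
        sub = w.extract_subprofile(_members(), "toy", consistency=1.0, min_abs_median=1.0)
    assert sub.feature_ids == ["f_0", "f_1", "f_2"]
    np.testing.assert_allclose(sub.values, [2.5, 2.8, 1.5])


def test_subprofile_identical_members_keep_all_large_features():
    z = np.array([3.0, -2.0, 0.4, 1.5])
    members = [make_profile(z, f"m{i}") for i in range(3)]
    sub = w.extract_subprofile(members, "ident", min_abs_median=1.0)
    assert sub.feature_ids == ["f_0", "f_1", "f_3"]  # |0.4| below min_abs_median
    np.testing.assert_allclose(sub.values, [3.0, -2.0, 1.5])


def test_subprofile_strict_consistency_drops_sign_flipped_feature():
    z = np.array([3.0, 2.0, -1.5])
    flipped = z.copy()
    flipped[1] = -2.0
    members = [make_profile(z, "a"), make_profile(z, "b"), make_profile(flipped, "c")]
    with pytest.warns(UserWarning):
        sub = w.extract_subprofile(members, "strict", consistency=1.0)
    assert "f_1" not in sub.feature_ids
    assert sub.feature_ids == ["f_0", "f_2"]


def test_subprofile_member_permutation_invariance(top_conc_profiles, cluster_plate):
    _, truth = cluster_plate
    members = [p for p in top_conc_profiles if truth.compound_cluster[p.compound_id] == 0]
    a = w.extract_subprofile(members, "c0")
    b = w.extract_subprofile(members[::-1], "c0")
    assert a.feature_ids == b.feature_ids
    np.testing.assert_array_equal(a.values, b.values)


def test_subprofile_empty_selection_suggests_lower_thresholds():
    members = [make_profile([0.1, -0.1, 0.2, -0.3], f"m{i}") for i in range(2)]
    with pytest.raises(ValueError, match="lower"):
        w.extract_subprofile(members, "none", min_abs_median=1.0)


def test_cluster_biosim_identity_and_antisymmetry():
    sub = w.Subprofile("c", ["f_0", "f_1", "f_2"], np.array([2.0, -1.5, 3.0]))
    p = make_profile([2.0, -1.5, 3.0, 0.0])
    assert w.cluster_biosim(p, sub) == pytest.approx(100.0)
    neg = make_profile([-2.0, 1.5, -3.0, 0.0])
    assert w.cluster_biosim(neg, sub) == pytest.approx(-100.0)


def test_cluster_biosim_too_few_shared_features():
    sub = w.Subprofile("c", ["f_0", "f_1"], np.array([2.0, -1.5]))
    with pytest.raises(ValueError, match="too small"):
        w.cluster_biosim(make_profile([1.0, 2.0, 3.0]), sub)


def test_member_scores_higher_against_own_cluster(top_conc_profiles, cluster_plate):
    _, truth = cluster_plate
    subs = {}
    for k in range(4):
        members = [p for p in top_conc_profiles if truth.compound_cluster[p.compound_id] == k]
        subs[k] = w.extract_subprofile(members, f"cluster_{k}")
    for p in top_conc_profiles[:10]:
        own = truth.compound_cluster[p.compound_id]
        own_score = w.cluster_biosim(p, subs[own])
        other = (own + 1) % 4
        assert own_score > w.cluster_biosim(p, subs[other])


def test_assignment_recovery_with_noise(cluster_plate, top_conc_profiles):
    _, truth = cluster_plate
    subs = [
        w.extract_subprofile(
            [p for p in top_conc_profiles if truth.compound_cluster[p.compound_id] == k],
            f"cluster_{k}",
        )
        for k in range(4)
    ]
    model = w.ClusterModel(subs)
    rng = np.random.default_rng(2)
    feature_ids = list(top_conc_profiles[0].feature_ids)
    ids = {f: i for i, f in enumerate(feature_ids)}
    probes = []
    expected = []
    for k, sub in enumerate(subs):
        z = np.zeros(579)
        for f, v in zip(sub.feature_ids, sub.values):
            z[ids[f]] = v + rng.normal(0, 0.1)
        p = w.MorphProfile(f"probe{k}", 10.0, z, feature_ids)
        probes.append(p)
        expected.append(f"cluster_{k}")
    out = w.assign_clusters(probes, model)
    assert [a.best_cluster for a in out] == expected


def test_orthogonal_profile_gets_no_cluster(top_conc_profiles, cluster_plate):
    _, truth = cluster_plate
    sub = w.extract_subprofile(
        [p for p in top_conc_profiles if truth.compound_cluster[p.compound_id] == 0], "c0"
    )
    model = w.ClusterModel([sub])
    rng = np.random.default_rng(3)
    noise = w.MorphProfile(
        "noise", 10.0, rng.normal(0, 1, size=579), list(top_conc_profiles[0].feature_ids)
    )
    out = w.assign_clusters([noise], model)[0]
    assert out.best_cluster is None
    assert np.isfinite(out.biosimilarities["c0"])


def test_tie_broken_by_model_order():
    sub_a = w.Subprofile("first", ["f_0", "f_1", "f_2"], np.array([1.0, 2.0, 3.0]))
    sub_b = w.Subprofile("second", ["f_0", "f_1", "f_2"], np.array([2.0, 4.0, 6.0]))
    p = make_profile([1.0, 2.0, 3.0])
    out = w.assign_clusters([p], w.ClusterModel([sub_a, sub_b]))[0]
    assert out.best_cluster == "first"


def test_unscorable_cells_are_nan_not_zero():
    sub_small = w.Subprofile("tiny", ["f_0", "f_1"], np.array([1.0, 2.0]))
    sub_ok = w.Subprofile("ok", ["f_0", "f_1", "f_2"], np.array([1.0, 2.0, 3.0]))
    p = make_profile([1.0, 2.0, 3.0, 4.0])
    out = w.assign_clusters([p], w.ClusterModel([sub_small, sub_ok]))[0]
    assert np.isnan(out.biosimilarities["tiny"])
    assert np.isfinite(out.biosimilarities["ok"])


def test_removing_unselected_feature_leaves_scores_unchanged(top_conc_profiles, cluster_plate):
    _, truth = cluster_plate
    members = [p for p in top_conc_profiles if truth.compound_cluster[p.compound_id] == 1]
    sub = w.extract_subprofile(members, "c1")
    p = top_conc_profiles[0]
    before = w.cluster_biosim(p, sub)
    drop = next(f for f in p.feature_ids if f not in sub.feature_ids)
    keep = [i for i, f in enumerate(p.feature_ids) if f != drop]
    reduced = w.MorphProfile(
        p.compound_id, p.concentration_um, p.z[keep], [p.feature_ids[i] for i in keep]
    )
    assert w.cluster_biosim(reduced, sub) == pytest.approx(before, abs=1e-12)


def test_cluster_model_json_round_trip(tmp_path, top_conc_profiles, cluster_plate):
    _, truth = cluster_plate
    subs = [
        w.extract_subprofile(
            [p for p in top_conc_profiles if truth.compound_cluster[p.compound_id] == k],
            f"cluster_{k}",
        )
        for k in range(2)
    ]
    model = w.ClusterModel(subs)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = w.ClusterModel.from_json(path)
    assert back.names == model.names
    for a, b in zip(back.subprofiles, model.subprofiles):
        assert a.feature_ids == b.feature_ids
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def test_duplicate_cluster_names_rejected():
    sub = w.Subprofile("x", ["f_0", "f_1", "f_2"], np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="unique"):
        w.ClusterModel([sub, sub])


def test_profile_umap_joint_embedding(cluster_profiles):
    profs = [p for p in cluster_profiles if p.concentration_um == 50.0][:12]
    refs = [p for p in cluster_profiles if p.concentration_um == 30.0][:8]
    emb = w.profile_umap(profs, refs, n_neighbors=10, seed=9)
    assert emb.coordinates.shape[0] == len(profs) + len(refs)
    assert list(emb.coordinates["is_reference"]) == [False] * 12 + [True] * 8
    np.testing.assert_array_equal(
        emb.coordinates["induction"].to_numpy()[:12], [p.induction for p in profs]
    )
    again = w.profile_umap(profs, refs, n_neighbors=10, seed=9)
    np.testing.assert_array_equal(
        emb.coordinates[["dim_1", "dim_2"]].to_numpy(),
        again.coordinates[["dim_1", "dim_2"]].to_numpy(),
    )
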