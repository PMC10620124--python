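"""Zero-filled fold-change matrix, correlation clustering, PCA oracles."""

import numpy as np
import pandas as pd
import pytest

from lipidiff import multivariate as mv
from lipidiff.errors import ValidationError

from conftest import make_table
from test_interaction import contrast_frame


# ------------------------------------------------------- build_log2fc_matrix
def test_zero_fill_rules():
    c1 = contrast_frame(
        [("PC 16:0/18:1", 1.5, 0.01), ("PE 16:0/18:1", -2.0, 0.001)]
    )
    c2 = contrast_frame(
        [("PC 16:0/18:1", 0.4, 0.30)]  # eligible but non-significant
    )
    matrix = mv.build_log2fc_matrix({"c1": c1, "c2": c2})
    assert matrix.values.loc["PC 16:0/18:1"].tolist() == [1.5, 0.0]
    assert matrix.mask.loc["PC 16:0/18:1"].tolist() == [mv.MASK_DRL, mv.MASK_NONSIGNIFICANT]
    # PE was never eligible in c2: filled-missing zero
    assert matrix.values.loc["PE 16:0/18:1", "c2"] == 0.0
    assert matrix.mask.loc["PE 16:0/18:1", "c2"] == mv.MASK_MISSING
    assert not matrix.values.isna().any().any()


def test_zero_fill_never_touches_significant_cells(rng):
    rows = [(f"PC {i}:0/18:1", rng.normal(), rng.random()) for i in range(1, 40)]
    c = contrast_frame(rows)
    matrix = mv.build_log2fc_matrix({"only": c})
    drls = c[c["is_drl"]].set_index("lipid")
    for lipid, row in drls.iterrows():
        assert matrix.values.loc[lipid, "only"] == row["log2fc"]
        assert matrix.mask.loc[lipid, "only"] == mv.MASK_DRL


def test_single_contrast_all_significant_equals_vector():
    c = contrast_frame([("PC 16:0/18:1", 1.0, 0.01), ("PE 16:0/18:1", -1.0, 0.02)])
    matrix = mv.build_log2fc_matrix({"c": c})
    assert matrix.values["c"].sort_index().tolist() == [1.0, -1.0]


def test_duplicate_labels_rejected():
    with pytest.raises(ValidationError):
        mv.build_log2fc_matrix({})


# ------------------------------------------------------------------- cluster
def brute_force_average_linkage(dist):
    """Naive agglomerative average linkage; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    next_id = len(dist)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


def _matrix_from_array(arr, labels=None):
    arr = np.asarray(arr, dtype=float)
    labels = labels or [f"c{j}" for j in range(arr.shape[1])]
    values = pd.DataFrame(
        arr, index=[f"PC {i + 10}:0/18:1" for i in range(arr.shape[0])], columns=labels
    )
    mask = pd.DataFrame(mv.MASK_DRL, index=values.index, columns=values.columns)
    return mv.Log2FCMatrix(values=values, mask=mask)


def test_identical_columns_merge_first_at_zero():
    matrix = _matrix_from_array(
        [[1.0, 1.0, 5.0], [2.0, 2.0, -1.0], [3.0, 3.0, 2.0], [0.0, 0.0, 7.0]]
    )
    result = mv.cluster(matrix, axis="contrasts")
    assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert set(result.leaf_order[:2]) == {"c0", "c1"} or set(
        result.leaf_order[-2:]
    ) == {"c0", "c1"}


def test_anticorrelated_column_at_distance_two():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    orth = np.array([1.0, -1.0, 1.0, -1.0])
    matrix = _matrix_from_array(np.column_stack([base, -base, orth]))
    result = mv.cluster(matrix, axis="contrasts")
    d = result.distances
    assert d.loc["c0", "c1"] == pytest.approx(2.0, abs=1e-12)
    # the anticorrelated pair merges last in this 3-column fixture
    assert result.linkage[-1, 2] == pytest.approx(max(result.linkage[:, 2]))


def test_merge_heights_match_brute_force_oracle(rng):
    for _ in range(10):
        arr = rng.normal(size=(5, 4))
        matrix = _matrix_from_array(arr)
        result = mv.cluster(matrix, axis="lipids")
        dist = mv.pearson_distance_matrix(arr)
        np.testing.assert_allclose(
            sorted(result.linkage[:, 2]),
            brute_force_average_linkage(dist),
            atol=1e-10,
        )


def test_zero_variance_profile_at_distance_one(rng):
    arr = np.vstack([np.zeros(4), rng.normal(size=(3, 4))])
    dist = mv.pearson_distance_matrix(arr)
    np.testing.assert_allclose(dist[0, 1:], 1.0)
    assert dist[0, 0] == 0.0


def test_pearson_distance_scale_invariant(rng):
    arr = rng.normal(size=(4, 6))
    scaled = arr.copy()
    scaled[1] = 3.7 * scaled[1] + 2.0  # positive affine rescale of one profile
    np.testing.assert_allclose(
        mv.pearson_distance_matrix(arr),
        mv.pearson_distance_matrix(scaled),
        atol=1e-12,
    )


def test_cluster_needs_two_items():
    matrix = _matrix_from_array([[1.0], [2.0]])
    with pytest.raises(ValidationError):
        mv.cluster(matrix, axis="contrasts")


# ----------------------------------------------------------------------- PCA
def _molpct_table(arr, groups):
    names = [f"PC {i + 10}:0/18:1" for i in range(arr.shape[0])]
    return make_table(dict(zip(names, arr.tolist())), groups).normalize()


def test_two_group_limit_separates_on_pc1(rng):
    # two tight sample groups with distinct profiles
    g1 = np.array([50.0, 30.0, 20.0])
    g2 = np.array([20.0, 30.0, 50.0])
    arr = np.column_stack([g1, g1, g1, g2, g2, g2])
    arr = arr * (1 + rng.normal(0, 1e-4, size=arr.shape))
    table = _molpct_table(arr, [("A", "none")] * 3 + [("B", "none")] * 3)
    result = mv.pca_molpct(table, n_components=2)
    pc1 = result.scores["PC1"].to_numpy()
    assert (pc1[:3] > 0).all() != (pc1[3:] > 0).all()  # groups on opposite sides
    assert result.explained_variance_fraction[0] > 0.999


def test_rank_one_data_has_one_component():
    # profiles differ along a single direction -> variance beyond PC1 is 0
    base = np.array([10.0, 20.0, 30.0, 40.0])
    direction = np.array([1.0, -1.0, 2.0, -2.0])
    arr = np.column_stack([base + t * direction for t in (0.0, 1.0, 2.0, 3.0)])
    table = make_table(
        {f"PC {i + 10}:0/18:1": row for i, row in enumerate(arr.tolist())},
        [("A", "none")] * 4,
        unit="mol_pct",
    )
    result = mv.pca_molpct(table, n_components=3)
    assert result.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)
    assert result.explained_variance_fraction[1:] == pytest.approx(0.0, abs=1e-9)


def test_scores_match_eigendecomposition_oracle(rng):
    arr = rng.lognormal(1, 0.4, size=(20, 6))
    table = _molpct_table(arr, [("A", "none")] * 3 + [("B", "none")] * 3)
    result = mv.pca_molpct(table, n_components=3)
    X = table.values.to_numpy().T
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for k in range(3):
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        np.testing.assert_allclose(
            result.scores.iloc[:, k].to_numpy(), Xc @ v, atol=1e-8
        )
        np.testing.assert_allclose(
            result.explained_variance_fraction[k],
            evals[k] / evals.sum(),
            atol=1e-10,
        )


def test_explained_variance_nonincreasing_and_bounded(rng):
    arr = rng.lognormal(1, 0.6, size=(15, 8))
    table = _molpct_table(arr, [("A", "none")] * 4 + [("B", "none")] * 4)
    result = mv.pca_molpct(table, n_components=5)
    evr = result.explained_variance_fraction
    assert (np.diff(evr) <= 1e-12).all()
    assert evr.sum() <= 1 + 1e-9


def test_explained_variance_invariant_to_sample_order(rng):
    arr = rng.lognormal(1, 0.5, size=(12, 6))
    groups = [("A", "none")] * 3 + [("B", "none")] * 3
    table = _molpct_table(arr, groups)
    perm = [5, 2, 0, 4, 1, 3]
    shuffled = _molpct_table(arr[:, perm], [groups[i] for i in perm])
    np.testing.assert_allclose(
        mv.pca_molpct(table, 3).explained_variance_fraction,
        mv.pca_molpct(shuffled, 3).explained_variance_fraction,
        atol=1e-10,
    )


def test_lipids_with_missing_values_dropped(rng):
    arr = rng.lognormal(1, 0.5, size=(10, 5))
    table = _molpct_table(arr, [("A", "none")] * 3 + [("B", "none")] * 2)
    table.values.iloc[2, 1] = np.nan
    result = mv.pca_molpct(table, n_components=2)
    assert result.dropped_lipids == [table.values.index[2]]
    assert len(result.loadings) == 9


def test_too_many_components_rejected(rng):
    arr = rng.lognormal(1, 0.5, size=(10, 4))
    table = _molpct_table(arr, [("A", "none")] * 2 + [("B", "none")] * 2)
    with pytest.raises(ValidationError):
        mv.pca_molpct(table, n_components=4)  # min(4-1, 10) = 3
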