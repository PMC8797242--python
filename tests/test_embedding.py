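"""Latent-space analytics: rankings, active dimensions, walks, feature
correlation, PC regression and population shifts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statcell as sc
from statcell.embedding import EmbeddingTable


def test_embedding_rows_deterministic_and_duplicated(tiny_model, rng):
    x = rng.random((3, 2, 32, 32)).astype(np.float32)
    xx = np.concatenate([x, x[:1]])
    table = sc.embed_population(tiny_model, xx)
    assert table.values.shape == (4, 6)
    np.testing.assert_array_equal(table.values[0], table.values[3])
    again = sc.embed_population(tiny_model, xx)
    np.testing.assert_array_equal(table.values, again.values)


def test_embedding_metadata_length_checked():
    with pytest.raises(ValueError, match="metadata"):
        EmbeddingTable(values=np.zeros((3, 2)), metadata=pd.DataFrame({"a": [1]}))


def test_mad_ranking_matches_brute_force(rng):
    vals = rng.standard_normal((50, 8))
    table = EmbeddingTable(values=vals)
    order, mad = sc.rank_dimensions_by_mad(table)
    brute = sorted(range(8), key=lambda d: (-np.abs(vals[:, d]).mean(), d))
    assert list(order) == brute
    np.testing.assert_allclose(mad, np.abs(vals).mean(axis=0))


def test_mad_ranking_tie_break_by_index():
    vals = np.zeros((5, 4))
    vals[:, 2] = 3.0
    order, _ = sc.rank_dimensions_by_mad(EmbeddingTable(values=vals))
    assert order[0] == 2
    assert list(order[1:]) == [0, 1, 3]  # all-zero tie resolved by index


def test_dimension_kld_thresholds(tiny_model, rng):
    x = rng.random((10, 2, 32, 32)).astype(np.float32)
    mean_kld, active = sc.dimension_kld(tiny_model, x, threshold=0.6)
    assert mean_kld.shape == (6,)
    assert np.all(mean_kld >= 0)
    _, all_active = sc.dimension_kld(tiny_model, x, threshold=0.0)
    assert set(active) <= set(all_active)
    np.testing.assert_array_equal(all_active, np.flatnonzero(mean_kld > 0))


def test_latent_walk_steps_and_symmetry(tiny_model, rng):
    table = EmbeddingTable(values=rng.standard_normal((30, 6)))
    frames = sc.latent_walk(tiny_model, table, dim=2, n_steps=9)
    assert frames.shape[0] == 9
    middle = frames[4]
    np.testing.assert_allclose(
        middle, tiny_model.decode(np.zeros((1, 6), dtype=np.float32))[0],
        rtol=1e-5, atol=1e-6,
    )
    with pytest.raises(IndexError):
        sc.latent_walk(tiny_model, table, dim=6)


def test_latent_walk_along_dead_dimension_is_constant(tiny_model):
    """A dimension with zero population variation decodes to a constant
    sequence."""
    vals = np.zeros((10, 6))
    vals[:, 1] = 0.0  # dead dimension: SD = 0
    table = EmbeddingTable(values=vals)
    frames = sc.latent_walk(tiny_model, table, dim=1, n_steps=5)
    for k in range(1, 5):
        np.testing.assert_allclose(frames[k], frames[0], atol=1e-6)


def test_correlation_identity_and_missing(rng):
    vals = rng.standard_normal((40, 3))
    feats = pd.DataFrame(
        {"copy_of_z1": vals[:, 1], "noise": rng.standard_normal(40), "const": 1.0}
    )
    table = EmbeddingTable(values=vals)
    corr = sc.correlate_features(table, feats, method="spearman")
    assert corr.loc["z1", "copy_of_z1"] == pytest.approx(1.0)
    assert np.isnan(corr.loc["z0", "const"])
    expected = stats.spearmanr(vals[:, 0], feats["noise"]).statistic
    assert corr.loc["z0", "noise"] == pytest.approx(expected)


def test_correlation_null_within_permutation_band(rng):
    """Independent noise features correlate within the permutation null."""
    n = 60
    vals = rng.standard_normal((n, 6))
    feats = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
    corr = sc.correlate_features(EmbeddingTable(values=vals), feats).to_numpy()
    null = []
    for _ in range(200):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        null.append(abs(stats.spearmanr(x, y).statistic))
    band = np.quantile(null, 0.95)
    assert (np.abs(corr) <= band).mean() >= 0.80


def test_pc_regression_recovers_linear_features(rng):
    """Features constructed linearly from the latents are decodable."""
    z = rng.standard_normal((120, 6))
    w = rng.standard_normal((6, 4))
    feats = z @ w + 0.01 * rng.standard_normal((120, 4))
    res = sc.feature_pc_regression(
        EmbeddingTable(values=z), feats, active_set=np.arange(6), n_pcs=3, seed=0
    )
    assert res.r2_per_pc.min() > 0.5
    assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9
    assert res.loadings.shape == (3, 4)


def test_pc_regression_null_response(rng):
    z = rng.standard_normal((100, 5))
    feats = rng.standard_normal((100, 4))
    res = sc.feature_pc_regression(
        EmbeddingTable(values=z), feats, active_set=np.arange(5), n_pcs=3, seed=1
    )
    assert np.all(res.r2_per_pc < 0.5)


def test_pc_regression_empty_active_set_warns(rng):
    z = rng.standard_normal((50, 5))
    feats = rng.standard_normal((50, 4))
    with pytest.warns(UserWarning, match="active"):
        res = sc.feature_pc_regression(
            EmbeddingTable(values=z), feats, active_set=np.array([]), n_pcs=2
        )
    assert np.all(res.r2_per_pc == 0)


def test_population_shift_identical_populations_is_zero(rng):
    vals = rng.standard_normal((30, 4))
    t = EmbeddingTable(values=vals)
    res = sc.population_shift(t, EmbeddingTable(values=vals.copy()))
    np.testing.assert_allclose(res.shift, 0.0)
    np.testing.assert_allclose(res.direction, 0.0)


def test_population_shift_recovers_planted_offset(rng):
    control = rng.standard_normal((200, 5))
    delta = np.array([2.0, -1.0, 0.0, 0.5, 0.0])
    treated = control + delta + 0.05 * rng.standard_normal((200, 5))
    res = sc.population_shift(
        EmbeddingTable(values=treated), EmbeddingTable(values=control)
    )
    np.testing.assert_allclose(res.shift, delta, atol=0.25)
    assert res.control_projection.mean() == pytest.approx(0.0, abs=1e-9)
    assert res.treated_projection.mean() > res.control_projection.mean()
    qs = res.cells_at_quantiles([0.0, 0.5, 1.0])
    assert len(qs) == 3


def test_population_shift_rejects_empty_or_mismatched(rng):
    t = EmbeddingTable(values=rng.standard_normal((5, 3)))
    with pytest.raises(ValueError, match="dimension"):
        sc.population_shift(t, EmbeddingTable(values=rng.standard_normal((5, 4))))
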