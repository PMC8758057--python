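"""SOM training, diagnostics, metaclustering and bin purity labels."""

import numpy as np
import pandas as pd
import pytest

from bladderpheno import (
    SOMConfig,
    SOMModel,
    SelfOrganizingMap,
    classify_bins,
    convergence_index,
    metacluster_nodes,
    neighbor_distance_map,
    train_som,
)
from bladderpheno.errors import ConfigurationError, ValidationError
from bladderpheno.som import _grid_coords


def _measure_cloud(n_per=30, noise=0.05, seed=0):
    """Synthetic unit-scaled measure vectors: controls + three pure groups."""
    rng = np.random.default_rng(seed)
    protos = {
        "CONTROL": (0.05, 0.05, 0.05),
        "BPS": (0.85, 0.1, 0.1),
        "NUPP": (0.1, 0.85, 0.1),
        "MFP": (0.1, 0.1, 0.85),
    }
    rows, labels = [], []
    for name, proto in protos.items():
        pts = np.clip(rng.normal(proto, noise, size=(n_per, 3)), 0, 1)
        rows.append(pts)
        labels += [name] * n_per
    df = pd.DataFrame(np.vstack(rows),
                      columns=["bps_measure", "nupp_measure", "mfp_measure"])
    return df, labels


def test_default_grid_has_24_nodes():
    cfg = SOMConfig()
    assert (cfg.rows, cfg.cols, cfg.n_nodes) == (4, 6, 24)
    with pytest.raises(ConfigurationError):
        SOMConfig(rows=1, cols=1)
    with pytest.raises(ConfigurationError):
        SOMConfig(alpha0=0.0)


def test_single_unique_point_contracts_all_codebooks():
    X = np.tile([0.3, 0.7, 0.1], (10, 1))
    model = train_som(X, SOMConfig(iterations=5000, seed=0))
    assert np.all(np.abs(model.codebook - X[0]) < 1e-6)


def test_training_deterministic_given_seed():
    df, _ = _measure_cloud(seed=1)
    a = train_som(df, SOMConfig(iterations=3000, seed=5))
    b = train_som(df, SOMConfig(iterations=3000, seed=5))
    np.testing.assert_array_equal(a.codebook, b.codebook)


def test_bmu_is_exact_nearest_codebook():
    df, _ = _measure_cloud(seed=2)
    model = train_som(df, SOMConfig(iterations=3000, seed=2))
    X = df.to_numpy()
    bmu = model.bmu(X)
    for i in range(len(X)):
        d = ((model.codebook - X[i]) ** 2).sum(axis=1)
        assert bmu[i] == d.argmin()


def test_quantization_error_improves_with_training():
    """Trained QE <= QE at (data-row) initialisation, averaged over 10 seeds."""
    df, _ = _measure_cloud(seed=3)
    X = df.to_numpy()
    deltas = []
    for seed in range(10):
        cfg = SOMConfig(iterations=4000, seed=seed)
        trained = train_som(df, cfg)
        rng = np.random.default_rng(seed)  # replicate the documented init
        lo, hi = X.min(axis=0), X.max(axis=0)
        W0 = lo + rng.random((cfg.n_nodes, X.shape[1])) * (hi - lo)
        init = SOMModel(codebook=W0, grid=_grid_coords(cfg.rows, cfg.cols), config=cfg)
        deltas.append(init.quantization_error(X) - trained.quantization_error(X))
    assert np.mean(deltas) >= 0


def test_convergence_index_bounds_and_training_gain():
    df, _ = _measure_cloud(seed=4)
    trained = train_som(df, SOMConfig(iterations=20_000, seed=1))
    ci_trained = convergence_index(trained, df)
    rng = np.random.default_rng(99)
    untrained = SOMModel(codebook=rng.uniform(-3, 3, size=(24, 3)),
                         grid=_grid_coords(4, 6), config=SOMConfig(seed=0))
    ci_untrained = convergence_index(untrained, df)
    assert 0 <= ci_untrained <= 1 and 0 <= ci_trained <= 1
    assert ci_trained > ci_untrained


def test_metacluster_bounds_and_blob_separation():
    df, _ = _measure_cloud(seed=5)
    model = train_som(df, SOMConfig(iterations=10_000, seed=3))
    m = model.config.n_nodes
    assert len(set(metacluster_nodes(model, m).tolist())) == m
    assert set(metacluster_nodes(model, 1).tolist()) == {1}
    with pytest.raises(ValidationError):
        metacluster_nodes(model, 0)
    # two well-separated blobs: metaclustering at 2 separates their BMU nodes
    rng = np.random.default_rng(6)
    X2 = np.vstack([rng.normal(0, 0.05, (40, 3)), rng.normal(1, 0.05, (40, 3))])
    model2 = train_som(X2, SOMConfig(iterations=10_000, seed=4))
    meta = metacluster_nodes(model2, 2)
    bmu = model2.bmu(X2)
    groups_a = set(meta[bmu[:40]].tolist())
    groups_b = set(meta[bmu[40:]].tolist())
    assert groups_a.isdisjoint(groups_b)


def test_neighbor_distance_map_hand_oracle():
    # hand-set 2x2 codebook in 1-D feature space
    cfg = SOMConfig(rows=2, cols=2, seed=0)
    W = np.array([[0.0], [1.0], [2.0], [5.0]])  # nodes (0,0),(0,1),(1,0),(1,1)
    model = SOMModel(codebook=W, grid=_grid_coords(2, 2), config=cfg)
    nd = neighbor_distance_map(model)
    assert nd[0, 0] == pytest.approx((1 + 2) / 2)     # neighbors 1.0 and 2.0
    assert nd[0, 1] == pytest.approx((1 + 4) / 2)
    assert nd[1, 0] == pytest.approx((2 + 3) / 2)
    assert nd[1, 1] == pytest.approx((4 + 3) / 2)
    same = SOMModel(codebook=np.ones((4, 1)), grid=_grid_coords(2, 2), config=cfg)
    assert np.all(neighbor_distance_map(same) == 0)


def test_classify_bins_labels_and_validation():
    df, labels = _measure_cloud(n_per=40, noise=0.04, seed=7)
    model = train_som(df, SOMConfig(iterations=20_000, seed=8))
    bins = classify_bins(model, df)
    assert bins.table["count"].sum() == len(df)
    present = set(bins.table["label"])
    assert "control" in present
    assert any(lab.startswith("pure-") for lab in present)
    # a cohort of pure phenotypes + controls lands mostly in pure/control bins
    assert bins.pure_or_control_fraction() > 0.8
    bad = df.copy()
    bad.iloc[0, 0] = 1.5
    with pytest.raises(ValidationError):
        classify_bins(model, bad)


def test_bin_label_rules_on_forced_prototypes():
    """Bins built directly at prototype codebooks get the expected labels."""
    cfg = SOMConfig(rows=2, cols=2, seed=0)
    W = np.array([
        [0.0, 0.0, 0.0],    # control
        [0.8, 0.1, 0.1],    # pure-BPS (dominance forced)
        [0.8, 0.8, 0.8],    # global
        [0.5, 0.45, 0.1],   # mixed
    ])
    model = SOMModel(codebook=W, grid=_grid_coords(2, 2), config=cfg,
                     feature_names=["bps_measure", "nupp_measure", "mfp_measure"])
    measures = pd.DataFrame(np.repeat(W, 5, axis=0),
                            columns=["bps_measure", "nupp_measure", "mfp_measure"])
    bins = classify_bins(model, measures)
    assert list(bins.table["label"]) == ["control", "pure-BPS", "global", "mixed"]


def test_purity_increases_as_noise_shrinks():
    fracs = []
    for noise in (0.03, 0.22):
        df, _ = _measure_cloud(n_per=40, noise=noise, seed=9)
        res = SelfOrganizingMap(df, SOMConfig(iterations=15_000, seed=10)).fit()
        fracs.append(res.classify_bins().pure_or_control_fraction())
    assert fracs[0] > fracs[1]


def test_results_surface(default_cohort):
    """Model/Results wrapper: fit on the cohort's scaled measures."""
    from bladderpheno import score_dataframe
    from bladderpheno.pipeline import scale_measures
    cohort, _ = default_cohort
    scored = score_dataframe(cohort, with_measures=True)
    measures = scale_measures(scored.set_index("subject_id")[
        ["bps_measure", "nupp_measure", "mfp_measure"]])
    res = SelfOrganizingMap(measures, SOMConfig(iterations=30_000, seed=11)).fit()
    assert res.codebook.shape == (24, 3)
    assert 0 <= res.convergence_index() <= 1
    assert res.neighbor_distance_map().shape == (4, 6)
    assert "Self-organizing map" in res.summary()
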