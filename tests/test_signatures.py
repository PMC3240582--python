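"""TSS signature matrices, hierarchical clustering, and the expression-
predicting feed-forward network with Garson importance."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import flychip as fc
from conftest import constant_track, track_from_flat


MARKS = ("H3K4me3", "H3K9me3", "H3K9ac", "H3K27me3", "HP1a", "polII")


def _gene(gid, chrom, strand, start, end):
    return fc.GeneModel(gid, chrom, strand,
                        (fc.Transcript(f"{gid}.t1", start, end, ((start, end),)),))


@pytest.fixture(scope="module")
def sig_setup():
    rng = np.random.default_rng(0)
    genes = [_gene(f"g{i}", "c", "+", 20_000 + 10_000 * i, 24_000 + 10_000 * i)
             for i in range(40)]
    layout = {"c": 500_000}
    tracks = {}
    for m in MARKS:
        scores = rng.random(fc.n_bins(layout["c"]))
        tracks[m] = track_from_flat(scores, chrom="c")
    return genes, layout, tracks


def test_windows_mode_yields_ten_named_columns(sig_setup):
    genes, _, tracks = sig_setup
    sm = fc.build_signature_matrix(tracks, genes, mode="windows")
    assert list(sm.data.columns) == list(fc.DEFAULT_TSS_WINDOWS)
    assert sm.data.shape == (40, 10)
    # z-standardized
    assert np.allclose(sm.data.mean(), 0, atol=1e-9)
    assert np.allclose(sm.data.std(ddof=0), 1, atol=1e-9)


def test_positions_mode_yields_114_columns(sig_setup):
    genes, _, tracks = sig_setup
    sm = fc.build_signature_matrix(tracks, genes, mode="positions")
    assert sm.data.shape == (40, 6 * 19)


def test_identical_neighborhoods_give_identical_rows(sig_setup):
    genes, layout, _ = sig_setup
    tracks = {m: constant_track(layout, 2.0) for m in MARKS}
    # constant tracks are zero-variance features -> all dropped with warning
    with pytest.warns(UserWarning):
        sm = fc.build_signature_matrix(tracks, genes, mode="windows")
    assert sm.data.shape[1] == 0
    # periodic track + equally spaced genes: every gene sees the same window
    period = 10_000 // 50
    scores = np.tile(np.arange(period, dtype=float), 1_000)[:fc.n_bins(500_000)]
    tracks2 = {m: track_from_flat(scores, chrom="c") for m in MARKS}
    sm2 = fc.build_signature_matrix(tracks2, genes[:8], mode="windows")
    assert np.allclose(sm2.data.to_numpy() - sm2.data.to_numpy()[0], 0, atol=1e-9)


def _archetype_matrix(n=60, seed=1):
    rng = np.random.default_rng(seed)
    a = np.array([3.0, 0.0, 2.0, -1.0, 0.0, 1.0, 0.0, 0.0, 2.0, 1.0])
    b = np.array([-2.0, 1.0, -3.0, 2.0, 1.0, -1.0, 2.0, 1.0, -2.0, 0.0])
    rows, truth = [], []
    for i in range(n):
        arch = a if i % 2 == 0 else b
        rows.append(arch + rng.normal(0, 0.1, 10))
        truth.append(i % 2)
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(n)],
                      columns=list(fc.DEFAULT_TSS_WINDOWS))
    return fc.SignatureMatrix(df, df.mean(), df.std(ddof=0), "windows"), truth


def test_two_planted_archetypes_separate_perfectly():
    sm, truth = _archetype_matrix()
    res = fc.cluster_genes(sm, k=2)
    assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0
    assert res.summary.loc[1, "n_genes"] + res.summary.loc[2, "n_genes"] == 60


def test_k1_and_duplicated_data_stability():
    sm, _ = _archetype_matrix(n=20)
    res1 = fc.cluster_genes(sm, k=1)
    assert res1.labels.nunique() == 1
    dup = pd.concat([sm.data, sm.data.set_axis([f"d{i}" for i in range(20)])])
    sm_dup = fc.SignatureMatrix(dup, dup.mean(), dup.std(ddof=0), "windows")
    res2 = fc.cluster_genes(sm_dup, k=2)
    # co-duplicates always co-cluster
    for i in range(20):
        assert res2.labels[f"g{i}"] == res2.labels[f"d{i}"]
    with pytest.raises(ValueError):
        fc.cluster_genes(sm, k=21)


def test_clustering_invariant_to_feature_order():
    sm, _ = _archetype_matrix(n=30)
    perm = list(sm.data.columns[::-1])
    sm_perm = fc.SignatureMatrix(sm.data[perm], sm.mean[perm], sm.std[perm],
                                 "windows")
    r1 = fc.cluster_genes(sm, k=3)
    r2 = fc.cluster_genes(sm_perm, k=3)
    assert adjusted_rand_score(r1.labels, r2.labels) == 1.0


def test_newick_export_covers_all_genes():
    sm, _ = _archetype_matrix(n=12)
    res = fc.cluster_genes(sm, k=2)
    nwk = res.to_newick()
    assert nwk.endswith(";")
    assert all(f"g{i}" in nwk for i in range(12))


def _linear_problem(n=240, n_features=10, driver=0, noise=0.0, seed=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, n_features))
    y = 5.0 + 2.5 * X[:, driver] + rng.normal(0, noise, n)
    y = np.clip(y, 0, 10)
    df = pd.DataFrame(X, index=[f"g{i}" for i in range(n)],
                      columns=[f"f{j}" for j in range(n_features)])
    sm = fc.SignatureMatrix(df, df.mean(), df.std(ddof=0), "windows")
    return sm, pd.Series(y, index=df.index)


def test_noiseless_linear_target_is_learnable():
    sm, y = _linear_problem()
    res = fc.train_ann(sm, y, fc.ANNConfig(runs=3, seed=7))
    assert res.mean_r > 0.99
    assert res.mean_accuracy > 0.95


def test_permuted_labels_give_chance_performance():
    sm, y = _linear_problem()
    rng = np.random.default_rng(3)
    y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    res = fc.train_ann(sm, y_perm, fc.ANNConfig(runs=3, seed=8))
    assert abs(res.mean_r) < 0.3
    # accuracy no better than predicting the mean
    baseline = 1.0 - np.mean(np.abs(y_perm - y_perm.mean())) / 10.0
    assert res.mean_accuracy < baseline + 0.05


def test_same_seed_reproduces_identical_results():
    sm, y = _linear_problem()
    cfg = fc.ANNConfig(runs=2, seed=11)
    r1 = fc.train_ann(sm, y, cfg)
    r2 = fc.train_ann(sm, y, cfg)
    assert r1.accuracies == r2.accuracies
    assert np.array_equal(r1.run_importances, r2.run_importances)


def test_driver_feature_ranks_first_in_at_least_9_of_10_runs():
    sm, y = _linear_problem(driver=4, noise=0.2)
    res = fc.train_ann(sm, y, fc.ANNConfig(runs=10, seed=9))
    wins = sum(int(np.argmax(imp) == 4) for imp in res.run_importances)
    assert wins >= 9
    assert res.importance["mean"].idxmax() == "f4"


def test_garson_importance_normalization():
    # single-input network: importance is exactly [1.0]
    coefs = [np.array([[0.7, -0.2]]), np.array([[0.5], [0.3]])]
    imp = fc.garson_importance(coefs)
    assert imp.shape == (1,) and imp[0] == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    coefs = [rng.normal(size=(10, 2)), rng.normal(size=(2, 3)), rng.normal(size=(3, 1))]
    imp = fc.garson_importance(coefs)
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)
    assert (imp >= 0).all()


def test_h3k9ac_downstream_drives_importance_when_it_drives_expression():
    """When expression is generated from the planted H3K9ac gene-body rate,
    the H3K9ac downstream-of-TSS window outranks the median feature."""
    world = fc.build_world(fc.WorldConfig(
        chrom_lengths={"chr1": 600_000, "chr2": 600_000}, n_genes=80,
        silent_fraction=0.25, n_transposon_families=0), seed=13)
    matrix = fc.build_score_matrix(fc.FragmentLengthDist.triangular())
    tracks = {}
    for i, m in enumerate(MARKS):
        model = (fc.MarkModel(m, 0.5, body_rate=400.0) if m == "H3K9ac"
                 else fc.MarkModel(m, 1.0))
        sim = fc.simulate_mark_tags(world, model, 80_000, seed=20 + i,
                                    emit_reads=False)
        tracks[m] = fc.score_table(fc.table_from_origins(sim.origins), matrix,
                                   "U", world.layout, mark=m)
    sm = fc.build_signature_matrix(tracks, world.genes, mode="windows")
    expr = fc.scale_expression(pd.Series(world.expression))
    res = fc.train_ann(sm, expr, fc.ANNConfig(runs=10, seed=14))
    imp = res.importance["mean"]
    assert imp["H3K9ac_D"] > imp.median()


def test_importance_sd_uses_independent_runs():
    sm, y = _linear_problem()
    res = fc.train_ann(sm, y, fc.ANNConfig(runs=4, seed=10))
    assert res.run_importances.shape == (4, 10)
    assert (res.importance["sd"] >= 0).all()
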