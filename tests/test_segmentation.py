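"""Correlation distance, bisecting k-means, cluster-mask overlap scoring."""

import numpy as np
import pytest

import lipidmsi as lm
import lipidmsi.preprocess as pp
from lipidmsi.segmentation import (
    ClusterMap,
    bisecting_kmeans,
    correlation_distance,
    score_overlap,
    select_adipose_cluster,
)


def test_correlation_distance_examples():
    u = np.array([1.0, 2.0, 3.0, 4.0])
    assert correlation_distance(u, u) == pytest.approx(0.0)
    assert correlation_distance(u, -u + 10) == pytest.approx(2.0)
    assert correlation_distance([1, 2, 3, 4], [1, 3, 2, 4]) == \
        pytest.approx(0.2)  # hand-computed Pearson r = 0.8


def test_correlation_distance_zero_variance():
    z = np.zeros(4)
    assert correlation_distance(z, z) == 0.0
    assert correlation_distance(z, np.ones(4) * 3) == 1.0
    assert correlation_distance(z, np.array([1, 2, 3, 4])) == 1.0
    with pytest.raises(ValueError):
        correlation_distance([1, 2], [1, 2, 3])


def _two_signature_table(n=400, seed=0):
    """Half the pixels follow one spectral signature, half another."""
    rng = np.random.default_rng(seed)
    sig_a = np.array([10.0, 1.0, 1.0, 5.0, 1.0])
    sig_b = np.array([1.0, 8.0, 4.0, 1.0, 6.0])
    X = np.empty((n, 5))
    X[:n // 2] = sig_a * rng.lognormal(0, 0.1, (n // 2, 5))
    X[n // 2:] = sig_b * rng.lognormal(0, 0.1, (n - n // 2, 5))
    table = pp.FeatureTable("r1", "negative", list("abcde"),
                            np.linspace(200, 600, 5), X.T,
                            pixel_tic=np.full(n, 100.0))
    labels = np.array(["muscle"] * (n // 2) + ["adipose"] * (n - n // 2))
    mask = lm.TissueMask(width=n, height=1, labels=labels.reshape(1, n))
    return table, mask


def test_two_signatures_perfectly_recovered():
    table, mask = _two_signature_table()
    cm = bisecting_kmeans(table, n_leaves=2, seed=1)
    report = score_overlap(cm, mask)
    assert report.ari == pytest.approx(1.0)


def test_identical_pixels_single_leaf():
    X = np.ones((4, 10))
    table = pp.FeatureTable("r", "negative", list("abcd"),
                            np.linspace(200, 500, 4), X,
                            pixel_tic=np.full(10, 50.0))
    cm = bisecting_kmeans(table, n_leaves=4, seed=1)
    assert cm.n_leaves == 1


def test_bisecting_deterministic(preprocessed_tables):
    a = bisecting_kmeans(preprocessed_tables[0], n_leaves=6, seed=3)
    b = bisecting_kmeans(preprocessed_tables[0], n_leaves=6, seed=3)
    assert np.array_equal(a.labels, b.labels)


def test_dispersion_monotone_under_splits(preprocessed_tables):
    cm = bisecting_kmeans(preprocessed_tables[0], n_leaves=8, seed=1)
    for node in cm.tree:
        if node.children is not None:
            for child in node.children:
                assert cm.tree[child].dispersion <= node.dispersion + 1e-9


def test_default_phantom_adipose_dice(preprocessed_tables, default_phantom):
    _, _, truth = default_phantom
    cm = bisecting_kmeans(preprocessed_tables[0], n_leaves=8, seed=1)
    report = score_overlap(cm, truth.mask)
    best_dice = max(d for (lab, d, _) in report.per_leaf.values()
                    if lab == "adipose")
    assert best_dice >= 0.9


def test_ari_increases_with_signature_separation(default_phantom):
    """Stronger tissue signatures give better mask recovery."""
    import dataclasses
    aris = []
    for boost in (1.0, 3.0, 8.0):
        panel = []
        for p in lm.default_panel():
            w = {t: 1 + (v - 1) * boost / 8.0
                 for t, v in p.tissue_weights.items()}
            fold = 1 + (p.adipose_fold - 1) * boost / 8.0
            panel.append(dataclasses.replace(
                p, tissue_weights=w, adipose_fold=fold))
        spec = lm.PhantomSpec(seed=1, panel=panel)
        datasets, truth = lm.simulate_dataset(spec)
        table = pp.pick_features(pp.tic_normalize(datasets[0]))
        cm = bisecting_kmeans(table, n_leaves=6, seed=1)
        aris.append(score_overlap(cm, truth.mask).ari)
    assert aris[0] <= aris[1] + 0.02
    assert aris[1] <= aris[2] + 0.02


def test_score_overlap_trivial_and_null_cases(default_phantom):
    _, _, truth = default_phantom
    flat = truth.mask.flat()
    tissue_labels = [l for l in np.unique(flat) if l != "background"]
    lab_to_int = {l: i for i, l in enumerate(tissue_labels)}
    labels = np.array([lab_to_int.get(l, -1) for l in flat])
    cm = ClusterMap(labels=labels, leaf_ids=list(range(len(tissue_labels))))
    report = score_overlap(cm, truth.mask)
    assert report.ari == pytest.approx(1.0)
    assert all(d == pytest.approx(1.0) for (_, d, _) in
               report.per_leaf.values())
    # random permutation of labels over tissue pixels: ARI near zero
    rng = np.random.default_rng(0)
    perm = labels.copy()
    tissue = labels >= 0
    perm[tissue] = rng.permutation(labels[tissue])
    report2 = score_overlap(ClusterMap(
        labels=perm, leaf_ids=list(range(len(tissue_labels)))), truth.mask)
    assert abs(report2.ari) < 0.05


def test_one_cluster_vs_two_equal_halves_dice():
    labels = np.array([["muscle"] * 10 + ["adipose"] * 10])
    mask = lm.TissueMask(width=20, height=1, labels=labels)
    cm = ClusterMap(labels=np.zeros(20, dtype=int), leaf_ids=[0])
    report = score_overlap(cm, mask)
    _, dice, _ = report.per_leaf[0]
    assert dice == pytest.approx(2 / 3)  # 2n n / (2n + n)


def test_select_adipose_cluster(preprocessed_tables, default_phantom):
    _, _, truth = default_phantom
    cm = bisecting_kmeans(preprocessed_tables[0], n_leaves=8, seed=1)
    leaf, nonadipose = select_adipose_cluster(cm, truth.mask)
    flat = truth.mask.flat()
    # merged non-adipose set spans several tissues and excludes background
    assert len({l for l in flat[nonadipose]}) >= 2
    assert "background" not in set(flat[nonadipose])
    leaf_px = cm.leaf_pixels(leaf)
    adipose_px = set(np.nonzero(flat == "adipose")[0])
    overlap = len(adipose_px & set(leaf_px)) / len(adipose_px)
    assert overlap >= 0.9
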