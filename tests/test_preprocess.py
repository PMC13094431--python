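"""TIC normalization, baseline correction, picking, alignment, deisotoping."""

import numpy as np
import pytest

import lipidmsi as lm
import lipidmsi.preprocess as pp
from lipidmsi.io import MSIDataset


def _dataset(rows, mz=None, polarity="negative"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[1]
    mz = np.asarray(mz, dtype=float) if mz is not None else \
        np.linspace(200, 200 + 10 * (n - 1), n)
    return MSIDataset("r1", polarity, rows.shape[0], 1, mz, rows)


def test_tic_normalize_sums_to_one():
    ds = _dataset([[2, 3, 5]])
    out = pp.tic_normalize(ds)
    assert np.allclose(out.intensities, [[0.2, 0.3, 0.5]])


def test_tic_normalize_zero_pixel_flagged():
    ds = _dataset([[2, 3, 5], [0, 0, 0]])
    out = pp.tic_normalize(ds)
    assert np.all(out.intensities[1] == 0)
    assert list(out.metadata["zero_tic_pixels"]) == [1]


def test_tic_normalize_idempotent_and_whole_phantom(default_phantom):
    _, datasets, _ = default_phantom
    once = pp.tic_normalize(datasets[0])
    tic = once.tic()
    nz = tic > 0
    assert np.allclose(tic[nz], 1.0, atol=1e-6)
    twice = pp.tic_normalize(once)
    assert np.allclose(twice.intensities, once.intensities, atol=1e-7)
    # raw TIC preserved for background detection
    assert np.allclose(once.metadata["raw_tic"], datasets[0].tic())


def test_baseline_flat_spectrum_to_zero():
    ds = _dataset([[4.0] * 8])
    out = pp.baseline_correct(ds, window_da=5.0)
    assert np.allclose(out.intensities, 0.0)


def test_baseline_preserves_peak_height():
    base = np.full(9, 2.0)
    base[4] += 10.0  # peak of height 10 on offset 2
    ds = _dataset([base], mz=np.linspace(300, 308, 9))
    out = pp.baseline_correct(ds, window_da=2.5)
    assert out.intensities[0, 4] == pytest.approx(10.0, rel=0.01)


def test_baseline_idempotent_on_baseline_free():
    spec = np.zeros(9)
    spec[3] = 7.0
    ds = _dataset([spec], mz=np.linspace(300, 308, 9))
    out = pp.baseline_correct(ds, window_da=2.5)
    assert np.allclose(out.intensities, ds.intensities, atol=1e-6)


def test_baseline_window_wider_than_axis_global_min():
    ds = _dataset([[3, 4, 5]])
    out = pp.baseline_correct(ds, window_da=1e6)
    assert np.allclose(out.intensities, [[0, 1, 2]])


def test_pick_features_recovers_planted_panel(default_phantom):
    _, datasets, truth = default_phantom
    norm = pp.tic_normalize(datasets[0])
    table = pp.pick_features(norm, top_n=200)
    # 50 planted lipids + 50 isotope satellites
    assert table.n_features == 100
    assert np.all(np.diff(table.mz) > 0)
    for mz in truth.feature_mz:
        assert np.min(np.abs(table.mz - mz)) < 1e-6


def test_pick_features_top1_is_strongest_planted(default_phantom):
    _, datasets, truth = default_phantom
    norm = pp.tic_normalize(datasets[0])
    table = pp.pick_features(norm, top_n=1)
    assert table.n_features == 1
    assert np.min(np.abs(truth.feature_mz - table.mz[0])) < 1e-6


def test_pick_features_flat_spectra_empty():
    ds = _dataset([[0, 0, 0], [0, 0, 0]])
    assert pp.pick_features(ds).n_features == 0


def test_align_features_groups_and_splits():
    t1 = pp.FeatureTable("r1", "negative", ["a"], [295.228], [[1.0, 1.0]])
    t2 = pp.FeatureTable("r2", "negative", ["b"], [295.232], [[1.0, 1.0]])
    aligned = pp.align_features([t1, t2], tol_da=0.02)
    assert len(aligned.features) == 1
    f = aligned.features[0]
    assert f.avg_mz == pytest.approx(295.230)
    assert f.n_replicates == 2
    t3 = pp.FeatureTable("r2", "negative", ["b"], [295.30], [[1.0, 1.0]])
    aligned2 = pp.align_features([t1, t3], tol_da=0.02)
    assert len(aligned2.features) == 2


def test_align_mixed_polarity_rejected():
    t1 = pp.FeatureTable("r1", "negative", ["a"], [295.0], [[1.0, 1.0]])
    t2 = pp.FeatureTable("r2", "positive", ["b"], [295.0], [[1.0, 1.0]])
    with pytest.raises(ValueError, match="polarit"):
        pp.align_features([t1, t2])


def test_align_order_independent(preprocessed_tables):
    fwd = pp.align_features(preprocessed_tables)
    rev = pp.align_features(list(reversed(preprocessed_tables)))
    assert [(f.avg_mz, sorted(f.members)) for f in fwd.features] == \
        [(f.avg_mz, sorted(f.members)) for f in rev.features]


def test_align_phantom_one_consensus_per_lipid(preprocessed_tables,
                                               default_phantom):
    _, _, truth = default_phantom
    aligned = pp.align_features(preprocessed_tables)
    full = aligned.covered_by_all()
    assert len(full) == len(aligned.features)
    for mz in truth.feature_mz:
        close = [f for f in full if abs(f.avg_mz - mz) < 0.01]
        assert len(close) == 1


def test_deisotope_rules():
    t = pp.FeatureTable("r", "negative", ["a", "b"],
                        [255.2330, 256.2364],
                        [[100.0, 100.0], [17.3, 17.3]])
    out = pp.deisotope(t)
    assert out.feature_ids == ["a"]
    assert out.removed_isotopologues == [("b", "a")]
    # wrong spacing: both kept
    t2 = pp.FeatureTable("r", "negative", ["a", "b"],
                         [255.2330, 255.7330],
                         [[100.0, 100.0], [17.3, 17.3]])
    assert pp.deisotope(t2).n_features == 2
    # satellite more intense than parent: not a satellite
    t3 = pp.FeatureTable("r", "negative", ["a", "b"],
                         [255.2330, 256.2364],
                         [[10.0, 10.0], [100.0, 100.0]])
    assert pp.deisotope(t3).n_features == 2


def test_deisotope_phantom_removes_exactly_satellites(default_phantom):
    _, datasets, truth = default_phantom
    for ds in datasets:
        table = pp.pick_features(pp.tic_normalize(ds))
        out = pp.deisotope(table)
        assert len(out.removed_isotopologues) == len(truth.satellite_mz)
        # the strongest feature survives
        top = table.feature_ids[int(np.argmax(table.mean_intensity()))]
        assert top in out.feature_ids


def test_interday_rescale_identity_and_half():
    t = pp.FeatureTable("a", "negative", ["x"], [300.0], [[2.0, 2.0, 2.0]])
    roi = np.array([0, 1, 2])
    scale, out = pp.interday_rescale(t, roi, t, roi)
    assert scale == pytest.approx(1.0)
    half = pp.FeatureTable("b", "negative", ["x"], [300.0], [[1.0, 1.0, 1.0]])
    scale, out = pp.interday_rescale(t, roi, half, roi)
    assert scale == pytest.approx(2.0)
    assert np.allclose(out.matrix, t.matrix)
    zero = pp.FeatureTable("c", "negative", ["x"], [300.0], [[0.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="zero"):
        pp.interday_rescale(t, roi, zero, roi)


def test_interday_rescale_recovers_planted_replicate_scales(default_phantom):
    _, datasets, truth = default_phantom
    roi = truth.mask.tissue_pixels()
    ref = pp.pick_features(datasets[0])
    for r in (1, 2):
        tgt = pp.pick_features(datasets[r])
        scale, _ = pp.interday_rescale(ref, roi, tgt, roi)
        assert scale == pytest.approx(1.0 / truth.replicate_scales[r],
                                      rel=0.02)
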