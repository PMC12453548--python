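"""Mask construction, endpoint extraction, gating, classification and
aggregation on image input."""

import dataclasses

import numpy as np
import pytest

from ifcdose.imaging import (
    CellFeatures,
    GateConfig,
    HealthyCellClassifier,
    aggregate_sample,
    classify_healthy,
    count_spots,
    extract_features,
    gate_events,
    gh2ax_positive_threshold,
    nucleus_mask,
    object_mask,
    spot_area,
    spot_mask,
    Mask,
)
from ifcdose.synthdata import CellImage, simulate_cell_image, simulate_contaminant_image


def disc_image(size=64, radius=20, fluor=None):
    rr, cc = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    disc = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    bf = np.where(disc, 1.0, 0.05)
    fl = np.zeros((size, size)) if fluor is None else fluor
    return CellImage(brightfield=bf, fluorescence=fl, truth=[], label="lymphocyte"), disc, (c, c)


def gaussian_focus(size, center, sigma=1.5, amplitude=1.0):
    rr, cc = np.mgrid[0:size, 0:size]
    return amplitude * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def test_disc_erosion_matches_analytic_annulus():
    img, disc, _ = disc_image(radius=20)
    nuc = nucleus_mask(img, erosion_radius=4)
    expected_ratio = (16 / 20) ** 2
    ratio = nuc.area / disc.sum()
    assert ratio == pytest.approx(expected_ratio, abs=0.06)


def test_blank_image_gives_flagged_empty_mask():
    blank = CellImage(brightfield=np.zeros((32, 32)), fluorescence=np.zeros((32, 32)), truth=[])
    nuc = nucleus_mask(blank)
    assert nuc.empty_flag and nuc.area == 0


def test_erosion_strictly_contained_in_object(rng, small_image_params):
    for dose in (0.0, 4.0, 10.0):
        img = simulate_cell_image(dose, small_image_params, rng)
        obj = object_mask(img)
        nuc = nucleus_mask(img)
        assert np.all(~nuc.data | obj.data)  # nucleus subset of object
        assert nuc.area < obj.area


def test_mask_nesting_everywhere(rng, small_image_params):
    for dose in (0.5, 2.0, 6.0, 10.0):
        img = simulate_cell_image(dose, small_image_params, rng)
        obj = object_mask(img)
        nuc = nucleus_mask(img)
        spots = spot_mask(img, nuc)
        assert np.all(~spots.data | nuc.data)
        assert np.all(~nuc.data | obj.data)


def test_uniform_fluorescence_has_no_spots():
    img, disc, _ = disc_image(fluor=np.full((64, 64), 3.7))
    nuc = nucleus_mask(img)
    spots = spot_mask(img, nuc)
    assert spots.area == 0
    assert count_spots(spots) == 0


def test_single_focus_detected_at_true_center():
    size = 64
    img, disc, c = disc_image(size)
    img.fluorescence = gaussian_focus(size, c) + np.where(disc, 0.01, 0.0)
    nuc = nucleus_mask(img)
    spots = spot_mask(img, nuc)
    assert count_spots(spots) == 1
    assert spots.data[int(c[0]), int(c[1])]


@pytest.mark.parametrize("separation, expected", [(2.0, 1), (3.0, 1), (12.0, 2)])
def test_two_foci_merge_below_separation_threshold(separation, expected):
    # co-located foci in the 2-D projection are counted as a single spot
    size = 64
    img, disc, c = disc_image(size)
    a = (c[0], c[1] - separation / 2)
    b = (c[0], c[1] + separation / 2)
    img.fluorescence = gaussian_focus(size, a) + gaussian_focus(size, b) + np.where(disc, 0.01, 0.0)
    spots = spot_mask(img, nucleus_mask(img))
    assert count_spots(spots) == expected


def test_detected_never_exceeds_true_on_noiseless_cells(rng):
    from ifcdose.synthdata import SimulationParams

    p = SimulationParams(cell_noise_sd=0.0)
    for dose in (1.0, 4.0, 10.0):
        for _ in range(10):
            img = simulate_cell_image(dose, p, rng)
            f = extract_features(img)
            assert f.spot_count <= img.true_focus_count


def _bruteforce_components(mask):
    # flood-fill oracle, 8-connectivity
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    coords = list(zip(*np.nonzero(mask)))
    for start in coords:
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return n


def test_count_spots_matches_floodfill_oracle(rng):
    for _ in range(100):
        m = rng.random((16, 16)) < 0.25
        assert count_spots(Mask(m, "spot")) == _bruteforce_components(m)


def test_spot_area_totals():
    m = np.zeros((16, 16), dtype=bool)
    m[1:2, 1:6] = True  # 5 px
    m[10:11, 3:10] = True  # 7 px
    spots = Mask(m, "spot")
    assert spot_area(spots) == 12.0
    assert spot_area(Mask(np.zeros((4, 4), bool), "spot")) == 0.0


def test_spot_area_monotone_when_focus_added():
    size = 64
    img, disc, c = disc_image(size)
    base = gaussian_focus(size, (c[0] - 8, c[1])) + np.where(disc, 0.01, 0.0)
    img.fluorescence = base
    a1 = spot_area(spot_mask(img, nucleus_mask(img)))
    img.fluorescence = base + gaussian_focus(size, (c[0] + 8, c[1]))
    a2 = spot_area(spot_mask(img, nucleus_mask(img)))
    assert a2 >= a1 > 0


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def test_mfi_of_constant_fluorescence_is_that_constant():
    img, disc, _ = disc_image(fluor=np.full((64, 64), 2.5))
    f = extract_features(img)
    assert f.mfi_cell == pytest.approx(2.5)


def test_cellfeatures_invariants():
    with pytest.raises(ValueError):
        CellFeatures(1.0, 0, 5.0, 0.9, 0.1, 100.0, 1.0, 50.0)  # count 0 but area > 0
    with pytest.raises(ValueError):
        CellFeatures(1.0, 1, 5.0, 1.5, 0.1, 100.0, 1.0, 50.0)  # circularity > 1


def test_zero_dose_zero_background_population_spot_count(rng, small_image_params):
    p = dataclasses.replace(small_image_params, beta_true=0.0)
    counts = [extract_features(simulate_cell_image(0.0, p, rng)).spot_count for _ in range(20)]
    assert np.mean(counts) == pytest.approx(0.0, abs=0.05)


def test_endpoints_increase_and_spots_saturate_with_dose(rng, small_image_params):
    doses = [0.0, 1.0, 2.0, 4.0, 8.0, 10.0]
    mfi, cnt = [], []
    for d in doses:
        fs = [extract_features(simulate_cell_image(d, small_image_params, rng)) for _ in range(25)]
        mfi.append(np.mean([f.mfi_cell for f in fs]))
        cnt.append(np.mean([f.spot_count for f in fs]))
    assert all(np.diff(mfi) > 0)  # MFI keeps rising over the whole range
    assert cnt[1] > cnt[0] and cnt[3] > cnt[1]  # spot count rises at low dose
    # saturation: late increments much smaller than early per-Gy increments
    early_slope = (cnt[3] - cnt[0]) / 4.0
    late_slope = (cnt[5] - cnt[4]) / 2.0
    assert late_slope < 0.5 * early_slope


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


def _features(**overrides):
    base = dict(
        mfi_cell=10.0,
        spot_count=2,
        spot_area=20.0,
        circularity=0.9,
        texture_contrast=0.1,
        brightfield_area=1200.0,
        aspect_ratio=0.95,
        focus_score=60.0,
    )
    base.update(overrides)
    return CellFeatures(**base)


def test_identity_gate_passes_everything():
    cfg = GateConfig(focus_threshold=0.0, area_range=(0.0, 1e6), aspect_ratio_range=(0.0, 1.0))
    events = [_features() for _ in range(5)]
    gated, report = gate_events(events, cfg)
    assert gated == events
    assert report.n_retained == 5


def test_doublet_excluded_by_area_gate():
    cfg = GateConfig(area_range=(300.0, 2000.0))
    singlet = _features(brightfield_area=1200.0)
    doublet = _features(brightfield_area=2400.0)
    gated, report = gate_events([singlet, doublet], cfg)
    assert gated == [singlet]
    assert report.stages[1][:1] == ("singlet",)


def test_gate_report_conserves_counts():
    cfg = GateConfig(focus_threshold=50.0, area_range=(300.0, 2000.0))
    events = [_features(focus_score=s, brightfield_area=a) for s, a in [(60, 1200), (40, 1200), (60, 2500), (60, 900)]]
    _, report = gate_events(events, cfg)
    for name, n_in, n_pass in report.stages:
        assert 0 <= n_pass <= n_in
    # each stage's input equals the previous stage's passes
    for (_, _, prev_pass), (_, n_in, _) in zip(report.stages, report.stages[1:]):
        assert n_in == prev_pass


def test_empty_input_is_an_error_and_empty_output_a_warning():
    with pytest.raises(ValueError):
        gate_events([], GateConfig())
    cfg = GateConfig(focus_threshold=1e9)
    with pytest.warns(UserWarning, match="focus"):
        gated, _ = gate_events([_features()], cfg)
    assert gated == []


def test_gh2ax_threshold_is_a_quantile():
    assert gh2ax_positive_threshold([1.0, 2.0, 3.0, 4.0], 0.5) == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# healthy-cell classification
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def populations():
    from ifcdose.synthdata import SimulationParams

    p = SimulationParams(image_size=48, nucleus_radius=14)
    rng = np.random.default_rng(99)
    lymph = [extract_features(simulate_cell_image(2.0, p, rng)) for _ in range(200)]
    other = [
        extract_features(simulate_contaminant_image("apoptotic" if i % 2 else "debris", p, rng)) for i in range(200)
    ]
    return lymph, other


def test_classifier_balanced_accuracy_above_090(populations):
    lymph, other = populations
    train = lymph[:100] + other[:100]
    labels = ["healthy"] * 100 + ["other"] * 100
    pred = classify_healthy(train, labels, lymph[100:] + other[100:])
    truth = ["healthy"] * 100 + ["other"] * 100
    rec_h = np.mean([p == t for p, t in zip(pred[:100], truth[:100])])
    rec_o = np.mean([p == t for p, t in zip(pred[100:], truth[100:])])
    assert (rec_h + rec_o) / 2 > 0.9


def test_training_exemplar_labelled_healthy(populations):
    lymph, other = populations
    train = lymph[:50] + other[:50]
    labels = ["healthy"] * 50 + ["other"] * 50
    assert classify_healthy(train, labels, [lymph[0]]) == ["healthy"]


def test_swapping_training_labels_swaps_predictions(populations):
    lymph, other = populations
    train = lymph[:50] + other[:50]
    labels = ["healthy"] * 50 + ["other"] * 50
    swapped = ["other"] * 50 + ["healthy"] * 50
    query = lymph[50:60] + other[50:60]
    a = classify_healthy(train, labels, query)
    b = classify_healthy(train, swapped, query)
    flip = {"healthy": "other", "other": "healthy"}
    assert b == [flip[x] for x in a]


def test_single_class_training_is_an_error(populations):
    lymph, _ = populations
    with pytest.raises(ValueError, match="both classes"):
        classify_healthy(lymph[:10], ["healthy"] * 10, lymph[10:12])


def test_classifier_round_trips_through_file(populations, tmp_path):
    lymph, other = populations
    clf = HealthyCellClassifier().fit(lymph[:50] + other[:50], ["healthy"] * 50 + ["other"] * 50)
    path = tmp_path / "clf.joblib"
    clf.save(path)
    reloaded = HealthyCellClassifier.load(path)
    query = lymph[50:70] + other[50:70]
    assert reloaded.predict(query) == clf.predict(query)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_aggregate_identical_cells_returns_their_vector():
    cells = [_features() for _ in range(10)]
    agg = aggregate_sample(cells)
    assert agg.as_vector() == pytest.approx([10.0, 2.0, 20.0])
    assert agg.n_retained == 10


def test_aggregate_matches_bruteforce_mean(rng):
    cells = [
        _features(mfi_cell=float(m), spot_count=int(k), spot_area=float(k) * 3.0)
        for m, k in zip(rng.uniform(5, 50, 40), rng.integers(0, 9, 40))
    ]
    agg = aggregate_sample(cells)
    brute = np.mean([[c.mfi_cell, c.spot_count, c.spot_area] for c in cells], axis=0)
    np.testing.assert_allclose(agg.as_vector(), brute)


def test_aggregate_error_names_emptying_gate():
    cfg = GateConfig(focus_threshold=1e9)
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="focus"):
            aggregate_sample([_features()], cfg)
    with pytest.raises(ValueError, match="healthy-classifier"):
        aggregate_sample([_features()], GateConfig(), healthy_labels=["other"])


def test_removing_contaminants_changes_the_sample_vector():
    lymph = [_features(mfi_cell=10.0) for _ in range(20)]
    cont = [_features(mfi_cell=80.0, spot_count=0, spot_area=0.0) for _ in range(5)]
    cells = lymph + cont
    labels = ["healthy"] * 20 + ["other"] * 5
    with_cont = aggregate_sample(cells)
    cleaned = aggregate_sample(cells, healthy_labels=labels)
    assert cleaned.mfi == pytest.approx(10.0)
    assert with_cont.mfi > cleaned.mfi
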