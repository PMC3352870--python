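"""Flattening, reference height, edema area and ONHV/ONHH integration."""

import numpy as np
import pytest

from onhquant.errors import ParameterError, QuantificationError
from onhquant.phantom import make_phantom
from onhquant.quantify import (
    QuantifyParams,
    edema_area,
    flatten_bscan,
    onh_height,
    onh_volume,
    process_volume,
    quantify_volume,
    reference_height,
)
from onhquant.segmentation import LayerTrace, VolumeSegmentation, segment_volume
from tests.conftest import ZERO_NOISE, small_spec


def _trace(rows):
    rows = np.asarray(rows, dtype=float)
    return LayerTrace(rows=rows, valid_mask=np.ones(rows.size, bool))


def _flat(heights):
    heights = np.asarray(heights, dtype=float)
    from onhquant.quantify import FlattenedBscan

    return FlattenedBscan(
        ilm_height=heights, rpe_row=0.0, shift_applied=np.zeros(heights.size)
    )


# ---------------------------------------------------------------- flatten


def test_flatten_constant_geometry():
    flat = flatten_bscan(_trace(np.full(50, 50.0)), _trace(np.full(50, 150.0)))
    np.testing.assert_allclose(flat.ilm_height, 100.0)
    assert flat.rpe_row == 150.0
    np.testing.assert_allclose(flat.shift_applied, 0.0)


def test_flatten_parallel_tilted_surfaces():
    x = np.arange(80, dtype=float)
    rpe = 100.0 + 0.3 * x
    flat = flatten_bscan(_trace(rpe - 42.0), _trace(rpe))
    np.testing.assert_allclose(flat.ilm_height, 42.0)
    # flattened RPE deviates from rpe_row by construction only via the shift
    np.testing.assert_allclose(rpe - flat.shift_applied, flat.rpe_row)


def test_flatten_phantom_swelling_amplitude_recovered():
    spec = small_spec(**ZERO_NOISE)
    volume, truth = make_phantom(spec)
    seg = segment_volume(volume)
    b = volume.n_bscans // 2
    flat = flatten_bscan(seg.ilm[b], seg.rpe[b])
    baseline = reference_height(flat, 0.10)
    assert flat.ilm_height.max() - baseline == pytest.approx(
        spec.swell_amplitude_px, abs=1.5
    )


def test_flatten_clamps_excessive_heights():
    flat = flatten_bscan(_trace(np.full(20, -500.0)), _trace(np.full(20, 100.0)),
                         n_depth=160)
    assert flat.clamped
    assert flat.ilm_height.max() == 160.0


# ---------------------------------------------------------------- reference


def test_reference_of_constant_heights():
    assert reference_height(_flat(np.full(40, 77.0)), 0.10) == 77.0


def test_reference_pools_left_and_right_margins():
    heights = np.zeros(100)
    heights[:10] = 80.0
    heights[-10:] = 120.0
    assert reference_height(_flat(heights), 0.10) == 100.0


# ---------------------------------------------------------------- area


def test_area_zero_when_ilm_below_baseline():
    params = QuantifyParams(threshold_px=0.0)
    flat = _flat(np.full(60, 50.0))
    # reference equals 50, baseline 50, no excess anywhere
    assert edema_area(flat, params, 15.0, 4.0) == 0.0


def test_rectangular_bump_area_exact():
    # heights: baseline b in margins; b + 40 over 100 central A-scans
    n = 140
    heights = np.full(n, 30.0)
    heights[20:120] = 70.0
    params = QuantifyParams(threshold_px=0.0, margin_frac=0.10)
    # reference = 30 (margins flat), baseline = 30, excess = 40 over 100 cols
    area = edema_area(_flat(heights), params, 15.0, 4.0)
    assert area == pytest.approx(40 * 100 * 15 * 4 * 1e-6)  # 0.024 mm2


def test_gaussian_bump_area_matches_numeric_integral():
    n = 400
    x = np.arange(n, dtype=float)
    bump = 60.0 * np.exp(-((x - 199.5) ** 2) / (2 * 30.0**2))
    heights = 100.0 + bump
    params = QuantifyParams(threshold_px=0.0, margin_frac=0.10)
    area = edema_area(_flat(heights), params, 15.0, 4.0)
    ref = reference_height(_flat(heights), 0.10)
    oracle = np.trapezoid(np.clip(heights - ref, 0, None)) * 15.0 * 4.0 * 1e-6
    assert area == pytest.approx(oracle, rel=0.005)


def test_threshold_monotonicity_below_reference():
    heights = np.concatenate([np.full(20, 50.0), np.full(60, 90.0), np.full(20, 50.0)])
    areas = [
        edema_area(_flat(heights), QuantifyParams(threshold_px=t), 15.0, 4.0)
        for t in (0.0, 5.0, 10.0, 20.0, 40.0)
    ]
    assert all(b >= a for a, b in zip(areas, areas[1:]))


def test_above_reference_threshold_shrinks_area():
    heights = np.concatenate([np.full(20, 50.0), np.full(60, 90.0), np.full(20, 50.0)])
    below = edema_area(_flat(heights), QuantifyParams(threshold_px=10.0), 15.0, 4.0)
    above = edema_area(
        _flat(heights),
        QuantifyParams(threshold_px=10.0, threshold_sign="above_reference"),
        15.0,
        4.0,
    )
    assert above < below


# ---------------------------------------------------------------- volume/height


def test_volume_arithmetic():
    assert onh_volume([1.0, 2.0, 3.0], 100.0) == pytest.approx(0.6)
    assert onh_volume([0.0, 0.0], 100.0) == 0.0
    with pytest.raises(ParameterError):
        onh_volume([-1.0], 100.0)


def test_volume_additivity_in_bscan_spacing():
    areas = [0.3, 0.7, 1.1]
    assert onh_volume(areas, 200.0) == pytest.approx(2 * onh_volume(areas, 100.0))


def test_height_of_flat_retina():
    ilm = [_trace(np.full(30, 50.0))]
    rpe = [_trace(np.full(30, 150.0))]
    seg = VolumeSegmentation(ilm=ilm, rpe=rpe, fits=[None], flags=[])
    assert onh_height(seg, 4.0) == pytest.approx(0.4)


def test_height_invariant_under_flattening():
    rng = np.random.default_rng(3)
    x = np.arange(60, dtype=float)
    rpe_rows = 120.0 + 0.4 * x + rng.normal(0, 1, 60)
    ilm_rows = rpe_rows - (40.0 + 10 * np.exp(-((x - 30) ** 2) / 50.0))
    seg = VolumeSegmentation(
        ilm=[_trace(ilm_rows)], rpe=[_trace(rpe_rows)], fits=[None], flags=[]
    )
    raw = onh_height(seg, 3.9)
    flat = flatten_bscan(_trace(ilm_rows), _trace(rpe_rows))
    assert raw == flat.ilm_height.max() * 3.9 * 1e-3


# ---------------------------------------------------------------- whole volume


def test_quantify_matches_truth_on_clean_phantom():
    spec = small_spec(**ZERO_NOISE)
    volume, truth = make_phantom(spec)
    report = process_volume(volume)
    tv = truth.true_onhv_mm3(20.0, 0.10)
    assert report.onhv_mm3 == pytest.approx(tv, rel=0.02)
    assert report.onhh_mm == pytest.approx(
        truth.true_onhh_mm, abs=1.5 * spec.axial_spacing * 1e-3
    )
    assert report.onhv_mm3 == pytest.approx(
        sum(report.area_profile_mm2) * volume.bscan_spacing * 1e-3
    )


def test_amplitude_monotonicity_small_grid():
    vols = []
    for amp in (0.0, 12.0, 25.0):
        volume, _ = make_phantom(small_spec(swell_amplitude_px=amp, **ZERO_NOISE))
        vols.append(process_volume(volume).onhv_mm3)
    assert vols[0] < vols[1] < vols[2]


def test_all_bscans_flagged_is_quantification_error():
    volume, _ = make_phantom(small_spec(**ZERO_NOISE))
    n, w = volume.n_bscans, volume.n_ascans
    seg = VolumeSegmentation(
        ilm=[_trace(np.zeros(w)) for _ in range(n)],
        rpe=[None] * n,
        fits=[None] * n,
        flags=[{"bscan_index": b, "reason": "dark"} for b in range(n)],
    )
    with pytest.raises(QuantificationError, match="20%"):
        quantify_volume(volume, seg)


def test_flagged_bscans_contribute_zero_area():
    volume, _ = make_phantom(small_spec(**ZERO_NOISE))
    seg = segment_volume(volume)
    # flag one B-scan manually
    seg.flags.append({"bscan_index": 0, "reason": "test"})
    report = quantify_volume(volume, seg)
    assert report.area_profile_mm2[0] == 0.0
    assert {f["bscan_index"] for f in report.per_bscan_flags} >= {0}
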