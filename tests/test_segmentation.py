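"""Layer detection and RPE spline reconstruction against phantom truth."""

import numpy as np
import pytest

from onhquant.config import DEFAULTS
from onhquant.errors import ParameterError, SegmentationError
from onhquant.preprocess import DenoiseParams, denoise_bscan
from onhquant.segmentation import (
    LayerTrace,
    RpeCandidates,
    choose_spline_order,
    detect_rpe_candidates,
    fit_rpe_spline,
    mask_upper_layers,
    segment_bscan,
    segment_ilm,
)


def _band_image(width=256, depth=200, center=120.0, slope=0.0, gap=None):
    """Bright horizontal band with Gaussian axial profile; optional column gap."""
    d = np.arange(depth, dtype=float)[:, None]
    rows = center + slope * np.arange(width)
    img = 0.9 * np.exp(-((d - rows[None, :]) ** 2) / (2 * 1.5**2))
    if gap is not None:
        img[:, gap[0]:gap[1]] = 0.0
    return img


# ---------------------------------------------------------------- ILM


def test_ilm_on_clean_phantom_within_one_row(clean_phantom):
    # a noise-free scan needs no blurring; median alone keeps the edge crisp
    volume, truth = clean_phantom
    b = volume.n_bscans // 2
    den = denoise_bscan(volume.bscans[b], DenoiseParams(enabled_stages=("median",)))
    trace = segment_ilm(den, 0.25)
    assert trace.valid_mask.all()
    err = np.abs(trace.rows - truth.ilm_surface[b])
    assert err.max() <= 1.0


def test_ilm_all_zero_bscan_is_all_invalid():
    trace = segment_ilm(np.zeros((64, 32)), 0.25)
    assert not trace.valid_mask.any()


def test_ilm_noisy_phantom_mae_below_two_rows(noisy_phantom):
    volume, truth = noisy_phantom
    errs = []
    for b in range(0, volume.n_bscans, 5):
        den = denoise_bscan(volume.bscans[b], DenoiseParams())
        trace = segment_ilm(den, 0.25)
        errs.append(
            np.abs(trace.rows - truth.ilm_surface[b])[trace.valid_mask].mean()
        )
    assert np.mean(errs) <= 2.0


# ---------------------------------------------------------------- masking


def test_mask_zeroes_upper_band_keeps_lower():
    img = np.zeros((100, 40))
    img[20:24] = 0.8  # upper band (ILM)
    img[70:74] = 0.8  # lower band (RPE)
    ilm = LayerTrace(rows=np.full(40, 20.0), valid_mask=np.ones(40, bool))
    out = mask_upper_layers(img, ilm, offset_px=30.0)
    assert out[20:24].max() == 0.0
    np.testing.assert_array_equal(out[70:74], img[70:74])


def test_mask_requires_half_valid_ilm():
    img = np.ones((50, 40))
    valid = np.zeros(40, bool)
    valid[:10] = True
    ilm = LayerTrace(rows=np.full(40, 10.0), valid_mask=valid)
    with pytest.raises(SegmentationError, match="50%"):
        mask_upper_layers(img, ilm, offset_px=5.0)


def test_masked_brightest_pixel_is_rpe_on_phantom(clean_phantom):
    volume, truth = clean_phantom
    spec = truth.spec
    b = volume.n_bscans // 2
    den = denoise_bscan(volume.bscans[b], DenoiseParams())
    ilm = segment_ilm(den, 0.25)
    masked = mask_upper_layers(den, ilm, DEFAULTS["segmentation.mask_offset_px"])
    brightest = masked.argmax(axis=0)
    u = np.arange(spec.n_ascans) - (spec.n_ascans - 1) / 2
    v = (b - (spec.n_bscans - 1) / 2) * spec.bscan_spacing / spec.lateral_spacing
    outside = np.sqrt(u**2 + v**2) > spec.disc_radius_px + spec.rpe_band_px
    hits = np.abs(brightest - truth.rpe_surface[b])[outside] <= 2.0
    assert hits.mean() >= 0.95


# ---------------------------------------------------------------- candidates


def test_single_band_gives_one_full_segment():
    img = _band_image(slope=0.02)
    cand = detect_rpe_candidates(img)
    assert cand.n_segments == 1
    assert cand.segments[0] == (0, img.shape[1] - 1)
    centers = 120.0 + 0.02 * cand.ascans
    assert np.abs(cand.rows - centers).max() <= 1.0


def test_central_gap_splits_candidates_into_two_segments():
    img = _band_image(width=256, gap=(98, 158))  # 60-column disc gap
    cand = detect_rpe_candidates(img)
    assert cand.n_segments == 2


def test_dark_anchors_raise_segmentation_error():
    img = np.zeros((100, 200))
    img[50, 95:105] = 1.0  # bright only at the center, both anchors dark
    with pytest.raises(SegmentationError, match="anchor"):
        detect_rpe_candidates(img)


def test_noisy_phantom_candidates_near_true_rpe(noisy_phantom):
    volume, truth = noisy_phantom
    spec = truth.spec
    b = volume.n_bscans // 2
    den = denoise_bscan(volume.bscans[b], DenoiseParams())
    ilm = segment_ilm(den, 0.25)
    masked = mask_upper_layers(den, ilm, DEFAULTS["segmentation.mask_offset_px"])
    cand = detect_rpe_candidates(masked)
    u = cand.ascans - (spec.n_ascans - 1) / 2
    v = (b - (spec.n_bscans - 1) / 2) * spec.bscan_spacing / spec.lateral_spacing
    outside = np.sqrt(u**2 + v**2) > spec.disc_radius_px + spec.rpe_band_px
    err = np.abs(cand.rows - truth.rpe_surface[b][cand.ascans])[outside]
    assert (err <= 3.0).mean() >= 0.90


def test_wider_band_never_loses_candidates(clean_phantom):
    volume, _ = clean_phantom
    den = denoise_bscan(volume.bscans[volume.n_bscans // 2], DenoiseParams())
    ilm = segment_ilm(den, 0.25)
    masked = mask_upper_layers(den, ilm, DEFAULTS["segmentation.mask_offset_px"])
    counts = [
        detect_rpe_candidates(masked, anchor_band_halfwidth=w).n_candidates
        for w in (5.0, 10.0, 15.0, 25.0)
    ]
    assert counts == sorted(counts)


# ---------------------------------------------------------------- order rule


@pytest.mark.parametrize("n_segments,expected", [(1, 3), (2, 2), (3, 2), (5, 2)])
def test_spline_order_rule(n_segments, expected):
    assert choose_spline_order(n_segments) == expected
    # pure function: same input, same output
    assert choose_spline_order(n_segments) == expected


def test_zero_segments_is_error():
    with pytest.raises(SegmentationError):
        choose_spline_order(0)


# ---------------------------------------------------------------- spline fit


def _candidates_from(x, rows, width):
    return RpeCandidates(
        ascans=np.asarray(x, dtype=int),
        rows=np.asarray(rows, dtype=float),
        intensities=np.ones(len(x)),
        segments=[],
        width=width,
    )


def test_exact_parabola_is_reproduced_everywhere():
    width = 200
    x = np.arange(width)
    parab = 80.0 + 0.001 * (x - 99.5) ** 2
    trace, fit = fit_rpe_spline(_candidates_from(x, parab, width), order=2)
    assert fit.rss <= 1e-8
    np.testing.assert_allclose(trace.rows, parab, atol=1e-6)


def test_parabola_with_central_half_removed_recovered_in_gap():
    width = 384
    x = np.arange(width)
    parab = 300.0 + 5e-4 * (x - (width - 1) / 2) ** 2
    keep = (x < width // 4) | (x >= 3 * width // 4)
    trace, _ = fit_rpe_spline(
        _candidates_from(x[keep], parab[keep], width), order=2
    )
    gap_err = np.abs(trace.rows - parab)[~keep]
    assert gap_err.max() <= 0.5


def test_underdetermined_fit_is_error():
    with pytest.raises(SegmentationError, match="underdetermined"):
        fit_rpe_spline(_candidates_from([0, 5, 9], [1.0, 2.0, 3.0], 100), order=2)


def test_noisy_gap_extrapolation_rmse_bounded(rng):
    width = 384
    x = np.arange(width)
    parab = 300.0 + 5e-4 * (x - (width - 1) / 2) ** 2
    keep = (x < width // 4) | (x >= 3 * width // 4)
    rmses = []
    for _ in range(5):
        noisy = parab[keep] + rng.normal(0, 2.0, int(keep.sum()))
        trace, _ = fit_rpe_spline(
            _candidates_from(x[keep], noisy, width), order=2
        )
        rmses.append(np.sqrt(np.mean((trace.rows - parab)[~keep] ** 2)))
    assert max(rmses) <= 4.0


# ---------------------------------------------------------------- end-to-end


def test_fitted_rpe_tracks_truth_on_clean_gap_phantom(clean_phantom):
    """Noise-free gap phantom: |fitted - true RPE| <= 1 row at >= 95% of
    A-scans, pooled over the volume."""
    volume, truth = clean_phantom
    hits, total = 0, 0
    for b in range(0, volume.n_bscans, 2):
        _ilm, rpe, _fit = segment_bscan(volume.bscans[b], DEFAULTS)
        err = np.abs(rpe.rows - truth.rpe_surface[b])
        hits += int((err <= 1.0).sum())
        total += err.size
    assert hits / total >= 0.95


def test_invalid_order_rejected():
    with pytest.raises(ParameterError):
        fit_rpe_spline(
            _candidates_from(np.arange(50), np.zeros(50), 50), order=4
        )
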