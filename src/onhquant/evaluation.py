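"""Reproducibility experiments: pipeline-vs-oracle closure on phantoms.

Each function runs the full pipeline on freshly generated phantom volumes
at the default acquisition geometry (145 B-scans x 384 A-scans x 496 depth
pixels) and compares against the analytic ground truth, mirroring the
evaluation designs used for the clinical measures: oracle closure on a
parameter grid, coefficient of variation under speckle noise, a 6-eyes x
3-repeats reliability ICC, group discrimination by ROC AUC, and the
normative percentile cutoff.
"""

from __future__ import annotations

import json
from typing import Any, Sequence

import numpy as np

from .config import resolve_config
from .oct_io import OnhReport
from .phantom import PhantomSpec, make_cohort, make_phantom
from .quantify import process_volume
from .segmentation import RpeCandidates, fit_rpe_spline
from .stats import (
    GroupedValues,
    RepeatedMeasures,
    icc_two_way_mixed,
    mann_whitney_auc,
    normative_percentile,
)

ZERO_NOISE = {"speckle_shape": None, "additive_sigma": 0.0}


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def oracle_closure_grid(
    amplitudes: Sequence[float] = (0.0, 30.0, 80.0),
    sigmas: Sequence[float] = (25.0, 40.0, 60.0),
    thicknesses: Sequence[float] = (80.0, 100.0, 120.0),
    base_spec: PhantomSpec | None = None,
) -> dict[str, Any]:
    """Zero-noise closure: pipeline ONHV/ONHH vs analytic truth on a grid.

    Returns the worst relative volume error (%) and worst height error
    (axial px) over the amplitude x sigma x thickness grid.
    """
    base = base_spec or PhantomSpec()
    cfg = resolve_config(None)
    thr = float(cfg["quantify.threshold_px"])
    mf = float(cfg["quantify.margin_frac"])
    vol_errs, h_errs = [], []
    for amp in amplitudes:
        for sig in sigmas:
            for thick in thicknesses:
                spec = base.replace(
                    swell_amplitude_px=amp,
                    swell_sigma_px=sig,
                    retina_thickness_px=thick,
                    **ZERO_NOISE,
                )
                volume, truth = make_phantom(spec)
                report = process_volume(volume, cfg)
                tv = truth.true_onhv_mm3(thr, mf)
                vol_errs.append(abs(report.onhv_mm3 - tv) / tv * 100.0)
                h_errs.append(
                    abs(report.onhh_mm - truth.true_onhh_mm)
                    * 1000.0
                    / spec.axial_spacing
                )
    return {
        "max_vol_rel_err_pct": float(max(vol_errs)),
        "max_height_err_px": float(max(h_errs)),
        "n": len(vol_errs),
    }


def noise_robustness(
    amplitudes: Sequence[float] = (0.0, 40.0, 80.0),
    n_seeds: int = 20,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> dict[str, Any]:
    """ONHV coefficient of variation and bias under default speckle noise.

    For each swelling amplitude, ``n_seeds`` independent noise realisations
    of the same anatomy are quantified; reports the worst CV (%) and worst
    mean bias vs truth (%) across amplitudes.
    """
    base = base_spec or PhantomSpec()
    cfg = resolve_config(None)
    thr = float(cfg["quantify.threshold_px"])
    mf = float(cfg["quantify.margin_frac"])
    cvs, biases = [], []
    seeds = _child_seeds(seed, n_seeds * len(amplitudes))
    k = 0
    for amp in amplitudes:
        vals = []
        truth_v = None
        for _ in range(n_seeds):
            spec = base.replace(swell_amplitude_px=amp, seed=seeds[k])
            k += 1
            volume, truth = make_phantom(spec)
            truth_v = truth.true_onhv_mm3(thr, mf)
            vals.append(process_volume(volume, cfg).onhv_mm3)
        arr = np.asarray(vals)
        cvs.append(arr.std(ddof=1) / arr.mean() * 100.0)
        biases.append((arr.mean() - truth_v) / truth_v * 100.0)
    return {
        "max_cv_pct": float(max(cvs)),
        "max_abs_bias_pct": float(max(abs(b) for b in biases)),
        "per_amplitude_cv_pct": [float(c) for c in cvs],
        "per_amplitude_bias_pct": [float(b) for b in biases],
        "n": n_seeds * len(amplitudes),
    }


def repeatability_icc(
    n_eyes: int = 6,
    n_repeats: int = 3,
    seed: int = 0,
    amplitudes: Sequence[float] | None = None,
    base_spec: PhantomSpec | None = None,
) -> dict[str, Any]:
    """Test-retest reliability: n phantom eyes, each rendered n_repeats times.

    Each "eye" is a fixed anatomy (one swelling amplitude); repeats differ
    only in the speckle realisation, emulating repeated acquisitions of the
    same eye.  Returns ICC(3,1) for ONHV and ONHH.
    """
    base = base_spec or PhantomSpec()
    if amplitudes is None:
        amplitudes = np.linspace(0.0, 80.0, n_eyes).tolist()
    if len(amplitudes) != n_eyes:
        raise ValueError("amplitudes must have n_eyes entries")
    seeds = _child_seeds(seed, n_eyes * n_repeats)
    onhv = np.empty((n_eyes, n_repeats))
    onhh = np.empty((n_eyes, n_repeats))
    k = 0
    for i, amp in enumerate(amplitudes):
        for j in range(n_repeats):
            spec = base.replace(swell_amplitude_px=amp, seed=seeds[k])
            k += 1
            volume, _ = make_phantom(spec)
            report = process_volume(volume)
            onhv[i, j] = report.onhv_mm3
            onhh[i, j] = report.onhh_mm
    return {
        "icc_onhv": float(icc_two_way_mixed(RepeatedMeasures(onhv))),
        "icc_onhh": float(icc_two_way_mixed(RepeatedMeasures(onhh))),
        "n": n_eyes * n_repeats,
    }


def cohort_discrimination(
    n_per_group: int = 8,
    seed: int = 0,
    control_amplitude: tuple[float, float] = (0.0, 30.0),
    patient_amplitude: tuple[float, float] = (15.0, 80.0),
    q: float = 95.0,
    base_spec: PhantomSpec | None = None,
) -> dict[str, Any]:
    """Group discrimination on a synthetic cohort with overlapping severity.

    Quantifies every phantom eye through the pipeline, then computes the
    ROC AUC for ONHV between groups and the q-th percentile normative
    cutoff of the controls with the fraction of patient eyes above it.
    """
    cohort = make_cohort(
        n_per_group,
        {"swell_amplitude_px": control_amplitude},
        {"swell_amplitude_px": patient_amplitude},
        seed=seed,
        base_spec=base_spec,
    )
    values, labels = [], []
    for volume, _truth, label in cohort:
        values.append(process_volume(volume).onhv_mm3)
        labels.append(1 if label == "patient" else 0)
    values = np.asarray(values)
    labels = np.asarray(labels)
    auc = mann_whitney_auc(GroupedValues(values=values, labels=labels))
    cut = normative_percentile(values[labels == 0], q, values[labels == 1])
    return {
        "auc_onhv": float(auc),
        "p95_cutoff_mm3": float(cut.cutoff),
        "frac_patients_above_cutoff": float(cut.frac_exceeding),
        "n": int(values.size),
    }


def spline_gap_metrics(
    n_seeds: int = 20, noise_sigma: float = 2.0, seed: int = 0, width: int = 384
) -> dict[str, Any]:
    """RPE spline extrapolation across a removed central half of a parabola.

    Reports the exact-data maximum gap error and the gap RMSE under
    candidate noise, averaged over seeds.
    """
    x = np.arange(width, dtype=float)
    parab = 300.0 + 5e-4 * (x - (width - 1) / 2) ** 2
    keep = (x < width / 4) | (x >= 3 * width / 4)
    gap = ~keep

    def fit(rows: np.ndarray):
        cand = RpeCandidates(
            ascans=np.nonzero(keep)[0],
            rows=rows,
            intensities=np.ones(int(keep.sum())),
            segments=[(0, width // 4 - 1), (3 * width // 4, width - 1)],
            width=width,
        )
        trace, _ = fit_rpe_spline(cand, order=2, n_knots=5, width=width)
        return trace.rows

    exact_err = float(np.abs(fit(parab[keep]) - parab)[gap].max())
    rmses = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        noisy = parab[keep] + rng.normal(0.0, noise_sigma, int(keep.sum()))
        rmses.append(float(np.sqrt(np.mean((fit(noisy) - parab)[gap] ** 2))))
    return {
        "exact_gap_max_err_rows": exact_err,
        "noisy_gap_rmse_rows": float(np.mean(rmses)),
        "noisy_gap_rmse_rows_max": float(np.max(rmses)),
        "n": n_seeds,
    }


def _report_blob(report: OnhReport) -> str:
    from .oct_io import _report_dict

    return json.dumps(_report_dict(report), sort_keys=True)


def determinism_check(seed: int = 0, base_spec: PhantomSpec | None = None) -> bool:
    """Two runs with identical resolved configs produce byte-identical reports."""
    spec = (base_spec or PhantomSpec()).replace(seed=seed)
    cfg = resolve_config(None)
    volume1, _ = make_phantom(spec)
    volume2, _ = make_phantom(spec)
    if not np.array_equal(volume1.bscans, volume2.bscans):
        return False
    r1 = process_volume(volume1, cfg)
    r2 = process_volume(volume2, cfg)
    return _report_blob(r1) == _report_blob(r2)
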