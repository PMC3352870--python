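"""Edema quantification on flattened B-scans.

Each B-scan is flattened on its fitted RPE spline, the peripheral reference
height is taken from the lateral edge margins of the flattened ILM, a pixel
threshold (default 20 axial px, toward the RPE) defines the baseline plane,
and the ILM height above that plane integrates to the per-B-scan edema
area.  Areas, multiplied by the B-scan spacing, sum to the ONH volume
(ONHV, mm³); the maximum ILM elevation above the RPE gives the ONH height
(ONHH, mm).

Heights are computed directly from the traces — flattening shifts stay
sub-pixel and no image is resampled — so quantification is free of
interpolation bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np

from .config import config_digest as _digest_of
from .errors import ParameterError, QuantificationError
from .oct_io import OCTVolume, OnhReport
from .segmentation import LayerTrace, VolumeSegmentation

THRESHOLD_SIGNS = ("below_reference", "above_reference")


@dataclass
class QuantifyParams:
    """Quantification parameters.

    ``threshold_px`` is in native axial pixels (the reference threshold of
    20 px); ``margin_frac`` is the fraction of A-scans at each lateral edge
    pooled into the peripheral reference height; ``threshold_sign`` places
    the baseline plane below (toward the RPE, default) or above the
    reference.
    """

    threshold_px: float = 20.0
    margin_frac: float = 0.10
    threshold_sign: str = "below_reference"

    def __post_init__(self) -> None:
        if self.threshold_px < 0:
            raise ParameterError("threshold_px must be >= 0")
        if not 0 < self.margin_frac <= 0.25:
            raise ParameterError("margin_frac must be in (0, 0.25]")
        if self.threshold_sign not in THRESHOLD_SIGNS:
            raise ParameterError(
                f"threshold_sign must be one of {THRESHOLD_SIGNS}, "
                f"got {self.threshold_sign!r}"
            )

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "QuantifyParams":
        return cls(
            threshold_px=float(cfg["quantify.threshold_px"]),
            margin_frac=float(cfg["quantify.margin_frac"]),
            threshold_sign=str(cfg["quantify.threshold_sign"]),
        )


@dataclass
class FlattenedBscan:
    """A B-scan flattened on its RPE: per-A-scan ILM height above the
    constant reference row, and the shift that flattening applied."""

    ilm_height: np.ndarray
    rpe_row: float
    shift_applied: np.ndarray
    clamped: bool = False

    @property
    def n_ascans(self) -> int:
        return self.ilm_height.size


def flatten_bscan(
    ilm: LayerTrace, rpe: LayerTrace, n_depth: int | None = None
) -> FlattenedBscan:
    """Flatten one B-scan on the fitted RPE.

    The flattened RPE sits at the constant row ``median(rpe.rows)``; the ILM
    height is simply ``rpe - ilm`` per A-scan (flattening is a per-column
    shift, which cancels in the difference).  If ``n_depth`` is given,
    heights exceeding it (ILM shifted above the image top) are clamped and
    the result is marked ``clamped``.
    """
    if ilm.n_ascans != rpe.n_ascans:
        raise ParameterError("ILM and RPE traces must have equal width")
    rpe_row = float(np.median(rpe.rows))
    shift = rpe.rows - rpe_row
    heights = rpe.rows - ilm.rows
    clamped = False
    if n_depth is not None and np.any(heights > n_depth):
        heights = np.minimum(heights, float(n_depth))
        clamped = True
    return FlattenedBscan(
        ilm_height=heights, rpe_row=rpe_row, shift_applied=shift, clamped=clamped
    )


def reference_height(flat: FlattenedBscan, margin_frac: float = 0.10) -> float:
    """Peripheral reference: pooled mean ILM height over both edge margins.

    Uses the leftmost and rightmost ``ceil(margin_frac * n)`` A-scans of the
    flattened B-scan (one pooled mean over the two windows).
    """
    if not 0 < margin_frac <= 0.25:
        raise ParameterError("margin_frac must be in (0, 0.25]")
    n = flat.n_ascans
    m = math.ceil(margin_frac * n)
    window = np.concatenate([flat.ilm_height[:m], flat.ilm_height[n - m:]])
    return float(window.mean())


def edema_area(
    flat: FlattenedBscan,
    params: QuantifyParams,
    lateral_spacing: float,
    axial_spacing: float,
) -> float:
    """Edema area of one flattened B-scan, in mm².

    The baseline is the reference height shifted by ``threshold_px`` toward
    the RPE (``below_reference``, default) or away from it; the area is the
    positive part of the ILM height above the baseline, summed over A-scans
    and scaled by the pixel pitch.  Never negative.
    """
    ref = reference_height(flat, params.margin_frac)
    if params.threshold_sign == "below_reference":
        baseline = ref - params.threshold_px
    else:
        baseline = ref + params.threshold_px
    excess = np.clip(flat.ilm_height - baseline, 0.0, None)
    area_um2 = float(excess.sum()) * lateral_spacing * axial_spacing
    return area_um2 * 1e-6


def onh_volume(areas_mm2: Sequence[float], bscan_spacing: float) -> float:
    """ONHV in mm³: per-B-scan areas summed and scaled by the B-scan spacing (µm)."""
    areas = np.asarray(areas_mm2, dtype=np.float64)
    if np.any(areas < 0):
        raise ParameterError("areas must be non-negative")
    return float(areas.sum() * bscan_spacing * 1e-3)


def onh_height(segmentation: VolumeSegmentation, axial_spacing: float) -> float:
    """ONHH in mm: maximum ILM elevation above the fitted RPE over the volume.

    Computed from the raw traces (rpe - ilm); identical to the maximum of
    the flattened heights, since flattening is a per-column shift.
    """
    best = 0.0
    flagged = segmentation.flagged_indices
    for b, (ilm, rpe) in enumerate(zip(segmentation.ilm, segmentation.rpe)):
        if b in flagged or rpe is None:
            continue
        best = max(best, float(np.max(rpe.rows - ilm.rows)))
    return best * axial_spacing * 1e-3


def quantify_volume(
    volume: OCTVolume,
    segmentation: VolumeSegmentation,
    params: QuantifyParams | None = None,
    cfg: Mapping[str, Any] | None = None,
) -> OnhReport:
    """Assemble flatten -> reference -> area per B-scan into an OnhReport.

    Flagged B-scans contribute zero area and are listed in
    ``per_bscan_flags``; more than 20% flagged B-scans make the volume
    unreliable and raise :class:`QuantificationError`.
    """
    if params is None:
        params = QuantifyParams.from_config(cfg) if cfg else QuantifyParams()
    if segmentation.n_bscans != volume.n_bscans:
        raise ParameterError("segmentation does not cover the volume")
    flags = list(segmentation.flags)
    flagged = {f["bscan_index"] for f in flags}
    if len(flagged) > 0.2 * volume.n_bscans:
        raise QuantificationError(
            f"{len(flagged)}/{volume.n_bscans} B-scans flagged (> 20%); "
            "volume unreliable"
        )
    areas: list[float] = []
    for b in range(volume.n_bscans):
        rpe = segmentation.rpe[b]
        if b in flagged or rpe is None:
            areas.append(0.0)
            continue
        flat = flatten_bscan(segmentation.ilm[b], rpe, n_depth=volume.n_depth)
        if flat.clamped:
            flags.append({"bscan_index": b, "reason": "ilm height clamped at n_depth"})
        areas.append(edema_area(flat, params, volume.lateral_spacing, volume.axial_spacing))
    digest = _digest_of(dict(cfg)) if cfg else _digest_of(vars(params))
    report = OnhReport(
        onhv_mm3=onh_volume(areas, volume.bscan_spacing),
        onhh_mm=onh_height(segmentation, volume.axial_spacing),
        area_profile_mm2=areas,
        threshold_px=params.threshold_px,
        config_digest=digest,
        per_bscan_flags=flags,
        bscan_spacing_um=volume.bscan_spacing,
        meta={
            "n_bscans": volume.n_bscans,
            "n_ascans": volume.n_ascans,
            "n_depth": volume.n_depth,
            "axial_spacing_um": volume.axial_spacing,
            "lateral_spacing_um": volume.lateral_spacing,
            "threshold_sign": params.threshold_sign,
            "margin_frac": params.margin_frac,
        },
    )
    report.validate()
    return report


def process_volume(
    volume: OCTVolume,
    cfg: Mapping[str, Any] | None = None,
    ilm_traces: Sequence[LayerTrace] | None = None,
) -> OnhReport:
    """End-to-end pipeline: segment a volume, then quantify it."""
    from .config import resolve_config
    from .segmentation import segment_volume

    resolved = resolve_config(None) if cfg is None else dict(cfg)
    seg = segment_volume(volume, resolved, ilm_traces=ilm_traces)
    return quantify_volume(volume, seg, cfg=resolved)
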