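"""ILM detection and RPE spline reconstruction on B-scans.

The RPE is absent at the optic disc, so its peripapillary course must be
extrapolated through the optic nerve head to obtain the lower reference
surface.  The steps, per B-scan:

1. detect (or accept from the device) the inner limiting membrane;
2. zero everything above the ILM plus an offset, so the brightest
   remaining pixels belong to the RPE band;
3. seed a search band from the brightest pixels of the A-scans at 25% and
   75% of the scan width and propagate it column-to-column to collect RPE
   candidate pixels; columns darker than an intensity floor contribute
   nothing — this is what opens the gap at the disc;
4. count candidate segments, choose the spline order from the count, and
   fit a least-squares B-spline through the candidates, evaluated across
   the full width — including the gap, which yields the hypothetical RPE
   extension through the ONH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .config import DEFAULTS
from .errors import ParameterError, SegmentationError
from .oct_io import OCTVolume
from .preprocess import DenoiseParams, denoise_bscan


@dataclass
class LayerTrace:
    """Per-A-scan axial position of one boundary on one B-scan.

    ``rows`` are floating-point row coordinates (sub-pixel); positions are
    meaningful only where ``valid_mask`` is true.
    """

    rows: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.rows.shape != self.valid_mask.shape or self.rows.ndim != 1:
            raise ParameterError("rows and valid_mask must be 1D and congruent")
        if not np.all(np.isfinite(self.rows[self.valid_mask])):
            raise ParameterError("valid positions must be finite")

    @property
    def n_ascans(self) -> int:
        return self.rows.size

    @property
    def valid_fraction(self) -> float:
        return float(self.valid_mask.mean())

    def filled(self) -> "LayerTrace":
        """Interpolate invalid columns from valid neighbours (full-width rows)."""
        if self.valid_mask.all():
            return self
        if not self.valid_mask.any():
            raise SegmentationError("cannot fill a trace with no valid columns")
        x = np.arange(self.n_ascans)
        rows = np.interp(x, x[self.valid_mask], self.rows[self.valid_mask])
        return LayerTrace(rows=rows, valid_mask=self.valid_mask.copy())


@dataclass
class RpeCandidates:
    """RPE candidate pixels and their grouping into contiguous segments."""

    ascans: np.ndarray  # sorted candidate column indices (one candidate each)
    rows: np.ndarray
    intensities: np.ndarray
    segments: list[tuple[int, int]]  # inclusive (first, last) columns per run
    width: int

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_candidates(self) -> int:
        return self.ascans.size

    @property
    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.ascans.tolist(), self.rows.tolist()))


@dataclass
class SplineFit:
    """Fitted least-squares spline: order, interior knots, coefficients, RSS."""

    order: int
    knots: np.ndarray
    coefficients: np.ndarray
    rss: float

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ParameterError(f"spline order must be 2 or 3, got {self.order}")
        if self.rss < 0:
            raise ParameterError("rss must be >= 0")


@dataclass
class VolumeSegmentation:
    """Per-B-scan ILM and fitted RPE traces for a whole volume."""

    ilm: list[LayerTrace]
    rpe: list[LayerTrace | None]
    fits: list["SplineFit | None"]
    flags: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_bscans(self) -> int:
        return len(self.ilm)

    @property
    def flagged_indices(self) -> set[int]:
        return {f["bscan_index"] for f in self.flags}


def segment_ilm(bscan: np.ndarray, min_intensity: float = 0.25) -> LayerTrace:
    """First suprathreshold crossing from the top, per A-scan, sub-pixel.

    A stand-in for the device's ILM segmentation: on a denoised B-scan the
    first row where intensity rises above ``min_intensity`` marks the
    vitreoretinal interface.  Columns with no crossing are marked invalid.
    """
    img = np.asarray(bscan, dtype=np.float64)
    above = img > min_intensity
    valid = above.any(axis=0)
    idx = above.argmax(axis=0)
    rows = idx.astype(np.float64)
    # linear interpolation between the last sub- and first supra-threshold pixel
    interp = valid & (idx > 0)
    cols = np.nonzero(interp)[0]
    if cols.size:
        hi = img[idx[cols], cols]
        lo = img[idx[cols] - 1, cols]
        denom = hi - lo
        frac = np.where(denom > 0, (min_intensity - lo) / np.where(denom > 0, denom, 1.0), 0.0)
        rows[cols] = idx[cols] - 1 + np.clip(frac, 0.0, 1.0)
    rows[~valid] = 0.0
    return LayerTrace(rows=rows, valid_mask=valid)


def mask_upper_layers(
    bscan: np.ndarray, ilm: LayerTrace, offset_px: float = 25.0
) -> np.ndarray:
    """Zero all pixels above ``ilm + offset_px`` per column.

    Removes the bright inner layers (RNFL) so the brightest remaining spots
    belong to the RPE.  Columns with an invalid ILM use the median valid
    ILM row; fewer than 50% valid columns is a segmentation error.
    """
    img = np.asarray(bscan, dtype=np.float64)
    if ilm.n_ascans != img.shape[1]:
        raise ParameterError("ILM trace width does not match the B-scan")
    if ilm.valid_fraction < 0.5:
        raise SegmentationError(
            f"ILM valid on only {ilm.valid_fraction:.0%} of A-scans (< 50%)"
        )
    cut = np.where(ilm.valid_mask, ilm.rows, np.median(ilm.rows[ilm.valid_mask]))
    depth = np.arange(img.shape[0], dtype=np.float64)[:, None]
    out = img.copy()
    out[depth < (cut[None, :] + offset_px)] = 0.0
    return out


def detect_rpe_candidates(
    masked: np.ndarray,
    n_per_ascan: int = 3,
    anchor_band_halfwidth: float = 15.0,
    gap_min: int = 20,
    intensity_floor_rel: float = 0.5,
) -> RpeCandidates:
    """Select RPE candidate pixels via band propagation from the quarter A-scans.

    The brightest pixels of the A-scans at 25% and 75% of the width seed a
    search band.  From each anchor the band walks column-to-column (outward
    to its edge and inward to the midline); per column the brightest of the
    ``n_per_ascan`` top pixels that lies within ``anchor_band_halfwidth``
    rows of the running band center and above the intensity floor is kept,
    and the center moves to it.  Columns below the floor contribute no
    candidate — at the disc this opens the gap that splits the candidates
    into segments (runs separated by more than ``gap_min`` columns).
    """
    img = np.asarray(masked, dtype=np.float64)
    n_depth, width = img.shape
    if n_per_ascan < 1:
        raise ParameterError("n_per_ascan must be >= 1")
    n_top = min(n_per_ascan, n_depth)
    part = np.argpartition(img, n_depth - n_top, axis=0)[n_depth - n_top:]
    top_rows = part  # (n_top, width) candidate rows, unordered
    top_vals = np.take_along_axis(img, top_rows, axis=0)

    c_left, c_right = width // 4, (3 * width) // 4
    global_max = float(img.max())
    peaks = [float(img[:, c].max()) for c in (c_left, c_right)]
    dark = [p < intensity_floor_rel * global_max for p in peaks]
    if all(dark) or global_max <= 0:
        raise SegmentationError(
            "both anchor A-scans (25% and 75% width) are below the intensity floor"
        )
    bright_peaks = [p for p, d in zip(peaks, dark) if not d]
    floor = intensity_floor_rel * float(np.mean(bright_peaks))

    accepted: dict[int, tuple[float, float]] = {}  # col -> (row, intensity)

    def walk(columns: Sequence[int], center: float) -> None:
        for col in columns:
            vals = top_vals[:, col]
            rows = top_rows[:, col].astype(np.float64)
            ok = (vals >= floor) & (np.abs(rows - center) <= anchor_band_halfwidth)
            if not ok.any():
                continue
            vals_ok, rows_ok = vals[ok], rows[ok]
            best = np.lexsort((rows_ok, -vals_ok))[0]  # brightest, tie -> smaller row
            row = float(rows_ok[best])
            prev = accepted.get(col)
            if prev is None or vals_ok[best] > prev[1]:
                accepted[col] = (row, float(vals_ok[best]))
            center = row

    mid = width // 2
    for anchor, is_dark in zip((c_left, c_right), dark):
        if is_dark:
            continue
        seed_row = float(img[:, anchor].argmax())
        if anchor == c_left:
            walk(range(anchor, -1, -1), seed_row)
            walk(range(anchor, mid), seed_row)
        else:
            walk(range(anchor, width), seed_row)
            walk(range(anchor, mid - 1, -1), seed_row)

    cols = np.array(sorted(accepted), dtype=np.int64)
    rows = np.array([accepted[c][0] for c in cols], dtype=np.float64)
    vals = np.array([accepted[c][1] for c in cols], dtype=np.float64)

    segments: list[tuple[int, int]] = []
    if cols.size:
        start = prev_col = int(cols[0])
        for c in cols[1:]:
            if c - prev_col > gap_min:
                segments.append((start, prev_col))
                start = int(c)
            prev_col = int(c)
        segments.append((start, prev_col))

    return RpeCandidates(
        ascans=cols, rows=rows, intensities=vals, segments=segments, width=width
    )


def choose_spline_order(
    n_segments: int, single_segment_order: int = 3, multi_segment_order: int = 2
) -> int:
    """Spline order from the RPE segment count.

    A disc gap splits the candidates into two or more segments; the default
    mapping uses the stiffer order 2 there (extrapolation across the gap is
    more stable at lower order) and order 3 for an uninterrupted band
    (follows the full retinal curvature).  Both mappings are configurable.
    """
    if n_segments < 1:
        raise SegmentationError("no RPE segments detected")
    return multi_segment_order if n_segments >= 2 else single_segment_order


def fit_rpe_spline(
    candidates: RpeCandidates,
    order: int,
    n_knots: int = 5,
    width: int | None = None,
    smooth_penalty: float = 1.0,
) -> tuple[LayerTrace, SplineFit]:
    """Least-squares B-spline through the RPE candidates, full-width.

    Knots are strictly uniform (``n_knots`` interior knots over the scan
    width, continued at the same spacing beyond both ends rather than
    clamped).  A difference penalty of order ``order + 1`` on the
    coefficients (weight ``smooth_penalty``) keeps the normal equations
    well-posed when the disc gap swallows the support of a basis function;
    on a uniform knot grid polynomials up to the spline degree lie in the
    penalty's null space, so exactly polynomial data is reproduced exactly,
    gap included.  The returned trace evaluates the spline at every A-scan
    0..width-1 — the hypothetical RPE extension through the ONH.
    """
    if order not in (2, 3):
        raise ParameterError(f"spline order must be 2 or 3, got {order}")
    if n_knots < 0:
        raise ParameterError("n_knots must be >= 0")
    width = int(width if width is not None else candidates.width)
    x = candidates.ascans.astype(np.float64)
    y = candidates.rows.astype(np.float64)
    n_coef = order + n_knots + 1
    if x.size < n_coef:
        raise SegmentationError(
            f"underdetermined spline fit: {x.size} candidates for {n_coef} "
            "coefficients"
        )
    h = (width - 1.0) / (n_knots + 1)
    t = (np.arange(n_knots + 2 + 2 * order) - order) * h
    interior = t[order + 1 : order + 1 + n_knots]
    B = BSpline.design_matrix(x, t, order).toarray()
    D = np.diff(np.eye(n_coef), n=order + 1, axis=0)
    lhs = B.T @ B + smooth_penalty * (D.T @ D)
    try:
        coef = np.linalg.solve(lhs, B.T @ y)
    except np.linalg.LinAlgError as exc:
        raise SegmentationError(f"singular spline system: {exc}") from exc
    rss = float(np.sum((y - B @ coef) ** 2))
    spline = BSpline(t, coef, order, extrapolate=True)
    xs = np.arange(width, dtype=np.float64)
    trace = LayerTrace(rows=spline(xs), valid_mask=np.ones(width, dtype=bool))
    return trace, SplineFit(order=order, knots=interior, coefficients=coef, rss=rss)


def load_ilm_csv(path: str | Path, n_bscans: int, n_ascans: int) -> list[LayerTrace]:
    """Read device-provided ILM traces: CSV columns (bscan_index, ascan_index, row)."""
    df = pd.read_csv(path)
    required = {"bscan_index", "ascan_index", "row"}
    if not required.issubset(df.columns):
        raise ParameterError(f"ILM CSV must have columns {sorted(required)}")
    traces = []
    for b in range(n_bscans):
        rows = np.zeros(n_ascans)
        valid = np.zeros(n_ascans, dtype=bool)
        sub = df[df["bscan_index"] == b]
        a = sub["ascan_index"].to_numpy(dtype=int)
        rows[a] = sub["row"].to_numpy(dtype=float)
        valid[a] = True
        traces.append(LayerTrace(rows=rows, valid_mask=valid))
    return traces


def segment_bscan(
    bscan: np.ndarray,
    cfg: Mapping[str, Any],
    ilm: LayerTrace | None = None,
) -> tuple[LayerTrace, LayerTrace, SplineFit]:
    """Run the per-B-scan chain: denoise -> ILM -> mask -> candidates -> spline.

    Returns (ilm_filled, rpe_trace, spline_fit); raises SegmentationError on
    failure so volume-level drivers can flag the B-scan.
    """
    den = denoise_bscan(bscan, DenoiseParams.from_config(dict(cfg)))
    if ilm is None:
        ilm = segment_ilm(den, float(cfg["segmentation.ilm_threshold"]))
    if ilm.valid_fraction < 0.5:
        raise SegmentationError(
            f"ILM valid on only {ilm.valid_fraction:.0%} of A-scans (< 50%)"
        )
    masked = mask_upper_layers(den, ilm, float(cfg["segmentation.mask_offset_px"]))
    candidates = detect_rpe_candidates(
        masked,
        n_per_ascan=int(cfg["segmentation.n_per_ascan"]),
        anchor_band_halfwidth=float(cfg["segmentation.band_halfwidth"]),
        gap_min=int(cfg["segmentation.gap_min"]),
        intensity_floor_rel=float(cfg["segmentation.intensity_floor_rel"]),
    )
    order = choose_spline_order(
        candidates.n_segments,
        single_segment_order=int(cfg["segmentation.order_single_segment"]),
        multi_segment_order=int(cfg["segmentation.order_multi_segment"]),
    )
    rpe, fit = fit_rpe_spline(
        candidates,
        order,
        n_knots=int(cfg["segmentation.n_knots"]),
        width=bscan.shape[1],
        smooth_penalty=float(cfg["segmentation.smooth_penalty"]),
    )
    return ilm.filled(), rpe, fit


def segment_volume(
    volume: OCTVolume,
    cfg: Mapping[str, Any] | None = None,
    ilm_traces: Sequence[LayerTrace] | None = None,
) -> VolumeSegmentation:
    """Segment every B-scan of a volume; failures flag the B-scan, not the run."""
    cfg = dict(cfg) if cfg is not None else dict(DEFAULTS)
    if ilm_traces is not None and len(ilm_traces) != volume.n_bscans:
        raise ParameterError("ilm_traces length must equal n_bscans")
    ilm_out: list[LayerTrace] = []
    rpe_out: list[LayerTrace | None] = []
    fits: list[SplineFit | None] = []
    flags: list[dict[str, Any]] = []
    for b in range(volume.n_bscans):
        provided = ilm_traces[b] if ilm_traces is not None else None
        try:
            ilm, rpe, fit = segment_bscan(volume.bscans[b], cfg, ilm=provided)
            ilm_out.append(ilm)
            rpe_out.append(rpe)
            fits.append(fit)
        except SegmentationError as exc:
            width = volume.n_ascans
            ilm_out.append(
                LayerTrace(rows=np.zeros(width), valid_mask=np.zeros(width, bool))
            )
            rpe_out.append(None)
            fits.append(None)
            flags.append({"bscan_index": b, "reason": str(exc)})
    return VolumeSegmentation(ilm=ilm_out, rpe=rpe_out, fits=fits, flags=flags)
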