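"""Reading and writing OCT volumes and quantification reports.

Volumes travel as a multi-page grayscale TIFF (one page per B-scan) or as a
raw little-endian binary block, each with a JSON sidecar declaring grid
dimensions, physical spacings and the stored intensity range.  Vendor
container formats are deliberately not parsed; the sidecar dialect below is
fully documented and device-independent.

Coordinate convention: row index 0 is the top of a B-scan (vitreous side),
depth increases with row index, A-scan index 0 is the left edge, and layer
positions are floating-point row coordinates.  Intensities are normalised to
[0, 1] on load using the declared ``intensity_range``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, MetadataError, ParameterError, ValidationError

SIDECAR_SPACING_KEYS = ("axial_spacing_um", "lateral_spacing_um", "bscan_spacing_um")


@dataclass
class OCTVolume:
    """An ordered stack of B-scans with physical spacing metadata.

    ``bscans`` has shape ``(n_bscans, n_depth, n_ascans)``: rows are axial
    depth, columns are A-scans.  Spacings are in µm per pixel (axial,
    lateral) and µm between consecutive B-scans.
    """

    bscans: np.ndarray
    axial_spacing: float
    lateral_spacing: float
    bscan_spacing: float
    intensity_range: tuple[float, float] = (0.0, 1.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bscans = np.asarray(self.bscans)
        if self.bscans.ndim != 3:
            raise ValidationError(
                f"bscans must be a 3D (n_bscans, n_depth, n_ascans) array, "
                f"got ndim={self.bscans.ndim}"
            )
        n_b, n_d, n_a = self.bscans.shape
        if n_b < 1 or n_a < 8 or n_d < 8:
            raise ValidationError(
                f"volume too small: n_bscans={n_b}, n_depth={n_d}, n_ascans={n_a} "
                "(need n_bscans>=1, n_depth>=8, n_ascans>=8)"
            )
        for name in ("axial_spacing", "lateral_spacing", "bscan_spacing"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        lo, hi = self.intensity_range
        if not hi > lo:
            raise ValidationError("intensity_range must satisfy max > min")

    @property
    def n_bscans(self) -> int:
        return self.bscans.shape[0]

    @property
    def n_depth(self) -> int:
        return self.bscans.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.bscans.shape[2]


@dataclass
class OnhReport:
    """Result of quantifying one ONH volume scan.

    ``onhv_mm3`` is the edema volume above the thresholded reference plane;
    ``onhh_mm`` the maximum ILM elevation above the fitted RPE.  The
    per-B-scan ``area_profile_mm2`` integrates to ``onhv_mm3`` via the
    B-scan spacing.
    """

    onhv_mm3: float
    onhh_mm: float
    area_profile_mm2: list[float]
    threshold_px: float
    config_digest: str
    per_bscan_flags: list[dict[str, Any]] = field(default_factory=list)
    bscan_spacing_um: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.onhv_mm3 < 0 or self.onhh_mm < 0:
            raise ValidationError("onhv_mm3 and onhh_mm must be non-negative")
        if any(a < 0 for a in self.area_profile_mm2):
            raise ValidationError("area profile entries must be non-negative")
        n_meta = self.meta.get("n_bscans")
        if n_meta is not None and n_meta != len(self.area_profile_mm2):
            raise ValidationError(
                f"area profile has {len(self.area_profile_mm2)} entries but meta "
                f"declares n_bscans={n_meta}"
            )
        if self.bscan_spacing_um > 0:
            expect = sum(self.area_profile_mm2) * self.bscan_spacing_um * 1e-3
            if not math.isclose(expect, self.onhv_mm3, rel_tol=1e-9, abs_tol=1e-12):
                raise ValidationError(
                    f"onhv_mm3={self.onhv_mm3} inconsistent with area profile sum "
                    f"({expect})"
                )


def _read_sidecar(path: Path) -> dict[str, Any]:
    if not path.exists():
        raise MetadataError(f"sidecar file not found: {path}")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"sidecar {path} is not valid JSON: {exc}") from exc


def _spacings_from(meta: dict[str, Any]) -> tuple[float, float, float]:
    missing = [k for k in SIDECAR_SPACING_KEYS if k not in meta]
    if missing:
        raise MetadataError(f"sidecar missing spacing keys: {missing}")
    return tuple(float(meta[k]) for k in SIDECAR_SPACING_KEYS)  # type: ignore[return-value]


def _normalise(stack: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    lo, hi = float(rng[0]), float(rng[1])
    stack = stack.astype(np.float32)
    if (lo, hi) != (0.0, 1.0):
        stack = (stack - lo) / (hi - lo)
    return stack


def default_sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def load_volume(
    path: str | Path,
    format: str = "tiff_stack",
    sidecar: str | Path | None = None,
) -> OCTVolume:
    """Load a volume from ``tiff_stack`` or ``raw`` (+ JSON sidecar).

    The sidecar declares physical spacings, the stored intensity range and,
    for raw blocks, the grid dimensions and dtype.  Declared and actual
    element counts must match exactly; mismatches raise rather than truncate.
    """
    path = Path(path)
    if not path.exists():
        raise MetadataError(f"input volume not found: {path}")
    sidecar_path = Path(sidecar) if sidecar else default_sidecar_path(path)
    meta = _read_sidecar(sidecar_path)
    spacings = _spacings_from(meta)
    intensity_range = tuple(meta.get("intensity_range", (0.0, 1.0)))

    if format == "tiff_stack":
        try:
            stack = tifffile.imread(path)
        except Exception as exc:  # ragged pages, truncated file...
            raise FormatError(f"could not read TIFF stack {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise FormatError(
                f"TIFF stack must hold 2D grayscale pages, got shape {stack.shape}"
            )
        for key, axis in (("n_bscans", 0), ("n_depth", 1), ("n_ascans", 2)):
            if key in meta and int(meta[key]) != stack.shape[axis]:
                raise MetadataError(
                    f"sidecar declares {key}={meta[key]} but stack has "
                    f"{stack.shape[axis]}"
                )
    elif format == "raw":
        for key in ("n_bscans", "n_depth", "n_ascans"):
            if key not in meta:
                raise MetadataError(f"raw sidecar missing dimension key: {key}")
        shape = (int(meta["n_bscans"]), int(meta["n_depth"]), int(meta["n_ascans"]))
        dtype_name = meta.get("dtype", "float32")
        if dtype_name not in ("float32", "uint8"):
            raise FormatError(f"unsupported raw dtype: {dtype_name}")
        dtype = np.dtype(dtype_name).newbyteorder("<")
        expected = int(np.prod(shape)) * dtype.itemsize
        data = path.read_bytes()
        if len(data) != expected:
            raise MetadataError(
                f"raw file holds {len(data)} bytes but sidecar dimensions imply "
                f"{expected}"
            )
        stack = np.frombuffer(data, dtype=dtype).reshape(shape)
        if dtype_name == "uint8" and "intensity_range" not in meta:
            intensity_range = (0.0, 255.0)
    else:
        raise ParameterError(
            f"unknown volume format: {format!r} (use 'tiff_stack' or 'raw')"
        )

    stack = _normalise(stack, intensity_range)
    return OCTVolume(
        bscans=stack,
        axial_spacing=spacings[0],
        lateral_spacing=spacings[1],
        bscan_spacing=spacings[2],
        intensity_range=(0.0, 1.0),
        meta={"source": str(path), **{k: meta[k] for k in meta if k.startswith("_")}},
    )


def save_volume(
    volume: OCTVolume,
    path: str | Path,
    format: str = "tiff_stack",
    sidecar: str | Path | None = None,
) -> None:
    """Write a volume plus its JSON sidecar (intensities stored as float32)."""
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar else default_sidecar_path(path)
    stack = volume.bscans.astype(np.float32)
    if format == "tiff_stack":
        tifffile.imwrite(path, stack, photometric="minisblack")
    elif format == "raw":
        path.write_bytes(stack.astype("<f4").tobytes())
    else:
        raise ParameterError(
            f"unknown volume format: {format!r} (use 'tiff_stack' or 'raw')"
        )
    meta = {
        "n_bscans": volume.n_bscans,
        "n_depth": volume.n_depth,
        "n_ascans": volume.n_ascans,
        "axial_spacing_um": volume.axial_spacing,
        "lateral_spacing_um": volume.lateral_spacing,
        "bscan_spacing_um": volume.bscan_spacing,
        "intensity_range": list(volume.intensity_range),
        "dtype": "float32",
    }
    sidecar_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def _report_dict(report: OnhReport) -> dict[str, Any]:
    return {
        "onhv_mm3": report.onhv_mm3,
        "onhh_mm": report.onhh_mm,
        "area_profile_mm2": list(report.area_profile_mm2),
        "threshold_px": report.threshold_px,
        "config_digest": report.config_digest,
        "per_bscan_flags": report.per_bscan_flags,
        "bscan_spacing_um": report.bscan_spacing_um,
        "meta": report.meta,
    }


def save_report(report: OnhReport, path: str | Path, format: str = "json") -> None:
    """Serialise a report as canonical JSON or flat CSV.

    JSON is byte-stable (sorted keys, fixed separators) and round-trips all
    numeric fields to full precision.
    """
    report.validate()
    path = Path(path)
    if format == "json":
        blob = json.dumps(_report_dict(report), sort_keys=True, indent=2)
        path.write_text(blob + "\n")
    elif format == "csv":
        flagged = {f["bscan_index"] for f in report.per_bscan_flags}
        rows = [
            {
                "record": "bscan",
                "index": i,
                "name": "area_mm2",
                "value": a,
                "flagged": int(i in flagged),
            }
            for i, a in enumerate(report.area_profile_mm2)
        ]
        for name, value in (
            ("onhv_mm3", report.onhv_mm3),
            ("onhh_mm", report.onhh_mm),
            ("threshold_px", report.threshold_px),
            ("bscan_spacing_um", report.bscan_spacing_um),
        ):
            rows.append(
                {"record": "summary", "index": "", "name": name, "value": value,
                 "flagged": ""}
            )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ParameterError(f"unknown report format: {format!r}")


def load_report(path: str | Path) -> OnhReport:
    """Load a JSON report back into an :class:`OnhReport`."""
    data = json.loads(Path(path).read_text())
    report = OnhReport(
        onhv_mm3=data["onhv_mm3"],
        onhh_mm=data["onhh_mm"],
        area_profile_mm2=list(data["area_profile_mm2"]),
        threshold_px=data["threshold_px"],
        config_digest=data["config_digest"],
        per_bscan_flags=data.get("per_bscan_flags", []),
        bscan_spacing_um=data.get("bscan_spacing_um", 0.0),
        meta=data.get("meta", {}),
    )
    report.validate()
    return report
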