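"""Readers and writers for the formats the pipeline exchanges.

Force curves travel as two- or three-column plain text (``#`` comments);
images as TIFF with a YAML sidecar declaring channel roles, pixel size
and frame interval; masks as 8-bit TIFF; results as tidy CSV with
locale-independent, unit-suffixed column names; ground-truth and fit
records as JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import (
    CantileverCalibration,
    CellMechanicsSummary,
    ForceCurve,
    MechanicalEstimate,
)
from .morphometry import ImageFrame

__all__ = [
    "read_force_curve",
    "write_force_curve",
    "read_calibration",
    "write_calibration",
    "ESTIMATE_COLUMNS",
    "write_estimates_csv",
    "read_estimates_csv",
    "write_summaries_csv",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_polyline_csv",
    "read_polyline_csv",
    "write_json",
    "read_json",
]


# ---------------------------------------------------------------------------
# force curves & calibration
# ---------------------------------------------------------------------------

def read_force_curve(
    path,
    calibration: CantileverCalibration,
    cell_id: str = "",
    curve_id: str = "",
) -> ForceCurve:
    """Read a plain-text force curve.

    Two numeric columns are (z_nm, deflection_nm); three columns are
    (z_nm, detector_V, ...) and the calibration's deflection sensitivity
    converts volts to nm.  Lines starting with ``#`` are comments; the
    delimiter may be whitespace or commas.
    """
    path = Path(path)
    data = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 numeric columns")
    z = data[:, 0]
    if data.shape[1] >= 3:
        if calibration.deflection_sensitivity is None:
            raise ValueError(
                f"{path}: 3-column (detector V) file needs a deflection sensitivity"
            )
        d = data[:, 1] * calibration.deflection_sensitivity
    else:
        d = data[:, 1]
    if not curve_id:
        curve_id = path.stem
    return ForceCurve(z=z, d=d, calibration=calibration, cell_id=cell_id, curve_id=curve_id)


def _is_whitespace(path: Path) -> bool:
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            return "," not in line
    return True


def write_force_curve(curve: ForceCurve, path, header: str = "") -> None:
    """Write (z_nm, deflection_nm) columns with ``#`` header comments."""
    path = Path(path)
    lines = ["# z_nm deflection_nm"]
    if header:
        lines = [f"# {header}"] + lines
    for z, d in zip(curve.z, curve.d):
        lines.append(f"{z:.6f} {d:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_calibration(path) -> CantileverCalibration:
    """YAML calibration record: spring_constant_N_per_m, optional
    deflection_sensitivity_nm_per_V, optional label."""
    with open(path) as fh:
        rec = yaml.safe_load(fh)
    return CantileverCalibration(
        spring_constant=float(rec["spring_constant_N_per_m"]),
        deflection_sensitivity=(
            float(rec["deflection_sensitivity_nm_per_V"])
            if rec.get("deflection_sensitivity_nm_per_V") is not None
            else None
        ),
        label=str(rec.get("label", "")),
    )


def write_calibration(cal: CantileverCalibration, path) -> None:
    rec = {
        "spring_constant_N_per_m": cal.spring_constant,
        "deflection_sensitivity_nm_per_V": cal.deflection_sensitivity,
        "label": cal.label,
    }
    Path(path).write_text(yaml.safe_dump(rec, sort_keys=False))


# ---------------------------------------------------------------------------
# estimate tables
# ---------------------------------------------------------------------------

ESTIMATE_COLUMNS = [
    "cell_id", "curve_id", "contact_z0_nm", "slope", "r2",
    "accepted", "reason", "T_mN_per_m", "P_Pa",
]


def write_estimates_csv(estimates: Sequence[MechanicalEstimate], path) -> pd.DataFrame:
    """Per-curve results in a stable column order; tension in mN/m."""
    rows = []
    for e in estimates:
        rows.append({
            "cell_id": e.cell_id,
            "curve_id": e.curve_id,
            "contact_z0_nm": e.contact_z0,
            "slope": e.slope,
            "r2": e.r_squared,
            "accepted": e.accepted,
            "reason": e.reason,
            "T_mN_per_m": e.tension * 1e3 if math.isfinite(e.tension) else math.nan,
            "P_Pa": e.pressure,
        })
    df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_estimates_csv(path) -> list[MechanicalEstimate]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        T = row["T_mN_per_m"]
        out.append(MechanicalEstimate(
            cell_id=str(row["cell_id"]),
            curve_id=str(row["curve_id"]),
            contact_z0=float(row["contact_z0_nm"]),
            slope=float(row["slope"]),
            r_squared=float(row["r2"]),
            accepted=bool(row["accepted"]),
            reason=str(row["reason"]),
            tension=float(T) * 1e-3 if pd.notna(T) else math.nan,
            pressure=float(row["P_Pa"]) if pd.notna(row["P_Pa"]) else math.nan,
        ))
    return out


def write_summaries_csv(summaries: Sequence[CellMechanicsSummary], path) -> pd.DataFrame:
    rows = [{
        "cell_id": s.cell_id,
        "n_curves_total": s.n_curves_total,
        "n_curves_accepted": s.n_curves_accepted,
        "T_mean_mN_per_m": s.tension_mean * 1e3 if math.isfinite(s.tension_mean) else math.nan,
        "T_sd_mN_per_m": s.tension_sd * 1e3 if math.isfinite(s.tension_sd) else math.nan,
        "P_mean_Pa": s.pressure_mean,
        "P_sd_Pa": s.pressure_sd,
    } for s in summaries]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# images, masks, polylines
# ---------------------------------------------------------------------------

def write_image(frame: ImageFrame, tiff_path, meta_path: Optional[str] = None) -> None:
    """Multi-channel TIFF plus a YAML sidecar with roles and pixel size."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, frame.data.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_um": frame.pixel_size,
        "channel_roles": dict(frame.channel_roles),
        "timestamp_s": frame.timestamp,
    }
    if meta_path is None:
        meta_path = tiff_path.with_suffix(".yaml")
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_image(tiff_path, meta_path: Optional[str] = None) -> ImageFrame:
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    if meta_path is None:
        meta_path = tiff_path.with_suffix(".yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    return ImageFrame(
        data=data,
        pixel_size=float(meta["pixel_size_um"]),
        channel_roles={str(k): int(v) for k, v in (meta.get("channel_roles") or {}).items()},
        timestamp=meta.get("timestamp_s"),
    )


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_polyline_csv(polyline: np.ndarray, path) -> None:
    """CSV of (row, col) vertices."""
    pd.DataFrame(np.asarray(polyline), columns=["row", "col"]).to_csv(path, index=False)


def read_polyline_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["row", "col"]].to_numpy()


# ---------------------------------------------------------------------------
# JSON records
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(record: Dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(record), indent=2, sort_keys=True) + "\n")


def read_json(path) -> Dict:
    return json.loads(Path(path).read_text())
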