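"""AFM force-curve inversion to cortical tension and intracellular pressure.

A rounded, non-adherent cell gently compressed by a soft tipless cantilever
deforms while its actomyosin cortex resists with an in-plane tension ``T``.
A vertical force balance between the cantilever load, the cortical tension
and the intracellular hydrostatic pressure gives, for a Z-piezo extension
``Z`` beyond the contact point and cantilever deflection ``d``,

    T = k_c / (pi * (Z/d - 1))

with ``k_c`` the cantilever spring constant.  Writing the post-contact
deflection slope ``s = d / (Z - Z0)`` (dimensionless, 0 <= s < 1) this is

    T = k_c * s / (pi * (1 - s))

and Laplace's law relates tension to the excess hydrostatic pressure of a
spherical cell of radius ``R``:

    P = 2 T / R.

The pipeline is: contact-point detection on the approach curve, a
through-origin linear fit of deflection vs post-contact extension over a
0-400 nm window, an R^2 >= 0.9 quality gate, conversion of the slope to
tension and pressure, and per-cell aggregation over ~10 repeat curves.

Units: curve coordinates (z, d) are in nm; ``k_c`` in N/m; because the
slope is dimensionless the tension comes out directly in N/m, and with the
cell radius in metres the pressure is in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateBaseline,
    InsufficientPoints,
    NoContact,
    RigidContact,
)

__all__ = [
    "CantileverCalibration",
    "ForceCurve",
    "CellGeometry",
    "MechanicalEstimate",
    "CellMechanicsSummary",
    "AfmConfig",
    "detect_contact_point",
    "fit_deflection_slope",
    "tension_from_slope",
    "pressure_from_tension",
    "analyze_curve",
    "summarize_cell",
]

#: slopes closer to 1 than this are treated as rigid contact to avoid the
#: singularity of the force balance
_RIGID_TOL = 1e-6

_MIN_SAMPLES = 16
_MIN_FIT_POINTS = 8


@dataclass(frozen=True)
class CantileverCalibration:
    """Cantilever calibration record.

    Parameters
    ----------
    spring_constant : float
        Effective spring constant k_c in N/m (thermal-noise calibrated;
        typical soft tipless levers are 0.08-0.11 N/m).
    deflection_sensitivity : float, optional
        nm of deflection per raw detector unit (V).  Only needed when
        curves carry raw photodetector readings instead of nm.
    label : str
        Free-text identifier of the lever.
    """

    spring_constant: float
    deflection_sensitivity: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be > 0")
        if self.deflection_sensitivity is not None and not self.deflection_sensitivity > 0:
            raise ValueError("deflection_sensitivity must be > 0 when given")


@dataclass
class ForceCurve:
    """One AFM approach ramp: Z-piezo extension vs cantilever deflection.

    ``z`` and ``d`` are in nm.  On construction the samples are sorted by
    z, exact duplicate z values are averaged, and basic sanity checks run.
    """

    z: np.ndarray
    d: np.ndarray
    calibration: CantileverCalibration
    cell_id: str = ""
    curve_id: str = ""

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if z.ndim != 1 or d.ndim != 1 or z.shape != d.shape:
            raise ValueError("z and d must be 1-D arrays of equal length")
        if not (np.isfinite(z).all() and np.isfinite(d).all()):
            raise ValueError("z and d must be finite")
        order = np.argsort(z, kind="stable")
        z, d = z[order], d[order]
        # average deflection over exact duplicate z samples
        zu, inverse, counts = np.unique(z, return_inverse=True, return_counts=True)
        if len(zu) < len(z):
            dsum = np.zeros(len(zu))
            np.add.at(dsum, inverse, d)
            z, d = zu, dsum / counts
        if len(z) < _MIN_SAMPLES:
            raise ValueError(f"force curve needs >= {_MIN_SAMPLES} distinct samples")
        self.z, self.d = z, d

    def __len__(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class CellGeometry:
    """Cell radius (m) measured from bright-field images; optional cortex
    thickness (m, informational only)."""

    radius: float
    cortex_thickness: Optional[float] = None

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.cortex_thickness is not None and not (
            0 < self.cortex_thickness < 2 * self.radius
        ):
            raise ValueError("cortex_thickness must be in (0, 2R)")


@dataclass
class MechanicalEstimate:
    """Per-curve inversion result.

    Tension (N/m) and pressure (Pa) are populated only when ``accepted``;
    rejected curves carry a machine-readable ``reason`` code instead of
    raising.
    """

    cell_id: str = ""
    curve_id: str = ""
    contact_z0: float = math.nan           # nm
    slope: float = math.nan                # dimensionless
    r_squared: float = math.nan
    tension: float = math.nan              # N/m
    pressure: float = math.nan             # Pa
    n_fit_points: int = 0
    accepted: bool = False
    reason: str = ""


@dataclass
class CellMechanicsSummary:
    """Per-cell aggregate over accepted curves (arithmetic mean and SD)."""

    cell_id: str
    n_curves_total: int
    n_curves_accepted: int
    tension_mean: float = math.nan
    tension_sd: float = math.nan
    pressure_mean: float = math.nan
    pressure_sd: float = math.nan


@dataclass(frozen=True)
class AfmConfig:
    """Tunable parameters of the curve-analysis pipeline.

    ``noise_window`` first samples estimate the baseline; contact is the
    first run of ``persistence`` samples exceeding mean + k_sigma*SD, then
    refined by extrapolating a post-contact line back to the baseline
    level.  The slope fit spans 0 < z - z0 <= ``fit_window_nm`` and curves
    with R^2 below ``r2_min`` are rejected, as are slopes >= 1 (rigid).
    """

    noise_window: int = 64
    k_sigma: float = 3.0
    persistence: int = 8
    fit_window_nm: float = 400.0
    r2_min: float = 0.9
    refine_contact: bool = True


def detect_contact_point(
    curve: ForceCurve,
    noise_window: int = 64,
    k_sigma: float = 3.0,
    persistence: int = 8,
    refine: bool = True,
) -> float:
    """Locate the piezo extension at which the lever first touches the cell.

    Baseline mean and SD come from the first ``noise_window`` samples.  The
    coarse contact index is the first sample from which the deflection
    stays above mean + k_sigma*SD for ``persistence`` consecutive samples.
    Because at shallow slopes the threshold is crossed well after true
    contact, the estimate is then refined (``refine=True``) by fitting a
    line to the post-crossing segment and extrapolating it back to the
    baseline level; on noiseless piecewise-linear curves this recovers the
    breakpoint exactly.

    Returns the contact Z0 in nm.

    Raises
    ------
    NoContact
        if the deflection never persistently exceeds the threshold.
    DegenerateBaseline
        if the baseline SD is zero and the deflection never rises.
    """
    n = len(curve)
    if not 0 < noise_window < n / 2:
        raise ValueError("noise_window must be in (0, len(curve)/2)")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    z, d = curve.z, curve.d
    base = d[:noise_window]
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    thresh = mu + k_sigma * sd

    above = d > thresh
    # first index starting a run of `persistence` True values
    idx = _first_run(above, persistence)
    if idx is None:
        if sd == 0.0:
            raise DegenerateBaseline("flat baseline and deflection never rises")
        raise NoContact("deflection never persistently exceeds baseline threshold")

    z_cross = float(z[idx])
    if not refine:
        return z_cross

    # refine: line through the rising segment, extrapolated back to the
    # baseline level; iterate so the fit window re-anchors at the refined
    # estimate, shrinking the extrapolation distance (the threshold is
    # crossed well after contact at shallow slopes)
    span = 400.0
    z0 = z_cross
    for _ in range(3):
        sel = (z >= z0) & (z <= z0 + span)
        if sel.sum() < 3:
            break
        b, a = np.polyfit(z[sel], d[sel], 1)  # d = a + b z
        if b <= 0:
            break
        # keep the refinement inside [start of curve, coarse crossing]
        z0 = float(min(max((mu - a) / b, z[0]), z_cross))
    return z0


def _first_run(mask: np.ndarray, run: int) -> Optional[int]:
    """Index of the first run of `run` consecutive True values, else None."""
    if run == 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    conv = np.convolve(mask.astype(int), np.ones(run, dtype=int), mode="valid")
    hits = np.flatnonzero(conv == run)
    return int(hits[0]) if hits.size else None


def fit_deflection_slope(
    curve: ForceCurve,
    contact_z0: float,
    fit_window: float = 400.0,
) -> tuple[float, float, int]:
    """Through-origin OLS of deflection on post-contact extension.

    Uses samples with 0 < z - contact_z0 <= fit_window.  The force balance
    implies d is proportional to (z - z0) after contact, so the regression
    is constrained through the origin; R^2 is the through-origin
    coefficient of determination 1 - SS_res / sum(d^2).

    Returns (slope, r_squared, n_fit_points).
    """
    if not curve.z[0] <= contact_z0 <= curve.z[-1]:
        raise ValueError("contact_z0 outside the curve z-range")
    x = curve.z - contact_z0
    sel = (x > 0) & (x <= fit_window)
    npts = int(sel.sum())
    if npts < _MIN_FIT_POINTS:
        raise InsufficientPoints(
            f"{npts} samples in the fit window, need >= {_MIN_FIT_POINTS}"
        )
    xx, dd = x[sel], curve.d[sel]
    sxx = float(xx @ xx)
    slope = float(xx @ dd) / sxx
    ss_res = float(np.sum((dd - slope * xx) ** 2))
    ss_tot = float(dd @ dd)
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, r2, npts


def tension_from_slope(s: float, k_c: float) -> float:
    """Cortical tension from the post-contact deflection slope.

    T = k_c * s / (pi * (1 - s)); equivalently k_c / (pi * (Z/d - 1)) with
    Z measured from contact.  Strictly increasing in s on [0, 1) and in
    k_c; T = 0 iff s = 0.

    Raises RigidContact for s >= 1 - 1e-6 (deflection tracks the piezo and
    the soft-contact model is invalid).
    """
    if not k_c > 0:
        raise ValueError("k_c must be > 0")
    if s < 0:
        raise ValueError("slope must be >= 0")
    if s >= 1.0 - _RIGID_TOL:
        raise RigidContact(f"slope {s} >= 1: sample rigid on the lever scale")
    return k_c * s / (math.pi * (1.0 - s))


def pressure_from_tension(T: float, geometry: CellGeometry) -> float:
    """Intracellular pressure from Laplace's law, P = 2T/R (Pa)."""
    if T < 0:
        raise ValueError("tension must be >= 0")
    return 2.0 * T / geometry.radius


def analyze_curve(
    curve: ForceCurve,
    geometry: CellGeometry,
    config: AfmConfig = AfmConfig(),
) -> MechanicalEstimate:
    """Full per-curve inversion with quality control.

    Composes contact detection, the windowed slope fit, the R^2 >= r2_min
    gate and the tension/pressure conversion.  Failures (no contact, too
    few fit points, low R^2, rigid or negative slope) yield
    ``accepted=False`` with a reason code rather than an exception, so
    slip-corrupted or noisy curves are simply filtered out of per-cell
    statistics.
    """
    est = MechanicalEstimate(cell_id=curve.cell_id, curve_id=curve.curve_id)
    try:
        z0 = detect_contact_point(
            curve,
            noise_window=config.noise_window,
            k_sigma=config.k_sigma,
            persistence=config.persistence,
            refine=config.refine_contact,
        )
    except DegenerateBaseline:
        est.reason = "degenerate_baseline"
        return est
    except NoContact:
        est.reason = "no_contact"
        return est
    est.contact_z0 = z0

    try:
        s, r2, npts = fit_deflection_slope(curve, z0, config.fit_window_nm)
    except InsufficientPoints:
        est.reason = "insufficient_points"
        return est
    est.slope, est.r_squared, est.n_fit_points = s, r2, npts

    if s < 0:
        est.reason = "negative_slope"
        return est
    if r2 < config.r2_min:
        est.reason = "low_r2"
        return est
    try:
        T = tension_from_slope(s, curve.calibration.spring_constant)
    except RigidContact:
        est.reason = "rigid_contact"
        return est

    est.tension = T
    est.pressure = pressure_from_tension(T, geometry)
    est.accepted = True
    est.reason = "ok"
    return est


def summarize_cell(
    estimates: Sequence[MechanicalEstimate],
    cell_id: str = "",
) -> CellMechanicsSummary:
    """Aggregate repeat curves of one cell: mean and SD over accepted only.

    With zero accepted curves the means/SDs stay NaN; with one accepted
    curve the SD is 0 by convention.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    if not cell_id:
        cell_id = estimates[0].cell_id
    acc = [e for e in estimates if e.accepted]
    out = CellMechanicsSummary(
        cell_id=cell_id,
        n_curves_total=len(estimates),
        n_curves_accepted=len(acc),
    )
    if acc:
        T = np.array([e.tension for e in acc])
        P = np.array([e.pressure for e in acc])
        out.tension_mean = float(T.mean())
        out.pressure_mean = float(P.mean())
        out.tension_sd = float(T.std(ddof=1)) if len(acc) > 1 else 0.0
        out.pressure_sd = float(P.std(ddof=1)) if len(acc) > 1 else 0.0
    return out
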