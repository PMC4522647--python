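"""Seeded ground-truth generators for every pipeline stage.

Each generator forward-models the physics or imaging process the
corresponding analysis inverts, and returns the data together with a
machine-readable ground-truth record, so recovery can be verified without
any external download:

* force curves obeying the cantilever force balance (post-contact
  deflection slope s = pi*T / (pi*T + k_c)), with deflection noise,
  optional baseline tilt and slip artifacts;
* images of a round cell body with a cortical rim plus an attached
  sausage-shaped leader bleb carrying a configurable axial intensity
  gradient and an oriented stripe texture;
* dual-Gaussian line scans across the cell edge;
* FRET donor/acceptor stacks with a known activity map, mono-exponential
  photobleaching and a drifting background;
* photoconversion series following two-compartment first-order exchange.

Defaults mirror the measured operating regime of the AFM assay
(k_c in 0.08-0.11 N/m, 4 um ramps, peak forces of order 1 nN) and typical
confocal sampling.  All randomness flows from an explicit seed or
numpy Generator per call; identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Union

import numpy as np

from .afm import CantileverCalibration, ForceCurve
from .morphometry import BlebSegmentation, ImageFrame, LineScan
from .ratiometric import RatioStack

__all__ = [
    "SimulationConfig",
    "SCENARIOS",
    "gen_force_curve",
    "gen_cell_image",
    "gen_linescan",
    "gen_fret_stack",
    "gen_photoconversion",
]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Named, seeded bundle of generator parameters.

    ``params`` are forwarded to the generator of ``kind``; the record is
    serialisable so every simulated dataset can be regenerated exactly.
    """

    seed: int
    scenario: str = "control"
    kind: str = "force_curve"
    params: Dict = field(default_factory=dict)

    def as_dict(self) -> Dict:
        return asdict(self)


#: Illustrative condition presets for the AFM scenario grid: a control,
#: a contractility-inhibited ("blebbistatin-like") and a knockdown-like
#: reduced-tension condition.  The tension values are plausible for
#: rounded melanoma cells, not measured ones.
SCENARIOS: Dict[str, Dict[str, float]] = {
    "control": {"tension": 1.0e-3, "radius_um": 10.0},
    "blebbistatin-like": {"tension": 0.3e-3, "radius_um": 10.0},
    "knockdown-like": {"tension": 0.6e-3, "radius_um": 10.0},
}


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def gen_force_curve(
    tension: float = 1.0e-3,
    spring_constant: float = 0.1,
    contact_z0_nm: float = 3600.0,
    ramp_nm: float = 4000.0,
    n_samples: int = 2048,
    noise_sd_nm: float = 0.5,
    baseline_tilt_nm_per_um: float = 0.0,
    slip: bool = False,
    slip_fraction: float = 0.5,
    slip_window_nm: float = 400.0,
    slip_pos_range: tuple = (0.25, 0.75),
    seed: RngLike = None,
    cell_id: str = "sim",
    curve_id: str = "0",
) -> tuple[ForceCurve, Dict]:
    """Forward-model one AFM approach curve from the cortical force balance.

    Post-contact the deflection follows d = s*(z - Z0) with
    s = pi*T / (pi*T + k_c), zero before contact, plus additive Gaussian
    deflection noise and an optional linear baseline tilt.  With
    ``slip=True`` the deflection drops abruptly by
    ``slip_fraction * s * slip_window_nm`` at a random position inside the
    fit window, emulating cantilever slippage on a weakly adhered cell —
    an artifact the R^2 quality gate must reject.

    Returns (ForceCurve, truth) where truth records T, k_c, Z0, the exact
    slope and the artifact parameters.
    """
    if not tension > 0:
        raise ValueError("tension must be > 0")
    if not 0 < contact_z0_nm < ramp_nm:
        raise ValueError("contact_z0_nm must lie inside the ramp")
    rng = _rng(seed)
    s = math.pi * tension / (math.pi * tension + spring_constant)
    z = np.linspace(0.0, ramp_nm, n_samples)
    d = s * np.clip(z - contact_z0_nm, 0.0, None)
    d += baseline_tilt_nm_per_um * z / 1000.0
    truth = {
        "tension_N_per_m": tension,
        "spring_constant_N_per_m": spring_constant,
        "contact_z0_nm": contact_z0_nm,
        "slope": s,
        "noise_sd_nm": noise_sd_nm,
        "slip": bool(slip),
    }
    if slip:
        lo, hi = slip_pos_range
        z_slip = contact_z0_nm + rng.uniform(lo, hi) * slip_window_nm
        drop = slip_fraction * s * slip_window_nm
        d = np.where(z >= z_slip, d - drop, d)
        truth["slip_z_nm"] = float(z_slip)
        truth["slip_drop_nm"] = float(drop)
    if noise_sd_nm > 0:
        d = d + rng.normal(0.0, noise_sd_nm, size=n_samples)
    curve = ForceCurve(
        z=z, d=d,
        calibration=CantileverCalibration(spring_constant=spring_constant),
        cell_id=cell_id, curve_id=curve_id,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------

def _linear_bin_means(n_bins: int) -> np.ndarray:
    """Exact per-bin means of a 1 -> 0 linear ramp over equal fifths."""
    j = np.arange(n_bins)
    return 1.0 - (j + 0.5) / n_bins


def gen_cell_image(
    shape: tuple = (256, 512),
    pixel_size_um: float = 0.1,
    body_center: tuple = (128, 80),
    body_radius: int = 60,
    neck_half_width: int = 10,
    neck_length: int = 20,
    bleb_half_width: int = 35,
    bleb_length: int = 200,
    cap_style: str = "flat",
    gradient: str = "linear",
    body_level: float = 0.5,
    background_level: float = 0.05,
    rim_amplitude: float = 1.0,
    rim_width: int = 3,
    fibril_angle_deg: Optional[float] = None,
    stripe_period_px: float = 16.0,
    noise_sd: float = 0.0,
    seed: RngLike = None,
) -> tuple[ImageFrame, BlebSegmentation, Dict]:
    """Render a confined blebbing cell with exact ground truth.

    Geometry: a disk cell body, a short narrow neck, and an elongated
    sausage-shaped leader bleb extending along +x (columns), with either
    flat or rounded caps.  Channels:

    * ``gradient`` — bleb filled with a configurable axial profile
      (``"linear"`` ramps 1 -> 0 from neck to tip as a function of the
      pixel-centre arclength fraction; ``"uniform"`` is constant 1),
      body at ``body_level``, everything over ``background_level``;
    * ``cortex_stain`` — cytoplasm at ``body_level`` with a bright rim of
      amplitude ``rim_amplitude`` above it along the body cortex;
    * ``texture`` (when ``fibril_angle_deg`` is set) — sinusoidal stripes
      inside the bleb whose crests run along the requested fibril angle
      (degrees from the +x axis, positive toward +y/rows).
    * ``fill`` — binary-ish cell silhouette for segmentation tests.

    Returns (ImageFrame, ground-truth BlebSegmentation, truth record with
    analytic bin means, rim levels and texture orientation).
    """
    if not neck_half_width < bleb_half_width < body_radius:
        raise ValueError("need neck_half_width < bleb_half_width < body_radius")
    rng = _rng(seed)
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = body_center

    body = (rr - cy) ** 2 + (cc - cx) ** 2 <= body_radius ** 2
    neck_x0 = cx + body_radius - 2  # slight overlap so the shape is connected
    neck_x1 = neck_x0 + neck_length
    neck = (
        (cc >= neck_x0) & (cc < neck_x1) & (np.abs(rr - cy) <= neck_half_width)
    ) & ~body
    bleb_x0 = neck_x1
    bleb_x1 = bleb_x0 + bleb_length  # exclusive
    if bleb_x1 > W:
        raise ValueError("bleb extends past the image; enlarge shape")
    if cap_style == "flat":
        bleb = (cc >= bleb_x0) & (cc < bleb_x1) & (np.abs(rr - cy) <= bleb_half_width)
    elif cap_style == "round":
        core_x1 = bleb_x1 - bleb_half_width
        core = (cc >= bleb_x0) & (cc < core_x1) & (np.abs(rr - cy) <= bleb_half_width)
        cap = (rr - cy) ** 2 + (cc - (core_x1 - 1)) ** 2 <= bleb_half_width ** 2
        bleb = core | (cap & (cc >= core_x1))
    else:
        raise ValueError("cap_style must be 'flat' or 'round'")
    bleb &= ~body

    # bleb is considered to include its neck-side attachment; the neck
    # corridor itself belongs to neither mask (transition zone)
    axis_cols = np.arange(bleb_x0, bleb_x0 + bleb_length)
    if cap_style == "round":
        axis_cols = axis_cols[axis_cols < bleb_x1]
    axis = np.column_stack([np.full(len(axis_cols), cy), axis_cols]).astype(int)
    neck_point = (int(cy), int(bleb_x0))

    # axial profile as a function of pixel-centre arclength fraction
    L = bleb_length
    t_of_col = (cc - bleb_x0 + 0.5) / L
    if gradient == "linear":
        profile = np.clip(1.0 - t_of_col, 0.0, 1.0)
        bin_means = _linear_bin_means(5)
    elif gradient == "uniform":
        profile = np.ones_like(t_of_col)
        bin_means = np.ones(5)
    else:
        raise ValueError("gradient must be 'linear' or 'uniform'")

    grad_img = np.full(shape, background_level)
    grad_img[body | neck] = body_level
    grad_img[bleb] = background_level + profile[bleb]

    cortex = np.full(shape, background_level)
    cortex[body | neck | bleb] = body_level
    radial = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    rim = body & (radial >= body_radius - rim_width)
    cortex[rim] = body_level + rim_amplitude

    fill = np.full(shape, background_level)
    fill[body | neck | bleb] = 1.0

    channels = [grad_img, cortex, fill]
    roles = {"gradient": 0, "cortex_stain": 1, "fill": 2}
    truth: Dict = {
        "bin_means": bin_means.tolist(),
        "gradient": gradient,
        "body_level": body_level,
        "background_level": background_level,
        "rim_amplitude": rim_amplitude,
        "body_area_px": int(body.sum()),
        "bleb_area_px": int(bleb.sum()),
        "pixel_size_um": pixel_size_um,
    }
    if fibril_angle_deg is not None:
        th = math.radians(fibril_angle_deg)
        # stripes constant along the fibril direction (cos th, sin th):
        # intensity varies along the normal (-sin th, cos th)
        phase = 2.0 * math.pi * (-cc * math.sin(th) + rr * math.cos(th)) / stripe_period_px
        tex = np.full(shape, background_level)
        tex[bleb] = 0.5 + 0.5 * np.sin(phase[bleb])
        channels.append(tex)
        roles["texture"] = len(channels) - 1
        truth["fibril_angle_rad"] = ((th + math.pi / 2) % math.pi) - math.pi / 2
    data = np.stack(channels)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    frame = ImageFrame(data=data, pixel_size=pixel_size_um, channel_roles=roles)
    seg = BlebSegmentation(body_mask=body, bleb_mask=bleb, axis=axis, neck_point=neck_point)
    return frame, seg, truth


# ---------------------------------------------------------------------------
# line scans
# ---------------------------------------------------------------------------

def gen_linescan(
    separation_um: float = 0.2,
    psf_sigma_um: float = 0.1,
    pixel_um: float = 0.04,
    window_um: float = 3.0,
    center_um: Optional[float] = None,
    amplitude_a: float = 1.0,
    amplitude_b: float = 1.0,
    noise_sd: float = 0.0,
    seed: RngLike = None,
) -> tuple[LineScan, Dict]:
    """Dual-Gaussian edge line scan with known peak separation.

    Channel a (membrane stain) peaks ``separation_um`` outside channel b
    (actin stain); both are Gaussians of width ``psf_sigma_um`` (the
    point-spread function).  ``center_um`` places the actin peak, which
    need not fall on a sample — use it to scan sub-pixel offsets.
    """
    rng = _rng(seed)
    x = np.arange(0.0, window_um, pixel_um)
    if center_um is None:
        center_um = window_um / 2.0
    c_b = center_um
    c_a = center_um + separation_um
    a = amplitude_a * np.exp(-0.5 * ((x - c_a) / psf_sigma_um) ** 2)
    b = amplitude_b * np.exp(-0.5 * ((x - c_b) / psf_sigma_um) ** 2)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=x.shape)
        b = b + rng.normal(0.0, noise_sd, size=x.shape)
    truth = {
        "separation_um": separation_um,
        "center_a_um": c_a,
        "center_b_um": c_b,
        "psf_sigma_um": psf_sigma_um,
        "pixel_um": pixel_um,
        "noise_sd": noise_sd,
    }
    return LineScan(positions=x, intensity_a=a, intensity_b=b), truth


# ---------------------------------------------------------------------------
# FRET stacks
# ---------------------------------------------------------------------------

def gen_fret_stack(
    shape: tuple = (64, 112),
    n_frames: int = 30,
    frame_interval_s: float = 10.0,
    body_center: tuple = (32, 26),
    body_radius: int = 16,
    bleb_box: tuple = (22, 42, 52, 100),  # (r0, r1, c0, c1)
    donor_level: float = 100.0,
    background_level: float = 10.0,
    background_drift: float = 0.0,
    body_activity: float = 1.0,
    bleb_activity: float = 2.5,
    bleach_donor: float = 0.01,
    bleach_acceptor: float = 0.005,
    noise_sd: float = 0.0,
    seed: RngLike = None,
) -> tuple[RatioStack, BlebSegmentation, Dict]:
    """FRET biosensor time series with a known activity map.

    Donor = morphology * exp(-k_d t) + background(t) + noise; acceptor =
    morphology * activity * exp(-k_a t) + background(t) + noise, where
    activity is ``body_activity`` in the cell body and ``bleb_activity``
    in the bleb (elevated bleb kinase activity).  ``background_drift``
    adds a linear ramp to the per-frame background so residual-background
    recovery can be checked.  The background ROI is a corner square
    outside the cell.
    """
    rng = _rng(seed)
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = body_center
    body = (rr - cy) ** 2 + (cc - cx) ** 2 <= body_radius ** 2
    r0, r1, c0, c1 = bleb_box
    bleb = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1) & ~body
    cell = body | bleb
    activity = np.zeros(shape)
    activity[body] = body_activity
    activity[bleb] = bleb_activity
    morph = np.where(cell, donor_level, 0.0)

    t = np.arange(n_frames) * frame_interval_s
    bg_t = background_level + background_drift * t / max(t[-1], 1.0)
    donor = morph[None] * np.exp(-bleach_donor * t)[:, None, None] + bg_t[:, None, None]
    acceptor = (
        (morph * activity)[None] * np.exp(-bleach_acceptor * t)[:, None, None]
        + bg_t[:, None, None]
    )
    if noise_sd > 0:
        donor = donor + rng.normal(0.0, noise_sd, size=donor.shape)
        acceptor = acceptor + rng.normal(0.0, noise_sd, size=acceptor.shape)

    bg_roi = np.zeros(shape, dtype=bool)
    bg_roi[H - 10:H, W - 10:W] = True
    stack = RatioStack(
        donor=donor, acceptor=acceptor,
        background_roi=bg_roi, frame_interval=frame_interval_s,
    )
    seg = BlebSegmentation(body_mask=body, bleb_mask=bleb)
    truth = {
        "body_activity": body_activity,
        "bleb_activity": bleb_activity,
        "bleach_donor_per_s": bleach_donor,
        "bleach_acceptor_per_s": bleach_acceptor,
        "donor_level": donor_level,
        "background_level": background_level,
        "background_drift": background_drift,
    }
    return stack, seg, truth


# ---------------------------------------------------------------------------
# photoconversion
# ---------------------------------------------------------------------------

def gen_photoconversion(
    shape: tuple = (48, 96),
    n_frames: int = 80,
    frame_interval_s: float = 0.13,
    exchange_rate: float = 0.02,
    initial_bleb_fraction: float = 0.95,
    bleb_box: tuple = (14, 34, 52, 92),
    body_center: tuple = (24, 24),
    body_radius: int = 16,
    total_signal: float = 1.0e4,
    conversion_frame: int = 2,
    noise_sd: float = 0.0,
    seed: RngLike = None,
) -> tuple[np.ndarray, BlebSegmentation, Dict]:
    """Converted-channel series under two-compartment neck exchange.

    After the conversion pulse a fraction ``initial_bleb_fraction`` of the
    converted pool sits in the bleb; the bleb fraction then relaxes as
    r(t) = r_eq + (r0 - r_eq)exp(-k t) toward the bleb's share of the
    total volume (areas proxy volumes), conserving total signal.  Frames
    before ``conversion_frame`` carry no converted signal.

    Returns (red_series (T,H,W), segmentation, truth).
    """
    rng = _rng(seed)
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = body_center
    body = (rr - cy) ** 2 + (cc - cx) ** 2 <= body_radius ** 2
    r0_, r1_, c0_, c1_ = bleb_box
    bleb = (rr >= r0_) & (rr < r1_) & (cc >= c0_) & (cc < c1_) & ~body
    area_bleb = int(bleb.sum())
    area_body = int(body.sum())
    r_eq = area_bleb / (area_bleb + area_body)
    r0 = initial_bleb_fraction

    series = np.zeros((n_frames,) + shape)
    n_post = n_frames - conversion_frame
    t = np.arange(n_post) * frame_interval_s
    r_t = r_eq + (r0 - r_eq) * np.exp(-exchange_rate * t)
    for i, r in enumerate(r_t):
        f = conversion_frame + i
        series[f][bleb] = total_signal * r / area_bleb
        series[f][body] = total_signal * (1.0 - r) / area_body
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=series.shape)
    seg = BlebSegmentation(body_mask=body, bleb_mask=bleb)
    truth = {
        "exchange_rate_per_s": exchange_rate,
        "equilibrium_fraction": r_eq,
        "initial_bleb_fraction": r0,
        "conversion_frame": conversion_frame,
        "frame_interval_s": frame_interval_s,
        "bleb_area_px": area_bleb,
        "body_area_px": area_body,
    }
    return series, seg, truth
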