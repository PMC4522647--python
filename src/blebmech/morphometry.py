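"""Cortex and leader-bleb morphometrics from fluorescence images.

Covers the image-derived measurements used to characterise confined,
non-adherent blebbing cells:

* cortical actin density: mean intensity along a widened line over the
  cortex minus a cytoplasmic background ROI;
* cortex thickness: sub-pixel separation of the membrane-stain and
  actin-stain peaks of a dual-channel line scan across the cell edge;
* cell-body / leader-bleb segmentation (validated user masks, or an
  automated Otsu + narrowest-neck split) with a geodesic bleb axis;
* leader-bleb area as a percent of cell-body area, and the fraction of
  cells that migrate;
* regional profiles: five equal-arclength bins along the bleb axis with
  per-bin mean intensity and nematic-tensor fibril anisotropy;
* arrival timing of proteins on the bleb rim relative to maximal
  protrusion.

Pixel coordinates are 0-based (row, col) with a pixel-centre convention;
areas convert to um^2 via pixel_size**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, distance_transform_edt, gaussian_filter1d
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.graph import MCP_Geometric
from skimage.segmentation import watershed

from .errors import (
    EmptyBin,
    EmptyRegion,
    NeverAboveBackground,
    NoBleb,
    NoPeak,
    ZeroMean,
)

__all__ = [
    "ImageFrame",
    "LineScan",
    "BlebSegmentation",
    "RegionalProfile",
    "ArrivalTiming",
    "polyline_to_mask",
    "measure_cortex_density",
    "measure_cortex_thickness",
    "segment_cell_and_bleb",
    "leader_bleb_area_percent",
    "migration_fraction",
    "regional_profile",
    "anisotropy_nematic",
    "contrast_index",
    "bleb_arrival_timing",
]


@dataclass
class ImageFrame:
    """Multi-channel image with physical pixel size.

    ``data`` has shape (n_channels, H, W); ``channel_roles`` maps role
    names such as ``"cortex_stain"`` to channel indices.
    """

    data: np.ndarray
    pixel_size: float                       # um / pixel
    channel_roles: Dict[str, int] = field(default_factory=dict)
    timestamp: Optional[float] = None       # s

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError("data must be 2-D or (C, H, W)")
        if not np.isfinite(data).all():
            raise ValueError("intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < data.shape[0]:
                raise ValueError(f"channel index {idx} for role '{role}' out of range")
        self.data = data

    def channel(self, role_or_index) -> np.ndarray:
        if isinstance(role_or_index, str):
            return self.data[self.channel_roles[role_or_index]]
        return self.data[int(role_or_index)]


@dataclass
class LineScan:
    """Dual-channel intensity profile across the cell edge.

    ``intensity_a`` is the membrane stain (e.g. wheat-germ agglutinin) and
    ``intensity_b`` the actin stain (phalloidin); positions in um,
    strictly increasing.
    """

    positions: np.ndarray
    intensity_a: np.ndarray
    intensity_b: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        a = np.asarray(self.intensity_a, dtype=float)
        b = np.asarray(self.intensity_b, dtype=float)
        if not (p.ndim == 1 and p.shape == a.shape == b.shape):
            raise ValueError("positions and intensities must be 1-D, equal length")
        if not np.all(np.diff(p) > 0):
            raise ValueError("positions must be strictly increasing")
        self.positions, self.intensity_a, self.intensity_b = p, a, b


@dataclass
class BlebSegmentation:
    """Cell body and leader-bleb masks plus the neck-to-tip axis polyline.

    ``axis`` is an (N, 2) integer array of (row, col) pixel coordinates
    ordered from the bleb neck to the distal tip.  ``bleb_mask`` may be
    empty (no-bleb cell); masks are always disjoint.
    """

    body_mask: np.ndarray
    bleb_mask: np.ndarray
    axis: Optional[np.ndarray] = None
    neck_point: Optional[tuple] = None

    def __post_init__(self):
        body = np.asarray(self.body_mask, dtype=bool)
        bleb = np.asarray(self.bleb_mask, dtype=bool)
        if body.shape != bleb.shape:
            raise ValueError("masks must share a shape")
        if not body.any():
            raise ValueError("body_mask is empty")
        if (body & bleb).any():
            raise ValueError("body and bleb masks overlap")
        self.body_mask, self.bleb_mask = body, bleb
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=int)

    @property
    def has_bleb(self) -> bool:
        return bool(self.bleb_mask.any())


@dataclass
class RegionalProfile:
    """Per-bin statistics along the bleb axis (bin 0 = neck, last = tip)."""

    n_bins: int
    mean_intensity: Dict[str, np.ndarray]
    normalized_intensity: Dict[str, np.ndarray]
    anisotropy: Optional[np.ndarray] = None
    mean_orientation: Optional[np.ndarray] = None
    pixels_per_bin: Optional[np.ndarray] = None


@dataclass(frozen=True)
class ArrivalTiming:
    """Arrival of a protein on the bleb rim relative to maximal protrusion
    (negative = before max protrusion); always a multiple of the frame
    interval."""

    label: str
    arrival_time: float  # s


# ---------------------------------------------------------------------------
# density & thickness
# ---------------------------------------------------------------------------

def polyline_to_mask(shape, polyline, width: int = 1) -> np.ndarray:
    """Rasterise a polyline of (row, col) vertices into a boolean mask,
    widened symmetrically to ``width`` pixels."""
    poly = np.asarray(polyline)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
        raise ValueError("polyline must be (N>=2, 2) of (row, col)")
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
        rr, cc = skdraw.line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    if width > 1:
        mask = binary_dilation(mask, structure=disk((width - 1) // 2))
    return mask


def measure_cortex_density(
    frame: ImageFrame,
    cortex_line,
    background_roi: np.ndarray,
    line_width: int = 5,
    channel="cortex_stain",
) -> float:
    """Cortical stain density: mean over a widened cortex line minus the
    mean over a cytoplasmic background ROI.

    The line should follow a bleb-free stretch of the cortex; the result
    may be negative and is reported as-is.  Invariant under adding any
    constant to the whole image.
    """
    img = frame.channel(channel)
    line_mask = polyline_to_mask(img.shape, cortex_line, width=line_width)
    bg = np.asarray(background_roi, dtype=bool)
    if not line_mask.any():
        raise EmptyRegion("cortex line covers zero pixels")
    if not bg.any():
        raise EmptyRegion("background ROI covers zero pixels")
    return float(img[line_mask].mean() - img[bg].mean())


def _subpixel_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Peak position by 3-point quadratic interpolation around the argmax.

    Ties break toward the smaller coordinate (first argmax).  A profile
    that is monotone over the window raises NoPeak; a peak at either end
    of the window cannot be interpolated and also raises NoPeak.
    """
    dy = np.diff(y)
    if np.all(dy >= 0) or np.all(dy <= 0):
        raise NoPeak("profile is monotone over the window")
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise NoPeak("maximum at the window boundary")
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
    h = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + offset * h)


def measure_cortex_thickness(
    scan: LineScan,
    correction: Optional[Callable[[float], float]] = None,
    smooth_sigma_px: float = 2.0,
) -> tuple[float, float]:
    """Cortex thickness from the membrane-stain / actin-stain peak offset.

    Each profile is lightly Gaussian-smoothed (``smooth_sigma_px``, below
    the optical PSF so peak positions are preserved — smoothing a
    Gaussian peak keeps its centre) and the peak located to sub-pixel
    precision by 3-point quadratic interpolation; ``peak_separation`` is
    the absolute distance between the two peaks (um).  By default the
    cortex midline is assumed to sit half a thickness inside the
    membrane, so ``thickness = 2 * peak_separation``; pass ``correction``
    to substitute a different separation-to-thickness mapping (e.g. a
    PSF-aware model).

    Returns (peak_separation_um, thickness_um).
    """
    ia, ib = scan.intensity_a, scan.intensity_b
    if smooth_sigma_px > 0:
        ia = gaussian_filter1d(ia, smooth_sigma_px)
        ib = gaussian_filter1d(ib, smooth_sigma_px)
    pa = _subpixel_peak(scan.positions, ia)
    pb = _subpixel_peak(scan.positions, ib)
    sep = abs(pa - pb)
    thickness = correction(sep) if correction is not None else 2.0 * sep
    return sep, thickness


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _neck_point_between(body: np.ndarray, bleb: np.ndarray) -> tuple:
    """Centroid of bleb pixels bordering the body (the neck)."""
    body_dil = binary_dilation(body, structure=disk(2))
    border = bleb & body_dil
    if not border.any():
        # fall back: bleb pixel closest to the body
        br, bc = np.nonzero(bleb)
        rr, cc = np.nonzero(body)
        tree = cKDTree(np.column_stack([rr, cc]))
        dist, _ = tree.query(np.column_stack([br, bc]))
        i = int(np.argmin(dist))
        return (int(br[i]), int(bc[i]))
    rr, cc = np.nonzero(border)
    r, c = int(round(rr.mean())), int(round(cc.mean()))
    if not bleb[r, c]:  # snap the centroid back onto the bleb
        i = int(np.argmin((rr - r) ** 2 + (cc - c) ** 2))
        r, c = int(rr[i]), int(cc[i])
    return (r, c)


def _geodesic_axis(bleb: np.ndarray, neck: tuple) -> np.ndarray:
    """Geodesic path inside the bleb from the neck to the farthest pixel."""
    costs = np.where(bleb, 1.0, np.inf)
    costs[neck] = 1.0  # the neck point always belongs to the travel domain
    mcp = MCP_Geometric(costs)
    cum, _ = mcp.find_costs([neck])
    cum = np.where(np.isfinite(cum), cum, -1.0)
    tip = np.unravel_index(int(np.argmax(cum)), cum.shape)
    path = mcp.traceback(tip)  # neck -> tip
    return np.asarray(path, dtype=int)


def segment_cell_and_bleb(
    source,
    mode: str = "provided_masks",
    *,
    body_mask: Optional[np.ndarray] = None,
    bleb_mask: Optional[np.ndarray] = None,
    axis: Optional[np.ndarray] = None,
    neck_point: Optional[tuple] = None,
    channel=0,
    max_erosion: int = 40,
    min_lobe_area: int = 25,
) -> BlebSegmentation:
    """Package user-drawn masks, or segment body and leader bleb automatically.

    ``provided_masks`` (canonical, mirrors manual outlining): validates the
    supplied masks, and derives the neck point and the geodesic axis when
    not given.

    ``threshold_auto`` (convenience, non-canonical): Otsu-thresholds the
    image, keeps the largest connected component, erodes with growing
    disks until the shape splits at its narrowest neck, takes the largest
    eroded lobe as the body seed and the largest remaining lobe as the
    leader bleb seed, then assigns every pixel by watershed on the
    distance transform.  Raises NoBleb if the shape never splits.
    """
    if mode == "provided_masks":
        if body_mask is None:
            raise ValueError("provided_masks mode requires body_mask")
        if bleb_mask is None:
            bleb_mask = np.zeros_like(np.asarray(body_mask, bool))
        seg = BlebSegmentation(body_mask, bleb_mask, axis=axis, neck_point=neck_point)
        if seg.has_bleb:
            if seg.neck_point is None:
                seg.neck_point = _neck_point_between(seg.body_mask, seg.bleb_mask)
            if seg.axis is None:
                seg.axis = _geodesic_axis(seg.bleb_mask, seg.neck_point)
        return seg

    if mode != "threshold_auto":
        raise ValueError(f"unknown mode '{mode}'")

    img = source.channel(channel) if isinstance(source, ImageFrame) else np.asarray(source, float)
    mask = img > threshold_otsu(img)
    labels = skmeasure.label(mask)
    if labels.max() == 0:
        raise NoBleb("threshold produced an empty mask")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    cell = labels == largest

    # erode until the cell splits at its narrowest constriction
    seeds = None
    for r in range(1, max_erosion + 1):
        eroded = binary_erosion(cell, structure=disk(r))
        lab = skmeasure.label(eroded)
        if lab.max() < 2:
            if not eroded.any():
                break
            continue
        areas = np.bincount(lab.ravel())[1:]
        big = np.flatnonzero(areas >= min_lobe_area) + 1
        if len(big) >= 2:
            seeds = np.where(np.isin(lab, big), lab, 0)
            break
    if seeds is None:
        raise NoBleb("cell mask never split into body and bleb")

    edt = distance_transform_edt(cell)
    ws = watershed(-edt, markers=seeds, mask=cell)
    labels_present = np.unique(ws)
    labels_present = labels_present[labels_present > 0]
    if len(labels_present) < 2:
        raise NoBleb("no lobe beyond the body")
    # the body is the roundest lobe: largest inscribed disk (max EDT);
    # a leader bleb can exceed the body in area but is always narrower
    body_label = max(labels_present, key=lambda l: edt[ws == l].max())
    body = ws == body_label
    rest = [l for l in labels_present if l != body_label]
    bleb_label = max(rest, key=lambda l: (ws == l).sum())
    bleb = ws == bleb_label

    neck = _neck_point_between(body, bleb)
    ax = _geodesic_axis(bleb, neck)
    return BlebSegmentation(body, bleb, axis=ax, neck_point=neck)


def leader_bleb_area_percent(seg: BlebSegmentation) -> float:
    """Leader-bleb area as a percent of cell-body area (exact pixel
    counts; 0 when there is no bleb)."""
    body = int(seg.body_mask.sum())
    if body == 0:
        raise EmptyRegion("body mask is empty")
    return 100.0 * int(seg.bleb_mask.sum()) / body


def migration_fraction(
    centroid_tracks: Sequence[np.ndarray],
    min_displacement: float = 10.0,
    window: float = 60.0,
) -> float:
    """Percent of cells whose net centroid displacement over the window
    exceeds the threshold.

    Each track is an (N, 3) array of (time_min, x_um, y_um), N >= 2.  A
    cell is "moving" when the straight-line distance between its position
    at t = 0 and its last position with t <= window exceeds
    ``min_displacement`` (default 10 um over 60 min — a declared
    operationalisation of a manual moving/stationary count).
    """
    if not centroid_tracks:
        raise ValueError("need at least one track")
    moving = 0
    for tr in centroid_tracks:
        tr = np.asarray(tr, dtype=float)
        if tr.ndim != 2 or tr.shape[1] != 3 or len(tr) < 2:
            raise ValueError("each track must be (N>=2, 3) of (t, x, y)")
        t = tr[:, 0] - tr[0, 0]
        inside = np.flatnonzero(t <= window)
        j = int(inside[-1]) if inside.size else len(tr) - 1
        disp = float(np.hypot(tr[j, 1] - tr[0, 1], tr[j, 2] - tr[0, 2]))
        if disp > min_displacement:
            moving += 1
    return 100.0 * moving / len(centroid_tracks)


# ---------------------------------------------------------------------------
# regional profiles & anisotropy
# ---------------------------------------------------------------------------

def _axis_bin_fractions(axis: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index of each axis point by cell-centred arclength fraction.

    Each axis sample owns one arclength cell; the fraction of sample i is
    (s_i + h/2) / (S + h) with h the mean spacing, so for a uniformly
    sampled axis the points split into bins as evenly as possible and the
    bins tile the axis exactly.
    """
    diffs = np.diff(axis.astype(float), axis=0)
    steps = np.hypot(diffs[:, 0], diffs[:, 1])
    s = np.concatenate([[0.0], np.cumsum(steps)])
    h = steps.mean() if len(steps) else 1.0
    frac = (s + h / 2.0) / (s[-1] + h)
    bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    return bins


def regional_profile(
    frame: ImageFrame,
    seg: BlebSegmentation,
    channels: Optional[Sequence] = None,
    n_bins: int = 5,
    compute_anisotropy: bool = False,
    min_anisotropy_pixels: int = 64,
) -> RegionalProfile:
    """Per-bin mean intensity (and optional fibril anisotropy) along the bleb.

    The axis arclength is split into ``n_bins`` equal segments (bin 0 at
    the neck); every bleb pixel is assigned to the bin of its nearest axis
    point, so the bins partition the bleb exactly.  Means are reported
    per channel both raw and normalised to the maximum bin.
    """
    if seg.axis is None or len(seg.axis) < n_bins:
        raise ValueError(f"axis must have >= {n_bins} points")
    if channels is None:
        channels = (
            list(frame.channel_roles) if frame.channel_roles
            else list(range(frame.data.shape[0]))
        )

    axis = seg.axis
    axis_bins = _axis_bin_fractions(axis, n_bins)
    rr, cc = np.nonzero(seg.bleb_mask)
    if rr.size == 0:
        raise EmptyRegion("bleb mask is empty")
    tree = cKDTree(axis.astype(float))
    _, nearest = tree.query(np.column_stack([rr, cc]).astype(float))
    pix_bins = axis_bins[nearest]
    counts = np.bincount(pix_bins, minlength=n_bins)
    if (counts == 0).any():
        raise EmptyBin(f"bins with zero pixels: {np.flatnonzero(counts == 0).tolist()}")

    means: Dict[str, np.ndarray] = {}
    normed: Dict[str, np.ndarray] = {}
    for ch in channels:
        img = frame.channel(ch)
        sums = np.bincount(pix_bins, weights=img[rr, cc], minlength=n_bins)
        m = sums / counts
        key = ch if isinstance(ch, str) else str(ch)
        means[key] = m
        peak = np.abs(m).max()
        normed[key] = m / peak if peak > 0 else m.copy()

    aniso = orient = None
    if compute_anisotropy:
        ref = frame.channel(channels[0])
        gr, gc = np.gradient(ref.astype(float))
        aniso = np.full(n_bins, np.nan)
        orient = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = pix_bins == b
            if sel.sum() < min_anisotropy_pixels:
                continue
            a, th = _nematic_from_gradients(gr[rr[sel], cc[sel]], gc[rr[sel], cc[sel]])
            aniso[b], orient[b] = a, th

    return RegionalProfile(
        n_bins=n_bins,
        mean_intensity=means,
        normalized_intensity=normed,
        anisotropy=aniso,
        mean_orientation=orient,
        pixels_per_bin=counts,
    )


def _nematic_from_gradients(gr: np.ndarray, gc: np.ndarray) -> tuple[float, float]:
    """Anisotropy score and fibril orientation from gradient samples.

    Averages the outer product of unit gradient vectors; the score is the
    eigenvalue gap lambda1 - lambda2 of the mean tensor (eigenvalues sum
    to 1), and the fibril orientation is the dominant gradient direction
    rotated by 90 deg (fibrils run perpendicular to intensity gradients).
    Orientation is measured from the +x (column) axis, positive toward +y
    (rows), wrapped to (-pi/2, pi/2].
    """
    mag = np.hypot(gr, gc)
    ok = mag > 0
    if not ok.any():
        return 0.0, math.nan
    # x = columns, y = rows
    ux = gc[ok] / mag[ok]
    uy = gr[ok] / mag[ok]
    mxx = float(np.mean(ux * ux))
    myy = float(np.mean(uy * uy))
    mxy = float(np.mean(ux * uy))
    # eigenvalue gap of [[mxx, mxy], [mxy, myy]] (trace = 1)
    gap = math.hypot(mxx - myy, 2.0 * mxy)
    grad_angle = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    theta = grad_angle + math.pi / 2.0
    # wrap to (-pi/2, pi/2]
    theta = (theta + math.pi / 2.0) % math.pi - math.pi / 2.0
    if theta == -math.pi / 2.0:
        theta = math.pi / 2.0
    return gap, theta


def anisotropy_nematic(image, roi: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Nematic-tensor anisotropy of fibril texture in an ROI.

    Returns (anisotropy in [0, 1], mean fibril orientation in radians).
    A constant ROI (no gradients) yields (0, nan).  The score is
    invariant under affine intensity rescaling and under 90-degree image
    rotation (which shifts the orientation by exactly pi/2).
    """
    img = image.channel(0) if isinstance(image, ImageFrame) else np.asarray(image, float)
    if roi is None:
        roi = np.ones(img.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() < 256:
        raise ValueError("ROI must contain >= 256 pixels (>= 16x16)")
    gr, gc = np.gradient(img.astype(float))
    return _nematic_from_gradients(gr[roi], gc[roi])


def contrast_index(image, roi: Optional[np.ndarray] = None) -> float:
    """SD/mean of ROI intensities, used to gate images entering anisotropy
    comparisons (only images of similar contrast are comparable)."""
    img = image.channel(0) if isinstance(image, ImageFrame) else np.asarray(image, float)
    if roi is None:
        roi = np.ones(img.shape, dtype=bool)
    vals = img[np.asarray(roi, bool)]
    if vals.size == 0:
        raise EmptyRegion("ROI covers zero pixels")
    mean = float(vals.mean())
    if mean == 0:
        raise ZeroMean("ROI mean is zero")
    return float(vals.std()) / mean


# ---------------------------------------------------------------------------
# arrival timing
# ---------------------------------------------------------------------------

def bleb_arrival_timing(
    protein_series: np.ndarray,
    protrusion_series: np.ndarray,
    background_level: float,
    frame_interval: float = 5.0,
    label: str = "",
) -> ArrivalTiming:
    """When a protein arrives on the bleb rim, relative to maximal protrusion.

    Time 0 is the frame of maximal protrusion (argmax of the boundary
    displacement series, first frame on ties); arrival is the first frame
    whose rim intensity exceeds ``background_level``.  The signed arrival
    time is (arrival - t0) * frame_interval, negative when the protein
    precedes maximal protrusion.
    """
    protein = np.asarray(protein_series, dtype=float)
    protr = np.asarray(protrusion_series, dtype=float)
    if protein.shape != protr.shape or protein.ndim != 1:
        raise ValueError("series must be 1-D and share a length")
    t0 = int(np.argmax(protr))
    above = np.flatnonzero(protein > background_level)
    if above.size == 0:
        raise NeverAboveBackground(f"'{label}' never exceeds background")
    return ArrivalTiming(label=label, arrival_time=float((int(above[0]) - t0) * frame_interval))
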