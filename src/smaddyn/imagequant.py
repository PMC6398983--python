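"""From segmented images to per-cell measurements, radial profiles and fronts.

The signaling readout is the background-subtracted nuclear:cytoplasmic mean
intensity ratio per cell, ``(nuc - bg) / (cyt - bg)``; purely nuclear markers
(pSMAD1, BRA) are instead quantified as nuclear intensity normalized by the
per-cell DAPI mean.  For micropatterned colonies, per-cell values are binned
into annuli around the colony center to give radial profiles; stacking
profiles over time gives a kymograph, on which the position of the
half-maximum crossing tracks the inward-traveling signaling wavefront.

Channel normalization conventions (the ``normalize_channel`` rules):

* ``minmax`` — each time row scaled so its lowest value is 0 and highest 1
  (used for SMAD2/3 and pSMAD1, whose extreme levels are similar at all
  times while their spatial distribution varies);
* ``smad4_rule`` — each row divided by the maximum of the SMAD4 profile over
  positions interior to the innermost half-maximum of the pSMAD1 profile
  (that position reflects the peak of Nodal-dependent SMAD4 signaling);
* ``bra_rule`` — all rows divided by the maximum of the final time row
  (BRA levels change substantially over time, so a global reference).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import expand_labels, relabel_sequential, watershed

__all__ = [
    "LabeledImage",
    "CellMeasurement",
    "RadialProfile",
    "Kymograph",
    "FrontTrack",
    "MaskError",
    "measure_cells",
    "radial_profile",
    "profiles_to_kymograph",
    "normalize_channel",
    "track_front",
    "restriction_time",
    "expression_domain",
    "segment_fixture",
]


class MaskError(ValueError):
    """An empty or inconsistent segmentation mask."""


@dataclass
class LabeledImage:
    """Intensity channels plus matched nuclear/cytoplasm label masks.

    ``intensity`` maps channel name -> 2-D float array; ``nuclear_labels``
    and ``cyto_labels`` share the same positive label ids (0 = none);
    ``background_mask`` marks pixels used for background estimation.
    """

    intensity: dict[str, np.ndarray]
    nuclear_labels: np.ndarray
    cyto_labels: np.ndarray
    background_mask: np.ndarray
    pixel_size: float  # um / pixel

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        nl = set(np.unique(self.nuclear_labels)) - {0}
        cl = set(np.unique(self.cyto_labels)) - {0}
        if nl != cl:
            raise MaskError("nuclear and cytoplasm masks carry different label sets")
        if np.any((self.nuclear_labels > 0) & (self.cyto_labels > 0)):
            raise MaskError("nuclear and cytoplasm masks overlap")

    @property
    def labels(self) -> np.ndarray:
        return np.array(sorted(set(np.unique(self.nuclear_labels)) - {0}), dtype=int)


@dataclass(frozen=True)
class CellMeasurement:
    """Background-subtracted intensity readout for one cell."""

    cell_id: int
    nuc_mean: float
    cyt_mean: float
    bg_mean: float
    nc_ratio: float
    centroid: tuple[float, float]  # (x, y) in um
    nuc_norm: float = math.nan     # nuclear marker / DAPI, for nuclear-only markers


@dataclass
class RadialProfile:
    """Mean signal per annulus around a colony center."""

    r_centers: np.ndarray  # um from colony center
    values: np.ndarray     # NaN where a bin holds no cells
    n_cells_per_bin: np.ndarray
    t: float = math.nan    # hours
    channel: str = ""


@dataclass
class Kymograph:
    """radius x time matrix of a signaling channel, ``matrix[t, r]``."""

    r_centers: np.ndarray
    t: np.ndarray
    matrix: np.ndarray
    channel: str = ""
    normalization: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.t), len(self.r_centers)):
            raise ValueError("matrix shape must be (len(t), len(r_centers))")

    @property
    def colony_radius(self) -> float:
        return float(self.meta.get("colony_radius",
                                   self.r_centers[-1] + 0.5 * self._bin_width()))

    def _bin_width(self) -> float:
        return float(np.median(np.diff(self.r_centers))) if len(self.r_centers) > 1 else 1.0


@dataclass
class FrontTrack:
    """Half-maximum position of a front vs time, with a fitted velocity."""

    t: np.ndarray
    r_half: np.ndarray          # um; NaN where no crossing exists
    velocity: float             # um/hr, positive = inward motion
    velocity_window: tuple[float, float]
    onset_time: float           # hr; NaN if the front never leaves the edge
    level: float = 0.5


# --------------------------------------------------------------------------
# per-cell measurement
# --------------------------------------------------------------------------


def measure_cells(
    img: LabeledImage,
    channel: str = "signal",
    dapi_channel: str | None = None,
) -> list[CellMeasurement]:
    """Per-cell background-subtracted means and nuclear:cytoplasmic ratios.

    Cells whose background-subtracted cytoplasmic mean is non-positive are
    excluded (with a logged count): their ratio is undefined.  If
    ``dapi_channel`` is given, ``nuc_norm`` (nuclear mean / DAPI mean, no
    background subtraction) is also reported for nuclear-only markers.
    """
    if channel not in img.intensity:
        raise KeyError(f"channel {channel!r} not in image")
    if not img.background_mask.any():
        raise MaskError("background mask is empty")
    labels = img.labels
    if len(labels) == 0:
        return []
    if not (img.nuclear_labels > 0).any():
        raise MaskError("nuclear mask is empty")
    if not (img.cyto_labels > 0).any():
        raise MaskError("cytoplasm mask is empty")

    data = np.asarray(img.intensity[channel], dtype=float)
    bg = float(data[img.background_mask].mean())
    nuc_means = ndimage.mean(data, labels=img.nuclear_labels, index=labels)
    cyt_means = ndimage.mean(data, labels=img.cyto_labels, index=labels)
    cent = ndimage.center_of_mass(np.ones_like(data), labels=img.nuclear_labels,
                                  index=labels)
    if dapi_channel is not None:
        dapi = np.asarray(img.intensity[dapi_channel], dtype=float)
        dapi_means = ndimage.mean(dapi, labels=img.nuclear_labels, index=labels)
    else:
        dapi_means = [math.nan] * len(labels)

    out: list[CellMeasurement] = []
    n_excluded = 0
    for lab, nm, cm, (cy, cx), dm in zip(labels, nuc_means, cyt_means, cent, dapi_means):
        denom = cm - bg
        if denom <= 0:
            n_excluded += 1
            continue
        out.append(CellMeasurement(
            cell_id=int(lab),
            nuc_mean=float(nm), cyt_mean=float(cm), bg_mean=bg,
            nc_ratio=float((nm - bg) / denom),
            centroid=(float(cx) * img.pixel_size, float(cy) * img.pixel_size),
            nuc_norm=float(nm / dm) if np.isfinite(dm) and dm > 0 else math.nan,
        ))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} cell(s) with non-positive "
                      "background-subtracted cytoplasmic mean")
    return out


# --------------------------------------------------------------------------
# radial profiles and kymographs
# --------------------------------------------------------------------------


def radial_profile(
    cells: Sequence[CellMeasurement],
    center: tuple[float, float],
    bin_width: float = 20.0,
    colony_radius: float | None = None,
    value: str = "nc_ratio",
    t: float = math.nan,
    channel: str = "",
) -> RadialProfile:
    """Annulus means of a per-cell value around ``center`` (um coordinates).

    Empty bins carry NaN, never zero: no cells is missing data, not zero
    signal.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    xs = np.array([c.centroid[0] for c in cells], dtype=float)
    ys = np.array([c.centroid[1] for c in cells], dtype=float)
    vals = np.array([getattr(c, value) for c in cells], dtype=float)
    r = np.hypot(xs - center[0], ys - center[1])
    if colony_radius is None:
        colony_radius = float(r.max()) + bin_width if len(r) else bin_width
    edges = np.arange(0.0, colony_radius + bin_width * 0.999, bin_width)
    if edges[-1] < colony_radius:
        edges = np.append(edges, colony_radius)
    n_bins = len(edges) - 1
    values = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    idx = np.digitize(r, edges) - 1
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            values[b] = float(np.nanmean(vals[sel]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r_centers=centers, values=values,
                         n_cells_per_bin=counts, t=t, channel=channel)


def profiles_to_kymograph(
    profiles: Sequence[RadialProfile],
    channel: str = "",
    colony_radius: float | None = None,
    smooth_bins: int = 0,
) -> Kymograph:
    """Stack per-time radial profiles into a kymograph (rows sorted by time).

    ``smooth_bins`` applies a centered moving average along radius (odd
    width), which suppresses per-bin sampling noise without moving a
    symmetric front's half-max crossing.
    """
    profs = sorted(profiles, key=lambda p: p.t)
    r = profs[0].r_centers
    for p in profs[1:]:
        if not np.allclose(p.r_centers, r):
            raise ValueError("profiles must share a radial grid")
    mat = np.vstack([p.values for p in profs])
    if smooth_bins and smooth_bins > 1:
        if smooth_bins % 2 == 0:
            raise ValueError("smooth_bins must be odd")
        kernel = np.ones(smooth_bins) / smooth_bins
        sm = np.empty_like(mat)
        for i, row in enumerate(mat):
            # fill gaps by holding the nearest valid value so smoothing does
            # not drag profile shoulders toward unsampled bins
            filled = pd.Series(row).ffill().bfill().to_numpy()
            sm[i] = np.convolve(filled, kernel, mode="same")
            # shrink-at-edges correction for the constant kernel
            norm = np.convolve(np.ones_like(row), kernel, mode="same")
            sm[i] /= norm
            sm[i][np.isnan(row)] = np.nan  # missing stays missing
        mat = sm
    meta = {}
    if colony_radius is not None:
        meta["colony_radius"] = colony_radius
    return Kymograph(r_centers=r, t=np.array([p.t for p in profs]), matrix=mat,
                     channel=channel, normalization="raw", meta=meta)


def normalize_channel(
    kym: Kymograph,
    rule: str,
    auxiliary: Kymograph | None = None,
) -> Kymograph:
    """Apply a normalization convention; returns a new kymograph.

    ``minmax`` is per-row and idempotent; ``smad4_rule`` needs the pSMAD1
    kymograph as ``auxiliary``; ``bra_rule`` is global (final-time maximum).
    Constant rows under minmax are set to 0 with a warning.
    """
    mat = kym.matrix.copy()
    if rule == "minmax":
        for i, row in enumerate(mat):
            lo, hi = np.nanmin(row), np.nanmax(row)
            if not np.isfinite(hi - lo) or hi - lo <= 0:
                warnings.warn(f"constant row at t={kym.t[i]:g}; set to 0 under minmax")
                mat[i] = 0.0
            else:
                mat[i] = (row - lo) / (hi - lo)
    elif rule == "smad4_rule":
        if auxiliary is None:
            raise ValueError("smad4_rule requires the pSMAD1 kymograph as auxiliary")
        aux = normalize_channel(auxiliary, "minmax")
        for i, row in enumerate(mat):
            r_half = _innermost_crossing(kym.r_centers, aux.matrix[i], 0.5)
            interior = kym.r_centers < (r_half if np.isfinite(r_half)
                                        else kym.r_centers[-1])
            ref = np.nanmax(row[interior]) if interior.any() else np.nanmax(row)
            if not np.isfinite(ref) or ref <= 0:
                warnings.warn(f"no interior reference at t={kym.t[i]:g}; row left raw")
                continue
            mat[i] = row / ref
    elif rule == "bra_rule":
        ref = np.nanmax(mat[-1])
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError("final-time row has no positive maximum for bra_rule")
        mat = mat / ref
    else:
        raise ValueError(f"unknown normalization rule {rule!r}")
    return replace(kym, matrix=mat, normalization=rule)


# --------------------------------------------------------------------------
# front tracking
# --------------------------------------------------------------------------


def _innermost_crossing(r: np.ndarray, row: np.ndarray, level: float) -> float:
    """Innermost radius where the profile crosses ``level`` moving inward.

    Scans from the colony edge toward the center; linear interpolation
    between bins; NaN when the row never crosses the level.
    """
    valid = np.isfinite(row)
    if valid.sum() < 2:
        return math.nan
    rv, yv = r[valid], row[valid]
    crossing = math.nan
    # walk inward over adjacent pairs; record the innermost sign change
    for i in range(len(rv) - 1, 0, -1):
        y_out, y_in = yv[i], yv[i - 1]
        if (y_in - level) * (y_out - level) <= 0 and y_in != y_out:
            frac = (level - y_in) / (y_out - y_in)
            crossing = rv[i - 1] + frac * (rv[i] - rv[i - 1])
    return crossing


def track_front(
    kym: Kymograph,
    level: float = 0.5,
    window: tuple[float, float] = (25.0, 40.0),
    edge_zone_fraction: float = 0.10,
) -> FrontTrack:
    """Track the half-maximum front of a (row-normalized) kymograph.

    Per time row, the innermost radius where the profile crosses ``level``
    moving inward from the edge.  The velocity is the negated slope of a
    least-squares line over rows inside ``window`` (positive = inward).

    Onset is the first time the front *departs the edge region*: the first
    row, after the front has been within one bin of the edge zone (the
    outermost ``edge_zone_fraction`` of the radius), at which it sits more
    than one bin inside that zone.  Requiring prior presence at the edge
    makes the detector robust to the early uniform-response phase, when the
    near-flat profile has no meaningful crossing.
    """
    r_half = np.array([_innermost_crossing(kym.r_centers, row, level)
                       for row in kym.matrix])
    bin_w = kym._bin_width()
    R = kym.colony_radius
    edge_inner = (1.0 - edge_zone_fraction) * R

    onset = math.nan
    seen_at_edge = False
    for ti, rh in zip(kym.t, r_half):
        if not np.isfinite(rh):
            continue
        if rh >= edge_inner - bin_w:
            seen_at_edge = True
        elif seen_at_edge and rh < edge_inner - bin_w:
            onset = float(ti)
            break

    sel = (kym.t >= window[0]) & (kym.t <= window[1]) & np.isfinite(r_half)
    if sel.sum() >= 2:
        slope = np.polyfit(kym.t[sel], r_half[sel], 1)[0]
        velocity = float(-slope)
    else:
        velocity = math.nan
    return FrontTrack(t=kym.t.copy(), r_half=r_half, velocity=velocity,
                      velocity_window=window, onset_time=onset, level=level)


def restriction_time(
    kym: Kymograph,
    edge_band_width: float = 50.0,
    ratio: float = 0.5,
    until: float | None = None,
) -> float:
    """Earliest time after which the colony interior stays below
    ``ratio`` x the edge-band signal (up to ``until``, e.g. the wave onset).

    Operates on a raw (baseline-subtracted) kymograph: the interior mean is
    taken over the inner half of the radius, the edge mean over the outermost
    ``edge_band_width``.  NaN if the condition is never met and held.
    """
    R = kym.colony_radius
    inner = kym.r_centers < 0.5 * R
    edge = kym.r_centers >= R - edge_band_width
    if not inner.any() or not edge.any():
        raise ValueError("kymograph too coarse to define interior and edge bands")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        inner_mean = np.nanmean(kym.matrix[:, inner], axis=1)
        edge_mean = np.nanmean(kym.matrix[:, edge], axis=1)
    ok = inner_mean < ratio * edge_mean
    tmask = np.ones_like(kym.t, dtype=bool) if until is None else (kym.t <= until)
    consider = np.nonzero(tmask)[0]
    # earliest index from which the condition holds for all later considered rows
    for i in consider:
        if np.all(ok[consider[consider >= i]]):
            return float(kym.t[i])
    return math.nan


def expression_domain(
    profile: RadialProfile,
    threshold_fraction: float = 0.20,
) -> tuple[float, float] | None:
    """Radial extent where expression is >= ``threshold_fraction`` of its max.

    Returns the (inner, outer) boundary in um of the contiguous super-
    threshold interval containing the profile maximum, with the inner
    boundary located by linear interpolation; None (flagged) when the
    profile has no positive values.
    """
    r, v = profile.r_centers, profile.values
    finite = np.isfinite(v)
    if not finite.any() or np.nanmax(v) <= 0:
        warnings.warn("profile has no positive expression; empty domain")
        return None
    vmax = float(np.nanmax(v))
    level = threshold_fraction * vmax
    i_max = int(np.nanargmax(v))
    above = (v >= level) & finite
    # contiguous run containing the maximum
    i0 = i_max
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = i_max
    while i1 < len(v) - 1 and above[i1 + 1]:
        i1 += 1
    if i0 > 0 and np.isfinite(v[i0 - 1]) and v[i0 - 1] != v[i0]:
        frac = (level - v[i0 - 1]) / (v[i0] - v[i0 - 1])
        inner = float(r[i0 - 1] + frac * (r[i0] - r[i0 - 1]))
    else:
        inner = float(r[i0]) if i0 > 0 else 0.0
    if i1 < len(v) - 1 and np.isfinite(v[i1 + 1]) and v[i1 + 1] != v[i1]:
        frac = (v[i1] - level) / (v[i1] - v[i1 + 1])
        outer = float(r[i1] + frac * (r[i1 + 1] - r[i1]))
    else:
        outer = float(r[i1])
    return inner, outer


# --------------------------------------------------------------------------
# synthetic-image segmentation
# --------------------------------------------------------------------------


def segment_fixture(
    intensity: dict[str, np.ndarray],
    nuclear_channel: str = "dapi",
    ring_width: int = 2,
    pixel_size: float = 1.0,
    min_nucleus_area: int = 4,
    seed_min_distance: int = 3,
) -> LabeledImage:
    """Threshold + watershed segmentation of a synthetic nuclear channel.

    Nuclei are Otsu-thresholded and split at touching points by a watershed
    on the distance transform (seeds: distance-transform peaks at least
    ``seed_min_distance`` px apart); the cytoplasm of each cell is a ring of
    ``ring_width`` pixels around its nucleus (excluding other nuclei); the
    background is everything beyond any ring.  Intended for rendered
    fixtures, not for real micrographs.
    """
    nuc_img = np.asarray(intensity[nuclear_channel], dtype=float)
    if nuc_img.max() <= nuc_img.min():
        fg = np.zeros(nuc_img.shape, dtype=bool)
    else:
        fg = nuc_img > threshold_otsu(nuc_img)
    nuclear_labels = np.zeros(nuc_img.shape, dtype=np.int32)
    if fg.any():
        dist = ndimage.distance_transform_edt(fg)
        coords = peak_local_max(dist, min_distance=seed_min_distance,
                                labels=fg, exclude_border=False)
        seeds = np.zeros(nuc_img.shape, dtype=np.int32)
        seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        nuclear_labels = watershed(-dist, seeds, mask=fg).astype(np.int32)
        sizes = ndimage.sum_labels(np.ones_like(nuclear_labels), nuclear_labels,
                                   index=np.arange(1, nuclear_labels.max() + 1))
        small = np.nonzero(sizes < min_nucleus_area)[0] + 1
        if len(small):
            nuclear_labels[np.isin(nuclear_labels, small)] = 0
        nuclear_labels = relabel_sequential(nuclear_labels)[0].astype(np.int32)

    expanded = expand_labels(nuclear_labels, distance=ring_width)
    cyto_labels = np.where(nuclear_labels > 0, 0, expanded).astype(np.int32)
    # keep label sets identical (a nucleus fully enclosed by neighbors could
    # lose its ring)
    nuc_set = set(np.unique(nuclear_labels)) - {0}
    cyt_set = set(np.unique(cyto_labels)) - {0}
    for missing in nuc_set - cyt_set:
        nuclear_labels[nuclear_labels == missing] = 0
    background = expanded == 0
    return LabeledImage(intensity=dict(intensity),
                        nuclear_labels=nuclear_labels,
                        cyto_labels=cyto_labels,
                        background_mask=background,
                        pixel_size=pixel_size)
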