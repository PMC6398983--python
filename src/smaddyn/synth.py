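"""Synthetic-data generators with machine-readable ground truth.

Everything the measurement modules consume can be generated here with known
truth: single-cell signaling trajectory ensembles, rendered cell-field
images (disk nuclei + ring cytoplasms with calibrated shot/read noise),
FRAP trace ensembles from the shuttling model, and micropattern colony
radial dynamics.

Colony dynamics are phenomenological — a programmed edge restriction and a
programmed inward-traveling wave — because the claim under test downstream
is the *measurement* of rapid signaling change (front position, velocity,
onset), not its mechanism.  Channels:

* SMAD4   — uniform early response, restriction to an edge band, then an
            inward wave (edge + wave superimposed; the shared co-transducer
            convolves both pathways);
* pSMAD1  — uniform early response restricted to the edge band; no wave;
* SMAD2/3 — the inward wave (with a faint edge presence beforehand);
* BRA     — first-order accumulation behind the wavefront (gene kinetics),
            the lagging expression domain.

Every generator emits a ground-truth sidecar; closure tests elsewhere read
only the sidecar.  All randomness flows through a seed; identical seed and
parameters reproduce identical arrays bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import ShuttlingParams, FrapTrace, simulate_frap
from .imagequant import Kymograph
from .models import SignalTrajectory

__all__ = [
    "ColonyDynamicsParams",
    "RenderParams",
    "generate_trajectories",
    "render_cell_field",
    "generate_frap_ensemble",
    "generate_colony",
    "colony_signal",
    "write_image_stack",
    "read_image_stack",
]


def write_image_stack(path: str | Path, channels: dict[str, np.ndarray]) -> None:
    """Write named 2-D channels as one multi-page TIFF (one page per channel).

    Channel names are stored in the page descriptions; label masks can be
    passed alongside intensity channels (integer arrays stay integer).
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, arr in channels.items():
            tif.write(np.asarray(arr), description=name)


def read_image_stack(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multi-page TIFF written by :func:`write_image_stack`."""
    out: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = page.description or f"channel_{i}"
            out[name] = page.asarray()
    return out


# --------------------------------------------------------------------------
# trajectory ensembles
# --------------------------------------------------------------------------


def generate_trajectories(
    base: SignalTrajectory,
    n_cells: int = 700,
    noise_cv: float = 0.2,
    obs_noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Per-cell trajectories around a shared model solution.

    Each cell scales the excess over baseline by a lognormal amplitude with
    unit mean and coefficient of variation ``noise_cv`` (cell-to-cell
    variability), plus additive Gaussian observation noise.  Returns an
    ``(n_cells, len(t))`` array and a ground-truth sidecar.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    s0 = base.S0
    excess = base.S - s0
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        amps = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n_cells)
    else:
        amps = np.ones(n_cells)
    traj = s0 + amps[:, None] * excess[None, :]
    if obs_noise_sd > 0:
        traj = traj + rng.normal(0.0, obs_noise_sd, size=traj.shape)
    sidecar = {
        "kind": "trajectory_ensemble", "n_cells": n_cells, "noise_cv": noise_cv,
        "obs_noise_sd": obs_noise_sd, "seed": seed, "S0": s0,
        "model_name": base.model_name, "schedule_name": base.schedule_name,
        "mean_solution": base.S.tolist(),
    }
    return traj, sidecar


# --------------------------------------------------------------------------
# rendered cell fields
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderParams:
    """Parameters for rendering a field of disk-nucleus / ring-cytoplasm cells.

    Intensities are set so the noiseless background-subtracted
    nuclear:cytoplasmic ratio equals each cell's programmed value:
    ``nuc = bg + ratio * (cyt - bg)``.  Shot noise is Poisson at the pixel
    intensity (photon gain 1), read noise additive Gaussian.
    """

    shape: tuple[int, int] = (512, 512)
    n_cells: int = 200
    nucleus_radius_px: int = 4
    ring_width_px: int = 2
    pixel_size: float = 1.0        # um / px
    bg_level: float = 20.0
    cyt_level: float = 120.0
    dapi_level: float = 200.0
    poisson_noise: bool = True
    read_noise_sd: float = 1.0
    max_place_attempts: int = 20000

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_px < 1 or self.ring_width_px < 1:
            raise ValueError("nucleus radius and ring width must be >= 1 px")
        if self.cyt_level <= self.bg_level:
            raise ValueError("cytoplasm level must exceed background")


def _place_cells(
    rp: RenderParams,
    rng: np.random.Generator,
    region_center: tuple[float, float] | None = None,
    region_radius: float | None = None,
) -> np.ndarray:
    """Non-overlapping (row, col) centers by rejection sampling."""
    h, w = rp.shape
    min_d = 2 * (rp.nucleus_radius_px + rp.ring_width_px) + 1
    margin = rp.nucleus_radius_px + rp.ring_width_px + 1
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < rp.n_cells and attempts < rp.max_place_attempts:
        attempts += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if region_radius is not None:
            cy, cx = region_center
            if math.hypot(y - cy, x - cx) > region_radius - margin:
                continue
        if all((y - py) ** 2 + (x - px) ** 2 >= min_d ** 2 for py, px in pts):
            pts.append((y, x))
    if len(pts) < rp.n_cells:
        raise RuntimeError(
            f"placed only {len(pts)}/{rp.n_cells} non-overlapping cells; "
            "reduce n_cells or cell size"
        )
    return np.array(pts)


def render_cell_field(
    ratios: Sequence[float],
    render: RenderParams,
    seed: int = 0,
    positions: np.ndarray | None = None,
    region_center: tuple[float, float] | None = None,
    region_radius: float | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], pd.DataFrame]:
    """Render cells with programmed nuc:cyt ratios.

    Returns ``(images, masks, truth)``: intensity channels ('signal',
    'dapi'), ground-truth label masks ('nuclear_labels', 'cyto_labels',
    'background_mask'), and a per-cell table (cell_id, x_um, y_um,
    true_ratio).  ``positions`` (row, col pixel centers) may be supplied to
    keep cells fixed across frames.
    """
    rp = render
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) != rp.n_cells:
        rp = RenderParams(**{**asdict(rp), "n_cells": len(ratios)})
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = _place_cells(rp, rng, region_center, region_radius)
    h, w = rp.shape
    yy, xx = np.mgrid[0:h, 0:w]
    signal = np.full((h, w), rp.bg_level)
    dapi = np.full((h, w), rp.bg_level * 0.25)
    nuclear_labels = np.zeros((h, w), dtype=np.int32)
    cyto_labels = np.zeros((h, w), dtype=np.int32)

    rows = []
    for i, ((cy, cx), ratio) in enumerate(zip(positions, ratios), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuc = d2 <= rp.nucleus_radius_px ** 2
        ring = (d2 <= (rp.nucleus_radius_px + rp.ring_width_px) ** 2) & ~nuc
        nuc_val = rp.bg_level + ratio * (rp.cyt_level - rp.bg_level)
        signal[nuc] = nuc_val
        signal[ring] = rp.cyt_level
        dapi[nuc] = rp.dapi_level
        nuclear_labels[nuc] = i
        cyto_labels[ring] = i
        rows.append({"cell_id": i, "x_um": cx * rp.pixel_size,
                     "y_um": cy * rp.pixel_size, "true_ratio": float(ratio)})

    if rp.poisson_noise:
        signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
        dapi = rng.poisson(np.clip(dapi, 0, None)).astype(float)
    if rp.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, rp.read_noise_sd, size=signal.shape)
        dapi = dapi + rng.normal(0.0, rp.read_noise_sd, size=dapi.shape)

    images = {"signal": signal, "dapi": dapi}
    masks = {"nuclear_labels": nuclear_labels, "cyto_labels": cyto_labels,
             "background_mask": (nuclear_labels == 0) & (cyto_labels == 0)}
    truth = pd.DataFrame(rows)
    return images, masks, truth


# --------------------------------------------------------------------------
# FRAP ensembles
# --------------------------------------------------------------------------


def generate_frap_ensemble(
    shuttling: ShuttlingParams,
    n_cells: int = 12,
    jitter_cv: float = 0.05,
    noise_sd: float = 0.5,
    seed: int = 0,
    condition: str = "untreated",
    dt: float = 10.0,
) -> tuple[list[FrapTrace], dict]:
    """FRAP traces for an ensemble of cells sharing k_in.

    Per-cell lognormal jitter (CV ``jitter_cv``) is applied to k_out and to
    the sequestered fractions (clipped below 0.95); measurement noise is
    additive Gaussian on the intensities.  The floor of 12 cells matches
    typical per-condition FRAP sample sizes.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + jitter_cv ** 2)) if jitter_cv > 0 else 0.0

    def jitter(x: float) -> float:
        if sigma == 0:
            return x
        return float(x * rng.lognormal(-0.5 * sigma ** 2, sigma))

    traces = []
    for i in range(n_cells):
        p = ShuttlingParams(
            k_in=shuttling.k_in,
            k_out=jitter(shuttling.k_out),
            f_ns=min(jitter(shuttling.f_ns), 0.95) if shuttling.f_ns > 0 else 0.0,
            f_cs=min(jitter(shuttling.f_cs), 0.95) if shuttling.f_cs > 0 else 0.0,
            bleach_eff=shuttling.bleach_eff,
        )
        traces.append(simulate_frap(p, dt=dt, rng=rng, noise_sd=noise_sd,
                                    cell_id=i, condition=condition))
    sidecar = {
        "kind": "frap_ensemble", "n_cells": n_cells, "jitter_cv": jitter_cv,
        "noise_sd": noise_sd, "seed": seed, "condition": condition,
        "k_in": shuttling.k_in, "k_out": shuttling.k_out,
        "f_ns": shuttling.f_ns, "f_cs": shuttling.f_cs,
        "bleach_eff": shuttling.bleach_eff,
        "recovery_rate": shuttling.recovery_rate,
    }
    return traces, sidecar


# --------------------------------------------------------------------------
# micropattern colony dynamics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ColonyDynamicsParams:
    """Programmed radial dynamics of a micropatterned colony ensemble.

    colony_diameter        um (700 for live-imaged colonies)
    uniform_phase_end      hr; initial uniform response lasts at least this long
    edge_restriction_time  hr; interior response has fallen below half the
                           edge signal by this time
    edge_band_width        um; width of the persistent edge response band
    wave_onset             hr; the inward wave leaves the edge band
    wave_velocity          um/hr (~ one cell diameter per hour)
    front_width            um; 10-90% extent of the logistic front
    restriction_tau        hr; sharpness of the interior shutdown
    noise_cv               per-colony lognormal amplitude variation
    read_noise_sd          per-bin Gaussian noise, fraction of dynamic range
    n_colonies             kymographs are averaged over this many colonies

    The wavefront emanates from the inner shoulder of the edge band:
    r_front(t) = (colony_radius - edge_band_width) - wave_velocity*(t - wave_onset),
    clipped at 0.
    """

    colony_diameter: float = 700.0
    uniform_phase_end: float = 4.0
    edge_restriction_time: float = 12.0
    edge_band_width: float = 50.0
    wave_onset: float = 25.0
    wave_velocity: float = 10.0
    front_width: float = 40.0
    restriction_tau: float = 1.5
    bin_width: float = 20.0
    t_end: float = 42.0
    dt: float = 0.5
    noise_cv: float = 0.2
    read_noise_sd: float = 0.01
    n_colonies: int = 4
    bra_rate: float = 1.0       # 1/hr
    bra_decay: float = 0.05     # 1/hr
    bra_theta: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.uniform_phase_end < self.edge_restriction_time < self.wave_onset:
            raise ValueError(
                "need 0 < uniform_phase_end < edge_restriction_time < wave_onset"
            )
        if self.wave_velocity < 0:
            raise ValueError("wave_velocity must be non-negative")
        if self.edge_band_width <= 0 or self.edge_band_width >= self.colony_radius:
            raise ValueError("edge_band_width must lie inside the colony")

    @property
    def colony_radius(self) -> float:
        return 0.5 * self.colony_diameter

    @property
    def band_shoulder(self) -> float:
        return self.colony_radius - self.edge_band_width

    def front_position(self, t) -> np.ndarray:
        """Programmed front (half-max) radius at time(s) t, clipped at 0."""
        t = np.asarray(t, dtype=float)
        r = self.band_shoulder - self.wave_velocity * (t - self.wave_onset)
        r = np.where(t < self.wave_onset, self.band_shoulder, r)
        return np.clip(r, 0.0, None)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def colony_signal(params: ColonyDynamicsParams, r, t, channel: str = "SMAD4"):
    """Noiseless programmed signal (baseline-subtracted, ~[0, 1]) at (r, t).

    Vectorized over ``r``; scalar ``t``.  Channels: SMAD4, pSMAD1, SMAD2/3.
    (BRA requires time integration; see :func:`generate_colony`.)
    """
    p = params
    r = np.asarray(r, dtype=float)
    w = p.front_width / 4.4  # logistic scale from 10-90% extent
    interior = float(_logistic(-(np.asarray(t) - (p.edge_restriction_time
                                                  - p.restriction_tau))
                               / p.restriction_tau))
    band = _logistic((r - p.band_shoulder) / w)
    if channel == "pSMAD1":
        return np.maximum(interior, band)
    wave = np.zeros_like(r)
    if t >= p.wave_onset:
        c = float(p.front_position(t))
        wave = _logistic((r - c) / w)
    if channel == "SMAD4":
        return np.maximum(np.maximum(interior, band), wave)
    if channel == "SMAD2/3":
        return 0.05 + 0.95 * np.maximum(wave, 0.15 * band)
    raise ValueError(f"unknown channel {channel!r}")


def generate_colony(
    params: ColonyDynamicsParams | None = None,
) -> tuple[dict[str, Kymograph], dict]:
    """Per-channel raw kymographs for a colony ensemble, plus ground truth.

    Values are baseline-subtracted signaling intensities in arbitrary units;
    each of ``n_colonies`` colonies gets a lognormal amplitude factor
    (CV ``noise_cv``) and per-bin Gaussian read noise before averaging.
    """
    p = params if params is not None else ColonyDynamicsParams()
    rng = np.random.default_rng(p.seed)
    R = p.colony_radius
    r = np.arange(0.5 * p.bin_width, R - 0.5 * p.bin_width + 1e-9, p.bin_width)
    t = np.arange(0.0, p.t_end + 1e-9, p.dt)

    clean: dict[str, np.ndarray] = {}
    for ch in ("SMAD4", "pSMAD1", "SMAD2/3"):
        clean[ch] = np.vstack([colony_signal(p, r, ti, ch) for ti in t])

    # BRA: first-order production behind the wavefront driven by SMAD2/3
    s23 = clean["SMAD2/3"]
    bra = np.zeros_like(s23)
    for i in range(1, len(t)):
        drive = np.maximum(s23[i] - p.bra_theta, 0.0)
        h = drive / (drive + 0.1)
        dtau = t[i] - t[i - 1]
        decay = math.exp(-p.bra_decay * dtau)
        bra[i] = bra[i - 1] * decay + p.bra_rate * h / p.bra_decay * (1 - decay)
    clean["BRA"] = bra

    sigma = math.sqrt(math.log(1.0 + p.noise_cv ** 2)) if p.noise_cv > 0 else 0.0
    kyms: dict[str, Kymograph] = {}
    for ch, mat in clean.items():
        rngs = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))  # stream per channel
        acc = np.zeros_like(mat)
        scale = float(np.nanmax(mat) - np.nanmin(mat)) or 1.0
        for _c in range(p.n_colonies):
            amp = (rngs.lognormal(-0.5 * sigma ** 2, sigma) if sigma > 0 else 1.0)
            noisy = amp * mat + rngs.normal(0.0, p.read_noise_sd * scale, mat.shape)
            acc += noisy
        acc /= p.n_colonies
        kyms[ch] = Kymograph(
            r_centers=r.copy(), t=t.copy(), matrix=acc, channel=ch,
            normalization="raw",
            meta={"colony_radius": R, "bin_width": p.bin_width,
                  "n_colonies": p.n_colonies, "seed": p.seed},
        )

    sidecar = {
        "kind": "colony_dynamics",
        "params": asdict(p),
        "wave_onset": p.wave_onset,
        "wave_velocity": p.wave_velocity,
        "edge_restriction_time": p.edge_restriction_time,
        "front_start_radius": p.band_shoulder,
        "colony_radius": R,
    }
    return kyms, sidecar


def generate_colony_frames(
    params: ColonyDynamicsParams,
    render: RenderParams,
    times: Sequence[float],
    seed: int = 0,
    cell_noise_cv: float = 0.2,
):
    """Rendered image series of one colony: yields (t, images, masks, truth).

    Cells are placed once inside the colony disk and keep their positions;
    at each frame every cell's nuc:cyt ratio is ``1 + s(r, t) * f`` with the
    noiseless SMAD4 signal ``s`` at the cell's radius and a fresh per-cell
    lognormal factor ``f`` (CV ``cell_noise_cv``).  The rendered baseline
    ratio is 1.  A ground-truth sidecar dict is yielded first.
    """
    p, rp = params, render
    rng = np.random.default_rng(seed)
    center_px = (rp.shape[0] / 2.0, rp.shape[1] / 2.0)
    radius_px = p.colony_radius / rp.pixel_size
    positions = _place_cells(rp, rng, region_center=center_px,
                             region_radius=radius_px)
    r_um = np.hypot(positions[:, 0] - center_px[0],
                    positions[:, 1] - center_px[1]) * rp.pixel_size
    sigma = (math.sqrt(math.log(1.0 + cell_noise_cv ** 2))
             if cell_noise_cv > 0 else 0.0)
    sidecar = {
        "kind": "colony_frames", "seed": seed, "cell_noise_cv": cell_noise_cv,
        "n_cells": len(positions), "center_um":
            (center_px[1] * rp.pixel_size, center_px[0] * rp.pixel_size),
        "colony_radius": p.colony_radius, "wave_onset": p.wave_onset,
        "wave_velocity": p.wave_velocity,
        "edge_restriction_time": p.edge_restriction_time,
        "front_start_radius": p.band_shoulder, "baseline_ratio": 1.0,
    }
    yield sidecar
    for t in times:
        s = colony_signal(p, r_um, float(t), "SMAD4")
        if sigma > 0:
            f = rng.lognormal(-0.5 * sigma ** 2, sigma, size=len(s))
        else:
            f = np.ones_like(s)
        ratios = 1.0 + s * f
        frame_seed = int(rng.integers(0, 2 ** 31 - 1))
        images, masks, truth = render_cell_field(
            ratios, rp, seed=frame_seed, positions=positions)
        yield float(t), images, masks, truth
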