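"""Seeded synthetic-data generators for every analysis input.

Each generator is bit-reproducible given its parameters and seed, and
returns the ground truth used to construct the data alongside the data
itself, so parameter-recovery tests can compare against construction-time
labels rather than re-derived quantities.

Defaults mirror realistic culture statistics: inter-neuron distance peak
around 70 um, a ~10-um astrocyte-rich shell, calcium bursts tens of
seconds long sampled at 0.2 s/frame, LFP at 6 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import FluorescenceTrace, LfpTrace
from .model_core import CellType
from .simulator import CellPopulation

__all__ = [
    "make_cell_field",
    "make_fiber_image",
    "make_nucleus_stack",
    "make_ca_trace",
    "make_lfp_pair",
]


# --------------------------------------------------------------------------
# cell fields
# --------------------------------------------------------------------------

def make_cell_field(
    kind: str = "uniform",
    n_cells: int = 2000,
    astrocyte_fraction: float = 0.2,
    box: tuple = (1000.0, 200.0, 100.0),
    cluster_centers: tuple = (),
    cluster_sigma: float = 100.0,
    shell_thickness: float = 10.0,
    shell_astro_fraction: float = 0.393,
    core_astro_fraction: float = 0.058,
    min_spacing: float = 0.0,
    seed: int = 0,
) -> tuple[CellPopulation, dict]:
    """Synthetic post-aggregation cell fields with known ground truth.

    kinds
    -----
    ``uniform``
        Cells uniform in the box, astrocytes drawn at ``astrocyte_fraction``.
    ``clusters``
        Neuron positions drawn from isotropic Gaussians at
        ``cluster_centers`` (x positions; y/z centered in the box), clipped
        to the box.
    ``shell``
        An astrocyte-enriched surface layer of ``shell_thickness`` um
        (astrocyte probability ``shell_astro_fraction``) over a deep layer
        at ``core_astro_fraction`` — the synthetic analogue of the
        astrocytic sheath.
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = box
    truth: dict = {"kind": kind, "seed": seed}

    if kind == "uniform":
        pos = rng.uniform((0, 0, 0), (lx, ly, lz), size=(n_cells, 3))
        types = _draw_types(rng, n_cells, astrocyte_fraction)
        truth["astrocyte_fraction"] = astrocyte_fraction
    elif kind == "clusters":
        if not cluster_centers:
            raise ValueError("clusters kind requires cluster_centers")
        per = n_cells // len(cluster_centers)
        chunks = []
        for cx in cluster_centers:
            c = rng.normal(
                loc=(cx, ly / 2.0, lz / 2.0), scale=cluster_sigma, size=(per, 3)
            )
            chunks.append(c)
        pos = np.clip(np.concatenate(chunks), 0, (lx, ly, lz))
        types = _draw_types(rng, len(pos), astrocyte_fraction)
        truth["cluster_centers"] = tuple(cluster_centers)
    elif kind == "shell":
        pos = rng.uniform((0, 0, 0), (lx, ly, lz), size=(n_cells, 3))
        depth = lz - pos[:, 2]  # flat slab: surface is the top plane
        p_astro = np.where(depth <= shell_thickness, shell_astro_fraction, core_astro_fraction)
        types = np.where(
            rng.uniform(size=n_cells) < p_astro,
            int(CellType.ASTROCYTE),
            int(CellType.NEURON),
        )
        truth.update(
            shell_thickness=shell_thickness,
            shell_astro_fraction=shell_astro_fraction,
            core_astro_fraction=core_astro_fraction,
            n_shell=int((depth <= shell_thickness).sum()),
        )
    else:
        raise ValueError(f"unknown cell-field kind {kind!r}")

    if min_spacing > 0:  # thin to a hard-core process
        keep = _hard_core_filter(pos, min_spacing)
        pos, types = pos[keep], types[keep]
        truth["min_spacing"] = min_spacing
    truth["n_cells"] = len(pos)
    return CellPopulation(pos, types), truth


def _draw_types(rng, n, astro_fraction):
    types = np.full(n, int(CellType.NEURON))
    n_astro = int(round(astro_fraction * n))
    types[rng.choice(n, size=n_astro, replace=False)] = int(CellType.ASTROCYTE)
    return types


def _hard_core_filter(pos: np.ndarray, spacing: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    keep = np.zeros(len(pos), dtype=bool)
    tree = cKDTree(pos)
    taken: list[int] = []
    for i in range(len(pos)):
        ok = True
        for j in tree.query_ball_point(pos[i], spacing):
            if j != i and keep[j]:
                ok = False
                break
        if ok:
            keep[i] = True
            taken.append(i)
    return keep


# --------------------------------------------------------------------------
# fiber images
# --------------------------------------------------------------------------

def make_fiber_image(
    angle_deg: float = 0.0,
    angular_jitter_deg: float = 0.0,
    n_fibers: int = 12,
    shape: tuple = (40, 40),
    fiber_intensity: float = 200.0,
    background: float = 10.0,
    noise_sigma: float = 5.0,
    line_width: int = 3,
    blur_sigma: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render line fibers at a dominant angle with angular jitter.

    Fibers are a few pixels wide and slightly blurred (confocal PSF
    analogue) so their autocorrelation decays smoothly along every lattice
    direction; 1-px unblurred lines only overlap themselves at special
    angles.  ``angular_jitter_deg`` large relative to 180 yields an
    effectively isotropic patch.
    """
    from skimage.draw import line as draw_line

    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background, dtype=float)
    diag = int(np.hypot(h, w))
    for _ in range(n_fibers):
        theta = np.deg2rad(angle_deg + rng.normal(0.0, angular_jitter_deg)) if angular_jitter_deg < 1e3 else rng.uniform(0, np.pi)
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        dy = -np.sin(theta)  # rows grow downward; CCW-positive angles
        dx = np.cos(theta)
        r0 = int(round(cy - dy * diag))
        c0 = int(round(cx - dx * diag))
        r1 = int(round(cy + dy * diag))
        c1 = int(round(cx + dx * diag))
        rr, cc = draw_line(r0, c0, r1, c1)
        for off in range(line_width):
            rr2 = np.clip(rr + off, 0, h - 1)
            inside = (cc >= 0) & (cc < w)
            img[rr2[inside], cc[inside]] = fiber_intensity
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, blur_sigma)
    img += rng.normal(0.0, noise_sigma, size=shape)
    img = np.clip(img, 0.0, None)
    truth = {"angle_deg": angle_deg, "angular_jitter_deg": angular_jitter_deg, "seed": seed}
    return img, truth


# --------------------------------------------------------------------------
# nucleus stacks
# --------------------------------------------------------------------------

def make_nucleus_stack(
    semi_axes: tuple = (10.0, 4.0, 4.0),
    angle_deg: float = 0.0,
    voxel_size: float = 1.0,
    pad: int = 4,
    intensity: float = 200.0,
    background: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Voxelized ellipsoid nucleus with semi-axes (a, b, c) um.

    ``a`` lies along x rotated by ``angle_deg`` in the XY plane, ``b`` is
    the in-plane normal and ``c`` the z semi-axis.  Returns a (z, y, x)
    grayscale stack.
    """
    rng = np.random.default_rng(seed)
    a, b, c = semi_axes
    th = np.deg2rad(angle_deg)
    extent_xy = max(a, b) / voxel_size + pad
    extent_z = c / voxel_size + pad
    nx = int(np.ceil(2 * extent_xy)) | 1
    nz = int(np.ceil(2 * extent_z)) | 1
    zc, yc, xc = nz // 2, nx // 2, nx // 2
    z, y, x = np.mgrid[0:nz, 0:nx, 0:nx].astype(float)
    x = (x - xc) * voxel_size
    y = (y - yc) * voxel_size
    z = (z - zc) * voxel_size
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 + (z / c) ** 2 <= 1.0
    vol = np.where(inside, intensity, background)
    if noise_sigma > 0:
        vol = np.clip(vol + rng.normal(0, noise_sigma, vol.shape), 0, None)
    truth = {"semi_axes": semi_axes, "angle_deg": angle_deg, "voxel_size": voxel_size}
    return vol, truth


# --------------------------------------------------------------------------
# calcium traces
# --------------------------------------------------------------------------

@dataclass
class CaTraceSpec:
    """Parameters of a synthetic calcium trace."""

    duration_s: float = 600.0
    frame_interval: float = 0.2
    baseline_level: float = 100.0
    drift_amplitude: float = 3.0
    drift_period_s: float = 300.0
    trend_per_s: float = 0.005
    burst_onsets_s: tuple = (60.0, 180.0, 300.0, 420.0, 520.0)
    burst_durations_s: tuple = (30.0, 35.0, 34.0, 40.0, 34.0)
    burst_amplitude: float = 50.0
    noise_sigma: float = 1.0


def make_ca_trace(spec: CaTraceSpec | None = None, seed: int = 0) -> tuple[FluorescenceTrace, dict]:
    """Drifting baseline + boxcar-with-rounded-edges burst transients + noise."""
    spec = spec or CaTraceSpec()
    if len(spec.burst_onsets_s) != len(spec.burst_durations_s):
        raise ValueError("burst onsets and durations must have equal length")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.duration_s, spec.frame_interval)
    base = (
        spec.baseline_level
        + spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period_s)
        + spec.trend_per_s * t
    )
    from scipy.special import expit

    signal = np.zeros_like(t)
    for onset, dur in zip(spec.burst_onsets_s, spec.burst_durations_s):
        # sharp (50 ms) edges: the nominal onset is recoverable to a frame
        rise = expit((t - onset) / 0.05)
        fall = expit(-(t - onset - dur) / 0.05)
        signal += spec.burst_amplitude * rise * fall
    values = np.clip(base + signal + rng.normal(0, spec.noise_sigma, t.shape), 0, None)
    truth = {
        "burst_onsets_s": tuple(spec.burst_onsets_s),
        "burst_durations_s": tuple(spec.burst_durations_s),
        "burst_amplitude": spec.burst_amplitude,
        "baseline": base,
        "seed": seed,
    }
    return FluorescenceTrace(values, spec.frame_interval), truth


# --------------------------------------------------------------------------
# LFP channel pairs
# --------------------------------------------------------------------------

@dataclass
class LfpPairSpec:
    """Parameters of a synthetic center/edge LFP channel pair."""

    duration_s: float = 120.0
    sample_rate: float = 6000.0
    n_bursts: int = 8
    burst_duration_s: float = 1.0
    burst_amplitude: float = 60.0
    noise_sigma: float = 0.5
    center_lead_prob: float = 0.92
    lead_ms: float = 30.0


def make_lfp_pair(spec: LfpPairSpec | None = None, seed: int = 0) -> tuple[LfpTrace, LfpTrace, dict]:
    """Shared burst envelopes on two channels with per-burst lead/lag.

    Each burst leads on the center channel with probability
    ``center_lead_prob`` by ``lead_ms`` (otherwise the edge leads).
    Returns (edge, center, truth) with the per-burst initiation times and
    lead labels.
    """
    spec = spec or LfpPairSpec()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.sample_rate))
    edge = rng.normal(0, spec.noise_sigma, n)
    center = rng.normal(0, spec.noise_sigma, n)
    gap = spec.duration_s / (spec.n_bursts + 1)
    onsets = (np.arange(1, spec.n_bursts + 1) * gap) + rng.uniform(-0.1, 0.1, spec.n_bursts)
    leads = rng.uniform(size=spec.n_bursts) < spec.center_lead_prob
    burst_len = int(round(spec.burst_duration_s * spec.sample_rate))
    shift = int(round(spec.lead_ms / 1000.0 * spec.sample_rate))
    # trapezoidal rectified envelope: a sharp (2 ms) attack pins the
    # threshold-crossing time to the burst onset within a sample or two
    attack = max(int(round(0.002 * spec.sample_rate)), 1)
    release = max(burst_len - attack, 1)
    burst_wave = spec.burst_amplitude * np.concatenate(
        [np.linspace(0.0, 1.0, attack, endpoint=False), np.linspace(1.0, 0.0, release)]
    )[:burst_len]
    t_edge, t_center = [], []
    for onset, center_leads in zip(onsets, leads):
        i0 = int(round(onset * spec.sample_rate))
        ic, ie = (i0, i0 + shift) if center_leads else (i0 + shift, i0)
        for sig, i, rec in ((center, ic, t_center), (edge, ie, t_edge)):
            j = min(i + burst_len, n)
            sig[i:j] += burst_wave[: j - i]
            rec.append(i / spec.sample_rate)
    truth = {
        "center_lead": leads,
        "edge_times_s": np.array(t_edge),
        "center_times_s": np.array(t_center),
        "lead_ms": spec.lead_ms,
        "seed": seed,
    }
    return LfpTrace(edge, spec.sample_rate), LfpTrace(center, spec.sample_rate), truth
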