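"""Quantitative descriptors of culture morphology.

* **CCDP** (cell-to-cell distance profile): probability-normalized histogram
  of pairwise neuron-center distances at 5-um bin width; its peak is the
  most probable inter-neuron distance.
* **Cluster segmentation**: neurons counted in 10-um bins along the
  culture's long axis; local minima of the (smoothed) count profile mark
  cluster edges.
* **Cluster CCDP**: within each cluster, planar pairwise distances are
  accumulated per 10-um z-slab (cells in different slabs are never paired),
  pooled into a per-cluster CCDP; the mean CCDP averages clusters.
* **Contraction**: percent shortening of the robust x-extent between the
  initial and the final state.
* **Depth profile**: astrocyte fraction versus depth below the local
  aggregate surface, with the superficial (top 10 um) ratio and the maximum
  deep-layer ratio as scalar summaries.
* **Force-morphology correlation**: Pearson correlation of each type-pair
  attraction constant against superficial astrocyte ratio across a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .simulator import CellPopulation

__all__ = [
    "CCDProfile",
    "ClusterSegmentation",
    "DepthProfile",
    "ccdp",
    "ccdp_from_population",
    "segment_clusters",
    "cluster_ccdp",
    "contraction",
    "normalized_contraction",
    "depth_profile",
    "force_morphology_correlation",
]

CCDP_BIN_WIDTH = 5.0  # um
CLUSTER_BIN_WIDTH = 10.0  # um
Z_BIN_WIDTH = 10.0  # um


@dataclass
class CCDProfile:
    """Probability-normalized pairwise-distance histogram."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("need len(bin_edges) == len(probabilities) + 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be >= 0")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak(self) -> float:
        """Center of the maximal bin; ties broken toward smaller distance."""
        return float(self.bin_centers[int(np.argmax(self.probabilities))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers, "probability": self.probabilities}
        )


@dataclass
class ClusterSegmentation:
    """Cluster intervals along the culture long axis."""

    bin_width_x: float
    cluster_intervals: list  # list of (x_start, x_end)
    culture_extent: tuple  # (x_min, x_max)

    def __post_init__(self):
        lo, hi = self.culture_extent
        prev_end = lo
        for a, b in self.cluster_intervals:
            if not (lo - 1e-9 <= a < b <= hi + 1e-9) or a < prev_end - 1e-9:
                raise ValueError("cluster intervals must be ordered, disjoint and in extent")
            prev_end = b


@dataclass
class DepthProfile:
    """Astrocyte fraction binned by depth below the aggregate surface."""

    depth_bin_edges: np.ndarray
    astrocyte_ratio: np.ndarray
    total_count: np.ndarray
    superficial_ratio: float
    deep_max_ratio: float
    deep_ratio: float  # overall astrocyte fraction below the superficial layer


def ccdp(distances, bin_width: float = CCDP_BIN_WIDTH) -> CCDProfile:
    """CCDP of a set of pairwise distances (um)."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("ccdp requires at least one distance")
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return CCDProfile(edges, counts / counts.sum())


def ccdp_from_population(
    population: CellPopulation, bin_width: float = CCDP_BIN_WIDTH, planar: bool = False
) -> CCDProfile:
    """CCDP over all neuron pairs of a population (3D distances by default)."""
    pos = population.positions[population.neuron_mask]
    if len(pos) < 2:
        raise ValueError("need at least two neurons")
    return ccdp(pdist(pos[:, :2] if planar else pos), bin_width)


def _binned_neuron_counts(x: np.ndarray, bin_width: float):
    lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = int(np.floor((x.max() - lo) / bin_width)) + 1
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    return edges, counts


def segment_clusters(
    population: CellPopulation,
    bin_width: float = CLUSTER_BIN_WIDTH,
    smooth_bins: int = 3,
    extent_frac: float = 0.05,
    min_prominence_frac: float = 0.05,
) -> ClusterSegmentation:
    """Segment neuron clusters along x from the binned count profile.

    Neuron counts in ``bin_width`` x-bins are smoothed by a ``smooth_bins``
    moving average.  Bins with a smoothed count of at least ``extent_frac``
    of the maximum are *occupied*; the culture extent spans the first to
    the last occupied bin.  Cluster edges are local minima of the smoothed
    profile inside the extent whose dip prominence is at least
    ``max(min_prominence_frac * max_count, 2 * sqrt(max_count))`` — the
    shot-noise floor suppresses the spurious strict minima that Poisson
    count fluctuations produce in both sparse fields and dense aggregates,
    while genuine inter-cluster gaps (density dropping to near zero between
    tall peaks) always qualify.
    """
    x = population.positions[population.neuron_mask, 0]
    if x.size == 0:
        raise ValueError("segment_clusters requires neurons")
    edges, counts = _binned_neuron_counts(x, bin_width)
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(counts, kernel, mode="same")

    thresh = extent_frac * smoothed.max()
    occupied = smoothed >= thresh
    left = int(np.argmax(occupied))
    right = len(occupied) - 1 - int(np.argmax(occupied[::-1]))
    x_min, x_max = edges[left], edges[right + 1]

    from scipy.signal import find_peaks

    prominence = max(min_prominence_frac * smoothed.max(), 2.0 * np.sqrt(smoothed.max()))
    minima, _ = find_peaks(-smoothed[left : right + 1], prominence=prominence)
    cuts = [edges[left + i] + bin_width / 2.0 for i in minima]
    bounds = [x_min, *cuts, x_max]

    # Candidate intervals that never rise above the valley floor are
    # straggler territory between clusters (flat near-zero valleys can
    # contain several equal-depth minima); merge each into its neighbors,
    # splitting it at its center so the cluster edge lands mid-valley.
    def is_cluster(a, b):
        lo_bin = max(int(np.searchsorted(edges, a, side="right")) - 1, 0)
        hi_bin = max(min(int(np.searchsorted(edges, b, side="left")), len(smoothed)), lo_bin + 1)
        return smoothed[lo_bin:hi_bin].max() >= prominence

    candidates = list(zip(bounds[:-1], bounds[1:]))
    flags = [is_cluster(a, b) for a, b in candidates]
    if not any(flags):
        candidates, flags = [(x_min, x_max)], [True]
    merged: list[list] = []
    carry = None  # left edge inherited from a preceding valley half
    for (a, b), good in zip(candidates, flags):
        if good:
            merged.append([a if carry is None else carry, b])
            carry = None
        else:
            mid = (a + b) / 2.0
            if merged:
                merged[-1][1] = mid  # left half joins the previous cluster
                carry = mid
            else:
                carry = a  # leading valley joins the first cluster
    if flags and not flags[-1] and merged:  # trailing valley joins the last
        merged[-1][1] = x_max
    intervals = [
        (a, b)
        for a, b in merged
        if np.any((x >= a) & ((x < b) if b < x_max else (x <= b)))
    ]
    return ClusterSegmentation(bin_width, intervals, (x_min, x_max))


def cluster_ccdp(
    population: CellPopulation,
    segmentation: ClusterSegmentation,
    z_bin: float = Z_BIN_WIDTH,
    bin_width: float = CCDP_BIN_WIDTH,
) -> tuple[list, CCDProfile]:
    """Per-cluster CCDPs (planar, z-slab restricted) and their mean.

    Within each cluster interval the culture is sliced into ``z_bin`` slabs;
    only neuron pairs sharing a slab contribute, with planar (x-y)
    distances.  Clusters with fewer than two neurons in every slab are
    excluded.  The mean CCDP averages the per-cluster probability profiles
    on a common bin grid (and renormalizes, so mass stays exactly 1).
    """
    pos = population.positions[population.neuron_mask]
    profiles = []
    all_dists = []
    for a, b in segmentation.cluster_intervals:
        hi = segmentation.culture_extent[1]
        in_cluster = (pos[:, 0] >= a) & (pos[:, 0] < b if b < hi else pos[:, 0] <= b)
        cpos = pos[in_cluster]
        dists = []
        if len(cpos) >= 2:
            zidx = np.floor(cpos[:, 2] / z_bin).astype(int)
            for zb in np.unique(zidx):
                slab = cpos[zidx == zb]
                if len(slab) >= 2:
                    dists.append(pdist(slab[:, :2]))
        if dists:
            d = np.concatenate(dists)
            all_dists.append(d)
            profiles.append(ccdp(d, bin_width))
    if not profiles:
        raise ValueError("no cluster has two neurons sharing a z-slab")
    n_bins = max(len(p.probabilities) for p in profiles)
    edges = np.arange(n_bins + 1) * bin_width
    stack = np.zeros((len(profiles), n_bins))
    for r, p in enumerate(profiles):
        stack[r, : len(p.probabilities)] = p.probabilities
    mean_prob = stack.mean(axis=0)
    mean_prob = mean_prob / mean_prob.sum()
    return profiles, CCDProfile(edges, mean_prob)


def _robust_extent(x: np.ndarray) -> float:
    lo, hi = np.percentile(x, [0.5, 99.5])
    return float(hi - lo)


def contraction(initial: CellPopulation, final: CellPopulation) -> float:
    """Percent shortening of the robust culture x-extent (0.5-99.5 pctile).

    The extent covers all cells (neurons and astrocytes): the culture size
    seen in a phase-contrast image is the footprint of every cell, and a
    neuron-only extent would confound contraction with neuron count when
    comparing conditions of different cellular composition.
    """
    if len(initial) == 0 or len(final) == 0:
        raise ValueError("populations must be non-empty")
    l0 = _robust_extent(initial.positions[:, 0])
    lf = _robust_extent(final.positions[:, 0])
    if l0 <= 0:
        raise ValueError("initial extent is zero")
    return 100.0 * (l0 - lf) / l0


def normalized_contraction(values, reference_values) -> np.ndarray:
    """Contractions divided by the mean contraction of a reference condition."""
    ref = float(np.mean(reference_values))
    if ref == 0:
        raise ValueError("reference condition has zero mean contraction")
    return np.asarray(values, dtype=float) / ref


def depth_profile(
    population: CellPopulation,
    depth_bin: float = 10.0,
    column_pitch: float = 10.0,
    superficial_depth: float = 10.0,
    min_bin_count: int = 10,
) -> DepthProfile:
    """Astrocyte fraction versus depth below the local aggregate surface.

    Depth is measured per (x, y) grid column of ``column_pitch`` um: the
    local surface height is the maximum cell z over the column's 3x3
    neighborhood, and a cell's depth is surface minus its own z.  Cells on
    the lateral faces of the aggregate are excluded: there "depth below the
    top surface" is ill-defined because the column pierces the side shell.
    A lateral face is detected on a coarser footprint grid (3x the column
    pitch, so that shot noise in sparse fields does not punch spurious
    holes): a cell is excluded when its coarse column has an unoccupied
    neighbor.  The superficial ratio covers depths <= ``superficial_depth``;
    the deep maximum is the largest per-bin ratio at depths beyond it,
    among bins with at least ``min_bin_count`` cells.  Both scalars are
    invariant under rigid translation of the population.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    pos = population.positions
    # grids anchored at the population minimum: translation invariant
    x0, y0 = pos[:, 0].min(), pos[:, 1].min()
    ix = np.floor((pos[:, 0] - x0) / column_pitch).astype(int)
    iy = np.floor((pos[:, 1] - y0) / column_pitch).astype(int)
    top: dict[tuple, float] = {}
    for cx, cy, z in zip(ix, iy, pos[:, 2]):
        key = (cx, cy)
        if top.get(key, -np.inf) < z:
            top[key] = z
    surface = np.empty(len(pos))
    for n, (cx, cy) in enumerate(zip(ix, iy)):
        s = -np.inf
        for ax in (-1, 0, 1):
            for ay in (-1, 0, 1):
                t = top.get((cx + ax, cy + ay))
                if t is not None and t > s:
                    s = t
        surface[n] = s

    coarse = 3.0 * column_pitch
    cx_ = np.floor((pos[:, 0] - x0) / coarse).astype(int)
    cy_ = np.floor((pos[:, 1] - y0) / coarse).astype(int)
    occupied = set(zip(cx_.tolist(), cy_.tolist()))
    interior = np.array(
        [
            all(
                (cx + ax, cy + ay) in occupied
                for ax in (-1, 0, 1)
                for ay in (-1, 0, 1)
            )
            for cx, cy in zip(cx_, cy_)
        ]
    )
    if interior.any():  # keep lateral-face cells only if nothing else exists
        pos = pos[interior]
        surface = surface[interior]
    else:
        interior = np.ones(len(pos), dtype=bool)
    depth = surface - pos[:, 2]
    astro = population.astrocyte_mask[interior]

    n_bins = int(np.floor(depth.max() / depth_bin)) + 1
    edges = np.arange(n_bins + 1) * depth_bin
    total, _ = np.histogram(depth, bins=edges)
    astro_counts, _ = np.histogram(depth[astro], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, astro_counts / np.maximum(total, 1), np.nan)

    sup = depth <= superficial_depth
    superficial_ratio = float(astro[sup].mean()) if sup.any() else np.nan
    deep_bins = (edges[:-1] >= superficial_depth) & (total >= min_bin_count)
    deep_max = float(np.nanmax(ratio[deep_bins])) if deep_bins.any() else np.nan
    deep = ~sup
    deep_ratio = float(astro[deep].mean()) if deep.any() else np.nan
    return DepthProfile(edges, ratio, total, superficial_ratio, deep_max, deep_ratio)


def force_morphology_correlation(sweep_table: pd.DataFrame) -> pd.Series:
    """Pearson correlation of each attraction-constant column against the
    superficial astrocyte ratio over a force-configuration sweep.

    Expects columns ``AS_NN, AS_NA, AS_AN, AS_AA`` and
    ``superficial_astro_ratio``.  Zero-variance force columns yield NaN.
    """
    cols = ["AS_NN", "AS_NA", "AS_AN", "AS_AA"]
    missing = [c for c in cols + ["superficial_astro_ratio"] if c not in sweep_table]
    if missing:
        raise ValueError(f"sweep table lacks columns {missing}")
    y_all = sweep_table["superficial_astro_ratio"].to_numpy(dtype=float)
    valid = np.isfinite(y_all)
    if valid.sum() < 3:
        raise ValueError("need at least 3 configurations with a finite ratio")
    y = y_all[valid]
    out = {}
    for c in cols:
        x = sweep_table[c].to_numpy(dtype=float)[valid]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out)
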