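"""Directionality of stained processes and nucleus axis/height morphometry.

Directionality of a 10 x 10 um image patch is decided from the anisotropy
of its thresholded binary autocorrelation: the central blob of the
correlation surface (thresholded at 70% of its maximum) is elongated when
the patch contains aligned fibers.  A patch is *directional* when the blob's
major/minor axis ratio is >= 2 and the major axis is >= 5 px; the alignment
angle is then the major-axis angle against the image x-axis (the culture's
long axis), in degrees within (-90, 90], counter-clockwise positive.

Nucleus morphometry consumes a 3D grayscale cuboid containing one nucleus:
components touching the lateral border are removed, each z-plane is eroded
(3x3 cross) and its outline extracted, and the maximum 3D distance between
outline voxels defines the major axis; the XY-projected angle of that axis
is the nucleus alignment, the z-range of the outline its height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d
from scipy.spatial.distance import pdist
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "RoiImage",
    "DirectionalityResult",
    "xcorr2d",
    "roi_directionality",
    "nucleus_axis_height",
]

DEFAULT_PIXEL_PITCH = 0.25  # um/px for a 40x40-px 10-um ROI


@dataclass
class RoiImage:
    """Single-channel grayscale ROI patch."""

    pixels: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ROI must be a 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class DirectionalityResult:
    directional: bool
    angle: float | None  # degrees in (-90, 90], None when non-directional
    major_len: float  # px
    minor_len: float  # px

    def __post_init__(self):
        if self.directional and self.angle is None:
            raise ValueError("directional result requires an angle")


def xcorr2d(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Full 2D cross-correlation of two equally shaped binary images.

    Returns the (2M-1) x (2N-1) surface with zero padding outside the
    supports; the central element equals ``sum(X * Y)``.
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if not (np.isin(X, (0, 1)).all() and np.isin(Y, (0, 1)).all()):
        raise ValueError("inputs must be binary (values in {0, 1})")
    return correlate2d(X.astype(float), Y.astype(float), mode="full")


def _central_blob(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    center = tuple(s // 2 for s in mask.shape)
    lab = labels[center]
    if lab == 0:  # pick the blob nearest to center (threshold ties)
        ids = np.unique(labels[labels > 0])
        if len(ids) == 0:
            return np.zeros_like(mask, dtype=bool)
        best, best_d = ids[0], np.inf
        for i in ids:
            pts = np.argwhere(labels == i)
            d = np.min(np.linalg.norm(pts - np.array(center), axis=1))
            if d < best_d:
                best, best_d = i, d
        lab = best
    return labels == lab


def _edge_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the blob's boundary pixels."""
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    inner = ndi.binary_erosion(mask, structure=cross)
    return np.argwhere(mask & ~inner)


def _major_axis(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Longest pairwise separation between edge points."""
    if len(points) == 1:
        return 0.0, points[0], points[0]
    d = pdist(points.astype(float))
    k = int(np.argmax(d))
    # map condensed index back to the pair
    n = len(points)
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
    return float(d[k]), points[i], points[j]


def _minor_axis(mask: np.ndarray, midpoint: np.ndarray, major_dir: np.ndarray) -> float:
    """Shortest chord of the blob through the major-axis midpoint.

    Scans candidate directions and measures the in-blob extent of the ray
    through the midpoint in each; ties resolve to the shorter chord.
    """
    h, w = mask.shape
    best = np.inf
    for theta in np.deg2rad(np.arange(0.0, 180.0, 1.0)):
        u = np.array([np.sin(theta), np.cos(theta)])  # (row, col)
        length = 0.0
        for sgn in (1.0, -1.0):
            t = 0.0
            while True:
                t += 0.25
                p = midpoint + sgn * t * u
                r, c = int(round(p[0])), int(round(p[1]))
                if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
                    break
            length += t - 0.25
        best = min(best, length)
    return float(best)


def roi_directionality(
    roi: RoiImage | np.ndarray,
    intensity_threshold: float = 55.0,
    surface_threshold_frac: float = 0.70,
    min_axis_ratio: float = 2.0,
    min_major_px: float = 5.0,
) -> DirectionalityResult:
    """Directionality verdict and alignment angle of one ROI.

    The patch is binarized at ``intensity_threshold``, autocorrelated, the
    correlation surface thresholded at ``surface_threshold_frac`` of its
    own maximum, and the central blob's major/minor axes measured.  The ROI
    is non-directional when the axis ratio is < 2 or the major axis < 5 px.
    """
    pixels = roi.pixels if isinstance(roi, RoiImage) else np.asarray(roi)
    if pixels.size == 0:
        raise ValueError("empty ROI")
    binary = (pixels >= intensity_threshold).astype(int)
    if not binary.any():
        return DirectionalityResult(False, None, 0.0, 0.0)
    surface = xcorr2d(binary, binary)
    assert np.allclose(surface, surface[::-1, ::-1]), "autocorrelation not symmetric"
    mask = surface >= surface_threshold_frac * surface.max()
    blob = _central_blob(mask)
    pts = _edge_points(blob)
    if len(pts) == 0:
        return DirectionalityResult(False, None, 0.0, 0.0)
    major, p1, p2 = _major_axis(pts)
    mid = (p1 + p2) / 2.0
    vec = (p2 - p1).astype(float)
    minor = _minor_axis(blob, mid, vec / max(np.linalg.norm(vec), 1e-12)) if major > 0 else 0.0
    directional = minor > 0 and major / minor >= min_axis_ratio and major >= min_major_px
    angle = None
    if directional:
        # rows grow downward: negate the row component for CCW-positive angles
        angle = float(np.degrees(np.arctan2(-vec[0], vec[1])))
        if angle <= -90.0:
            angle += 180.0
        elif angle > 90.0:
            angle -= 180.0
    return DirectionalityResult(directional, angle, major, minor)


def nucleus_axis_height(
    voxels: np.ndarray,
    voxel_size: float | tuple = 1.0,
    threshold: float | None = None,
) -> tuple[float, float]:
    """Alignment angle (deg, XY vs x-axis) and height (um) of one nucleus.

    ``voxels`` is a (z, y, x) grayscale cuboid containing a single nucleus.
    Steps: binarize (midpoint threshold unless given), remove components
    touching the lateral (x/y) border, erode each z-plane with a 3x3 cross,
    take each plane's outline, then the maximum 3D Euclidean distance
    between outline voxels defines the major axis.  ``voxel_size`` may be a
    scalar or (dz, dy, dx) in um.
    """
    vol = np.asarray(voxels, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    if threshold is None:
        threshold = 0.5 * (vol.min() + vol.max())
    mask = vol > threshold

    # clear components touching the lateral border only (6-connectivity)
    labels = measure.label(mask, connectivity=1)
    border_labels = set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    border_labels.discard(0)
    for lab in border_labels:
        mask[labels == lab] = False
    if not mask.any():
        raise ValueError("nucleus touches border: nothing left after clearing")

    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    outline_pts = []
    for z in range(mask.shape[0]):
        plane = mask[z]
        if not plane.any():
            continue
        eroded = ndi.binary_erosion(plane, structure=cross)
        if not eroded.any():
            continue
        perim = eroded & ~ndi.binary_erosion(eroded, structure=cross)
        for r, c in np.argwhere(perim):
            outline_pts.append((z, r, c))
    if not outline_pts:
        raise ValueError("nucleus vanished under erosion")
    pts = np.asarray(outline_pts, dtype=float)
    scale = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    phys = pts * scale  # (z, y, x) um

    _, p1, p2 = _major_axis_phys(phys)
    dz, dy, dx = p2 - p1
    angle = float(np.degrees(np.arctan2(dy, dx)))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    height = float(phys[:, 0].max() - phys[:, 0].min())
    return angle, height


def _major_axis_phys(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Max-distance pair among 3D points (convex hull pruning for speed)."""
    pts = points
    if len(pts) > 400:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar) sets fall back to all pairs
            pass
    d = pdist(pts)
    k = int(np.argmax(d))
    n = len(pts)
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
    return float(d[k]), pts[i], pts[j]
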