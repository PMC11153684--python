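"""Initial-condition extraction from the CT volume.

Two artifacts are produced: the primary tumor (location tau_l in mm, radius
tau_s in mm) and the binary mask of healthy lung tissue where circulating
cancer cells can settle.

The lung mask is built slice-by-slice along z (the axial acquisition axis):
adaptive Canny edges -> a bounded discretized ellipse Hough search for the two
lung boundary ellipses -> accretion of edges connected to those ellipses and
morphological closure into two filled regions -> stacking and volumetric
Laplacian smoothing of the 3D shape.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import NoTumorFoundError, SegmentationError
from .io import VolumeImage

logger = logging.getLogger(__name__)

__all__ = [
    "TumorSpec",
    "LungMask",
    "Ellipse2D",
    "SegmentationParams",
    "detect_primary_tumor",
    "canny_slice",
    "hough_two_ellipses",
    "close_lung_contours",
    "reconstruct_lung_mask",
    "segment_lungs",
]


@dataclass
class TumorSpec:
    """Primary tumor: world-coordinate location (mm) and radius (mm)."""

    location: np.ndarray
    size: float

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        if self.location.shape != (3,):
            raise ValueError("tumor location must be a 3-vector")
        if not self.size > 0:
            raise ValueError("tumor size must be positive")


@dataclass
class LungMask:
    """Binary mask of settleable healthy tissue, with per-slice QC provenance."""

    mask: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("lung mask must be 3D")


@dataclass
class Ellipse2D:
    cx: float
    cy: float
    a: float  # semi-axis along the first slice axis
    b: float  # semi-axis along the second slice axis
    theta: float = 0.0
    score: float = 0.0

    def contains(self, x: float, y: float, scale: float = 1.0) -> bool:
        dx, dy = x - self.cx, y - self.cy
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        return (u / (scale * self.a)) ** 2 + (v / (scale * self.b)) ** 2 <= 1.0


@dataclass
class SegmentationParams:
    """Knobs of the slice-wise lung segmentation (all unconstrained defaults)."""

    canny_k: float = 0.33          # median-relative hysteresis band
    canny_sigma: float = 1.0
    center_stride: int = 2         # Hough center lattice stride (px)
    axis_min: int = 4              # smallest semi-axis searched (px)
    axis_max: int | None = None    # defaults to ~min(H, W)/2 - 2
    axis_stride: int = 2
    rotations: tuple = (0.0,)
    n_perimeter: int = 24          # perimeter samples scored per candidate
    min_coverage: float = 0.45     # vote threshold (fraction of perimeter on edges)
    max_interior_edges: float = 0.8  # reject candidates whose (shrunken) interior
                                     # holds more edge pixels than this fraction
                                     # of their perimeter votes
    max_axis_ratio: float = 3.0    # eccentricity bound; organs are not slivers
    max_close_radius: int = 4      # largest closing disk tried per slice
    smooth_iterations: int = 10
    smooth_weight: float = 0.5


# --------------------------------------------------------------------------
# primary tumor
# --------------------------------------------------------------------------

def detect_primary_tumor(
    volume: VolumeImage, manual: TumorSpec | None = None
) -> TumorSpec:
    """Locate the primary tumor, or pass through a clinician's manual tag.

    The automatic path derives the intensity threshold by applying Otsu's rule
    recursively to the upper tail (three levels: background/tissue, tissue/
    vascular, vascular/tumor) and returns the centroid and equivalent-sphere
    radius of the brightest connected component above it.  Recursion on the
    tail keeps the split adaptive even though bright voxels are a tiny minority.
    """
    if manual is not None:
        return manual
    data = volume.data.astype(float)
    if data.size == 0 or np.ptp(data) < 1e-12:
        raise NoTumorFoundError("volume has no intensity contrast")
    vals = data.ravel()
    thr = None
    for _ in range(3):
        if np.ptp(vals) < 1e-12:
            break  # nothing left to split
        try:
            t = threshold_otsu(vals)
        except ValueError:
            break
        sub = vals[vals > t]
        if sub.size < 8:
            break
        thr = t
        vals = sub
    if thr is None:
        raise NoTumorFoundError("adaptive threshold failed: no separable bright class")
    cand = data > thr
    if not cand.any():
        raise NoTumorFoundError("no voxels above the adaptive threshold")
    labels, nlab = ndimage.label(cand)
    means = ndimage.mean(data, labels, index=np.arange(1, nlab + 1))
    sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, nlab + 1))
    # brightest component; tiny speckles (noise) are ignored
    order = np.argsort(-means)
    best = None
    for k in order:
        if sizes[k] >= 8:
            best = k + 1
            break
    if best is None:
        best = int(order[0]) + 1
    vox = np.argwhere(labels == best)
    spacing = np.asarray(volume.spacing)
    centroid = (vox.mean(axis=0)) * spacing
    vol_mm3 = float(sizes[best - 1]) * float(np.prod(spacing))
    radius = (3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return TumorSpec(centroid, radius)


# --------------------------------------------------------------------------
# per-slice edge detection and ellipse search
# --------------------------------------------------------------------------

def canny_slice(slice2d: np.ndarray, k: float = 0.33, sigma: float = 1.0) -> np.ndarray:
    """Canny edges with hysteresis thresholds adapted to the slice median.

    low = (1 - k) * median, high = (1 + k) * median of the slice intensities.
    A constant slice yields an empty edge map.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    if slice2d.shape[0] < 3 or slice2d.shape[1] < 3:
        raise ValueError("slice must be at least 3x3")
    if np.ptp(slice2d) < 1e-12:
        return np.zeros_like(slice2d, dtype=bool)
    med = float(np.median(slice2d))
    low = max((1.0 - k) * med, 0.0)
    high = max((1.0 + k) * med, low)
    return feature.canny(slice2d, sigma=sigma, low_threshold=low, high_threshold=high)


def _ellipse_perimeter_len(a: float, b: float) -> float:
    """Ramanujan's approximation of the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _perimeter_offsets(a: float, b: float, theta: float, n: int):
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ux = a * np.cos(ang)
    uy = b * np.sin(ang)
    ct, st = math.cos(theta), math.sin(theta)
    return ct * ux - st * uy, st * ux + ct * uy


def _score_centers(tol_map, cxs, cys, a, b, theta, n_perim):
    offx, offy = _perimeter_offsets(a, b, theta, n_perim)
    px = np.rint(cxs[:, None] + offx[None, :]).astype(int)
    py = np.rint(cys[:, None] + offy[None, :]).astype(int)
    inside = (px >= 0) & (px < tol_map.shape[0]) & (py >= 0) & (py < tol_map.shape[1])
    hit = np.zeros(px.shape, dtype=bool)
    hit[inside] = tol_map[px[inside], py[inside]]
    return hit.mean(axis=1)


def hough_two_ellipses(edges: np.ndarray, params: SegmentationParams | None = None) -> tuple[Ellipse2D, Ellipse2D]:
    """The two highest-scoring, mutually exterior ellipses in an edge map.

    A coarse accumulator scores rasterized perimeters over a discretized
    (center, semi-axes, rotation) grid against the 1-px-dilated edge map, then
    the two picks are refined by a local stride-1 search.  Raises if fewer than
    two candidates clear the vote threshold.
    """
    params = params or SegmentationParams()
    edges = np.asarray(edges).astype(bool)
    if not edges.any():
        raise SegmentationError("empty edge map")
    H, W = edges.shape
    tol_map = ndimage.binary_dilation(edges, structure=disk(1))
    xs, ys = np.nonzero(edges)
    margin = 2
    x0, x1 = max(xs.min() - margin, 0), min(xs.max() + margin, H - 1)
    y0, y1 = max(ys.min() - margin, 0), min(ys.max() + margin, W - 1)
    cx = np.arange(x0, x1 + 1, params.center_stride)
    cy = np.arange(y0, y1 + 1, params.center_stride)
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    cxs, cys = CX.ravel().astype(float), CY.ravel().astype(float)
    if cxs.size == 0:
        raise SegmentationError("edge map too small for the Hough search")

    axis_max = params.axis_max or max(params.axis_min + 1, min(H, W) // 2 - 2)
    axes = np.arange(params.axis_min, axis_max + 1, params.axis_stride)
    # rank candidates by absolute votes (coverage x perimeter length), as a
    # classical accumulator would: a small perfectly-covered circle must not
    # outrank the large lung boundary ellipse
    best_votes = np.zeros(cxs.size)
    best_cov = np.zeros(cxs.size)
    best_combo = np.zeros((cxs.size, 3))
    coarse_floor = max(0.5 * params.min_coverage, 0.2)  # lattice quantization slack
    for a in axes:
        for b in axes:
            if max(a, b) / min(a, b) > params.max_axis_ratio:
                continue
            perim = _ellipse_perimeter_len(a, b)
            for theta in params.rotations:
                cov = _score_centers(tol_map, cxs, cys, a, b, theta, params.n_perimeter)
                votes = np.where(cov >= coarse_floor, cov * perim, 0.0)
                upd = votes > best_votes
                best_votes[upd] = votes[upd]
                best_cov[upd] = cov[upd]
                best_combo[upd] = (a, b, theta)

    # Scan candidates in vote order under a descending coverage hierarchy: a
    # true boundary ellipse on clean edges has near-perfect perimeter coverage,
    # so demanding 0.9 first keeps partially-fitting large contours (which can
    # span both lungs) from shadowing the real ones; lower levels engage only
    # when noise erodes coverage.  Each accepted pair must be mutually exterior
    # and have a nearly edge-free interior.
    order = np.argsort(-best_votes, kind="stable")
    exs = xs.astype(float)
    eys = ys.astype(float)
    refined_cache: dict[int, Ellipse2D] = {}
    levels = [lv for lv in (0.9, 0.75, 0.6, 0.45) if lv >= params.min_coverage]
    levels = levels or [params.min_coverage]
    picks: list[Ellipse2D] = []
    for level in levels:
        picks = []
        attempts = 0
        for idx in order:
            if best_votes[idx] <= 0 or attempts >= 60:
                break
            if best_cov[idx] < level - 0.25:  # lattice-quantization slack
                continue
            a, b, theta = best_combo[idx]
            cand = Ellipse2D(cxs[idx], cys[idx], a, b, theta, float(best_cov[idx]))
            if any(p.contains(cand.cx, cand.cy, 1.25) or cand.contains(p.cx, p.cy)
                   for p in picks):
                continue
            attempts += 1
            if idx not in refined_cache:
                refined_cache[idx] = _refine_ellipse(tol_map, edges, cand, params)
            cand = refined_cache[idx]
            if cand.score < level:
                continue
            votes = cand.score * _ellipse_perimeter_len(cand.a, cand.b)
            if _interior_edge_count(exs, eys, cand) > params.max_interior_edges * votes:
                continue
            if any(p.contains(cand.cx, cand.cy) or cand.contains(p.cx, p.cy) for p in picks):
                continue
            picks.append(cand)
            if len(picks) == 2:
                break
        if len(picks) == 2:
            return tuple(picks)
    raise SegmentationError(
        f"found {len(picks)} ellipse(s) above the vote threshold, need 2"
    )


def _interior_edge_count(xs, ys, e: Ellipse2D, shrink: float = 0.8) -> int:
    """Edge pixels strictly inside the candidate (ring excluded via shrink)."""
    dx, dy = xs - e.cx, ys - e.cy
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return int(np.sum((u / (shrink * e.a)) ** 2 + (v / (shrink * e.b)) ** 2 <= 1.0))


def _refine_ellipse(tol_map, raw_edges, e: Ellipse2D, params: SegmentationParams) -> Ellipse2D:
    """Local sub-lattice search around a coarse pick.

    The objective is scored against the *raw* edge map — the dilated map used
    by the accumulator plateaus within one pixel of the true contour and would
    bias the fit one pixel outward; the returned coverage score is still taken
    from the tolerant map.
    """
    best = None
    best_votes = -1.0
    n = max(params.n_perimeter, 48)
    deltas = [d * 0.5 for d in range(-4, 5)]
    for da in deltas:
        a = e.a + da
        if a < 2:
            continue
        for db in deltas:
            b = e.b + db
            if b < 2:
                continue
            offx = np.array([e.cx + d for d in deltas], dtype=float)
            offy = np.array([e.cy + d for d in deltas], dtype=float)
            CX, CY = np.meshgrid(offx, offy, indexing="ij")
            cov = _score_centers(raw_edges, CX.ravel(), CY.ravel(), a, b, e.theta, n)
            votes = cov * _ellipse_perimeter_len(a, b)
            k = int(np.argmax(votes))
            if votes[k] > best_votes:
                best_votes = votes[k]
                best = Ellipse2D(CX.ravel()[k], CY.ravel()[k], a, b, e.theta, 0.0)
    if best is None:
        return e
    best.score = float(
        _score_centers(tol_map, np.array([best.cx]), np.array([best.cy]),
                       best.a, best.b, best.theta, n)[0]
    )
    return best


# --------------------------------------------------------------------------
# contour closure and 3D reconstruction
# --------------------------------------------------------------------------

def _ellipse_ring(shape, e: Ellipse2D) -> np.ndarray:
    n = int(max(32, 4 * math.pi * max(e.a, e.b)))
    offx, offy = _perimeter_offsets(e.a, e.b, e.theta, n)
    px = np.rint(e.cx + offx).astype(int)
    py = np.rint(e.cy + offy).astype(int)
    ok = (px >= 0) & (px < shape[0]) & (py >= 0) & (py < shape[1])
    ring = np.zeros(shape, dtype=bool)
    ring[px[ok], py[ok]] = True
    return ring


def close_lung_contours(
    edges: np.ndarray,
    ellipses: tuple[Ellipse2D, Ellipse2D],
    params: SegmentationParams | None = None,
) -> list[np.ndarray]:
    """Accrete edges connected to each boundary ellipse and fill the interior.

    Edge components 8-connected to the ellipse rasterization join the contour,
    which is then morphologically closed (growing the disk up to a bound) until
    hole-filling produces a closed interior; the inner side of each shape is the
    healthy-tissue region.
    """
    params = params or SegmentationParams()
    edges = np.asarray(edges).astype(bool)
    labels, _ = ndimage.label(edges, structure=np.ones((3, 3)))
    regions = []
    for e in ellipses:
        ring = _ellipse_ring(edges.shape, e)
        seed = ndimage.binary_dilation(ring, structure=np.ones((3, 3)))
        touched = np.unique(labels[seed & edges])
        touched = touched[touched > 0]
        contour = ring | np.isin(labels, touched)
        target = math.pi * e.a * e.b
        filled = None
        for rad in range(1, params.max_close_radius + 1):
            closed = ndimage.binary_closing(
                contour, structure=disk(rad), border_value=0
            )
            cand = ndimage.binary_fill_holes(closed)
            if cand.sum() >= 0.5 * target:
                filled = cand
                break
        if filled is None:
            raise SegmentationError(
                f"contour around ({e.cx:.0f},{e.cy:.0f}) could not be closed"
            )
        # the contour band straddles the true boundary; keep only its inner
        # half (contour pixels outside the fitted ellipse are trimmed) so the
        # region area matches the enclosed analytic area instead of inflating
        # by one pixel all around
        ii, jj = np.nonzero(closed)
        outside = np.array([not e.contains(float(i), float(j)) for i, j in zip(ii, jj)])
        trimmed = filled.copy()
        trimmed[ii[outside], jj[outside]] = False
        regions.append(ndimage.binary_fill_holes(trimmed))
    return regions


def reconstruct_lung_mask(
    slices: list[np.ndarray | None],
    params: SegmentationParams | None = None,
) -> LungMask:
    """Stack per-slice regions into 3D and Laplacian-smooth the shape.

    ``slices[z]`` is the filled 2D region for slice z, or None where slice
    segmentation failed.  Failed slices sandwiched between successes copy their
    nearest successful neighbor (logged); failures beyond the first/last success
    stay empty.  Smoothing relaxes the field toward its 6-neighbor mean with
    alternating positive/negative weights (Taubin's shrink-compensated
    Laplacian scheme — the plain scheme acts as curvature flow and measurably
    erodes the organ volume) for a fixed iteration count, then re-binarizes
    at 0.5.
    """
    params = params or SegmentationParams()
    if not slices:
        raise ValueError("need at least one slice")
    ok = [z for z, s in enumerate(slices) if s is not None]
    if not ok:
        raise SegmentationError("no slice segmented successfully")
    shape2d = slices[ok[0]].shape
    nz = len(slices)
    vol = np.zeros(shape2d + (nz,), dtype=bool)
    for z in range(nz):
        if slices[z] is not None:
            vol[:, :, z] = slices[z]
        elif ok[0] <= z <= ok[-1]:
            nearest = min(ok, key=lambda zz: (abs(zz - z), zz))
            logger.info("slice %d interpolated from slice %d", z, nearest)
            vol[:, :, z] = slices[nearest]

    smooth = vol.astype(float)
    if nz == 1:
        kernel = np.zeros((3, 3, 1))
        kernel[0, 1, 0] = kernel[2, 1, 0] = kernel[1, 0, 0] = kernel[1, 2, 0] = 0.25
    else:
        kernel = np.zeros((3, 3, 3))
        for off in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
            kernel[off] = 1.0 / 6.0
    lam = params.smooth_weight
    mu = -(lam + 0.02)
    for i in range(params.smooth_iterations):
        w = lam if i % 2 == 0 else mu
        smooth = smooth + w * (ndimage.convolve(smooth, kernel, mode="nearest") - smooth)
    return LungMask(smooth > 0.5)


def segment_lungs(
    volume: VolumeImage,
    tumor: TumorSpec | None = None,
    params: SegmentationParams | None = None,
) -> LungMask:
    """Full slice-wise lung segmentation of a volume.

    Slices along z; per-slice failures are tolerated (interpolated during
    reconstruction).  If a tumor is given, its sphere is excluded from the
    healthy-tissue mask — settlement targets must be healthy tissue.
    """
    params = params or SegmentationParams()
    nz = volume.shape[2]
    slices: list[np.ndarray | None] = []
    provenance: list = []
    for z in range(nz):
        sl = volume.data[:, :, z]
        try:
            edges = canny_slice(sl, k=params.canny_k, sigma=params.canny_sigma)
            if edges.sum() < 20:
                raise SegmentationError("too few edge pixels")
            ellipses = hough_two_ellipses(edges, params)
            regions = close_lung_contours(edges, ellipses, params)
            slices.append(regions[0] | regions[1])
            provenance.append((z, ellipses))
        except SegmentationError as exc:
            logger.debug("slice %d failed: %s", z, exc)
            slices.append(None)
            provenance.append((z, None))
    lung = reconstruct_lung_mask(slices, params)
    lung.provenance = provenance
    if tumor is not None:
        spacing = np.asarray(volume.spacing)
        grid = np.stack(
            np.meshgrid(*[np.arange(n) for n in volume.shape], indexing="ij"), axis=-1
        ) * spacing
        d2 = np.sum((grid - tumor.location) ** 2, axis=-1)
        lung.mask &= d2 > tumor.size**2
    return lung
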