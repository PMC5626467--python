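"""Cortical intensity-profile extraction from midsagittal embryo images.

Measurement pipeline: pick the midsagittal-most plane of a stack, segment the
embryo and fit its ellipse, locate the anterior/posterior poles, trace the
dorsal cortex, slide overlapping elliptical discs along it to read out a mean
intensity per % egg length (%EL), aggregate batches of embryos, convert
profiles to percent-of-total form, and render the 8-bit color-scale views
used for qualitative comparison.

%EL is the normalized projection onto the fitted major axis: 0 at the
anterior pole, 100 at the posterior pole.  Anterior is detected from the
signal itself (the morphogen is anterior-enriched), so extracted profiles are
invariant to horizontal flips of the input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label

__all__ = [
    "EmbryoGeometry",
    "ROISpec",
    "DorsalPath",
    "IntensityProfile",
    "MeanProfile",
    "NormalizedProfile",
    "SegmentationError",
    "select_midsagittal",
    "segment_embryo",
    "geometry_from_truth",
    "trace_dorsal_cortex",
    "sample_profile",
    "batch_mean_profile",
    "to_percent_of_total",
    "color_convert",
    "apply_color_lut",
    "estimate_expression_ratio",
]


class SegmentationError(ValueError):
    """The plane could not be segmented into a single oriented embryo."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class EmbryoGeometry:
    """Fitted ellipse and pole assignment of one midsagittal plane."""

    mask: np.ndarray
    center: tuple[float, float]          # (row, col)
    semi_major_px: float
    semi_minor_px: float
    orientation_deg: float               # major-axis angle from horizontal
    anterior_pole: tuple[float, float]   # (row, col)
    posterior_pole: tuple[float, float]
    dorsal_side: str = "up"

    @property
    def egg_length_px(self) -> float:
        ar, ac = self.anterior_pole
        pr, pc = self.posterior_pole
        return math.hypot(pr - ar, pc - ac)

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector (row, col) pointing anterior -> posterior."""
        d = np.asarray(self.posterior_pole) - np.asarray(self.anterior_pole)
        return d / np.linalg.norm(d)

    def pct_el(self, points: np.ndarray) -> np.ndarray:
        """%EL of (row, col) points by projection onto the A–P axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        proj = (pts - np.asarray(self.anterior_pole)) @ self.axis_unit
        return np.squeeze(proj / self.egg_length_px * 100.0)


@dataclass(frozen=True)
class ROISpec:
    """Sliding-disc geometry: overlapping ellipses stepped along the cortex.

    Defaults give 50% overlap between successive discs; the normal semi-axis
    is half the default shell width (expressed as a fraction of the embryo
    semi-minor axis).
    """

    disc_semi_axis_along_pct_el: float = 2.5
    disc_semi_axis_normal_frac: float = 0.04
    step_pct_el: float = 1.25

    def __post_init__(self) -> None:
        if not (0 < self.step_pct_el <= 2 * self.disc_semi_axis_along_pct_el):
            raise ValueError("step must be positive and discs must overlap")
        if self.disc_semi_axis_normal_frac <= 0:
            raise ValueError("normal semi-axis must be positive")


@dataclass
class DorsalPath:
    """Ordered dorsal-cortex sampling path with %EL per point."""

    points: np.ndarray    # (N, 2) (row, col)
    pct_el: np.ndarray    # (N,), strictly increasing 0..100
    tangents: np.ndarray  # (N, 2) unit tangent (row, col)


@dataclass
class IntensityProfile:
    """Ordered (position %EL, mean ROI intensity) samples for one embryo."""

    positions: np.ndarray
    values: np.ndarray
    n_pixels: np.ndarray | None = None
    background: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")
        if self.n_pixels is not None:
            self.n_pixels = np.asarray(self.n_pixels)


@dataclass
class MeanProfile:
    """Pointwise mean of a batch of profiles on a common %EL grid."""

    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def as_profile(self, **metadata) -> IntensityProfile:
        return IntensityProfile(self.positions, self.mean, metadata=metadata)


@dataclass
class NormalizedProfile:
    """Percent-of-total transformation: each sample's share of profile mass.

    ``fractions`` are trapezoid-weighted shares summing to 1; ``density`` is
    the underlying normalized intensity curve (value per %EL), which is what
    content quantiles integrate.
    """

    positions: np.ndarray
    fractions: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if not np.isclose(self.fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1")
        if np.any(self.fractions < -1e-12):
            raise ValueError("fractions must be non-negative")

    def cumulative(self) -> np.ndarray:
        """Trapezoid cumulative mass at each sample position (0 .. 1)."""
        x, d = self.positions, self.density
        seg = np.diff(x) * (d[:-1] + d[1:]) / 2.0
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cum / cum[-1]


# ---------------------------------------------------------------------------
# Plane selection and segmentation
# ---------------------------------------------------------------------------

def _segment_mask(plane: np.ndarray) -> np.ndarray | None:
    """Threshold -> largest connected component -> fill holes.

    The embryo sits on a darker slide background but itself spans dim
    (autofluorescent interior) to bright (anterior signal) grey levels, so a
    three-class Otsu split is taken and the lowest threshold separates slide
    from embryo; plain Otsu is the fallback for near-binary images.
    """
    img = np.asarray(plane, dtype=float)
    if img.max() <= img.min():
        return None
    try:
        thr = threshold_multiotsu(img, classes=3)[0]
    except ValueError:  # fewer than 3 distinct grey levels
        thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        return None
    lab = label(fg)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def select_midsagittal(stack: np.ndarray) -> int:
    """Index of the plane with the largest segmented embryo area.

    Ties break toward the lower index; planes that cannot be segmented count
    as area zero.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("stack must have at least 3 planes")
    areas = []
    for plane in stack:
        mask = _segment_mask(plane)
        areas.append(0 if mask is None else int(mask.sum()))
    if max(areas) == 0:
        raise SegmentationError("no plane of the stack is segmentable")
    return int(np.argmax(areas))


def _principal_axes(mask: np.ndarray):
    """Centroid, unit major/minor axes and semi-axis lengths from moments."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols]).astype(float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    e_major = evecs[:, 1]
    e_minor = evecs[:, 0]
    # semi-axis of an ellipse with matching second moments: a = 2*sqrt(eig)
    a = 2.0 * math.sqrt(max(evals[1], 0.0))
    b = 2.0 * math.sqrt(max(evals[0], 0.0))
    return c, e_major, e_minor, a, b


def _boundary_pole(mask: np.ndarray, center: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Last in-mask point marching from the center along a direction."""
    h, w = mask.shape
    pos = center.copy()
    last = center.copy()
    step = 0.5
    for _ in range(int(2 * max(h, w) / step)):
        pos = pos + direction * step
        r, c = int(round(pos[0])), int(round(pos[1]))
        if r < 0 or r >= h or c < 0 or c >= w or not mask[r, c]:
            break
        last = pos.copy()
    return last


def segment_embryo(plane: np.ndarray, dorsal_side: str = "up") -> EmbryoGeometry:
    """Segment one plane and return its oriented embryo geometry.

    Otsu threshold, largest connected component, hole filling, moment-based
    ellipse fit; poles are the intersections of the major axis with the mask
    boundary; the anterior pole is the one whose flanking 10%EL region has the
    higher mean intensity.
    """
    mask = _segment_mask(plane)
    if mask is None or mask.sum() < 50:
        raise SegmentationError("no foreground found in plane")
    c, e_major, _, a, b = _principal_axes(mask)
    if b <= 0 or a / b < 1.2:
        raise SegmentationError(f"aspect ratio {a / max(b, 1e-9):.2f} < 1.2: cannot orient embryo")
    pole1 = _boundary_pole(mask, c, e_major)
    pole2 = _boundary_pole(mask, c, -e_major)
    # anterior = pole with brighter flanking 10 %EL region
    img = np.asarray(plane, dtype=float)
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows, cols]).astype(float)
    egg_len = np.linalg.norm(pole2 - pole1)
    axis = (pole2 - pole1) / egg_len
    proj = (pts - pole1) @ axis / egg_len * 100.0
    mean1 = img[rows[proj <= 10.0], cols[proj <= 10.0]].mean()
    mean2 = img[rows[proj >= 90.0], cols[proj >= 90.0]].mean()
    if mean1 >= mean2:
        anterior, posterior = pole1, pole2
    else:
        anterior, posterior = pole2, pole1
    orientation = math.degrees(math.atan2(-(posterior[0] - anterior[0]),
                                          posterior[1] - anterior[1]))
    return EmbryoGeometry(
        mask=mask,
        center=(float(c[0]), float(c[1])),
        semi_major_px=float(a),
        semi_minor_px=float(b),
        orientation_deg=float(orientation),
        anterior_pole=(float(anterior[0]), float(anterior[1])),
        posterior_pole=(float(posterior[0]), float(posterior[1])),
        dorsal_side=dorsal_side,
    )


def geometry_from_truth(gt) -> EmbryoGeometry:
    """Exact geometry from a synthetic ground-truth record (no segmentation)."""
    spec = gt.spec
    th = math.radians(spec.orientation_deg)
    e = np.array([-math.sin(th), math.cos(th)])  # (row, col) unit along +u
    c = np.asarray(spec.ellipse_center, dtype=float)
    left = c - e * spec.semi_major_px
    right = c + e * spec.semi_major_px
    if spec.anterior_side == "left":
        anterior, posterior = left, right
    else:
        anterior, posterior = right, left
    return EmbryoGeometry(
        mask=gt.mask,
        center=tuple(c),
        semi_major_px=spec.semi_major_px,
        semi_minor_px=spec.semi_minor_px,
        orientation_deg=spec.orientation_deg,
        anterior_pole=tuple(anterior),
        posterior_pole=tuple(posterior),
    )


# ---------------------------------------------------------------------------
# Cortex tracing and disc sampling
# ---------------------------------------------------------------------------

def trace_dorsal_cortex(
    geometry: EmbryoGeometry, n_points: int = 201, shell_width_frac: float = 0.08
) -> DorsalPath:
    """Ordered sampling path along the dorsal cortex, anterior to posterior.

    The path runs on an ellipse with the fitted semi-major axis and the minor
    semi-axis shrunk by half the shell width, so it touches both poles (%EL
    spans exactly 0..100) while sitting mid-shell at the dorsal apex.  %EL per
    point is the projection onto the major axis normalized by egg length.
    """
    if geometry.egg_length_px <= 0:
        raise ValueError("degenerate geometry: zero egg length")
    a = geometry.egg_length_px / 2.0
    d = 0.5 * shell_width_frac * geometry.semi_minor_px
    b_path = geometry.semi_minor_px - d
    if b_path <= 0:
        raise ValueError("degenerate geometry: shell wider than the embryo")
    e_ap = geometry.axis_unit
    # dorsal normal: perpendicular to the A-P axis pointing toward smaller row
    # ('up') or larger row ('down')
    n = np.array([-e_ap[1], e_ap[0]])
    if (n[0] > 0) == (geometry.dorsal_side == "up"):
        n = -n
    mid = (np.asarray(geometry.anterior_pole) + np.asarray(geometry.posterior_pole)) / 2.0
    s = np.linspace(0.0, math.pi, n_points)
    axial = -a * np.cos(s)          # -a (anterior) .. +a (posterior)
    normal = b_path * np.sin(s)     # >= 0, dorsal
    points = mid[None, :] + axial[:, None] * e_ap[None, :] + normal[:, None] * n[None, :]
    pct = (axial + a) / (2 * a) * 100.0
    d_ax = a * np.sin(s)
    d_no = b_path * np.cos(s)
    tang = d_ax[:, None] * e_ap[None, :] + d_no[:, None] * n[None, :]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return DorsalPath(points=points, pct_el=pct, tangents=tang)


def _modal_background(plane: np.ndarray, mask: np.ndarray) -> float:
    outside = np.asarray(plane)[~mask]
    if outside.size == 0:
        return 0.0
    counts = np.bincount(np.round(outside.astype(float)).astype(int).clip(min=0))
    return float(counts.argmax())


def sample_profile(
    plane: np.ndarray,
    geometry: EmbryoGeometry,
    path: DorsalPath,
    roi: ROISpec | None = None,
    subtract_background: bool = True,
    metadata: dict | None = None,
) -> IntensityProfile:
    """Mean intensity in overlapping elliptical discs slid along the cortex.

    Disc centers step by ``roi.step_pct_el`` along the path; each disc is an
    ellipse oriented along the local path tangent (semi-axis along the path in
    %EL units, normal semi-axis as a fraction of the embryo semi-minor axis),
    clipped to the embryo mask.  The modal out-of-mask intensity is subtracted
    when flagged, flooring at zero.
    """
    roi = roi or ROISpec()
    img = np.asarray(plane, dtype=float)
    egg_len = geometry.egg_length_px
    sa = roi.disc_semi_axis_along_pct_el / 100.0 * egg_len
    sn = roi.disc_semi_axis_normal_frac * geometry.semi_minor_px
    bg = _modal_background(img, geometry.mask) if subtract_background else 0.0
    h, w = img.shape
    targets = np.arange(0.0, 100.0 + 1e-9, roi.step_pct_el)
    positions, values, n_pixels = [], [], []
    for t in targets:
        idx = int(np.argmin(np.abs(path.pct_el - t)))
        cr, cc = path.points[idx]
        tr, tc = path.tangents[idx]
        r0, r1 = int(max(0, cr - sa - sn)), int(min(h, cr + sa + sn + 2))
        c0, c1 = int(max(0, cc - sa - sn)), int(min(w, cc + sa + sn + 2))
        rr, cols = np.mgrid[r0:r1, c0:c1]
        dr, dc = rr - cr, cols - cc
        along = dr * tr + dc * tc
        across = -dr * tc + dc * tr
        inside = (along / sa) ** 2 + (across / sn) ** 2 <= 1.0
        inside &= geometry.mask[r0:r1, c0:c1]
        n = int(inside.sum())
        if n == 0:
            raise ValueError(f"ROI at {t:.2f} %EL lies entirely outside the embryo mask")
        val = float(img[r0:r1, c0:c1][inside].mean()) - bg
        positions.append(t)
        values.append(max(val, 0.0))
        n_pixels.append(n)
    return IntensityProfile(
        positions=np.asarray(positions),
        values=np.asarray(values),
        n_pixels=np.asarray(n_pixels),
        background=bg,
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# Batch aggregation and normalization
# ---------------------------------------------------------------------------

def batch_mean_profile(
    profiles: list[IntensityProfile],
    grid: np.ndarray,
    rescale: bool = False,
) -> MeanProfile:
    """Pointwise mean ± SD of several embryo profiles on a common %EL grid.

    Profiles are resampled to the grid by linear interpolation.  Profiles
    recorded under identical gain are averaged as-is (the default); with
    ``rescale`` each profile is first normalized to unit trapezoid integral
    (use when sessions differ), and a warning notes the rescaling.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    grid = np.asarray(grid, dtype=float)
    for p in profiles:
        if grid[0] < p.positions[0] - 1e-9 or grid[-1] > p.positions[-1] + 1e-9:
            raise ValueError("grid extends outside the sampled range of a profile")
    if rescale:
        warnings.warn("rescaling each profile to unit integral before averaging", stacklevel=2)
    rows = []
    for p in profiles:
        v = p.values
        if rescale:
            v = v / np.trapezoid(v, p.positions)
        rows.append(np.interp(grid, p.positions, v))
    arr = np.asarray(rows)
    return MeanProfile(
        positions=grid,
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=1),
        n=np.full(grid.shape, len(profiles), dtype=int),
    )


def to_percent_of_total(profile: IntensityProfile) -> NormalizedProfile:
    """Percent-of-total transformation of an intensity profile.

    Each sample's fraction is its trapezoid weight times its value, divided by
    the trapezoid integral over the sampled range; fractions sum to one.
    """
    x, v = profile.positions, profile.values
    total = np.trapezoid(v, x)
    if total <= 0:
        raise ValueError("profile has no positive mass")
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return NormalizedProfile(positions=x, fractions=v * w / total, density=v / total)


# ---------------------------------------------------------------------------
# Color conversion and dosage ratio
# ---------------------------------------------------------------------------

def color_convert(plane: np.ndarray, scale_max: int = 255) -> np.ndarray:
    """Map intensities [0, scale_max] linearly onto the full 0–255 color LUT.

    Intensities above ``scale_max`` clip to the top color index (used for the
    one-third-scale view of a one-third-dosage embryo).
    """
    if not (1 <= scale_max <= 255):
        raise ValueError("scale_max must lie in [1, 255]")
    img = np.clip(np.asarray(plane, dtype=float), 0.0, scale_max)
    return np.floor(img / scale_max * 255.0).astype(np.uint8)


def apply_color_lut(index_image: np.ndarray, cmap: str = "turbo") -> np.ndarray:
    """RGB rendering of a color-index image via a matplotlib colormap."""
    import matplotlib.pyplot as plt

    lut = plt.get_cmap(cmap)(np.linspace(0, 1, 256))[:, :3]
    return (lut[np.asarray(index_image, dtype=int)] * 255).astype(np.uint8)


def estimate_expression_ratio(
    plane_a: np.ndarray,
    geometry_a: EmbryoGeometry,
    plane_b: np.ndarray,
    geometry_b: EmbryoGeometry,
) -> float:
    """Ratio of background-subtracted total in-mask signal, A over B.

    The mean out-of-mask intensity times the in-mask pixel count is removed
    from each total, so detector offset and quantization bias cancel between
    the two embryos (they must be recorded under identical settings).
    Swapping the arguments inverts the ratio.
    """
    def total(plane, geom):
        img = np.asarray(plane, dtype=float)
        bg = float(img[~geom.mask].mean()) if (~geom.mask).any() else 0.0
        return float(img[geom.mask].sum() - bg * geom.mask.sum())

    tb = total(plane_b, geometry_b)
    if tb <= 0:
        raise ZeroDivisionError("denominator embryo has no signal above background")
    return total(plane_a, geometry_a) / tb
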