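"""Synthetic midsagittal embryo images with known ground truth.

Generates confocal-style 8-bit image planes and stacks of a syncytial
*Drosophila*-like embryo: an elliptical midsagittal section (~2.5:1 aspect)
carrying an anterior-concentrated morphogen signal that is either confined to
a thin cortical shell, spread through the interior as a broad front, or
running down the axis as a thin interior streak.  Every image comes with a
ground-truth record (the noiseless painted signal and the generating spec) so
the measurement pipeline can be validated end to end without real data.

Rendering order per plane: paint the truth gradient on the selected region,
stamp nuclei, apply Poisson photon noise, add a uniform in-mask
autofluorescence baseline and an out-of-mask background, add Gaussian read
noise, clip and floor-quantize to the requested bit depth.  Gain is chosen the
way a microscopist would: the no-saturation flag guarantees no pixel reaches
the top grey level.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TruthProfile",
    "SyntheticSpec",
    "GroundTruth",
    "SaturationError",
    "STRAIN_AMPLITUDES",
    "make_truth_profile",
    "generate_midsagittal_image",
    "generate_stack",
    "render_stripe_image",
]


class SaturationError(ValueError):
    """Requested signal would saturate the detector with no-saturation set."""


#: Truth-gradient amplitudes (grey levels at the anterior pole) for the two
#: strains compared in the dosage experiment: the over-expressing strain
#: carries three times the wild-type amplitude.
STRAIN_AMPLITUDES = {"wild_type": 50.0, "bcd_5_8": 150.0}


# ---------------------------------------------------------------------------
# Truth profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth axial intensity profile, evaluable on %EL in [0, 100].

    kind is one of ``uniform``, ``exponential``, ``step``, ``tabulated``.
    ``length_constant_pct_el`` is the exponential decay length in % egg
    length; ``edge_pct_el`` the step edge; ``table`` an (N, 2) array of
    (position %EL, value) pairs interpolated linearly.
    """

    kind: str
    amplitude: float = 1.0
    length_constant_pct_el: float | None = None
    edge_pct_el: float | None = None
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "exponential", "step", "tabulated"):
            raise ValueError(f"unknown truth-profile kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.kind == "exponential":
            if self.length_constant_pct_el is None or self.length_constant_pct_el <= 0:
                raise ValueError("exponential profile needs a positive length constant")
        if self.kind == "step" and self.edge_pct_el is None:
            raise ValueError("step profile needs an edge position")
        if self.kind == "tabulated":
            if not self.table:
                raise ValueError("tabulated profile needs a table")
            pos = np.asarray([p for p, _ in self.table], dtype=float)
            if np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] > 100:
                raise ValueError("table positions must be strictly increasing within [0, 100]")

    def __call__(self, pct_el: np.ndarray | float) -> np.ndarray:
        x = np.asarray(pct_el, dtype=float)
        if self.kind == "uniform":
            out = np.full_like(x, self.amplitude)
        elif self.kind == "exponential":
            out = self.amplitude * np.exp(-x / self.length_constant_pct_el)
        elif self.kind == "step":
            out = np.where(x < self.edge_pct_el, self.amplitude, 0.0)
        else:
            pos = np.asarray([p for p, _ in self.table], dtype=float)
            val = np.asarray([v for _, v in self.table], dtype=float)
            out = np.interp(x, pos, val)
        return out


def make_truth_profile(kind: str, **parameters: float) -> TruthProfile:
    """Build a :class:`TruthProfile` of the given kind.

    Accepted parameters: ``amplitude`` (all kinds), ``length_constant_pct_el``
    (exponential), ``edge_pct_el`` (step), ``table`` (tabulated).
    """
    return TruthProfile(kind=kind, **parameters)


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative description of one synthetic embryo plane/stack.

    Geometry is a rotated ellipse (semi-axes in pixels, 2.5:1 default aspect);
    ``cortex_thickness_frac`` is the shell width as a fraction of the
    semi-minor axis.  ``interior_mode`` selects where the truth gradient is
    painted: ``none`` (cortical shell only), ``broad_front`` (whole interior),
    ``streak`` (thin axial band), ``energid_accumulation`` (shell plus bright
    interior nuclei).  ``photon_scale`` is the expected photon count at unit
    truth intensity (``inf`` disables shot noise); ``embryo_baseline`` is a
    uniform in-mask autofluorescence level.
    """

    image_height_px: int = 260
    image_width_px: int = 560
    ellipse_center: tuple[float, float] = (130.0, 280.0)
    semi_major_px: float = 250.0
    semi_minor_px: float = 100.0
    orientation_deg: float = 0.0
    anterior_side: str = "left"
    cortex_thickness_frac: float = 0.08
    truth_profile: TruthProfile = field(
        default_factory=lambda: TruthProfile(
            kind="exponential", amplitude=150.0, length_constant_pct_el=20.0
        )
    )
    interior_mode: str = "none"
    streak_halfwidth_frac: float = 0.15
    nuclei_count: int = 32
    nuclei_radius_px: float = 5.0
    nuclei_signal: str = "dark"
    photon_scale: float = 20.0
    read_noise_sd: float = 1.5
    background_level: float = 8.0
    embryo_baseline: float = 12.0
    bit_depth: int = 8
    forbid_saturation: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.semi_major_px > self.semi_minor_px > 0):
            raise ValueError("need semi_major_px > semi_minor_px > 0")
        if not (0 < self.cortex_thickness_frac < 0.5):
            raise ValueError("cortex_thickness_frac must be in (0, 0.5)")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.background_level < 0 or self.embryo_baseline < 0:
            raise ValueError("background and baseline must be non-negative")
        if self.anterior_side not in ("left", "right"):
            raise ValueError("anterior_side must be 'left' or 'right'")
        if self.interior_mode not in ("none", "broad_front", "streak", "energid_accumulation"):
            raise ValueError(f"unknown interior_mode {self.interior_mode!r}")
        if self.nuclei_signal not in ("dark", "bright"):
            raise ValueError("nuclei_signal must be 'dark' or 'bright'")
        if self.nuclei_count < 0:
            raise ValueError("nuclei_count must be >= 0")


@dataclass
class GroundTruth:
    """Noiseless per-pixel signal and the spec that produced an image."""

    spec: SyntheticSpec
    noiseless: np.ndarray        # truth-gradient painting only (no baseline/background)
    mask: np.ndarray             # embryo interior (bool)
    region: np.ndarray           # pixels carrying the painted gradient (bool)
    pct_el: np.ndarray           # axial %EL coordinate per pixel
    plane_offset_px: float = 0.0

    @property
    def noiseless_total(self) -> float:
        return float(self.noiseless[self.mask].sum())

    def to_json_dict(self) -> dict:
        spec = dataclasses.asdict(self.spec)
        spec["truth_profile"] = dataclasses.asdict(self.spec.truth_profile)
        return {
            "spec": spec,
            "plane_offset_px": self.plane_offset_px,
            "noiseless_total": self.noiseless_total,
            "mask_area_px": int(self.mask.sum()),
        }


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _embryo_frame(spec: SyntheticSpec):
    """Per-pixel embryo-frame coordinates.

    Returns (u, v, r, pct_el): u along the major axis (px, image-left
    negative), v along the minor axis with dorsal (image-up) positive, the
    normalized elliptical radius r, and the axial %EL coordinate (0 at the
    anterior pole).
    """
    rows, cols = np.indices((spec.image_height_px, spec.image_width_px), dtype=float)
    cy, cx = spec.ellipse_center
    dx = cols - cx
    dy_up = cy - rows  # y axis pointing up (dorsal)
    th = math.radians(spec.orientation_deg)
    u = dx * math.cos(th) + dy_up * math.sin(th)
    v = -dx * math.sin(th) + dy_up * math.cos(th)
    r = np.sqrt((u / spec.semi_major_px) ** 2 + (v / spec.semi_minor_px) ** 2)
    s = u / spec.semi_major_px  # -1 .. 1 along the axis
    if spec.anterior_side == "left":
        pct_el = (s + 1.0) * 50.0
    else:
        pct_el = (1.0 - s) * 50.0
    return u, v, r, pct_el


def _paint_region(spec: SyntheticSpec, v: np.ndarray, r: np.ndarray) -> np.ndarray:
    mask = r <= 1.0
    if spec.interior_mode == "broad_front":
        return mask
    if spec.interior_mode == "streak":
        band = np.abs(v) <= spec.streak_halfwidth_frac * spec.semi_minor_px
        return mask & band
    # 'none' and 'energid_accumulation': constant-thickness cortical shell
    # (periplasm), measured as Euclidean depth from the embryo surface
    depth = ndimage.distance_transform_edt(mask)
    return mask & (depth <= spec.cortex_thickness_frac * spec.semi_minor_px)


def _stamp_nuclei(spec: SyntheticSpec, signal: np.ndarray, mask: np.ndarray,
                  pct_el: np.ndarray, rng: np.random.Generator) -> None:
    """Stamp nuclei discs in place: signal-free holes or bright accumulations."""
    if spec.nuclei_count == 0:
        return
    in_rows, in_cols = np.nonzero(mask)
    if in_rows.size == 0:
        return
    pick = rng.choice(in_rows.size, size=spec.nuclei_count, replace=True)
    rr, cc = np.indices(signal.shape, sparse=True)
    bright = spec.nuclei_signal == "bright" or spec.interior_mode == "energid_accumulation"
    for k in pick:
        disc = (rr - in_rows[k]) ** 2 + (cc - in_cols[k]) ** 2 <= spec.nuclei_radius_px ** 2
        disc &= mask
        if bright:
            local = spec.truth_profile(pct_el[disc])
            signal[disc] = np.maximum(signal[disc], local)
        else:
            signal[disc] = 0.0


def _render(spec: SyntheticSpec, signal: np.ndarray, mask: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the noise/quantization chain to a noiseless signal painting."""
    top = 2 ** spec.bit_depth - 1
    expected_peak = signal.max() + spec.background_level + spec.embryo_baseline
    if spec.forbid_saturation and expected_peak >= top:
        raise SaturationError(
            f"expected peak intensity {expected_peak:.1f} would saturate the "
            f"{spec.bit_depth}-bit range; lower the amplitude or background"
        )
    if math.isinf(spec.photon_scale):
        photons = signal.copy()
    else:
        photons = rng.poisson(signal * spec.photon_scale) / spec.photon_scale
    img = photons + spec.background_level + np.where(mask, spec.embryo_baseline, 0.0)
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    ceil = top - 1 if spec.forbid_saturation else top
    img = np.clip(img, 0.0, ceil)
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    return np.floor(img).astype(dtype)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_midsagittal_image(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render one midsagittal plane and its ground-truth record.

    The truth profile is painted along the anterior–posterior coordinate on
    the region selected by ``interior_mode``; the returned record keeps the
    noiseless painting, the embryo mask, the painted region and the per-pixel
    %EL coordinate.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    _, v, r, pct_el = _embryo_frame(spec)
    mask = r <= 1.0
    region = _paint_region(spec, v, r)
    signal = np.where(region, spec.truth_profile(np.clip(pct_el, 0.0, 100.0)), 0.0)
    _stamp_nuclei(spec, signal, mask, pct_el, rng)
    img = _render(spec, signal, mask, rng)
    return img, GroundTruth(spec=spec, noiseless=signal, mask=mask, region=region, pct_el=pct_el)


def generate_stack(
    spec: SyntheticSpec, n_planes: int = 7, plane_spacing_frac: float = 0.25
) -> tuple[np.ndarray, list[GroundTruth]]:
    """Render a confocal-style stack of parallel sections of the 3D embryo.

    The embryo is an ellipsoid with semi-axes (a, b, b); a section offset by z
    from the midplane is an ellipse scaled by sqrt(1 - (z/b)^2).  Offsets are
    symmetric about the midplane, spaced by ``plane_spacing_frac`` times the
    semi-minor axis, so the central plane has the largest cross-section and
    reproduces :func:`generate_midsagittal_image` for the same spec and seed.
    """
    if n_planes < 3 or n_planes > 15:
        raise ValueError("n_planes must be between 3 and 15")
    b = spec.semi_minor_px
    offsets = (np.arange(n_planes) - (n_planes - 1) / 2.0) * plane_spacing_frac * b
    if np.max(np.abs(offsets)) >= b:
        raise ValueError("plane spacing puts outer planes beyond the embryo surface")
    planes, records = [], []
    for k, z in enumerate(offsets):
        scale = math.sqrt(max(0.0, 1.0 - (z / b) ** 2))
        if z == 0.0:
            img, gt = generate_midsagittal_image(spec)
        else:
            plane_spec = dataclasses.replace(
                spec,
                semi_major_px=spec.semi_major_px * scale,
                semi_minor_px=b * scale,
                nuclei_count=max(1, int(round(spec.nuclei_count * scale))),
            )
            child = np.random.default_rng(np.random.SeedSequence(spec.rng_seed, spawn_key=(k + 1,)))
            img, gt = generate_midsagittal_image(plane_spec, rng=child)
        gt.plane_offset_px = float(z)
        planes.append(img)
        records.append(gt)
    return np.stack(planes), records


def render_stripe_image(
    stripe_centers_pct_el,
    stripe_width_pct_el: float,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a pair-rule-style striped embryo (Gaussian transverse bands).

    ``stripe_width_pct_el`` is the Gaussian sigma of each band in %EL; centers
    must be strictly increasing within (0, 100).  Overlapping stripes (center
    spacing below the width) trigger a warning, not a failure.
    """
    centers = np.asarray(stripe_centers_pct_el, dtype=float)
    if centers.ndim != 1 or centers.size == 0:
        raise ValueError("need at least one stripe center")
    if np.any(np.diff(centers) <= 0) or centers[0] <= 0 or centers[-1] >= 100:
        raise ValueError("stripe centers must be strictly increasing within (0, 100)")
    if stripe_width_pct_el <= 0:
        raise ValueError("stripe width must be positive")
    if centers.size > 1 and np.min(np.diff(centers)) < stripe_width_pct_el:
        warnings.warn("stripe spacing below stripe width: bands overlap", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    _, v, r, pct_el = _embryo_frame(spec)
    mask = r <= 1.0
    amp = spec.truth_profile.amplitude
    signal = np.zeros_like(pct_el)
    for c in centers:
        signal += amp * np.exp(-0.5 * ((pct_el - c) / stripe_width_pct_el) ** 2)
    signal = np.where(mask, signal, 0.0)
    img = _render(spec, signal, mask, rng)
    return img, GroundTruth(spec=spec, noiseless=signal, mask=mask, region=mask, pct_el=pct_el)
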