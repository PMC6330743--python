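"""Synthetic corneal angiography simulator.

Generates seeded ground-truth vasculature and renders modality-specific
en-face angiography images and depth-resolved volumes, emulating the
image character of three corneal angiography modalities:

* ``SSADA``  -- amplitude-decorrelation OCTA: finer point-spread function
  (15 um lateral), low motion-artefact rate, but projection artefacts that
  replicate superficial vessel signal into deeper layers.
* ``OMAG``   -- complex-signal OCTA: 20 um lateral PSF, no projection
  artefact, higher motion-line rate and speckle.
* ``ICGA``   -- dye angiography: purely 2D (no volume support), smooth,
  low-noise reference images.

Vessels grow from the limbus (the image border) toward the cornea centre
by a biased random walk with Bernoulli branching, mimicking suture-induced
neovascularisation that reaches the central cornea over two weeks.

All operations are pure functions of their inputs and an integer seed.
The random state is split into two independent streams (geometry and
branching) via :class:`numpy.random.SeedSequence` so that the branching
process alone can be replayed deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, UnsupportedModalityError

__all__ = [
    "VesselSegment",
    "GrowthParams",
    "VesselTree",
    "ModalityProfile",
    "SSADA_PROFILE",
    "OMAG_PROFILE",
    "ICGA_PROFILE",
    "default_profile",
    "grow_vessel_tree",
    "rasterize_tree",
    "render_enface",
    "render_volume",
    "ground_truth_density",
]

# Intensity (on the unit scale) of a rasterized vessel tube and of an
# injected motion line.  Lines sit above typical blurred-vessel levels so
# that a robust per-line statistic can single them out.
VESSEL_LEVEL = 0.85
MOTION_LINE_LEVEL = 0.95

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class VesselSegment:
    """One straight vessel piece in normalized cornea coordinates.

    ``start``/``end`` are (x, y) in the unit square; ``radius_um`` is the
    tube radius; ``depth_um`` is measured from the anterior surface.
    ``parent`` is the index of the upstream segment, or ``None`` for a
    root sprouting at the limbus.
    """

    parent: int | None
    start: tuple[float, float]
    end: tuple[float, float]
    radius_um: float
    depth_um: float


@dataclass(frozen=True)
class GrowthParams:
    """Knobs of the biased-random-walk vessel growth model.

    branch_prob
        Bernoulli probability, per tip per step, of sprouting a child.
    step_len
        Step length in normalized image units.
    center_bias
        Weight in [0, 1] pulling the walk direction toward the cornea
        centre (0.5, 0.5); the remainder follows the previous heading
        perturbed by ``angle_sd`` radians of Gaussian noise.
    n_steps
        Number of global growth steps; every active tip advances once
        per step.
    taper
        Child radius = parent radius x taper (<= 1, keeps radii
        non-increasing along the tree).
    root_radius_um
        Radius of limbal root segments.
    depth_range_um
        Roots sprout at a uniform depth in this interval; depth then
        drifts by a per-step Gaussian of SD ``depth_drift_um``, clipped
        to ``[0, depth_max_um]``.
    """

    branch_prob: float = 0.12
    step_len: float = 0.045
    center_bias: float = 0.35
    angle_sd: float = 0.45
    n_steps: int = 24
    taper: float = 0.88
    root_radius_um: float = 22.0
    depth_range_um: tuple[float, float] = (100.0, 350.0)
    depth_drift_um: float = 12.0
    depth_max_um: float = 500.0
    max_tips: int = 256


@dataclass(frozen=True)
class VesselTree:
    """Ground-truth synthetic vasculature: a forest of tapered tubes."""

    segments: tuple[VesselSegment, ...]
    growth_params: GrowthParams
    seed: int

    def __post_init__(self) -> None:
        for i, seg in enumerate(self.segments):
            if seg.radius_um <= 0:
                raise InvalidParameterError(f"segment {i}: radius must be > 0")
            if not 0.0 <= seg.depth_um <= self.growth_params.depth_max_um:
                raise InvalidParameterError(
                    f"segment {i}: depth {seg.depth_um} outside "
                    f"[0, {self.growth_params.depth_max_um}]"
                )
            if seg.parent is not None:
                parent = self.segments[seg.parent]
                if parent.end != seg.start:
                    raise InvalidParameterError(
                        f"segment {i} does not start at its parent's end"
                    )
                if seg.radius_um > parent.radius_um + 1e-12:
                    raise InvalidParameterError(
                        f"segment {i}: radius exceeds parent radius"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    def with_segment(self, segment: VesselSegment) -> "VesselTree":
        return replace(self, segments=self.segments + (segment,))


@dataclass(frozen=True)
class ModalityProfile:
    """Rendering character of one angiography modality."""

    name: str
    psf_fwhm_um: float
    speckle_shape: float | None  # gamma shape of unit-mean multiplicative noise; None = off
    motion_line_rate: float  # expected full-width artefact lines per image
    projection_strength: float  # fraction of superficial signal replicated deeper
    background_level: float  # mean background intensity fraction
    supports_volume: bool
    projection_decay_um: float = 250.0  # e-folding depth of the projected tail

    def __post_init__(self) -> None:
        if not 0.0 <= self.projection_strength <= 1.0:
            raise InvalidParameterError("projection_strength must be in [0, 1]")
        if self.psf_fwhm_um <= 0:
            raise InvalidParameterError("psf_fwhm_um must be > 0")
        if self.motion_line_rate < 0:
            raise InvalidParameterError("motion_line_rate must be >= 0")
        if self.name == "ICGA" and self.supports_volume:
            raise InvalidParameterError("ICGA is a 2D modality (supports_volume=False)")


# Default profiles.  PSF widths follow the systems' stated lateral
# resolutions (SSADA 15 um, OMAG 20 um); SSADA carries the projection
# artefact, OMAG the higher motion-line rate and speckle, ICGA is the
# smooth 2D dye reference.
SSADA_PROFILE = ModalityProfile(
    name="SSADA", psf_fwhm_um=15.0, speckle_shape=18.0, motion_line_rate=0.6,
    projection_strength=0.55, background_level=0.10, supports_volume=True,
)
OMAG_PROFILE = ModalityProfile(
    name="OMAG", psf_fwhm_um=20.0, speckle_shape=9.0, motion_line_rate=2.0,
    projection_strength=0.0, background_level=0.12, supports_volume=True,
)
ICGA_PROFILE = ModalityProfile(
    name="ICGA", psf_fwhm_um=25.0, speckle_shape=40.0, motion_line_rate=0.0,
    projection_strength=0.0, background_level=0.08, supports_volume=False,
)

_PROFILES = {p.name: p for p in (SSADA_PROFILE, OMAG_PROFILE, ICGA_PROFILE)}


def default_profile(name: str) -> ModalityProfile:
    """Return the default profile for a modality name (case-insensitive)."""
    try:
        return _PROFILES[name.upper()]
    except KeyError:
        raise UnsupportedModalityError(
            f"unknown modality {name!r}; expected one of {sorted(_PROFILES)}"
        ) from None


def _rotate(vx: float, vy: float, angle: float) -> tuple[float, float]:
    c, s = math.cos(angle), math.sin(angle)
    return c * vx - s * vy, s * vx + c * vy


def _unit(vx: float, vy: float) -> tuple[float, float]:
    n = math.hypot(vx, vy)
    if n == 0.0:
        return 1.0, 0.0
    return vx / n, vy / n


def grow_vessel_tree(
    growth_params: GrowthParams, n_sprouts: int, seed: int
) -> VesselTree:
    """Grow a seeded vessel forest from the limbus toward the cornea centre.

    ``n_sprouts`` roots are placed uniformly on the border of the unit
    square, heading inward.  At each of ``n_steps`` global steps every
    active tip advances by ``step_len`` along a direction blending its
    perturbed previous heading with the pull toward the centre, appends
    one segment, and branches with probability ``branch_prob`` (the child
    tip starts advancing at the next step, with tapered radius).

    Geometry draws and branching draws come from two independent streams
    spawned from ``seed``, so the branching process is a plain Bernoulli
    sequence consumed one draw per tip per step, in tip order.
    """
    p = growth_params
    if n_sprouts < 1:
        raise InvalidParameterError("n_sprouts must be >= 1")
    if p.step_len <= 0:
        raise InvalidParameterError("step_len must be > 0")
    if not 0.0 <= p.branch_prob <= 1.0:
        raise InvalidParameterError("branch_prob must be in [0, 1]")
    if not 0.0 < p.taper <= 1.0:
        raise InvalidParameterError("taper must be in (0, 1]")

    geom_ss, branch_ss = np.random.SeedSequence(seed).spawn(2)
    geom = np.random.default_rng(geom_ss)
    branch = np.random.default_rng(branch_ss)

    # tips: [x, y, dir_x, dir_y, radius, depth, parent segment index]
    tips: list[list] = []
    for _ in range(n_sprouts):
        side = int(geom.integers(4))
        t = float(geom.uniform())
        if side == 0:
            x, y = t, 0.0
        elif side == 1:
            x, y = t, 1.0
        elif side == 2:
            x, y = 0.0, t
        else:
            x, y = 1.0, t
        dx, dy = _unit(0.5 - x, 0.5 - y)
        depth = float(geom.uniform(*p.depth_range_um))
        tips.append([x, y, dx, dy, p.root_radius_um, depth, None])

    segments: list[VesselSegment] = []
    for _ in range(p.n_steps):
        new_tips: list[list] = []
        for tip in tips:
            x, y, dx, dy, radius, depth, parent = tip
            ang = float(geom.normal(0.0, p.angle_sd))
            hx, hy = _rotate(dx, dy, ang)
            cx, cy = _unit(0.5 - x, 0.5 - y)
            ndx, ndy = _unit(
                (1.0 - p.center_bias) * hx + p.center_bias * cx,
                (1.0 - p.center_bias) * hy + p.center_bias * cy,
            )
            nx = min(1.0, max(0.0, x + p.step_len * ndx))
            ny = min(1.0, max(0.0, y + p.step_len * ndy))
            ndepth = float(
                np.clip(depth + geom.normal(0.0, p.depth_drift_um), 0.0, p.depth_max_um)
            )
            segments.append(
                VesselSegment(
                    parent=parent, start=(x, y), end=(nx, ny),
                    radius_um=radius, depth_um=ndepth,
                )
            )
            seg_idx = len(segments) - 1
            tip[0], tip[1], tip[2], tip[3], tip[5], tip[6] = nx, ny, ndx, ndy, ndepth, seg_idx
            do_branch = float(branch.uniform()) < p.branch_prob
            if do_branch and len(tips) + len(new_tips) < p.max_tips:
                bang = float(geom.choice([-1.0, 1.0])) * float(
                    geom.uniform(0.4, 1.0)
                )
                bdx, bdy = _rotate(ndx, ndy, bang)
                new_tips.append(
                    [nx, ny, bdx, bdy, radius * p.taper, ndepth, seg_idx]
                )
        tips.extend(new_tips)

    return VesselTree(segments=tuple(segments), growth_params=p, seed=seed)


def _segment_mask(
    shape: tuple[int, int],
    seg: VesselSegment,
    pixel_size_um: float,
) -> np.ndarray | None:
    """Boolean capsule footprint of one segment on the pixel grid.

    Pixel (r, c) covers normalized point ((c + 0.5)/W, (r + 0.5)/H);
    a pixel is vessel if its centre lies within ``radius_um`` of the
    segment (distances in um, isotropic lateral spacing).
    """
    h, w = shape
    x0, y0 = seg.start
    x1, y1 = seg.end
    # segment endpoints in pixel coordinates (column, row)
    c0, r0 = x0 * w - 0.5, y0 * h - 0.5
    c1, r1 = x1 * w - 0.5, y1 * h - 0.5
    rad_px = seg.radius_um / pixel_size_um
    rmin = max(0, int(math.floor(min(r0, r1) - rad_px - 1)))
    rmax = min(h - 1, int(math.ceil(max(r0, r1) + rad_px + 1)))
    cmin = max(0, int(math.floor(min(c0, c1) - rad_px - 1)))
    cmax = min(w - 1, int(math.ceil(max(c0, c1) + rad_px + 1)))
    if rmin > rmax or cmin > cmax:
        return None
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    vr, vc = r1 - r0, c1 - c0
    seg_len2 = vr * vr + vc * vc
    if seg_len2 == 0.0:
        t = np.zeros_like(rr, dtype=float)
    else:
        t = np.clip(((rr - r0) * vr + (cc - c0) * vc) / seg_len2, 0.0, 1.0)
    dist2 = (rr - (r0 + t * vr)) ** 2 + (cc - (c0 + t * vc)) ** 2
    local = dist2 <= rad_px * rad_px
    if not local.any():
        return None
    out = np.zeros(shape, dtype=bool)
    out[rmin : rmax + 1, cmin : cmax + 1] = local
    return out


def rasterize_tree(
    tree: VesselTree,
    image_shape: tuple[int, int],
    pixel_size_um: float,
    depth_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Noise-free boolean vessel mask of the tree on a pixel grid.

    ``depth_window`` restricts to segments whose depth lies in the
    half-open interval [low, high) um.
    """
    h, w = image_shape
    if h <= 0 or w <= 0:
        raise InvalidParameterError("image_shape must be positive")
    if pixel_size_um <= 0:
        raise InvalidParameterError("pixel_size_um must be > 0")
    if depth_window is not None and not depth_window[0] < depth_window[1]:
        raise InvalidParameterError("depth_window must be a non-empty [low, high)")
    mask = np.zeros(image_shape, dtype=bool)
    for seg in tree.segments:
        if depth_window is not None and not (
            depth_window[0] <= seg.depth_um < depth_window[1]
        ):
            continue
        m = _segment_mask(image_shape, seg, pixel_size_um)
        if m is not None:
            mask |= m
    return mask


def ground_truth_density(
    tree: VesselTree,
    image_shape: tuple[int, int],
    pixel_size_um: float,
    depth_window: tuple[float, float] | None = None,
) -> float:
    """True vessel density (%): rasterized vessel pixels / total pixels."""
    mask = rasterize_tree(tree, image_shape, pixel_size_um, depth_window)
    return 100.0 * float(mask.sum()) / mask.size


def _apply_noise(
    img: np.ndarray,
    profile: ModalityProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiplicative speckle then motion-line overwrite, in place order."""
    if profile.speckle_shape is not None and profile.speckle_shape > 0:
        k = profile.speckle_shape
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    n_lines = int(rng.poisson(profile.motion_line_rate))
    for _ in range(n_lines):
        along_rows = bool(rng.integers(2))
        if along_rows:
            img[int(rng.integers(img.shape[0])), :] = MOTION_LINE_LEVEL
        else:
            img[:, int(rng.integers(img.shape[1]))] = MOTION_LINE_LEVEL
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def render_enface(
    tree: VesselTree,
    profile: ModalityProfile,
    image_shape: tuple[int, int],
    pixel_size_um: float,
    seed: int,
):
    """Render a whole-depth 2D en-face angiogram of the tree.

    Rasterizes the vessels as bright tubes, blurs with the modality PSF,
    adds background, applies unit-mean multiplicative speckle, then
    overwrites a Poisson number of full-width rows/columns with a bright
    motion-line level.  Output is 8-bit, deterministic per seed.
    """
    from .pipeline import EnFaceImage  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mask = rasterize_tree(tree, image_shape, pixel_size_um)
    img = np.where(mask, VESSEL_LEVEL, 0.0)
    sigma_px = profile.psf_fwhm_um * _FWHM_TO_SIGMA / pixel_size_um
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma_px)
    img = img + profile.background_level
    img = _apply_noise(img, profile, rng)
    return EnFaceImage(
        pixels=_quantize(img),
        pixel_size_um=pixel_size_um,
        modality=profile.name,
        provenance=f"synthetic seed={seed} tree_seed={tree.seed}",
    )


def render_volume(
    tree: VesselTree,
    profile: ModalityProfile,
    volume_shape: tuple[int, int, int],
    axial_spacing_um: float,
    pixel_size_um: float,
    seed: int,
):
    """Render a depth-resolved angiography volume (rows, cols, slices).

    Each segment's tube is placed in the slice whose depth window
    contains the segment depth (slice k spans [k, k+1) x spacing).  For
    modalities with ``projection_strength`` > 0, every vessel voxel's
    signal is replicated into all deeper voxels at the same lateral
    position, scaled by ``projection_strength x exp(-dz / decay)`` --
    the tail artefact that inflates deep-slab densities.  Speckle and
    motion lines are applied per slice; output is 8-bit.
    """
    from .pipeline import AngiographyVolume

    if not profile.supports_volume:
        raise UnsupportedModalityError(
            f"{profile.name} is a 2D modality; volumes are not defined"
        )
    if axial_spacing_um <= 0:
        raise InvalidParameterError("axial_spacing_um must be > 0")
    h, w, n_slices = volume_shape
    if h <= 0 or w <= 0 or n_slices <= 0:
        raise InvalidParameterError("volume_shape must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma_px = profile.psf_fwhm_um * _FWHM_TO_SIGMA / pixel_size_um

    clean = np.zeros((h, w, n_slices), dtype=float)
    for k in range(n_slices):
        window = (k * axial_spacing_um, (k + 1) * axial_spacing_um)
        mask = rasterize_tree(tree, (h, w), pixel_size_um, depth_window=window)
        if mask.any():
            sl = np.where(mask, VESSEL_LEVEL, 0.0)
            if sigma_px > 0:
                sl = ndimage.gaussian_filter(sl, sigma_px)
            clean[:, :, k] = sl

    if profile.projection_strength > 0:
        proj = np.zeros_like(clean)
        for k in range(n_slices - 1):
            dz = (np.arange(k + 1, n_slices) - k) * axial_spacing_um
            decay = profile.projection_strength * np.exp(
                -dz / profile.projection_decay_um
            )
            proj[:, :, k + 1 :] += clean[:, :, k : k + 1] * decay[None, None, :]
        clean = clean + proj

    out = np.empty((h, w, n_slices), dtype=np.uint8)
    for k in range(n_slices):
        sl = clean[:, :, k] + profile.background_level
        sl = _apply_noise(sl, profile, rng)
        out[:, :, k] = _quantize(sl)

    return AngiographyVolume(
        voxels=out,
        axial_spacing_um=axial_spacing_um,
        pixel_size_um=pixel_size_um,
        modality=profile.name,
    )
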