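"""Synthetic beating-heart phantom with analytic ground truth.

The phantom models the left-ventricular myocardium as an annulus that
contracts and relaxes sinusoidally over one cardiac cycle.  Lesions are
discs (in material coordinates) that alter both local intensity and local
motion: a ``motion_damping`` of 1 renders the tissue fully akinetic, as in
a transmural infarct.  Because the deformation is analytic, the true dense
displacement field between consecutive frames is known exactly, which makes
the phantom a ground-truth oracle for optical-flow estimation, for the
motion-consistency map, and for lesion segmentation.

Texture is generated in material coordinates (it advects with the tissue)
so that flow estimators have trackable structure everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass(frozen=True)
class LesionSpec:
    """A circular lesion in material (end-diastolic) coordinates.

    intensity_delta > 0 brightens the tissue (edema-like on T2-weighted
    contrast); intensity_delta < 0 darkens it (infarct-like).  motion_damping
    scales the local displacement by (1 - damping): 0 moves with the healthy
    wall, 1 is fully akinetic.
    """

    center: tuple[float, float]  # (row, col), px
    radius: float  # px
    intensity_delta: float  # in [-1, 1]
    motion_damping: float  # in [0, 1]


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 224
    width: int = 224
    n_frames: int = 20
    ring_center: tuple[float, float] | None = None  # default: image centre
    ring_radii: tuple[float, float] = (48.0, 72.0)  # (inner, outer), px
    contraction_amplitude: float = 0.1  # fraction of outer radius
    lesion_specs: tuple[LesionSpec, ...] = ()
    noise_sd: float = 0.01
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.ring_center is not None:
            return self.ring_center
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)

    def validate(self) -> None:
        inner, outer = self.ring_radii
        if not inner < outer:
            raise ValueError(f"ring_radii: inner ({inner}) must be < outer ({outer})")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0.0 <= self.contraction_amplitude < 1.0:
            raise ValueError("contraction_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cr, cc = self.center
        for les in self.lesion_specs:
            if not 0.0 <= les.motion_damping <= 1.0:
                raise ValueError("motion_damping must be in [0, 1]")
            if not -1.0 <= les.intensity_delta <= 1.0:
                raise ValueError("intensity_delta must be in [-1, 1]")
            lr, lc = les.center
            if (lr - les.radius < 0 or lr + les.radius > self.height - 1
                    or lc - les.radius < 0 or lc + les.radius > self.width - 1):
                raise ValueError(f"lesion at {les.center} r={les.radius} extends outside image")
            d = np.hypot(lr - cr, lc - cc)
            if d - les.radius > outer or d + les.radius < inner:
                raise ValueError(
                    f"lesion at {les.center} r={les.radius} does not intersect the "
                    f"myocardial annulus (radii {inner}-{outer})")


@dataclass
class CineSequence:
    """Ordered image frames over one cardiac cycle, intensities in [0, 1]."""

    frames: np.ndarray  # (T, H, W) float in [0, 1]
    frame_phase: np.ndarray  # (T,) in [0, 1), strictly increasing
    pixel_spacing: float = 1.25  # mm, metadata only

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.frame_phase = np.asarray(self.frame_phase, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T, H, W) with T >= 2")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")
        if self.frame_phase.shape != (self.frames.shape[0],):
            raise ValueError("frame_phase length must equal T")
        if np.any(np.diff(self.frame_phase) <= 0):
            raise ValueError("frame phases must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class PhantomTruth:
    myocardium_mask: np.ndarray  # (T, H, W) bool
    lesion_mask: np.ndarray  # (T, H, W) bool
    true_flow: np.ndarray  # (T-1, H, W, 2) px/frame, (drow, dcol)
    pathology_map: np.ndarray  # (H, W) in [0, 1]
    class_label: str  # normal | infarct | edema | mixed

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.true_flow)):
            raise ValueError("true_flow contains non-finite values")
        if np.any(self.lesion_mask & ~self.myocardium_mask):
            raise ValueError("lesion_mask must be contained in myocardium_mask")


def _contraction_scale(phase: np.ndarray, amplitude: float) -> np.ndarray:
    """Radial scale factor: 1 at end-diastole, 1 - amplitude at end-systole."""
    return 1.0 - amplitude * (1.0 - np.cos(2.0 * np.pi * phase)) / 2.0


def _soft_disc(rr: np.ndarray, cc: np.ndarray, center, radius, edge=1.0) -> np.ndarray:
    d = np.hypot(rr - center[0], cc - center[1])
    return np.clip((radius - d) / edge + 0.5, 0.0, 1.0)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


class _Renderer:
    """Analytic phantom renderer working in material coordinates."""

    def __init__(self, config: PhantomConfig):
        self.cfg = config
        self.center = np.array(config.center)
        rng = np.random.default_rng(config.seed)
        # advected texture: a few random plane waves in material coordinates
        n_waves = 6
        wavelen = rng.uniform(8.0, 22.0, size=n_waves)
        theta = rng.uniform(0, 2 * np.pi, size=n_waves)
        self._tex_k = (2 * np.pi / wavelen)[:, None] * np.stack(
            [np.sin(theta), np.cos(theta)], axis=1)
        self._tex_phase = rng.uniform(0, 2 * np.pi, size=n_waves)
        self._tex_amp = rng.uniform(0.5, 1.0, size=n_waves)
        self._tex_amp *= 0.06 / np.sum(self._tex_amp)
        self.noise_rng = np.random.default_rng(rng.integers(0, 2**31))

    def _damping_at(self, q_r: np.ndarray, q_c: np.ndarray) -> np.ndarray:
        w = np.zeros_like(q_r)
        for les in self.cfg.lesion_specs:
            if les.motion_damping > 0:
                m = _soft_disc(q_r, q_c, les.center, les.radius, edge=1.5)
                w = np.maximum(w, les.motion_damping * m)
        return w

    def ref_coords(self, scale: float, rr: np.ndarray, cc: np.ndarray):
        """Invert the deformation: pixel grid -> material coordinates.

        The healthy wall maps material radius rho to rho*scale; lesion tissue
        uses an effective scale 1 + (scale-1)*(1-damping).  The inverse is
        found by fixed-point iteration (3 steps suffice at the small
        amplitudes of a cardiac cycle).
        """
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        q_r = self.center[0] + dr / scale
        q_c = self.center[1] + dc / scale
        if any(l.motion_damping > 0 for l in self.cfg.lesion_specs):
            for _ in range(3):
                w = self._damping_at(q_r, q_c)
                s_eff = 1.0 + (scale - 1.0) * (1.0 - w)
                q_r = self.center[0] + dr / s_eff
                q_c = self.center[1] + dc / s_eff
        return q_r, q_c

    def fwd_coords(self, scale: float, q_r: np.ndarray, q_c: np.ndarray):
        """Material coordinates -> deformed pixel positions at given scale."""
        w = self._damping_at(q_r, q_c)
        s_eff = 1.0 + (scale - 1.0) * (1.0 - w)
        x_r = self.center[0] + (q_r - self.center[0]) * s_eff
        x_c = self.center[1] + (q_c - self.center[1]) * s_eff
        return x_r, x_c

    def intensity(self, q_r: np.ndarray, q_c: np.ndarray) -> np.ndarray:
        """Base tissue intensity at material coordinates."""
        inner, outer = self.cfg.ring_radii
        rho = np.hypot(q_r - self.center[0], q_c - self.center[1])
        edge = 1.5
        in_pool = _smoothstep((inner - rho) / edge + 0.5)
        in_ring = _smoothstep((rho - inner) / edge + 0.5) * _smoothstep(
            (outer - rho) / edge + 0.5)
        img = 0.2 + 0.25 * in_pool + 0.55 * in_ring
        tex = np.zeros_like(img)
        for k, ph, a in zip(self._tex_k, self._tex_phase, self._tex_amp):
            tex += a * np.cos(k[0] * q_r + k[1] * q_c + ph)
        img = img + tex
        for les in self.cfg.lesion_specs:
            m = _soft_disc(q_r, q_c, les.center, les.radius, edge=1.5)
            img = img + les.intensity_delta * m * in_ring
        return img

    def masks(self, q_r: np.ndarray, q_c: np.ndarray):
        inner, outer = self.cfg.ring_radii
        rho = np.hypot(q_r - self.center[0], q_c - self.center[1])
        myo = (rho >= inner) & (rho <= outer)
        les = np.zeros_like(myo)
        for spec in self.cfg.lesion_specs:
            d = np.hypot(q_r - spec.center[0], q_c - spec.center[1])
            les |= d <= spec.radius
        return myo, les & myo


def _class_label(specs) -> str:
    if not specs:
        return "normal"
    has_inf = any(l.intensity_delta < 0 for l in specs)
    has_ede = any(l.intensity_delta >= 0 for l in specs)
    if has_inf and has_ede:
        return "mixed"
    return "infarct" if has_inf else "edema"


def generate_phantom(config: PhantomConfig) -> tuple[CineSequence, PhantomTruth]:
    """Render a full cardiac cycle with analytic ground truth.

    The annulus radius varies sinusoidally with period ``n_frames``; the true
    flow field for pair t is the backward displacement that samples frame t
    at the material point imaged at each pixel of frame t+1, so that
    ``warp(frame_t, true_flow[t]) ~= frame_{t+1}``.
    """
    config.validate()
    T, H, W = config.n_frames, config.height, config.width
    ren = _Renderer(config)
    phase = np.arange(T) / T
    scales = _contraction_scale(phase, config.contraction_amplitude)
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")

    frames = np.empty((T, H, W))
    myo = np.empty((T, H, W), dtype=bool)
    les = np.empty((T, H, W), dtype=bool)
    q_cache = []
    for t in range(T):
        q_r, q_c = ren.ref_coords(scales[t], rr, cc)
        q_cache.append((q_r, q_c))
        frames[t] = ren.intensity(q_r, q_c)
        myo[t], les[t] = ren.masks(q_r, q_c)

    true_flow = np.empty((T - 1, H, W, 2))
    for t in range(T - 1):
        q_r, q_c = q_cache[t + 1]
        x_r, x_c = ren.fwd_coords(scales[t], q_r, q_c)
        true_flow[t, ..., 0] = x_r - rr
        true_flow[t, ..., 1] = x_c - cc

    if config.noise_sd > 0:
        frames = frames + ren.noise_rng.normal(0.0, config.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, 1.0)

    patho = ndimage.gaussian_filter(les.any(axis=0).astype(float), sigma=2.0)
    if patho.max() > 0:
        patho = patho / patho.max()

    seq = CineSequence(frames=frames, frame_phase=phase)
    truth = PhantomTruth(
        myocardium_mask=myo,
        lesion_mask=les,
        true_flow=true_flow,
        pathology_map=patho,
        class_label=_class_label(config.lesion_specs),
    )
    return seq, truth


def degrade(seq: CineSequence, factor: int, noise_sd: float,
            seed: int = 0) -> CineSequence:
    """Bicubic down/up round trip plus additive Gaussian noise.

    Emulates the acquisition-quality gap: frames are bicubically downsampled
    by ``factor`` (e.g. 256 -> 128), bicubically upsampled back to the
    original grid, then corrupted with clipped Gaussian noise.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    T, H, W = seq.frames.shape
    if H % factor or W % factor:
        raise ValueError(f"factor {factor} must divide frame shape {H}x{W}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(seq.frames)
    for t in range(T):
        f = seq.frames[t]
        if factor > 1:
            low = resize(f, (H // factor, W // factor), order=3,
                         anti_aliasing=True, mode="reflect")
            f = resize(low, (H, W), order=3, anti_aliasing=False, mode="reflect")
        out[t] = f
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    out = np.clip(out, 0.0, 1.0)
    return CineSequence(frames=out, frame_phase=seq.frame_phase.copy(),
                        pixel_spacing=seq.pixel_spacing)


def augment(image: np.ndarray, mask: np.ndarray | None = None,
            max_rotation: float = 20.0, elastic_sd: float = 5.0,
            max_intensity_shift: float = 0.1, seed: int = 0):
    """Random rotation, elastic deformation and intensity scaling.

    Defaults follow common cine-MRI training practice: rotations up to
    +/-20 degrees, elastic displacement fields with 5 px standard deviation,
    and global multiplicative intensity shifts up to +/-10%.  The identical
    geometric transform is applied to the image (bilinear) and the optional
    mask (nearest-neighbour); only the image receives the intensity shift.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if max_rotation < 0 or elastic_sd < 0:
        raise ValueError("max_rotation and elastic_sd must be >= 0")
    if not 0.0 <= max_intensity_shift < 1.0:
        raise ValueError("max_intensity_shift must be in [0, 1)")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    rng = np.random.default_rng(seed)
    H, W = image.shape
    angle = np.deg2rad(rng.uniform(-max_rotation, max_rotation))
    shift = rng.uniform(-max_intensity_shift, max_intensity_shift)

    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    cr, ccen = (H - 1) / 2.0, (W - 1) / 2.0
    # inverse rotation about the image centre
    ca, sa = np.cos(-angle), np.sin(-angle)
    src_r = cr + ca * (rr - cr) - sa * (cc - ccen)
    src_c = ccen + sa * (rr - cr) + ca * (cc - ccen)
    if elastic_sd > 0:
        disp = rng.normal(size=(2, H, W))
        disp = ndimage.gaussian_filter(disp, sigma=(0, 8, 8))
        std = disp.std()
        if std > 0:
            disp *= elastic_sd / std
        src_r = src_r + disp[0]
        src_c = src_c + disp[1]

    coords = np.stack([src_r, src_c])
    out = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    out = np.clip(out * (1.0 + shift), 0.0, 1.0)
    out_mask = None
    if mask is not None:
        out_mask = ndimage.map_coordinates(mask.astype(np.uint8), coords,
                                           order=0, mode="nearest")
        out_mask = out_mask.astype(mask.dtype)
    return out, out_mask
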