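"""Dense optical flow for cine sequences.

A deterministic coarse-to-fine Horn-Schunck solver estimates one dense
displacement field per consecutive frame pair.  Flow vectors follow the
backward-warping convention used throughout the package: ``flow[t]`` maps
the pixel grid of frame t+1 into frame t, so that
``warp(frames[t], flow[t]) ~= frames[t+1]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from cineclust.phantom import CineSequence

# weighted 8-neighbour average used by the Horn-Schunck update
_HS_KERNEL = np.array([[1 / 12, 1 / 6, 1 / 12],
                       [1 / 6, 0.0, 1 / 6],
                       [1 / 12, 1 / 6, 1 / 12]])


@dataclass
class FlowField:
    """Per-frame-pair dense motion vectors in (drow, dcol) px/frame."""

    vectors: np.ndarray  # (T-1, H, W, 2)
    valid_mask: np.ndarray | None = None  # (T-1,) bool, None = all valid
    phase_offset: int = 0  # roll applied by phase normalization

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 2:
            raise ValueError("vectors must have shape (T-1, H, W, 2)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("flow vectors contain non-finite values")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.vectors.shape[0],):
                raise ValueError("valid_mask must have one entry per frame pair")

    @property
    def n_pairs(self) -> int:
        return self.vectors.shape[0]

    def valid(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones(self.n_pairs, dtype=bool)
        return self.valid_mask


def warp(frame: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Backward-warp a frame: output(p) = frame(p + flow(p)).

    Bilinear interpolation; samples outside the image take the border value.
    Linear in the frame argument.
    """
    frame = np.asarray(frame, dtype=np.float64)
    flow = np.asarray(flow, dtype=np.float64)
    if flow.shape != frame.shape + (2,):
        raise ValueError(f"flow shape {flow.shape} incompatible with frame {frame.shape}")
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow contains non-finite values")
    H, W = frame.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    coords = np.stack([rr + flow[..., 0], cc + flow[..., 1]])
    return ndimage.map_coordinates(frame, coords, order=1, mode="nearest")


def _hs_increment(w0: np.ndarray, f1: np.ndarray, alpha: float,
                  iterations: int) -> tuple[np.ndarray, np.ndarray]:
    """Horn-Schunck iterations for the flow increment between w0 and f1."""
    avg = (w0 + f1) / 2.0
    Ir, Ic = np.gradient(avg)
    It = w0 - f1
    denom = alpha ** 2 + Ir ** 2 + Ic ** 2
    du = np.zeros_like(w0)
    dv = np.zeros_like(w0)
    for _ in range(iterations):
        du_bar = ndimage.convolve(du, _HS_KERNEL, mode="nearest")
        dv_bar = ndimage.convolve(dv, _HS_KERNEL, mode="nearest")
        t = (Ir * du_bar + Ic * dv_bar + It) / denom
        du = du_bar - Ir * t
        dv = dv_bar - Ic * t
    return du, dv


def _estimate_pair(f0: np.ndarray, f1: np.ndarray, n_levels: int,
                   iterations: int, smoothness: float) -> np.ndarray:
    """Coarse-to-fine Horn-Schunck flow for one frame pair."""
    # intensities on the conventional 0-255 scale the smoothness weight assumes
    f0 = f0 * 255.0
    f1 = f1 * 255.0
    pyr0, pyr1 = [f0], [f1]
    for _ in range(n_levels - 1):
        prev0, prev1 = pyr0[-1], pyr1[-1]
        if min(prev0.shape) < 16:
            break
        shape = (prev0.shape[0] // 2, prev0.shape[1] // 2)
        pyr0.append(resize(prev0, shape, order=1, anti_aliasing=True, mode="reflect"))
        pyr1.append(resize(prev1, shape, order=1, anti_aliasing=True, mode="reflect"))

    flow = np.zeros(pyr0[-1].shape + (2,))
    for level in range(len(pyr0) - 1, -1, -1):
        g0, g1 = pyr0[level], pyr1[level]
        if flow.shape[:2] != g0.shape:
            scale_r = g0.shape[0] / flow.shape[0]
            scale_c = g0.shape[1] / flow.shape[1]
            up = np.stack([
                resize(flow[..., 0], g0.shape, order=1, mode="edge") * scale_r,
                resize(flow[..., 1], g0.shape, order=1, mode="edge") * scale_c,
            ], axis=-1)
            flow = up
        for _ in range(3):  # re-linearize around the warped image
            w0 = warp(g0, flow)
            du, dv = _hs_increment(w0, g1, smoothness, iterations)
            flow = flow + np.stack([du, dv], axis=-1)
    return flow


def estimate_flow(seq: CineSequence, n_levels: int = 3, iterations: int = 50,
                  smoothness: float = 15.0) -> FlowField:
    """Estimate dense flow between every pair of consecutive frames.

    Parameters
    ----------
    seq : CineSequence
        Input cycle with T >= 2 frames.
    n_levels : int
        Pyramid depth of the coarse-to-fine scheme.
    iterations : int
        Horn-Schunck relaxation iterations per pyramid level.
    smoothness : float
        Regularization weight (alpha); larger values give smoother fields.

    The solver is fully deterministic.  A frame pair in which both frames
    are constant carries no motion information; it yields zero flow with a
    warning rather than an error.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    T = seq.n_frames
    H, W = seq.shape
    vectors = np.zeros((T - 1, H, W, 2))
    for t in range(T - 1):
        f0, f1 = seq.frames[t], seq.frames[t + 1]
        if f0.std() == 0 and f1.std() == 0:
            warnings.warn(f"frame pair {t}: zero-variance frames, returning zero flow")
            continue
        vectors[t] = _estimate_pair(f0, f1, n_levels, iterations, smoothness)
    return FlowField(vectors=vectors)
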