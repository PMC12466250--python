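"""Loss terms, selection rules and schedules of the training objective.

Every function here is a pure computation on supplied arrays: the
adversarial value is evaluated on given discriminator outputs, the topology
loss on given latent features and cluster assignments, and so on.  No
networks are trained; the functions define the objective a trainer would
optimize and make each term individually testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import squareform, pdist

LOSS_TERMS = ("adv", "ssim", "patho", "motion", "topo", "curr")
DEFAULT_LAMBDA_TOPO = 0.2


@dataclass(frozen=True)
class FeatureStack:
    """A bank of 2-D correlation kernels with bias and activation."""

    kernels: np.ndarray  # (C, kh, kw), odd kernel dims
    bias: np.ndarray  # (C,)
    activation: str = "identity"  # relu | tanh | identity

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=np.float64)
        if k.ndim != 3:
            raise ValueError("kernels must be (C, kh, kw)")
        if k.shape[1] % 2 == 0 or k.shape[2] % 2 == 0:
            raise ValueError("kernel dims must be odd")
        if not np.all(np.isfinite(k)):
            raise ValueError("kernels must be finite")
        if self.activation not in ("relu", "tanh", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class CurriculumSchedule:
    """Annealing endpoints for the difficulty threshold and mixing weight.

    The difficulty threshold delta shrinks from 0.5 to 0.1 over the first
    50 epochs; the supervised/consistency mixing weight alpha anneals from
    1 to 0 over the whole run.
    """

    delta_start: float = 0.5
    delta_end: float = 0.1
    delta_epochs: int = 50
    alpha_start: float = 1.0
    alpha_end: float = 0.0
    alpha_epochs: int = 150
    delta_mode: str = "linear"  # linear | cosine

    def __post_init__(self) -> None:
        for v in (self.delta_start, self.delta_end, self.alpha_start, self.alpha_end):
            if not 0.0 <= v <= 1.0:
                raise ValueError("schedule endpoints must lie in [0, 1]")
        if self.delta_epochs < 1 or self.alpha_epochs < 1:
            raise ValueError("schedule epochs must be >= 1")
        if self.delta_mode not in ("linear", "cosine"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")


@dataclass
class LossReport:
    terms: dict[str, float]
    weights: dict[str, float]
    total: float

    def to_dict(self) -> dict:
        return {"terms": dict(self.terms), "weights": dict(self.weights),
                "total": self.total}


def extract_features(image: np.ndarray, stack: FeatureStack) -> np.ndarray:
    """Per-channel 2-D correlation ('same' padding, reflected borders),
    plus bias, through the activation."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    kernels = np.asarray(stack.kernels, dtype=np.float64)
    bias = np.asarray(stack.bias, dtype=np.float64).ravel()
    if bias.shape[0] != kernels.shape[0]:
        raise ValueError("bias length must match number of kernels")
    out = np.stack([
        ndimage.correlate(image, k, mode="reflect") + b
        for k, b in zip(kernels, bias)
    ])
    if stack.activation == "relu":
        out = np.maximum(out, 0.0)
    elif stack.activation == "tanh":
        out = np.tanh(out)
    return out


def adversarial_value(d_real: np.ndarray, d_fake: np.ndarray,
                      eps: float = 1e-7) -> float:
    """GAN value function on given discriminator outputs.

    mean(log d_real) + mean(log(1 - d_fake)) with probabilities clamped to
    [eps, 1-eps].  The discriminator maximizes this value; the generator
    minimizes its negation.
    """
    d_real = np.asarray(d_real, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("discriminator outputs must be non-empty")
    if d_real.min() < 0 or d_real.max() > 1 or d_fake.min() < 0 or d_fake.max() > 1:
        raise ValueError("discriminator outputs must lie in [0, 1]")
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    dr = np.clip(d_real, eps, 1 - eps)
    df = np.clip(d_fake, eps, 1 - eps)
    return float(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df)))


def _gaussian_kernel_1d(window: int, sigma: float) -> np.ndarray:
    r = (window - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def _win_filter(x: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(x, k1d, axis=0, mode="nearest")
    return ndimage.correlate1d(out, k1d, axis=1, mode="nearest")


def ssim(a: np.ndarray, b: np.ndarray, window: int = 11, k1: float = 0.01,
         k2: float = 0.03, data_range: float = 1.0,
         sigma: float = 1.5) -> float:
    """Mean structural similarity with a Gaussian window.

    Standard windowed SSIM (11x11 Gaussian window of sd 1.5, k1 = 0.01,
    k2 = 0.03); local statistics use the Gaussian-weighted (population)
    moments and the mean is taken over windows fully inside the image.
    Result lies in [-1, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("inputs must be 2-D")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if min(a.shape) < window:
        raise ValueError("image smaller than the SSIM window")
    k = _gaussian_kernel_1d(window, sigma)
    mu_a = _win_filter(a, k)
    mu_b = _win_filter(b, k)
    var_a = _win_filter(a * a, k) - mu_a ** 2
    var_b = _win_filter(b * b, k) - mu_b ** 2
    cov = _win_filter(a * b, k) - mu_a * mu_b
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
    pad = (window - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def ssim_loss(a: np.ndarray, b: np.ndarray, **kwargs) -> float:
    """Structural similarity loss, 1 - SSIM, in [0, 2]."""
    return 1.0 - ssim(a, b, **kwargs)


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are equal."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def concat_pathology(latent: np.ndarray, mp: np.ndarray) -> np.ndarray:
    """Append a pathology constraint map as an extra latent channel."""
    latent = np.asarray(latent, dtype=np.float64)
    mp = np.asarray(mp, dtype=np.float64)
    if latent.ndim != 3 or mp.ndim != 2 or latent.shape[1:] != mp.shape:
        raise ValueError(
            f"spatial shapes must agree: latent {latent.shape}, map {mp.shape}")
    return np.concatenate([latent, mp[None]], axis=0)


def pathology_kl(mp: np.ndarray, mp_hat: np.ndarray, eps: float = 1e-8) -> float:
    """KL divergence between pathology maps viewed as pixel distributions.

    Each non-negative map is smoothed by eps and normalized to sum to 1 over
    pixels; returns D_KL(P || Q) in nats, >= 0 with equality iff the maps
    are proportional.
    """
    p = np.asarray(mp, dtype=np.float64)
    q = np.asarray(mp_hat, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("pathology maps must share a shape")
    if p.min() < 0 or q.min() < 0:
        raise ValueError("pathology maps must be non-negative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("pathology maps must not be all-zero")
    p = (p + eps) / (p + eps).sum()
    q = (q + eps) / (q + eps).sum()
    return float(np.sum(p * np.log(p / q)))


def _laplacian_dense(W: np.ndarray) -> np.ndarray:
    return np.diag(W.sum(axis=1)) - W


def topo_loss(latent_features: np.ndarray, assign, sigma_latent: float = 1.5,
              lambda_topo: float = DEFAULT_LAMBDA_TOPO) -> float:
    """Topology-consistency loss between latent geometry and clusters.

    L_latent is the Laplacian of a Gaussian affinity over latent feature
    distances (same kernel as the descriptor graph); L_cluster the Laplacian
    of binary co-membership (W_ij = 1 within a cluster, W_ii = 1).  Returns
    lambda_topo * ||L_latent - L_cluster||_F^2; zero when the latent
    geometry reproduces the partition exactly.  Noise nodes are dropped.
    """
    z = np.asarray(latent_features, dtype=np.float64)
    if z.ndim == 1:
        z = z[:, None]
    labels = np.asarray(assign.labels if hasattr(assign, "labels") else assign,
                        dtype=int)
    if z.shape[0] != labels.size:
        raise ValueError("latent features and assignment lengths differ")
    keep = labels >= 0
    z, labels = z[keep], labels[keep]
    n = z.shape[0]
    if n < 2:
        raise ValueError("at least 2 non-noise nodes required")
    if sigma_latent <= 0:
        raise ValueError("sigma_latent must be > 0")
    d2 = squareform(pdist(z, metric="sqeuclidean"))
    W_lat = np.exp(-d2 / (2.0 * sigma_latent ** 2))
    W_clu = (labels[:, None] == labels[None, :]).astype(np.float64)
    diff = _laplacian_dense(W_lat) - _laplacian_dense(W_clu)
    return float(lambda_topo * np.sum(diff ** 2))


def curriculum_select(entropies: np.ndarray, delta: float) -> np.ndarray:
    """Easy-sample index set: Se = { x : H(x) < delta } (strict)."""
    entropies = np.asarray(entropies, dtype=np.float64)
    if entropies.size and entropies.min() < 0:
        raise ValueError("entropies must be >= 0")
    return np.flatnonzero(entropies < delta)


def schedule(epoch: int, sched: CurriculumSchedule) -> tuple[float, float]:
    """(alpha, delta) at a given epoch.

    delta interpolates linearly (or with a half-cosine) from delta_start to
    delta_end over delta_epochs and stays clamped afterwards; alpha anneals
    linearly from alpha_start to alpha_end over alpha_epochs.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    f_d = min(epoch / sched.delta_epochs, 1.0)
    if sched.delta_mode == "cosine":
        f_d = (1.0 - np.cos(np.pi * f_d)) / 2.0
    delta = sched.delta_start + (sched.delta_end - sched.delta_start) * f_d
    f_a = min(epoch / sched.alpha_epochs, 1.0)
    alpha = sched.alpha_start + (sched.alpha_end - sched.alpha_start) * f_a
    return float(alpha), float(delta)


def curriculum_loss(l_sup: float, l_cons: float, alpha: float) -> float:
    """alpha * supervised loss + (1 - alpha) * consistency loss."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return float(alpha * l_sup + (1.0 - alpha) * l_cons)


def total_loss(terms: dict, weights: dict | None = None) -> LossReport:
    """Weighted sum of the six objective terms.

    Expected term names: adv, ssim, patho, motion, topo, curr.  A missing
    term is treated as 0 with a warning.  The motion term may be a MotionMap
    or array, in which case its (ROI-)mean scalarizes it.  Default weights
    are 1 except the topology weight of 0.2.
    """
    w = {name: 1.0 for name in LOSS_TERMS}
    w["topo"] = DEFAULT_LAMBDA_TOPO
    if weights:
        unknown = set(weights) - set(LOSS_TERMS)
        if unknown:
            raise ValueError(f"unknown loss weights: {sorted(unknown)}")
        w.update({k: float(v) for k, v in weights.items()})
    vals = {}
    for name in LOSS_TERMS:
        if name not in terms:
            warnings.warn(f"loss term {name!r} missing; treated as 0")
            vals[name] = 0.0
            continue
        v = terms[name]
        if hasattr(v, "values"):  # MotionMap
            roi = getattr(v, "roi", None)
            arr = v.values
            v = arr[roi].mean() if roi is not None else arr.mean()
        elif isinstance(v, np.ndarray):
            v = v.mean()
        v = float(v)
        if not np.isfinite(v):
            raise ValueError(f"loss term {name!r} is non-finite")
        vals[name] = v
    unknown = set(terms) - set(LOSS_TERMS)
    if unknown:
        raise ValueError(f"unknown loss terms: {sorted(unknown)}")
    total = sum(w[n] * vals[n] for n in LOSS_TERMS)
    return LossReport(terms=vals, weights=w, total=float(total))
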