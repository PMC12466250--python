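"""Spatio-temporal consistency clustering.

The stages in order: the motion-consistency integral accumulates the squared
spatial gradient of the flow field over the cycle (coherently moving tissue
scores low, motion abnormalities high); phase normalization suppresses the
global contraction/relaxation peaks so local abnormalities dominate; the
hybrid descriptor mixes appearance and motion; a Gaussian-kernel affinity
graph over ROI pixels is clustered spectrally and refined with DBSCAN; and
entropy/compactness quantify partition quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN, KMeans

from cineclust.flow import FlowField
from cineclust.phantom import CineSequence

DEFAULT_SIGMA = 1.5  # Gaussian affinity scale
DEFAULT_NEIGHBOR_RADIUS = 3  # px, Chebyshev sparsification radius
DEFAULT_EPS = 2.5  # px, DBSCAN neighbourhood
DEFAULT_MIN_SAMPLES = 5
DEFAULT_K = 6
MAX_NODES = 20000


@dataclass
class MotionMap:
    """Integrated squared flow-gradient magnitude per pixel (>= 0)."""

    values: np.ndarray  # (H, W)
    roi: np.ndarray | None = None  # (H, W) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion map contains non-finite values")
        if self.values.min() < 0:
            raise ValueError("motion map must be non-negative")


@dataclass
class DescriptorMap:
    values: np.ndarray  # (H, W)
    lambda_s: float
    lambda_t: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor contains non-finite values")
        if self.lambda_s < 0 or self.lambda_t < 0:
            raise ValueError("descriptor weights must be >= 0")
        if self.lambda_s == 0 and self.lambda_t == 0:
            raise ValueError("descriptor weights must not both be zero")


@dataclass
class AffinityGraph:
    """Sparsified Gaussian affinity over ROI pixels with L = D - W."""

    nodes: np.ndarray  # (n, 2) int pixel coordinates (row, col)
    W: sparse.csr_matrix  # symmetric, W_ii = 1, entries in (0, 1]
    degree: sparse.csr_matrix  # diagonal row-sum matrix D
    laplacian: sparse.csr_matrix  # L = D - W

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


@dataclass
class ClusterAssignment:
    """Hard labels (-1 = noise) with optional row-stochastic soft membership."""

    labels: np.ndarray  # (n,) int
    k: int
    soft: np.ndarray | None = None  # (n, k)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < -1 or self.labels.max() >= self.k):
            raise ValueError("labels must lie in {-1, 0..k-1}")
        if self.soft is not None:
            self.soft = np.asarray(self.soft, dtype=np.float64)
            if self.soft.shape != (self.labels.size, self.k):
                raise ValueError("soft membership must be (n, k)")

    @property
    def n_nodes(self) -> int:
        return self.labels.size


def _spatial_gradient_sq(field: np.ndarray) -> np.ndarray:
    """Squared gradient magnitude of a (H, W, 2) flow frame.

    Central differences on an edge-replicated grid, summed over the four
    partial derivatives (d drow/d row, d drow/d col, d dcol/d row,
    d dcol/d col).
    """
    out = np.zeros(field.shape[:2])
    for comp in range(2):
        f = np.pad(field[..., comp], 1, mode="edge")
        d_r = (f[2:, 1:-1] - f[:-2, 1:-1]) / 2.0
        d_c = (f[1:-1, 2:] - f[1:-1, :-2]) / 2.0
        out += d_r ** 2 + d_c ** 2
    return out


def motion_integral(flow: FlowField) -> MotionMap:
    """Temporal consistency integral: sum_t ||grad V_t||^2 * dt, dt = 1 frame.

    Frame pairs excluded by phase normalization (valid_mask False) do not
    contribute.
    """
    if flow.n_pairs == 0:
        raise ValueError("flow field has no frame pairs")
    valid = flow.valid()
    if not valid.any():
        raise ValueError("all frame pairs are excluded")
    values = np.zeros(flow.vectors.shape[1:3])
    for t in np.flatnonzero(valid):
        values += _spatial_gradient_sq(flow.vectors[t])
    return MotionMap(values=values)


def phase_normalize(flow: FlowField, energy_quantile: float = 0.8) -> FlowField:
    """Exclude global contraction/relaxation peaks from the motion integral.

    The mean squared flow magnitude of each frame pair is its global motion
    energy; pairs with energy strictly above the given quantile of the
    cycle's energies are marked invalid, so end-systolic and end-diastolic
    phase transitions do not masquerade as motion abnormalities.  The phase
    origin is rolled so the minimum-energy pair comes first.
    """
    if not 0 < energy_quantile <= 1:
        raise ValueError("energy_quantile must be in (0, 1]")
    energy = np.mean(np.sum(flow.vectors ** 2, axis=-1), axis=(1, 2))
    thresh = np.quantile(energy, energy_quantile)
    keep = energy <= thresh  # ties kept
    prior = flow.valid()
    keep &= prior
    if not keep.any():
        raise ValueError("phase normalization excluded every frame pair")
    origin = int(np.argmin(energy))
    vectors = np.roll(flow.vectors, -origin, axis=0)
    keep = np.roll(keep, -origin)
    return FlowField(vectors=vectors, valid_mask=keep, phase_offset=origin)


def _local_scale_standardize(x: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Center on the ROI median and scale by the median absolute
    adjacent-pixel difference inside the ROI.

    The affinity kernel compares descriptor values of *neighbouring* pixels,
    so its bandwidth sigma must be calibrated against the typical local
    descriptor variation of healthy tissue (in the spirit of self-tuning
    spectral clustering), not against the global standard deviation, which
    the pathological tail itself inflates.  After this scaling a typical
    healthy neighbour pair differs by ~1 unit while a pathological boundary
    differs by many units, so the Gaussian kernel severs lesion boundaries
    while keeping healthy tissue strongly connected.
    """
    med = float(np.median(x[roi]))
    diffs = []
    for ax in (0, 1):
        a = np.take(x, range(1, x.shape[ax]), axis=ax)
        b = np.take(x, range(0, x.shape[ax] - 1), axis=ax)
        both = (np.take(roi, range(1, roi.shape[ax]), axis=ax)
                & np.take(roi, range(0, roi.shape[ax] - 1), axis=ax))
        diffs.append(np.abs(a - b)[both])
    diffs = np.concatenate(diffs) if diffs else np.array([])
    scale = float(np.median(diffs)) if diffs.size else 0.0
    if scale == 0:
        scale = float(x[roi].std()) or 1.0
    return (x - med) / scale


def hybrid_descriptor(seq: CineSequence, motion: MotionMap,
                      lambda_s: float = 0.5, lambda_t: float = 0.5,
                      standardize: bool = True) -> DescriptorMap:
    """Hybrid appearance/motion descriptor.

    Ds = lambda_s * SpatialIntensity + lambda_t * Imotion, where
    SpatialIntensity is the temporal mean intensity per pixel.  With
    ``standardize`` each term is centred on its ROI median and scaled by its
    median local (adjacent-pixel) variation before weighting, so the two
    weights act on comparable scales and the affinity bandwidth downstream
    is expressed in units of healthy-tissue local contrast.
    """
    if motion.values.shape != seq.shape:
        raise ValueError("motion map shape does not match sequence frames")
    if lambda_s == 0 and lambda_t == 0:
        raise ValueError("lambda_s and lambda_t must not both be zero")
    spatial = seq.frames.mean(axis=0)
    temporal = motion.values
    if standardize:
        roi = motion.roi if motion.roi is not None else np.ones(seq.shape, bool)
        spatial = _local_scale_standardize(spatial, roi)
        temporal = _local_scale_standardize(temporal, roi)
    return DescriptorMap(values=lambda_s * spatial + lambda_t * temporal,
                         lambda_s=lambda_s, lambda_t=lambda_t)


def build_affinity(desc: DescriptorMap, roi: np.ndarray, sigma: float = DEFAULT_SIGMA,
                   neighbor_radius: int = DEFAULT_NEIGHBOR_RADIUS,
                   max_nodes: int = MAX_NODES) -> AffinityGraph:
    """Gaussian-kernel affinity graph over ROI pixels.

    W_ij = exp(-|Ds(i) - Ds(j)|^2 / (2 sigma^2)) for pixel pairs within
    ``neighbor_radius`` (Chebyshev distance), 0 otherwise; W_ii = 1.
    D = diag(row sums), L = D - W.  Sparsification keeps the graph tractable
    on full images; a dense affinity over all pixel pairs is quadratic in
    the ROI size.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != desc.values.shape:
        raise ValueError("roi shape does not match descriptor")
    nodes = np.argwhere(roi)
    n = nodes.shape[0]
    if n == 0:
        raise ValueError("ROI is empty")
    if n > max_nodes:
        raise ValueError(
            f"ROI has {n} pixels, exceeding max_nodes={max_nodes}; subsample the "
            "ROI or raise max_nodes (memory grows quadratically)")
    vals = desc.values[nodes[:, 0], nodes[:, 1]]
    tree = cKDTree(nodes.astype(float))
    pairs = tree.query_pairs(r=neighbor_radius, p=np.inf, output_type="ndarray")
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        w = np.exp(-((vals[i] - vals[j]) ** 2) / (2.0 * sigma ** 2))
        rows = np.concatenate([i, j, np.arange(n)])
        cols = np.concatenate([j, i, np.arange(n)])
        data = np.concatenate([w, w, np.ones(n)])
    else:
        rows = cols = np.arange(n)
        data = np.ones(n)
    W = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    deg = np.asarray(W.sum(axis=1)).ravel()
    D = sparse.diags(deg, format="csr")
    L = (D - W).tocsr()
    return AffinityGraph(nodes=nodes, W=W, degree=D, laplacian=L)


def _spectral_embedding(graph: AffinityGraph, k: int) -> np.ndarray:
    """Embedding from the k smallest generalized eigenvectors of (L, D).

    Solved through the symmetric normalization L_sym = D^-1/2 L D^-1/2 whose
    eigenvectors u map back via v = D^-1/2 u; this is the standard relaxation
    of the minimum normalized cut.  Rows are normalized to unit length.
    """
    n = graph.n_nodes
    deg = graph.degree.diagonal()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    Dis = sparse.diags(d_inv_sqrt)
    L_sym = Dis @ graph.laplacian @ Dis
    if n <= 3000:
        _, vecs = eigh(L_sym.toarray(), subset_by_index=(0, k - 1))
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        _, vecs = eigsh(L_sym, k=k, which="SA", v0=v0)
    emb = d_inv_sqrt[:, None] * vecs
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return emb / norms


def _ncut_value(off: np.ndarray, d: np.ndarray, inA: np.ndarray) -> float:
    volA, volB = d[inA].sum(), d[~inA].sum()
    if volA <= 0 or volB <= 0:
        return np.inf
    cut = off[inA][:, ~inA].sum()
    return cut / volA + cut / volB


def _refine_bipartition(off: np.ndarray, d: np.ndarray,
                        labels: np.ndarray, max_passes: int = 10) -> np.ndarray:
    """Greedy single-node moves that lower the normalized cut (deterministic).

    Standard local refinement of the spectral sweep cut; each pass tries
    moving every node to the other side and keeps improvements.
    """
    labels = labels.copy()
    n = labels.size
    best = _ncut_value(off, d, labels == 0)
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            side = labels[i]
            if np.sum(labels == side) == 1:
                continue  # never empty a side
            labels[i] = 1 - side
            nc = _ncut_value(off, d, labels == 0)
            if nc < best - 1e-12:
                best = nc
                improved = True
            else:
                labels[i] = side
        if not improved and n <= 64:
            # pair swaps escape single-move local minima on small graphs
            for i in range(n):
                for j in range(i + 1, n):
                    if labels[i] == labels[j]:
                        continue
                    labels[i], labels[j] = labels[j], labels[i]
                    nc = _ncut_value(off, d, labels == 0)
                    if nc < best - 1e-12:
                        best = nc
                        improved = True
                    else:
                        labels[i], labels[j] = labels[j], labels[i]
        if not improved:
            break
    return labels


def _sweep_labels(off: np.ndarray, d: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Threshold a sweep vector where the normalized cut is minimal."""
    n = vec.size
    order = np.argsort(vec, kind="stable")
    total_vol = d.sum()
    best_nc, best_m = np.inf, 1
    inA = np.zeros(n, dtype=bool)
    cut = 0.0
    volA = 0.0
    for m in range(n - 1):  # incremental cut update along the sweep
        i = order[m]
        cut += off[i, ~inA].sum() - off[i, inA].sum()
        inA[i] = True
        volA += d[i]
        volB = total_vol - volA
        if volA <= 0 or volB <= 0:
            continue
        nc = cut / volA + cut / volB
        if nc < best_nc - 1e-12:
            best_nc, best_m = nc, m + 1
    labels = np.ones(n, dtype=int)
    labels[order[:best_m]] = 0
    return labels


def _sweep_bipartition(graph: AffinityGraph) -> ClusterAssignment:
    """Two-way cut: sweep candidate Fiedler vectors for the threshold with
    the minimal normalized cut, then refine locally; deterministic.

    Candidates are the generalized (random-walk) Fiedler vector, the
    symmetric-normalized one, and the unnormalized one — cheap relaxations
    whose best refined sweep is kept.
    """
    n = graph.n_nodes
    off = (graph.W - sparse.diags(graph.W.diagonal())).toarray()
    d = off.sum(axis=1)
    deg = graph.degree.diagonal()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    Dis = sparse.diags(d_inv_sqrt)
    L_sym = (Dis @ graph.laplacian @ Dis).toarray()
    _, vecs = eigh(L_sym, subset_by_index=(0, 1))
    u_sym = vecs[:, 1]
    candidates = [d_inv_sqrt * u_sym, u_sym]
    if n <= 3000:
        _, vecs_un = eigh(graph.laplacian.toarray(), subset_by_index=(0, 1))
        candidates.append(vecs_un[:, 1])
    best_nc, labels = np.inf, None
    for vec in candidates:
        starts = [_sweep_labels(off, d, vec)]
        if n <= 64:
            # refine from every sweep threshold, not just the best one
            order = np.argsort(vec, kind="stable")
            for m in range(1, n):
                lab = np.ones(n, dtype=int)
                lab[order[:m]] = 0
                starts.append(lab)
        for start in starts:
            lab = _refine_bipartition(off, d, start)
            nc = _ncut_value(off, d, lab == 0)
            # labels is None handles edgeless graphs where every cut is inf
            if labels is None or nc < best_nc - 1e-12:
                best_nc, labels = nc, lab
    fiedler = candidates[0]
    centroid = np.array([fiedler[labels == 0].mean(), fiedler[labels == 1].mean()])
    d2 = (fiedler[:, None] - centroid[None, :]) ** 2
    logits = -d2
    logits -= logits.max(axis=1, keepdims=True)
    soft = np.exp(logits)
    soft /= soft.sum(axis=1, keepdims=True)
    return ClusterAssignment(labels=labels, k=2, soft=soft)


def spectral_cluster(graph: AffinityGraph, k: int = DEFAULT_K,
                     seed: int = 0) -> ClusterAssignment:
    """Spectral clustering of the affinity graph into k clusters.

    Nodes are embedded with the eigenvectors of the k smallest Laplacian
    eigenvalues (generalized problem L v = lambda D v, rows normalized).
    For k = 2 the partition is the classical sweep cut of the Fiedler
    vector (the threshold minimizing the normalized cut); for k > 2 the
    embedding is grouped by k-means with a fixed seed.  Soft memberships
    are the softmax of negative squared embedding distances to the cluster
    centroids (temperature 1), giving the probabilities the entropy
    measures need.
    """
    n = graph.n_nodes
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of nodes ({n})")
    n_comp, _ = connected_components(graph.W, directed=False)
    if n_comp > k:
        warnings.warn(f"graph has {n_comp} connected components > k={k}; "
                      "clustering proceeds but cannot separate them all")
    if k == n:
        labels = np.arange(n)
        return ClusterAssignment(labels=labels, k=k, soft=np.eye(n))
    if k == 2:
        return _sweep_bipartition(graph)
    emb = _spectral_embedding(graph, k)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    d2 = km.transform(emb) ** 2
    logits = -d2
    logits -= logits.max(axis=1, keepdims=True)
    soft = np.exp(logits)
    soft /= soft.sum(axis=1, keepdims=True)
    return ClusterAssignment(labels=labels, k=k, soft=soft)


def dbscan_refine(assign: ClusterAssignment, nodes: np.ndarray,
                  eps: float = DEFAULT_EPS,
                  min_samples: int = DEFAULT_MIN_SAMPLES) -> ClusterAssignment:
    """Density-based refinement of each spectral cluster in pixel space.

    Within every spectral cluster DBSCAN over the pixel coordinates splits
    spatially disconnected fragments and demotes density-unreachable pixels
    or fragments smaller than ``min_samples`` to noise (-1).  The cluster
    count may grow; existing noise passes through unchanged.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape[0] != assign.n_nodes:
        raise ValueError("nodes and assignment lengths differ")
    new_labels = np.full(assign.n_nodes, -1, dtype=int)
    next_id = 0
    for c in range(assign.k):
        idx = np.flatnonzero(assign.labels == c)
        if idx.size == 0:
            continue
        sub = DBSCAN(eps=eps, min_samples=min_samples).fit(nodes[idx])
        for frag in np.unique(sub.labels_):
            if frag == -1:
                continue
            new_labels[idx[sub.labels_ == frag]] = next_id
            next_id += 1
    return ClusterAssignment(labels=new_labels, k=max(next_id, 1))


def _soft_or_onehot(assign: ClusterAssignment) -> np.ndarray:
    if assign.soft is not None:
        return assign.soft
    onehot = np.zeros((assign.n_nodes, assign.k))
    ok = assign.labels >= 0
    onehot[np.flatnonzero(ok), assign.labels[ok]] = 1.0
    onehot[~ok] = 1.0 / assign.k  # noise rows: uninformative membership
    return onehot


def cluster_entropy(assign: ClusterAssignment) -> tuple[np.ndarray, float]:
    """Per-node membership entropy H(x) = -sum_k p_k ln p_k (nats).

    Hard labels are one-hot encoded first (entropy 0).  The mean is taken
    over non-noise nodes.
    """
    p = _soft_or_onehot(assign)
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("soft membership rows must sum to 1 within 1e-6")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    keep = assign.labels >= 0
    if not keep.any():
        raise ValueError("no non-noise nodes for the entropy mean")
    return h, float(h[keep].mean())


def cluster_compactness(assign: ClusterAssignment, desc,
                        nodes: np.ndarray | None = None) -> float:
    """Explained-variance compactness of a partition, in percent.

    100 * (1 - pooled within-cluster descriptor variance / total variance),
    clipped to [0, 100].  Noise nodes are excluded.  ``desc`` may be a
    DescriptorMap (then ``nodes`` indexes it) or a per-node value array.
    """
    if isinstance(desc, DescriptorMap):
        if nodes is None:
            raise ValueError("nodes required when desc is a DescriptorMap")
        values = desc.values[np.asarray(nodes)[:, 0], np.asarray(nodes)[:, 1]]
    else:
        values = np.asarray(desc, dtype=np.float64)
    if values.shape[0] != assign.n_nodes:
        raise ValueError("descriptor values and assignment lengths differ")
    keep = assign.labels >= 0
    if not keep.any():
        raise ValueError("at least one non-noise cluster required")
    x = values[keep]
    lab = assign.labels[keep]
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero total descriptor variance; compactness = 100")
        return 100.0
    ssw = 0.0
    for c in np.unique(lab):
        xc = x[lab == c]
        ssw += float(np.sum((xc - xc.mean()) ** 2))
    return float(np.clip(100.0 * (1.0 - ssw / sst), 0.0, 100.0))
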