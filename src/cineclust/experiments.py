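"""Reference experiments on the synthetic phantom.

These functions pin down the study conditions used to validate the method:
the lesion-recovery experiment (can the clustering recover a known akinetic,
intensity-altered lesion?), the phase-normalization experiment (does
excluding global contraction peaks lower the motion integral over healthy
tissue?), and the random-graph generator used to compare the two-way
spectral cut against exhaustive search.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np

from cineclust.config import PipelineConfig
from cineclust.flow import estimate_flow
from cineclust.metrics import dice
from cineclust.phantom import LesionSpec, PhantomConfig, generate_phantom
from cineclust.pipeline import analyze_sequence, best_matching_cluster
from cineclust.stc2 import motion_integral, phase_normalize

# lesion-recovery study conditions: 128 x 128 grid, 20 frames per cycle,
# one 9 px lesion with damping 0.8 and intensity shift +0.2, light noise
RECOVERY_GRID = 128
RECOVERY_FRAMES = 20
RECOVERY_DAMPING = 0.8
RECOVERY_DELTA = 0.2
RECOVERY_RADIUS = 9.0
RECOVERY_RING = (26.0, 40.0)
RECOVERY_NOISE = 0.01


def recovery_phantom_config(seed: int, angle: float) -> PhantomConfig:
    """One lesion-recovery phantom; the lesion sits at the given angular
    position on the mid-wall circle."""
    c = (RECOVERY_GRID - 1) / 2.0
    mid = sum(RECOVERY_RING) / 2.0
    center = (c + mid * np.sin(angle), c + mid * np.cos(angle))
    return PhantomConfig(
        height=RECOVERY_GRID, width=RECOVERY_GRID, n_frames=RECOVERY_FRAMES,
        ring_radii=RECOVERY_RING, contraction_amplitude=0.1,
        lesion_specs=(LesionSpec(center=center, radius=RECOVERY_RADIUS,
                                 intensity_delta=RECOVERY_DELTA,
                                 motion_damping=RECOVERY_DAMPING),),
        noise_sd=RECOVERY_NOISE, seed=seed)


def lesion_recovery_experiment(n_runs: int = 20, base_seed: int = 0) -> list[float]:
    """Dice of the best-matching refined cluster against the true lesion,
    over ``n_runs`` independently seeded phantoms."""
    rng = np.random.default_rng(base_seed)
    cfg = PipelineConfig()
    scores = []
    for _ in range(n_runs):
        seed = int(rng.integers(0, 2**31 - 1))
        angle = float(rng.uniform(0, 2 * np.pi))
        pcfg = recovery_phantom_config(seed, angle)
        run_cfg = dataclasses.replace(cfg, phantom=pcfg, seed=seed)
        seq, truth = generate_phantom(pcfg)
        roi = truth.myocardium_mask.all(axis=0)
        _, _, _, _, graph, _, refined = analyze_sequence(seq, roi, run_cfg)
        lesion = truth.lesion_mask.any(axis=0)
        pred = best_matching_cluster(refined.labels, graph.nodes, lesion)
        scores.append(dice(pred, lesion))
    return scores


def phase_normalization_experiment(n_runs: int = 10,
                                   base_seed: int = 0) -> list[tuple[float, float]]:
    """Mean motion integral over healthy myocardium before and after phase
    normalization, per phantom."""
    rng = np.random.default_rng(base_seed)
    out = []
    for _ in range(n_runs):
        seed = int(rng.integers(0, 2**31 - 1))
        angle = float(rng.uniform(0, 2 * np.pi))
        pcfg = recovery_phantom_config(seed, angle)
        seq, truth = generate_phantom(pcfg)
        healthy = (truth.myocardium_mask.all(axis=0)
                   & ~truth.lesion_mask.any(axis=0))
        fl = estimate_flow(seq)
        before = float(motion_integral(fl).values[healthy].mean())
        after = float(motion_integral(phase_normalize(fl, 0.8)).values[healthy].mean())
        out.append((before, after))
    return out


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random connected weighted graph: a uniform spanning backbone plus
    Bernoulli(0.4) extra edges with uniform(0.05, 1) weights; unit diagonal."""
    W = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        w = rng.uniform(0.05, 1.0)
        W[order[i], j] = W[j, order[i]] = w
    for i, j in combinations(range(n), 2):
        if W[i, j] == 0 and rng.random() < 0.4:
            w = rng.uniform(0.05, 1.0)
            W[i, j] = W[j, i] = w
    np.fill_diagonal(W, 1.0)
    return W
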