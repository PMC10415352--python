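"""Recurrent weight-matrix builders and structural perturbations.

Weights w_ij give the current contribution (uA/cm^2) to postsynaptic neuron
i per unit of presynaptic activation s_j; column j is the source, row i the
target.  Inhibition is expressed through negative weight components (the
ring's long-range surround), not a separate population.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "build_all_to_all",
    "build_ring",
    "build_directed",
    "perturb_weights",
    "sparsify",
    "save_weights",
    "load_weights",
]


def build_all_to_all(N: int, w_total: float) -> np.ndarray:
    """Uniform all-to-all coupling w_ij = w_total / N (self-connections kept).

    Every row sums to ``w_total``, so the population mean field reproduces
    the single-neuron autapse with weight ``w_total`` regardless of N.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    if w_total < 0:
        raise ValueError("w_total must be nonnegative")
    return np.full((N, N), w_total / N)


def build_ring(N: int, A: float, B: float) -> np.ndarray:
    """Symmetric ring: w_ij = A + B*cos(2*pi*(i-j)/N).

    A < 0 with A + B > 0 gives local excitation and long-range inhibition,
    the classic bump-attractor profile.  The matrix is circulant and
    symmetric (cosine is even in i-j).
    """
    if N < 2:
        raise ValueError("ring requires N >= 2")
    idx = np.arange(N)
    d = idx[:, None] - idx[None, :]
    return A + B * np.cos(2.0 * np.pi * d / N)


def build_directed(N: int, A: float, B: float, C: float,
                   wrap: bool = False) -> np.ndarray:
    """Directed (chain-like) coupling producing a drifting activity bump.

    w_ij = [A + B*cos(4*pi*(i-j)/N + 0.1)] * H(C - |i-j|), with H the
    Heaviside step.  The +0.1 phase offset breaks the i<->j symmetry, so
    activity drifts along the chain.  ``|i-j|`` is the plain (non-wrapped)
    index difference by default; set ``wrap=True`` for circular distance.
    """
    if N < 2:
        raise ValueError("directed structure requires N >= 2")
    if C < 1:
        raise ValueError("C must be at least 1")
    idx = np.arange(N)
    d = idx[:, None] - idx[None, :]
    dist = np.abs(d)
    if wrap:
        dist = np.minimum(dist, N - dist)
    H = (C - dist > 0).astype(float)
    return (A + B * np.cos(4.0 * np.pi * d / N + 0.1)) * H


def perturb_weights(W: np.ndarray, sigma_w: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Add one frozen i.i.d. N(0, sigma_w^2) draw to every entry.

    The perturbation is static: drawn once and fixed for the whole
    simulation (quenched disorder in the connectivity).
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be nonnegative")
    if sigma_w == 0:
        return W.copy()
    return W + sigma_w * rng.standard_normal(W.shape)


def sparsify(W: np.ndarray, keep_prob: float, rng: np.random.Generator,
             rescale: bool = False) -> np.ndarray:
    """Independently zero entries with probability 1 - keep_prob.

    With ``rescale``, surviving entries are divided by keep_prob so the
    expected row sum (total recurrent drive) is preserved.
    """
    if not (0.0 < keep_prob <= 1.0):
        raise ValueError("keep_prob must lie in (0, 1]")
    if keep_prob == 1.0:
        return W.copy()
    mask = rng.random(W.shape) < keep_prob
    out = W * mask
    if rescale:
        out = out / keep_prob
    return out


def save_weights(W: np.ndarray, path, meta: dict | None = None) -> None:
    """Persist a weight matrix as a dense array with a JSON sidecar.

    ``meta`` records provenance (builder name, parameters, seed); it is
    written next to the array file with the suffix ``.meta.json``.
    """
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(W, dtype=float))
    sidecar = {"shape": list(np.shape(W))}
    sidecar.update(meta or {})
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def load_weights(path) -> tuple[np.ndarray, dict]:
    """Load a weight matrix and its sidecar metadata."""
    path = Path(path)
    W = np.load(path.with_suffix(".npy"))
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return W, meta
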