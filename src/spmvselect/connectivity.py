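"""Random connectivity generators for building benchmark datasets.

Benchmark matrices emulate projections between two neural populations whose
sizes are drawn from a fixed set (by default the multiples of 1,000 between
1,000 and 20,000).  Connectivity is drawn in one of two modes:

* *random-probability*: every synapse (i, j) exists independently with
  probability ``p`` drawn from a configurable density range (default
  1–100%);
* *fixed-nonzeros-per-row*: every post-synaptic neuron receives exactly
  ``k`` synapses with distinct, uniformly sampled pre-synaptic partners
  (``k`` from a fixed set, default the powers of two 128–4,096).

Synaptic weights are U(0,1); SpMV timing is value-independent so any
nondegenerate distribution serves.  All draws go through a
``numpy.random.Generator`` so datasets are bitwise reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Tuple

import numpy as np

from .formats import ConnectivityMatrix

__all__ = [
    "GeneratorConfig",
    "generate_random_p",
    "generate_fixed_nnz",
    "sample_configuration",
]

DEFAULT_SIZES = tuple(range(1000, 20001, 1000))
DEFAULT_FIXED_NNZ = (128, 256, 512, 1024, 2048, 4096)


@dataclass(frozen=True)
class GeneratorConfig:
    """Distribution over network configurations used for dataset creation.

    Parameters
    ----------
    size_set
        Allowed population sizes; row and column counts are drawn from it.
    density_range
        Interval for the random-probability mode, ``0 < low <= high <= 1``.
    fixed_nnz_set
        Allowed per-row synapse counts for the fixed-nonzeros mode.
    mode_mix
        Probability of choosing the fixed-nonzeros mode for a sample.
    equal_dims
        If true, draw one size and use it for both dimensions; otherwise
        row and column counts are drawn independently.
    """

    size_set: Tuple[int, ...] = DEFAULT_SIZES
    density_range: Tuple[float, float] = (0.01, 1.0)
    fixed_nnz_set: Tuple[int, ...] = DEFAULT_FIXED_NNZ
    mode_mix: float = 0.5
    equal_dims: bool = False

    def __post_init__(self) -> None:
        if not self.size_set or min(self.size_set) < 1:
            raise ValueError("size_set must contain positive sizes")
        lo, hi = self.density_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("density_range must satisfy 0 < low <= high <= 1")
        if not self.fixed_nnz_set or min(self.fixed_nnz_set) < 1:
            raise ValueError("fixed_nnz_set must contain counts >= 1")
        if not 0 <= self.mode_mix <= 1:
            raise ValueError("mode_mix must be a probability")
        object.__setattr__(self, "size_set", tuple(sorted(self.size_set)))
        object.__setattr__(self, "fixed_nnz_set", tuple(sorted(self.fixed_nnz_set)))


def generate_random_p(
    n_rows: int, n_cols: int, p: float, rng: np.random.Generator
) -> ConnectivityMatrix:
    """Bernoulli connectivity: each cell present independently with prob ``p``.

    Drawn row-by-row as a Binomial(n_cols, p) count followed by a uniform
    choice of that many distinct columns — exactly equivalent to independent
    per-cell coin flips, without materializing an n_rows x n_cols grid.
    """
    if not 0 < p <= 1:
        raise ValueError(f"connection probability must be in (0, 1], got {p}")
    counts = rng.binomial(n_cols, p, size=n_rows)
    rows = np.repeat(np.arange(n_rows), counts)
    cols = np.concatenate(
        [rng.choice(n_cols, size=k, replace=False) for k in counts]
    ) if counts.sum() else np.empty(0, dtype=np.int64)
    values = rng.random(counts.sum())
    return ConnectivityMatrix(n_rows, n_cols, rows, cols, values)


def generate_fixed_nnz(
    n_rows: int, n_cols: int, k: int, rng: np.random.Generator
) -> ConnectivityMatrix:
    """Exactly ``k`` distinct, uniformly chosen columns in every row."""
    if k > n_cols:
        raise ValueError(f"per-row count k={k} exceeds n_cols={n_cols}")
    if k < 1:
        raise ValueError("per-row count k must be >= 1")
    rows = np.repeat(np.arange(n_rows), k)
    cols = np.concatenate(
        [rng.choice(n_cols, size=k, replace=False) for _ in range(n_rows)]
    )
    values = rng.random(n_rows * k)
    return ConnectivityMatrix(n_rows, n_cols, rows, cols, values)


def _draw_dims(cfg: GeneratorConfig, rng: np.random.Generator) -> Tuple[int, int]:
    sizes = np.asarray(cfg.size_set)
    if cfg.equal_dims:
        n = int(rng.choice(sizes))
        return n, n
    return int(rng.choice(sizes)), int(rng.choice(sizes))


def draw_configuration(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> Tuple[int, int, str, float]:
    """Draw ``(n_rows, n_cols, mode, parameter)`` for one sample.

    ``mode`` is ``"fixed_nnz"`` (parameter ``k``) or ``"random_p"``
    (parameter ``p``).  If no configured ``k`` fits within ``n_cols`` the
    sample falls back to the random-probability mode.
    """
    n_rows, n_cols = _draw_dims(cfg, rng)
    use_fixed = rng.random() < cfg.mode_mix
    if use_fixed:
        eligible = [k for k in cfg.fixed_nnz_set if k <= n_cols]
        if eligible:
            return n_rows, n_cols, "fixed_nnz", float(rng.choice(eligible))
    p = rng.uniform(*cfg.density_range)
    return n_rows, n_cols, "random_p", p


def sample_configuration(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> ConnectivityMatrix:
    """Draw one network configuration and generate its connectivity matrix."""
    n_rows, n_cols, mode, param = draw_configuration(cfg, rng)
    if mode == "fixed_nnz":
        return generate_fixed_nnz(n_rows, n_cols, int(param), rng)
    return generate_random_p(n_rows, n_cols, param, rng)
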