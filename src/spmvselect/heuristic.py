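"""Two-stage decision-tree heuristic for format selection.

Stage 1: if the density DES is *strictly greater* than the density
threshold (default 60%), the matrix is treated as dense.  Stage 2:
otherwise, if the average row length AVGNZR is *lower or equal to* the
row-length threshold (default 128, a multiple of the GPU warp size),
ELLPACK-R is selected, else CSR.  Both thresholds are configuration, not
constants: the row-length cutoff in particular is device-dependent and can
be re-tuned.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import FeatureVector

__all__ = ["HeuristicConfig", "heuristic_select"]


@dataclass(frozen=True)
class HeuristicConfig:
    density_threshold: float = 0.60
    avgnzr_threshold: float = 128.0

    def __post_init__(self) -> None:
        if not 0 < self.density_threshold < 1:
            raise ValueError("density_threshold must be in (0, 1)")
        if self.avgnzr_threshold <= 0:
            raise ValueError("avgnzr_threshold must be positive")


def heuristic_select(
    f: FeatureVector, cfg: HeuristicConfig = HeuristicConfig()
) -> str:
    """Map a feature vector to ``dense``, ``ellpack_r`` or ``csr``."""
    if f.des > cfg.density_threshold:
        return "dense"
    if f.avgnzr <= cfg.avgnzr_threshold:
        return "ellpack_r"
    return "csr"
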