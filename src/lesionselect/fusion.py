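"""Serial fusion of feature blocks.

Fusion is plain ordered concatenation: blocks of widths p and q yield a
fused matrix of width p + q (ℝ^p ⊕ ℝ^q → ℝ^{p+q}), with a per-column origin
map remembering which block and within-block index every fused column came
from.  No rescaling is applied — downstream selection and classification see
the raw activations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reference import STANDARD_COMBINATIONS
from .store import FeatureBlock

__all__ = ["FusedFeatures", "fuse", "standard_combinations", "reduction_percentage"]


@dataclass(frozen=True)
class FusedFeatures:
    """Ordered concatenation of feature blocks with provenance.

    ``column_origin[j]`` is ``(block_name, index_within_block)`` for fused
    column j; ``block_names`` keeps the concatenation order.
    """

    values: np.ndarray
    column_origin: tuple[tuple[str, int], ...]
    block_names: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("fused values must be 2-D")
        if len(self.column_origin) != arr.shape[1]:
            raise ValueError("column_origin length must equal fused width")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def d_fused(self) -> int:
        return int(self.values.shape[1])

    @property
    def combination_id(self) -> str:
        return "-".join(self.block_names)

    def columns_of(self, block_name: str) -> np.ndarray:
        """Fused column indices originating from ``block_name``, in order."""
        idx = np.array(
            [j for j, (name, _) in enumerate(self.column_origin) if name == block_name],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"no columns originate from block {block_name!r}")
        return idx

    def project(self, block_name: str) -> np.ndarray:
        """Reconstruct a source block's values from the fused matrix."""
        return self.values[:, self.columns_of(block_name)]


def fuse(blocks: Sequence[FeatureBlock]) -> FusedFeatures:
    """Concatenate blocks column-wise in the given order.

    Row order is untouched; fused width is the sum of block widths.
    """
    if not blocks:
        raise ValueError("fuse requires at least one block")
    n = blocks[0].n_samples
    for b in blocks:
        if b.n_samples != n:
            raise ValueError(
                f"block {b.name!r} has {b.n_samples} samples, expected {n}"
            )
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate block names in fusion: {names}")
    values = np.hstack([np.asarray(b.values) for b in blocks])
    origin = tuple(
        (b.name, j) for b in blocks for j in range(b.n_features)
    )
    return FusedFeatures(values=values, column_origin=origin, block_names=tuple(names))


def standard_combinations(blocks: Sequence[FeatureBlock]) -> list[FusedFeatures]:
    """The five benchmark fusion combinations of blocks FV1..FV4, in order.

    Returns fusions for FV2-FV3, FV3-FV4, FV2-FV4, FV2-FV3-FV4 and
    FV1-FV2-FV3-FV4.  All four named blocks must be present.
    """
    by_name = {b.name: b for b in blocks}
    missing = {n for combo in STANDARD_COMBINATIONS for n in combo} - set(by_name)
    if missing:
        raise ValueError(f"missing named blocks: {sorted(missing)}")
    return [fuse([by_name[n] for n in combo]) for combo in STANDARD_COMBINATIONS]


def reduction_percentage(d_in: int, d_out: int) -> int:
    """Integer percent of columns removed: round-half-away-from-zero of
    ``100·(1 − d_out/d_in)``.

    Requires ``1 ≤ d_out ≤ d_in``; result lies in [0, 99].
    """
    if d_out < 1 or d_in < 1:
        raise ValueError("dimensions must be ≥ 1")
    if d_out > d_in:
        raise ValueError(f"d_out={d_out} exceeds d_in={d_in}")
    pct = 100.0 * (1.0 - d_out / d_in)
    # pct ≥ 0, so floor(pct + 0.5) is round-half-away-from-zero; cap at 99
    # because at least one column is always kept.
    return min(int(math.floor(pct + 0.5)), 99)
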