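"""Seeded generator of multi-block synthetic feature datasets.

The generator emulates the *shape* of fused deep-feature data — several
named blocks of very different widths, a skewed benign/malignant class
balance — with a known ground-truth partition of columns into informative,
redundant and noise sets, so that selection and evaluation can be tested
for recovery without any image data.

Informative columns are class-conditional Gaussians with class means
separated by ``effect_size`` within-class standard deviations; redundant
columns are noisy random linear combinations of 1–3 informative columns;
noise columns are standard normal and class-independent.  Default widths
(2, 154, 102, 190) are the benchmark extractor widths (2, 1536, 1026, 1920)
scaled by ×0.1, and the default 0.8/0.2 class balance mirrors the 160/40
benign/melanoma composition of the PH2 collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fusion import fuse
from .harness import holdout_split
from .store import Dataset, FeatureBlock, LabelVector

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "oracle_separability"]

_BLOCK_NAMES = ("FV1", "FV2", "FV3", "FV4")
_SOURCE_TAGS = (
    "darknet53/fc-emulated",
    "inceptionv3/avg_pool-emulated",
    "inceptionresnetv2/avg_pool-emulated",
    "densenet201/avg_pool-emulated",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for one synthetic dataset."""

    n_samples: int = 200
    class_proportions: tuple[float, ...] = (0.8, 0.2)
    class_names: tuple[str, ...] = ("benign", "melanoma")
    block_widths: tuple[int, ...] = (2, 154, 102, 190)
    n_informative: tuple[int, ...] = (0, 8, 5, 7)
    n_redundant: tuple[int, ...] = (0, 8, 5, 7)
    effect_size: float = 2.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be ≥ 2")
        if len(self.class_proportions) != len(self.class_names):
            raise ValueError("class_proportions and class_names lengths differ")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if min(self.class_proportions) <= 0:
            raise ValueError("class proportions must be positive")
        if not (
            len(self.block_widths) == len(self.n_informative) == len(self.n_redundant)
        ):
            raise ValueError("per-block tuples must share one length")
        for w, ni, nr in zip(self.block_widths, self.n_informative, self.n_redundant):
            if w < 1:
                raise ValueError("block widths must be ≥ 1")
            if ni < 0 or nr < 0 or ni + nr > w:
                raise ValueError("informative + redundant must fit within block width")
        if self.effect_size < 0:
            raise ValueError("effect_size must be ≥ 0")
        if self.redundancy_noise_sd < 0:
            raise ValueError("redundancy_noise_sd must be ≥ 0")
        if sum(self.n_redundant) > 0 and sum(self.n_informative) == 0:
            raise ValueError("redundant columns need at least one informative parent")

    @property
    def d_fused(self) -> int:
        return sum(self.block_widths)

    @classmethod
    def recovery_default(cls, seed: int = 0) -> "SyntheticSpec":
        """The recovery-benchmark condition: 500 fused columns, 20 informative,
        no redundancy, effect size 2."""
        return cls(
            block_widths=(2, 171, 114, 213),
            n_informative=(0, 7, 6, 7),
            n_redundant=(0, 0, 0, 0),
            seed=seed,
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth column partition, in fused coordinates."""

    informative_columns: np.ndarray
    redundant_columns: np.ndarray
    noise_columns: np.ndarray
    redundant_parents: tuple[tuple[int, tuple[int, ...], tuple[float, ...]], ...]
    spec: SyntheticSpec

    def partition_ok(self) -> bool:
        all_cols = np.concatenate(
            [self.informative_columns, self.redundant_columns, self.noise_columns]
        )
        return (
            all_cols.size == self.spec.d_fused
            and np.array_equal(np.sort(all_cols), np.arange(self.spec.d_fused))
        )


def generate(spec: SyntheticSpec) -> tuple[Dataset, SyntheticTruth]:
    """Draw one dataset; fully determined by ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    C = len(spec.class_names)

    # class sizes by largest-remainder rounding, then a seeded row shuffle
    counts = [int(np.floor(p * n)) for p in spec.class_proportions]
    remainders = [p * n - c for p, c in zip(spec.class_proportions, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1
    y_idx = np.repeat(np.arange(C), counts)
    y_idx = y_idx[rng.permutation(n)]
    labels = LabelVector(
        labels=tuple(spec.class_names[i] for i in y_idx),
        classes=spec.class_names,
        positive_class=spec.class_names[-1] if C >= 2 else spec.class_names[0],
    )

    # class means spaced effect_size apart, centred at zero
    class_means = (np.arange(C) - (C - 1) / 2.0) * spec.effect_size

    widths = spec.block_widths
    offsets = np.concatenate([[0], np.cumsum(widths)])
    d = spec.d_fused

    # assign roles to fused columns, randomly placed within each block
    role = np.full(d, "noise", dtype=object)
    for b, (w, ni, nr) in enumerate(zip(widths, spec.n_informative, spec.n_redundant)):
        cols = offsets[b] + rng.permutation(w)
        role[cols[:ni]] = "informative"
        role[cols[ni : ni + nr]] = "redundant"
    informative = np.flatnonzero(role == "informative")
    redundant = np.flatnonzero(role == "redundant")
    noise = np.flatnonzero(role == "noise")

    X = rng.standard_normal((n, d))
    for j in informative:
        X[:, j] += class_means[y_idx]

    parents_record = []
    for j in redundant:
        k = int(rng.integers(1, min(3, informative.size) + 1))
        parents = rng.choice(informative, size=k, replace=False)
        weights = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
        combo = X[:, parents] @ weights
        combo = combo / np.sqrt(float(weights @ weights))  # ≈ unit within-class SD
        X[:, j] = combo + rng.normal(0.0, spec.redundancy_noise_sd, size=n)
        parents_record.append((int(j), tuple(int(p) for p in parents), tuple(map(float, weights))))

    blocks = tuple(
        FeatureBlock(
            name=_BLOCK_NAMES[b] if b < len(_BLOCK_NAMES) else f"FV{b + 1}",
            values=X[:, offsets[b] : offsets[b + 1]],
            source_tag=_SOURCE_TAGS[b] if b < len(_SOURCE_TAGS) else "synthetic",
        )
        for b in range(len(widths))
    )
    truth = SyntheticTruth(
        informative_columns=informative,
        redundant_columns=redundant,
        noise_columns=noise,
        redundant_parents=tuple(parents_record),
        spec=spec,
    )
    return Dataset(blocks=blocks, labels=labels), truth


def oracle_separability(
    dataset: Dataset, truth: SyntheticTruth, seed: int = 0
) -> float:
    """Hold-out accuracy of a prior-weighted nearest-centroid rule on the
    informative columns.

    Scores argmax_c −‖x − μ_c‖²/2 + log π_c — the Bayes rule for the
    generator's unit-variance Gaussian model.  An upper reference for what
    any selector + classifier can recover; near the majority-class
    proportion when effect size is 0 (the prior term dominates).
    """
    fused = fuse(dataset.blocks)
    X = np.asarray(fused.values)[:, truth.informative_columns]
    y = dataset.labels.as_array()
    train_idx, test_idx = holdout_split(dataset.labels, 0.7, seed)
    classes = np.unique(y[train_idx])
    centroids = np.stack([X[train_idx][y[train_idx] == c].mean(axis=0) for c in classes])
    log_priors = np.log(
        [np.mean(y[train_idx] == c) for c in classes]
    )
    scores = (
        -0.5 * ((X[test_idx, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        + log_priors[None, :]
    )
    pred = classes[np.argmax(scores, axis=1)]
    return float(np.mean(pred == y[test_idx]))
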