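"""Entropy-controlled gray wolf feature-subset selection (ECGWO).

Wolves live in the continuous unit cube [0,1]^d; a position decodes to a
binary inclusion mask by thresholding at 0.5 (with a repair rule that keeps
the mask non-empty).  The default fitness is a *filter* objective built on
Shannon entropy: the per-selected-feature mean absolute value ("energy") is
normalized into a probability vector η over the selected subset, and a
candidate scores

    fitness = H(η) / log2(max(k, 2)) − λ · k / d,

where H(η) = −Σ η_p log2 η_p, k is the selected count and d the fused
width.  The normalized entropy term rewards subsets whose selected features
carry evenly spread information; the λ·k/d term creates the pressure toward
small subsets that the raw entropy (which grows like log2 k) cannot supply.
λ = 0 recovers the bare entropy objective.

An optional *hybrid* wrapper mode blends inner-validation accuracy of a
contract classifier with the entropy objective:

    fitness = w · accuracy + (1 − w) · entropy_fitness,   w = 0.9 by default.

The entropy mode never sees labels; hybrid mode requires them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from . import gwo
from .fusion import FusedFeatures, reduction_percentage
from .store import Dataset, LabelVector, SelectionMask

__all__ = [
    "EntropyDistribution",
    "SelectorConfig",
    "SelectionResult",
    "binarize",
    "feature_energy",
    "entropy_distribution",
    "shannon_entropy",
    "entropy_fitness",
    "hybrid_fitness",
    "select",
]


@dataclass(frozen=True)
class EntropyDistribution:
    """Probability vector η over the selected feature columns."""

    eta: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=np.float64)
        support = np.asarray(self.support, dtype=np.intp)
        if support.size == 0:
            raise ValueError("support must be non-empty")
        if eta.shape != support.shape:
            raise ValueError("eta and support must have equal length")
        if (eta < 0).any() or abs(float(eta.sum()) - 1.0) > 1e-9:
            raise ValueError("eta must be non-negative and sum to 1")
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "support", support)


@dataclass(frozen=True)
class SelectorConfig:
    """Configuration of the ECGWO selector.

    ``sparsity_weight`` is λ above.  ``hybrid_accuracy_weight`` (w) and
    ``inner_validation_fraction`` apply only in hybrid mode; the hybrid
    classifier defaults to the 1-nearest-neighbour contract.
    """

    gwo: gwo.GWOConfig = field(default_factory=gwo.GWOConfig)
    binarize_threshold: float = 0.5
    fitness_mode: str = "entropy"
    sparsity_weight: float = 0.5
    hybrid_accuracy_weight: float = 0.9
    inner_validation_fraction: float = 0.2
    n_inner_splits: int = 3
    hybrid_classifier: str = "fine-knn"

    def __post_init__(self) -> None:
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.fitness_mode not in ("entropy", "hybrid"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be ≥ 0")
        if not 0.0 <= self.hybrid_accuracy_weight <= 1.0:
            raise ValueError("hybrid_accuracy_weight must lie in [0, 1]")
        if not 0.0 < self.inner_validation_fraction < 1.0:
            raise ValueError("inner_validation_fraction must lie in (0, 1)")
        if self.n_inner_splits < 1:
            raise ValueError("n_inner_splits must be ≥ 1")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selector run: the mask plus reduction accounting."""

    mask: SelectionMask
    fitness_trace: np.ndarray
    d_in: int
    d_out: int
    reduction_pct: int
    config: SelectorConfig
    seed: int

    def __post_init__(self) -> None:
        if self.d_out != self.mask.selected_count:
            raise ValueError("d_out must equal the mask's selected count")
        if self.reduction_pct != reduction_percentage(self.d_in, self.d_out):
            raise ValueError("reduction_pct inconsistent with (d_in, d_out)")

    def as_report(self) -> dict:
        """A serializable summary mirroring the published reduction tables."""
        return {
            "input_dim": self.d_in,
            "output_dim": self.d_out,
            "reduction_pct": self.reduction_pct,
            "seed": self.seed,
            "fitness_final": float(self.fitness_trace[-1]),
            "fitness_mode": self.config.fitness_mode,
            "sparsity_weight": self.config.sparsity_weight,
        }


def binarize(position: np.ndarray, threshold: float = 0.5) -> SelectionMask:
    """Threshold a [0,1]^d position into a non-empty inclusion mask.

    Bit j is 1 iff position_j ≥ threshold.  If no component clears the
    threshold, the single largest component is set (ties → lowest index).
    """
    position = np.asarray(position, dtype=np.float64)
    bits = (position >= threshold).astype(np.int8)
    if bits.sum() == 0:
        bits[int(np.argmax(position))] = 1  # argmax takes the lowest index on ties
    return SelectionMask(bits=bits)


def feature_energy(matrix: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Per-selected-column energy: mean over samples of |x_ij|."""
    support = np.asarray(support, dtype=np.intp)
    if support.size == 0:
        raise ValueError("support must be non-empty")
    return np.abs(np.asarray(matrix, dtype=np.float64)[:, support]).mean(axis=0)


def entropy_distribution(
    energies: np.ndarray, support: np.ndarray | None = None
) -> EntropyDistribution:
    """Normalize energies into η; all-zero energies fall back to uniform."""
    energies = np.asarray(energies, dtype=np.float64)
    if energies.size == 0:
        raise ValueError("need at least one energy value")
    total = float(energies.sum())
    if total <= 0.0:
        eta = np.full(energies.size, 1.0 / energies.size)
    else:
        eta = energies / total
    if support is None:
        support = np.arange(energies.size)
    return EntropyDistribution(eta=eta, support=np.asarray(support, dtype=np.intp))


def shannon_entropy(eta: EntropyDistribution | np.ndarray) -> float:
    """Shannon entropy H = −Σ η_p log2 η_p in bits, with 0·log2 0 := 0."""
    p = eta.eta if isinstance(eta, EntropyDistribution) else np.asarray(eta, dtype=float)
    return float(_scipy_entropy(p, base=2))


def _fitness_from_energies(
    energies: np.ndarray, k: int, d: int, sparsity_weight: float
) -> float:
    h = shannon_entropy(entropy_distribution(energies).eta)
    return h / np.log2(max(k, 2)) - sparsity_weight * (k / d)


def entropy_fitness(
    matrix: np.ndarray, mask: SelectionMask, sparsity_weight: float = 0.5
) -> float:
    """Normalized selected-subset entropy minus the λ·k/d sparsity penalty.

    The entropy term lies in [0, 1]; larger is better (maximized).
    """
    support = mask.support
    energies = feature_energy(matrix, support)
    return _fitness_from_energies(
        energies, mask.selected_count, mask.n_columns, sparsity_weight
    )


def _inner_splits(
    labels: np.ndarray, holdout_fraction: float, seed: int, n_splits: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified (fit, validate) index splits for the hybrid objective.

    Several distinct splits are derived from the run seed; averaging accuracy
    across them damps the wrapper's tendency to overfit any one small
    validation subset.
    """
    from .harness import holdout_split  # local import avoids a module cycle

    child_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    return [
        holdout_split(labels, train_fraction=1.0 - holdout_fraction, seed=int(s))
        for s in child_seeds
    ]


def hybrid_fitness(
    matrix: np.ndarray,
    labels: LabelVector | np.ndarray,
    mask: SelectionMask,
    config: SelectorConfig,
    classifier=None,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Wrapper objective: w·(inner-validation accuracy) + (1−w)·entropy_fitness.

    The accuracy term is the mean over ``n_inner_splits`` stratified splits
    derived from the run seed, so repeated evaluations of the same mask are
    identical.  ``classifier`` may be any fit/predict estimator; default is
    the configured contract classifier.
    """
    from .harness import make_classifier

    y = labels.as_array() if isinstance(labels, LabelVector) else np.asarray(labels)
    if splits is None:
        splits = _inner_splits(
            y, config.inner_validation_fraction, config.gwo.seed, config.n_inner_splits
        )
    if classifier is None:
        classifier = make_classifier(config.hybrid_classifier, seed=config.gwo.seed)
    sub = np.asarray(matrix, dtype=np.float64)[:, mask.support]
    accs = []
    for fit_idx, val_idx in splits:
        if len(np.unique(y[fit_idx])) < 2:
            raise ValueError(
                "hybrid fitness needs ≥ 2 classes in the inner training split"
            )
        classifier.fit(sub[fit_idx], y[fit_idx])
        accs.append(float(np.mean(classifier.predict(sub[val_idx]) == y[val_idx])))
    w = config.hybrid_accuracy_weight
    ent = entropy_fitness(matrix, mask, config.sparsity_weight)
    return w * float(np.mean(accs)) + (1.0 - w) * ent


def select(
    data: FusedFeatures | Dataset | np.ndarray,
    config: SelectorConfig | None = None,
    labels: LabelVector | np.ndarray | None = None,
) -> SelectionResult:
    """Run ECGWO over the fused columns and return the decoded best subset.

    ``data`` may be a :class:`FusedFeatures`, a :class:`Dataset` (its blocks
    are fused in order) or a plain matrix.  Hybrid mode requires labels.
    The optimizer maximizes the configured fitness over [0,1]^d; the final
    alpha position decodes to the returned mask.
    """
    from .fusion import fuse

    config = config or SelectorConfig()
    if isinstance(data, Dataset):
        fused = fuse(data.blocks)
        matrix = np.asarray(fused.values)
        if labels is None:
            labels = data.labels
    elif isinstance(data, FusedFeatures):
        matrix = np.asarray(data.values)
    else:
        matrix = np.asarray(data, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("selection needs a matrix with at least 2 columns")
    d = matrix.shape[1]
    threshold = config.binarize_threshold
    lam = config.sparsity_weight

    if config.fitness_mode == "entropy":
        col_energy = np.abs(matrix).mean(axis=0)  # mask-independent, precompute once

        def objective(pos: np.ndarray) -> float:
            mask = binarize(pos, threshold)
            sup = mask.support
            return _fitness_from_energies(col_energy[sup], sup.size, d, lam)

    else:  # hybrid
        if labels is None:
            raise ValueError("hybrid mode requires labels")
        y = labels.as_array() if isinstance(labels, LabelVector) else np.asarray(labels)
        if y.shape[0] != matrix.shape[0]:
            raise ValueError("label count does not match sample count")
        from .harness import make_classifier

        splits = _inner_splits(
            y, config.inner_validation_fraction, config.gwo.seed, config.n_inner_splits
        )
        classifier = make_classifier(config.hybrid_classifier, seed=config.gwo.seed)

        def objective(pos: np.ndarray) -> float:
            mask = binarize(pos, threshold)
            return hybrid_fitness(matrix, y, mask, config, classifier, splits)

    run_cfg = replace(config.gwo, bounds=(0.0, 1.0))
    result = gwo.optimize(run_cfg, d, objective, sense="maximize")
    mask = binarize(result.best_position, threshold)
    return SelectionResult(
        mask=mask,
        fitness_trace=result.trace,
        d_in=d,
        d_out=mask.selected_count,
        reduction_pct=reduction_percentage(d, mask.selected_count),
        config=config,
        seed=run_cfg.seed,
    )
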