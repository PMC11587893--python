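"""Permutation maximum-statistics inference for decoding accuracies.

The family-wise corrected threshold is obtained by randomly permuting the
category labels (one shuffle per permutation, reused across every window and
pair so the dependence structure of the family is preserved), recomputing the
full decoding grid, and recording the maximum accuracy over all windows and
pairs.  The (1 - alpha) empirical quantile of those maxima — ceiling-index
convention, no interpolation — is the corrected threshold; an observed
accuracy is significant iff it strictly exceeds it.  Permutations are run and
the threshold applied per subject, matching per-subject inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .decoding import (
    DecodingResult,
    WindowSpec,
    _config_echo,
    _resolve_channels,
    average_triplets,
    binary_svm_cv,
    category_pairs,
    make_windows,
    vectorize,
)
from .synthetic import EpochsSet, derive_seed

log = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "empirical_threshold",
    "permutation_null",
    "mark_significant",
    "percent_significant_per_window",
    "percent_subjects_significant",
    "pair_group",
    "PAIR_GROUPS",
]

_DOG = {"AD", "ND", "HD"}
_HUMAN = {"AH", "NH", "HH"}

PAIR_GROUPS = ("dog-human", "dog", "human", "other")


def pair_group(pair: tuple[str, str]) -> str:
    """Comparison group of a category pair: dog-human, within-dog,
    within-human, or other (object/scrambled comparisons)."""
    a, b = pair
    if {a, b} <= _DOG:
        return "dog"
    if {a, b} <= _HUMAN:
        return "human"
    if (a in _DOG and b in _HUMAN) or (a in _HUMAN and b in _DOG):
        return "dog-human"
    return "other"


@dataclass
class NullModel:
    """Permutation null of the maximum decoding accuracy and its threshold."""

    n_permutations: int
    max_statistics: np.ndarray
    alpha: float
    threshold: float
    config: dict

    def __post_init__(self) -> None:
        self.max_statistics = np.asarray(self.max_statistics, dtype=float)
        if len(self.max_statistics) != self.n_permutations:
            raise ValueError("max_statistics length must equal n_permutations")


def empirical_threshold(stats: np.ndarray, alpha: float) -> float:
    """(1 - alpha) empirical quantile, ceiling-index convention.

    For n sorted statistics the threshold is the ceil((1 - alpha) * n)-th
    order statistic (1-based): with n = 200 and alpha = 0.05, the 190th.
    """
    stats = np.sort(np.asarray(stats, dtype=float))
    n = len(stats)
    if n < 1:
        raise ValueError("need at least one statistic")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    k = math.ceil((1.0 - alpha) * n)
    return float(stats[k - 1])


def _grid_accuracies(
    epochs: EpochsSet,
    labels: np.ndarray,
    Xw: list[np.ndarray],
    pairs: list[tuple[str, str]],
    n_folds: int,
    seed: int,
) -> list[float]:
    """Accuracies over all pairs x pre-vectorized windows for given labels."""
    accs = []
    for pair in pairs:
        trials = np.flatnonzero(np.isin(labels.astype(str), pair))
        y = labels[trials].astype(str)
        for wi, X in enumerate(Xw):
            acc, _ = binary_svm_cv(
                X[trials],
                y,
                k_folds=n_folds,
                seed=derive_seed(seed, f"cv:{pair[0]}|{pair[1]}", wi),
            )
            accs.append(acc)
    return accs


def _static_accuracies(
    epochs: EpochsSet,
    labels: np.ndarray,
    sel: np.ndarray,
    sl: slice,
    pairs: list[tuple[str, str]],
    n_folds: int,
    triplet_size: int,
    seed: int,
) -> list[float]:
    accs = []
    for pi, pair in enumerate(pairs):
        feats, labs = [], []
        for cat in pair:
            trials = epochs.data[labels == cat][:, sel, sl]
            pseudo = average_triplets(
                trials,
                np.random.default_rng(derive_seed(seed, f"triplet:{cat}", pi)),
                triplet_size,
            )
            feats.append(pseudo.reshape(pseudo.shape[0], -1))
            labs.extend([cat] * pseudo.shape[0])
        acc, _ = binary_svm_cv(
            np.concatenate(feats, axis=0),
            np.array(labs),
            k_folds=n_folds,
            seed=derive_seed(seed, f"cv:{pair[0]}|{pair[1]}", 0),
        )
        accs.append(acc)
    return accs


def permutation_null(
    epochs: EpochsSet,
    spec: WindowSpec | None = None,
    k_channels: int | None = 50,
    n_folds: int = 5,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    modality: str = "meg",
    mode: str = "timewise",
    selection_window: tuple[float, float] = (0.0, 500.0),
    triplet_size: int = 3,
    channels: Sequence[int] | None = None,
) -> NullModel:
    """Label-permutation null of the maximum accuracy over windows and pairs.

    Channel selection depends only on the data (not the labels) and is
    therefore computed once and reused across permutations.  Each permutation
    shuffles the labels once and recomputes the full decoding grid with the
    same cross-validation scheme as the observed analysis.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("timewise", "static"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = _resolve_channels(epochs, modality, k_channels, selection_window, channels)
    cats = epochs.categories()
    pairs = category_pairs(cats)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    if mode == "timewise":
        spec = spec or WindowSpec.overlapping()
        windows = make_windows(spec)
        Xw = [vectorize(epochs, w, sel) for w in windows]
        echo = _config_echo(modality, k_channels, n_folds, "timewise", windows)
        for p in range(n_perm):
            perm_labels = rng.permutation(epochs.labels)
            accs = _grid_accuracies(
                epochs, perm_labels, Xw, pairs, n_folds, derive_seed(seed, "perm", p)
            )
            maxima[p] = max(accs)
    else:
        sl = epochs.window_slice(*selection_window)
        echo = _config_echo(modality, k_channels, n_folds, "static", [])
        for p in range(n_perm):
            perm_labels = rng.permutation(epochs.labels)
            accs = _static_accuracies(
                epochs,
                perm_labels,
                sel,
                sl,
                pairs,
                n_folds,
                triplet_size,
                derive_seed(seed, "perm", p),
            )
            maxima[p] = max(accs)
    return NullModel(
        n_permutations=n_perm,
        max_statistics=maxima,
        alpha=alpha,
        threshold=empirical_threshold(maxima, alpha),
        config=echo,
    )


def mark_significant(
    results: Sequence[DecodingResult], null: NullModel
) -> list[DecodingResult]:
    """Flag each result significant iff its accuracy strictly exceeds the
    corrected threshold.  The decoding configuration must match the null's."""
    out = []
    for r in results:
        for key in ("modality", "k_channels", "n_folds", "mode"):
            if r.config.get(key) != null.config.get(key):
                raise ValueError(
                    f"decoding configuration mismatch on {key!r}: result has "
                    f"{r.config.get(key)!r}, null has {null.config.get(key)!r}"
                )
        out.append(replace(r, significant=bool(r.accuracy > null.threshold)))
    return out


def percent_significant_per_window(
    results: Sequence[DecodingResult],
    pairs: Sequence[tuple[str, str]] | None = None,
    group: str | None = None,
) -> dict[tuple[float, float], float]:
    """100 x (significant pairs / pairs considered), per time window.

    ``pairs`` restricts to an explicit pair subset; ``group`` restricts to a
    comparison group ('dog-human', 'dog', 'human', 'other').
    """
    def keep(r: DecodingResult) -> bool:
        if r.window == "static" or r.significant is None:
            return False
        if pairs is not None and tuple(r.pair) not in {tuple(p) for p in pairs}:
            return False
        if group is not None and pair_group(r.pair) != group:
            return False
        return True

    kept = [r for r in results if keep(r)]
    if not kept:
        raise ValueError("no timewise results match the requested pair subset")
    out: dict[tuple[float, float], list[bool]] = {}
    for r in kept:
        out.setdefault(tuple(r.window), []).append(bool(r.significant))
    return {w: 100.0 * np.mean(flags) for w, flags in sorted(out.items())}


def percent_subjects_significant(
    results: Sequence[DecodingResult], pair: tuple[str, str]
) -> float:
    """100 x (subjects significant for the pair) / (subjects with the pair)."""
    subjects: dict[str, bool] = {}
    for r in results:
        if tuple(r.pair) == tuple(pair) and r.significant is not None:
            subjects[r.subject_id] = subjects.get(r.subject_id, False) or bool(r.significant)
    if not subjects:
        raise ValueError(f"no annotated results for pair {pair}")
    return 100.0 * sum(subjects.values()) / len(subjects)
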