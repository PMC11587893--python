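"""Relating per-subject decoding accuracies to trait empathy and behaviour.

Whole-window accuracies are graded (excellent >= 90%, good >= 70%, fair
60-70%), and per-subject accuracy is correlated with trait scores (IRI
subscales EC/PT and their animal-directed variants) or rating response times
using Spearman's rho with a bias-corrected and accelerated (BCa) bootstrap
confidence interval over case (subject) resampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import spearmanr

from .synthetic import derive_seed

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "grade_accuracy",
    "bca_interval",
    "spearman_bca",
    "trait_accuracy_table",
    "responsetime_accuracy_table",
    "associations_to_frame",
    "DOG_CATEGORIES",
]

DOG_CATEGORIES = {"AD", "ND", "HD"}

GRADES = ("excellent", "good", "fair", "below")


def grade_accuracy(acc: float) -> str:
    """Grade a whole-window accuracy fraction.

    >= 0.90 excellent, [0.70, 0.90) good, [0.60, 0.70) fair, else below.
    """
    if not (0.0 <= acc <= 1.0) or not np.isfinite(acc):
        raise ValueError(f"accuracy {acc} outside [0, 1]")
    if acc >= 0.90:
        return "excellent"
    if acc >= 0.70:
        return "good"
    if acc >= 0.60:
        return "fair"
    return "below"


@dataclass
class AssociationResult:
    """Spearman correlation of one (pair, predictor) with its BCa interval."""

    pair: str
    trait: str
    rho: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_subjects: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def bca_interval(
    theta_hat: float,
    boot: np.ndarray,
    jackknife: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from given bootstrap replicates.

    The bias correction ``z0`` comes from the position of ``theta_hat`` in the
    bootstrap distribution (ties counted half); the acceleration ``a`` from
    the skewness of the jackknife replicates.  If the bootstrap distribution
    is entirely to one side of the estimate or the jackknife variance is zero,
    the plain percentile interval is returned with a warning.  Quantiles of
    the bootstrap distribution use linear interpolation.
    """
    boot = np.asarray(boot, dtype=float)
    boot = boot[np.isfinite(boot)]
    if len(boot) < 2:
        raise ValueError("need at least two finite bootstrap replicates")

    def percentile() -> tuple[float, float]:
        lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(lo), float(hi)

    p = ((boot < theta_hat).sum() + 0.5 * (boot == theta_hat).sum()) / len(boot)
    if p <= 0.0 or p >= 1.0:
        warnings.warn(
            "degenerate bootstrap distribution; falling back to percentile interval"
        )
        return percentile()
    z0 = ndtri(p)
    jackknife = np.asarray(jackknife, dtype=float)
    d = jackknife.mean() - jackknife
    denom = (d**2).sum() ** 1.5
    if denom == 0.0:
        warnings.warn(
            "zero jackknife variance; acceleration undefined, falling back to "
            "percentile interval"
        )
        return percentile()
    a = (d**3).sum() / (6.0 * denom)
    out = []
    for z in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.quantile(boot, float(ndtr(adj)))))
    lo, hi = out
    return (lo, hi) if lo <= hi else (hi, lo)


def spearman_bca(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Spearman's rho with a BCa bootstrap interval over case resampling.

    Ranks use the average-rank convention for ties (scipy).  Returns
    ``(rho, ci_low, ci_high)``; deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned by subject")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; Spearman's rho is undefined")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; Spearman's rho is undefined")
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot[b] = spearmanr(x[idx], y[idx]).statistic
    n_bad = int(np.sum(~np.isfinite(boot)))
    if n_bad:
        log.warning("spearman_bca: dropped %d constant resamples", n_bad)
    jack = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        jack[i] = spearmanr(x[keep], y[keep]).statistic
    lo, hi = bca_interval(rho, boot, jack, alpha)
    return rho, lo, hi


def _pair_key(pair) -> str:
    if isinstance(pair, str):
        return pair
    return "-".join(pair)


def _association_table(
    accuracies: pd.DataFrame,
    predictors: pd.DataFrame,
    pair_list: Sequence,
    predictor_lists: Mapping[str, Sequence[str]],
    n_boot: int,
    alpha: float,
    seed: int,
) -> list[AssociationResult]:
    """Shared engine: one AssociationResult per (pair, predictor column)."""
    required = {"subject_id", "pair", "accuracy"}
    if not required <= set(accuracies.columns):
        raise ValueError(f"accuracy table must have columns {sorted(required)}")
    predictors = predictors.set_index("subject_id")
    results: list[AssociationResult] = []
    for pair in pair_list:
        key = _pair_key(pair)
        sub = accuracies[accuracies["pair"] == key]
        missing = sorted(set(sub["subject_id"]) - set(predictors.index))
        if missing:
            raise ValueError(f"subjects missing from predictor table: {missing}")
        sub = sub.set_index("subject_id")
        for var in predictor_lists[key]:
            if var not in predictors.columns:
                raise ValueError(f"predictor column {var!r} not found")
            acc = sub["accuracy"].astype(float)
            pred = predictors.loc[acc.index, var].astype(float)
            rho, lo, hi = spearman_bca(
                pred.to_numpy(),
                acc.to_numpy(),
                n_boot=n_boot,
                alpha=alpha,
                seed=derive_seed(seed, f"assoc:{key}:{var}"),
            )
            results.append(
                AssociationResult(
                    pair=key,
                    trait=var,
                    rho=rho,
                    ci_low=lo,
                    ci_high=hi,
                    n_boot=n_boot,
                    n_subjects=len(acc),
                )
            )
    return results


def trait_accuracy_table(
    accuracies: pd.DataFrame,
    traits: pd.DataFrame,
    pair_list: Sequence = ("AD-HD", "AD-ND", "AH-HH", "AH-NH", "HH-NH"),
    trait_list: Sequence[str] = ("EC", "PT"),
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    ani_traits: Sequence[str] = ("ani_EC", "ani_PT"),
) -> list[AssociationResult]:
    """Trait x accuracy associations for the configured category pairs.

    For pairs involving dog-face categories the animal-directed subscales are
    computed in addition to the human-directed ones.
    """
    lists: dict[str, list[str]] = {}
    for pair in pair_list:
        key = _pair_key(pair)
        cats = set(key.split("-"))
        vars_ = list(trait_list)
        if cats & DOG_CATEGORIES:
            vars_ += list(ani_traits)
        lists[key] = vars_
    return _association_table(accuracies, traits, pair_list, lists, n_boot, alpha, seed)


def responsetime_accuracy_table(
    accuracies: pd.DataFrame,
    response_times: pd.DataFrame,
    pair_list: Sequence,
    rt_list: Sequence[str],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[AssociationResult]:
    """Response-time x accuracy associations (same mechanics as traits)."""
    lists = {_pair_key(p): list(rt_list) for p in pair_list}
    return _association_table(
        accuracies, response_times, pair_list, lists, n_boot, alpha, seed
    )


def associations_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": r.pair,
                "trait": r.trait,
                "rho": r.rho,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_boot": r.n_boot,
                "n_subjects": r.n_subjects,
            }
            for r in results
        ],
        columns=["pair", "trait", "rho", "ci_low", "ci_high", "n_boot", "n_subjects"],
    )
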