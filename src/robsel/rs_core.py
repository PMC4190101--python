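"""Robust selection (RS): subsample, fit, average, threshold.

Given a train set I, the RS loop draws ``t_in`` random sub-train/tuning
splits of I (63.2% : 36.8%, mirroring the effective sample fraction of a
bootstrap resample), fits the base learner — preconditioned lasso or
lasso-penalized Cox — on each sub-train set, averages the resulting
coefficient vectors, and then *shrinks* the average: a grid of thresholds
spanning the nonzero magnitudes is scanned, coefficients below the threshold
are zeroed, and the threshold whose truncated model predicts best (mean
concordance) across the tuning sets is kept.  Averaging reduces the variance
of any single unstable fit; thresholding removes the long tail of small
coefficients that the union of supports accumulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cox_core import (
    CoefficientVector,
    PenaltySpec,
    cv_select_lambda,
    default_lambda_grid,
    fit_penalized_cox,
)
from .data_io import Dataset, SurvivalOutcome
from .metrics import concordance_index
from .precond import PLConfig, pl_fit

logger = logging.getLogger(__name__)

__all__ = [
    "RSConfig",
    "AggregatedModel",
    "ShrunkenModel",
    "prefilter_by_sd",
    "inner_splits",
    "aggregate",
    "shrink",
    "rs_fit",
]


@dataclass
class RSConfig:
    """Configuration of the robust-selection inner loop.

    ``prefilter_percentile`` drops features whose training-set standard
    deviation lies below the given percentile; 0 disables the filter (the
    synthetic cohorts draw all features with equal variance, so variance
    filtering carries no signal there — on real microarray data 90 or 99 are
    typical).  ``base_learner`` is "PL" (preconditioned lasso) or "L"
    (lasso-penalized Cox).
    """

    t_in: int = 100
    subtrain_fraction: float = 0.632
    prefilter_percentile: float = 0.0
    threshold_grid_size: int = 50
    base_learner: str = "PL"
    pl: PLConfig = field(default_factory=PLConfig)
    lambda_grid_size: int = 30
    cv_folds: int = 5
    seed: int = 0
    max_fit_failures: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.subtrain_fraction < 1.0:
            raise ValueError("subtrain_fraction must be in (0, 1)")
        if self.t_in < 1:
            raise ValueError("t_in must be >= 1")
        if self.threshold_grid_size < 2:
            raise ValueError("threshold_grid_size must be >= 2")
        if self.base_learner not in ("PL", "L"):
            raise ValueError("base_learner must be 'PL' or 'L'")
        if not 0.0 <= self.prefilter_percentile < 100.0:
            raise ValueError("prefilter_percentile must be in [0, 100)")


@dataclass
class AggregatedModel:
    """Mean of the inner-subsample coefficient vectors plus their supports."""

    beta_bar: np.ndarray
    component_supports: list[np.ndarray]


@dataclass
class ShrunkenModel:
    """Thresholded aggregate: the robust model for one train set."""

    beta_tilde: np.ndarray
    theta_star: float
    tuning_curve: list[tuple[float, float]]
    feature_ids: list[str] | None = None

    def coefficients(self) -> CoefficientVector:
        return CoefficientVector(self.beta_tilde, self.feature_ids)


def prefilter_by_sd(X_train: np.ndarray, percentile_q: float) -> np.ndarray:
    """Indices of features whose training-set SD reaches the q-th percentile.

    Exactly ``floor(p * q / 100)`` features are dropped (the lowest-SD ones),
    so with distinct SDs ``p - floor(p*q/100)`` remain; ties at the cutoff
    keep the lower feature index.  SDs must be computed on training samples
    only, which is why this takes the already-restricted training matrix.
    """
    if not 0.0 <= percentile_q < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]
    sds = X_train.std(axis=0)
    if np.all(sds == 0.0):
        raise ValueError("all features are constant on the training set")
    n_drop = int(np.floor(p * percentile_q / 100.0))
    if n_drop == 0:
        return np.arange(p)
    # keep the p - n_drop features with largest SD; equal SDs prefer lower index
    order = np.lexsort((np.arange(p), -sds))
    return np.sort(order[: p - n_drop])


def inner_splits(
    train_index_I: np.ndarray,
    t_in: int,
    fraction: float,
    seed: int,
    events: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``t_in`` independent random (sub-train J, tuning) partitions of I.

    |J| = round(fraction * |I|); J and the tuning set are disjoint and
    exhaust I.  When ``events`` (aligned with the full cohort indexing) is
    given, splits whose J carries zero events are redrawn, up to 100 times.
    """
    I = np.asarray(train_index_I)
    if len(I) < 10:
        raise ValueError("train set too small to subsample")
    rng = np.random.default_rng(seed)
    n_sub = int(round(fraction * len(I)))
    n_sub = min(max(n_sub, 1), len(I) - 1)
    splits = []
    for _ in range(t_in):
        for attempt in range(100):
            perm = rng.permutation(len(I))
            J, tune = I[perm[:n_sub]], I[perm[n_sub:]]
            if events is None or events[J].sum() > 0:
                break
        else:
            raise RuntimeError("could not draw a sub-train set containing an event")
        splits.append((np.sort(J), np.sort(tune)))
    return splits


def aggregate(coefficient_vectors) -> AggregatedModel:
    """Arithmetic mean of equal-dimension coefficient vectors.

    The support of the mean is the union of component supports, except where
    contributions cancel exactly (possible with opposite signs; kept as-is).
    """
    betas = [
        v.beta if isinstance(v, CoefficientVector) else np.asarray(v, dtype=float)
        for v in coefficient_vectors
    ]
    dims = {b.shape for b in betas}
    if len(dims) != 1:
        raise ValueError(f"coefficient vectors of unequal dimension: {dims}")
    stacked = np.vstack(betas)
    return AggregatedModel(
        beta_bar=stacked.mean(axis=0),
        component_supports=[np.flatnonzero(b != 0.0) for b in betas],
    )


def shrink(
    beta_bar: np.ndarray,
    X: np.ndarray,
    outcome: SurvivalOutcome,
    tuning_sets: list[np.ndarray],
    K: int = 50,
) -> ShrunkenModel:
    """Threshold the aggregated vector at the best-predicting cut.

    The grid is K evenly spaced thresholds from the smallest to the largest
    nonzero |beta_bar| component.  For each threshold the truncated linear
    predictor is scored by its mean concordance over the tuning sets; the
    argmax wins, with ties resolved toward the larger threshold (the sparser
    model).  Surviving coefficients keep their averaged values — no refit.
    """
    beta_bar = np.asarray(beta_bar, dtype=float)
    mags = np.abs(beta_bar[beta_bar != 0.0])
    if mags.size == 0:
        logger.warning("all-zero aggregated model: nothing to shrink")
        return ShrunkenModel(beta_bar.copy(), 0.0, [])
    grid = np.linspace(mags.min(), mags.max(), K)
    X = np.asarray(X, dtype=float)
    curve = []
    for theta in grid:
        beta_t = np.where(np.abs(beta_bar) >= theta, beta_bar, 0.0)
        eta = X @ beta_t
        scores = []
        for tune in tuning_sets:
            try:
                scores.append(concordance_index(eta[tune], outcome.subset(tune)))
            except ValueError:
                continue
        curve.append((float(theta), float(np.mean(scores)) if scores else np.nan))
    finite = [(th, sc) for th, sc in curve if np.isfinite(sc)]
    if not finite:
        raise ValueError("no tuning set produced a comparable pair")
    best_score = max(sc for _, sc in finite)
    theta_star = max(th for th, sc in finite if sc == best_score)
    beta_tilde = np.where(np.abs(beta_bar) >= theta_star, beta_bar, 0.0)
    return ShrunkenModel(beta_tilde, float(theta_star), curve)


def _fit_base_learner(
    X: np.ndarray, outcome: SurvivalOutcome, config: RSConfig, seed: int
) -> CoefficientVector:
    if config.base_learner == "PL":
        pl_cfg = PLConfig(
            m_grid=config.pl.m_grid,
            n_thresholds=config.pl.n_thresholds,
            quantile_range=config.pl.quantile_range,
            k_folds=config.pl.k_folds,
            seed=seed,
        )
        return pl_fit(X, outcome, pl_cfg)
    grid = default_lambda_grid(X, outcome, size=config.lambda_grid_size)
    spec = cv_select_lambda(
        X, outcome, 1.0, k_folds=config.cv_folds, lambda_grid=grid, seed=seed
    )
    return fit_penalized_cox(X, outcome, spec)


def rs_fit(dataset_I: Dataset, config: RSConfig) -> ShrunkenModel:
    """Run the full RS inner loop on a train set.

    Prefilters features by SD, draws the inner splits, fits the base learner
    (with its own hyperparameter tuning) on every sub-train set, averages and
    shrinks.  The returned coefficients span the complete feature universe of
    the input dataset, with zeros at prefiltered-out positions.  More than
    ``max_fit_failures`` of failing inner fits aborts with diagnostics.
    """
    X_full = dataset_I.expression.design()
    outcome = dataset_I.outcome
    keep = prefilter_by_sd(X_full, config.prefilter_percentile)
    X = X_full[:, keep]
    idx_I = np.arange(dataset_I.n)
    splits = inner_splits(
        idx_I, config.t_in, config.subtrain_fraction, config.seed, outcome.events
    )
    betas, failures = [], []
    for t, (J, _) in enumerate(splits):
        try:
            fit = _fit_base_learner(X[J], outcome.subset(J), config, seed=config.seed + 1000 + t)
            betas.append(fit.beta)
        except Exception as exc:  # noqa: BLE001 - individual fit failures tolerated
            failures.append((t, repr(exc)))
    if len(failures) > config.max_fit_failures * config.t_in:
        raise RuntimeError(f"{len(failures)}/{config.t_in} inner fits failed: {failures[:5]}")
    if failures:
        logger.warning("rs_fit: %d/%d inner fits failed", len(failures), config.t_in)
    agg = aggregate(betas)
    tuning_sets = [tune for _, tune in splits]
    if np.any(agg.beta_bar != 0.0):
        shrunk = shrink(agg.beta_bar, X, outcome, tuning_sets, K=config.threshold_grid_size)
    else:
        shrunk = ShrunkenModel(agg.beta_bar.copy(), 0.0, [])
    beta_full = np.zeros(dataset_I.p)
    beta_full[keep] = shrunk.beta_tilde
    return ShrunkenModel(
        beta_full, shrunk.theta_star, shrunk.tuning_curve,
        feature_ids=list(dataset_I.expression.feature_ids),
    )
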