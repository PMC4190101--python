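"""Outer subsampling harness: method comparison, selection probabilities, signatures.

The cohort is split ``t_out`` times into a train set I (63.2%) and a test set
(36.8%).  Every requested method is fitted on each I — the identical split
list is reused across methods so comparisons are paired — and scored by the
concordance of its linear predictor on the held-out test set.  The fraction
of trials in which a feature enters a method's fitted support estimates its
selection probability; features at or above a baseline probability ``pi``
form the robust signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox_core import (
    CoefficientVector,
    PenaltySpec,
    cv_select_lambda,
    default_lambda_grid,
    fit_penalized_cox,
    linear_predictor,
)
from .data_io import Dataset
from .metrics import (
    SignatureSet,
    concordance_index,
    jaccard_stability,
    signature_from_coefficients,
    univariate_concordance,
)
from .precond import PLConfig, pl_fit
from .rs_core import RSConfig, inner_splits, prefilter_by_sd, rs_fit

logger = logging.getLogger(__name__)

__all__ = [
    "OuterConfig",
    "SelectionProfile",
    "TrialResult",
    "outer_splits",
    "run_evaluation",
    "robust_signature",
    "extra_shrinkage",
    "fit_dev",
    "fit_cor",
    "fit_cli",
    "KNOWN_METHODS",
]

KNOWN_METHODS = ("RS-PL", "RS-L", "PL", "L", "Dev", "Cor", "Cli")

#: default ridge penalty grid for the Dev/Cor baselines (glmnet-scale lambdas
#: on standardized features)
_RIDGE_GRID = np.geomspace(10.0, 1e-3, 10)


@dataclass
class OuterConfig:
    """Outer-loop settings: trial count, split fraction, methods, thresholds."""

    t_out: int = 100
    train_fraction: float = 0.632
    methods: tuple[str, ...] = ("RS-PL",)
    pi_threshold: float = 0.5
    extra_shrinkage_sizes: tuple[int, ...] = ()
    n_top: int = 100           # Dev/Cor univariate list size
    seed: int = 0
    max_trial_failures: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.pi_threshold <= 1.0:
            raise ValueError("pi_threshold must be in [0, 1]")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {KNOWN_METHODS}")


@dataclass
class SelectionProfile:
    """Per-feature selection probabilities over the outer trials."""

    feature_ids: list[str]
    probabilities: np.ndarray
    mean_coefficients: np.ndarray
    t_out: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "selection_probability": self.probabilities,
                "mean_coefficient": self.mean_coefficients,
            }
        )


@dataclass
class TrialResult:
    trial: int
    method: str
    beta: CoefficientVector | None
    test_concordance: float
    signature: SignatureSet
    support_size: int


def outer_splits(
    n: int,
    t_out: int,
    fraction: float,
    seed: int,
    events: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``t_out`` random (train I, test) partitions of ``range(n)``.

    Delegates to the same splitter as the inner loop so event-free train or
    test sides are redrawn; the resulting list is shared verbatim by all
    methods of a run.
    """
    if n < 20:
        raise ValueError("cohort too small for outer subsampling")
    splits = inner_splits(np.arange(n), t_out, fraction, seed, events)
    if events is not None:
        for t, (I, test) in enumerate(splits):
            if events[test].sum() == 0:
                raise RuntimeError(f"outer split {t}: test set has no events")
    return splits


# ---------------------------------------------------------------------------
# baseline methods


def fit_dev(train: Dataset, n_top: int = 100, seed: int = 0) -> CoefficientVector:
    """Deviation baseline: ridge Cox on the ``n_top`` highest-SD features.

    Selection is fully unsupervised (outcome-agnostic); known to be a very
    stable, if weak, selector.
    """
    X = train.expression.design()
    if X.shape[1] < n_top:
        raise ValueError("fewer features than n_top")
    sds = X.std(axis=0)
    top = np.sort(np.lexsort((np.arange(X.shape[1]), -sds))[:n_top])
    beta_top = _ridge_cv(X[:, top], train, seed)
    beta = np.zeros(train.p)
    beta[top] = beta_top
    return CoefficientVector(beta, list(train.expression.feature_ids))


def fit_cor(train: Dataset, n_top: int = 100, seed: int = 0) -> CoefficientVector:
    """Correlation baseline: ridge Cox on the ``n_top`` features whose
    univariate concordance with survival deviates most from 0.5.

    Ranking by |c - 0.5| keeps strongly protective (anti-concordant) features
    in the list; a constant feature sits at chance level and ranks last.
    """
    X = train.expression.design()
    if X.shape[1] < n_top:
        raise ValueError("fewer features than n_top")
    c = univariate_concordance(X, train.outcome)
    strength = np.abs(c - 0.5)
    top = np.sort(np.lexsort((np.arange(X.shape[1]), -strength))[:n_top])
    beta_top = _ridge_cv(X[:, top], train, seed)
    beta = np.zeros(train.p)
    beta[top] = beta_top
    return CoefficientVector(beta, list(train.expression.feature_ids))


def _ridge_cv(X: np.ndarray, train: Dataset, seed: int) -> np.ndarray:
    spec = cv_select_lambda(
        X, train.outcome, penalty_alpha=0.0, lambda_grid=_RIDGE_GRID, seed=seed
    )
    return fit_penalized_cox(X, train.outcome, PenaltySpec(spec.lam, 0.0)).beta


class _ClinicalModel:
    """Unpenalized Cox model on clinical covariates (one-hot categoricals)."""

    def __init__(self, train: Dataset):
        if train.clinical is None or train.clinical.covariates is None:
            raise ValueError("method Cli requires clinical covariates")
        from lifelines import CoxPHFitter

        design = _one_hot(train.clinical.covariates)
        self.columns = list(design.columns)
        df = design.copy()
        df["_time"] = train.outcome.times
        df["_event"] = train.outcome.events
        fitter = CoxPHFitter()
        try:
            fitter.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:
            raise RuntimeError(f"clinical Cox fit failed: {exc}") from exc
        self.params = fitter.params_

    def predict(self, data: Dataset) -> np.ndarray:
        design = _one_hot(data.clinical.covariates).reindex(
            columns=self.columns, fill_value=0.0
        )
        return design.to_numpy(dtype=float) @ self.params.to_numpy()

    def coefficients(self) -> CoefficientVector:
        return CoefficientVector(self.params.to_numpy(), list(self.columns))


def _one_hot(covariates: pd.DataFrame) -> pd.DataFrame:
    return pd.get_dummies(covariates, drop_first=True, dtype=float)


def fit_cli(train: Dataset) -> CoefficientVector:
    """Coefficient vector of the unpenalized clinical-covariate Cox model."""
    return _ClinicalModel(train).coefficients()


# ---------------------------------------------------------------------------
# the harness


def _fit_method(method: str, train: Dataset, outer: OuterConfig, rs: RSConfig, seed: int):
    """Fit one method; returns (beta_expression | None, predict_fn, signature_beta)."""
    if method in ("RS-PL", "RS-L"):
        cfg = RSConfig(
            t_in=rs.t_in,
            subtrain_fraction=rs.subtrain_fraction,
            prefilter_percentile=rs.prefilter_percentile,
            threshold_grid_size=rs.threshold_grid_size,
            base_learner="PL" if method == "RS-PL" else "L",
            pl=rs.pl,
            lambda_grid_size=rs.lambda_grid_size,
            cv_folds=rs.cv_folds,
            seed=seed,
        )
        model = rs_fit(train, cfg)
        beta = model.coefficients()
    elif method in ("PL", "L"):
        X_full = train.expression.design()
        keep = prefilter_by_sd(X_full, rs.prefilter_percentile)
        X = X_full[:, keep]
        if method == "PL":
            cfg = PLConfig(
                m_grid=rs.pl.m_grid,
                n_thresholds=rs.pl.n_thresholds,
                quantile_range=rs.pl.quantile_range,
                k_folds=rs.pl.k_folds,
                seed=seed,
            )
            sub = pl_fit(X, train.outcome, cfg)
        else:
            grid = default_lambda_grid(X, train.outcome, size=rs.lambda_grid_size)
            grid_spec = cv_select_lambda(
                X, train.outcome, 1.0, k_folds=rs.cv_folds, seed=seed, lambda_grid=grid
            )
            sub = fit_penalized_cox(X, train.outcome, grid_spec)
        full = np.zeros(train.p)
        full[keep] = sub.beta
        beta = CoefficientVector(full, list(train.expression.feature_ids))
    elif method == "Dev":
        beta = fit_dev(train, outer.n_top, seed)
    elif method == "Cor":
        beta = fit_cor(train, outer.n_top, seed)
    elif method == "Cli":
        model = _ClinicalModel(train)
        return None, model.predict, model.coefficients()
    else:  # pragma: no cover
        raise ValueError(method)

    def predict(data: Dataset) -> np.ndarray:
        return linear_predictor(beta, data.expression.design())

    return beta, predict, beta


def run_evaluation(
    dataset: Dataset,
    outer_config: OuterConfig,
    rs_config: RSConfig | None = None,
) -> tuple[list[TrialResult], dict[str, SelectionProfile]]:
    """Fit and test every configured method over shared outer splits.

    Returns per-trial results (fitted vector, held-out concordance, signature)
    and, for each expression-based method, the per-feature selection profile.
    The per-trial signature counted into the profile is the support of the
    method's final coefficient vector — after RS shrinkage where applicable,
    before any extra top-G truncation.  Test samples never enter fitting or
    tuning of the same trial.  More than ``max_trial_failures`` failing trials
    for a method aborts the run.
    """
    rs_config = rs_config or RSConfig()
    splits = outer_splits(
        dataset.n, outer_config.t_out, outer_config.train_fraction,
        outer_config.seed, dataset.outcome.events,
    )
    feature_ids = list(dataset.expression.feature_ids)
    trials: list[TrialResult] = []
    counts = {m: np.zeros(dataset.p) for m in outer_config.methods if m != "Cli"}
    coef_sums = {m: np.zeros(dataset.p) for m in outer_config.methods if m != "Cli"}
    failures: dict[str, list[tuple[int, str]]] = {m: [] for m in outer_config.methods}

    for t, (I, test) in enumerate(splits):
        train_ds = dataset.subset(I)
        test_ds = dataset.subset(test)
        assert not set(I) & set(test)
        for method in outer_config.methods:
            trial_seed = outer_config.seed + 7919 * (t + 1)
            try:
                beta, predict, sig_beta = _fit_method(
                    method, train_ds, outer_config, rs_config, trial_seed
                )
                c = concordance_index(predict(test_ds), test_ds.outcome)
            except Exception as exc:  # noqa: BLE001 - per-trial failures recorded
                failures[method].append((t, repr(exc)))
                logger.warning("trial %d method %s failed: %r", t, method, exc)
                continue
            signature = signature_from_coefficients(
                sig_beta.beta, sig_beta.feature_ids
            )
            if method != "Cli":
                sel = beta.support()
                counts[method][sel] += 1
                coef_sums[method][sel] += beta.beta[sel]
            trials.append(
                TrialResult(t, method, beta, float(c), signature, signature.size)
            )
    for method, fails in failures.items():
        if len(fails) > outer_config.max_trial_failures * outer_config.t_out:
            raise RuntimeError(f"method {method}: {len(fails)} trials failed: {fails[:3]}")

    profiles = {}
    for method in counts:
        with np.errstate(invalid="ignore"):
            mean_coef = np.where(counts[method] > 0, coef_sums[method] / np.maximum(counts[method], 1), 0.0)
        profiles[method] = SelectionProfile(
            feature_ids,
            counts[method] / outer_config.t_out,
            mean_coef,
            outer_config.t_out,
        )
    return trials, profiles


def robust_signature(profile: SelectionProfile, pi_threshold: float) -> SignatureSet:
    """Features whose selection probability reaches the baseline ``pi``.

    Ordered by decreasing probability, then decreasing |mean coefficient|,
    then feature id; may be empty.
    """
    if not 0.0 <= pi_threshold <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    idx = np.flatnonzero(profile.probabilities >= pi_threshold)
    if pi_threshold == 0.0:
        idx = np.flatnonzero(profile.probabilities > 0.0)
    order = sorted(
        idx,
        key=lambda k: (
            -profile.probabilities[k],
            -abs(profile.mean_coefficients[k]),
            profile.feature_ids[k],
        ),
    )
    return SignatureSet(
        tuple(profile.feature_ids[k] for k in order),
        tuple(abs(profile.mean_coefficients[k]) for k in order),
    )


def extra_shrinkage(beta: CoefficientVector, G: int) -> tuple[SignatureSet, bool]:
    """Top-G features of a fitted vector by |coefficient|, with ranks 1..G.

    Ties at the G-th magnitude keep the lower feature index.  When the support
    holds fewer than G features the full support is returned and the trial is
    flagged so size-G stability curves can exclude it.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    sig = signature_from_coefficients(beta.beta, beta.feature_ids, top=G)
    flagged = sig.size < G
    return sig, flagged
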