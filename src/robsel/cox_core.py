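"""Cox proportional-hazards engine: partial likelihood, penalized fits, prediction.

The hazard for a sample with feature vector x is ``h(t|x) = h0(t) exp(x @ beta)``.
Everything here works on the n x p design-matrix orientation (samples in rows).
Tied event times are handled with the Breslow approximation throughout, which
matches the risk-set formulation of both the partial likelihood and the
Cox-Oakes baseline-hazard estimator.

Penalized fitting follows the glmnet convention: the objective maximized is

    (1/n) * pll(beta)  -  lambda * ( alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 )

with ``alpha = 1`` the lasso and ``alpha = 0`` the ridge.  Features are
standardized (mean 0, unit variance) on the training data before fitting and
coefficients are mapped back to the original scale, since the penalties are
scale-sensitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import SurvivalOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientVector",
    "PenaltySpec",
    "BaselineHazard",
    "partial_log_likelihood",
    "fit_penalized_cox",
    "fit_cox_newton",
    "lambda_max",
    "default_lambda_grid",
    "cv_select_lambda",
    "linear_predictor",
    "estimate_baseline_hazard",
    "survival_function",
    "stratified_event_folds",
]

#: coefficients with standardized magnitude below this are snapped to exact zero
#: so that support() is well-defined for lasso fits
ZERO_TOL = 1e-9


@dataclass
class CoefficientVector:
    """A (possibly sparse) linear risk model over a feature universe."""

    beta: np.ndarray
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.feature_ids is not None and len(self.feature_ids) != self.beta.shape[0]:
            raise ValueError("feature_ids length does not match beta dimension")

    def support(self) -> np.ndarray:
        """Indices of features with nonzero coefficient."""
        return np.flatnonzero(self.beta != 0.0)

    def support_ids(self) -> list[str]:
        if self.feature_ids is None:
            raise ValueError("coefficient vector has no feature ids")
        return [self.feature_ids[k] for k in self.support()]


@dataclass
class PenaltySpec:
    """Elastic-net penalty: weight ``lam`` >= 0 and mixing ``alpha`` in [0, 1]."""

    lam: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class BaselineHazard:
    """Discrete baseline-hazard estimate: mass ``increments`` at ``event_times``."""

    event_times: np.ndarray
    increments: np.ndarray
    event_counts: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        self.event_counts = np.asarray(self.event_counts, dtype=int)
        if not np.all(np.diff(self.event_times) > 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(self.increments < 0):
            raise ValueError("hazard increments must be nonnegative")

    def cumulative(self, t: float) -> float:
        """Cumulative baseline hazard H0(t) = sum of increments at times <= t."""
        return float(self.increments[self.event_times <= t].sum())


def _risk_set_order(outcome: SurvivalOutcome):
    """Sort samples by decreasing time so risk sets are prefixes.

    Returns (order, times_sorted, events_sorted).  Ties in time are kept
    together; the prefix up to the *last* occurrence of a time value is the
    risk set for an event at that time.
    """
    order = np.argsort(-outcome.times, kind="stable")
    return order, outcome.times[order], outcome.events[order]


def partial_log_likelihood(X: np.ndarray, outcome: SurvivalOutcome, beta: np.ndarray) -> float:
    """Breslow partial log-likelihood of ``beta`` on (X, outcome).

    Computes ``sum over events i of [ x_i @ beta - log sum_{j in R_i} exp(x_j @ beta) ]``
    where R_i is the set of samples still at risk at the event time of i.
    """
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    return _pll_from_eta(eta, outcome)


def _pll_from_eta(eta: np.ndarray, outcome: SurvivalOutcome) -> float:
    if outcome.n_events == 0:
        raise ValueError("partial likelihood undefined with zero events")
    order, times, events = _risk_set_order(outcome)
    eta = eta[order]
    # numerically safe cumulative log-sum-exp over the descending-time prefix
    m = eta.max()
    log_cum = np.log(np.cumsum(np.exp(eta - m))) + m
    # risk set for time t = all with time >= t: index of last tie in the prefix
    last_tie = _last_tie_index(times)
    ev = events == 1
    return float(eta[ev].sum() - log_cum[last_tie[ev]].sum())


def _last_tie_index(times_desc: np.ndarray) -> np.ndarray:
    """For each position in a descending-sorted time array, the index of the
    last position holding the same time value."""
    n = len(times_desc)
    idx = np.arange(n)
    # positions that close a tie group (next value differs, or end of array)
    change = np.r_[times_desc[1:] != times_desc[:-1], True]
    last = np.where(change, idx, n)
    # backward running minimum propagates each group's closing index to its members
    last = np.minimum.accumulate(last[::-1])[::-1]
    return last


def _breslow_terms(outcome: SurvivalOutcome):
    """Pre-sorted quantities reused by gradient/Hessian computations."""
    order, times, events = _risk_set_order(outcome)
    last_tie = _last_tie_index(times)
    ev = np.flatnonzero(events == 1)
    # distinct event times and their multiplicities, as prefix indices
    risk_idx = last_tie[ev]
    uniq, counts = np.unique(risk_idx, return_counts=True)
    return order, ev, risk_idx, uniq, counts


def fit_cox_newton(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> np.ndarray:
    """Newton-Raphson fit of a (ridge-)penalized Cox model; suited to low p.

    Maximizes ``pll(beta) - ridge/2 * ||beta||^2``.  Used for the small dense
    fits inside supervised-PC tuning and for the ridge baselines; raises on
    non-convergence with iteration diagnostics.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    order, ev, risk_idx, uniq, counts = _breslow_terms(outcome)
    Xs = X[order]
    beta = np.zeros(d)
    step_halvings = 0
    ll_prev = -np.inf
    for it in range(max_iter):
        eta = Xs @ beta
        w = np.exp(eta - eta.max())
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * Xs, axis=0)
        S2 = np.cumsum(np.einsum("i,ij,ik->ijk", w, Xs, Xs), axis=0)
        mu = S1[uniq] / S0[uniq, None]                     # risk-set means
        V = S2[uniq] / S0[uniq, None, None] - np.einsum("ij,ik->ijk", mu, mu)
        grad = Xs[ev].sum(axis=0) - (counts[:, None] * mu).sum(axis=0) - ridge * beta
        hess = (counts[:, None, None] * V).sum(axis=0) + ridge * np.eye(d)
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped update: halve until the penalized objective does not decrease
        step = 1.0
        ll_new = None
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _pll_from_eta(X @ cand, outcome) - 0.5 * ridge * cand @ cand
            if np.isfinite(ll_new) and ll_new >= ll_prev - 1e-12:
                break
            step /= 2.0
            step_halvings += 1
        beta = beta + step * delta
        if ll_new is not None and abs(ll_new - ll_prev) < tol * (abs(ll_prev) + 1.0):
            return beta
        ll_prev = ll_new if ll_new is not None else ll_prev
    if np.linalg.norm(grad) > 1e-4 * (1 + np.linalg.norm(beta)):
        raise RuntimeError(
            f"Cox Newton did not converge: {max_iter} iterations, "
            f"|grad|={np.linalg.norm(grad):.3g}, {step_halvings} step halvings"
        )
    return beta


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def lambda_max(X: np.ndarray, outcome: SurvivalOutcome, alpha: float = 1.0) -> float:
    """Smallest penalty weight at which the elastic-net Cox solution is all-zero.

    Computed on standardized features as ``max_j |U_j| / (n * max(alpha, 1e-3))``
    with U the partial-likelihood score at beta = 0.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    n = Xs.shape[0]
    order, ev, risk_idx, uniq, counts = _breslow_terms(outcome)
    Xo = Xs[order]
    S0 = np.cumsum(np.ones(n))
    S1 = np.cumsum(Xo, axis=0)
    mu = S1[uniq] / S0[uniq, None]
    U = Xo[ev].sum(axis=0) - (counts[:, None] * mu).sum(axis=0)
    return float(np.abs(U).max() / (n * max(alpha, 1e-3)))


def default_lambda_grid(
    X: np.ndarray, outcome: SurvivalOutcome, alpha: float = 1.0, size: int = 100, ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced grid of ``size`` penalties from lambda_max down to ratio*lambda_max."""
    lmax = lambda_max(X, outcome, alpha)
    return np.geomspace(lmax, ratio * lmax, size)


def fit_penalized_cox(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    penalty: PenaltySpec,
    standardize: bool = True,
) -> CoefficientVector:
    """Fit an elastic-net penalized Cox model at a fixed penalty.

    Lasso/elastic-net fits (``alpha > 0``) are solved by the coordinate-descent
    path solver of scikit-survival; ridge and unpenalized fits use the Newton
    solver above.  Coefficients whose standardized magnitude falls below
    ``ZERO_TOL`` are set to exact zero.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2 or outcome.n_events < 1:
        raise ValueError("need at least 2 samples and 1 event")
    if standardize:
        Xs, _, sd = _standardize(X)
    else:
        Xs, sd = X, np.ones(X.shape[1])

    if penalty.alpha > 0 and penalty.lam > 0:
        beta_std = _coxnet_fixed(Xs, outcome, penalty)
    else:
        ridge = penalty.lam * (1 - penalty.alpha) * n
        beta_std = fit_cox_newton(Xs, outcome, ridge=ridge)
    beta_std[np.abs(beta_std) < ZERO_TOL] = 0.0
    return CoefficientVector(beta_std / sd)


def _sksurv_y(outcome: SurvivalOutcome):
    from sksurv.util import Surv

    return Surv.from_arrays(event=outcome.events.astype(bool), time=outcome.times)


def _coxnet_fixed(Xs: np.ndarray, outcome: SurvivalOutcome, penalty: PenaltySpec) -> np.ndarray:
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    lmax = lambda_max(Xs, outcome, penalty.alpha)
    if penalty.lam >= lmax:
        return np.zeros(Xs.shape[1])
    # a short warm-start path down to the requested penalty improves stability
    path = np.geomspace(lmax, penalty.lam, 8)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=penalty.alpha, alphas=path, normalize=False, fit_baseline_model=False, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, _sksurv_y(outcome))
    return model.coef_[:, -1].copy()


def _coxnet_path(Xs: np.ndarray, outcome: SurvivalOutcome, alpha: float, grid: np.ndarray):
    """Coefficients along a descending penalty grid; shape (p, len(grid))."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    model = CoxnetSurvivalAnalysis(
        l1_ratio=alpha, alphas=np.sort(grid)[::-1], normalize=False,
        fit_baseline_model=False, tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, _sksurv_y(outcome))
    fitted = np.asarray(model.alphas_)
    coefs = model.coef_
    # map requested grid points onto the fitted path (nearest on log scale)
    order = np.argsort(-grid)
    out = np.zeros((Xs.shape[1], len(grid)))
    for pos, g in enumerate(grid):
        j = int(np.argmin(np.abs(np.log(fitted) - np.log(g))))
        out[:, pos] = coefs[:, j]
    del order
    return out


def stratified_event_folds(outcome: SurvivalOutcome, k: int, seed: int):
    """K-fold assignments stratified by the event indicator."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dummy = np.zeros(len(outcome))
    return list(skf.split(dummy.reshape(-1, 1), outcome.events))


def cv_select_lambda(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    penalty_alpha: float = 1.0,
    k_folds: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    criterion: str = "pll",
) -> PenaltySpec:
    """Choose the penalty weight by stratified k-fold cross-validation.

    For each fold the model path is fitted on the training part and scored on
    the held-out part, either by the held-out partial log-likelihood
    (``criterion="pll"``, default) or by the held-out concordance index.  The
    grid defaults to 100 log-spaced points from lambda_max down to
    0.01*lambda_max.  On the (rare) event-free fold the data are refolded once
    with a new seed before giving up.
    """
    X = np.asarray(X, dtype=float)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    Xs, _, _ = _standardize(X)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xs, outcome, penalty_alpha)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if len(lambda_grid) == 1:
        return PenaltySpec(float(lambda_grid[0]), penalty_alpha)

    for attempt in range(2):
        folds = stratified_event_folds(outcome, k_folds, seed + attempt)
        if all(outcome.events[te].sum() > 0 and outcome.events[tr].sum() > 0 for tr, te in folds):
            break
    else:
        raise ValueError("could not build folds with events on both sides")

    scores = np.zeros((k_folds, len(lambda_grid)))
    for f, (tr, te) in enumerate(folds):
        out_tr, out_te = outcome.subset(tr), outcome.subset(te)
        if penalty_alpha > 0:
            coefs = _coxnet_path(Xs[tr], out_tr, penalty_alpha, lambda_grid)
        else:
            coefs = np.zeros((Xs.shape[1], len(lambda_grid)))
            beta = np.zeros(Xs.shape[1])
            for j in np.argsort(-lambda_grid):
                beta = fit_cox_newton(
                    Xs[tr], out_tr, ridge=lambda_grid[j] * len(tr)
                )
                coefs[:, j] = beta
        for j in range(len(lambda_grid)):
            eta_te = Xs[te] @ coefs[:, j]
            if criterion == "pll":
                scores[f, j] = _pll_from_eta(eta_te, out_te)
            else:
                from .metrics import concordance_index

                try:
                    scores[f, j] = concordance_index(eta_te, out_te)
                except ValueError:
                    scores[f, j] = 0.5
    mean_scores = scores.mean(axis=0)
    # ties broken toward the larger penalty (sparser model)
    best = max(
        range(len(lambda_grid)),
        key=lambda j: (mean_scores[j], lambda_grid[j]),
    )
    logger.debug("cv_select_lambda: best lambda %.4g", lambda_grid[best])
    return PenaltySpec(float(lambda_grid[best]), penalty_alpha)


def linear_predictor(beta: CoefficientVector | np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-sample risk score x @ beta; score differences are log hazard ratios."""
    b = beta.beta if isinstance(beta, CoefficientVector) else np.asarray(beta, dtype=float)
    return np.asarray(X, dtype=float) @ b


def estimate_baseline_hazard(
    X: np.ndarray, outcome: SurvivalOutcome, beta: CoefficientVector | np.ndarray
) -> BaselineHazard:
    """Cox-Oakes baseline-hazard estimate.

    The hazard mass at each distinct event time t is ``d_t / sum_{j in R_t}
    exp(x_j @ beta)`` with d_t the number of events at t.  With beta = 0 this
    reduces to the Nelson-Aalen increments d_t / |R_t|.
    """
    if outcome.n_events == 0:
        raise ValueError("no events: baseline hazard undefined")
    eta = linear_predictor(beta, X)
    order, times, events = _risk_set_order(outcome)
    w = np.exp(eta[order])
    S0 = np.cumsum(w)
    last_tie = _last_tie_index(times)
    ev = np.flatnonzero(events == 1)
    risk_idx = last_tie[ev]
    uniq, counts = np.unique(risk_idx, return_counts=True)
    event_times = times[uniq]  # descending
    increments = counts / S0[uniq]
    rev = np.argsort(event_times)
    return BaselineHazard(event_times[rev], increments[rev], counts[rev])


def survival_function(
    baseline: BaselineHazard,
    beta: CoefficientVector | np.ndarray,
    x: np.ndarray,
    t: float,
) -> float:
    """P(survive beyond t | x) = exp(-H0(t) * exp(x @ beta))."""
    if t < 0:
        raise ValueError("t must be >= 0")
    b = beta.beta if isinstance(beta, CoefficientVector) else np.asarray(beta, dtype=float)
    eta = float(np.asarray(x, dtype=float) @ b)
    return float(np.exp(-baseline.cumulative(t) * np.exp(eta)))
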