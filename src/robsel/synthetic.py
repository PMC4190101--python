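"""Synthetic survival cohorts with known sparse linear Cox-model structure.

The generator emulates the high-dimensional transcriptomics regime where the
number of candidate features far exceeds (or is comparable to) the number of
patients, so that every stage of the selection pipeline can be exercised with
a known ground truth.  Event times follow an exponential-baseline Cox model

    T_i = -log(U_i) / (baseline_rate * exp(x_i @ beta*)),   U_i ~ Uniform(0,1)

and censoring times are exponential with a rate calibrated by bisection so
that the expected censored fraction matches ``target_censoring``.  Features
are block-correlated Gaussians: independent blocks with exchangeable
correlation ``block_rho`` inside each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox_core import CoefficientVector
from .data_io import ClinicalTable, Dataset, ExpressionMatrix, SurvivalOutcome

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "make_fixture", "FIXTURES"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Defaults describe the study condition used throughout the package's
    simulation experiments: 150 patients, 300 candidate features of which 5
    carry signal with coefficient magnitude 1.5 (alternating signs), mild
    within-block correlation, and 30% random censoring.
    """

    n: int = 150
    p: int = 300
    s: int = 5
    effect_size: float = 1.5
    block_size: int = 10
    block_rho: float = 0.2
    baseline_rate: float = 0.1
    target_censoring: float = 0.3
    sign_pattern: str = "alternating"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s > self.p:
            raise ValueError("true-support size s cannot exceed p")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if not 0.0 <= self.target_censoring < 1.0:
            raise ValueError("target_censoring must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class GroundTruth:
    """The population coefficient vector behind a simulated cohort."""

    true_beta: CoefficientVector
    support: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.support is None:
            self.support = self.true_beta.support()
        self.support = np.asarray(self.support, dtype=int)


def _block_gaussian(rng: np.random.Generator, n: int, p: int, block: int, rho: float) -> np.ndarray:
    """n x p standard Gaussians with exchangeable correlation rho per block."""
    X = rng.standard_normal((n, p))
    if rho == 0.0:
        return X
    n_blocks = int(np.ceil(p / block))
    shared = rng.standard_normal((n, n_blocks))
    shared_full = np.repeat(shared, block, axis=1)[:, :p]
    return np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * X


def _calibrate_censoring_rate(theta: np.ndarray, target: float) -> float:
    """Bisection for the exponential censoring rate c solving

        mean_i  c / (c + theta_i)  =  target

    where ``theta_i`` is sample i's total event-time hazard.  The left side is
    the probability of censoring before the event given the linear predictors,
    monotone increasing in c from 0 to 1, so bisection converges.
    """
    def frac(c: float) -> float:
        return float(np.mean(c / (c + theta)))

    lo, hi = 1e-12, float(theta.max())
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12 * theta.max():  # pragma: no cover - unreachable for target < 1
            raise RuntimeError("censoring calibration failed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Draw a cohort from the configured sparse Cox model.

    Returns the aligned :class:`~robsel.data_io.Dataset` (with a minimal
    clinical table carrying the outcome) and the generating
    :class:`GroundTruth`.  Bit-reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    X = _block_gaussian(rng, config.n, config.p, config.block_size, config.block_rho)

    beta = np.zeros(config.p)
    # spread the true support across distinct blocks so correlation does not
    # collapse the signal onto a single latent factor
    stride = max(config.block_size, config.p // max(config.s, 1))
    support = (np.arange(config.s) * stride) % config.p
    support = np.unique(support)[: config.s]
    if len(support) < config.s:  # fallback when p is tiny
        support = np.arange(config.s)
    if config.sign_pattern == "alternating":
        signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(config.s)])
    else:
        signs = rng.choice([-1.0, 1.0], size=config.s)
    beta[support] = config.effect_size * signs

    eta = X @ beta
    theta = config.baseline_rate * np.exp(eta)
    T = -np.log(rng.uniform(size=config.n)) / theta
    if config.target_censoring == 0.0:
        times, events = T, np.ones(config.n, dtype=int)
    else:
        c_rate = _calibrate_censoring_rate(theta, config.target_censoring)
        C = rng.exponential(1.0 / c_rate, size=config.n)
        times = np.minimum(T, C)
        events = (T <= C).astype(int)
    times = np.maximum(times, 1e-12)  # guard against underflow to 0

    feature_ids = [f"g{k:05d}" for k in range(config.p)]
    sample_ids = [f"S{i:04d}" for i in range(config.n)]
    expr = ExpressionMatrix(feature_ids, sample_ids, X.T)
    outcome = SurvivalOutcome(times, events)
    clinical = ClinicalTable(sample_ids, outcome)
    dataset = Dataset(expr, outcome, clinical)
    truth = GroundTruth(CoefficientVector(beta, feature_ids), support)
    return dataset, truth


# ---------------------------------------------------------------------------
# hand-checkable micro fixtures for metric unit tests


def _fixture_perfect_order() -> Dataset:
    # predictions equal to -times with all events -> concordance exactly 1
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    events = np.ones(8, dtype=int)
    X = (-times).reshape(1, -1)
    expr = ExpressionMatrix(["risk"], [f"S{i}" for i in range(8)], X)
    return Dataset(expr, SurvivalOutcome(times, events))

def _fixture_tied_events() -> Dataset:
    # samples S0/S1 share an event time: that pair is not comparable
    times = np.array([2.0, 2.0, 4.0, 5.0, 7.0])
    events = np.array([1, 1, 1, 0, 1])
    X = np.array([[5.0, 4.0, 3.0, 2.0, 1.0]])
    expr = ExpressionMatrix(["risk"], [f"S{i}" for i in range(5)], X)
    return Dataset(expr, SurvivalOutcome(times, events))

def _fixture_binary_pred() -> Dataset:
    # binary risk groups, all events: concordance equals the AUC of the
    # indicator for short survival
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    events = np.ones(8, dtype=int)
    X = np.array([[1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0]])
    expr = ExpressionMatrix(["risk"], [f"S{i}" for i in range(8)], X)
    return Dataset(expr, SurvivalOutcome(times, events))


FIXTURES = {
    "perfect_order": _fixture_perfect_order,
    "tied_events": _fixture_tied_events,
    "binary_pred": _fixture_binary_pred,
}


def make_fixture(name: str) -> Dataset:
    """Deterministic tiny datasets with hand-checkable risk orderings."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
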