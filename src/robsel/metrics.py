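"""Prediction-performance and signature-stability measures.

Prediction is scored with Harrell's concordance index in its order-indicator
form: a patient pair is usable unless both have events at the same time or the
shorter observed time is censored; a pair is concordant when the patient with
the larger risk prediction has the earlier event.  The index is the fraction
of concordant pairs among the concordant-or-disconcordant ones, so a pair
with tied predictions (order-indicator product 0) counts in neither the
numerator nor the denominator — the convention under which a binary
predictor's concordance coincides with its AUC.

Stability across repeatedly selected signatures is scored with the Jaccard
index (sets of any size), the chance-corrected Kuncheva index (equal-size
sets), a normalized top-k Canberra rank distance, and their ratio, the
rank-penalized Kuncheva index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import SurvivalOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "StabilityReport",
    "concordance_index",
    "jaccard_stability",
    "kuncheva_index",
    "canberra_rank_distance",
    "rank_penalized_kuncheva",
    "paired_welch_test",
    "signature_from_coefficients",
]

_CANBERRA_MC_DRAWS = 10_000
_CANBERRA_MC_SEED = 171_717  # internal: fixed so the normalizer is a constant of (k, p)


@dataclass(frozen=True)
class SignatureSet:
    """An ordered feature subset, optionally with magnitudes and ranks.

    ``features`` are listed in rank order when ranks are present (rank 1 =
    largest coefficient magnitude).
    """

    features: tuple
    magnitudes: tuple | None = None
    ranked: bool = False

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("signature features must be unique")
        if self.magnitudes is not None and len(self.magnitudes) != len(self.features):
            raise ValueError("magnitudes length mismatch")

    @property
    def size(self) -> int:
        return len(self.features)

    def as_set(self) -> frozenset:
        return frozenset(self.features)

    def rank_of(self, feature) -> int:
        """1-based magnitude rank; raises if the set is unranked."""
        if not self.ranked:
            raise ValueError("signature carries no ranks")
        return self.features.index(feature) + 1


@dataclass
class StabilityReport:
    jaccard: float
    kuncheva: float | None = None
    canberra: float | None = None
    rank_penalized_kuncheva: float | None = None


def signature_from_coefficients(
    beta: np.ndarray, feature_ids: Sequence | None = None, top: int | None = None
) -> SignatureSet:
    """Build a ranked signature from a coefficient vector.

    Features are ordered by decreasing |coefficient|; ties are broken toward
    the lower feature index.  ``top`` truncates to the G largest magnitudes.
    """
    beta = np.asarray(beta, dtype=float)
    support = np.flatnonzero(beta != 0.0)
    order = sorted(support, key=lambda k: (-abs(beta[k]), k))
    if top is not None:
        order = order[:top]
    feats = tuple(feature_ids[k] for k in order) if feature_ids is not None else tuple(order)
    return SignatureSet(feats, tuple(abs(beta[k]) for k in order), ranked=True)


# ---------------------------------------------------------------------------
# concordance


def _first_in_pair_mask(outcome: SurvivalOutcome) -> np.ndarray:
    """Boolean matrix M with M[i, j] true when patient i is known to precede j.

    A pair is usable except when both patients have events at the same time,
    or the shorter observed time is censored.  A censored patient tied in time
    with an event patient is taken to outlive them.  Exactly one of M[i, j],
    M[j, i] is set for each usable pair.
    """
    t = outcome.times
    e = outcome.events.astype(bool)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    strictly_first = (ti < tj) & ei
    tied_first = (ti == tj) & ei & ~ej
    mask = strictly_first | tied_first
    np.fill_diagonal(mask, False)
    return mask


def concordance_index(predictions: np.ndarray, outcome: SurvivalOutcome) -> float:
    """Fraction of concordant pairs among all comparable pairs.

    ``predictions`` are risk scores: larger values should accompany earlier
    events.  Prediction-tied pairs are neither concordant nor disconcordant
    and drop out of the ratio.  Raises when no pair is comparable.
    """
    pred = np.asarray(predictions, dtype=float)
    if pred.shape[0] != len(outcome):
        raise ValueError("predictions and outcome length differ")
    first = _first_in_pair_mask(outcome)
    comparable = int((first & (pred[:, None] != pred[None, :])).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    concordant = int((first & (pred[:, None] > pred[None, :])).sum())
    return concordant / comparable


def univariate_concordance(X: np.ndarray, outcome: SurvivalOutcome, chunk: int = 64) -> np.ndarray:
    """Concordance index of each column of the n x p matrix X as a predictor.

    Columns with no untied usable pair (e.g. constant features) score 0.5,
    the chance level.
    """
    X = np.asarray(X, dtype=float)
    first = _first_in_pair_mask(outcome)
    ii, jj = np.nonzero(first)
    if len(ii) == 0:
        raise ValueError("no comparable pairs")
    out = np.empty(X.shape[1])
    for start in range(0, X.shape[1], chunk):
        block = X[:, start : start + chunk]
        num = (block[ii] > block[jj]).sum(axis=0)
        den = (block[ii] != block[jj]).sum(axis=0)
        out[start : start + chunk] = np.where(den > 0, num / np.maximum(den, 1), 0.5)
    return out


# ---------------------------------------------------------------------------
# stability


def jaccard_stability(signatures: Sequence[SignatureSet]) -> float:
    """Mean pairwise |A∩B| / |A∪B| over all unordered signature pairs.

    A pair of two empty signatures counts as perfectly stable (1); this
    convention is logged and does not arise in normal operation.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    sets = [s.as_set() for s in signatures]
    vals = []
    for a, b in combinations(sets, 2):
        union = len(a | b)
        if union == 0:
            logger.warning("jaccard: pair of empty signatures counted as 1")
            vals.append(1.0)
        else:
            vals.append(len(a & b) / union)
    return float(np.mean(vals))


def kuncheva_index(signatures: Sequence[SignatureSet], p: int) -> float:
    """Chance-corrected mean pairwise overlap of equal-size signatures.

    For sets of common size k out of p features, each pair contributes
    ``(|A∩B| - k^2/p) / (k - k^2/p)``; identical sets score 1 and
    chance-level overlap scores 0.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    sizes = {s.size for s in signatures}
    if len(sizes) != 1:
        raise ValueError("Kuncheva index requires signatures to be of the same size")
    k = sizes.pop()
    if k == 0 or k >= p:
        raise ValueError("need 0 < k < p for chance correction")
    expect = k * k / p
    denom = k - expect
    sets = [s.as_set() for s in signatures]
    vals = [(len(a & b) - expect) / denom for a, b in combinations(sets, 2)]
    return float(np.mean(vals))


def _pair_canberra(sig_a: SignatureSet, sig_b: SignatureSet, k: int) -> float:
    ra = {f: i + 1 for i, f in enumerate(sig_a.features)}
    rb = {f: i + 1 for i, f in enumerate(sig_b.features)}
    total = 0.0
    for f in set(ra) | set(rb):
        a = ra.get(f, k + 1)
        b = rb.get(f, k + 1)
        total += abs(a - b) / (a + b)
    return total


@lru_cache(maxsize=64)
def _canberra_null_expectation(k: int, p: int) -> float:
    """Monte-Carlo expected top-k Canberra distance of two independent,
    uniformly random ranked k-subsets of p features (fixed internal seed)."""
    rng = np.random.default_rng(_CANBERRA_MC_SEED)
    total = 0.0
    for _ in range(_CANBERRA_MC_DRAWS):
        ra = np.full(p, k + 1.0)
        rb = np.full(p, k + 1.0)
        ra[rng.choice(p, size=k, replace=False)] = np.arange(1, k + 1)
        rb[rng.choice(p, size=k, replace=False)] = np.arange(1, k + 1)
        touched = (ra <= k) | (rb <= k)
        total += float((np.abs(ra - rb) / (ra + rb))[touched].sum())
    return total / _CANBERRA_MC_DRAWS


def canberra_rank_distance(signatures: Sequence[SignatureSet], p: int) -> float:
    """Normalized mean pairwise Canberra distance between ranked top-k lists.

    Unselected features take rank k+1 (top-k-list convention).  The raw mean
    pairwise distance is divided by the expected distance of two independent
    uniformly random top-k lists over p features, so chance-level rank
    agreement scores about 1 and identical rankings score 0.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    sizes = {s.size for s in signatures}
    if len(sizes) != 1:
        raise ValueError("Canberra rank distance requires equal-size signatures")
    if not all(s.ranked for s in signatures):
        raise ValueError("all signatures must carry ranks")
    k = sizes.pop()
    if k == 0:
        raise ValueError("signatures are empty")
    raw = float(
        np.mean([_pair_canberra(a, b, k) for a, b in combinations(signatures, 2)])
    )
    return raw / _canberra_null_expectation(k, p)


def rank_penalized_kuncheva(signatures: Sequence[SignatureSet], p: int) -> float:
    """Ratio of the (non-negative part of the) Kuncheva index to the Canberra
    rank distance.

    Ranges from 0 (chance-level or worse overlap) to +inf (identical sets with
    identical rank orderings, where the distance vanishes).
    """
    ku = max(kuncheva_index(signatures, p), 0.0)
    if ku == 0.0:
        return 0.0
    cd = canberra_rank_distance(signatures, p)
    if cd == 0.0:
        return float("inf")
    return ku / cd


def paired_welch_test(a: Sequence[float], b: Sequence[float], side: str = "greater") -> float:
    """One-sided paired t-test that method A beats method B over shared splits.

    ``side="greater"`` tests mean(A - B) > 0.  Despite the conventional name
    used for this comparison, the pairing over shared data splits makes this a
    paired t-test on the per-split differences.  Degenerate zero-variance
    differences return 0.5 when identically zero, otherwise 0 or 1 by the sign
    of the (constant) difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need equal-length 1-d samples of length >= 3")
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        m = d.mean()
        if m == 0.0:
            logger.warning("paired test on identical samples; returning 0.5")
            return 0.5
        wins = (m > 0) if side == "greater" else (m < 0)
        logger.warning("zero-variance differences; p collapsed to %s", 0.0 if wins else 1.0)
        return 0.0 if wins else 1.0
    return float(stats.ttest_rel(a, b, alternative=side).pvalue)
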