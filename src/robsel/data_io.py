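"""Reading, aligning and writing of expression matrices and clinical survival tables.

The canonical on-disk layout for expression data is features x samples
(microarray convention): first column holds feature identifiers, the header
row holds sample identifiers.  Clinical tables are CSV with one row per
sample.  Sample alignment across the two inputs restricts both to the sorted
intersection of their sample identifiers, which makes runs deterministic
regardless of input ordering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalOutcome",
    "ClinicalTable",
    "Dataset",
    "read_expression",
    "read_clinical",
    "align",
    "write_results",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of real-valued expression summaries.

    Parameters
    ----------
    feature_ids : list of str
        Unique feature (probeset/gene) identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (p, n)
        Finite expression values (e.g. log2 summaries); unitless.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def design(self) -> np.ndarray:
        """Return the n x p design matrix (samples in rows) used by model code."""
        return self.values.T

    def restrict_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx])


@dataclass
class SurvivalOutcome:
    """Right-censored survival annotation: positive times and 0/1 event flags."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if np.any(self.times <= 0) or not np.all(np.isfinite(self.times)):
            raise ValueError("survival times must be positive finite reals")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be coded 0 (censored) / 1 (event)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.times[idx], self.events[idx])


@dataclass
class ClinicalTable:
    """Per-sample survival annotation plus optional clinical covariates.

    ``covariates`` is a DataFrame indexed like ``sample_ids`` whose columns are
    numeric or categorical; categorical level encodings are recorded in
    ``encodings`` so that output metadata can reproduce them.
    """

    sample_ids: list[str]
    outcome: SurvivalOutcome
    covariates: pd.DataFrame | None = None
    encodings: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample_ids")
        if len(self.outcome) != len(self.sample_ids):
            raise ValueError("outcome length does not match sample_ids")
        if self.covariates is not None and len(self.covariates) != len(self.sample_ids):
            raise ValueError("covariate table length does not match sample_ids")

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return ClinicalTable(list(sample_ids), self.outcome.subset(idx), cov, dict(self.encodings))


@dataclass
class Dataset:
    """An aligned bundle of expression matrix, survival outcome and clinical data.

    All components carry identical, identically ordered sample identifiers.
    """

    expression: ExpressionMatrix
    outcome: SurvivalOutcome
    clinical: ClinicalTable | None = None

    def __post_init__(self) -> None:
        if len(self.outcome) != self.expression.n:
            raise ValueError("outcome length does not match expression sample count")
        if self.clinical is not None and self.clinical.sample_ids != self.expression.sample_ids:
            raise ValueError("clinical sample_ids differ from expression sample_ids")

    @property
    def n(self) -> int:
        return self.expression.n

    @property
    def p(self) -> int:
        return self.expression.p

    def subset(self, idx) -> "Dataset":
        """Restrict to the samples at positional indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        sample_ids = [self.expression.sample_ids[i] for i in idx]
        expr = ExpressionMatrix(
            list(self.expression.feature_ids), sample_ids, self.expression.values[:, idx]
        )
        clin = self.clinical.subset(sample_ids) if self.clinical is not None else None
        return Dataset(expr, self.outcome.subset(idx), clin)


def _read_table(path: str, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        ext = os.path.splitext(path)[1].lower()
        delimiter = "\t" if ext in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_expression(
    path: str,
    samples_in_rows: bool = False,
    delimiter: str | None = None,
    on_missing: str = "error",
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV.

    Parameters
    ----------
    path : str
        File with a header row and an identifier first column.
    samples_in_rows : bool
        Set when the file stores samples in rows; the matrix is transposed to
        the canonical features x samples orientation.  The orientation is an
        explicit flag rather than auto-detected, since detection is fragile
        when p is close to n.
    delimiter : str, optional
        Overrides the extension-sniffed delimiter (``.tsv``/``.txt`` -> tab).
    on_missing : {"error", "drop"}
        Missing cells either abort the load (default) or drop the offending
        features; values are never imputed.
    """
    df = _read_table(path, delimiter)
    if samples_in_rows:
        df = df.T
    bad = df.map(lambda v: isinstance(v, str)) if df.dtypes.eq(object).any() else None
    if bad is not None and bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at feature {df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    values = df.to_numpy(dtype=float)
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    _check_unique(feature_ids, f"feature ids in {path}")
    _check_unique(sample_ids, f"sample ids in {path}")
    if np.isnan(values).any():
        if on_missing == "drop":
            keep = ~np.isnan(values).any(axis=1)
            logger.warning("dropping %d features with missing values", (~keep).sum())
            values = values[keep]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        else:
            rows = [feature_ids[i] for i in np.unique(np.argwhere(np.isnan(values))[:, 0])]
            raise ValueError(f"missing expression values for features {rows[:5]} in {path}")
    return ExpressionMatrix(feature_ids, sample_ids, values)


def read_clinical(
    path: str,
    time_col: str,
    event_col: str,
    covariate_cols: Sequence[str] | None = None,
    event_map: Mapping[object, int] | None = None,
    delimiter: str | None = None,
) -> ClinicalTable:
    """Read a clinical table (CSV by default) into a :class:`ClinicalTable`.

    ``event_map`` translates non-numeric event labels (e.g. ``{"yes": 1,
    "no": 0}``); without it the column must already be coded 0/1.
    """
    df = _read_table(path, delimiter)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    times = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    if np.any(times <= 0):
        bad = df.index[times <= 0].tolist()
        raise ValueError(f"non-positive survival time for samples {bad}")
    raw_events = df[event_col]
    if event_map is not None:
        unknown = sorted(set(raw_events) - set(event_map))
        if unknown:
            raise ValueError(f"event labels {unknown} outside the configured mapping")
        events = raw_events.map(event_map).to_numpy(dtype=int)
    else:
        events = pd.to_numeric(raw_events, errors="raise").to_numpy()
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event column must be coded 0/1 (or supply event_map)")
    sample_ids = [str(i) for i in df.index]
    covariates = None
    encodings: dict[str, list[str]] = {}
    if covariate_cols:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns {missing} not found in {path}")
        covariates = df[list(covariate_cols)].reset_index(drop=True)
        for c in covariate_cols:
            if not pd.api.types.is_numeric_dtype(covariates[c]):
                levels = sorted(covariates[c].astype(str).unique())
                encodings[c] = levels
    return ClinicalTable(sample_ids, SurvivalOutcome(times, events.astype(int)), covariates, encodings)


def align(expr: ExpressionMatrix, clinical: ClinicalTable) -> Dataset:
    """Join expression and clinical data on their shared samples.

    Both components are restricted and reordered to the *sorted* intersection
    of sample ids; the number of dropped samples is logged.  Raises on an
    empty intersection.
    """
    shared = sorted(set(expr.sample_ids) & set(clinical.sample_ids))
    if not shared:
        raise ValueError("expression and clinical tables share no sample ids")
    dropped = (len(expr.sample_ids) - len(shared)) + (len(clinical.sample_ids) - len(shared))
    if dropped:
        logger.info("align: dropped %d unmatched samples", dropped)
    expr_a = expr.restrict_samples(shared)
    clin_a = clinical.subset(shared)
    return Dataset(expr_a, clin_a.outcome, clin_a)


def write_results(selection_profiles, models, metrics: Mapping, config: Mapping, out_dir: str) -> dict[str, str]:
    """Write pipeline outputs: ``signature.tsv``, ``metrics.json``, ``config.json``.

    ``selection_profiles`` maps method name -> SelectionProfile (see
    :mod:`robsel.evaluate`); the TSV is written for each method, sorted by
    decreasing selection probability.  Returns the mapping of logical name to
    written path.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}
    for method, profile in (selection_profiles or {}).items():
        suffix = "" if len(selection_profiles) == 1 else f".{method}"
        path = os.path.join(out_dir, f"signature{suffix}.tsv")
        df = pd.DataFrame(
            {
                "feature_id": profile.feature_ids,
                "selection_probability": profile.probabilities,
                "mean_coefficient": profile.mean_coefficients,
            }
        )
        df = df.sort_values(
            ["selection_probability", "feature_id"], ascending=[False, True]
        )
        df[df.selection_probability > 0].to_csv(path, sep="\t", index=False)
        written[f"signature:{method}"] = path
    for name, payload in (("metrics", metrics), ("config", config)):
        path = os.path.join(out_dir, f"{name}.json")
        with open(path, "w") as fh:
            json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        written[name] = path
    if models:
        path = os.path.join(out_dir, "trials.tsv")
        pd.DataFrame(models).to_csv(path, sep="\t", index=False)
        written["trials"] = path
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
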