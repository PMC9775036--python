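"""Censored-survival data model and Cox partial-likelihood machinery.

The proportional-hazards model underlying everything here is

    h(t | x) = h0(t) * exp(eta(x)),

where ``eta`` is a per-sample log-risk (linear predictor) produced upstream
(by a cascade of survival forests linked with an elastic-net Cox model) and
``h0`` is a baseline hazard shared by all samples.  This module provides the
dataset container, risk sets, the log partial likelihood, the Breslow
estimator of the cumulative baseline hazard and survival-curve prediction,
plus TSV/CSV loaders for expression + clinical tables.

Conventions: right censoring only; Breslow tie handling; the risk set at a
subject's event time includes the subject itself (``time_i >= time_j``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "BaselineHazard",
    "risk_set",
    "cox_partial_likelihood",
    "breslow_baseline",
    "predict_survival_function",
    "load_expression",
    "load_clinical",
    "load_dataset",
]


@dataclass
class SurvivalDataset:
    """Expression matrix plus right-censored outcomes.

    Rows with ``labeled_mask == False`` form the unlabeled pool: their
    ``time``/``event`` entries are placeholders (NaN / 0) and must never be
    read by likelihood or metric code.

    Parameters
    ----------
    sample_ids : unique sample identifiers, length n.
    gene_ids : unique gene identifiers, length p.
    X : float array, shape (n, p); no missing values.
    time : float array, shape (n,); follow-up time (study units), >= 0 where
        labeled.
    event : int array, shape (n,); 1 = event observed, 0 = right-censored.
    labeled_mask : bool array, shape (n,); False rows carry no outcome.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    labeled_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if self.labeled_mask is None:
            self.labeled_mask = np.ones(n, dtype=bool)
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event must be length-n vectors")
        if np.isnan(self.X).any():
            raise ValueError("expression matrix contains missing values")
        lab = self.labeled_mask
        t_lab, e_lab = self.time[lab], self.event[lab]
        if np.isnan(t_lab).any() or (t_lab < 0).any():
            raise ValueError("labeled samples need finite non-negative time")
        if not np.isin(e_lab, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = np.where(lab, np.nan_to_num(self.event.astype(float)), 0.0).astype(int)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def labeled(self) -> "SurvivalDataset":
        """Return the labeled sub-dataset (copy of views)."""
        return self.subset(np.flatnonzero(self.labeled_mask))

    def unlabeled(self) -> "SurvivalDataset":
        return self.subset(np.flatnonzero(~self.labeled_mask))

    def subset(self, idx: np.ndarray | Sequence[int]) -> "SurvivalDataset":
        idx = np.asarray(idx, dtype=int)
        return SurvivalDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            X=self.X[idx],
            time=self.time[idx],
            event=self.event[idx],
            labeled_mask=self.labeled_mask[idx],
        )

    def align_genes(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Return X with columns reordered to ``gene_ids`` (id-based match)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:10]}")
        return self.X[:, [pos[g] for g in gene_ids]]


@dataclass(frozen=True)
class BaselineHazard:
    """Cumulative baseline hazard H0 evaluated at the distinct event times."""

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        H = np.asarray(self.cumulative_hazard, dtype=float)
        if t.shape != H.shape or t.ndim != 1:
            raise ValueError("event_times and cumulative_hazard must align")
        if (np.diff(t) <= 0).any():
            raise ValueError("event_times must be strictly increasing")
        if (H < 0).any() or (np.diff(H) < -1e-12).any():
            raise ValueError("cumulative hazard must be non-negative, non-decreasing")
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "cumulative_hazard", H)

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """H0(t): right-continuous step function, zero before the first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        return np.where(idx == 0, 0.0, self.cumulative_hazard[np.maximum(idx - 1, 0)])


def _require_labeled(dataset: SurvivalDataset) -> None:
    if not dataset.labeled_mask.all():
        raise ValueError(
            "operation needs outcomes for every row; call .labeled() first"
        )


def risk_set(dataset: SurvivalDataset, j: int) -> set[int]:
    """Indices of subjects still at risk at subject ``j``'s observed time.

    R_j = {i : time_i >= time_j} over labeled samples; the subject itself is
    included (standard Cox convention, ties included).
    """
    if not dataset.labeled_mask[j]:
        raise ValueError(f"sample {dataset.sample_ids[j]} has no observed outcome")
    lab = np.flatnonzero(dataset.labeled_mask)
    return set(lab[dataset.time[lab] >= dataset.time[j]].tolist())


def cox_partial_likelihood(eta: np.ndarray, dataset: SurvivalDataset) -> float:
    """Log partial likelihood of a log-risk vector under the Cox model.

    log l = sum_{j : event_j=1} [ eta_j - log sum_{i in R_j} exp(eta_i) ],
    computed in the log domain (logsumexp) so forest-scale eta cannot
    overflow.  Censored subjects contribute only through risk sets.
    """
    _require_labeled(dataset)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (dataset.n_samples,):
        raise ValueError("eta must align with the dataset's samples")
    if not np.isfinite(eta).all():
        raise ValueError("eta must be finite")
    if dataset.event.sum() == 0:
        warnings.warn("no events: partial likelihood is an empty product", stacklevel=2)
        return 0.0
    return _log_partial_likelihood(eta, dataset.time, dataset.event)


def _log_partial_likelihood(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    # sort by descending time: risk set of each event is a suffix -> prefix here
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    eta_sorted = eta[order]
    # running logsumexp over the growing risk set
    run = np.logaddexp.accumulate(eta_sorted)
    # for tied times, every tied event uses the full tied block (time_i >= time_j)
    # -> take the last cumulative entry within each tie block
    last_in_block = np.searchsorted(-t_sorted, -t_sorted, side="right") - 1
    log_denom = run[last_in_block]
    return float(np.sum(e_sorted * (eta_sorted - log_denom)))


def breslow_baseline(eta: np.ndarray, dataset: SurvivalDataset) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard.

    At each distinct event time t_k with d_k events, the hazard increments by
    d_k / sum_{i in R(t_k)} exp(eta_i).
    """
    _require_labeled(dataset)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (dataset.n_samples,):
        raise ValueError("eta must align with the dataset's samples")
    if dataset.event.sum() == 0:
        raise ValueError("Breslow estimator needs at least one event")
    # stabilise: exp on shifted eta, rescale at the end (exact in exact arithmetic)
    shift = eta.max()
    w = np.exp(eta - shift)
    times = dataset.time
    event_times = np.unique(times[dataset.event == 1])
    increments = np.empty_like(event_times)
    for k, t_k in enumerate(event_times):
        at_risk = times >= t_k
        d_k = int(((times == t_k) & (dataset.event == 1)).sum())
        increments[k] = d_k / (w[at_risk].sum() * np.exp(shift))
    return BaselineHazard(event_times, np.cumsum(increments))


def predict_survival_function(
    eta: np.ndarray, baseline: BaselineHazard, t: float | np.ndarray
) -> np.ndarray:
    """S(t | x) = exp(-H0(t) * exp(eta)) for each sample.

    Returns shape (n,) for scalar ``t`` and (n, len(t)) for a grid.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise ValueError("survival probabilities are defined for t >= 0")
    H = baseline.at(t_arr)
    S = np.exp(-np.outer(np.exp(eta), np.atleast_1d(H)))
    return S[:, 0] if t_arr.ndim == 0 else S


# ---------------------------------------------------------------------------
# File loading (TSV/CSV external interface)
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def load_expression(
    path: str | Path, *, transpose: bool = False, impute_median: bool = False
) -> pd.DataFrame:
    """Read an expression table (first column sample ids, columns genes).

    ``transpose=True`` accepts the genes-as-rows dialect common to TCGA
    exports.  Missing values are rejected unless ``impute_median`` is set, in
    which case per-gene medians fill them (silent imputation hides data bugs,
    hence opt-in).
    """
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    if transpose:
        df = df.T
    df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        if not impute_median:
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(
                f"missing expression values in genes {bad[:5]}; "
                "pass impute_median=True to fill with per-gene medians"
            )
        df = df.fillna(df.median())
    df.index = df.index.astype(str)
    return df


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table with columns sample_id, time, event.

    Rows with empty time/event are the unlabeled pool.
    """
    df = _read_table(path)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return df


def load_dataset(
    expression_path: str | Path,
    clinical_path: str | Path,
    *,
    transpose: bool = False,
    impute_median: bool = False,
) -> SurvivalDataset:
    """Join expression and clinical tables into a :class:`SurvivalDataset`."""
    expr = load_expression(expression_path, transpose=transpose, impute_median=impute_median)
    clin = load_clinical(clinical_path)
    common = [s for s in expr.index if s in clin.index]
    if not common:
        raise ValueError("no shared sample ids between expression and clinical tables")
    expr = expr.loc[common]
    clin = clin.loc[common]
    labeled = clin["time"].notna() & clin["event"].notna()
    return SurvivalDataset(
        sample_ids=list(expr.index),
        gene_ids=list(expr.columns),
        X=expr.to_numpy(dtype=float),
        time=clin["time"].fillna(0.0).to_numpy(dtype=float),
        event=clin["event"].fillna(0).to_numpy(),
        labeled_mask=labeled.to_numpy(),
    )


def concat_datasets(a: SurvivalDataset, b: SurvivalDataset) -> SurvivalDataset:
    """Row-wise concatenation; gene ids must match exactly."""
    if list(a.gene_ids) != list(b.gene_ids):
        raise ValueError("gene ids differ; align before concatenating")
    return SurvivalDataset(
        sample_ids=list(a.sample_ids) + list(b.sample_ids),
        gene_ids=list(a.gene_ids),
        X=np.vstack([a.X, b.X]),
        time=np.concatenate([a.time, b.time]),
        event=np.concatenate([a.event, b.event]),
        labeled_mask=np.concatenate([a.labeled_mask, b.labeled_mask]),
    )
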