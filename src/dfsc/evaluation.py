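"""Censoring-aware model assessment: Harrell C-index, IPCW Brier score,
event-stratified cross-validation, and paired model comparison.

C-index here is Harrell's risk-ordering concordance: a pair (i, j) is
comparable iff time_i < time_j and subject i had the event; the pair is
concordant when the earlier event carries the higher predicted risk, and
tied risks count half.  The Brier score at horizon t is inverse-probability-
of-censoring weighted (IPCW): events before t are weighted by 1/G(T_i-),
subjects still at risk past t by 1/G(t), where G is the Kaplan-Meier
estimate of the censoring distribution; subjects censored before t get zero
weight.  The integrated Brier score averages the pointwise score over a
time grid by the trapezoid rule, normalized by the grid span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.model_selection import StratifiedKFold

from .survival_core import SurvivalDataset

__all__ = [
    "concordance_index",
    "brier_score",
    "integrated_brier",
    "cross_validate",
    "compare_models",
    "EvaluationReport",
    "ModelSpec",
]


def concordance_index(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's C: (#concordant + 0.5 #risk-ties) / #comparable pairs."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    if not time.shape == event.shape == risk.shape:
        raise ValueError("time, event and risk must align")
    # comparable pairs: i with event, time_i < time_j
    diff_t = time[:, None] < time[None, :]
    comparable = diff_t & (event[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (check events and time spread)")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    concordant = float((comparable & higher).sum())
    half = float((comparable & tied).sum())
    return (concordant + 0.5 * half) / n_comp


def _censoring_km(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    return km


def _km_at(km: KaplanMeierFitter, t: np.ndarray) -> np.ndarray:
    return km.survival_function_at_times(t).to_numpy()


def brier_score(
    time: np.ndarray,
    event: np.ndarray,
    predicted_survival_at_t: np.ndarray,
    t: float,
    censor_km: KaplanMeierFitter | None = None,
) -> float:
    """IPCW Brier score at horizon ``t``."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    S = np.asarray(predicted_survival_at_t, dtype=float)
    if censor_km is None:
        censor_km = _censoring_km(time, event)
    died = (time <= t) & (event == 1)
    alive = time > t
    G_minus = _km_at(censor_km, np.clip(time - 1e-12, 0, None))
    G_t = float(_km_at(censor_km, np.asarray([t]))[0])
    if (died & (G_minus <= 0)).any() or (alive.any() and G_t <= 0):
        raise ValueError(f"censoring survival hits 0 before t={t}; use a smaller horizon")
    w = np.zeros_like(time)
    w[died] = 1.0 / G_minus[died]
    if alive.any():
        w[alive] = 1.0 / G_t
    sq = np.where(died, (0.0 - S) ** 2, np.where(alive, (1.0 - S) ** 2, 0.0))
    return float(np.sum(w * sq) / len(time))


def integrated_brier(
    time: np.ndarray,
    event: np.ndarray,
    survival_curves: np.ndarray,
    grid: np.ndarray,
) -> float:
    """Trapezoidal average of the IPCW Brier score over ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty integration grid")
    survival_curves = np.asarray(survival_curves, dtype=float)
    km = _censoring_km(np.asarray(time, float), np.asarray(event, int))
    scores = np.array([
        brier_score(time, event, survival_curves[:, k], t, censor_km=km)
        for k, t in enumerate(grid)
    ])
    if grid.size == 1:
        return float(scores[0])
    return float(np.trapezoid(scores, grid) / (grid[-1] - grid[0]))


def default_time_grid(time: np.ndarray, event: np.ndarray, n_points: int = 10) -> np.ndarray:
    """Horizons between the 10% and 80% follow-up quantiles of event times."""
    t_ev = np.asarray(time)[np.asarray(event) == 1]
    if t_ev.size == 0:
        raise ValueError("no events to anchor the grid")
    lo, hi = np.quantile(t_ev, [0.1, 0.8])
    if hi <= lo:
        hi = lo * (1 + 1e-6) + 1e-12
    return np.linspace(lo, hi, n_points)


class ModelSpec(Protocol):
    """A named survival model the CV harness can fit and score.

    ``fit`` receives the labeled training data, an optional unlabeled pool,
    and a seed; it returns an object with ``predict_risk(dataset)`` and
    ``predict_survival(dataset, times)``.
    """

    name: str

    def fit(self, train: SurvivalDataset, unlabeled: SurvivalDataset | None,
            random_seed: int): ...


@dataclass
class EvaluationReport:
    """Per-model, per-fold metrics with mean +/- sd summaries."""

    rows: pd.DataFrame  # columns: model, fold, cindex, ibrier

    def summary(self) -> pd.DataFrame:
        return (
            self.rows.groupby("model", sort=False)[["cindex", "ibrier"]]
            .agg(["mean", "std"])
        )

    def mean_cindex(self, model: str | None = None) -> float:
        rows = self.rows if model is None else self.rows[self.rows["model"] == model]
        return float(rows["cindex"].mean())


def _stratified_folds(dataset: SurvivalDataset, k: int, seed: int) -> list[np.ndarray]:
    event = dataset.event
    if k > len(event):
        raise ValueError("more folds than samples")
    if min((event == 1).sum(), k) < 1:
        raise ValueError("no events to stratify on")
    if (event == 1).sum() >= k and (event == 0).sum() >= k:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in skf.split(np.zeros(len(event)), event)]
    # tiny data (e.g. leave-one-out): plain shuffled partition
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(event))
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _score_fold(fitted, test: SurvivalDataset, train: SurvivalDataset) -> tuple[float, float]:
    risk = fitted.predict_risk(test)
    try:
        ci = concordance_index(test.time, test.event, risk)
    except ValueError:
        ci = np.nan  # tiny folds (e.g. leave-one-out) have no comparable pairs
    try:
        grid = default_time_grid(train.time, train.event)
        grid = grid[grid < test.time.max()]
        curves = fitted.predict_survival(test, grid)
        ib = integrated_brier(test.time, test.event, curves, grid) if grid.size else np.nan
    except ValueError:
        ib = np.nan
    return ci, ib


def cross_validate(
    dataset: SurvivalDataset,
    model_spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    unlabeled: SurvivalDataset | None = None,
) -> EvaluationReport:
    """Event-stratified k-fold CV; the unlabeled pool (if any) is available
    to every training fold but never to a test fold."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    lab = dataset.labeled()
    folds = _stratified_folds(lab, k, seed)
    records = []
    all_idx = np.arange(lab.n_samples)
    for f, test_idx in enumerate(folds):
        train = lab.subset(np.setdiff1d(all_idx, test_idx))
        test = lab.subset(test_idx)
        if train.event.sum() < 2:
            raise ValueError(f"fold {f}: fewer than 2 training events")
        fitted = model_spec.fit(train, unlabeled, random_seed=seed + f)
        ci, ib = _score_fold(fitted, test, train)
        records.append({"model": model_spec.name, "fold": f, "cindex": ci, "ibrier": ib})
    return EvaluationReport(pd.DataFrame.from_records(records))


def compare_models(
    dataset: SurvivalDataset,
    specs: Sequence[ModelSpec],
    k: int = 5,
    seed: int = 0,
    unlabeled: SurvivalDataset | None = None,
) -> EvaluationReport:
    """Paired comparison: every spec sees the same folds."""
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    lab = dataset.labeled()
    folds = _stratified_folds(lab, k, seed)
    all_idx = np.arange(lab.n_samples)
    records = []
    for spec in specs:
        for f, test_idx in enumerate(folds):
            train = lab.subset(np.setdiff1d(all_idx, test_idx))
            test = lab.subset(test_idx)
            try:
                fitted = spec.fit(train, unlabeled, random_seed=seed + f)
                ci, ib = _score_fold(fitted, test, train)
            except Exception as exc:  # keep partial results per spec
                records.append({"model": spec.name, "fold": f, "cindex": np.nan,
                                "ibrier": np.nan, "error": str(exc)})
                continue
            records.append({"model": spec.name, "fold": f, "cindex": ci, "ibrier": ib})
    return EvaluationReport(pd.DataFrame.from_records(records))
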