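"""Stable-LASSO gene ranking.

Repeatedly subsample the cohort (without replacement), fit an L1-penalized
Cox model along a fixed penalty grid, and record which genes ever receive a
nonzero coefficient.  A gene's stability score is the fraction of subsamples
in which it was selected at any grid penalty — a score near 1 marks a gene
the sparse model keeps choosing no matter which patients are in hand.
Significance is reported separately as the per-gene univariate Cox Wald
p-value on the full data (raw, with an optional Benjamini-Hochberg column),
keeping robustness and significance as independent columns of the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = ["StabilityConfig", "StabilityReport", "stability_select", "gene_correlation_matrix"]

from .survival_core import SurvivalDataset


@dataclass(frozen=True)
class StabilityConfig:
    """Stability-selection settings (conventional defaults).

    B=100 half-subsamples and a 10-point log-spaced penalty grid anchored at
    the data-driven maximal penalty; genes beyond the 5000 most variable are
    pre-screened away for speed (disable with ``prescreen=False``).
    """

    n_subsamples: int = 100
    subsample_fraction: float = 0.5
    n_penalties: int = 10
    penalty_min_ratio: float = 0.1
    penalty_grid: tuple[float, ...] | None = None  # overrides the auto grid
    top_k: int = 20
    prescreen: bool = True
    prescreen_top: int = 5000
    benjamini_hochberg: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsamples < 50:
            raise ValueError("need B >= 50 subsamples")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class StabilityReport:
    """Ranked per-gene stability scores and p-values."""

    table: pd.DataFrame  # columns gene_symbol, stable_score, p_value [, p_adjusted]
    flagged_constant: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _univariate_cox_pvalues(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                            gene_ids: list[str]) -> np.ndarray:
    """Wald p-value of each gene in a single-covariate Cox fit."""
    pvals = np.ones(X.shape[1])
    cph = CoxPHFitter()
    df = pd.DataFrame({"time": time, "event": event})
    for j in range(X.shape[1]):
        if X[:, j].std() == 0:
            continue
        df["g"] = X[:, j]
        try:
            cph.fit(df, duration_col="time", event_col="event")
            pvals[j] = float(cph.summary.loc["g", "p"])
        except Exception:
            pvals[j] = 1.0
    return pvals


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def _penalty_grid(X: np.ndarray, y: np.ndarray, cfg: StabilityConfig) -> np.ndarray:
    if cfg.penalty_grid is not None:
        return np.asarray(sorted(cfg.penalty_grid, reverse=True), dtype=float)
    # reuse coxnet's data-driven path so the grid brackets where genes enter
    probe = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=cfg.n_penalties,
                                   alpha_min_ratio=cfg.penalty_min_ratio,
                                   normalize=True)
    probe.fit(X, y)
    return np.asarray(probe.alphas_, dtype=float)


def stability_select(dataset: SurvivalDataset, config: StabilityConfig) -> StabilityReport:
    """Rank genes by selection frequency across subsampled L1 Cox fits."""
    ds = dataset.labeled()
    n_events = int(ds.event.sum())
    if n_events < 5:
        raise ValueError("stability selection needs at least 5 events")
    X, gene_ids = ds.X, list(ds.gene_ids)

    variances = X.var(axis=0)
    constant = variances == 0
    flagged = [g for g, c in zip(gene_ids, constant) if c]

    active = ~constant
    if config.prescreen and active.sum() > config.prescreen_top:
        order = np.argsort(variances)[::-1]
        keep = np.zeros(len(gene_ids), dtype=bool)
        keep[order[: config.prescreen_top]] = True
        active &= keep
    act_idx = np.flatnonzero(active)
    Xa = X[:, act_idx]

    y = Surv.from_arrays(ds.event.astype(bool), ds.time)
    grid = _penalty_grid(Xa, y, config)

    rng = np.random.default_rng(config.random_seed)
    m = max(2, int(round(config.subsample_fraction * ds.n_samples)))
    counts = np.zeros(len(act_idx))
    b_done = 0
    attempts = 0
    while b_done < config.n_subsamples and attempts < 20 * config.n_subsamples:
        attempts += 1
        sub = rng.choice(ds.n_samples, size=m, replace=False)
        if ds.event[sub].sum() < 2:
            continue  # essentially uninformative subsample; redraw
        try:
            est = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=list(grid), max_iter=int(1e5), normalize=True
            )
            with warnings.catch_warnings():
                # the top grid penalty often selects nothing; that is the point
                warnings.simplefilter("ignore", UserWarning)
                est.fit(Xa[sub], y[sub])
        except Exception:
            continue
        counts += (np.abs(est.coef_) > 0).any(axis=1)
        b_done += 1
    if b_done == 0:
        raise RuntimeError("no subsample admitted an L1 Cox fit")

    scores = np.zeros(len(gene_ids))
    scores[act_idx] = counts / b_done
    pvals = _univariate_cox_pvalues(X, ds.time, ds.event, gene_ids)
    pvals[constant] = 1.0

    df = pd.DataFrame({
        "gene_symbol": gene_ids,
        "stable_score": scores,
        "p_value": pvals,
    })
    if config.benjamini_hochberg:
        df["p_adjusted"] = _bh_adjust(pvals)
    df = df.sort_values(["stable_score", "p_value"], ascending=[False, True],
                        kind="stable").head(config.top_k).reset_index(drop=True)
    return StabilityReport(table=df, flagged_constant=flagged)


def gene_correlation_matrix(dataset: SurvivalDataset, genes: list[str]) -> pd.DataFrame:
    """Pearson correlations between the named genes (constant genes -> 0)."""
    Xg = dataset.align_genes(genes)
    sd = Xg.std(axis=0)
    const = sd == 0
    Xs = Xg.copy()
    Xs[:, const] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Xs, rowvar=False)
    R = np.atleast_2d(R)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    R[const, :] = 0.0
    R[:, const] = 0.0
    R[const, const] = 1.0
    return pd.DataFrame(R, index=genes, columns=genes)
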