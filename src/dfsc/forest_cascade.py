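"""Deep survival forest: stacked levels of survival-forest ensembles with
feature augmentation between levels and an elastic-net Cox link.

Each level holds an even mix of standard random survival forests
(log-rank splits, sqrt-feature subsampling) and completely-random survival
forests (one uniformly random candidate feature and threshold per split,
Nelson-Aalen leaves) — the two variants keep the ensemble diverse.  Every
forest contributes its ensemble log-risk as a prediction feature; the
features each forest feeds forward for its own training rows are computed
out-of-fold (internal 3-fold cross-fitting) so a level never sees its own
memorized outcomes.  Level l+1 trains on the original gene matrix
concatenated with all level-l forest outputs.  An elastic-net-penalized Cox
model on the augmented features supplies the level's log-risk eta and its
validation concordance; the cascade grows until validation concordance
stops improving and keeps only the levels up to the best score.  The final
model composes eta with a Breslow baseline hazard into survival curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sksurv.ensemble import ExtraSurvivalTrees, RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from sklearn.model_selection import KFold, train_test_split

from .evaluation import concordance_index
from .survival_core import (
    BaselineHazard,
    SurvivalDataset,
    _log_partial_likelihood,
    breslow_baseline,
    predict_survival_function,
)

__all__ = [
    "CascadeConfig",
    "CascadeLevel",
    "CascadeModel",
    "fit_cascade",
    "cascade_predict_risk",
    "cascade_predict_survival",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters of the cascade.

    Defaults follow deep-forest convention at desk-compute scale: 4 forests
    per level (2 standard + 2 completely random), 100 trees each, at most 5
    levels with patience 1, an elastic-net Cox link with l1_ratio 0.5 whose
    penalty strength is picked on a small internal CV grid, and a 20%
    event-stratified validation split steering growth.
    """

    n_forests_per_level: int = 4
    n_trees_per_forest: int = 100
    max_levels: int = 5
    patience: int = 1
    elasticnet_alpha: float | None = None  # None -> internal 5-point grid
    elasticnet_l1_ratio: float = 0.5
    validation_fraction: float = 0.2
    n_outputs_per_forest: int = 1
    oof_folds: int = 3
    min_improvement: float = 0.005  # validation C-index gain a new level must clear
    min_samples_leaf: int = 3
    screen_top_k: int | None = None  # variance screen for very large p
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_forests_per_level < 2 or self.n_forests_per_level % 2:
            raise ValueError("n_forests_per_level must be an even integer >= 2")
        if self.max_levels < 1 or self.patience < 1:
            raise ValueError("max_levels and patience must be >= 1")
        if self.elasticnet_alpha is not None and self.elasticnet_alpha < 0:
            raise ValueError("elasticnet_alpha must be >= 0")
        if not 0 <= self.elasticnet_l1_ratio <= 1:
            raise ValueError("elasticnet_l1_ratio must lie in [0, 1]")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.n_outputs_per_forest < 1 or self.oof_folds < 2:
            raise ValueError("need >= 1 output per forest and >= 2 OOF folds")


@dataclass
class CascadeLevel:
    """One fitted level: its forests (3 fold-models each) and Cox link."""

    forest_fold_models: list[list]  # [forest][fold]
    cox_link: CoxnetSurvivalAnalysis
    cox_alpha: float
    cox_link_coefficients: np.ndarray
    feature_quantile_times: np.ndarray  # extra per-forest outputs (empty if 1)
    validation_cindex: float

    @property
    def outputs_per_forest(self) -> int:
        return 1 + len(self.feature_quantile_times)


@dataclass
class CascadeModel:
    """A fitted cascade: ordered levels, baseline hazard, training log-risks."""

    levels: list[CascadeLevel]
    baseline: BaselineHazard
    config: CascadeConfig
    gene_ids: list[str]
    selected_feature_ids: list[str]
    train_eta: np.ndarray
    validation_history: list[float] = field(default_factory=list)
    validation_sample_ids: list[str] = field(default_factory=list)

    @property
    def best_validation_cindex(self) -> float:
        return self.levels[-1].validation_cindex

    def predict_risk(self, data: SurvivalDataset | np.ndarray) -> np.ndarray:
        return cascade_predict_risk(self, data)

    def predict_survival(
        self, data: SurvivalDataset | np.ndarray, times: np.ndarray
    ) -> np.ndarray:
        return cascade_predict_survival(self, data, times)


def _surv_y(dataset: SurvivalDataset) -> np.ndarray:
    return Surv.from_arrays(dataset.event.astype(bool), dataset.time)


def _make_forest(kind: str, config: CascadeConfig, seed: int):
    common = dict(
        n_estimators=config.n_trees_per_forest,
        min_samples_leaf=config.min_samples_leaf,
        n_jobs=1,
        random_state=seed,
    )
    if kind == "standard":
        return RandomSurvivalForest(max_features="sqrt", **common)
    # completely-random: one uniformly random candidate feature + threshold
    return ExtraSurvivalTrees(max_features=1, **common)


def _forest_outputs(model, X: np.ndarray, q_times: np.ndarray) -> np.ndarray:
    """Per-sample features from one fitted forest: log1p(ensemble risk),
    plus survival probabilities at the level's quantile times if requested."""
    cols = [np.log1p(model.predict(X))]
    if len(q_times):
        surv = model.predict_survival_function(X, return_array=True)
        for t in q_times:
            k = np.searchsorted(model.unique_times_, t, side="right") - 1
            cols.append(surv[:, max(k, 0)] if k >= 0 else np.ones(len(X)))
    return np.column_stack(cols)


def _fold_average_outputs(fold_models: list, X: np.ndarray, q_times: np.ndarray) -> np.ndarray:
    return np.mean([_forest_outputs(m, X, q_times) for m in fold_models], axis=0)


def _fit_cox_link(
    F: np.ndarray,
    y: np.ndarray,
    config: CascadeConfig,
    seed: int,
    time: np.ndarray,
    event: np.ndarray,
) -> tuple[CoxnetSurvivalAnalysis, float]:
    """Elastic-net Cox on augmented features; penalty from a 5-point grid
    scored by 3-fold cross-validated partial likelihood (skipped if alpha is
    fixed)."""
    l1 = max(config.elasticnet_l1_ratio, 1e-6)  # coxnet needs l1_ratio > 0
    kw = dict(l1_ratio=l1, max_iter=int(1e5), normalize=True, tol=1e-7)
    if config.elasticnet_alpha is not None and config.elasticnet_alpha > 0:
        est = CoxnetSurvivalAnalysis(alphas=[config.elasticnet_alpha], **kw)
        est.fit(F, y)
        return est, float(config.elasticnet_alpha)
    probe = CoxnetSurvivalAnalysis(n_alphas=5, alpha_min_ratio=0.01, **kw)
    probe.fit(F, y)
    grid = list(probe.alphas_)
    scores = np.zeros(len(grid))
    n_ok = 0
    kf = KFold(n_splits=3, shuffle=True, random_state=seed)
    for tr, te in kf.split(F):
        try:
            cv_est = CoxnetSurvivalAnalysis(alphas=grid, **kw)
            cv_est.fit(F[tr], y[tr])
        except Exception:
            continue
        n_ok += 1
        for a, alpha in enumerate(grid):
            # held-out log partial likelihood: the standard CV criterion,
            # and well-behaved where small-fold concordance is not
            eta_te = cv_est.predict(F[te], alpha=alpha)
            scores[a] += _log_partial_likelihood(eta_te, time[te], event[te])
    if n_ok == 0:  # every CV fold failed; fall back to mid-path
        return probe, float(grid[len(grid) // 2])
    # a constant predictor cannot rank: bar empty-support alphas from the
    # choice unless the whole path is empty
    support = (np.abs(probe.coef_) > 0).any(axis=0)
    if support.any():
        scores = np.where(support, scores, -np.inf)
    best_alpha = grid[int(np.argmax(scores))]
    return probe, float(best_alpha)


def fit_cascade(
    train: SurvivalDataset,
    config: CascadeConfig,
    *,
    validation_eligible: np.ndarray | None = None,
    _leak_validation: bool = False,
) -> CascadeModel:
    """Grow the cascade on fully labeled training data.

    ``validation_eligible`` restricts which rows may enter the internal
    validation split (the semi-supervised driver uses it to keep
    pseudo-labeled rows out of validation); by default all rows are
    eligible.  ``_leak_validation`` exists solely so tests can demonstrate
    the optimism that in-fold feature computation would cause — never set
    it in analysis code.
    """
    if not train.labeled_mask.all():
        raise ValueError("fit_cascade needs fully labeled rows; use fit_dfsc for SSL")
    n, p = train.X.shape
    if p == 0:
        raise ValueError("no genes")
    if train.event.sum() == 0:
        raise ValueError("no events in training data")
    if n < 20 or train.event.sum() < 5:
        raise ValueError("need >= 20 labeled samples with >= 5 events")

    ss = np.random.SeedSequence(config.random_seed)
    split_seed, link_base, *level_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + config.max_levels)
    ]

    if validation_eligible is None:
        validation_eligible = np.ones(n, dtype=bool)
    eligible_idx = np.flatnonzero(validation_eligible)
    n_val = max(2, int(round(config.validation_fraction * len(eligible_idx))))
    strat = train.event[eligible_idx]
    try:
        _, val_rel = train_test_split(
            np.arange(len(eligible_idx)), test_size=n_val,
            random_state=split_seed, stratify=strat,
        )
    except ValueError:  # too few of one class to stratify
        _, val_rel = train_test_split(
            np.arange(len(eligible_idx)), test_size=n_val, random_state=split_seed
        )
    val_idx = np.sort(eligible_idx[val_rel])
    fit_idx = np.setdiff1d(np.arange(n), val_idx)
    fit_ds, val_ds = train.subset(fit_idx), train.subset(val_idx)
    if val_ds.event.sum() == 0 or fit_ds.event.sum() == 0:
        raise ValueError("validation split has no events; lower validation_fraction")

    # optional variance screen for very large p
    if config.screen_top_k is not None and p > config.screen_top_k:
        keep = np.argsort(train.X.var(axis=0))[::-1][: config.screen_top_k]
        keep = np.sort(keep)
        selected_ids = [train.gene_ids[j] for j in keep]
    else:
        keep = np.arange(p)
        selected_ids = list(train.gene_ids)
    X_fit, X_val = fit_ds.X[:, keep], val_ds.X[:, keep]
    y_fit = _surv_y(fit_ds)

    half = config.n_forests_per_level // 2
    levels: list[CascadeLevel] = []
    history: list[float] = []
    best_ci, best_len, bad = -np.inf, 0, 0
    F_fit, F_val = X_fit, X_val  # current-level inputs

    for lvl in range(config.max_levels):
        lseed = level_seeds[lvl]
        if len(levels):  # augment with previous level's forest outputs
            F_fit = np.hstack([X_fit, prev_out_fit])
            F_val = np.hstack([X_val, prev_out_val])
        q_times = (
            np.quantile(fit_ds.time[fit_ds.event == 1],
                        np.linspace(0.25, 0.75, config.n_outputs_per_forest - 1))
            if config.n_outputs_per_forest > 1 else np.empty(0)
        )
        fold_models_per_forest: list[list] = []
        out_fit = np.zeros((len(fit_idx), config.n_forests_per_level * (1 + len(q_times))))
        out_val = np.zeros((len(val_idx), out_fit.shape[1]))
        w = 1 + len(q_times)
        for fi in range(config.n_forests_per_level):
            kind = "standard" if fi < half else "random"
            fseed = (lseed + 7919 * fi) % (2**31)
            if _leak_validation:
                # intentional leak (tests only): one forest on fit+val rows,
                # in-sample features everywhere
                leak_X = np.vstack([F_fit, F_val])
                leak_y = _surv_y(train.subset(np.concatenate([fit_idx, val_idx])))
                m = _make_forest(kind, config, fseed).fit(leak_X, leak_y)
                fold_models_per_forest.append([m])
                feats = _forest_outputs(m, leak_X, q_times)
                out_fit[:, fi * w:(fi + 1) * w] = feats[: len(fit_idx)]
                out_val[:, fi * w:(fi + 1) * w] = feats[len(fit_idx):]
                continue
            kf = KFold(n_splits=config.oof_folds, shuffle=True, random_state=fseed)
            fold_models = []
            for tr, te in kf.split(F_fit):
                m = _make_forest(kind, config, fseed).fit(F_fit[tr], y_fit[tr])
                fold_models.append(m)
                out_fit[te, fi * w:(fi + 1) * w] = _forest_outputs(m, F_fit[te], q_times)
            fold_models_per_forest.append(fold_models)
            out_val[:, fi * w:(fi + 1) * w] = _fold_average_outputs(fold_models, F_val, q_times)

        aug_fit = np.hstack([X_fit, out_fit])
        aug_val = np.hstack([X_val, out_val])
        link, alpha = _fit_cox_link(
            aug_fit, y_fit, config, (link_base + lvl) % (2**31),
            fit_ds.time, fit_ds.event,
        )
        eta_val = link.predict(aug_val, alpha=alpha)
        try:
            val_ci = concordance_index(val_ds.time, val_ds.event, eta_val)
        except ValueError:
            val_ci = 0.5
        history.append(float(val_ci))
        levels.append(CascadeLevel(
            forest_fold_models=fold_models_per_forest,
            cox_link=link,
            cox_alpha=alpha,
            cox_link_coefficients=np.asarray(
                link.coef_[:, list(link.alphas_).index(alpha)]
                if alpha in list(link.alphas_) else link.coef_[:, 0]
            ).ravel(),
            feature_quantile_times=q_times,
            validation_cindex=float(val_ci),
        ))
        if val_ci > best_ci + (config.min_improvement if levels[:-1] else 0.0):
            best_ci, best_len, bad = val_ci, len(levels), 0
        else:
            bad += 1
            if bad >= config.patience:
                break
        prev_out_fit, prev_out_val = out_fit, out_val

    levels = levels[:best_len]
    model = CascadeModel(
        levels=levels,
        baseline=BaselineHazard(np.array([1.0]), np.array([0.0])),  # placeholder
        config=config,
        gene_ids=list(train.gene_ids),
        selected_feature_ids=selected_ids,
        train_eta=np.zeros(n),
        validation_history=history,
        validation_sample_ids=[train.sample_ids[i] for i in val_idx],
    )
    eta_train = cascade_predict_risk(model, train)
    model.train_eta = eta_train
    model.baseline = breslow_baseline(eta_train, train)
    return model


def _coerce_matrix(model: CascadeModel, data: SurvivalDataset | np.ndarray) -> np.ndarray:
    if isinstance(data, SurvivalDataset):
        return data.align_genes(model.gene_ids)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.gene_ids):
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {len(model.gene_ids)} genes (pass a SurvivalDataset "
            "for id-based alignment)"
        )
    return X


def cascade_predict_risk(
    model: CascadeModel, data: SurvivalDataset | np.ndarray
) -> np.ndarray:
    """Replay the cascade on new samples and return the final log-risk eta.

    A :class:`SurvivalDataset` is aligned to the training genes by id (column
    order never matters); a bare matrix must already be in training order.
    """
    X_full = _coerce_matrix(model, data)
    gene_pos = {g: i for i, g in enumerate(model.gene_ids)}
    keep = [gene_pos[g] for g in model.selected_feature_ids]
    X = X_full[:, keep]
    F = X
    eta = None
    for lvl, level in enumerate(model.levels):
        if lvl:
            F = np.hstack([X, out])
        cols = [
            _fold_average_outputs(fold_models, F, level.feature_quantile_times)
            for fold_models in level.forest_fold_models
        ]
        out = np.hstack(cols)
        eta = level.cox_link.predict(np.hstack([X, out]), alpha=level.cox_alpha)
    return np.asarray(eta, dtype=float)


def cascade_predict_survival(
    model: CascadeModel, data: SurvivalDataset | np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Survival curves S(t|x) = exp(-H0(t) e^eta) on a time grid."""
    eta = cascade_predict_risk(model, data)
    return predict_survival_function(eta, model.baseline, np.asarray(times, dtype=float))


def save_model(model: CascadeModel, path: str | Path) -> None:
    """Serialize a fitted cascade to a single archive file."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> CascadeModel:
    model = joblib.load(path)
    if not isinstance(model, CascadeModel):
        raise TypeError(f"{path} does not contain a CascadeModel")
    return model
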