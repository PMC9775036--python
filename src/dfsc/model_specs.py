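"""Named model specs for the cross-validation harness.

Built-ins: the full semi-supervised cascade ("dfsc"), the supervised-only
cascade, an L1-penalized Cox baseline ("lasso-cox") and a single survival
forest ("rsf").  Each spec's ``fit`` returns an object exposing
``predict_risk(dataset)`` and ``predict_survival(dataset, times)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .forest_cascade import CascadeConfig, fit_cascade
from .semi_supervised import DistillationConfig, fit_dfsc
from .survival_core import (
    SurvivalDataset,
    breslow_baseline,
    predict_survival_function,
)

__all__ = ["CascadeSpec", "DFSCSpec", "LassoCoxSpec", "RSFSpec", "spec_by_name"]


@dataclass
class CascadeSpec:
    """Supervised deep survival forest (ignores the unlabeled pool)."""

    config: CascadeConfig = CascadeConfig()
    name: str = "cascade"

    def fit(self, train: SurvivalDataset, unlabeled: SurvivalDataset | None,
            random_seed: int):
        cfg = replace(self.config, random_seed=random_seed)
        return fit_cascade(train, cfg)


@dataclass
class DFSCSpec:
    """Semi-supervised cascade with pseudo-labeling/distillation."""

    config: CascadeConfig = CascadeConfig()
    distill: DistillationConfig = DistillationConfig()
    name: str = "dfsc"

    def fit(self, train: SurvivalDataset, unlabeled: SurvivalDataset | None,
            random_seed: int):
        cfg = replace(self.config, random_seed=random_seed)
        dcfg = replace(self.distill, random_seed=random_seed)
        return fit_dfsc(train, unlabeled, cfg, dcfg)


class _LinearModelFit:
    def __init__(self, est, alpha, train: SurvivalDataset):
        self.est, self.alpha = est, alpha
        self.gene_ids = list(train.gene_ids)
        eta = self.predict_risk(train)
        self.baseline = breslow_baseline(eta, train)

    def predict_risk(self, data: SurvivalDataset) -> np.ndarray:
        return self.est.predict(data.align_genes(self.gene_ids), alpha=self.alpha)

    def predict_survival(self, data: SurvivalDataset, times: np.ndarray) -> np.ndarray:
        return predict_survival_function(self.predict_risk(data), self.baseline,
                                         np.asarray(times, float))


@dataclass
class LassoCoxSpec:
    """L1-penalized Cox regression; penalty from the middle of the path."""

    n_alphas: int = 20
    name: str = "lasso-cox"

    def fit(self, train: SurvivalDataset, unlabeled: SurvivalDataset | None,
            random_seed: int):
        y = Surv.from_arrays(train.event.astype(bool), train.time)
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=self.n_alphas,
                                     alpha_min_ratio=0.05, max_iter=int(1e5),
                                     normalize=True)
        est.fit(train.X, y)
        alpha = est.alphas_[len(est.alphas_) // 2]
        return _LinearModelFit(est, float(alpha), train)


class _RSFFit:
    def __init__(self, forest, train: SurvivalDataset):
        self.forest = forest
        self.gene_ids = list(train.gene_ids)
        eta = self.predict_risk(train)
        self.baseline = breslow_baseline(eta, train)

    def predict_risk(self, data: SurvivalDataset) -> np.ndarray:
        return np.log1p(self.forest.predict(data.align_genes(self.gene_ids)))

    def predict_survival(self, data: SurvivalDataset, times: np.ndarray) -> np.ndarray:
        return predict_survival_function(self.predict_risk(data), self.baseline,
                                         np.asarray(times, float))


@dataclass
class RSFSpec:
    """Single random survival forest (the cascade's level-0 ingredient)."""

    n_trees: int = 200
    min_samples_leaf: int = 3
    name: str = "rsf"

    def fit(self, train: SurvivalDataset, unlabeled: SurvivalDataset | None,
            random_seed: int):
        y = Surv.from_arrays(train.event.astype(bool), train.time)
        forest = RandomSurvivalForest(
            n_estimators=self.n_trees, max_features="sqrt",
            min_samples_leaf=self.min_samples_leaf, n_jobs=1,
            random_state=random_seed % (2**31),
        ).fit(train.X, y)
        return _RSFFit(forest, train)


def spec_by_name(name: str, cascade_config: CascadeConfig | None = None,
                 distill_config: DistillationConfig | None = None):
    cfg = cascade_config or CascadeConfig()
    dcfg = distill_config or DistillationConfig()
    table = {
        "dfsc": DFSCSpec(cfg, dcfg),
        "cascade": CascadeSpec(cfg),
        "lasso-cox": LassoCoxSpec(),
        "rsf": RSFSpec(),
    }
    if name not in table:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(table)}")
    return table[name]
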