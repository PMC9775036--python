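"""Synthetic gene-expression survival data with known ground truth.

Emulates the shape of TCGA-style cohorts — high-dimensional (p >> n)
expression with a small set of truly prognostic genes, proportional-hazards
event times, right censoring, and a labeled / unlabeled / test partition —
so that models can be tested against parameter-recovery oracles instead of
downloaded data.

Generative model
----------------
Expression: block-correlated Gaussian.  Genes come in consecutive blocks of
``correlation_block_size`` with exchangeable within-block correlation
``block_rho`` (a co-expression stand-in); every gene is standardized to mean
0, sd 1 after sampling.  The first ``n_causal`` genes carry nonzero effects
beta with |beta| = ``beta_magnitude`` and random signs; these genes are
spread across distinct blocks.

Outcomes: latent event times T* ~ Exponential(rate = lambda0 * exp(x beta))
(proportional hazards with constant baseline; a Weibull shape is exposed as
an option but leaves rank-based metrics untouched).  Censoring times C are
Exponential with the rate solved numerically so the expected censored
fraction matches ``censoring_rate``.  Observed time = min(T*, C), event =
1[T* <= C].

The sample rows are partitioned uniformly at random into labeled /
unlabeled / test; unlabeled rows have their outcomes withheld (kept only in
the returned :class:`GroundTruth`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .survival_core import SurvivalDataset

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "tcga_like_preset", "TABLE2_SPLITS"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator (defaults = desk-scale preset).

    The default condition — n=300, p=1000, 10 causal genes, |beta|=1, 30%
    censoring, co-expression blocks of 10 at rho=0.4 — exercises the p >> n
    regime of genome-wide cohorts at a size that fits on a desk.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_causal: int = 10
    beta_magnitude: float = 1.0
    baseline_rate: float = 0.1
    censoring_rate: float = 0.3
    correlation_block_size: int = 10
    block_rho: float = 0.4
    unlabeled_fraction: float = 0.0
    test_fraction: float = 0.3
    weibull_shape: float = 1.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_causal <= self.n_genes:
            raise ValueError("need 0 <= n_causal <= n_genes")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.unlabeled_fraction < 0 or self.test_fraction < 0:
            raise ValueError("fractions must be non-negative")
        if self.unlabeled_fraction + self.test_fraction >= 1:
            raise ValueError("labeled remainder must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Everything a recovery oracle needs about a generated cohort."""

    causal_genes: list[str]
    beta: np.ndarray
    eta_true: np.ndarray
    realized_censoring: float
    hidden_time: np.ndarray
    hidden_event: np.ndarray
    partition: dict  # {"labeled": ids, "unlabeled": ids, "test": ids}


def _block_correlated_gaussian(rng: np.random.Generator, n: int, p: int,
                               block: int, rho: float) -> np.ndarray:
    X = rng.standard_normal((n, p))
    if rho > 0 and block > 1:
        a, b = np.sqrt(rho), np.sqrt(1 - rho)
        for start in range(0, p, block):
            stop = min(start + block, p)
            shared = rng.standard_normal(n)[:, None]
            X[:, start:stop] = a * shared + b * X[:, start:stop]
    # standardization contract: per-gene mean 0, sd 1
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    return X


def _solve_censoring_rate(rates: np.ndarray, target: float) -> float:
    """Censoring-time Exponential rate c with mean_i c/(c+rate_i) = target."""
    if target == 0:
        return 0.0

    def expected(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target

    lo, hi = 1e-12 * rates.min(), 1e12 * rates.max()
    if expected(lo) > 0 or expected(hi) < 0:
        raise ValueError(f"cannot reach censoring target {target}")
    return brentq(expected, lo, hi, xtol=1e-12, rtol=1e-10)


def generate(config: GeneratorConfig) -> tuple[SurvivalDataset, GroundTruth]:
    """Draw a cohort; return the dataset plus its generating truth.

    The dataset's ``labeled_mask`` is False for the unlabeled rows (their
    time/event are zeroed); test rows stay labeled so they can score models.
    Use ``GroundTruth.partition`` to split ids into labeled/unlabeled/test.
    """
    cfg = config
    rng = np.random.default_rng(cfg.random_seed)
    n, p = cfg.n_samples, cfg.n_genes
    X = _block_correlated_gaussian(rng, n, p, cfg.correlation_block_size, cfg.block_rho)

    # causal genes in distinct blocks so block correlation cannot alias them
    if cfg.n_causal == 0:
        causal_idx = np.empty(0, dtype=int)
    elif cfg.correlation_block_size > 1:
        n_blocks = int(np.ceil(p / cfg.correlation_block_size))
        blocks = rng.choice(n_blocks, size=min(cfg.n_causal, n_blocks), replace=False)
        causal_idx = np.sort(blocks * cfg.correlation_block_size)[: cfg.n_causal]
        if len(causal_idx) < cfg.n_causal:  # more causal genes than blocks
            extra = rng.choice(np.setdiff1d(np.arange(p), causal_idx),
                               size=cfg.n_causal - len(causal_idx), replace=False)
            causal_idx = np.sort(np.concatenate([causal_idx, extra]))
    else:
        causal_idx = np.sort(rng.choice(p, size=cfg.n_causal, replace=False))
    beta = np.zeros(p)
    beta[causal_idx] = cfg.beta_magnitude * rng.choice([-1.0, 1.0], size=cfg.n_causal)

    eta = X @ beta
    rates = cfg.baseline_rate * np.exp(eta)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / rates) ** (1.0 / cfg.weibull_shape)
    if cfg.censoring_rate > 0:
        # solve on the effective (post-shape) event-time scale
        eff_rates = rates ** (1.0 / cfg.weibull_shape) if cfg.weibull_shape != 1.0 else rates
        c_rate = _solve_censoring_rate(eff_rates, cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{j:05d}" for j in range(p)]

    perm = rng.permutation(n)
    n_unlab = int(round(cfg.unlabeled_fraction * n))
    n_test = int(round(cfg.test_fraction * n))
    unlab_idx = perm[:n_unlab]
    test_idx = perm[n_unlab:n_unlab + n_test]
    lab_idx = perm[n_unlab + n_test:]

    labeled_mask = np.ones(n, dtype=bool)
    labeled_mask[unlab_idx] = False
    shown_time = np.where(labeled_mask, time, 0.0)
    shown_event = np.where(labeled_mask, event, 0)

    dataset = SurvivalDataset(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        X=X,
        time=shown_time,
        event=shown_event,
        labeled_mask=labeled_mask,
    )
    truth = GroundTruth(
        causal_genes=[gene_ids[j] for j in causal_idx],
        beta=beta,
        eta_true=eta,
        realized_censoring=float(1 - event.mean()),
        hidden_time=time,
        hidden_event=event,
        partition={
            "labeled": [sample_ids[i] for i in np.sort(lab_idx)],
            "unlabeled": [sample_ids[i] for i in np.sort(unlab_idx)],
            "test": [sample_ids[i] for i in np.sort(test_idx)],
        },
    )
    return dataset, truth


def split_by_partition(
    dataset: SurvivalDataset, truth: GroundTruth
) -> tuple[SurvivalDataset, SurvivalDataset, SurvivalDataset]:
    """(labeled_train, unlabeled_pool, test) per the generator's partition."""
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    parts = []
    for key in ("labeled", "unlabeled", "test"):
        idx = np.array([pos[s] for s in truth.partition[key]], dtype=int)
        parts.append(dataset.subset(idx))
    return tuple(parts)  # type: ignore[return-value]


# Labeled / unlabeled / test sample counts of the four emulated TCGA cohorts.
TABLE2_SPLITS: dict[str, tuple[int, int, int]] = {
    "BRCA": (248, 245, 120),
    "CESC": (120, 110, 60),
    "COAD": (110, 85, 60),
    "PAAD": (65, 61, 50),
}
_FULL_P = 20502


def tcga_like_preset(name: str, scale: float = 1.0) -> GeneratorConfig:
    """Generator config mimicking a cohort's labeled/unlabeled/test counts.

    ``scale`` shrinks the sample counts proportionally (gene count is capped
    at 2000 so desk runs stay tractable).  At scale=1 the counts match the
    emulated cohorts exactly, e.g. PAAD 65/61/50.
    """
    key = name.upper()
    if key not in TABLE2_SPLITS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(TABLE2_SPLITS)}")
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    lab, unlab, test = (int(round(scale * c)) for c in TABLE2_SPLITS[key])
    total = lab + unlab + test
    return GeneratorConfig(
        n_samples=total,
        n_genes=min(2000, int(round(scale * _FULL_P))),
        unlabeled_fraction=unlab / total,
        test_fraction=test / total,
    )
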