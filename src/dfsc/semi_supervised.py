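"""Teacher-student pseudo-labeling with temperature distillation.

A cascade fitted on the labeled rows acts as teacher.  For every unlabeled
sample it predicts (i) a median survival time — the pseudo outcome — and
(ii) a temperature-softened distribution over discrete risk classes, whose
maximum is the pseudo-label's confidence.  Risk classes are quantile bins of
the teacher's training log-risk; a sample's class scores are the negative
absolute distances of its log-risk to the bin centers, pushed through a
softmax at temperature tau.  Confident pseudo-labels join the labeled rows
and a student cascade of the same capacity is refit; the student then
becomes the teacher.  Rounds continue while the concordance on a held-out
labeled validation split improves (pseudo-labeled rows are barred from that
split), and the best round — including round 0, the purely supervised fit —
is returned, so semi-supervision can never lose on the selection criterion.

The distillation loss is the cross-entropy -sum_y PT(y|x;tau) log PS(y|x;tau)
between teacher and student soft distributions, averaged per sample; with
the teacher fixed it is minimized exactly when the student matches the
teacher (Gibbs' inequality).  It is tracked per round on the pseudo-labeled
pool as a convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.special import softmax

from .evaluation import concordance_index
from .forest_cascade import CascadeConfig, CascadeModel, cascade_predict_risk, fit_cascade
from .survival_core import SurvivalDataset, concat_datasets

__all__ = [
    "DistillationConfig",
    "PseudoLabel",
    "soften",
    "distillation_loss",
    "pseudo_label",
    "fit_dfsc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistillationConfig:
    """Controls of the teacher-student loop.

    temperature : softmax temperature tau (>0); higher = softer targets.
    n_risk_bins : number of quantile risk classes the log-risk is
        discretized into for the distillation distributions.
    max_rounds : teacher-student iterations after the supervised round.
    confidence_threshold : minimum max-soft-probability for a pseudo-label
        to enter student training.
    pseudo_as_censored : treat pseudo outcomes as censored at the imputed
        median instead of events (sensitivity analysis).
    """

    temperature: float = 2.0
    n_risk_bins: int = 4
    max_rounds: int = 3
    confidence_threshold: float = 0.7
    pseudo_as_censored: bool = False
    min_improvement: float = 0.02  # validation C-index gain a round must clear
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_risk_bins < 2:
            raise ValueError("need >= 2 risk bins")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class PseudoLabel:
    sample_id: str
    imputed_time: float
    imputed_event: int
    soft_distribution: np.ndarray
    confidence: float


def soften(scores: np.ndarray, temperature: float) -> np.ndarray:
    """Temperature softmax P(y) = exp(s_y / tau) / sum exp(s_y' / tau).

    tau -> infinity gives the uniform distribution; tau -> 0+ a one-hot at
    the argmax.  Invariant to adding a constant to all scores.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return softmax(scores / temperature, axis=-1)


def distillation_loss(teacher: np.ndarray, student: np.ndarray) -> float:
    """Cross-entropy -sum PT log PS, averaged per sample (0*log 0 == 0).

    With the teacher fixed this is >= entropy(PT), with equality iff
    PS == PT, so minimizing it drives the student onto the teacher.
    """
    PT = np.atleast_2d(np.asarray(teacher, dtype=float))
    PS = np.atleast_2d(np.asarray(student, dtype=float))
    if PT.shape != PS.shape:
        raise ValueError("teacher and student distributions must align")
    for name, P in (("teacher", PT), ("student", PS)):
        if (P < -1e-12).any() or (np.abs(P.sum(axis=1) - 1) > 1e-6).any():
            raise ValueError(f"{name} rows must be probability distributions")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(PT > 0, -PT * np.log(PS), 0.0)
    if np.isinf(terms).any() or np.isnan(terms).any():
        return float("inf")  # teacher mass where student has none
    return float(terms.sum(axis=1).mean())


def _risk_bins(train_eta: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile bin edges and centers of the teacher's training log-risk."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(train_eta, qs)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def _soft_distributions(eta: np.ndarray, centers: np.ndarray, tau: float) -> np.ndarray:
    """Bin scores = negative |eta - center| measured in quarter-bin-spacing
    units, so at the default temperature a sample sitting on a bin center is
    confidently assigned (~0.87 max probability for 4 bins) while one on a
    bin boundary is not (~0.45)."""
    spacing = float(np.mean(np.diff(centers))) if len(centers) > 1 else 1.0
    unit = max(spacing / 4.0, 1e-12)
    scores = -np.abs(eta[:, None] - centers[None, :]) / unit
    return soften(scores, tau)


def _median_survival_times(teacher: CascadeModel, data: SurvivalDataset) -> np.ndarray:
    """Smallest baseline event time where the predicted curve drops to 0.5
    (the last observed event time if it never does)."""
    grid = teacher.baseline.event_times
    curves = teacher.predict_survival(data, grid)
    below = curves <= 0.5
    first = np.argmax(below, axis=1)
    t_med = grid[first]
    never = ~below.any(axis=1)
    t_med[never] = grid[-1]
    return t_med


def pseudo_label(
    teacher: CascadeModel,
    unlabeled: SurvivalDataset,
    config: DistillationConfig,
) -> list[PseudoLabel]:
    """Teacher-imputed outcomes for the unlabeled pool, confidence-filtered."""
    if unlabeled.n_samples == 0:
        return []
    eta_u = cascade_predict_risk(teacher, unlabeled)
    _, centers = _risk_bins(teacher.train_eta, config.n_risk_bins)
    P = _soft_distributions(eta_u, centers, config.temperature)
    t_med = _median_survival_times(teacher, unlabeled)
    event = 0 if config.pseudo_as_censored else 1
    out = []
    for i, sid in enumerate(unlabeled.sample_ids):
        conf = float(P[i].max())
        if conf >= config.confidence_threshold:
            out.append(PseudoLabel(
                sample_id=sid,
                imputed_time=float(max(t_med[i], np.finfo(float).tiny)),
                imputed_event=event,
                soft_distribution=P[i].copy(),
                confidence=conf,
            ))
    return out


def _augment(labeled: SurvivalDataset, unlabeled: SurvivalDataset,
             pseudo: list[PseudoLabel]) -> tuple[SurvivalDataset, np.ndarray]:
    """Labeled rows + accepted pseudo-labeled rows; returns the combined
    dataset and a mask marking the genuinely labeled rows (validation pool)."""
    pos = {s: i for i, s in enumerate(unlabeled.sample_ids)}
    idx = np.array([pos[p.sample_id] for p in pseudo], dtype=int)
    pseudo_ds = SurvivalDataset(
        sample_ids=[p.sample_id for p in pseudo],
        gene_ids=list(unlabeled.gene_ids),
        X=unlabeled.X[idx],
        time=np.array([p.imputed_time for p in pseudo]),
        event=np.array([p.imputed_event for p in pseudo]),
    )
    combined = concat_datasets(labeled, pseudo_ds)
    eligible = np.zeros(combined.n_samples, dtype=bool)
    eligible[: labeled.n_samples] = True
    return combined, eligible


def _outer_validation_split(
    labeled: SurvivalDataset, fraction: float, seed: int
) -> tuple[SurvivalDataset, SurvivalDataset]:
    from sklearn.model_selection import train_test_split

    n = labeled.n_samples
    n_val = max(2, int(round(fraction * n)))
    idx = np.arange(n)
    try:
        core, val = train_test_split(idx, test_size=n_val, random_state=seed % (2**31),
                                     stratify=labeled.event)
    except ValueError:
        core, val = train_test_split(idx, test_size=n_val, random_state=seed % (2**31))
    return labeled.subset(np.sort(core)), labeled.subset(np.sort(val))


def fit_dfsc(
    labeled: SurvivalDataset,
    unlabeled: SurvivalDataset | None,
    cascade_cfg: CascadeConfig,
    distill_cfg: DistillationConfig,
) -> CascadeModel:
    """Full semi-supervised fit.

    An outer labeled validation split is held out from *every* candidate —
    the teacher, the round-0 supervised baseline and all students — so round
    selection is untouched by teacher memorization (a teacher that saw the
    validation outcomes would launder them into its pseudo-labels and
    flatter every student).  Candidates are compared by concordance on that
    split; if a pseudo-labeled round wins, the winning round's pseudo-labels
    are combined with all labeled rows for a final refit, otherwise the
    plain supervised cascade on all labeled rows is returned.  With an empty
    unlabeled pool, or a confidence threshold no pseudo-label reaches, the
    result is bit-identical to ``fit_cascade(labeled)`` under the same seed.
    """
    if unlabeled is None or unlabeled.n_samples == 0:
        logger.info("no unlabeled samples: returning the supervised cascade")
        model = fit_cascade(labeled, cascade_cfg)
        model.ssl_history = [{"round": 0, "n_pseudo": 0,  # type: ignore[attr-defined]
                              "validation_cindex": model.best_validation_cindex,
                              "distillation_loss": None}]
        return model

    core, val = _outer_validation_split(
        labeled, cascade_cfg.validation_fraction, distill_cfg.random_seed
    )

    def _val_ci(model: CascadeModel) -> float:
        try:
            return concordance_index(val.time, val.event,
                                     cascade_predict_risk(model, val))
        except ValueError:
            return 0.5

    teacher = fit_cascade(core, cascade_cfg)
    ci0 = _val_ci(teacher)
    history = [{"round": 0, "n_pseudo": 0, "validation_cindex": ci0,
                "distillation_loss": None}]
    best_round, best_ci, best_pseudo = 0, ci0, []
    prev_pseudo_ids: set[str] | None = None
    for rnd in range(1, distill_cfg.max_rounds + 1):
        pseudo = pseudo_label(teacher, unlabeled, distill_cfg)
        if not pseudo:
            logger.info("round %d: no confident pseudo-labels; stopping", rnd)
            break
        ids = {p.sample_id for p in pseudo}
        combined, eligible = _augment(core, unlabeled, pseudo)
        student = fit_cascade(combined, cascade_cfg, validation_eligible=eligible)
        # distillation diagnostic on the pseudo-labeled pool
        _, centers = _risk_bins(teacher.train_eta, distill_cfg.n_risk_bins)
        pos = {s: i for i, s in enumerate(unlabeled.sample_ids)}
        sub = unlabeled.subset([pos[p.sample_id] for p in pseudo])
        PT = np.vstack([p.soft_distribution for p in pseudo])
        PS = _soft_distributions(
            cascade_predict_risk(student, sub), centers, distill_cfg.temperature
        )
        loss = distillation_loss(PT, PS)
        ci = _val_ci(student)
        history.append({"round": rnd, "n_pseudo": len(pseudo),
                        "validation_cindex": ci, "distillation_loss": loss})
        improved = ci > best_ci + distill_cfg.min_improvement
        if improved:
            best_round, best_ci, best_pseudo = rnd, ci, pseudo
        teacher = student
        if not improved or (prev_pseudo_ids is not None and ids == prev_pseudo_ids):
            break
        prev_pseudo_ids = ids

    if best_round == 0:
        final = fit_cascade(labeled, cascade_cfg)
    else:  # select-then-refit: winning round's pseudo-labels + all labeled rows
        combined, eligible = _augment(labeled, unlabeled, best_pseudo)
        final = fit_cascade(combined, cascade_cfg, validation_eligible=eligible)
    final.ssl_history = history  # type: ignore[attr-defined]
    final.ssl_selected_round = best_round  # type: ignore[attr-defined]
    return final
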