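"""Batch selection over a prediction ensemble.

Top-N exploitation, the constant-liar batch builder, a random baseline, and
batch-diversity accounting. Constant-liar treats the ensemble's consensus
mean and across-member covariance as a Gaussian belief: after each greedy
pick it conditions the belief on a pessimistic imagined outcome for the
pick (the "lie", the minimum initial consensus), which downweights
candidates correlated with what was already chosen and so promotes batch
diversity. A stabilizing observation noise α · median(diag Σ) is added to
the covariance diagonal once, up front; large α weakens the lie and
recovers plain top-N selection.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

from .landscape import Mutation
from .ranking import PredictionEnsemble

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AcquisitionConfig:
    """Knobs of batch selection.

    ``alpha`` multiplies the median ensemble variance to set the observation
    noise of constant-liar lies: low α → confident lies → aggressive
    exploration; high α → weak lies → top-N exploitation. ``ucb_beta``
    optionally adds β·σ to the greedy objective (0 keeps the posterior
    mean).
    """

    batch_size: int = 16
    alpha: float = 6.0
    strategy: str = "constant_liar"
    ucb_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.strategy == "constant_liar" and self.alpha <= 0:
            raise ValueError("constant-liar needs alpha > 0")
        if self.strategy not in ("top_n", "constant_liar", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclasses.dataclass(frozen=True)
class Batch:
    """An ordered batch of selected candidate ids.

    ``selection_trace`` records, for strategies that have one, the posterior
    mean of each pick at the moment it was chosen.
    """

    selected_ids: tuple[str, ...]
    selection_trace: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("duplicate ids in batch")

    def __len__(self) -> int:
        return len(self.selected_ids)


@dataclasses.dataclass(frozen=True)
class DiversityReport:
    """Locus diversity of one batch relative to a campaign's history."""

    unique_loci: int
    new_loci: int


# --------------------------------------------------------------------------
# Selection strategies
# --------------------------------------------------------------------------

def top_n_select(pred: PredictionEnsemble, batch_size: int) -> Batch:
    """The ``batch_size`` candidates with highest consensus mean.

    Ties break deterministically by candidate order.
    """
    n = len(pred)
    k = min(batch_size, n)
    if k < batch_size:
        log.warning("top_n_select: pool (%d) smaller than batch (%d)", n,
                    batch_size)
    order = np.lexsort((np.arange(n), -pred.consensus))[:k]
    return Batch(selected_ids=tuple(pred.candidate_ids[i] for i in order),
                 selection_trace=tuple(float(pred.consensus[i]) for i in order))


def covariance_posterior(cov: np.ndarray, pick_index: int) -> np.ndarray:
    """Covariance over the remaining candidates after observing one.

    Gaussian conditioning: Σ' = Σ_rest − v vᵀ / σ_i², where v couples the
    pick to the rest. Independent of the value observed (or lied).
    """
    cov = np.asarray(cov, dtype=float)
    sigma2 = cov[pick_index, pick_index]
    if sigma2 <= 0:
        raise ValueError(
            f"pick variance {sigma2} <= 0: stabilizing jitter missing")
    rest = np.delete(np.arange(cov.shape[0]), pick_index)
    v = cov[rest, pick_index]
    out = cov[np.ix_(rest, rest)] - np.outer(v, v) / sigma2
    return (out + out.T) / 2.0


def mean_posterior(mean: np.ndarray, cov: np.ndarray, pick_index: int,
                   y_lie: float) -> np.ndarray:
    """Mean over the remaining candidates given the lied observation.

    y' = y_rest + v (y_lie − y_i) / σ_i². A lie equal to the current
    prediction leaves the rest untouched.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    sigma2 = cov[pick_index, pick_index]
    if sigma2 <= 0:
        raise ValueError(
            f"pick variance {sigma2} <= 0: stabilizing jitter missing")
    rest = np.delete(np.arange(cov.shape[0]), pick_index)
    v = cov[rest, pick_index]
    return mean[rest] + v * (y_lie - mean[pick_index]) / sigma2


def constant_liar_select(pred: PredictionEnsemble,
                         config: AcquisitionConfig) -> Batch:
    """Greedy constant-liar batch construction.

    Procedure: (1) add I·α·median(diag Σ) to the covariance once, up front;
    (2) fix the lie at the minimum of the initial consensus; (3) repeatedly
    pick the arg-max of the current posterior mean (plus ``ucb_beta``·σ if
    configured), then condition mean and covariance on the lie. Falls back
    to top-N with a warning when the covariance carries no variance signal.
    """
    n = len(pred)
    k = min(config.batch_size, n)
    if k < config.batch_size:
        log.warning("constant_liar_select: pool (%d) smaller than batch (%d)",
                    n, config.batch_size)
    diag = np.diag(pred.covariance)
    if float(diag.max(initial=0.0)) <= 0.0:
        log.warning("constant_liar_select: zero covariance diagonal, "
                    "falling back to top-N")
        return top_n_select(pred, config.batch_size)

    cov = pred.covariance.copy()
    cov[np.diag_indices_from(cov)] += config.alpha * float(np.median(diag))
    mean = pred.consensus.copy()
    y_lie = float(pred.consensus.min())

    remaining = list(range(n))
    selected: list[str] = []
    trace: list[float] = []
    for _ in range(k):
        objective = mean
        if config.ucb_beta > 0:
            objective = mean + config.ucb_beta * np.sqrt(
                np.maximum(np.diag(cov), 0.0))
        pick = int(np.argmax(objective))     # ties → lowest candidate index
        selected.append(pred.candidate_ids[remaining[pick]])
        trace.append(float(mean[pick]))
        mean = mean_posterior(mean, cov, pick, y_lie)
        cov = covariance_posterior(cov, pick)
        del remaining[pick]
    return Batch(selected_ids=tuple(selected), selection_trace=tuple(trace))


def random_select(pool_ids: Sequence[str], batch_size: int,
                  seed: int | np.random.Generator = 0) -> Batch:
    """Uniform selection without replacement, seeded."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pool = list(pool_ids)
    k = min(batch_size, len(pool))
    if k < batch_size:
        log.warning("random_select: pool (%d) smaller than batch (%d)",
                    len(pool), batch_size)
    take = rng.choice(len(pool), size=k, replace=False)
    return Batch(selected_ids=tuple(pool[i] for i in take))


def diversity_report(batch_mutations: Sequence[Sequence[Mutation]],
                     history_mutations: Iterable[Sequence[Mutation]] = ()
                     ) -> DiversityReport:
    """Distinct and newly explored loci of one batch.

    ``history_mutations`` holds the mutation lists of every earlier-selected
    mutant in the campaign.
    """
    batch_loci = {m.position for muts in batch_mutations for m in muts}
    past_loci = {m.position for muts in history_mutations for m in muts}
    return DiversityReport(unique_loci=len(batch_loci),
                           new_loci=len(batch_loci - past_loci))
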