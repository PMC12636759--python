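"""Iterative optimization campaigns, baselines, metrics, and statistics.

A campaign runs for a fixed number of rounds (default 3) selecting a batch
of mutants (default 16) per round against a landscape oracle, with half of
the landscape held out from selection each replicate so benchmarks can be
bootstrapped. Strategies:

* ``folde`` — zero-shot naturalness selection in round 1; from round 2 a
  warm-started Bradley-Terry MLP ensemble predicts the candidate pool and
  constant-liar builds the batch (α = 6 in round 2, pure exploitation
  α = 100 afterwards by default);
* ``zero_shot`` — successive disjoint batches down the naturalness ranking;
* ``random`` — uniform selection, the traditional directed-evolution
  baseline;
* ``random_forest`` — random round 1, then a random-forest regressor on
  embeddings with top-N selection (an EVOLVEpro-style baseline).

Success is measured by the cumulative number of top-10% mutants discovered
and whether any top-1% mutant was found, with percentile thresholds
computed over the accessible half's ground-truth activities.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .acquisition import (AcquisitionConfig, Batch, DiversityReport,
                          constant_liar_select, diversity_report,
                          random_select, top_n_select)
from .landscape import Landscape, apply_mutations, holdout_split
from .naturalness import build_table, naturalness_score, zero_shot_select
from .plm import Embedder
from .ranking import (PredictionEnsemble, RankerEnsemble, TrainConfig,
                      fit_ensemble, predict_ensemble, warm_start_states)

log = logging.getLogger(__name__)

STRATEGIES = ("folde", "random", "zero_shot", "random_forest")


@dataclasses.dataclass
class CampaignConfig:
    """Configuration of one simulated campaign.

    ``alpha_schedule`` maps round index (≥ 2) to the constant-liar α; the
    default uses α = 6 in round 2 and reverts to pure exploitation
    (α = 100) from round 3 on. ``hit_rule`` defines "high-performing" for
    candidate-pool expansion: ``above_wt`` (measured activity strictly
    above the wild type's 0), ``top_quartile`` (top 25% of measured), or
    ``top_k`` (best ``hit_k`` measured).
    """

    rounds: int = 3
    batch_size: int = 16
    strategy: str = "folde"
    alpha_schedule: Mapping[int, float] | None = None
    warm_start: bool = True
    hit_rule: str = "above_wt"
    hit_k: int = 8
    holdout_fraction: float = 0.5
    seed: int = 0
    holdout_seed: int | None = None
    train: TrainConfig | None = None
    ucb_beta: float = 0.0
    max_per_locus: int | None = None
    heldout_eval_cap: int = 2000
    metrics_on: str = "accessible"

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.hit_rule not in ("above_wt", "top_quartile", "top_k"):
            raise ValueError(f"unknown hit rule {self.hit_rule!r}")
        if self.metrics_on not in ("accessible", "full"):
            raise ValueError("metrics_on must be 'accessible' or 'full'")

    def alpha_for_round(self, round_index: int) -> float:
        if self.alpha_schedule is not None:
            if round_index not in self.alpha_schedule:
                raise ValueError(f"alpha schedule missing round {round_index}")
            return float(self.alpha_schedule[round_index])
        return 6.0 if round_index == 2 else 100.0


@dataclasses.dataclass
class RoundResult:
    """What one round selected, measured, and diagnosed."""

    round_index: int
    selected: Batch
    measurements: dict[str, float]
    diversity: DiversityReport
    heldout_spearman: float | None = None


@dataclasses.dataclass
class CampaignMetrics:
    """End-of-campaign success metrics.

    ``cumulative_top10_hits`` counts selected mutants at or above the 90th
    activity percentile; ``found_top1`` flags any selection at or above the
    99th. Thresholds are computed over the accessible half by default.
    """

    cumulative_top10_hits: int
    found_top1: bool
    per_round_hits: list[int]
    top10_threshold: float
    top1_threshold: float


def compute_metrics(selected_rounds: Sequence[Sequence[str]],
                    landscape: Landscape,
                    accessible_ids: Sequence[str] | None = None) -> CampaignMetrics:
    """Score a campaign's selections against the landscape's ground truth."""
    base_ids = sorted(accessible_ids) if accessible_ids is not None \
        else landscape.ids
    base = landscape.activities(base_ids)
    thr10 = float(np.percentile(base, 90.0, method="linear"))
    thr1 = float(np.percentile(base, 99.0, method="linear"))
    per_round = []
    found_top1 = False
    for round_ids in selected_rounds:
        acts = landscape.activities(round_ids)
        per_round.append(int(np.sum(acts >= thr10)))
        found_top1 = found_top1 or bool(np.any(acts >= thr1))
    return CampaignMetrics(cumulative_top10_hits=int(sum(per_round)),
                           found_top1=found_top1, per_round_hits=per_round,
                           top10_threshold=thr10, top1_threshold=thr1)


def _hit_ids(measured: Mapping[str, float], rule: str, hit_k: int) -> set[str]:
    if not measured:
        return set()
    if rule == "above_wt":
        return {i for i, a in measured.items() if a > 0.0}
    acts = np.array(list(measured.values()))
    if rule == "top_quartile":
        thr = float(np.percentile(acts, 75.0, method="linear"))
        return {i for i, a in measured.items() if a >= thr}
    order = sorted(measured, key=lambda i: -measured[i])
    return set(order[:hit_k])


def expand_pool(measured: Mapping[str, float], landscape: Landscape,
                accessible_ids: frozenset[str] | set[str],
                hit_rule: str = "above_wt", hit_k: int = 8) -> list[str]:
    """Candidate pool for the next round.

    Unmeasured accessible records that are single mutants of the wild type,
    or single-mutation extensions of any measured high-performing mutant.
    Raises when the pool comes up empty (the campaign cannot continue).
    """
    if not measured:
        raise ValueError("expand_pool needs at least one measured round")
    hits = _hit_ids(measured, hit_rule, hit_k)
    hit_keys = [landscape.record(h).mutation_key for h in hits]
    pool: list[str] = []
    for rec in landscape.records:
        if rec.id in measured or rec.id not in accessible_ids:
            continue
        if len(rec.mutations) == 1:
            pool.append(rec.id)
            continue
        key = rec.mutation_key
        if any(hk < key and len(key) - len(hk) == 1 for hk in hit_keys):
            pool.append(rec.id)
    if not pool:
        raise ValueError("candidate pool is empty: campaign cannot continue")
    return sorted(pool)


class _EmbeddingStore:
    """Lazy id → embedding cache over a landscape and an embedder."""

    def __init__(self, landscape: Landscape, embedder: Embedder) -> None:
        self.landscape = landscape
        self.embedder = embedder
        self._vecs: dict[str, np.ndarray] = {}

    def ensure(self, ids: Sequence[str]) -> None:
        missing = [i for i in ids if i not in self._vecs]
        if missing:
            seqs = [self.landscape.sequence(i) for i in missing]
            X = self.embedder.embed_many(seqs)
            for i, v in zip(missing, X):
                self._vecs[i] = v

    def matrix(self, ids: Sequence[str]) -> np.ndarray:
        self.ensure(ids)
        return np.stack([self._vecs[i] for i in ids])

    def mapping(self, ids: Sequence[str]) -> dict[str, np.ndarray]:
        self.ensure(ids)
        return {i: self._vecs[i] for i in ids}


def _heldout_spearman(predict: Callable[[np.ndarray], np.ndarray],
                      store: _EmbeddingStore, landscape: Landscape,
                      held_out_ids: Sequence[str], cap: int,
                      rng: np.random.Generator) -> float | None:
    ids = sorted(held_out_ids)
    if len(ids) < 3:
        return None
    if len(ids) > cap:
        take = rng.choice(len(ids), size=cap, replace=False)
        ids = [ids[i] for i in sorted(take)]
    X = store.matrix(ids)
    preds = predict(X)
    truth = landscape.activities(ids)
    rho = stats.spearmanr(preds, truth).statistic
    return float(rho)


def run_campaign(landscape: Landscape, embedder: Embedder,
                 config: CampaignConfig
                 ) -> tuple[list[RoundResult], CampaignMetrics]:
    """Simulate one campaign of ``config.rounds`` batches.

    Selection and training see only the accessible half of the landscape;
    the held-out half is used solely for the ranking diagnostic reported in
    :class:`RoundResult`. Fully deterministic given the config seeds.
    """
    train_cfg = config.train or TrainConfig(input_dim=embedder.dim)
    split = holdout_split(landscape, config.holdout_fraction,
                          seed=config.holdout_seed
                          if config.holdout_seed is not None else config.seed)
    accessible = split.accessible_ids
    if len(accessible) < config.rounds * config.batch_size:
        raise ValueError("accessible set smaller than the campaign budget")

    rng = np.random.default_rng(config.seed)
    store = _EmbeddingStore(landscape, embedder)
    lp = embedder.logprobs(landscape.wild_type)
    table = build_table(lp)
    accessible_singles = {i for i in accessible
                          if len(landscape.record(i).mutations) == 1}

    measured: dict[str, float] = {}
    results: list[RoundResult] = []
    ws_states: list[dict] | None = None
    history_muts: list[Sequence] = []

    for r in range(1, config.rounds + 1):
        heldout_rho: float | None = None
        if r == 1:
            pool = sorted(accessible_singles)
            if config.strategy in ("folde", "zero_shot"):
                batch = zero_shot_select(
                    table, config.batch_size,
                    max_per_locus=config.max_per_locus,
                    exclude=set(table.entries) - set(pool))
            else:
                batch = random_select(pool, config.batch_size, rng)
        else:
            pool = expand_pool(measured, landscape, accessible,
                               config.hit_rule, config.hit_k)
            if config.strategy == "random":
                batch = random_select(pool, config.batch_size, rng)
            elif config.strategy == "zero_shot":
                scored = sorted(
                    pool,
                    key=lambda i: (-naturalness_score(
                        landscape.record(i).mutations, lp), i))
                batch = Batch(selected_ids=tuple(
                    scored[:config.batch_size]))
            elif config.strategy == "random_forest":
                from sklearn.ensemble import RandomForestRegressor
                ids = sorted(measured)
                rf = RandomForestRegressor(
                    random_state=int(rng.integers(2 ** 31)))
                rf.fit(store.matrix(ids), [measured[i] for i in ids])
                preds = rf.predict(store.matrix(pool))
                pe = PredictionEnsemble.from_member_scores(
                    pool, np.asarray(preds)[None, :])
                batch = top_n_select(pe, config.batch_size)
                heldout_rho = _heldout_spearman(
                    rf.predict, store, landscape,
                    sorted(split.held_out_ids), config.heldout_eval_cap, rng)
            else:  # folde
                if config.warm_start and ws_states is None:
                    # embed every possible single mutant, present in the
                    # landscape or not: warm-start targets the full table
                    ws_ids = sorted(table.entries)
                    ws_X = embedder.embed_many(
                        [apply_mutations(landscape.wild_type,
                                         [table.mutation(i)])
                         for i in ws_ids])
                    ws_states = warm_start_states(
                        table.entries, dict(zip(ws_ids, ws_X)),
                        train_cfg, base_seed=config.seed)
                ensemble = fit_ensemble(
                    measured, store.mapping(sorted(measured)), train_cfg,
                    base_seed=config.seed + 10 * r,
                    warmstart_states=ws_states)
                pred = predict_ensemble(ensemble, pool, store.matrix(pool))
                acq = AcquisitionConfig(batch_size=config.batch_size,
                                        alpha=config.alpha_for_round(r),
                                        ucb_beta=config.ucb_beta)
                batch = constant_liar_select(pred, acq)
                heldout_rho = _heldout_spearman(
                    lambda X: np.mean(
                        [m.predict(X) for m in ensemble.members], axis=0),
                    store, landscape, sorted(split.held_out_ids),
                    config.heldout_eval_cap, rng)

        batch_muts = [landscape.record(i).mutations
                      for i in batch.selected_ids]
        div = diversity_report(batch_muts, history_muts)
        history_muts.extend(batch_muts)
        round_measurements = {i: landscape.activity(i)
                              for i in batch.selected_ids}
        measured.update(round_measurements)
        results.append(RoundResult(round_index=r, selected=batch,
                                   measurements=round_measurements,
                                   diversity=div,
                                   heldout_spearman=heldout_rho))
        log.info("%s round %d: %d selected, %d unique loci, rho=%s",
                 config.strategy, r, len(batch), div.unique_loci, heldout_rho)

    metrics = compute_metrics(
        [rr.selected.selected_ids for rr in results], landscape,
        sorted(accessible) if config.metrics_on == "accessible" else None)
    return results, metrics


def bootstrap_benchmark(landscape: Landscape, embedder: Embedder,
                        configs: Mapping[str, CampaignConfig],
                        n_replicates: int, seed: int = 0
                        ) -> dict[str, list[CampaignMetrics]]:
    """Paired bootstrap over fresh 50% holdouts.

    Each replicate draws one holdout/selection seed shared by every
    strategy (pairing enables the signed-rank comparison); returns
    per-replicate metrics per strategy.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) \
        % (2 ** 31)
    out: dict[str, list[CampaignMetrics]] = {name: [] for name in configs}
    for rep, rep_seed in enumerate(rep_seeds):
        for name, cfg in configs.items():
            run_cfg = dataclasses.replace(cfg, seed=int(rep_seed),
                                          holdout_seed=int(rep_seed))
            _, metrics = run_campaign(landscape, embedder, run_cfg)
            out[name].append(metrics)
            log.info("replicate %d %s: hits=%d top1=%s", rep, name,
                     metrics.cumulative_top10_hits, metrics.found_top1)
    return out


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    """One-sided signed-rank comparison of paired hit counts."""

    p_value: float
    n_effective: int
    degenerate: bool
    shifted: bool


def wilcoxon_log_ratio(counts_a: Sequence[float],
                       counts_b: Sequence[float]) -> WilcoxonResult:
    """One-sided Wilcoxon signed-rank test on log(A) − log(B).

    Tests whether workflow A discovers more top performers than workflow B;
    the log transform makes the differences relative changes. When any
    count is zero both sides are shifted by +1 before the log (flagged in
    the result). Zero differences are discarded; if none remain the test is
    degenerate and p = 1. Exact null distribution for n ≤ 25 without ties,
    normal approximation otherwise.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts must be equal-length 1-D sequences")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    shifted = bool(np.any(a == 0) or np.any(b == 0))
    if shifted:
        log.info("wilcoxon_log_ratio: zero counts present, shifting by +1")
        a, b = a + 1.0, b + 1.0
    d = np.log(a) - np.log(b)
    d = d[d != 0.0]
    if len(d) == 0:
        return WilcoxonResult(p_value=1.0, n_effective=0, degenerate=True,
                              shifted=shifted)
    ranks_tied = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, alternative="greater", method=method)
    return WilcoxonResult(p_value=float(res.pvalue), n_effective=len(d),
                          degenerate=False, shifted=shifted)
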