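"""Few-shot activity prediction with a Bradley-Terry ranking ensemble.

The predictor is an ensemble of small MLPs trained with a pairwise
Bradley-Terry loss: the probability that mutant i outranks mutant j is
sigmoid(s_i - s_j), scored by binary cross-entropy over directed pairs.
Ranking loss is invariant to the scale and units of its targets, which is
what allows the two-phase protocol: each member is first warm-started to
reproduce PLM naturalness over all single mutants, then fine-tuned on the
measured activities accumulated during a campaign.

Because Bradley-Terry scores are translation invariant, per-member scores
are demeaned over the candidate set before the ensemble consensus and
across-member covariance are formed; that covariance is the substrate of
constant-liar batch acquisition.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from typing import Mapping, Sequence

import numpy as np

from .mlp import MLPRanker

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Directed pairs and the transitivity-aware split
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DirectedPair:
    """A winner-first comparison between two records."""

    winner_id: str
    loser_id: str

    def __post_init__(self) -> None:
        if self.winner_id == self.loser_id:
            raise ValueError(f"self-pair {self.winner_id!r}")


def build_directed_pairs(targets: Mapping[str, float]) -> list[DirectedPair]:
    """All directed pairs from a target map, winner first; ties drop out.

    Deterministic: ids are processed in sorted order.
    """
    ids = sorted(targets)
    pairs: list[DirectedPair] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ta, tb = targets[a], targets[b]
            if ta > tb:
                pairs.append(DirectedPair(a, b))
            elif tb > ta:
                pairs.append(DirectedPair(b, a))
    return pairs


@dataclasses.dataclass(frozen=True)
class PairSplit:
    """Train/validation partition of directed pairs.

    No validation pair (a, b) is reachable a→b through the train digraph,
    so validation loss cannot be trivially solved by transitivity.
    """

    train_pairs: tuple[DirectedPair, ...]
    val_pairs: tuple[DirectedPair, ...]
    seed: int


def _reachable(adj: dict[str, set[str]], src: str, dst: str) -> bool:
    """Breadth-first reachability src→dst over a directed adjacency map."""
    if src not in adj:
        return False
    seen = {src}
    queue = deque([src])
    while queue:
        node = queue.popleft()
        for nxt in adj.get(node, ()):
            if nxt == dst:
                return True
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return False


def split_pairs(pairs: Sequence[DirectedPair], val_fraction: float = 0.2,
                seed: int = 0) -> PairSplit:
    """80–20 split of directed pairs under the no-transitive-leakage rule.

    Pairs are shuffled once (seeded) and assigned to validation until the
    quota is met; a candidate (a, b) is rejected — kept in train — whenever
    b is still reachable from a through the remaining train pairs (checked
    by breadth-first search). Dense digraphs may under-fill the quota; that
    is logged, not an error.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction {val_fraction} outside (0, 1)")
    pairs = list(pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    quota = int(round(val_fraction * len(pairs)))

    adj: dict[str, set[str]] = {}
    radj: dict[str, set[str]] = {}
    for p in pairs:
        adj.setdefault(p.winner_id, set()).add(p.loser_id)
        radj.setdefault(p.loser_id, set()).add(p.winner_id)

    val: list[DirectedPair] = []
    val_set: set[int] = set()
    for k in order:
        if len(val) >= quota:
            break
        p = pairs[k]
        adj[p.winner_id].discard(p.loser_id)
        radj[p.loser_id].discard(p.winner_id)
        # cheap 2-hop screen before the full BFS
        two_hop = adj.get(p.winner_id, set()) & radj.get(p.loser_id, set())
        if two_hop or _reachable(adj, p.winner_id, p.loser_id):
            adj[p.winner_id].add(p.loser_id)      # rejected: stays in train
            radj[p.loser_id].add(p.winner_id)
            continue
        val.append(p)
        val_set.add(k)
    train = tuple(pairs[k] for k in range(len(pairs)) if k not in val_set)
    if len(val) < quota:
        log.info("split_pairs: validation quota under-filled (%d of %d)",
                 len(val), quota)
    return PairSplit(train_pairs=train, val_pairs=tuple(val), seed=seed)


# --------------------------------------------------------------------------
# Bradley-Terry loss
# --------------------------------------------------------------------------

def bt_loss(score_diffs: np.ndarray, labels: np.ndarray | None = None) -> float:
    """Mean binary cross-entropy of sigmoid(score differences).

    ``score_diffs`` are winner-minus-loser score differences; with the
    winner-first orientation every label is 1 (the default). Uses the
    softplus form for numerical stability: BCE(sigmoid(d), 1) = softplus(-d).
    """
    d = np.asarray(score_diffs, dtype=float)
    if labels is None:
        z = -d
    else:
        lab = np.asarray(labels, dtype=float)
        z = np.where(lab > 0.5, -d, d)
    return float(np.mean(np.logaddexp(0.0, z)))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    """Hyper-parameters of the ranking MLP and its two training phases.

    The architecture is input_dim → 100 → 50 → 1 with batch normalization
    after each hidden layer, ReLU, dropout 0.2, and no bias in the final
    layer; Adam at learning rate 3e-4 with weight decay 1e-5. Warm-start
    runs at most 50 epochs (early stopping patience 20, validation every 5);
    activity fine-tuning at most 200 epochs (patience 40, validation every
    10). ``max_split_pairs`` bounds the pair universe handed to the exact
    BFS-checked split; larger universes are seeded-subsampled first.
    """

    input_dim: int = 960
    hidden_dims: tuple[int, int] = (100, 50)
    dropout: float = 0.2
    lr: float = 3e-4
    weight_decay: float = 1e-5
    warmstart_max_epochs: int = 50
    warmstart_patience: int = 20
    warmstart_val_every: int = 5
    activity_max_epochs: int = 200
    activity_patience: int = 40
    activity_val_every: int = 10
    minibatch_size: int = 64
    val_fraction: float = 0.2
    max_split_pairs: int = 4000
    warmstart_cap: int = 2000
    n_members: int = 5

    def __post_init__(self) -> None:
        if self.warmstart_patience > self.warmstart_max_epochs:
            raise ValueError("warm-start patience exceeds max epochs")
        if self.activity_patience > self.activity_max_epochs:
            raise ValueError("activity patience exceeds max epochs")
        for f in ("lr", "weight_decay", "minibatch_size"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _train_bt(member: MLPRanker, X: np.ndarray, targets: np.ndarray,
              ids: Sequence[str], max_epochs: int, patience: int,
              val_every: int, config: TrainConfig,
              rng: np.random.Generator) -> list[dict]:
    """Minibatch Bradley-Terry training with early stopping.

    Pairs are formed among the records of each minibatch (excluding
    validation pairs); validation loss is the BT loss of the held-out pair
    set under eval-mode scores. Returns the training history.
    """
    n = len(ids)
    index = {rid: i for i, rid in enumerate(ids)}
    universe = build_directed_pairs(dict(zip(ids, targets)))
    if not universe:
        raise ValueError("no comparable pairs: all targets tied")
    if len(universe) > config.max_split_pairs:
        take = rng.choice(len(universe), size=config.max_split_pairs,
                          replace=False)
        split_universe = [universe[i] for i in sorted(take)]
    else:
        split_universe = universe

    has_val = len(split_universe) >= 5
    if has_val:
        split = split_pairs(split_universe, config.val_fraction,
                            seed=int(rng.integers(2 ** 31)))
        val_w = np.array([index[p.winner_id] for p in split.val_pairs], dtype=int)
        val_l = np.array([index[p.loser_id] for p in split.val_pairs], dtype=int)
        has_val = len(split.val_pairs) > 0
    if not has_val:
        log.info("_train_bt: <5 pairs, training without validation")
        val_w = val_l = np.empty(0, dtype=int)

    # minibatch pairs are any-comparable pairs minus validation pairs
    val_mask = np.zeros((n, n), dtype=bool)
    val_mask[val_w, val_l] = True
    wins = targets[:, None] > targets[None, :]

    best_state = member.get_state()
    best_loss = np.inf
    best_epoch = 0
    history: list[dict] = []
    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.minibatch_size):
            mb = perm[start:start + config.minibatch_size]
            if len(mb) < 2:
                continue
            grid = np.ix_(mb, mb)
            wi, li = np.nonzero(wins[grid] & ~val_mask[grid])
            if len(wi) == 0:
                continue
            scores, cache = member.forward(X[mb], training=True)
            d = scores[wi] - scores[li]
            epoch_losses.append(bt_loss(d))
            # d(mean softplus(-d))/d(scores)
            g = -1.0 / (1.0 + np.exp(d)) / len(wi)
            dscores = np.zeros(len(mb))
            np.add.at(dscores, wi, g)
            np.add.at(dscores, li, -g)
            grads = member.backward(cache, dscores)
            member.adam_step(grads, lr=config.lr,
                             weight_decay=config.weight_decay)
        entry = {"epoch": epoch,
                 "train_loss": float(np.mean(epoch_losses)) if epoch_losses else None}
        if has_val and (epoch % val_every == 0 or epoch == max_epochs):
            s = member.predict(X)
            entry["val_loss"] = bt_loss(s[val_w] - s[val_l])
            if entry["val_loss"] < best_loss - 1e-12:
                best_loss = entry["val_loss"]
                best_state = member.get_state()
                best_epoch = epoch
            elif epoch - best_epoch >= patience:
                history.append(entry)
                break
        history.append(entry)
    if has_val and np.isfinite(best_loss):
        member.set_state(best_state)
    return history


def warm_start_member(member: MLPRanker, naturalness_targets: Mapping[str, float],
                      embeddings: Mapping[str, np.ndarray] | None,
                      config: TrainConfig,
                      X: np.ndarray | None = None,
                      ids: Sequence[str] | None = None,
                      seed: int = 0) -> list[dict]:
    """Pretrain a member to reproduce the naturalness landscape.

    Targets are the naturalness scores of all single mutants (seeded
    subsample of at most ``config.warmstart_cap``); pairs and loss are the
    same Bradley-Terry machinery as activity training. Returns the history.
    """
    if not naturalness_targets:
        raise ValueError("empty naturalness table: nothing to warm-start on")
    rng = np.random.default_rng(seed)
    all_ids = sorted(naturalness_targets)
    if len(all_ids) > config.warmstart_cap:
        take = rng.choice(len(all_ids), size=config.warmstart_cap, replace=False)
        all_ids = [all_ids[i] for i in sorted(take)]
    if X is None:
        assert embeddings is not None, "need embeddings or an X matrix"
        X_use = np.stack([np.asarray(embeddings[i]) for i in all_ids])
        ids_use = all_ids
    else:
        assert ids is not None
        keep = [k for k, i in enumerate(ids) if i in set(all_ids)]
        X_use = X[keep]
        ids_use = [ids[k] for k in keep]
    t = np.array([naturalness_targets[i] for i in ids_use])
    return _train_bt(member, X_use, t, ids_use,
                     config.warmstart_max_epochs, config.warmstart_patience,
                     config.warmstart_val_every, config, rng)


def train_member_activity(member: MLPRanker, activities: Mapping[str, float],
                          embeddings: Mapping[str, np.ndarray], config: TrainConfig,
                          seed: int = 0) -> list[dict]:
    """Fine-tune a (possibly warm-started) member on measured activities."""
    ids = sorted(activities)
    if len(ids) < 2:
        raise ValueError("need at least 2 measured records")
    t = np.array([activities[i] for i in ids])
    if len(np.unique(t)) < 2:
        raise ValueError("all measured activities tied: no pairs to train on")
    X = np.stack([np.asarray(embeddings[i]) for i in ids])
    rng = np.random.default_rng(seed)
    return _train_bt(member, X, t, ids,
                     config.activity_max_epochs, config.activity_patience,
                     config.activity_val_every, config, rng)


# --------------------------------------------------------------------------
# Ensemble
# --------------------------------------------------------------------------

@dataclasses.dataclass
class RankerEnsemble:
    """Five independently seeded ranking MLPs (member k seeded base+k)."""

    members: list[MLPRanker]
    config: TrainConfig
    base_seed: int

    @classmethod
    def create(cls, config: TrainConfig, base_seed: int = 0) -> "RankerEnsemble":
        members = [MLPRanker(config.input_dim, config.hidden_dims,
                             config.dropout, seed=base_seed + k)
                   for k in range(config.n_members)]
        return cls(members=members, config=config, base_seed=base_seed)

    def member_seeds(self) -> list[int]:
        return [self.base_seed + k for k in range(len(self.members))]


def fit_ensemble(activities: Mapping[str, float],
                 embeddings: Mapping[str, np.ndarray],
                 config: TrainConfig, base_seed: int = 0,
                 warmstart_states: Sequence[dict] | None = None) -> RankerEnsemble:
    """Train a fresh ensemble on measured activities.

    If ``warmstart_states`` (one weight snapshot per member, e.g. from
    :func:`warm_start_states`) is given, each member starts from its
    snapshot instead of random initialization.
    """
    ensemble = RankerEnsemble.create(config, base_seed)
    for k, member in enumerate(ensemble.members):
        if warmstart_states is not None:
            member.set_state(warmstart_states[k])
        train_member_activity(member, activities, embeddings, config,
                              seed=base_seed + 1000 + k)
    return ensemble


def warm_start_states(naturalness_targets: Mapping[str, float],
                      embeddings: Mapping[str, np.ndarray],
                      config: TrainConfig, base_seed: int = 0) -> list[dict]:
    """Warm-started weight snapshots, one per ensemble member.

    Warm-start depends only on the naturalness table, so campaigns compute
    these once and reuse them as the starting point in every round.
    """
    states = []
    for k in range(config.n_members):
        member = MLPRanker(config.input_dim, config.hidden_dims,
                           config.dropout, seed=base_seed + k)
        warm_start_member(member, naturalness_targets, embeddings, config,
                          seed=base_seed + 500 + k)
        states.append(member.get_state())
    return states


@dataclasses.dataclass
class PredictionEnsemble:
    """Demeaned per-member scores, consensus mean, and covariance.

    ``member_scores`` is K×N with each member row demeaned over the
    candidate set (Bradley-Terry scores are translation invariant, so only
    the demeaned scores are identified). ``consensus`` is the column mean
    y_M and ``covariance`` the N×N across-member sample covariance Σ
    (deviations from consensus, 1/(K-1) normalization) — the inputs to
    constant-liar acquisition. Identical members give Σ = 0; rank(Σ) ≤ K-1.
    """

    candidate_ids: list[str]
    member_scores: np.ndarray
    consensus: np.ndarray
    covariance: np.ndarray

    @classmethod
    def from_member_scores(cls, candidate_ids: Sequence[str],
                           raw_scores: np.ndarray) -> "PredictionEnsemble":
        raw = np.asarray(raw_scores, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != len(candidate_ids):
            raise ValueError(f"expected (K, {len(candidate_ids)}) scores, "
                             f"got {raw.shape}")
        demeaned = raw - raw.mean(axis=1, keepdims=True)
        consensus = demeaned.mean(axis=0)
        K = demeaned.shape[0]
        centered = demeaned - consensus          # deviations from consensus
        cov = centered.T @ centered / max(K - 1, 1)
        return cls(candidate_ids=list(candidate_ids), member_scores=demeaned,
                   consensus=consensus, covariance=cov)

    def __len__(self) -> int:
        return len(self.candidate_ids)


def predict_ensemble(ensemble: RankerEnsemble, candidate_ids: Sequence[str],
                     embeddings: Mapping[str, np.ndarray] | np.ndarray) -> PredictionEnsemble:
    """Ensemble predictions over a candidate set.

    ``embeddings`` is either an id → vector mapping or an (N, dim) matrix
    aligned with ``candidate_ids``.
    """
    if len(candidate_ids) < 1:
        raise ValueError("need at least one candidate")
    if isinstance(embeddings, np.ndarray):
        X = embeddings
    else:
        X = np.stack([np.asarray(embeddings[i]) for i in candidate_ids])
    raw = np.stack([m.predict(X) for m in ensemble.members])
    return PredictionEnsemble.from_member_scores(candidate_ids, raw)
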