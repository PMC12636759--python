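"""Synthetic fitness landscapes and a synthetic PLM oracle.

Everything downstream (naturalness scoring, ranking ensembles, acquisition,
campaign simulation) is exercised against this module, which emulates the
statistical structure the method assumes:

* an additive-by-default fitness landscape over single (and optionally
  double) mutants, with tunable pairwise epistasis and measurement noise;
* per-position amino-acid log-probabilities whose induced naturalness
  (wild-type-marginal log-likelihood ratio) rank-correlates with activity at
  a requested Spearman level — mirroring the ρ ≈ 0.5 naturalness–activity
  correlation real protein language models show;
* deterministic fixed-length embeddings in which a configurable fraction of
  coordinates carry linear reads of the per-position fitness effects, the
  rest being a seeded random projection of sequence content.

All outputs are bit-reproducible under the config seed. The oracle exposes
the same contract as a real-PLM adapter (:class:`folde.plm.Embedder`).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import log_softmax

from .landscape import (AA_ALPHABET, AA_INDEX, Landscape, Mutation,
                        MutantRecord)
from .plm import LogProbMatrix


@dataclasses.dataclass(frozen=True)
class SyntheticOracleConfig:
    """Study conditions for the synthetic landscape + PLM oracle.

    Parameters
    ----------
    L : sequence length (residues).
    effect_scale : std of per-(position, amino-acid) fitness effects
        (activity units; wild type is anchored at 0).
    epistasis_weight : share of double-mutant activity variance contributed
        by pairwise interaction terms, in [0, 1).
    noise_sd : std of measurement noise added to ground-truth activities.
    naturalness_rho : target Spearman correlation between naturalness and
        single-mutant activity (real PLMs sit near 0.5).
    dim : embedding length (960 matches ESMC-300M mean pooling; tests use
        smaller values).
    signal_fraction : fraction of embedding coordinates that are linear
        reads of the per-position effects.
    n_doubles : number of double mutants sampled into the landscape.
    n_epistatic_pairs : number of position pairs given interaction terms.
    seed : master seed; all randomness flows from it.
    """

    L: int = 48
    effect_scale: float = 1.0
    epistasis_weight: float = 0.0
    noise_sd: float = 0.1
    naturalness_rho: float = 0.5
    dim: int = 960
    signal_fraction: float = 0.5
    n_doubles: int = 0
    n_epistatic_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not 0.0 <= self.epistasis_weight < 1.0:
            raise ValueError("epistasis_weight must be in [0, 1)")
        if not 0.0 < self.naturalness_rho <= 1.0:
            raise ValueError("naturalness_rho must be in (0, 1]")
        if not 0.0 < self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in (0, 1]")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclasses.dataclass
class EffectTable:
    """Ground truth behind a synthetic landscape.

    ``effects[p, a]`` is the additive activity effect of substituting
    amino acid ``a`` at 0-based position ``p`` (0 for the wild-type letter).
    ``pair_terms`` maps a frozen position pair (1-based) to its epistatic
    coefficient, applied when both positions are mutated.
    """

    wild_type: str
    effects: np.ndarray
    pair_terms: dict[frozenset[int], float]

    def additive_activity(self, sequence: str) -> float:
        return float(sum(self.effects[p, AA_INDEX[aa]]
                         for p, aa in enumerate(sequence)))

    def effect_vector(self, sequence: str) -> np.ndarray:
        """Length-L vector of per-position effects of ``sequence``."""
        idx = np.fromiter((AA_INDEX[a] for a in sequence), dtype=int,
                          count=len(sequence))
        return self.effects[np.arange(len(sequence)), idx]


#: Relative weight of the position-specific spread in signal coordinates
#: versus the shared fitness direction. At 2.0 most of the fitness
#: information is distributed across locus-specific directions — the regime
#: where training data confined to a few high-naturalness loci generalizes
#: poorly (the round-2 collapse the warm-start exists to fix) — while the
#: shared component keeps the landscape learnable from a few dozen
#: measurements.
_SIGNAL_MIX = 2.0


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_landscape(config: SyntheticOracleConfig,
                       name: str = "synthetic") -> tuple[Landscape, EffectTable]:
    """Generate a synthetic landscape enumerating all single mutants.

    Activity of a mutant is the sum of its per-(position, amino-acid)
    effects, plus pairwise interaction terms for epistatic position pairs
    when both are mutated, plus N(0, noise_sd) measurement noise. The wild
    type has activity exactly 0 by construction, so "above wild type" is a
    meaningful hit criterion downstream.
    """
    rng_wt, rng_eff, rng_pairs, rng_noise, rng_doubles = _rng_streams(config.seed, 5)
    L = config.L
    wt_idx = rng_wt.integers(0, 20, size=L)
    wild_type = "".join(AA_ALPHABET[i] for i in wt_idx)

    effects = rng_eff.normal(0.0, config.effect_scale, size=(L, 20))
    effects[np.arange(L), wt_idx] = 0.0

    # Epistatic coefficients live on a seeded subset of position pairs so
    # double-mutant landscapes stay enumerable at desk scale.
    pair_terms: dict[frozenset[int], float] = {}
    if config.n_epistatic_pairs > 0 and config.epistasis_weight > 0:
        # var(additive part of a double) = 2 * effect_scale^2
        sd = math.sqrt(config.epistasis_weight / (1 - config.epistasis_weight)
                       * 2.0) * config.effect_scale
        all_pairs = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]
        chosen = rng_pairs.choice(len(all_pairs),
                                  size=min(config.n_epistatic_pairs, len(all_pairs)),
                                  replace=False)
        for k in chosen:
            i, j = all_pairs[k]
            pair_terms[frozenset((i, j))] = float(rng_pairs.normal(0.0, sd))

    table = EffectTable(wild_type=wild_type, effects=effects,
                        pair_terms=pair_terms)

    def _activity(muts: Sequence[Mutation]) -> float:
        a = sum(float(effects[m.position - 1, AA_INDEX[m.mut_aa]]) for m in muts)
        if len(muts) == 2:
            key = frozenset(m.position for m in muts)
            a += pair_terms.get(key, 0.0)
        if config.noise_sd > 0:
            a += float(rng_noise.normal(0.0, config.noise_sd))
        return a

    records: list[MutantRecord] = []
    for p in range(L):
        for a in range(20):
            if a == wt_idx[p]:
                continue
            mut = Mutation(AA_ALPHABET[wt_idx[p]], p + 1, AA_ALPHABET[a])
            records.append(MutantRecord(id=str(mut), mutations=(mut,),
                                        activity=_activity([mut])))

    seen = {r.id for r in records}
    n_made = 0
    while n_made < config.n_doubles:
        p, q = sorted(rng_doubles.choice(L, size=2, replace=False))
        a = int(rng_doubles.integers(0, 20))
        b = int(rng_doubles.integers(0, 20))
        if a == wt_idx[p] or b == wt_idx[q]:
            continue
        m1 = Mutation(AA_ALPHABET[wt_idx[p]], p + 1, AA_ALPHABET[a])
        m2 = Mutation(AA_ALPHABET[wt_idx[q]], q + 1, AA_ALPHABET[b])
        rec_id = f"{m1}:{m2}"
        if rec_id in seen:
            continue
        seen.add(rec_id)
        records.append(MutantRecord(id=rec_id, mutations=(m1, m2),
                                    activity=_activity([m1, m2])))
        n_made += 1

    return Landscape(wild_type, records, name=name), table


def synthetic_logprobs(config: SyntheticOracleConfig,
                       table: EffectTable) -> LogProbMatrix:
    """Log-probabilities whose naturalness tracks activity at the target ρ.

    Row p is a log-softmax of (effects(p, ·) + noise). Because the
    naturalness of a single mutant is the log-ratio of two entries in the
    same row, the softmax normalizer cancels and naturalness reduces to
    effect + noise difference; the noise scale is calibrated in closed form
    (bivariate-normal Spearman↔Pearson conversion) so that
    Spearman(naturalness, activity) over all single mutants lands near
    ``naturalness_rho``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    sigma_e = config.effect_scale
    sigma_nu = config.noise_sd
    # Pearson r giving the requested Spearman under bivariate normality.
    r = 2.0 * math.sin(math.pi * config.naturalness_rho / 6.0)
    r_max = sigma_e / math.sqrt(sigma_e ** 2 + sigma_nu ** 2)
    if r >= r_max:
        s = 0.0
    else:
        # corr(e + delta, e + nu) = sigma_e^2 / sqrt((se^2+sd^2)(se^2+sn^2))
        var_delta = sigma_e ** 4 / (r ** 2 * (sigma_e ** 2 + sigma_nu ** 2)) \
            - sigma_e ** 2
        # delta = eta(p, mut) - eta(p, wt) has variance 2 s^2
        s = math.sqrt(max(var_delta, 0.0) / 2.0)
    eta = rng.normal(0.0, s, size=table.effects.shape) if s > 0 else 0.0
    logits = table.effects + eta
    return LogProbMatrix(log_softmax(logits, axis=1), table.wild_type)


class SyntheticOracle:
    """Deterministic stand-in for a protein language model.

    Implements the :class:`folde.plm.Embedder` contract. Embeddings
    concatenate ``n_signal = max(1, round(signal_fraction * dim))``
    coordinates that are a seeded Gaussian projection of the sequence's
    per-position effect vector (so a ranking model can learn activity) with
    ``dim - n_signal`` coordinates that are a seeded random projection of
    the one-hot sequence content.
    """

    def __init__(self, config: SyntheticOracleConfig, table: EffectTable) -> None:
        self.config = config
        self.table = table
        L = config.L
        self.n_signal = max(1, int(round(config.signal_fraction * config.dim)))
        self.n_signal = min(self.n_signal, config.dim)
        rng_sig, rng_bg = _rng_streams(config.seed + 1, 2)
        # Signal projection = all-ones mean + zero-mean spread: every signal
        # coordinate reads the summed per-position effects (a dominant
        # fitness direction, as mean-pooled PLM embeddings exhibit) plus a
        # position-specific component that separates loci.
        self._R_signal = 1.0 + _SIGNAL_MIX * rng_sig.normal(
            0.0, 1.0, size=(self.n_signal, L))
        n_bg = config.dim - self.n_signal
        self._R_background = rng_bg.normal(0.0, 1.0 / math.sqrt(L),
                                           size=(n_bg, 20 * L))
        self._logprobs: LogProbMatrix | None = None

    @property
    def dim(self) -> int:
        return self.config.dim

    def embed(self, sequence: str) -> np.ndarray:
        return self.embed_many([sequence])[0]

    def embed_many(self, sequences: Sequence[str]) -> np.ndarray:
        L = self.config.L
        n = len(sequences)
        idx = np.empty((n, L), dtype=int)
        for i, seq in enumerate(sequences):
            if len(seq) != L:
                raise ValueError(f"sequence length {len(seq)} != L={L}")
            idx[i] = [AA_INDEX[a] for a in seq]
        eff = self.table.effects[np.arange(L)[None, :], idx]       # (n, L)
        signal = eff @ self._R_signal.T                            # (n, n_sig)
        parts = [signal]
        if self._R_background.shape[0] > 0:
            onehot = np.zeros((n, L, 20))
            onehot[np.arange(n)[:, None], np.arange(L)[None, :], idx] = 1.0
            parts.append(onehot.reshape(n, -1) @ self._R_background.T)
        return np.concatenate(parts, axis=1)

    def logprobs(self, wild_type: str) -> LogProbMatrix:
        if wild_type != self.table.wild_type:
            raise ValueError("wild type does not match the oracle's landscape")
        if self._logprobs is None:
            self._logprobs = synthetic_logprobs(self.config, self.table)
        return self._logprobs


def clustered_prediction_ensemble(n_per_cluster: int = 16, n_members: int = 5,
                                  gap: float = 1.0, within_sd: float = 0.05,
                                  member_sd: float = 0.5, noise_sd: float = 0.02,
                                  seed: int = 0):
    """A two-cluster correlated prediction ensemble for acquisition studies.

    Candidates are single mutants at two loci (positions 1 and 2; at most 19
    per locus). Within a cluster, ensemble members share a common per-member
    offset (std ``member_sd``), so the across-member covariance has a
    two-block structure; cluster 1 sits ``gap`` activity units above
    cluster 2. This is the regime where constant-liar's lie matters: a
    pessimistic observation on one cluster-1 candidate drags down its
    correlated siblings, so small α alternates clusters while large α
    exhausts the top cluster.

    Returns ``(PredictionEnsemble, {candidate_id: [Mutation]})``.
    """
    from .ranking import PredictionEnsemble

    if not 1 <= n_per_cluster <= 19:
        raise ValueError("n_per_cluster must be in 1..19 (19 mutant letters)")
    rng = np.random.default_rng(seed)
    wt0, wt1 = "A", "C"
    ids: list[str] = []
    mutations: dict[str, list[Mutation]] = {}
    base: list[float] = []
    cluster: list[int] = []
    for c, (wt, pos) in enumerate(((wt0, 1), (wt1, 2))):
        letters = [a for a in AA_ALPHABET if a != wt][:n_per_cluster]
        for aa in letters:
            m = Mutation(wt, pos, aa)
            ids.append(str(m))
            mutations[str(m)] = [m]
            base.append((gap if c == 0 else 0.0)
                        + float(rng.normal(0.0, within_sd)))
            cluster.append(c)
    base_arr = np.array(base)
    cl = np.array(cluster)
    raw = np.empty((n_members, len(ids)))
    for k in range(n_members):
        offsets = rng.normal(0.0, member_sd, size=2)
        raw[k] = base_arr + offsets[cl] + rng.normal(0.0, noise_sd,
                                                     size=len(ids))
    return PredictionEnsemble.from_member_scores(ids, raw), mutations


def make_oracle(config: SyntheticOracleConfig,
                name: str = "synthetic") -> tuple[Landscape, SyntheticOracle]:
    """Convenience: landscape plus matching oracle from one config."""
    landscape, table = generate_landscape(config, name=name)
    return landscape, SyntheticOracle(config, table)
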