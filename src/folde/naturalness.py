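"""Naturalness scoring and zero-shot batch selection.

Naturalness of a mutant is the log-likelihood ratio a protein language
model assigns to the mutant versus the wild-type residues, summed over the
mutated positions:

    Naturalness(x', x) = Σ_{i ∈ T} [log P(x'_i | x) − log P(x_i | x)]

computed from a single wild-type-marginal forward pass; separate mutations
are treated independently and their effects add in log space. Ranking all
single mutants by naturalness and taking the top of the list is the
zero-shot round-1 policy — no activity measurements needed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .landscape import AA_ALPHABET, Mutation
from .plm import LogProbMatrix
from .acquisition import Batch


@dataclasses.dataclass
class NaturalnessTable:
    """Naturalness of every possible single mutant of a wild type.

    One entry per (position, mutant letter) pair with the mutant letter
    differing from the wild type: L × 19 entries in total. Keys of
    ``entries`` are the mutation strings (e.g. ``"A24G"``).
    """

    entries: dict[str, float]
    wild_type: str

    def __len__(self) -> int:
        return len(self.entries)

    def mutation(self, key: str) -> Mutation:
        from .landscape import parse_mutation_string
        return parse_mutation_string(key)[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mutant": list(self.entries),
                           "naturalness": list(self.entries.values())})
        return df.sort_values("naturalness", ascending=False,
                              kind="stable").reset_index(drop=True)


def naturalness_score(mutations: Sequence[Mutation], lp: LogProbMatrix) -> float:
    """Wild-type-marginal naturalness of a (possibly multi-)mutant.

    The empty mutation set (the wild type itself) scores exactly 0.
    Raises if a position is out of range or a mutation's wild-type letter
    disagrees with the log-prob matrix's conditioning sequence.
    """
    total = 0.0
    for m in mutations:
        if not 1 <= m.position <= lp.length:
            raise IndexError(
                f"position {m.position} outside 1..{lp.length}")
        if lp.wild_type[m.position - 1] != m.wt_aa:
            raise ValueError(
                f"mutation {m} disagrees with wild type "
                f"({lp.wild_type[m.position - 1]!r} at {m.position})")
        total += lp.logp(m.position, m.mut_aa) - lp.logp(m.position, m.wt_aa)
    return total


def build_table(lp: LogProbMatrix) -> NaturalnessTable:
    """Score all L × 19 single mutants of the wild type."""
    entries: dict[str, float] = {}
    for p in range(1, lp.length + 1):
        wt = lp.wild_type[p - 1]
        base = lp.logp(p, wt)
        for aa in AA_ALPHABET:
            if aa == wt:
                continue
            m = Mutation(wt, p, aa)
            entries[str(m)] = lp.logp(p, aa) - base
    return NaturalnessTable(entries=entries, wild_type=lp.wild_type)


def zero_shot_select(table: NaturalnessTable, batch_size: int = 16,
                     max_per_locus: int | None = None,
                     exclude: Iterable[str] = ()) -> Batch:
    """Greedy descending-naturalness selection of single mutants.

    Candidates are visited from highest to lowest naturalness (ties broken
    lexicographically by (position, mutant letter), deterministic and
    seed-free). A candidate is skipped if its id is excluded, or — when
    ``max_per_locus`` is set — once its position already holds that many
    picks in the batch. Successive zero-shot batches are made disjoint by
    excluding the earlier ones.
    """
    excluded = set(exclude)
    ranked = sorted(table.entries.items(),
                    key=lambda kv: (-kv[1],
                                    table.mutation(kv[0]).position,
                                    table.mutation(kv[0]).mut_aa))
    per_locus: dict[int, int] = {}
    picks: list[str] = []
    trace: list[float] = []
    for key, score in ranked:
        if len(picks) >= batch_size:
            break
        if key in excluded:
            continue
        pos = table.mutation(key).position
        if max_per_locus is not None and per_locus.get(pos, 0) >= max_per_locus:
            continue
        picks.append(key)
        trace.append(score)
        per_locus[pos] = per_locus.get(pos, 0) + 1
    if len(picks) < batch_size:
        raise ValueError(
            f"zero-shot selection short by {batch_size - len(picks)}: "
            f"only {len(picks)} eligible candidates")
    return Batch(selected_ids=tuple(picks), selection_trace=tuple(trace))
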