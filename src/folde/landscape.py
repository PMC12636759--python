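"""Mutant landscape data model.

Mutation notation (ProteinGym dialect, e.g. ``"A24G"`` or ``"A24G:T56C"``),
deep-mutational-scanning tables used as simulation oracles, 50% holdout
splitting for bootstrapped benchmarks, and the engineering-difficulty
statistic.

Positions are 1-based throughout the public API; 0-based indexing is an
internal detail.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_MUTATION_RE = re.compile(r"^([A-Z])([0-9]+)([A-Z])$")


class MutationError(ValueError):
    """Malformed or inconsistent mutation notation."""


@dataclasses.dataclass(frozen=True)
class Mutation:
    """A single amino-acid substitution, e.g. A24G.

    Attributes
    ----------
    wt_aa : str
        Wild-type residue (one canonical letter).
    position : int
        1-based residue index.
    mut_aa : str
        Mutant residue; must differ from ``wt_aa``.
    """

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_INDEX:
            raise MutationError(f"non-canonical wild-type letter {self.wt_aa!r}")
        if self.mut_aa not in AA_INDEX:
            raise MutationError(f"non-canonical mutant letter {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise MutationError(
                f"synonymous token {self.wt_aa}{self.position}{self.mut_aa}: "
                "wild-type and mutant letters are equal"
            )
        if self.position < 1:
            raise MutationError(f"position {self.position} is not 1-based")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_mutation_string(s: str) -> list[Mutation]:
    """Parse a colon-separated mutation string such as ``"A24G:T56C"``.

    Raises :class:`MutationError` on malformed tokens, non-canonical letters,
    synonymous tokens, or duplicated positions.
    """
    if not isinstance(s, str) or not s.strip():
        raise MutationError("empty mutation string")
    mutations: list[Mutation] = []
    seen: set[int] = set()
    for token in s.strip().split(":"):
        m = _MUTATION_RE.match(token)
        if m is None:
            raise MutationError(f"malformed mutation token {token!r}")
        mut = Mutation(m.group(1), int(m.group(2)), m.group(3))
        if mut.position in seen:
            raise MutationError(f"duplicate position {mut.position} in {s!r}")
        seen.add(mut.position)
        mutations.append(mut)
    return mutations


def format_mutations(mutations: Sequence[Mutation]) -> str:
    """Inverse of :func:`parse_mutation_string`."""
    return ":".join(str(m) for m in mutations)


def apply_mutations(wild_type: str, mutations: Sequence[Mutation]) -> str:
    """Apply substitutions to the wild-type sequence.

    Every mutation's ``wt_aa`` must match ``wild_type`` at its position;
    a mismatch raises :class:`MutationError` naming the position.
    """
    seq = list(wild_type)
    for m in mutations:
        if m.position > len(wild_type):
            raise MutationError(
                f"position {m.position} beyond sequence length {len(wild_type)}"
            )
        if wild_type[m.position - 1] != m.wt_aa:
            raise MutationError(
                f"wild-type mismatch at position {m.position}: "
                f"sequence holds {wild_type[m.position - 1]!r}, "
                f"mutation expects {m.wt_aa!r}"
            )
        seq[m.position - 1] = m.mut_aa
    return "".join(seq)


@dataclasses.dataclass(frozen=True)
class MutantRecord:
    """One mutant: an id, its substitutions, and (optionally) an activity."""

    id: str
    mutations: tuple[Mutation, ...]
    activity: float | None = None
    measured: bool = False

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise MutationError(f"record {self.id}: duplicated mutated positions")

    @property
    def loci(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    @property
    def mutation_key(self) -> frozenset[tuple[int, str]]:
        """Order-free identity of the substitution set."""
        return frozenset((m.position, m.mut_aa) for m in self.mutations)


class Landscape:
    """A wild-type sequence plus mutant records with ground-truth activities.

    Acts as the simulation oracle: campaigns "measure" a mutant by looking up
    its activity here.
    """

    def __init__(self, wild_type: str, records: Iterable[MutantRecord],
                 name: str = "landscape") -> None:
        self.wild_type = str(wild_type)
        self.name = name
        self.records: list[MutantRecord] = list(records)
        self._by_id: dict[str, MutantRecord] = {}
        L = len(self.wild_type)
        for rec in self.records:
            if rec.id in self._by_id:
                raise ValueError(f"duplicate record id {rec.id!r}")
            for m in rec.mutations:
                if m.position > L:
                    raise MutationError(
                        f"record {rec.id}: position {m.position} beyond length {L}")
                if self.wild_type[m.position - 1] != m.wt_aa:
                    raise MutationError(
                        f"record {rec.id}: wild type holds "
                        f"{self.wild_type[m.position - 1]!r} at {m.position}, "
                        f"not {m.wt_aa!r}")
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def record(self, record_id: str) -> MutantRecord:
        return self._by_id[record_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def activity(self, record_id: str) -> float:
        a = self._by_id[record_id].activity
        if a is None:
            raise ValueError(f"record {record_id} has no ground-truth activity")
        return float(a)

    def activities(self, ids: Iterable[str] | None = None) -> np.ndarray:
        use = self.ids if ids is None else list(ids)
        return np.array([self.activity(i) for i in use], dtype=float)

    def sequence(self, record_id: str) -> str:
        return apply_mutations(self.wild_type, self._by_id[record_id].mutations)

    def single_mutant_ids(self) -> list[str]:
        return [r.id for r in self.records if len(r.mutations) == 1]


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Row accounting for :func:`read_dms_csv`."""

    n_rows: int
    n_loaded: int
    n_skipped_missing_score: int


def read_fasta_sequence(path: str | Path) -> str:
    """Read the first sequence from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return str(rec.seq).upper()
    raise ValueError(f"no sequences in FASTA file {path}")


def write_fasta_sequence(path: str | Path, sequence: str, name: str = "wild_type") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{sequence}\n")


def _reconstruct_wild_type(mutation_lists: Sequence[Sequence[Mutation]]) -> str:
    letters: dict[int, str] = {}
    for muts in mutation_lists:
        for m in muts:
            prev = letters.get(m.position)
            if prev is not None and prev != m.wt_aa:
                raise ValueError(
                    f"inconsistent wild-type letters at position {m.position}: "
                    f"{prev!r} vs {m.wt_aa!r}")
            letters[m.position] = m.wt_aa
    if not letters:
        raise ValueError("cannot reconstruct wild type: no mutations present")
    L = max(letters)
    missing = [p for p in range(1, L + 1) if p not in letters]
    if missing:
        raise ValueError(
            "wild-type reconstruction leaves gaps at positions "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}; "
            "supply a FASTA sidecar")
    return "".join(letters[p] for p in range(1, L + 1))


def read_dms_csv(path: str | Path,
                 mutant_column: str = "mutant",
                 score_column: str = "DMS_score",
                 wild_type: str | None = None,
                 fasta: str | Path | None = None,
                 name: str | None = None) -> tuple[Landscape, LoadReport]:
    """Load a ProteinGym-style deep-mutational-scanning table.

    Wild-type resolution precedence: explicit ``fasta`` sidecar, then the
    ``wild_type`` argument, then reconstruction from the per-row wild-type
    letters (an error if reconstruction leaves gaps). Rows with a missing
    score are skipped with a warning and counted in the returned
    :class:`LoadReport`.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty DMS table {path}")
    for col in (mutant_column, score_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")

    records: list[MutantRecord] = []
    mutation_lists: list[list[Mutation]] = []
    n_skipped = 0
    for mut_str, score in zip(df[mutant_column], df[score_column]):
        muts = parse_mutation_string(str(mut_str))
        if pd.isna(score):
            n_skipped += 1
            continue
        mutation_lists.append(muts)
        records.append(MutantRecord(id=str(mut_str), mutations=tuple(muts),
                                    activity=float(score)))
    if not records:
        raise ValueError(f"no usable rows in {path}")

    if fasta is not None:
        wt = read_fasta_sequence(fasta)
    elif wild_type is not None:
        wt = wild_type
    else:
        wt = _reconstruct_wild_type(mutation_lists)

    report = LoadReport(n_rows=len(df), n_loaded=len(records),
                        n_skipped_missing_score=n_skipped)
    if n_skipped:
        log.warning("read_dms_csv(%s): skipped %d rows with missing scores",
                    path, n_skipped)
    log.info("read_dms_csv(%s): loaded %d/%d rows", path, report.n_loaded,
             report.n_rows)
    return Landscape(wt, records, name=name or Path(path).stem), report


@dataclasses.dataclass(frozen=True)
class HoldoutSplit:
    """Accessible / held-out partition of a landscape's record ids."""

    accessible_ids: frozenset[str]
    held_out_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.accessible_ids & self.held_out_ids:
            raise ValueError("accessible and held-out sets overlap")


def holdout_split(landscape: Landscape, fraction: float = 0.5,
                  seed: int = 0) -> HoldoutSplit:
    """Hold out ``round(fraction * N)`` mutants, deterministically per seed.

    The held-out half never enters selection or training; it supports
    bootstrapped benchmark replicates and held-out ranking diagnostics.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"holdout fraction {fraction} outside (0, 1)")
    ids = sorted(landscape.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 records to split")
    n_held = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    held = frozenset(ids[i] for i in perm[:n_held])
    acc = frozenset(ids[i] for i in perm[n_held:])
    return HoldoutSplit(accessible_ids=acc, held_out_ids=held, seed=seed)


def difficulty(landscape: Landscape, percentile: float = 99.375) -> float:
    """Engineering difficulty of a landscape in [0, 1].

    The relative activity of the mutant at the given percentile (default
    99.375, i.e. the expected best of 10 rounds of 16 random picks):
    ``(A_q - A_min) / (A_max - A_min)``. Percentiles use linear interpolation
    between order statistics. A value near 1 means near-optimal mutants are
    common (easy); near 0 means they are rare (hard).
    """
    acts = landscape.activities()
    if len(np.unique(acts)) < 2:
        raise ValueError("difficulty undefined: all activities equal")
    a_min, a_max = float(acts.min()), float(acts.max())
    a_q = float(np.percentile(acts, percentile, method="linear"))
    return (a_q - a_min) / (a_max - a_min)
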