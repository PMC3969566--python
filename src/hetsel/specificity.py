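"""Incompatibility-specificity analysis of allele-by-tester reaction matrices.

A het-c allele's *specificity* is its binary pattern of incompatibility
reactions against the het-d / het-e tester alleles.  This module partitions
alleles into phenotypic classes (identical reaction rows), mines implication
hierarchies between testers (e.g. every allele incompatible with het-e3 is
also incompatible with het-e2), locates single-residue determinants of
specificity, and finds the smallest set of variable protein positions that
distinguishes every pair of classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class IncompatibilityMatrix:
    """Binary alleles x testers reaction matrix (1 = incompatible)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("allele and tester names must be unique")
        if not df.isin([0, 1]).all().all():
            raise ValueError("incompatibility entries must be 0/1")

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def testers(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def row_pattern(self, allele: str) -> tuple[int, ...]:
        return tuple(int(v) for v in self.data.loc[allele])

    def reaction_counts(self) -> pd.Series:
        """Number of incompatible reactions per allele (row sums)."""
        return self.data.sum(axis=1)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IncompatibilityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0).astype(int))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SpecificityClasses:
    """Partition of alleles into classes of identical reaction patterns.

    Classes are ordered and labelled by their first-seen member allele.
    """

    classes: tuple[tuple[str, ...], ...]
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.classes)

    def class_of(self, allele: str) -> str:
        for label, members in zip(self.labels, self.classes):
            if allele in members:
                return label
        raise KeyError(f"allele {allele!r} is not classified")

    def members(self, label: str) -> tuple[str, ...]:
        return self.classes[self.labels.index(label)]

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(a for members in self.classes for a in members)

    def as_dict(self) -> dict[str, list[str]]:
        return {lab: list(mem) for lab, mem in zip(self.labels, self.classes)}


def partition_classes(m: IncompatibilityMatrix) -> SpecificityClasses:
    """Group alleles whose reaction rows are identical.

    Deterministic: classes appear in order of their first member, and the
    label is that first-seen allele's name.
    """
    seen: dict[tuple[int, ...], list[str]] = {}
    order: list[tuple[int, ...]] = []
    for allele in m.alleles:
        pattern = m.row_pattern(allele)
        if pattern not in seen:
            seen[pattern] = []
            order.append(pattern)
        seen[pattern].append(allele)
    classes = tuple(tuple(seen[p]) for p in order)
    return SpecificityClasses(
        classes=classes, labels=tuple(members[0] for members in classes)
    )


@dataclass(frozen=True)
class ImplicationRule:
    """Tester implication A => B: alleles incompatible with A are (almost)
    always incompatible with B."""

    antecedent: str
    consequent: str
    support: int
    exceptions: tuple[str, ...]

    @property
    def strict(self) -> bool:
        return not self.exceptions


def implication_rules(
    m: IncompatibilityMatrix, max_exceptions: int = 0
) -> list[ImplicationRule]:
    """Mine A => B implications over every ordered tester pair.

    A rule is reported when at least one allele is incompatible with the
    antecedent (non-vacuous support) and the number of counterexample
    alleles does not exceed ``max_exceptions``.
    """
    rules = []
    for a, b in itertools.permutations(m.testers, 2):
        with_a = [al for al in m.alleles if m.data.at[al, a] == 1]
        if not with_a:
            continue
        exceptions = tuple(al for al in with_a if m.data.at[al, b] == 0)
        if len(exceptions) <= max_exceptions:
            rules.append(
                ImplicationRule(
                    antecedent=a,
                    consequent=b,
                    support=len(with_a) - len(exceptions),
                    exceptions=exceptions,
                )
            )
    return [r for r in rules if r.support >= 1]


# ---------------------------------------------------------------------------
# protein-position analysis


def _profiles(
    protein_table: pd.DataFrame, alleles: tuple[str, ...]
) -> tuple[list[int], dict[str, tuple[str, ...]]]:
    """Variable positions and each allele's residue profile over them."""
    positions = [int(p) for p in protein_table["position"]]
    missing = [a for a in alleles if a not in protein_table.columns]
    if missing:
        raise ValueError(f"protein table lacks residue columns for alleles {missing}")
    prof = {a: tuple(protein_table[a]) for a in alleles}
    return positions, prof


def _between_class_pairs(classes: SpecificityClasses):
    for (la, ma), (lb, mb) in itertools.combinations(
        list(zip(classes.labels, classes.classes)), 2
    ):
        for a, b in itertools.product(ma, mb):
            yield a, b


def minimal_discriminating_set(
    protein_table: pd.DataFrame,
    classes: SpecificityClasses,
    *,
    all_solutions: bool = False,
) -> list[int] | list[list[int]]:
    """Smallest set of variable residue positions separating every class pair.

    Any two alleles in *different* classes must differ at at least one
    position of the set; alleles within a class may differ freely (the
    same specificity can be carried by quite different sequences).  Search
    is exact, by increasing cardinality, over the variable positions:
    positions forced by allele pairs that differ at a single position are
    fixed first, which prunes the combinatorial search to a trivial size.
    Ties are resolved to the lexicographically smallest position set; with
    ``all_solutions=True`` every minimum-size solution is returned.
    """
    positions, prof = _profiles(protein_table, classes.alleles)

    # the set of differing positions for every between-class allele pair
    diff_sets: list[frozenset[int]] = []
    for a, b in _between_class_pairs(classes):
        diffs = frozenset(
            pos
            for pos, ra, rb in zip(positions, prof[a], prof[b])
            if ra != rb
        )
        if not diffs:
            raise ValueError(
                f"alleles {a!r} and {b!r} are in different classes but have "
                "identical residue profiles; no discriminating set exists"
            )
        diff_sets.append(diffs)

    forced = {next(iter(d)) for d in diff_sets if len(d) == 1}
    remaining = [d for d in diff_sets if not (d & forced)]
    candidates = sorted(
        {p for d in remaining for p in d}
    )  # only positions that can still help

    def covers(extra: tuple[int, ...]) -> bool:
        chosen = forced.union(extra)
        return all(d & chosen for d in remaining)

    solutions: list[list[int]] = []
    for k in range(0, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            if covers(combo):
                solutions.append(sorted(forced.union(combo)))
        if solutions:
            break
    solutions.sort()
    return solutions if all_solutions else solutions[0]


@dataclass(frozen=True)
class DeterminantRecord:
    """An allele pair differing at exactly one variable position."""

    position: int
    allele_a: str
    allele_b: str
    class_a: str
    class_b: str

    @property
    def causal(self) -> bool:
        """True when the single residue difference coincides with a
        specificity-class difference."""
        return self.class_a != self.class_b


def determinant_positions(
    protein_table: pd.DataFrame, classes: SpecificityClasses
) -> list[DeterminantRecord]:
    """All allele pairs separated by a single residue, labelled causal when
    their specificity classes differ."""
    positions, prof = _profiles(protein_table, classes.alleles)
    records = []
    for a, b in itertools.combinations(classes.alleles, 2):
        diffs = [
            pos for pos, ra, rb in zip(positions, prof[a], prof[b]) if ra != rb
        ]
        if len(diffs) == 1:
            records.append(
                DeterminantRecord(
                    position=diffs[0],
                    allele_a=a,
                    allele_b=b,
                    class_a=classes.class_of(a),
                    class_b=classes.class_of(b),
                )
            )
    records.sort(key=lambda r: (r.position, r.allele_a, r.allele_b))
    return records
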