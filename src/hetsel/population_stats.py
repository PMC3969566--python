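"""Population summaries: allele/class frequencies, the association between
allorecognition reactivity and allele frequency, and the senescence-plasmid
association test.

The haploid population sample is a table of isolate counts per allele.
Class frequencies coarsen allele frequencies through the specificity
partition.  The reactivity association is a Spearman rank correlation
between an allele's number of incompatible reactions (its reaction-matrix
row sum) and its population frequency.  The plasmid test tabulates
pAL2-1 presence against specificity class and computes an exact p-value
(Fisher for 2x2, seeded Monte Carlo conditional test for r x 2 —
small-sample data should not lean on an asymptotic chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .specificity import IncompatibilityMatrix, SpecificityClasses


@dataclass(frozen=True)
class PopulationSample:
    """Isolate counts per allele for one population."""

    counts: dict[str, int]
    label: str = "population"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("allele counts must be nonnegative")
        if self.total == 0:
            raise ValueError("population sample is empty")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        n = self.total
        return {a: c / n for a, c in self.counts.items()}

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "population") -> "PopulationSample":
        df = pd.read_csv(path, sep="\t")
        return cls(counts=dict(zip(df["allele"], df["count"].astype(int))), label=label)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"allele": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)


def class_frequencies(
    sample: PopulationSample, classes: SpecificityClasses
) -> dict[str, float]:
    """Frequency of each specificity class: summed member-allele counts / n."""
    unclassified = [a for a, c in sample.counts.items() if c > 0 and a not in classes.alleles]
    if unclassified:
        raise ValueError(f"sampled alleles without a specificity class: {unclassified}")
    n = sample.total
    return {
        label: sum(sample.counts.get(a, 0) for a in members) / n
        for label, members in zip(classes.labels, classes.classes)
    }


def reaction_count_association(
    sample: PopulationSample,
    m: IncompatibilityMatrix,
    *,
    include_absent: bool = True,
) -> tuple[float, float]:
    """Spearman rank correlation between per-allele reaction count and
    population frequency.

    With ``include_absent`` (default) alleles known to the reaction matrix
    but unobserved in the sample enter with frequency 0 — the absence of
    the most reactive alleles is part of the signal.  Returns (rho, p);
    rho is NaN when either variable is constant.
    """
    counts = m.reaction_counts()
    freqs = sample.frequencies()
    alleles = [
        a for a in m.alleles if include_absent or sample.counts.get(a, 0) > 0
    ]
    if len(alleles) < 3:
        raise ValueError("need at least 3 alleles for a rank correlation")
    x = np.array([counts[a] for a in alleles], dtype=float)
    y = np.array([freqs.get(a, 0.0) for a in alleles])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class PlasmidTable:
    """Per-isolate het-c allele and pAL2-1 plasmid presence."""

    records: tuple[tuple[str, bool], ...]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlasmidTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            records=tuple(
                (str(a), bool(int(p))) for a, p in zip(df["allele"], df["plasmid"])
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "allele": [a for a, _ in self.records],
                "plasmid": [int(p) for _, p in self.records],
            }
        ).to_csv(path, sep="\t", index=False)


def contingency_table(pt: PlasmidTable, classes: SpecificityClasses) -> pd.DataFrame:
    """Specificity classes x {plasmid+, plasmid-} count table."""
    table = pd.DataFrame(
        0, index=list(classes.labels), columns=["plasmid+", "plasmid-"]
    )
    for allele, present in pt.records:
        label = classes.class_of(allele)
        table.at[label, "plasmid+" if present else "plasmid-"] += 1
    return table.loc[table.sum(axis=1) > 0]


def _monte_carlo_fisher(
    table: np.ndarray, n_samples: int, seed: int
) -> float:
    """Conditional Monte Carlo exact test for an r x 2 table.

    Sampling is conditional on both margins (random bipartitions of the
    pooled isolates); the p-value is the fraction of sampled tables whose
    conditional probability does not exceed the observed one, with the
    usual +1 correction for the observed table itself.
    """
    from scipy.special import gammaln

    rows = table.sum(axis=1)
    col_plus = int(table[:, 0].sum())
    n = int(table.sum())

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    def table_logp(col0: np.ndarray) -> float:
        # conditional (both margins fixed) probability, via log-binomials
        return float(sum(logc(r, k) for r, k in zip(rows, col0)) - logc(n, col_plus))

    observed = table_logp(table[:, 0])
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(rows)), rows.astype(int))
    hits = 0
    for _ in range(n_samples):
        chosen = rng.choice(pool, size=col_plus, replace=False)
        col0 = np.bincount(chosen, minlength=len(rows))
        if table_logp(col0) <= observed + 1e-12:
            hits += 1
    return (hits + 1) / (n_samples + 1)


def plasmid_association(
    pt: PlasmidTable,
    classes: SpecificityClasses,
    *,
    n_samples: int = 10000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Contingency table and exact p-value for class/plasmid association.

    2x2 tables use Fisher's exact test; larger r x 2 tables a seeded
    Monte Carlo version of the exact conditional test.  Tables with an
    empty margin carry no information and return p = 1.
    """
    table = contingency_table(pt, classes)
    if table.empty:
        raise ValueError("plasmid table is empty")
    arr = table.to_numpy(dtype=int)
    if arr.shape[0] < 2 or (arr.sum(axis=0) == 0).any():
        return table, 1.0
    if arr.shape[0] == 2:
        _, p = stats.fisher_exact(arr)
        return table, float(p)
    return table, _monte_carlo_fisher(arr, n_samples, seed)
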