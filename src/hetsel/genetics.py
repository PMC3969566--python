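"""Genetic-code tables and codon bookkeeping shared across the package.

The codon substitution machinery works on the 61 sense codons of the
standard nuclear code (stop codons are excluded from the state space).
Tables are derived once, at import time, from Biopython's standard codon
table so that translation and the selection engine cannot drift apart.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: Codon -> amino acid for all 64 codons, stops mapped to "*".
CODON_TO_AA: dict[str, str] = {
    "".join(c): _STANDARD.forward_table.get("".join(c), "*")
    for c in itertools.product(NUCLEOTIDES, repeat=3)
}

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons in lexicographic (A<C<G<T) order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TO_AA) if c not in STOP_CODONS
)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

#: Amino acid encoded by each sense codon, aligned with SENSE_CODONS.
SENSE_AA: tuple[str, ...] = tuple(CODON_TO_AA[c] for c in SENSE_CODONS)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return frozenset((a, b)) in TRANSITIONS


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon]


def _single_change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute the single-nucleotide-change structure of the sense codons.

    Returns boolean (61, 61) arrays: ``one_change`` (codons differ at exactly
    one position), ``transition`` (that one change is a transition) and
    ``nonsyn`` (the change alters the encoded amino acid).
    """
    one = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    ts = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    nonsyn = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            one[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            nonsyn[i, j] = SENSE_AA[i] != SENSE_AA[j]
    return one, ts, nonsyn


ONE_CHANGE, CHANGE_IS_TRANSITION, CHANGE_IS_NONSYN = _single_change_tables()
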