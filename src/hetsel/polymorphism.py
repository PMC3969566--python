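"""Polymorphic-site accounting across an allele set.

Counts variable alignment columns, partitions them into intron and ORF
sites, labels ORF sites as silent or replacement, and tabulates the
protein-level variant positions.  A column counts once however many
states it carries (site-based, not mutation-based, accounting).

Silent/replacement labelling works per nucleotide site with
background-restricted single-site swaps: an exonic site is *silent* iff
for every codon actually observed at its codon position, exchanging the
site's observed nucleotide states never changes the encoded amino acid.
A codon position can therefore carry both one silent and one replacement
nucleotide site without being double-counted at either level.  The
attribution rule is exposed so the alternative codon-level attribution
can be computed from the same table if ever needed.
"""

from __future__ import annotations

import pandas as pd

from .genetics import CODON_TO_AA
from .io_annotation import AlleleSet, CodonAlignment, RegionAnnotation

SILENT = "silent"
REPLACEMENT = "replacement"
NOT_APPLICABLE = "not_applicable"

_COLUMNS = ["site", "region", "states", "codon_index", "coding_class"]


def polymorphic_sites(alleles: AlleleSet, ann: RegionAnnotation) -> pd.DataFrame:
    """Table of variable alignment columns with their region labels.

    One row per 1-based alignment position at which >=2 distinct
    nucleotides occur; ``codon_index`` (1-based) is filled for exonic
    sites, ``coding_class`` is left for :func:`classify_coding_sites`.
    """
    records = []
    for site in range(1, alleles.length + 1):
        states = {seq[site - 1] for seq in alleles.sequences}
        if len(states) < 2:
            continue
        region = ann.region_of(site)
        offset = ann.orf_offset(site)
        records.append(
            {
                "site": site,
                "region": region,
                "states": "".join(sorted(states)),
                "codon_index": (offset // 3) + 1 if offset is not None else pd.NA,
                "coding_class": NOT_APPLICABLE,
            }
        )
    return pd.DataFrame.from_records(records, columns=_COLUMNS).astype(
        {"codon_index": "Int64"}
    )


def _site_is_silent(states: str, backgrounds: set[str], offset_in_codon: int) -> bool:
    """Single-site swap test over every observed codon background."""
    for codon in backgrounds:
        aas = set()
        for state in states:
            swapped = codon[:offset_in_codon] + state + codon[offset_in_codon + 1 :]
            aas.add(CODON_TO_AA[swapped])
        if len(aas) > 1:
            return False
    return True


def classify_coding_sites(
    table: pd.DataFrame, ca: CodonAlignment, ann: RegionAnnotation
) -> pd.DataFrame:
    """Fill ``coding_class`` for exonic rows of a polymorphism table."""
    out = table.copy()
    for idx, row in out.iterrows():
        if row["region"] != "exon":
            continue
        offset = ann.orf_offset(int(row["site"]))
        if offset is None or (offset // 3) + 1 != row["codon_index"]:
            raise ValueError(
                f"site {row['site']}: codon_index inconsistent with the annotation"
            )
        backgrounds = set(ca.column(int(row["codon_index"])))
        silent = _site_is_silent(row["states"], backgrounds, offset % 3)
        out.at[idx, "coding_class"] = SILENT if silent else REPLACEMENT
    return out


def protein_variants(proteins: dict[str, str]) -> pd.DataFrame:
    """Variable residue positions of a protein alignment.

    One row per 1-based residue position (numbered from the initiator
    methionine) at which >=2 distinct amino acids occur, with the
    per-allele residues.
    """
    rows = list(proteins.values())
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("protein rows are not all the same length")
    records = []
    for pos in range(1, next(iter(lengths)) + 1):
        residues = {r[pos - 1] for r in rows}
        if len(residues) < 2:
            continue
        records.append(
            {
                "position": pos,
                "residues": "".join(sorted(residues)),
                **{name: seq[pos - 1] for name, seq in proteins.items()},
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["position", "residues", *proteins]
    )


def summarize(classified: pd.DataFrame, protein_table: pd.DataFrame) -> dict[str, int]:
    """Headline polymorphism counts as a JSON-friendly dict."""
    exon = classified[classified["region"] == "exon"]
    return {
        "total": int(len(classified)),
        "intron": int((classified["region"] == "intron").sum()),
        "orf": int(len(exon)),
        "silent": int((exon["coding_class"] == SILENT).sum()),
        "replacement": int((exon["coding_class"] == REPLACEMENT).sum()),
        "protein_positions": int(len(protein_table)),
    }
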