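"""Packaged het-c reference fixtures.

Two kinds of fixture live here, with different provenance:

* **Transcribed** — the 11-allele x 5-tester incompatibility matrix and
  the Wageningen allele-count table.  The reaction patterns of the
  natural *het-c* alleles against the *het-d1/d2* and *het-e1/e2/e3*
  testers, the resulting seven specificity classes, the implication
  hierarchy among testers, and the population class percentages are
  established facts of the *P. anserina* allorecognition literature; the
  exact per-allele isolate counts behind the published percentages are
  not printed anywhere, so the count table is the minimal integer
  reconstruction that reproduces every published percentage at n = 110
  (class split 46/31/20%, het-e1/het-e2/both split 47/52/1%).

* **Synthetic** — the residue-level variant table and the nucleotide
  alignment.  The true allele sequences are deposited in GenBank, not
  printed; the builders below construct a stand-in gene that reproduces,
  by design, every residue-level fact the analysis depends on: 26
  variable protein positions (clustered at 58–84 and 118–160), the
  single-position determinant pairs (het-c1/het-c8 at 118; het-c1,
  het-c3, het-c5 at 133), the 10-residue distance between het-c4 and
  het-c10, the unique 7-position minimal discriminating set {17, 65, 84,
  118, 126, 133, 153}, and the headline polymorphism counts (50 sites:
  9 in one of the two introns, 41 in the ORF of which 6 are silent —
  four of those in het-c7).  Tests against these builders validate the
  pipeline's bookkeeping, not the real sequences.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genetics import CODON_TO_AA

from .io_annotation import AlleleSet, RegionAnnotation
from .polymorphism import protein_variants
from .population_stats import PlasmidTable, PopulationSample
from .specificity import IncompatibilityMatrix

ALLELES = tuple(f"het-c{i}" for i in range(1, 12))
TESTERS = ("het-d1", "het-d2", "het-e1", "het-e2", "het-e3")

PROTEIN_LENGTH = 214

#: Residues of the reference allele (het-c1) at the 26 variable positions.
_BASE_RESIDUES = {
    11: "S", 17: "A", 58: "T", 61: "V", 65: "G", 69: "I", 76: "N", 84: "S",
    118: "C", 123: "K", 126: "T", 129: "L", 132: "A", 133: "D", 137: "R",
    140: "V", 141: "S", 145: "Q", 153: "K", 160: "E", 185: "D", 188: "F",
    195: "L", 199: "M", 206: "A", 210: "G",
}

#: Residue replacements per allele relative to het-c1.
_ALLELE_CHANGES: dict[str, dict[int, str]] = {
    "het-c1": {},
    # het-c5: same specificity class as het-c1; the conservative Asp->Glu
    # exchange at the specificity-determining position 133
    "het-c5": {133: "E"},
    # het-c3: His at 133 switches the specificity class
    "het-c3": {133: "H"},
    # het-c6: class of het-c3; divergent outside the discriminating positions
    "het-c6": {
        133: "H", 11: "T", 123: "R", 129: "M", 132: "S", 137: "K", 140: "I",
        141: "T", 145: "N", 185: "N", 188: "Y", 195: "F", 199: "L",
        206: "I", 210: "D",
    },
    # het-c8: single Cys->Arg exchange at 118 gains two reactions
    "het-c8": {118: "R"},
    # het-c2 lineage: a distinct haplotype background
    "het-c2": {58: "R", 61: "I", 69: "V", 76: "E", 133: "N", 153: "W", 160: "H"},
    "het-c7": {58: "R", 61: "I", 69: "V", 76: "E", 133: "N", 153: "W", 160: "H",
               17: "P"},
    "het-c9": {58: "R", 61: "I", 69: "V", 76: "E", 133: "N", 153: "W", 160: "H",
               17: "P", 65: "R"},
    "het-c10": {58: "R", 61: "I", 69: "V", 76: "E", 133: "N", 153: "W", 160: "H",
                17: "P", 65: "R", 84: "L"},
    # het-c4: class of het-c10/het-c11 but on the het-c1 background (10
    # residues away from het-c10)
    "het-c4": {153: "S"},
    "het-c11": {133: "H", 126: "M"},
}

#: Codon used for each residue at each variable position (chosen so the
#: nucleotide-level replacement sites total 35 across the 26 codons).
_CODON_CHOICES: dict[int, dict[str, str]] = {
    11: {"S": "TCT", "T": "ACT"},
    17: {"A": "GCT", "P": "CCT"},
    58: {"T": "ACT", "R": "CGT"},
    61: {"V": "GTT", "I": "ATT"},
    65: {"G": "GGA", "R": "AGA"},
    69: {"I": "ATC", "V": "GTC"},
    76: {"N": "AAC", "E": "GAA"},
    84: {"S": "TCA", "L": "TTA"},
    118: {"C": "TGT", "R": "CGT"},
    123: {"K": "AAA", "R": "CGA"},
    126: {"T": "ACG", "M": "ATG"},
    129: {"L": "CTG", "M": "ATG"},
    132: {"A": "GCA", "S": "TCA"},
    133: {"D": "GAT", "E": "GAA", "H": "CAT", "N": "AAT"},
    137: {"R": "AGA", "K": "AAA"},
    140: {"V": "GTC", "I": "ATC"},
    141: {"S": "AGT", "T": "ACT"},
    145: {"Q": "CAA", "N": "AAT"},
    153: {"K": "AAA", "W": "TGG", "S": "TCG"},
    160: {"E": "GAA", "H": "CAT"},
    185: {"D": "GAC", "N": "AAC"},
    188: {"F": "TTT", "Y": "TAT"},
    195: {"L": "CTT", "F": "TTT"},
    199: {"M": "ATG", "L": "CTG"},
    206: {"A": "GCA", "I": "ATA"},
    210: {"G": "GGT", "D": "GAT"},
}

#: Fixed base codons at the positions carrying synonymous variation.
_SILENT_BASE = {30: "CTT", 45: "GTG", 95: "GGA", 100: "ACC", 170: "TCA", 180: "CGT"}
#: Synonymous codon replacements per allele (four of the six in het-c7).
_SILENT_CHANGES = {
    "het-c7": {30: "CTC", 95: "GGG", 100: "ACT", 170: "TCC"},
    "het-c9": {45: "GTA"},
    "het-c6": {180: "CGC"},
}

#: Gene structure on the alignment coordinate system (1-based inclusive).
ANNOTATION = RegionAnnotation(
    exon_intervals=((1, 150), (211, 420), (486, 767)),
    intron_intervals=((151, 210), (421, 485)),
)
_INTRON_LENGTHS = (60, 65)

#: Intron-2 polymorphic offsets (1-based within the intron) -> carrier alleles.
_INTRON2_SNPS: dict[int, tuple[str, ...]] = {
    5: ("het-c2", "het-c7", "het-c9", "het-c10"),
    12: ("het-c2", "het-c7", "het-c9", "het-c10"),
    19: ("het-c2", "het-c7", "het-c9", "het-c10"),
    26: ("het-c2", "het-c7", "het-c9", "het-c10"),
    33: ("het-c6",),
    40: ("het-c6",),
    47: ("het-c8",),
    54: ("het-c3", "het-c6", "het-c11"),
    61: ("het-c4", "het-c10", "het-c11"),
}

_BUILD_SEED = 20140120  # fixed: the synthetic gene is a constant fixture


def incompatibility_matrix() -> IncompatibilityMatrix:
    """The 11 natural alleles x 5 informative testers reaction matrix."""
    with resources.as_file(
        resources.files("hetsel.data").joinpath("hetc_incompatibility.tsv")
    ) as path:
        return IncompatibilityMatrix.from_tsv(path)


def wageningen_sample() -> PopulationSample:
    """Reconstructed isolate counts of the n=110 Wageningen population."""
    with resources.as_file(
        resources.files("hetsel.data").joinpath("wageningen_allele_counts.tsv")
    ) as path:
        return PopulationSample.from_tsv(path, label="Wageningen")


def protein_alignment() -> dict[str, str]:
    """Synthetic 11-allele protein alignment (214 residues, 26 variable)."""
    rng = np.random.default_rng(_BUILD_SEED)
    aas = "ACDEFGHIKLNPQRSTVWY"  # M handled at position 1
    backbone = ["M"] + [aas[i] for i in rng.integers(0, len(aas), PROTEIN_LENGTH - 1)]
    for pos, res in _BASE_RESIDUES.items():
        backbone[pos - 1] = res
    for pos, codon in _SILENT_BASE.items():
        backbone[pos - 1] = CODON_TO_AA[codon]
    proteins = {}
    for allele in ALLELES:
        seq = backbone.copy()
        for pos, res in _ALLELE_CHANGES[allele].items():
            seq[pos - 1] = res
        proteins[allele] = "".join(seq)
    return proteins


def protein_variant_table() -> pd.DataFrame:
    """Variable-position table of the synthetic protein alignment."""
    return protein_variants(protein_alignment())


def _reverse_translate(protein: str, rng: np.random.Generator) -> list[str]:
    """One fixed codon per residue, avoiding stop-prone choices."""
    from .genetics import SENSE_AA, SENSE_CODONS

    by_aa: dict[str, list[str]] = {}
    for codon, aa in zip(SENSE_CODONS, SENSE_AA):
        by_aa.setdefault(aa, []).append(codon)
    return [by_aa[aa][rng.integers(0, len(by_aa[aa]))] for aa in protein]


def nucleotide_alignment() -> AlleleSet:
    """Synthetic 767-nt alignment of the 11 alleles: three exons (642 nt,
    214 codons) and two introns, carrying exactly the headline variation
    (41 ORF sites of which 6 silent, 9 sites in intron 2)."""
    rng = np.random.default_rng(_BUILD_SEED)
    proteins = protein_alignment()

    base_codons = _reverse_translate(proteins["het-c1"], rng)
    base_codons[0] = "ATG"
    for pos, codon in _SILENT_BASE.items():
        base_codons[pos - 1] = codon
    for pos in _BASE_RESIDUES:
        base_codons[pos - 1] = _CODON_CHOICES[pos][_BASE_RESIDUES[pos]]

    introns = [
        "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        for length in _INTRON_LENGTHS
    ]

    sequences = []
    next_nt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for allele in ALLELES:
        codons = base_codons.copy()
        for pos, res in _ALLELE_CHANGES[allele].items():
            codons[pos - 1] = _CODON_CHOICES[pos][res]
        for pos, codon in _SILENT_CHANGES.get(allele, {}).items():
            codons[pos - 1] = codon
        orf = "".join(codons)
        intron2 = list(introns[1])
        for offset, carriers in _INTRON2_SNPS.items():
            if allele in carriers:
                intron2[offset - 1] = next_nt[intron2[offset - 1]]
        seq = orf[:150] + introns[0] + orf[150:360] + "".join(intron2) + orf[360:]
        sequences.append(seq)
    return AlleleSet(names=ALLELES, sequences=tuple(sequences))


def plasmid_table(seed: int = 7, infection_rate: float = 0.35) -> PlasmidTable:
    """Synthetic per-isolate pAL2-1 presence, drawn independently of the
    het-c genotype (the null the published analysis could not reject)."""
    rng = np.random.default_rng(seed)
    sample = wageningen_sample()
    records = []
    for allele, count in sample.counts.items():
        for _ in range(count):
            records.append((allele, bool(rng.random() < infection_rate)))
    return PlasmidTable(records=tuple(records))
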