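"""Sequence input/output, region annotation and ORF extraction.

The unit of analysis is an aligned set of allele sequences of one gene
(here the *het-c* glycolipid-transfer-protein gene of *Podospora
anserina*).  The natural alleles carry no indel polymorphism, so an
"alignment" is simply a set of equal-length sequences and a single
1-based coordinate system covers every allele.  Exon/intron structure is
supplied as an explicit annotation (the coordinates come from the
reference GenBank record or from user configuration, not from de novo
ORF finding).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STOP_CODONS, reverse_complement, translate_codon

_VALID = re.compile(r"^[ACGT]+$")


class SequenceFormatError(ValueError):
    """Raised for malformed or unsupported sequence input."""


@dataclass(frozen=True)
class AlleleSet:
    """Ordered set of equal-length, gap-free nucleotide allele sequences."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise SequenceFormatError("names and sequences differ in number")
        if len(self.names) < 2:
            raise SequenceFormatError("an allele set needs at least 2 alleles")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise SequenceFormatError(f"duplicate allele identifiers: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise SequenceFormatError(
                f"sequences are not all the same length (saw lengths {sorted(lengths)}); "
                "aligned, indel-free input is required"
            )
        for name, seq in zip(self.names, self.sequences):
            if not _VALID.match(seq):
                bad = sorted(set(seq) - set("ACGT"))
                raise SequenceFormatError(
                    f"sequence {name!r} contains non-ACGT characters {bad}; "
                    "IUPAC ambiguity codes are not accepted — resolve them upstream"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> str:
        return self.sequences[self.names.index(name)]


def read_fasta(path: str | Path | io.TextIOBase) -> AlleleSet:
    """Read an aligned FASTA file into an :class:`AlleleSet`.

    Record order is preserved, sequence letters are uppercased, and
    duplicate identifiers or ambiguity codes are rejected.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise SequenceFormatError(f"no FASTA records found in {path!r}")
    names = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper().replace("U", "T") for r in records)
    return AlleleSet(names=names, sequences=seqs)


def write_fasta(alleles: AlleleSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(alleles.names, alleles.sequences)
    ]
    SeqIO.write(records, path, "fasta")


Interval = tuple[int, int]  # 1-based, inclusive


@dataclass(frozen=True)
class RegionAnnotation:
    """Exon/intron intervals on the alignment coordinate system.

    Intervals are 1-based inclusive ``(start, end)`` pairs on the forward
    strand, non-overlapping and sorted; the concatenated exon length must
    be divisible by 3 (it is the ORF).
    """

    exon_intervals: tuple[Interval, ...]
    intron_intervals: tuple[Interval, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.exon_intervals:
            raise ValueError("at least one exon interval is required")
        everything = sorted(self.exon_intervals + self.intron_intervals)
        for (s, e) in everything:
            if not (1 <= s <= e):
                raise ValueError(f"bad interval ({s}, {e}): need 1 <= start <= end")
        for (_, e1), (s2, _) in zip(everything, everything[1:]):
            if s2 <= e1:
                raise ValueError("exon/intron intervals overlap")
        if self.exon_length % 3 != 0:
            raise ValueError(
                f"concatenated exon length {self.exon_length} is not divisible by 3"
            )

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exon_intervals)

    @property
    def span(self) -> int:
        return max(e for _, e in self.exon_intervals + self.intron_intervals)

    def region_of(self, site: int) -> str:
        """Classify a 1-based alignment position as 'exon', 'intron' or 'other'."""
        for s, e in self.exon_intervals:
            if s <= site <= e:
                return "exon"
        for s, e in self.intron_intervals:
            if s <= site <= e:
                return "intron"
        return "other"

    def orf_offset(self, site: int) -> int | None:
        """0-based position within the spliced ORF for an exonic site, else None."""
        offset = 0
        for s, e in self.exon_intervals:
            if s <= site <= e:
                return offset + (site - s)
            offset += e - s + 1
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionAnnotation":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            exon_intervals=tuple(tuple(iv) for iv in cfg["exons"]),
            intron_intervals=tuple(tuple(iv) for iv in cfg.get("introns", ())),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "exons": [list(iv) for iv in self.exon_intervals],
                    "introns": [list(iv) for iv in self.intron_intervals],
                },
                fh,
            )


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame codon matrix over named alleles (no internal stop codons)."""

    names: tuple[str, ...]
    rows: tuple[str, ...]  # spliced ORF nucleotide strings, length 3*H

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
            raise SequenceFormatError("ORF rows must share one length divisible by 3")
        for name, row in zip(self.names, self.rows):
            for h in range(len(row) // 3):
                codon = row[3 * h : 3 * h + 3]
                if codon in STOP_CODONS:
                    raise SequenceFormatError(
                        f"internal stop codon {codon} at codon {h + 1} of {name!r}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codon(self, name: str, h: int) -> str:
        """Codon at 1-based codon position ``h`` of allele ``name``."""
        row = self.rows[self.names.index(name)]
        return row[3 * (h - 1) : 3 * h]

    def column(self, h: int) -> tuple[str, ...]:
        """All alleles' codons at 1-based codon position ``h``."""
        return tuple(r[3 * (h - 1) : 3 * h] for r in self.rows)


def extract_region(alleles: AlleleSet, intervals: tuple[Interval, ...]) -> dict[str, str]:
    """Concatenate the given 1-based inclusive intervals for every allele."""
    for s, e in intervals:
        if e > alleles.length:
            raise ValueError(
                f"interval ({s}, {e}) extends beyond alignment length {alleles.length}"
            )
    return {
        n: "".join(seq[s - 1 : e] for s, e in intervals)
        for n, seq in zip(alleles.names, alleles.sequences)
    }


def extract_orf(alleles: AlleleSet, ann: RegionAnnotation) -> CodonAlignment:
    """Splice the exon intervals of every allele into an in-frame codon matrix."""
    if ann.span > alleles.length:
        raise ValueError(
            f"annotation spans {ann.span} nt but alignment is {alleles.length} nt"
        )
    spliced = extract_region(alleles, ann.exon_intervals)
    return CodonAlignment(names=alleles.names, rows=tuple(spliced[n] for n in alleles.names))


def extract_introns(alleles: AlleleSet, ann: RegionAnnotation) -> dict[str, str]:
    """Concatenated intron content per allele, kept for the site partition."""
    if not ann.intron_intervals:
        return {n: "" for n in alleles.names}
    return extract_region(alleles, ann.intron_intervals)


def translate(ca: CodonAlignment) -> dict[str, str]:
    """Translate every row with the standard code; residues numbered 1-based
    from the initiator methionine."""
    return {
        name: "".join(translate_codon(row[3 * h : 3 * h + 3]) for h in range(len(row) // 3))
        for name, row in zip(ca.names, ca.rows)
    }


class PrimerMatchError(ValueError):
    """Raised when a primer has zero or multiple binding sites."""


def _unique_match(template: str, site: str, label: str) -> int:
    hits = [m.start() for m in re.finditer(re.escape(site), template)]
    if len(hits) != 1:
        raise PrimerMatchError(
            f"{label} primer has {len(hits)} matches on the template; exactly one required"
        )
    return hits[0]


def in_silico_pcr(template: str, primer_fwd: str, primer_rev: str) -> int:
    """Predicted amplicon length (bp) for one primer pair on a template.

    The forward primer is matched on the given strand, the reverse primer
    as its reverse complement; each must match exactly once.  The product
    runs from the first base of the forward site to the last base of the
    reverse site, inclusive.
    """
    template = template.upper()
    fwd = primer_fwd.upper()
    rev = reverse_complement(primer_rev.upper())
    start = _unique_match(template, fwd, "forward")
    rev_start = _unique_match(template, rev, "reverse")
    end = rev_start + len(rev) - 1
    if end < start:
        raise PrimerMatchError("reverse-primer site lies upstream of the forward site")
    return end - start + 1
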