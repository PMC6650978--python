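"""Core domain types shared by every stage of the pipeline.

Coordinate convention: every interval held in memory is 0-based,
half-open ``[start, end)``.  GFF3 emission/parsing converts to and from
the 1-based inclusive convention at the file boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

SUBGENOMES = ("A", "B", "D")
CHROMOSOME_NUMBERS = tuple(range(1, 8))

_CHROM_RE = re.compile(r"^chr([1-7])([ABD])$")


class PolyfamError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PolyfamError):
    """A file did not conform to the expected text format."""


class StructuralError(PolyfamError):
    """A gene model violated a structural invariant (carries gene_id)."""


@dataclass(frozen=True, order=True)
class ChromosomeId:
    """One of the 21 chromosomes of a hexaploid: number 1-7 x subgenome A/B/D."""

    number: int
    subgenome: str

    def __post_init__(self) -> None:
        if self.number not in CHROMOSOME_NUMBERS:
            raise ValueError(f"chromosome number must be 1-7, got {self.number}")
        if self.subgenome not in SUBGENOMES:
            raise ValueError(f"subgenome must be one of A/B/D, got {self.subgenome!r}")

    @property
    def name(self) -> str:
        return f"chr{self.number}{self.subgenome}"

    @classmethod
    def from_name(cls, name: str) -> "ChromosomeId":
        m = _CHROM_RE.match(name)
        if m is None:
            raise FormatError(f"cannot parse chromosome name {name!r} (expected e.g. 'chr3B')")
        return cls(int(m.group(1)), m.group(2))

    def is_homoeologous_position(self, other: "ChromosomeId") -> bool:
        """Same chromosome number on a different subgenome."""
        return self.number == other.number and self.subgenome != other.subgenome

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


_VALID_NT = set("ACGTN")


@dataclass
class GenomeAssembly:
    """Chromosome-keyed nucleotide sequences (uppercase ACGTN)."""

    chromosomes: dict[ChromosomeId, str]

    def __post_init__(self) -> None:
        for cid, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {cid.name} has empty sequence")
            extra = set(seq) - _VALID_NT
            if extra:
                raise ValueError(f"chromosome {cid.name} contains invalid characters {extra}")

    def __getitem__(self, cid: ChromosomeId) -> str:
        return self.chromosomes[cid]

    def __contains__(self, cid: ChromosomeId) -> bool:
        return cid in self.chromosomes

    def length(self, cid: ChromosomeId) -> int:
        return len(self.chromosomes[cid])


@dataclass
class GeneModel:
    """A gene: location, exon structure, spliced CDS and protein.

    ``exons`` are genomic intervals (0-based half-open), non-overlapping and
    sorted by start regardless of strand.  ``cds`` is the spliced coding
    sequence in transcription order (reverse-complemented for minus-strand
    genes) and excludes the terminal stop codon; ``protein`` is its
    translation, so ``len(protein) == len(cds) // 3``.
    """

    gene_id: str
    chromosome: ChromosomeId
    strand: str
    exons: list[tuple[int, int]]
    cds: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise StructuralError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise StructuralError(f"{self.gene_id}: gene must have at least one exon")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise StructuralError(f"{self.gene_id}: empty or inverted exon ({start},{end})")
            if start < prev_end:
                raise StructuralError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if len(self.cds) % 3 != 0:
            raise StructuralError(f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3")
        if len(self.protein) != len(self.cds) // 3:
            raise StructuralError(
                f"{self.gene_id}: protein length {len(self.protein)} != CDS/3 {len(self.cds) // 3}"
            )

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def exon_cds_lengths(self) -> list[int]:
        """Per-exon CDS lengths in transcription order."""
        lengths = [end - start for start, end in self.exons]
        if self.strand == "-":
            lengths.reverse()
        return lengths

    def cds_intron_offsets(self) -> list[int]:
        """Intron positions as offsets into the spliced CDS (transcription order).

        An offset p means the intron falls between CDS bases p-1 and p.
        """
        lengths = self.exon_cds_lengths()
        offsets = []
        acc = 0
        for length in lengths[:-1]:
            acc += length
            offsets.append(acc)
        return offsets


TISSUES = ("grain", "spike", "leaf", "root")
TREATMENTS = ("control", "drought", "heat", "drought_heat")


@dataclass(frozen=True)
class ExpressionSampleMeta:
    """Metadata for one RNA-seq library."""

    sample_id: str
    tissue: str
    treatment: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def genes_by_id(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in out:
            raise StructuralError(f"duplicate gene id {g.gene_id}")
        out[g.gene_id] = g
    return out
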