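"""Readers and writers for FASTA, GFF3 and the TSV tables exchanged between stages.

GFF3 files carry 1-based inclusive coordinates; everything in memory is
0-based half-open.  The conversion happens here and only here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .models import (
    ChromosomeId,
    FormatError,
    GeneModel,
    GenomeAssembly,
    StructuralError,
)

logger = logging.getLogger(__name__)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


class TranslationError(StructuralError):
    """CDS could not be translated; carries the offending codon index."""

    def __init__(self, message: str, codon_index: int | None = None):
        super().__init__(message)
        self.codon_index = codon_index


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    A terminal stop codon is dropped silently; an internal stop raises
    :class:`TranslationError` carrying the codon index.  Codons containing
    N translate to 'X' unless unambiguous.
    """
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    n_codons = len(cds) // 3
    residues = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            if i == n_codons - 1:
                break
            raise TranslationError(f"internal stop codon at codon index {i}", codon_index=i)
        aa = _CODON_TABLE.get(codon)
        residues.append(aa if aa is not None else "X")
    return "".join(residues)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{record_id: uppercase sequence}`` map."""
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: FASTA must start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as out:
        for rid, seq in records.items():
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_assembly(path: str | Path) -> GenomeAssembly:
    """Read a genome FASTA whose record names follow the chr{1-7}{A|B|D} dialect."""
    raw = read_fasta(path)
    return GenomeAssembly({ChromosomeId.from_name(name): seq for name, seq in raw.items()})


def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    write_fasta({cid.name: seq for cid, seq in assembly.chromosomes.items()}, path)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def splice_cds(assembly: GenomeAssembly, chromosome: ChromosomeId, strand: str,
               exons: list[tuple[int, int]]) -> str:
    """Extract and splice the CDS for exon intervals (0-based half-open)."""
    chrom_seq = assembly[chromosome]
    parts = [chrom_seq[start:end] for start, end in sorted(exons)]
    cds = "".join(parts)
    if strand == "-":
        cds = _revcomp(cds)
    return cds


def read_gff3(path: str | Path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into :class:`GeneModel` objects.

    Exon structure is taken from CDS features (this pipeline works at the
    coding-gene level, where exons are fully coding).  A gene with several
    mRNAs keeps the transcript with the longest CDS and logs a warning.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        try:
            chromosome = ChromosomeId.from_name(gene.seqid)
        except FormatError as exc:
            raise FormatError(f"{path}: gene {gene.id}: unknown seqid {gene.seqid!r}") from exc
        if chromosome not in assembly:
            raise FormatError(f"{path}: gene {gene.id}: seqid {gene.seqid} not in assembly")
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            mrnas = [gene]
        best_exons: list[tuple[int, int]] | None = None
        for mrna in mrnas:
            cds_feats = list(db.children(mrna, featuretype="CDS", order_by="start"))
            if not cds_feats:
                continue
            exons = [(f.start - 1, f.end) for f in cds_feats]  # GFF3 1-based incl -> half-open
            if best_exons is None or sum(e - s for s, e in exons) > sum(
                e - s for s, e in best_exons
            ):
                if best_exons is not None:
                    logger.warning(
                        "gene %s has multiple transcripts; keeping the longest CDS", gene.id
                    )
                best_exons = exons
        if best_exons is None:
            raise StructuralError(f"{path}: gene {gene.id} has no CDS features")
        cds = splice_cds(assembly, chromosome, gene.strand, best_exons)
        if len(cds) % 3 != 0:
            raise StructuralError(
                f"gene {gene.id}: CDS length {len(cds)} not divisible by 3"
            )
        protein = translate(cds)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=chromosome,
                strand=gene.strand,
                exons=best_exons,
                cds=cds,
                protein=protein,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "polyfam") -> None:
    """Emit gene/mRNA/exon/CDS features, converting to 1-based inclusive coordinates."""
    path = Path(path)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            seqid = g.chromosome.name
            gstart, gend = g.start + 1, g.end
            out.write(
                f"{seqid}\t{source}\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            out.write(
                f"{seqid}\t{source}\tmRNA\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            phase = 0
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            for i, (start, end) in enumerate(exons, 1):
                out.write(
                    f"{seqid}\t{source}\texon\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (start, end) in enumerate(exons, 1):
                out.write(
                    f"{seqid}\t{source}\tCDS\t{start + 1}\t{end}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )
                phase = (3 - ((end - start) - phase) % 3) % 3


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_chromosome_map(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Tabular replacement for a chromosome-map figure."""
    rows = [
        {
            "gene_id": g.gene_id,
            "chromosome": g.chromosome.name,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for g in genes
    ]
    write_tsv(pd.DataFrame(rows), path)
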