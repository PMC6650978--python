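"""Intron-structure classification and retrotransposition signature scanning.

Gene-structure classes follow the standard scheme for this family:
Type Ia = one intron (subdivided by whether the intron sits at the
ancestral conserved position, recognisable by a fixed-length terminal
coding exon of 174 bp), Type Ib = intronless, Type II = more than one
intron.  Intron-position conservation between two one-intron genes is
decided on a global alignment of the coding sequences: the intron must
fall between the same two aligned, non-gap columns in both.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import GlobalAlignment, gap_runs, global_align_nt, revcomp
from .models import GeneModel, GenomeAssembly

CONSERVED_SECOND_EXON_LENGTH = 174


def classify_by_intron_count(gene: GeneModel) -> str:
    """TypeIb (0 introns), TypeIa (1), TypeII (>1). Conservation resolved separately."""
    n = gene.intron_count
    if n == 0:
        return "TypeIb"
    if n == 1:
        return "TypeIa"
    return "TypeII"


def _require_single_intron(gene: GeneModel) -> int:
    if gene.intron_count != 1:
        raise ValueError(
            f"{gene.gene_id}: expected exactly one intron, found {gene.intron_count}"
        )
    return gene.cds_intron_offsets()[0]


def canonical_conserved_rule(gene: GeneModel,
                             second_exon_length: int = CONSERVED_SECOND_EXON_LENGTH) -> bool:
    """True iff the CDS downstream of the single intron is exactly 174 bp."""
    offset = _require_single_intron(gene)
    return len(gene.cds) - offset == second_exon_length


def intron_position_conserved(gene: GeneModel, reference: GeneModel) -> bool:
    """Conserved iff both introns fall at the same column of the CDS alignment,
    flanked on both sides by residue-residue (non-gap) columns."""
    off_a = _require_single_intron(gene)
    off_b = _require_single_intron(reference)
    aln = global_align_nt(gene.cds, reference.cds)
    col_a = aln.column_of_a_position(off_a)
    aln_b = GlobalAlignment(aln.row_b, aln.row_a)
    col_b = aln_b.column_of_a_position(off_b)
    if col_a != col_b:
        return False
    col = col_a
    if col == 0 or col >= aln.n_columns:
        return False  # intron at the alignment edge has no flanking aligned pair
    for c in (col - 1, col):
        if aln.row_a[c] == "-" or aln.row_b[c] == "-":
            return False
    return True


def classify_structure(
    gene: GeneModel,
    reference: GeneModel | None = None,
    second_exon_length: int = CONSERVED_SECOND_EXON_LENGTH,
) -> str:
    """Full four-way structural class for one gene.

    One-intron genes are split into conserved/non-conserved intron position
    using the fixed-length terminal-exon rule, corroborated by the alignment
    test against ``reference`` when one is supplied.
    """
    base = classify_by_intron_count(gene)
    if base != "TypeIa":
        return base
    conserved = canonical_conserved_rule(gene, second_exon_length)
    if conserved and reference is not None and reference.intron_count == 1:
        conserved = intron_position_conserved(gene, reference)
    return "TypeIa_conserved" if conserved else "TypeIa_nonconserved"


@dataclass
class ExonIndelReport:
    gene_id: str
    reference_id: str
    net_indel_bp: int
    events: list[tuple[int, int, str]]  # (gene-relative position, length, kind)


def _second_exon_cds(gene: GeneModel) -> str:
    if len(gene.exons) < 2:
        raise ValueError(f"{gene.gene_id}: no second exon")
    lengths = gene.exon_cds_lengths()
    return gene.cds[lengths[0] : lengths[0] + lengths[1]]


def detect_second_exon_indels(gene: GeneModel, reference: GeneModel) -> ExonIndelReport:
    """Report insertion/deletion events in the second exon relative to a reference.

    Positions are offsets into the gene's second-exon CDS; insertions are
    bases the gene carries that the reference lacks, deletions the reverse.
    ``net_indel_bp`` is the signed sum (insertions positive).
    """
    seg_gene = _second_exon_cds(gene)
    seg_ref = _second_exon_cds(reference)
    aln = global_align_nt(seg_gene, seg_ref)
    events: list[tuple[int, int, str]] = []
    net = 0
    gene_pos = 0
    col = 0
    for start_col, length, kind in gap_runs(aln):
        while col < start_col:
            if aln.row_a[col] != "-":
                gene_pos += 1
            col += 1
        events.append((gene_pos, length, kind))
        net += length if kind == "insertion" else -length
    return ExonIndelReport(
        gene_id=gene.gene_id,
        reference_id=reference.gene_id,
        net_indel_bp=net,
        events=events,
    )


@dataclass
class RetroSignature:
    gene_id: str
    has_polya: bool
    polya_interval: tuple[int, int] | None
    has_tsd: bool
    tsd_seq: str | None


def _find_polya(seq: str, min_polya: int, purity: float = 0.90) -> tuple[int, int] | None:
    """Leftmost maximal A-rich run of length >= min_polya at >= 90% purity."""
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] != "A":
            i += 1
            continue
        best_end = i
        a_count = 0
        j = i
        while j < n:
            if seq[j] == "A":
                a_count += 1
                if a_count / (j - i + 1) >= purity:
                    best_end = j + 1
            else:
                if (a_count + 1) / (j - i + 1) < purity * 0.8:
                    break
            j += 1
        if best_end - i >= min_polya:
            return (i, best_end)
        i += 1
    return None


def scan_retro_signatures(
    gene: GeneModel,
    assembly: GenomeAssembly,
    flank: int = 200,
    min_polya: int = 8,
    tsd_range: tuple[int, int] = (4, 15),
    anchor_jitter: int = 3,
) -> RetroSignature:
    """Look for retrocopy vestiges around an intronless gene.

    In transcription orientation: a polyA stretch (>= min_polya bases at
    >= 90% A) within ``flank`` bp downstream of the gene end, and a
    target-site duplication, i.e. the k-mer (k in ``tsd_range``, longest
    first) immediately upstream of the gene recurring immediately after the
    polyA (or after the gene end if no polyA), within ``anchor_jitter`` bp
    of that anchor.  Strict adjacency keeps the false-positive rate of the
    k=4 end of the range low on random flanks.
    """
    if min_polya <= 0:
        raise ValueError("min_polya must be positive")
    chrom = assembly[gene.chromosome]
    if gene.strand == "+":
        up = chrom[max(0, gene.start - flank) : gene.start]
        down = chrom[gene.end : min(len(chrom), gene.end + flank)]
    else:
        up = revcomp(chrom[gene.end : min(len(chrom), gene.end + flank)])
        down = revcomp(chrom[max(0, gene.start - flank) : gene.start])

    polya = _find_polya(down, min_polya)
    has_polya = polya is not None

    anchor = polya[1] if polya is not None else 0
    tsd_seq = None
    k_lo, k_hi = tsd_range
    for k in range(min(k_hi, len(up)), k_lo - 1, -1):
        upstream_kmer = up[-k:]
        lo = max(0, anchor - anchor_jitter)
        hi = min(len(down) - k, anchor + anchor_jitter)
        found = any(down[p : p + k] == upstream_kmer for p in range(lo, hi + 1))
        if found:
            tsd_seq = upstream_kmer
            break
    polya_interval = None
    if polya is not None:
        polya_interval = polya
    return RetroSignature(
        gene_id=gene.gene_id,
        has_polya=has_polya,
        polya_interval=polya_interval,
        has_tsd=tsd_seq is not None,
        tsd_seq=tsd_seq,
    )


def nearest_conserved_reference(
    gene: GeneModel, references: list[GeneModel]
) -> GeneModel | None:
    """The conserved-intron gene with the highest CDS identity to ``gene``."""
    from ._align import global_identity

    best = None
    best_ident = -1.0
    for ref in references:
        if ref.gene_id == gene.gene_id:
            continue
        ident = global_identity(gene.cds, ref.cds)
        if ident > best_ident:
            best = ref
            best_ident = ident
    return best
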