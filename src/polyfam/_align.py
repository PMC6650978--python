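"""Shared pairwise-alignment helpers.

Thin wrappers around Bio.Align.PairwiseAligner (affine-gap global/local
alignment with explicit scoring) and edlib (fast unit-cost alignment used
where only match counts / gap runs are needed).  A gap of length k costs
``open + extend * k`` in all affine schemes, i.e. the first gapped position
is charged both the opening and one extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

# Classical protein-search gap penalties (existence 11, extension 1).
PROTEIN_GAP_OPEN = 11
PROTEIN_GAP_EXTEND = 1

# Nucleotide scoring used for CDS alignments.
NT_MATCH = 2
NT_MISMATCH = -3
NT_GAP_OPEN = 5
NT_GAP_EXTEND = 2


def protein_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -(PROTEIN_GAP_OPEN + PROTEIN_GAP_EXTEND)
    aligner.extend_gap_score = -PROTEIN_GAP_EXTEND
    return aligner


def nucleotide_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NT_MATCH
    aligner.mismatch_score = NT_MISMATCH
    aligner.open_gap_score = -(NT_GAP_OPEN + NT_GAP_EXTEND)
    aligner.extend_gap_score = -NT_GAP_EXTEND
    return aligner


_PROTEIN_LOCAL = protein_local_aligner()
_NT_GLOBAL = nucleotide_global_aligner()


def local_protein_score(query: str, target: str) -> float:
    """Smith-Waterman score under BLOSUM62 with affine gaps (11/1)."""
    return float(_PROTEIN_LOCAL.score(query, target))


@dataclass
class GlobalAlignment:
    """A global alignment as two gapped rows of equal length."""

    row_a: str
    row_b: str

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def matches(self) -> int:
        return sum(1 for x, y in zip(self.row_a, self.row_b) if x == y and x != "-")

    def column_of_a_position(self, pos: int) -> int:
        """Alignment column index holding sequence-a position ``pos`` (0-based).

        ``pos == len(a)`` maps to ``n_columns`` (one past the end).
        """
        seen = 0
        for col, ch in enumerate(self.row_a):
            if ch != "-":
                if seen == pos:
                    return col
                seen += 1
        if seen == pos:
            return self.n_columns
        raise IndexError(f"position {pos} beyond sequence length {seen}")


def global_align_nt(a: str, b: str) -> GlobalAlignment:
    """Global nucleotide alignment at match +2 / mismatch -3 / gap -5-2k."""
    alignment = _NT_GLOBAL.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return GlobalAlignment(row_a, row_b)


def edlib_global(a: str, b: str) -> GlobalAlignment:
    """Unit-cost (edit distance) global alignment via edlib; fast for long/near sequences."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return GlobalAlignment(nice["query_aligned"], nice["target_aligned"])


def global_identity(a: str, b: str) -> float:
    """Fraction of identical aligned residues over the length of the LONGER sequence.

    This is the clustering identity criterion: a truncated sequence is
    penalised for the residues it lacks.  Symmetric by construction.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if a == b:
        return 1.0
    # canonical argument order: co-optimal alignments may count matches
    # differently per direction, and the identity must be symmetric
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aln = edlib_global(a, b)
    return aln.matches() / max(len(a), len(b))


def gap_runs(aln: GlobalAlignment) -> list[tuple[int, int, str]]:
    """Gap runs of a global alignment as (column_start, length, kind).

    kind 'deletion'  = gap in row_a (sequence a lacks these bases),
    kind 'insertion' = gap in row_b (sequence a has extra bases).
    """
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = aln.n_columns
    while i < n:
        if aln.row_a[i] == "-":
            j = i
            while j < n and aln.row_a[j] == "-":
                j += 1
            runs.append((i, j - i, "deletion"))
            i = j
        elif aln.row_b[i] == "-":
            j = i
            while j < n and aln.row_b[j] == "-":
                j += 1
            runs.append((i, j - i, "insertion"))
            i = j
        else:
            i += 1
    return runs


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Map an ACGTN string to uint8 codes 0..4."""
    lut = np.full(256, 4, dtype=np.uint8)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
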