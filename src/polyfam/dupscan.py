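"""Small-scale duplication detection between windows around family genes.

Windows of ±100 kb are cut around each family gene (genes closer than the
merge gap share one window spanning the most distal coordinates ± flank).
Every distinct pair of windows is then scanned with a seed-and-extend local
aligner: shared 14-mers (both strands) anchor diagonals, anchors are
chained within a diagonal band, and each chained region is aligned
end-to-end (edlib, unit costs) to obtain identity, alignment length and a
score under match +1 / mismatch -2 / gap -(5+2k).  E-values use the
Karlin-Altschul form E = K*m*n*exp(-lambda*S) with ungapped nucleotide
defaults (lambda = 1.28, K = 0.46).  Hits are kept when identity >= 90%
over >= 3 kb with e-value < 1e-100, then reduced to a non-overlapping set
greedily by score with a 10% reciprocal-overlap tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._align import revcomp, seq_to_codes
from .models import ChromosomeId, GeneModel, GenomeAssembly

NT_LAMBDA = 1.28
NT_K = 0.46
MATCH = 1
MISMATCH = -2
GAP_OPEN = 5
GAP_EXTEND = 2

DEFAULT_FLANK = 100_000
DEFAULT_MERGE_GAP = 100_000
MIN_IDENTITY = 0.90
MIN_LENGTH = 3_000
MAX_EVALUE = 1e-100


@dataclass
class LocusWindow:
    window_id: str
    chromosome: ChromosomeId
    start: int
    end: int
    contained_genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentHit:
    window_a: LocusWindow
    window_b: LocusWindow
    coords_a: tuple[int, int]  # chromosome coordinates
    coords_b: tuple[int, int]
    strand: str  # sense / antisense
    length: int  # aligned span on locus a
    identity: float
    score: float
    evalue: float


@dataclass
class DuplicationFragment(AlignmentHit):
    fragment_id: str = ""


@dataclass
class DuplicationSummary:
    n_fragments: int
    min_len: int | None
    max_len: int | None
    mean_len: float | None
    median_len: float | None
    per_locus_counts: dict[str, int] = field(default_factory=dict)
    edges: list[tuple[str, str, int]] = field(default_factory=list)


def extract_windows(
    genes: list[GeneModel],
    assembly: GenomeAssembly,
    flank: int = DEFAULT_FLANK,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[LocusWindow]:
    """±flank windows around genes; same-chromosome genes closer than
    merge_gap share one window spanning the most distal coordinates."""
    by_chrom: dict[ChromosomeId, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    windows: list[LocusWindow] = []
    for cid in sorted(by_chrom):
        chrom_len = assembly.length(cid)
        members = sorted(by_chrom[cid], key=lambda g: g.start)
        cluster: list[GeneModel] = [members[0]]
        clusters: list[list[GeneModel]] = [cluster]
        for g in members[1:]:
            if g.start - cluster[-1].end < merge_gap:
                cluster.append(g)
            else:
                cluster = [g]
                clusters.append(cluster)
        for cl in clusters:
            start = max(0, cl[0].start - flank)
            end = min(chrom_len, cl[-1].end + flank)
            windows.append(
                LocusWindow(
                    window_id=f"W{len(windows):03d}_{cid.name}",
                    chromosome=cid,
                    start=start,
                    end=end,
                    contained_genes=[g.gene_id for g in cl],
                )
            )
    return windows


# ---------------------------------------------------------------------------
# seed-and-extend alignment between two window sequences


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, kmer integer codes) for all k-mers without N."""
    codes = seq_to_codes(seq).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes < 4
    # rolling polynomial code base 4
    vals = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        vals = vals * 4 + codes[i : i + n]
        ok &= valid[i : i + n]
    pos = np.flatnonzero(ok)
    return pos, vals[pos]


class KmerIndex:
    """Low-copy k-mers of one sequence, sorted by k-mer code for merging."""

    __slots__ = ("pos", "val")

    def __init__(self, seq: str, k: int, max_occ: int = 10):
        pos, val = _kmer_codes(seq, k)
        if len(val):
            order = np.argsort(val, kind="stable")
            val, pos = val[order], pos[order]
            _uniq, inverse, counts = np.unique(val, return_inverse=True, return_counts=True)
            mask = counts[inverse] <= max_occ
            val, pos = val[mask], pos[mask]
        self.pos = pos
        self.val = val


def _shared_anchors(
    index_a: KmerIndex, index_b: KmerIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (in a and b) of shared low-copy k-mers."""
    val_a, pos_a = index_a.val, index_a.pos
    val_b, pos_b = index_b.val, index_b.pos
    if len(val_a) == 0 or len(val_b) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lo = np.searchsorted(val_a, val_b, side="left")
    hi = np.searchsorted(val_a, val_b, side="right")
    counts = hi - lo
    matched = counts > 0
    if not matched.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    b_idx = np.repeat(np.flatnonzero(matched), counts[matched])
    a_idx = np.concatenate(
        [np.arange(l, h) for l, h in zip(lo[matched], hi[matched])]
    )
    return pos_a[a_idx], pos_b[b_idx]


def _chain_anchors(
    a_pos: np.ndarray,
    b_pos: np.ndarray,
    k: int,
    band: int = 16,
    max_gap: int = 2_000,
    min_anchors: int = 3,
    min_span: int = 1_000,
) -> list[tuple[int, int, int, int]]:
    """Greedy banded chaining of anchors into candidate regions.

    Returns (a_start, a_end, b_start, b_end) spans.  Anchors are grouped by
    diagonal (within ±band), then split on positional gaps > max_gap.
    """
    if len(a_pos) == 0:
        return []
    diag = a_pos - b_pos
    order = np.lexsort((a_pos, diag))
    diag_s, a_s, b_s = diag[order], a_pos[order], b_pos[order]
    chains: list[tuple[int, int, int, int]] = []
    group_start = 0
    for i in range(1, len(diag_s) + 1):
        if i == len(diag_s) or diag_s[i] - diag_s[i - 1] > band:
            idx = np.arange(group_start, i)
            sub_order = idx[np.argsort(a_s[idx], kind="stable")]
            seg_start = 0
            aa, bb = a_s[sub_order], b_s[sub_order]
            for j in range(1, len(sub_order) + 1):
                if j == len(sub_order) or aa[j] - aa[j - 1] > max_gap:
                    if j - seg_start >= min_anchors:
                        a0, a1 = int(aa[seg_start]), int(aa[j - 1]) + k
                        b0 = int(bb[seg_start : j].min())
                        b1 = int(bb[seg_start : j].max()) + k
                        if a1 - a0 >= min_span and b1 - b0 >= min_span:
                            chains.append((a0, a1, b0, b1))
                    seg_start = j
            group_start = i
    return _merge_chains(chains)


def _merge_chains(
    chains: list[tuple[int, int, int, int]], slack: int = 1_000
) -> list[tuple[int, int, int, int]]:
    """Union chains whose a- and b-spans overlap or nearly abut."""
    merged = True
    chains = list(chains)
    while merged:
        merged = False
        out: list[tuple[int, int, int, int]] = []
        for c in sorted(chains):
            for i, o in enumerate(out):
                if (
                    c[0] <= o[1] + slack
                    and o[0] <= c[1] + slack
                    and c[2] <= o[3] + slack
                    and o[2] <= c[3] + slack
                ):
                    out[i] = (
                        min(o[0], c[0]),
                        max(o[1], c[1]),
                        min(o[2], c[2]),
                        max(o[3], c[3]),
                    )
                    merged = True
                    break
            else:
                out.append(c)
        chains = out
    return chains


def _score_alignment(cigar: str) -> tuple[int, int, float]:
    """(matches, columns, score) from an edlib cigar string."""
    matches = 0
    columns = 0
    score = 0.0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
            score += MATCH * n
        elif ch == "X":
            score += MISMATCH * n
        elif ch in ("I", "D"):
            score -= GAP_OPEN + GAP_EXTEND * n
    return matches, columns, score


def find_local_alignments(
    window_a: LocusWindow,
    window_b: LocusWindow,
    seq_a: str,
    seq_b: str,
    k: int = 14,
    index_a: KmerIndex | None = None,
    index_b: KmerIndex | None = None,
    index_b_rc: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """Seed-and-extend local alignments between two window sequences (both strands).

    Precomputed :class:`KmerIndex` objects may be passed to amortise k-mer
    extraction across many window pairs.
    """
    if k < 8:
        raise ValueError("anchor length k must be >= 8")
    if not seq_a or not seq_b:
        raise ValueError("empty window sequence")
    if index_a is None:
        index_a = KmerIndex(seq_a, k)
    if index_b is None:
        index_b = KmerIndex(seq_b, k)
    if index_b_rc is None:
        index_b_rc = KmerIndex(revcomp(seq_b), k)
    hits: list[AlignmentHit] = []
    for strand, idx_b in (("sense", index_b), ("antisense", index_b_rc)):
        a_pos, b_pos = _shared_anchors(index_a, idx_b)
        chains = _chain_anchors(a_pos, b_pos, k)
        if not chains:
            continue
        sb = seq_b if strand == "sense" else revcomp(seq_b)
        for a0, a1, b0, b1 in chains:
            sub_a = seq_a[a0:a1]
            sub_b = sb[b0:b1]
            res = edlib.align(sub_a, sub_b, mode="NW", task="path")
            matches, columns, score = _score_alignment(res["cigar"])
            identity = matches / columns if columns else 0.0
            log_e = (
                math.log(NT_K)
                + math.log(max(len(seq_a), 1))
                + math.log(max(len(seq_b), 1))
                - NT_LAMBDA * score
            )
            evalue = math.exp(log_e) if log_e < 700 else math.inf
            if strand == "sense":
                coords_b = (window_b.start + b0, window_b.start + b1)
            else:
                coords_b = (
                    window_b.start + len(seq_b) - b1,
                    window_b.start + len(seq_b) - b0,
                )
            hits.append(
                AlignmentHit(
                    window_a=window_a,
                    window_b=window_b,
                    coords_a=(window_a.start + a0, window_a.start + a1),
                    coords_b=coords_b,
                    strand=strand,
                    length=a1 - a0,
                    identity=identity,
                    score=score,
                    evalue=evalue,
                )
            )
    return hits


def filter_hits(
    hits: list[AlignmentHit],
    min_identity: float = MIN_IDENTITY,
    min_length: int = MIN_LENGTH,
    max_evalue: float = MAX_EVALUE,
) -> list[AlignmentHit]:
    """Keep hits with identity >= min_identity over >= min_length and
    e-value < max_evalue; drop trivial self-diagonal hits."""
    out = []
    for h in hits:
        # a locus aligned to (part of) itself is not a duplication; this also
        # removes self-diagonal hits and overlap between nearby windows of
        # the same chromosome
        if (
            h.window_a.chromosome == h.window_b.chromosome
            and _overlap(h.coords_a, h.coords_b) > 0
        ):
            continue
        if h.identity >= min_identity and h.length >= min_length and h.evalue < max_evalue:
            out.append(h)
    return out


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> int:
    return max(0, min(x[1], y[1]) - max(x[0], y[0]))


def _loci(h: AlignmentHit) -> list[tuple[ChromosomeId, tuple[int, int]]]:
    return [
        (h.window_a.chromosome, h.coords_a),
        (h.window_b.chromosome, h.coords_b),
    ]


def resolve_non_overlapping(
    hits: list[AlignmentHit], max_overlap_frac: float = 0.10
) -> list[DuplicationFragment]:
    """Greedy score-ordered selection of fragments with bounded genomic overlap.

    A candidate is accepted iff, against every accepted fragment, the
    overlap of each of its loci with each same-chromosome locus of the
    accepted fragment does not exceed ``max_overlap_frac`` of the shorter
    span.
    """
    ordered = sorted(
        hits,
        key=lambda h: (-h.score, -h.length, h.window_a.window_id, h.coords_a, h.coords_b),
    )
    accepted: list[DuplicationFragment] = []
    for h in ordered:
        ok = True
        for f in accepted:
            for chrom_h, span_h in _loci(h):
                for chrom_f, span_f in _loci(f):
                    if chrom_h != chrom_f:
                        continue
                    ov = _overlap(span_h, span_f)
                    shorter = min(span_h[1] - span_h[0], span_f[1] - span_f[0])
                    if shorter > 0 and ov / shorter > max_overlap_frac:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(
                DuplicationFragment(
                    fragment_id=f"F{len(accepted):03d}",
                    **{
                        fld: getattr(h, fld)
                        for fld in (
                            "window_a", "window_b", "coords_a", "coords_b",
                            "strand", "length", "identity", "score", "evalue",
                        )
                    },
                )
            )
    return accepted


def summarize_duplications(fragments: list[DuplicationFragment]) -> DuplicationSummary:
    """Length statistics plus the per-locus-pair duplication graph."""
    lengths = [f.length for f in fragments]
    per_locus: dict[str, int] = {}
    edge_counts: dict[tuple[str, str], int] = {}
    for f in fragments:
        wa, wb = f.window_a.window_id, f.window_b.window_id
        per_locus[wa] = per_locus.get(wa, 0) + 1
        per_locus[wb] = per_locus.get(wb, 0) + 1
        key = tuple(sorted((wa, wb)))
        edge_counts[key] = edge_counts.get(key, 0) + 1
    if not lengths:
        return DuplicationSummary(
            n_fragments=0, min_len=None, max_len=None, mean_len=None, median_len=None
        )
    return DuplicationSummary(
        n_fragments=len(fragments),
        min_len=int(min(lengths)),
        max_len=int(max(lengths)),
        mean_len=float(np.mean(lengths)),
        median_len=float(np.median(lengths)),
        per_locus_counts=per_locus,
        edges=[(a, b, n) for (a, b), n in sorted(edge_counts.items())],
    )


def scan_duplications(
    assembly: GenomeAssembly,
    family_genes: list[GeneModel],
    flank: int = DEFAULT_FLANK,
    merge_gap: int = DEFAULT_MERGE_GAP,
    k: int = 14,
    min_identity: float = MIN_IDENTITY,
    min_length: int = MIN_LENGTH,
    max_evalue: float = MAX_EVALUE,
    max_overlap_frac: float = 0.10,
) -> tuple[list[LocusWindow], list[DuplicationFragment], DuplicationSummary]:
    """Full scan: windows -> pairwise alignment -> filters -> non-overlap set."""
    windows = extract_windows(family_genes, assembly, flank=flank, merge_gap=merge_gap)
    seqs = {w.window_id: assembly[w.chromosome][w.start : w.end] for w in windows}
    fwd = {wid: KmerIndex(s, k) for wid, s in seqs.items()}
    rc = {wid: KmerIndex(revcomp(s), k) for wid, s in seqs.items()}
    all_hits: list[AlignmentHit] = []
    for i in range(len(windows)):
        for j in range(i + 1, len(windows)):
            wa, wb = windows[i], windows[j]
            all_hits.extend(
                find_local_alignments(
                    wa, wb, seqs[wa.window_id], seqs[wb.window_id], k=k,
                    index_a=fwd[wa.window_id],
                    index_b=fwd[wb.window_id],
                    index_b_rc=rc[wb.window_id],
                )
            )
    kept = filter_hits(
        all_hits, min_identity=min_identity, min_length=min_length, max_evalue=max_evalue
    )
    fragments = resolve_non_overlapping(kept, max_overlap_frac=max_overlap_frac)
    summary = summarize_duplications(fragments)
    return windows, fragments, summary
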