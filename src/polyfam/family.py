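"""Iterative gene-family identification over a proteome.

The strategy mirrors a domain-profile scan combined with pairwise sequence
search, run to a fixpoint: (1) a position-specific scoring matrix (PSSM)
built from a seed alignment selects candidate proteins; (2) candidates are
confirmed by the domain rescan; (3) confirmed members seed Smith-Waterman
searches of the whole proteome; (4) new hits are rescanned for the domains;
repeat until the member set stops growing.

The PSSM scan e-value is calibrated against an empirical null of shuffled
query sequences.  Scores inside the shuffle range use the plus-one-smoothed
empirical tail; scores beyond every shuffle (the interesting case) use a
Gumbel right tail fitted to the shuffle scores by the method of moments, as
an empirical count cannot resolve probabilities below 1/(n_shuffles+1).
Pairwise-search e-values use the Karlin-Altschul form E = K*m*n*exp(-lambda*S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._align import BLOSUM62, local_protein_score
from .models import PolyfamError

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
BACKGROUND_FREQ = 0.05  # uniform over the 20 amino acids

# Ungapped-protein Karlin-Altschul constants (classical literature defaults);
# configurable via pairwise_protein_search arguments.
KA_LAMBDA = 0.267
KA_K = 0.041

SCAN_EVALUE_DEFAULT = 0.1
SEARCH_EVALUE_DEFAULT = 1e-5


@dataclass
class ProfileMatrix:
    """Per-position log-odds scores in half-bits over the 20 amino acids."""

    name: str
    scores: np.ndarray  # (length, 20)

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("profile scores must be (length, 20)")
        if self.scores.shape[0] < 10:
            raise ValueError("profile must have at least 10 positions")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass
class DomainHit:
    protein_id: str
    domain: str
    start: int
    end: int
    score: float
    evalue: float


def build_pssm(
    seed_alignment: list[str],
    pseudocount_weight: float = 1.0,
    name: str = "domain",
    max_gap_frac: float = 0.5,
) -> ProfileMatrix:
    """Build a PSSM from an aligned set of sequences.

    Columns with more than ``max_gap_frac`` gaps are dropped.  Scores are
    ``2 * log2(f_a / 0.05)`` where ``f_a = (count_a + w*0.05) / (n + w)``
    with gap characters excluded from the counts.
    """
    if not seed_alignment or len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    length = len(seed_alignment[0])
    if any(len(s) != length for s in seed_alignment):
        raise ValueError("seed alignment sequences must have equal length")
    w = float(pseudocount_weight)
    if w <= 0:
        raise ValueError("pseudocount weight must be positive")
    columns = []
    n_seqs = len(seed_alignment)
    for col in range(length):
        residues = [s[col].upper() for s in seed_alignment]
        gaps = sum(1 for r in residues if r in "-.")
        if gaps / n_seqs > max_gap_frac:
            continue
        counts = np.zeros(20)
        for r in residues:
            if r in _AA_INDEX:
                counts[_AA_INDEX[r]] += 1
        n_obs = counts.sum()
        freqs = (counts + w * BACKGROUND_FREQ) / (n_obs + w)
        columns.append(2.0 * np.log2(freqs / BACKGROUND_FREQ))
    scores = np.array(columns)
    return ProfileMatrix(name=name, scores=scores)


def _encode_protein(protein: str) -> np.ndarray:
    lut = np.full(256, 20, dtype=np.int64)
    for aa, i in _AA_INDEX.items():
        lut[ord(aa)] = i
    return lut[np.frombuffer(protein.upper().encode("ascii"), dtype=np.uint8)]


def _window_scores(score_cols: np.ndarray, seq_idx: np.ndarray) -> np.ndarray:
    """Ungapped window scores of a profile against a sequence, all offsets.

    ``score_cols`` is the (length, 21) profile with a zero column appended
    for unknown residues; returns an array of length L - plen + 1.
    """
    plen = score_cols.shape[0]
    L = len(seq_idx)
    n_off = L - plen + 1
    if n_off <= 0:
        return np.empty(0)
    m = score_cols[np.arange(plen)[:, None], seq_idx[None, :]]  # (plen, L)
    flat = np.ascontiguousarray(m).ravel()
    # window score at offset o = sum_i m[i, o+i]; diagonals via striding
    strided = np.lib.stride_tricks.as_strided(
        flat,
        shape=(n_off, plen),
        strides=(flat.strides[0], (L + 1) * flat.strides[0]),
    )
    return strided.sum(axis=1)


def _augment(pssm: ProfileMatrix) -> np.ndarray:
    """Profile with an extra neutral column for non-standard residues."""
    return np.concatenate([pssm.scores, np.zeros((pssm.length, 1))], axis=1)


def _gumbel_tail(shuffle_scores: np.ndarray, score: float) -> float:
    """Right-tail P(S >= score) under a Gumbel fitted by moments."""
    mean = float(shuffle_scores.mean())
    std = float(shuffle_scores.std(ddof=1))
    if std <= 0:
        return 1.0 if score <= mean else 0.0
    beta = std * math.sqrt(6.0) / math.pi
    mu = mean - 0.5772156649015329 * beta
    z = (score - mu) / beta
    # P(X >= x) = 1 - exp(-exp(-z))
    return float(-math.expm1(-math.exp(-z)))


def scan_protein(
    pssm: ProfileMatrix,
    protein: str,
    protein_id: str = "query",
    n_shuffles: int = 200,
    rng: np.random.Generator | None = None,
    database_size: int = 1,
    evalue_threshold: float = SCAN_EVALUE_DEFAULT,
) -> DomainHit | None:
    """Scan a protein with an ungapped profile; return the best hit or None.

    The best window score over all offsets is compared against the score
    distribution of ``n_shuffles`` shuffled versions of the same protein.
    The e-value is ``database_size`` times the tail probability (empirical
    plus-one inside the shuffle range, fitted Gumbel tail beyond it).
    """
    if not protein:
        raise ValueError("empty protein")
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    seq_idx = _encode_protein(protein)
    if len(seq_idx) < pssm.length:
        return None
    cols = _augment(pssm)
    scores = _window_scores(cols, seq_idx)
    best_offset = int(np.argmax(scores))
    best = float(scores[best_offset])

    # null distribution: best window score of shuffled residues
    perms = np.array([rng.permutation(len(seq_idx)) for _ in range(n_shuffles)])
    null_best = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null_best[s] = _window_scores(cols, seq_idx[perms[s]]).max()
    exceed = int((null_best >= best).sum())
    if exceed > 0:
        pvalue = (exceed + 1) / (n_shuffles + 1)
    else:
        pvalue = min(_gumbel_tail(null_best, best), 1.0 / (n_shuffles + 1))
    evalue = database_size * pvalue
    if evalue >= evalue_threshold:
        return None
    return DomainHit(
        protein_id=protein_id,
        domain=pssm.name,
        start=best_offset,
        end=best_offset + pssm.length,
        score=best,
        evalue=evalue,
    )


def best_window(pssm: ProfileMatrix, protein: str) -> tuple[float, int]:
    """Best ungapped window score and offset (no statistics); brute-force testable."""
    seq_idx = _encode_protein(protein)
    scores = _window_scores(_augment(pssm), seq_idx)
    if scores.size == 0:
        raise ValueError("protein shorter than profile")
    off = int(np.argmax(scores))
    return float(scores[off]), off


def pairwise_protein_search(
    query: str,
    database: dict[str, str],
    ka_lambda: float = KA_LAMBDA,
    ka_k: float = KA_K,
) -> list[tuple[str, float, float]]:
    """Smith-Waterman search of a query against a proteome.

    Returns (protein_id, score, evalue) sorted by e-value ascending;
    E = K * m * n * exp(-lambda * S) with n the total database length.
    """
    if not query:
        raise ValueError("empty query")
    if not database:
        raise ValueError("empty database")
    m = len(query)
    n_total = sum(len(s) for s in database.values())
    out = []
    for pid, seq in database.items():
        score = local_protein_score(query, seq)
        evalue = ka_k * m * n_total * math.exp(-ka_lambda * score)
        out.append((pid, score, evalue))
    out.sort(key=lambda t: (t[2], t[0]))
    return out


class ConvergenceError(PolyfamError):
    def __init__(self, message: str, unstable: set[str]):
        super().__init__(message)
        self.unstable = unstable


def scan_domains(
    pssms: list[ProfileMatrix],
    protein: str,
    protein_id: str,
    n_shuffles: int,
    rng: np.random.Generator,
    database_size: int,
    scan_threshold: float,
) -> list[DomainHit]:
    hits = []
    for pssm in pssms:
        hit = scan_protein(
            pssm, protein, protein_id=protein_id, n_shuffles=n_shuffles, rng=rng,
            database_size=database_size, evalue_threshold=scan_threshold,
        )
        if hit is not None:
            hits.append(hit)
    return hits


def iterative_family_search(
    proteome: dict[str, str],
    pssms: list[ProfileMatrix],
    scan_threshold: float = SCAN_EVALUE_DEFAULT,
    search_threshold: float = SEARCH_EVALUE_DEFAULT,
    n_shuffles: int = 200,
    seed: int = 0,
    max_iterations: int = 10,
) -> dict[str, list[DomainHit]]:
    """Fixpoint closure of domain scan + pairwise search over a proteome.

    Membership is confirmed by either domain (both are reported when found).
    Returns {member_id: domain hits}; monotone across iterations.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(seed)
    db_size = len(proteome)

    domain_hits: dict[str, list[DomainHit]] = {}

    def confirmed(pid: str) -> bool:
        if pid not in domain_hits:
            domain_hits[pid] = scan_domains(
                pssms, proteome[pid], pid, n_shuffles, rng, db_size, scan_threshold
            )
        return bool(domain_hits[pid])

    members: set[str] = {pid for pid in proteome if confirmed(pid)}
    searched: set[str] = set()
    for iteration in range(max_iterations):
        frontier = members - searched
        if not frontier:
            return {pid: domain_hits[pid] for pid in sorted(members)}
        new: set[str] = set()
        for pid in sorted(frontier):
            searched.add(pid)
            for hit_id, _score, evalue in pairwise_protein_search(proteome[pid], proteome):
                if evalue >= search_threshold or hit_id in members or hit_id in new:
                    continue
                if confirmed(hit_id):
                    new.add(hit_id)
        if not new:
            return {pid: domain_hits[pid] for pid in sorted(members)}
        members |= new
    raise ConvergenceError(
        f"family search did not converge within {max_iterations} iterations",
        unstable=members - searched,
    )
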