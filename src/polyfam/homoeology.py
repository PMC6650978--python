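"""Greedy identity clustering of family proteins and homoeolog group assignment.

Clustering follows the incremental greedy scheme of CD-HIT-style tools:
sequences are sorted by length (descending), the longest founds cluster #0,
and each subsequent sequence joins the first existing cluster whose
representative it matches at or above the identity threshold, else founds a
new cluster.  Identity is computed on a global protein alignment as
identical residues divided by the length of the longer sequence, so the
criterion reads "X% identity over the longest sequence".

Clusters of 2-3 members sitting on the same chromosome number across
distinct subgenomes become homoeolog pairs/triplets.  Larger clusters are
partitioned by chromosome number; qualifying sub-partitions are reported as
"probable" pairs/triplets.  Everything else is a singlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import global_identity
from .models import ChromosomeId, PolyfamError


@dataclass
class SequenceCluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)
    identity_to_rep: dict[str, float] = field(default_factory=dict)


GROUP_KINDS = ("triplet", "pair", "probable_triplet", "probable_pair", "singlet")


@dataclass
class HomoeologGroup:
    group_id: str
    kind: str
    chromosome_number: int | None
    members: list[tuple[str, str]]  # (gene_id, subgenome)
    notes: str = ""


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity over the longer sequence; symmetric."""
    return global_identity(a, b)


def greedy_cluster(
    sequences: dict[str, str], threshold: float = 0.90
) -> list[SequenceCluster]:
    """First-fit greedy incremental clustering at the given identity threshold."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[SequenceCluster] = []
    for gene_id in order:
        seq = sequences[gene_id]
        placed = False
        for cluster in clusters:
            ident = pairwise_identity(seq, sequences[cluster.representative])
            if ident >= threshold:
                cluster.members.append(gene_id)
                cluster.identity_to_rep[gene_id] = ident
                placed = True
                break
        if not placed:
            cluster = SequenceCluster(
                cluster_id=len(clusters), representative=gene_id, members=[gene_id],
                identity_to_rep={gene_id: 1.0},
            )
            clusters.append(cluster)
    return clusters


def _positional_group(
    members: list[str],
    locations: dict[str, tuple[ChromosomeId, tuple[int, int]]],
) -> int | None:
    """Chromosome number if members share it across pairwise-distinct subgenomes."""
    chroms = [locations[m][0] for m in members]
    numbers = {c.number for c in chroms}
    subgenomes = [c.subgenome for c in chroms]
    if len(numbers) == 1 and len(set(subgenomes)) == len(subgenomes):
        return chroms[0].number
    return None


def assign_homoeolog_groups(
    clusters: list[SequenceCluster],
    locations: dict[str, tuple[ChromosomeId, tuple[int, int]]],
) -> list[HomoeologGroup]:
    """Turn identity clusters + gene locations into homoeolog groups.

    Size-2/3 clusters passing the positional test become pairs/triplets;
    within larger clusters, chromosome-number sub-partitions of 2-3 members
    on distinct subgenomes become probable pairs/triplets; everything else
    is emitted as singlets.
    """
    for cluster in clusters:
        for m in cluster.members:
            if m not in locations:
                raise PolyfamError(f"cluster member {m} has no location")
    groups: list[HomoeologGroup] = []
    counter = 0

    def _new_id() -> str:
        nonlocal counter
        gid = f"HG{counter:03d}"
        counter += 1
        return gid

    def _emit(kind: str, members: list[str], number: int | None, notes: str = "") -> None:
        groups.append(
            HomoeologGroup(
                group_id=_new_id(),
                kind=kind,
                chromosome_number=number,
                members=[(m, locations[m][0].subgenome) for m in members],
                notes=notes,
            )
        )

    for cluster in clusters:
        size = len(cluster.members)
        if size == 1:
            _emit("singlet", cluster.members, None)
        elif size in (2, 3):
            number = _positional_group(cluster.members, locations)
            if number is not None:
                _emit("pair" if size == 2 else "triplet", cluster.members, number)
            else:
                for m in cluster.members:
                    _emit("singlet", [m], None, notes=f"cluster {cluster.cluster_id} failed positional test")
        else:
            by_number: dict[int, list[str]] = {}
            for m in cluster.members:
                by_number.setdefault(locations[m][0].number, []).append(m)
            for number in sorted(by_number):
                sub = by_number[number]
                if len(sub) in (2, 3) and _positional_group(sub, locations) is not None:
                    kind = "probable_pair" if len(sub) == 2 else "probable_triplet"
                    _emit(kind, sub, number, notes=f"from cluster {cluster.cluster_id} (size {size})")
                else:
                    for m in sub:
                        _emit("singlet", [m], None, notes=f"from cluster {cluster.cluster_id}")
    return groups


@dataclass
class GroupSummary:
    n_triplets: int
    n_pairs: int
    n_probable_triplets: int
    n_probable_pairs: int
    grouped_members: int
    probable_members: int
    singlets: int
    total_genes: int


def summarize_groups(groups: list[HomoeologGroup], total_genes: int) -> GroupSummary:
    """Bookkeeping over a set of homoeolog groups.

    grouped = 3*triplets + 2*pairs; probable members reported separately;
    singlets = total - grouped - probable.
    """
    seen: set[str] = set()
    for g in groups:
        for gene_id, _sub in g.members:
            if gene_id in seen:
                raise PolyfamError(f"gene {gene_id} appears in more than one group")
            seen.add(gene_id)
    n_triplets = sum(1 for g in groups if g.kind == "triplet")
    n_pairs = sum(1 for g in groups if g.kind == "pair")
    n_pt = sum(1 for g in groups if g.kind == "probable_triplet")
    n_pp = sum(1 for g in groups if g.kind == "probable_pair")
    grouped = 3 * n_triplets + 2 * n_pairs
    probable = 3 * n_pt + 2 * n_pp
    singlets = total_genes - grouped - probable
    if singlets < 0:
        raise PolyfamError("grouped members exceed total gene count")
    return GroupSummary(
        n_triplets=n_triplets,
        n_pairs=n_pairs,
        n_probable_triplets=n_pt,
        n_probable_pairs=n_pp,
        grouped_members=grouped,
        probable_members=probable,
        singlets=singlets,
        total_genes=total_genes,
    )


def compare_group_structures(
    group: HomoeologGroup, classes: dict[str, str]
) -> tuple[bool, dict[str, str], str]:
    """Flag intron-count divergence within a homoeolog group.

    Divergent iff members fall into different intron-count classes
    (TypeIa vs TypeIb vs TypeII); the conserved/non-conserved split within
    TypeIa is positional, not a count difference, and is reported in notes.
    """
    if group.kind == "singlet":
        raise ValueError("structure comparison needs a multi-member group")
    member_classes: dict[str, str] = {}
    for gene_id, _sub in group.members:
        if gene_id not in classes:
            raise PolyfamError(f"no structural class for {gene_id}")
        member_classes[gene_id] = classes[gene_id]

    def _count_class(cls: str) -> str:
        return "TypeIa" if cls.startswith("TypeIa") else cls

    count_classes = {_count_class(c) for c in member_classes.values()}
    divergent = len(count_classes) > 1
    notes = ""
    if not divergent and len(set(member_classes.values())) > 1:
        notes = "positional divergence within TypeIa (conserved vs non-conserved intron)"
    return divergent, member_classes, notes
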