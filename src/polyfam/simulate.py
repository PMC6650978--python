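"""Synthetic hexaploid genome, gene family and expression counts with planted truth.

The generator emulates the structures the downstream stages are built to
detect: a 21-chromosome (7 x A/B/D) genome; a gene family organised into
homoeolog triplets and pairs at high protein identity plus diverged
singlets; four intron-structure classes with a canonical position-conserved
intron (fixed-length terminal coding exon); intronless retrocopies with
optional target-site-duplication and polyA vestiges; segmental duplications
of 3-13 kb planted between family loci; repeat-rich background sequence;
and negative-binomial expression counts across tissues and stress
treatments with planted differential expression, silenced homoeologs and
tissue-specific genes.  Every planted feature is recorded in a
:class:`SimulatedTruth` that serialises losslessly to TSV.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from ._align import revcomp
from .models import (
    ChromosomeId,
    ExpressionSampleMeta,
    GeneModel,
    GenomeAssembly,
    PolyfamError,
    SUBGENOMES,
)
from .io import translate, write_assembly, write_fasta, write_gff3, write_tsv, read_tsv

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR_AA: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_FOR_AA[_aa].append(_codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()

STRUCTURAL_CLASSES = ("TypeIa_conserved", "TypeIa_nonconserved", "TypeIb", "TypeII")


class CapacityError(PolyfamError):
    """Requested genes/duplications exceed chromosome capacity."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults define the study conditions."""

    seed: int = 0
    chromosomes_per_subgenome: int = 7
    chromosome_length: int = 1_000_000
    n_triplets: int = 8
    n_pairs: int = 11
    n_singlets: int = 46
    homoeolog_identity: float = 0.95
    diverged_identity: float = 0.75
    n_planted_duplications: int = 30
    duplication_length_range: tuple[int, int] = (3_000, 13_000)
    duplication_identity_range: tuple[float, float] = (0.90, 0.99)
    retrocopy_fraction: float = 0.43
    tsd_length: int = 5
    polya_length: int = 12
    conserved_second_exon_length: int = 174
    nb_dispersion: float = 0.1
    planted_logfc: float = 2.0
    n_replicates: int = 3
    n_background_genes: int = 220
    family_protein_length: int = 160
    n_seed_sequences: int = 12
    n_silent_genes: int = 20
    n_partitioned_triplets: int = 3
    n_tissue_specific: int = 11
    de_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("homoeolog_identity", "diverged_identity", "retrocopy_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "n_triplets", "n_pairs", "n_singlets", "n_planted_duplications",
            "n_background_genes", "n_replicates",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def n_family_genes(self) -> int:
        return 3 * self.n_triplets + 2 * self.n_pairs + self.n_singlets


@dataclass
class SimulatedTruth:
    """Ground truth for every planted feature; the oracle for all stages."""

    homoeolog_groups: list[dict] = field(default_factory=list)
    structural_class: dict[str, str] = field(default_factory=dict)
    planted_duplications: list[dict] = field(default_factory=list)
    retro_signatures: dict[str, dict] = field(default_factory=dict)
    de_genes: list[dict] = field(default_factory=list)
    partitioned_triplets: list[dict] = field(default_factory=list)
    silent_genes: list[str] = field(default_factory=list)
    exon2_indels: list[dict] = field(default_factory=list)
    family_members: list[str] = field(default_factory=list)
    seed_alignment: dict[str, str] = field(default_factory=dict)
    domain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    tissue_specific: list[dict] = field(default_factory=list)
    constitutive_genes: list[str] = field(default_factory=list)

    def group_of(self) -> dict[str, dict]:
        """Map gene_id -> its homoeolog group record."""
        out: dict[str, dict] = {}
        for g in self.homoeolog_groups:
            for m in g["members"]:
                out[m["gene_id"]] = g
        return out


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(protein: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute exactly round((1-target)*L) positions with different residues."""
    if not protein:
        raise ValueError("empty protein")
    if not (0.0 < target_identity <= 1.0):
        raise ValueError(f"target identity must be in (0,1], got {target_identity}")
    n_sub = int(round((1.0 - target_identity) * len(protein)))
    if n_sub == 0:
        return protein
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def mutate_sequence(
    seq: str,
    target_identity: float,
    rng: np.random.Generator,
    allow_frame_indels: bool = False,
    indel_rate: float = 0.001,
) -> str:
    """Apply per-base substitutions (rate = 1 - target) and, optionally, rare
    frame-preserving (3-nt-multiple) indels.

    Realised Hamming identity concentrates on the target (binomial spread).
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not (0.0 < target_identity <= 1.0):
        raise ValueError(f"target identity must be in (0,1], got {target_identity}")
    if target_identity == 1.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    p_sub = 1.0 - target_identity
    hit = rng.random(len(arr)) < p_sub
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.flatnonzero(hit):
        alternatives = bases[bases != arr[i]]
        arr[i] = alternatives[rng.integers(len(alternatives))]
    out = arr.tobytes().decode("ascii")
    if allow_frame_indels:
        chunks = []
        pos = 0
        while pos < len(out):
            if rng.random() < indel_rate and pos > 0:
                size = 3 * int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    pos += size  # deletion
                    continue
                chunks.append("".join(rng.choice(list("ACGT"), size=size)))  # insertion
            chunks.append(out[pos])
            pos += 1
        out = "".join(chunks)
    return out


def back_translate(
    protein: str,
    rng: np.random.Generator,
    template_protein: str | None = None,
    template_cds: str | None = None,
) -> str:
    """Sample a CDS for a protein; where the residue matches an equal-length
    template, the template codon is reused (keeping nucleotide divergence
    proportional to protein divergence)."""
    codons = []
    for i, aa in enumerate(protein):
        if (
            template_protein is not None
            and i < len(template_protein)
            and template_protein[i] == aa
            and template_cds is not None
        ):
            codons.append(template_cds[3 * i : 3 * i + 3])
        else:
            options = _CODONS_FOR_AA[aa]
            codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return back_translate(random_protein(n_codons, rng), rng)


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class _PlannedGene:
    gene_id: str
    protein: str
    cds: str
    structural_class: str
    chromosome: ChromosomeId
    is_family: bool
    retro_flag: bool = False
    tandem_partner: str | None = None


def _intron_offsets_for_class(
    cls: str, cds_len: int, exon2_len: int, rng: np.random.Generator
) -> list[int]:
    """CDS offsets (between bases p-1 and p) of the introns for a class."""
    if cls == "TypeIb":
        return []
    if cls == "TypeIa_conserved":
        return [cds_len - exon2_len]
    if cls == "TypeIa_nonconserved":
        shift = int(rng.choice([-21, -15, -9, 9, 15, 21]))
        return [cds_len - exon2_len + shift]
    if cls == "TypeII":
        n_introns = int(rng.integers(2, 4))
        offsets = sorted(rng.choice(np.arange(30, cds_len - 30, 3), size=n_introns, replace=False))
        out = []
        for o in offsets:
            if not out or o - out[-1] >= 30:
                out.append(int(o))
        if len(out) < 2:
            out = [cds_len // 3, 2 * cds_len // 3]
        return out
    raise ValueError(f"unknown structural class {cls}")


def _build_gene_element(
    cds: str,
    intron_offsets: list[int],
    strand: str,
    rng: np.random.Generator,
    retro: bool,
    tsd_length: int,
    polya_length: int,
) -> tuple[str, list[tuple[int, int]], dict | None]:
    """Assemble the genomic segment to paste and relative exon intervals.

    Plus-orientation layout: [TSD] exon1 intron1 ... exonN [polyA] [TSD].
    For minus-strand genes the whole element is reverse-complemented and the
    exon intervals mirrored.  Returns (segment, exon_intervals, retro_info).
    """
    pieces: list[str] = []
    exon_rel: list[tuple[int, int]] = []
    cursor = 0
    retro_info = None
    if retro:
        # TSD must not start with A so the polyA run does not absorb it
        tsd = "".join(rng.choice(list("CGT"), size=1)) + _random_nt(tsd_length - 1, rng)
        polya = "A" * polya_length
        pieces.append(tsd)
        cursor += tsd_length
    bounds = [0] + list(intron_offsets) + [len(cds)]
    for i in range(len(bounds) - 1):
        exon_seq = cds[bounds[i] : bounds[i + 1]]
        exon_rel.append((cursor, cursor + len(exon_seq)))
        pieces.append(exon_seq)
        cursor += len(exon_seq)
        if i < len(bounds) - 2:
            intron = _random_nt(int(rng.integers(80, 800)), rng)
            pieces.append(intron)
            cursor += len(intron)
    if retro:
        pieces.append(polya)
        cursor += polya_length
        pieces.append(tsd)
        cursor += tsd_length
        retro_info = {"tsd_seq": tsd, "polya_length": polya_length}
    segment = "".join(pieces)
    if strand == "-":
        m = len(segment)
        segment = revcomp(segment)
        exon_rel = sorted((m - e, m - s) for s, e in exon_rel)
    return segment, exon_rel, retro_info


class _Placer:
    """Tracks occupied intervals per chromosome and finds free slots."""

    def __init__(self, lengths: dict[ChromosomeId, int], rng: np.random.Generator,
                 margin: int = 2_000, pad: int = 200):
        self.lengths = lengths
        self.rng = rng
        self.margin = margin
        self.pad = pad
        self.occupied: dict[ChromosomeId, list[tuple[int, int]]] = {c: [] for c in lengths}

    def _free(self, cid: ChromosomeId, start: int, end: int) -> bool:
        for s, e in self.occupied[cid]:
            if start < e + self.pad and s - self.pad < end:
                return False
        return True

    def reserve(self, cid: ChromosomeId, start: int, end: int) -> None:
        self.occupied[cid].append((start, end))

    def place(self, cid: ChromosomeId, length: int,
              near: tuple[int, int] | None = None, max_tries: int = 2_000) -> int:
        lo = self.margin
        hi = self.lengths[cid] - self.margin - length
        if near is not None:
            lo = max(lo, near[0])
            hi = min(hi, near[1] - length)
        if hi <= lo:
            raise CapacityError(f"no room for a {length} bp feature on {cid.name}")
        for _ in range(max_tries):
            start = int(self.rng.integers(lo, hi))
            if self._free(cid, start, start + length):
                self.reserve(cid, start, start + length)
                return start
        raise CapacityError(
            f"could not place a {length} bp feature on {cid.name} after {max_tries} tries"
        )


def _class_plan(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Decide how many groups/singlets fall in each structural class."""
    n_fam = cfg.n_family_genes
    n_ib = int(round(cfg.retrocopy_fraction * n_fam))
    remaining = n_fam - n_ib
    n_ii = max(2, int(round(0.21 * remaining)))
    n_ia_noncons = max(4, int(round(0.27 * remaining)))
    n_ia_cons = remaining - n_ii - n_ia_noncons
    return {
        "TypeIa_conserved": n_ia_cons,
        "TypeIa_nonconserved": n_ia_noncons,
        "TypeIb": n_ib,
        "TypeII": n_ii,
    }


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, list[GeneModel], SimulatedTruth]:
    """Build the synthetic genome, gene models and ground truth.

    Deterministic for a fixed config (byte-identical serialised outputs).
    """
    rng = np.random.default_rng(config.seed)
    truth = SimulatedTruth()

    chrom_ids = [
        ChromosomeId(num, sub)
        for num in range(1, config.chromosomes_per_subgenome + 1)
        for sub in SUBGENOMES
    ]
    lengths = {cid: config.chromosome_length for cid in chrom_ids}

    # --- chromosome background: uniform bases + interspersed repeat elements
    chrom_arrays: dict[ChromosomeId, np.ndarray] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for cid in chrom_ids:
        chrom_arrays[cid] = rng.choice(bases, size=lengths[cid])
    repeat_elements = [_random_nt(500, rng) for _ in range(3)]
    for cid in chrom_ids:
        n_copies = int(rng.integers(6, 11))
        for _ in range(n_copies):
            elem = repeat_elements[int(rng.integers(len(repeat_elements)))]
            elem = mutate_sequence(elem, 0.95, rng)
            start = int(rng.integers(0, lengths[cid] - len(elem)))
            chrom_arrays[cid][start : start + len(elem)] = np.frombuffer(
                elem.encode("ascii"), dtype=np.uint8
            )

    placer = _Placer(lengths, rng)

    # --- ancestral family template and PSSM seed alignment
    l_prot = config.family_protein_length
    ancestor_protein = random_protein(l_prot, rng)
    ancestor_cds = back_translate(ancestor_protein, rng)
    domain_split = int(round(l_prot * 0.69))
    truth.domain_ranges = {"SKP1": (0, domain_split), "SKP1_POZ": (domain_split, l_prot)}
    for i in range(config.n_seed_sequences):
        truth.seed_alignment[f"seed_{i:02d}"] = mutate_protein(ancestor_protein, 0.85, rng)

    # --- plan family genes: groups then singlets
    planned: list[_PlannedGene] = []
    exon2 = config.conserved_second_exon_length
    class_plan = _class_plan(config, rng)
    class_pool: list[str] = []
    for cls, n in class_plan.items():
        class_pool.extend([cls] * n)

    group_specs: list[dict] = []
    chrom_numbers = list(range(1, config.chromosomes_per_subgenome + 1))
    for gi in range(config.n_triplets):
        group_specs.append({"kind": "triplet", "subgenomes": list(SUBGENOMES)})
    for gi in range(config.n_pairs):
        subs = sorted(rng.choice(SUBGENOMES, size=2, replace=False))
        group_specs.append({"kind": "pair", "subgenomes": list(subs)})
    for i, spec in enumerate(group_specs):
        spec["group_id"] = f"G{i:02d}"
        spec["chromosome_number"] = int(chrom_numbers[i % len(chrom_numbers)])

    # one triplet diverges in structure (intron gain in one member)
    divergent_group = group_specs[0]["group_id"] if config.n_triplets > 0 else None

    def _take_class(preferred: str | None = None) -> str:
        if preferred is not None and preferred in class_pool:
            class_pool.remove(preferred)
            return preferred
        return class_pool.pop()

    rng.shuffle(class_pool)

    gene_counter = 0

    def _next_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"FAM_{gene_counter:03d}"

    for spec in group_specs:
        sub_template_prot = mutate_protein(ancestor_protein, 0.80, rng)
        sub_template_cds = back_translate(
            sub_template_prot, rng, ancestor_protein, ancestor_cds
        )
        if spec["group_id"] == divergent_group:
            member_classes = ["TypeIa_nonconserved"] + ["TypeIb"] * (
                len(spec["subgenomes"]) - 1
            )
            for cls in member_classes:
                if cls in class_pool:
                    class_pool.remove(cls)
        else:
            cls = _take_class()
            member_classes = [cls] * len(spec["subgenomes"])
        members = []
        for sub, cls in zip(spec["subgenomes"], member_classes):
            prot = mutate_protein(sub_template_prot, config.homoeolog_identity, rng)
            cds = back_translate(prot, rng, sub_template_prot, sub_template_cds)
            gid = _next_id()
            planned.append(
                _PlannedGene(
                    gene_id=gid,
                    protein=prot,
                    cds=cds,
                    structural_class=cls,
                    chromosome=ChromosomeId(spec["chromosome_number"], sub),
                    is_family=True,
                )
            )
            members.append({"gene_id": gid, "subgenome": sub})
        truth.homoeolog_groups.append(
            {
                "group_id": spec["group_id"],
                "kind": spec["kind"],
                "chromosome_number": spec["chromosome_number"],
                "members": members,
            }
        )

    # singlets: independent diverged copies; a few in tandem clusters
    singlet_genes: list[_PlannedGene] = []
    for si in range(config.n_singlets):
        prot = mutate_protein(ancestor_protein, config.diverged_identity, rng)
        cds = back_translate(prot, rng, ancestor_protein, ancestor_cds)
        cls = _take_class()
        cid = ChromosomeId(
            int(rng.integers(1, config.chromosomes_per_subgenome + 1)),
            SUBGENOMES[int(rng.integers(3))],
        )
        g = _PlannedGene(
            gene_id=_next_id(),
            protein=prot,
            cds=cds,
            structural_class=cls,
            chromosome=cid,
            is_family=True,
        )
        planned.append(g)
        singlet_genes.append(g)

    # plant exon-2 indel variants: derive two singlets from a conserved-intron
    # reference so indel reports have a known answer
    ia_cons_singlets = [g for g in singlet_genes if g.structural_class == "TypeIa_conserved"]
    ia_noncons_singlets = [g for g in singlet_genes if g.structural_class == "TypeIa_nonconserved"]
    if ia_cons_singlets and len(ia_noncons_singlets) >= 2:
        ref = ia_cons_singlets[0]
        plants = [
            {"events": [(40, 15, "deletion")], "net": -15},
            {"events": [(30, 3, "insertion"), (90, 6, "insertion")], "net": 9},
        ]
        # 0.88: close enough to the reference for a clean exon-2 alignment,
        # but safely below the 0.90 homoeolog clustering threshold
        for victim, plant in zip(ia_noncons_singlets[:2], plants):
            for attempt in range(100):
                prot = mutate_protein(ref.protein, 0.88, rng)
                cds = back_translate(prot, rng, ref.protein, ref.cds)
                exon1_len = len(cds) - exon2
                exon2_seq = cds[exon1_len:]
                ok = True
                for pos, length, kind in sorted(plant["events"], reverse=True):
                    if kind == "deletion":
                        exon2_seq = exon2_seq[:pos] + exon2_seq[pos + length :]
                    else:
                        exon2_seq = exon2_seq[:pos] + _random_nt(length, rng) + exon2_seq[pos:]
                new_cds = cds[:exon1_len] + exon2_seq
                try:
                    new_prot = translate(new_cds)
                except Exception:
                    ok = False
                if ok:
                    victim.cds = new_cds
                    victim.protein = new_prot
                    victim.structural_class = "TypeIa_nonconserved"
                    truth.exon2_indels.append(
                        {
                            "gene_id": victim.gene_id,
                            "reference_id": ref.gene_id,
                            "events": plant["events"],
                            "net_indel_bp": plant["net"],
                            "exon2_length": len(exon2_seq),
                        }
                    )
                    break

    # tandem clusters: relocate two runs of singlets onto shared chromosomes
    if len(singlet_genes) >= 8:
        for cluster, start_idx in (("T1", 0), ("T2", 4)):
            cid = singlet_genes[start_idx].chromosome
            for g in singlet_genes[start_idx : start_idx + 4]:
                g.chromosome = cid
                g.tandem_partner = cluster

    # retrocopy flags among intronless family genes
    for g in planned:
        if g.is_family and g.structural_class == "TypeIb" and rng.random() < 0.5:
            g.retro_flag = True

    # --- background genes
    for bi in range(config.n_background_genes):
        n_codons = int(rng.integers(100, 300))
        prot = random_protein(n_codons, rng)
        cds = back_translate(prot, rng)
        cid = chrom_ids[int(rng.integers(len(chrom_ids)))]
        n_exons = int(rng.integers(1, 4))
        planned.append(
            _PlannedGene(
                gene_id=f"BG_{bi + 1:03d}",
                protein=prot,
                cds=cds,
                structural_class="background",
                chromosome=cid,
                is_family=False,
            )
        )

    # --- build genomic elements and paste them
    genes: list[GeneModel] = []
    tandem_cursor: dict[tuple[ChromosomeId, str], int] = {}
    for g in planned:
        strand = "+" if rng.random() < 0.5 else "-"
        if g.is_family:
            offsets = _intron_offsets_for_class(g.structural_class, len(g.cds), exon2, rng)
            if g.structural_class == "TypeIa_nonconserved" and truth.exon2_indels:
                for rec in truth.exon2_indels:
                    if rec["gene_id"] == g.gene_id:
                        offsets = [len(g.cds) - rec["exon2_length"]]
        else:
            n_exons = int(rng.integers(1, 4))
            if n_exons == 1:
                offsets = []
            else:
                step = len(g.cds) // n_exons
                offsets = [step * k for k in range(1, n_exons)]
        segment, exon_rel, retro_info = _build_gene_element(
            g.cds, offsets, strand, rng, g.retro_flag,
            config.tsd_length, config.polya_length,
        )
        key = (g.chromosome, g.tandem_partner) if g.tandem_partner else None
        if key is not None and key in tandem_cursor:
            near_lo = tandem_cursor[key]
            near = (near_lo, min(near_lo + 30_000, lengths[g.chromosome]))
            try:
                start = placer.place(g.chromosome, len(segment), near=near)
            except CapacityError:
                start = placer.place(g.chromosome, len(segment))
        else:
            start = placer.place(g.chromosome, len(segment))
        if key is not None:
            tandem_cursor[key] = start + len(segment) + int(rng.integers(3_000, 15_000))
        chrom_arrays[g.chromosome][start : start + len(segment)] = np.frombuffer(
            segment.encode("ascii"), dtype=np.uint8
        )
        exons = [(start + s, start + e) for s, e in exon_rel]
        model = GeneModel(
            gene_id=g.gene_id,
            chromosome=g.chromosome,
            strand=strand,
            exons=exons,
            cds=g.cds,
            protein=g.protein,
        )
        genes.append(model)
        if g.is_family:
            truth.family_members.append(g.gene_id)
            truth.structural_class[g.gene_id] = g.structural_class
            if g.retro_flag and retro_info is not None:
                truth.retro_signatures[g.gene_id] = {
                    "has_tsd": True,
                    "tsd_seq": retro_info["tsd_seq"],
                    "has_polya": True,
                    "polya_length": retro_info["polya_length"],
                }

    # --- planted segmental duplications between family loci
    by_id = {g.gene_id: g for g in genes}
    family_models = [by_id[gid] for gid in truth.family_members]
    dup_lo, dup_hi = config.duplication_length_range
    id_lo, id_hi = config.duplication_identity_range
    for di in range(config.n_planted_duplications):
        planted = False
        for _ in range(200):
            ga, gb = rng.choice(family_models, size=2, replace=False)
            if ga.chromosome == gb.chromosome:
                continue
            length = int(rng.integers(dup_lo, dup_hi + 1))
            ident = float(rng.uniform(id_lo, id_hi))
            try:
                near_a = (max(0, ga.start - 80_000), min(lengths[ga.chromosome], ga.end + 80_000))
                start_a = placer.place(ga.chromosome, length, near=near_a, max_tries=50)
            except CapacityError:
                continue
            try:
                near_b = (max(0, gb.start - 80_000), min(lengths[gb.chromosome], gb.end + 80_000))
                start_b = placer.place(gb.chromosome, length, near=near_b, max_tries=50)
            except CapacityError:
                # release nothing (the reserved donor stays occupied but harmless)
                continue
            donor = (
                chrom_arrays[ga.chromosome][start_a : start_a + length]
                .tobytes()
                .decode("ascii")
            )
            copy = mutate_sequence(donor, ident, rng)
            chrom_arrays[gb.chromosome][start_b : start_b + length] = np.frombuffer(
                copy.encode("ascii"), dtype=np.uint8
            )
            truth.planted_duplications.append(
                {
                    "dup_id": f"DUP_{di:02d}",
                    "chrom_a": ga.chromosome.name,
                    "start_a": start_a,
                    "end_a": start_a + length,
                    "chrom_b": gb.chromosome.name,
                    "start_b": start_b,
                    "end_b": start_b + length,
                    "length": length,
                    "target_identity": round(ident, 4),
                }
            )
            planted = True
            break
        if not planted:
            raise CapacityError(f"could not plant duplication {di}")

    assembly = GenomeAssembly(
        {cid: arr.tobytes().decode("ascii") for cid, arr in chrom_arrays.items()}
    )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return assembly, genes, truth


# ----------------------------------------------------------------------------
# expression counts


def _build_sample_sheet(config: SimulationConfig) -> list[ExpressionSampleMeta]:
    samples: list[ExpressionSampleMeta] = []
    for tissue in ("grain", "spike", "root"):
        for rep in range(1, config.n_replicates + 1):
            samples.append(
                ExpressionSampleMeta(
                    sample_id=f"{tissue}_control_r{rep}",
                    tissue=tissue,
                    treatment="control",
                    timepoint="dev",
                    replicate=rep,
                )
            )
    for treatment in ("control", "drought", "heat", "drought_heat"):
        for rep in range(1, config.n_replicates + 1):
            samples.append(
                ExpressionSampleMeta(
                    sample_id=f"leaf_{treatment}_r{rep}",
                    tissue="leaf",
                    treatment=treatment,
                    timepoint="1h",
                    replicate=rep,
                )
            )
    return samples


def simulate_expression_counts(
    genes: list[GeneModel],
    truth: SimulatedTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[ExpressionSampleMeta]]:
    """Negative-binomial counts (genes x samples) with planted effects.

    Planted: silent genes (all-zero), tissue-specific genes, DE genes in the
    leaf heat-vs-control contrast (log2 fold change ±planted_logfc), and
    silenced members of partitioned homoeolog triplets.  Effects are recorded
    in ``truth``; re-running with the same rng state reproduces the matrix.
    """
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_654_321]))
    samples = _build_sample_sheet(config)
    gene_ids = [g.gene_id for g in genes]
    n_genes, n_samples = len(gene_ids), len(samples)

    base_log2 = rng.normal(6.0, 1.5, size=n_genes)
    lib_factor = rng.uniform(0.5, 2.0, size=n_samples)

    # per-gene x per-sample mean matrix on the linear scale
    mean = np.outer(2.0 ** base_log2, np.ones(n_samples))

    idx = {gid: i for i, gid in enumerate(gene_ids)}
    tissue_of = np.array([s.tissue for s in samples])
    treatment_of = np.array([s.treatment for s in samples])

    # silent genes: never expressed anywhere
    family = list(truth.family_members)
    non_family = [g for g in gene_ids if g not in set(family)]
    silent = list(rng.choice(non_family, size=min(config.n_silent_genes, len(non_family)),
                             replace=False))
    truth.silent_genes = sorted(silent)
    for gid in silent:
        mean[idx[gid], :] = 0.0

    # tissue-specific family genes (grain)
    candidates = [g for g in family if g not in silent]
    rng.shuffle(candidates)
    n_ts = min(config.n_tissue_specific, len(candidates) // 4)
    for gid in candidates[:n_ts]:
        i = idx[gid]
        mean[i, :] = 4.0
        mean[i, tissue_of == "grain"] = 2.0 ** 10
        truth.tissue_specific.append({"gene_id": gid, "tissue": "grain"})
    constitutive = candidates[n_ts : n_ts + 18]
    truth.constitutive_genes = sorted(constitutive)

    # partitioned triplets: one member silenced
    triplets = [g for g in truth.homoeolog_groups if g["kind"] == "triplet"]
    for group in triplets[: config.n_partitioned_triplets]:
        silenced = group["members"][int(rng.integers(len(group["members"])))]["gene_id"]
        i = idx[silenced]
        mean[i, :] = np.maximum(mean[i, :] / 200.0, 0.2)
        truth.partitioned_triplets.append(
            {"group_id": group["group_id"], "silenced_member": silenced}
        )

    # DE genes in the leaf heat-vs-control contrast; keep the planted effect
    # clean of the other planted expression patterns
    contrast = "leaf:heat-vs-control"
    de_mask = (tissue_of == "leaf") & (treatment_of == "heat")
    excluded = set(silent)
    excluded.update(r["gene_id"] for r in truth.tissue_specific)
    excluded.update(r["silenced_member"] for r in truth.partitioned_triplets)
    expressed = [g for g in gene_ids if g not in excluded]
    n_de = int(round(config.de_fraction * len(expressed)))
    if config.planted_logfc != 0.0 and n_de > 0:
        de_genes = list(rng.choice(expressed, size=n_de, replace=False))
        for gid in de_genes:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * config.planted_logfc
            mean[idx[gid], de_mask] *= 2.0 ** lfc
            truth.de_genes.append({"gene_id": gid, "contrast": contrast, "logfc": lfc})

    mu = mean * lib_factor[None, :]
    phi = config.nb_dispersion
    r = 1.0 / phi
    counts = np.zeros((n_genes, n_samples), dtype=np.int64)
    positive = mu > 0
    p = r / (r + mu[positive])
    counts[positive] = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=gene_ids, columns=[s.sample_id for s in samples])
    df.index.name = "gene_id"
    return df, samples


# ----------------------------------------------------------------------------
# truth / output serialisation


def _df(rows: list[dict], columns: list[str]) -> pd.DataFrame:
    """DataFrame that keeps its header even when there are no rows."""
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


def write_truth(truth: SimulatedTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in truth.homoeolog_groups:
        for m in g["members"]:
            rows.append(
                {
                    "group_id": g["group_id"],
                    "kind": g["kind"],
                    "chromosome_number": g["chromosome_number"],
                    "gene_id": m["gene_id"],
                    "subgenome": m["subgenome"],
                }
            )
    write_tsv(
        _df(rows, ["group_id", "kind", "chromosome_number", "gene_id", "subgenome"]),
        outdir / "homoeolog_groups.tsv",
    )
    write_tsv(
        _df(
            [{"gene_id": k, "structural_class": v} for k, v in truth.structural_class.items()],
            ["gene_id", "structural_class"],
        ),
        outdir / "structural_classes.tsv",
    )
    write_tsv(
        _df(
            truth.planted_duplications,
            ["dup_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
             "length", "target_identity"],
        ),
        outdir / "planted_duplications.tsv",
    )
    write_tsv(
        _df(
            [{"gene_id": k, **v} for k, v in truth.retro_signatures.items()],
            ["gene_id", "has_tsd", "tsd_seq", "has_polya", "polya_length"],
        ),
        outdir / "retro_signatures.tsv",
    )
    write_tsv(_df(truth.de_genes, ["gene_id", "contrast", "logfc"]), outdir / "de_genes.tsv")
    write_tsv(
        _df(truth.partitioned_triplets, ["group_id", "silenced_member"]),
        outdir / "partitioned_triplets.tsv",
    )
    write_tsv(
        _df([{"gene_id": g} for g in truth.silent_genes], ["gene_id"]),
        outdir / "silent_genes.tsv",
    )
    write_tsv(
        _df(
            [
                {
                    "gene_id": r["gene_id"],
                    "reference_id": r["reference_id"],
                    "net_indel_bp": r["net_indel_bp"],
                    "exon2_length": r["exon2_length"],
                    "events": json.dumps(r["events"]),
                }
                for r in truth.exon2_indels
            ],
            ["gene_id", "reference_id", "net_indel_bp", "exon2_length", "events"],
        ),
        outdir / "exon2_indels.tsv",
    )
    write_tsv(
        _df([{"gene_id": g} for g in truth.family_members], ["gene_id"]),
        outdir / "family_members.tsv",
    )
    write_fasta(truth.seed_alignment, outdir / "seed_alignment.fasta")
    write_tsv(
        _df(
            [{"domain": d, "start": s, "end": e} for d, (s, e) in truth.domain_ranges.items()],
            ["domain", "start", "end"],
        ),
        outdir / "domain_ranges.tsv",
    )
    write_tsv(
        _df(truth.tissue_specific, ["gene_id", "tissue"]), outdir / "tissue_specific.tsv"
    )
    write_tsv(
        _df([{"gene_id": g} for g in truth.constitutive_genes], ["gene_id"]),
        outdir / "constitutive_genes.tsv",
    )


def read_truth(outdir: str | Path) -> SimulatedTruth:
    outdir = Path(outdir)
    truth = SimulatedTruth()
    df = read_tsv(outdir / "homoeolog_groups.tsv")
    for gid, sub in df.groupby("group_id", sort=False):
        truth.homoeolog_groups.append(
            {
                "group_id": gid,
                "kind": sub.iloc[0]["kind"],
                "chromosome_number": int(sub.iloc[0]["chromosome_number"]),
                "members": [
                    {"gene_id": r.gene_id, "subgenome": r.subgenome}
                    for r in sub.itertuples()
                ],
            }
        )
    df = read_tsv(outdir / "structural_classes.tsv")
    truth.structural_class = dict(zip(df.gene_id, df.structural_class))
    df = read_tsv(outdir / "planted_duplications.tsv")
    truth.planted_duplications = df.to_dict("records") if not df.empty else []
    df = read_tsv(outdir / "retro_signatures.tsv")
    if not df.empty:
        for r in df.to_dict("records"):
            gid = r.pop("gene_id")
            truth.retro_signatures[gid] = r
    df = read_tsv(outdir / "de_genes.tsv")
    truth.de_genes = df.to_dict("records") if not df.empty else []
    df = read_tsv(outdir / "partitioned_triplets.tsv")
    truth.partitioned_triplets = df.to_dict("records") if not df.empty else []
    df = read_tsv(outdir / "silent_genes.tsv")
    truth.silent_genes = list(df.gene_id) if not df.empty else []
    df = read_tsv(outdir / "exon2_indels.tsv")
    for r in df.to_dict("records") if not df.empty else []:
        r["events"] = [tuple(e) for e in json.loads(r["events"])]
        truth.exon2_indels.append(r)
    df = read_tsv(outdir / "family_members.tsv")
    truth.family_members = list(df.gene_id)
    from .io import read_fasta

    truth.seed_alignment = read_fasta(outdir / "seed_alignment.fasta")
    df = read_tsv(outdir / "domain_ranges.tsv")
    truth.domain_ranges = {r.domain: (int(r.start), int(r.end)) for r in df.itertuples()}
    df = read_tsv(outdir / "tissue_specific.tsv")
    truth.tissue_specific = df.to_dict("records") if not df.empty else []
    df = read_tsv(outdir / "constitutive_genes.tsv")
    truth.constitutive_genes = list(df.gene_id) if not df.empty else []
    return truth


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
) -> tuple[GenomeAssembly, list[GeneModel], SimulatedTruth]:
    """Run the full simulation and serialise every artefact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, genes, truth = simulate_genome(config)
    counts, samples = simulate_expression_counts(genes, truth, config)
    write_assembly(assembly, outdir / "assembly.fasta")
    write_gff3(genes, outdir / "genes.gff3")
    write_fasta({g.gene_id: g.cds for g in genes}, outdir / "cds.fasta")
    write_fasta({g.gene_id: g.protein for g in genes}, outdir / "proteins.fasta")
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    write_tsv(
        pd.DataFrame([dataclasses.asdict(s) for s in samples]), outdir / "samples.tsv"
    )
    seeds_dir = outdir / "seeds"
    seeds_dir.mkdir(exist_ok=True)
    for domain, (start, end) in truth.domain_ranges.items():
        write_fasta(
            {name: aln[start:end] for name, aln in truth.seed_alignment.items()},
            seeds_dir / f"{domain}.fasta",
        )
    write_truth(truth, outdir / "truth")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    return assembly, genes, truth
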