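"""End-to-end orchestration: identify -> classify -> homoeologs -> dupscan -> express.

Stages communicate exclusively through files (FASTA/GFF3/TSV) under the
output directory, so each stage can be re-run and tested in isolation.  The
run report collects per-stage record counts and is deterministic for a
fixed config and seed; wall-clock timings go to the log and a separate
timings file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dupscan as dup
from . import expression as expr
from . import family as fam
from . import homoeology as hom
from . import structure as struct
from .io import (
    read_assembly,
    read_fasta,
    read_gff3,
    read_tsv,
    write_chromosome_map,
    write_tsv,
)
from .models import ExpressionSampleMeta, GeneModel, PolyfamError, SUBGENOMES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    assembly: str = ""
    gff3: str = ""
    proteins: str = ""
    counts: str = ""
    samples: str = ""
    seeds_dir: str = ""
    out_dir: str = "polyfam_out"
    seed: int = 0
    # stage toggles
    run_identify: bool = True
    run_classify: bool = True
    run_homoeologs: bool = True
    run_dupscan: bool = True
    run_express: bool = True
    # parameters
    scan_evalue: float = fam.SCAN_EVALUE_DEFAULT
    search_evalue: float = fam.SEARCH_EVALUE_DEFAULT
    n_shuffles: int = 200
    cluster_identity: float = 0.90
    flank: int = dup.DEFAULT_FLANK
    merge_gap: int = dup.DEFAULT_MERGE_GAP
    min_dup_identity: float = dup.MIN_IDENTITY
    min_dup_length: int = dup.MIN_LENGTH
    max_dup_evalue: float = dup.MAX_EVALUE
    min_cpm: float = 1.0
    min_cpm_samples: int = 3
    lfc_threshold: float = 1.0
    alpha: float = 0.05

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        flat.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise PolyfamError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self) -> None:
        checks = [
            (self.run_identify or self.run_homoeologs, self.proteins, "proteins"),
            (self.run_classify or self.run_dupscan, self.assembly, "assembly"),
            (self.run_classify or self.run_homoeologs or self.run_dupscan, self.gff3, "gff3"),
            (self.run_express, self.counts, "counts"),
            (self.run_express, self.samples, "samples"),
            (self.run_identify, self.seeds_dir, "seeds_dir"),
        ]
        for needed, path, name in checks:
            if needed and not path:
                raise PolyfamError(f"config: {name} path required for the enabled stages")
            if needed and path and not Path(path).exists():
                raise PolyfamError(f"config: {name} path {path} does not exist")


def make_table1(genes: list[GeneModel]) -> pd.DataFrame:
    """Per-chromosome gene counts: 7 rows x A/B/D columns with totals."""
    table = pd.DataFrame(
        0, index=pd.Index(range(1, 8), name="chromosome"), columns=list(SUBGENOMES)
    )
    for g in genes:
        table.loc[g.chromosome.number, g.chromosome.subgenome] += 1
    table["total"] = table.sum(axis=1)
    totals = table.sum(axis=0)
    table.loc["total"] = totals
    return table


def table1_from_counts(counts: dict[tuple[int, str], int]) -> pd.DataFrame:
    """Same table built from printed (chromosome, subgenome) -> count entries."""
    table = pd.DataFrame(
        0, index=pd.Index(range(1, 8), name="chromosome"), columns=list(SUBGENOMES)
    )
    for (number, subgenome), n in counts.items():
        table.loc[number, subgenome] = n
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def _read_seed_pssms(seeds_dir: str | Path) -> list[fam.ProfileMatrix]:
    seeds_dir = Path(seeds_dir)
    pssms = []
    for path in sorted(seeds_dir.glob("*.fasta")):
        alignment = list(read_fasta(path).values())
        pssms.append(fam.build_pssm(alignment, name=path.stem))
    if not pssms:
        raise PolyfamError(f"no seed alignment FASTA files in {seeds_dir}")
    return pssms


def stage_identify(config: PipelineConfig, out: Path) -> list[str]:
    proteome = read_fasta(config.proteins)
    pssms = _read_seed_pssms(config.seeds_dir)
    members = fam.iterative_family_search(
        proteome,
        pssms,
        scan_threshold=config.scan_evalue,
        search_threshold=config.search_evalue,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
    )
    rows = []
    for pid in sorted(members):
        for hit in members[pid]:
            rows.append(
                {
                    "protein_id": pid,
                    "domain": hit.domain,
                    "start": hit.start,
                    "end": hit.end,
                    "score": round(hit.score, 3),
                    "evalue": hit.evalue,
                }
            )
    write_tsv(
        pd.DataFrame(rows, columns=["protein_id", "domain", "start", "end", "score", "evalue"]),
        out / "members.tsv",
    )
    return sorted(members)


def stage_classify(
    config: PipelineConfig, member_ids: list[str], out: Path
) -> dict[str, str]:
    assembly = read_assembly(config.assembly)
    genes = {g.gene_id: g for g in read_gff3(config.gff3, assembly)}
    members = [genes[m] for m in member_ids if m in genes]

    one_intron = [g for g in members if g.intron_count == 1]
    conserved_refs = [g for g in one_intron if struct.canonical_conserved_rule(g)]
    classes: dict[str, str] = {}
    rows = []
    for g in members:
        ref = None
        if g.intron_count == 1 and conserved_refs:
            ref = struct.nearest_conserved_reference(g, conserved_refs)
        cls = struct.classify_structure(g, reference=ref)
        classes[g.gene_id] = cls
        second_exon = (
            g.exon_cds_lengths()[1] if len(g.exons) >= 2 else 0
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "class": cls,
                "intron_count": g.intron_count,
                "second_exon_len": second_exon,
                "conserved_flag": cls == "TypeIa_conserved",
            }
        )
    write_tsv(pd.DataFrame(rows), out / "classes.tsv")

    indel_rows = []
    for g in members:
        if classes[g.gene_id] != "TypeIa_nonconserved" or not conserved_refs:
            continue
        ref = struct.nearest_conserved_reference(g, conserved_refs)
        if ref is None or len(ref.exons) < 2 or len(g.exons) < 2:
            continue
        report = struct.detect_second_exon_indels(g, ref)
        indel_rows.append(
            {
                "gene_id": report.gene_id,
                "reference_id": report.reference_id,
                "net_indel_bp": report.net_indel_bp,
                "events": json.dumps(report.events),
            }
        )
    write_tsv(
        pd.DataFrame(indel_rows, columns=["gene_id", "reference_id", "net_indel_bp", "events"]),
        out / "second_exon_indels.tsv",
    )

    retro_rows = []
    for g in members:
        if g.intron_count != 0:
            continue
        sig = struct.scan_retro_signatures(g, assembly)
        retro_rows.append(
            {
                "gene_id": g.gene_id,
                "has_polya": sig.has_polya,
                "has_tsd": sig.has_tsd,
                "tsd_seq": sig.tsd_seq or "",
            }
        )
    write_tsv(
        pd.DataFrame(retro_rows, columns=["gene_id", "has_polya", "has_tsd", "tsd_seq"]),
        out / "retro_signatures.tsv",
    )
    write_chromosome_map(members, out / "chromosome_map.tsv")
    return classes


def stage_homoeologs(
    config: PipelineConfig, member_ids: list[str], classes: dict[str, str], out: Path
) -> hom.GroupSummary:
    proteome = read_fasta(config.proteins)
    assembly = read_assembly(config.assembly)
    genes = {g.gene_id: g for g in read_gff3(config.gff3, assembly)}
    sequences = {m: proteome[m] for m in member_ids if m in proteome}
    clusters = hom.greedy_cluster(sequences, threshold=config.cluster_identity)
    locations = {
        m: (genes[m].chromosome, genes[m].span) for m in sequences if m in genes
    }
    groups = hom.assign_homoeolog_groups(clusters, locations)
    summary = hom.summarize_groups(groups, total_genes=len(sequences))

    write_tsv(
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "representative": c.representative,
                    "member": m,
                    "identity_to_rep": round(c.identity_to_rep[m], 4),
                }
                for c in clusters
                for m in c.members
            ]
        ),
        out / "clusters.tsv",
    )
    group_rows = []
    for g in groups:
        divergent = ""
        if g.kind != "singlet" and classes:
            try:
                flag, _cls, notes = hom.compare_group_structures(g, classes)
                divergent = str(flag)
            except PolyfamError:
                divergent = ""
        for gene_id, sub in g.members:
            group_rows.append(
                {
                    "group_id": g.group_id,
                    "kind": g.kind,
                    "chromosome_number": g.chromosome_number if g.chromosome_number else "",
                    "gene_id": gene_id,
                    "subgenome": sub,
                    "structure_divergent": divergent,
                }
            )
    write_tsv(pd.DataFrame(group_rows), out / "groups.tsv")
    write_tsv(
        pd.DataFrame([dataclasses.asdict(summary)]), out / "group_summary.tsv"
    )
    return summary


def stage_dupscan(config: PipelineConfig, member_ids: list[str], out: Path):
    assembly = read_assembly(config.assembly)
    genes = {g.gene_id: g for g in read_gff3(config.gff3, assembly)}
    members = [genes[m] for m in member_ids if m in genes]
    windows, fragments, summary = dup.scan_duplications(
        assembly,
        members,
        flank=config.flank,
        merge_gap=config.merge_gap,
        min_identity=config.min_dup_identity,
        min_length=config.min_dup_length,
        max_evalue=config.max_dup_evalue,
    )
    with open(out / "windows.bed", "w") as fh:
        for w in windows:
            fh.write(
                f"{w.chromosome.name}\t{w.start}\t{w.end}\t{w.window_id};"
                + ",".join(w.contained_genes)
                + "\n"
            )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "fragment_id": f.fragment_id,
                    "window_a": f.window_a.window_id,
                    "window_b": f.window_b.window_id,
                    "chrom_a": f.window_a.chromosome.name,
                    "start_a": f.coords_a[0],
                    "end_a": f.coords_a[1],
                    "chrom_b": f.window_b.chromosome.name,
                    "start_b": f.coords_b[0],
                    "end_b": f.coords_b[1],
                    "strand": f.strand,
                    "length": f.length,
                    "identity": round(f.identity, 4),
                    "evalue": f.evalue,
                }
                for f in fragments
            ],
            columns=[
                "fragment_id", "window_a", "window_b", "chrom_a", "start_a", "end_a",
                "chrom_b", "start_b", "end_b", "strand", "length", "identity", "evalue",
            ],
        ),
        out / "fragments.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom_a": f.window_a.chromosome.name,
                    "start_a": f.coords_a[0],
                    "end_a": f.coords_a[1],
                    "chrom_b": f.window_b.chromosome.name,
                    "start_b": f.coords_b[0],
                    "end_b": f.coords_b[1],
                }
                for f in fragments
            ],
            columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"],
        ),
        out / "links.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "n_fragments": summary.n_fragments,
                    "min_len": summary.min_len,
                    "max_len": summary.max_len,
                    "mean_len": summary.mean_len,
                    "median_len": summary.median_len,
                }
            ]
        ),
        out / "duplication_summary.tsv",
    )
    write_tsv(
        pd.DataFrame(summary.edges, columns=["window_a", "window_b", "n_fragments"]),
        out / "duplication_graph.tsv",
    )
    return summary


def _read_samples(path: str | Path) -> list[ExpressionSampleMeta]:
    df = read_tsv(path)
    return [
        ExpressionSampleMeta(
            sample_id=r.sample_id,
            tissue=r.tissue,
            treatment=r.treatment,
            timepoint=str(r.timepoint),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def stage_express(
    config: PipelineConfig, member_ids: list[str], out: Path
) -> dict[str, int]:
    counts = read_tsv(config.counts, index_col=0)
    samples = _read_samples(config.samples)
    matrix = expr.CountMatrix(counts, samples)
    filtered = expr.filter_low_expression(
        matrix, min_cpm=config.min_cpm, min_samples=config.min_cpm_samples
    )
    factors = expr.tmm_factors(filtered)
    normalized = expr.log_cpm(filtered, factors)
    normalized.logcpm.round(4).to_csv(out / "normalized_logcpm.tsv", sep="\t")

    # stress contrasts within the leaf samples
    deg_counts: dict[str, int] = {}
    leaf = [s for s in samples if s.tissue == "leaf"]
    leaf_cols = [s.sample_id for s in leaf]
    union_degs: set[str] = set()
    contrast_tables = {}
    for treatment in ("drought", "heat", "drought_heat"):
        cols = [s.sample_id for s in leaf if s.treatment in (treatment, "control")]
        metas = [s for s in leaf if s.sample_id in cols]
        if sum(1 for s in metas if s.treatment == treatment) < 2:
            continue
        sub = expr.CountMatrix(filtered.counts[cols], metas)
        f = expr.tmm_factors(sub)
        norm = expr.log_cpm(sub, f)
        grp = [s.treatment for s in metas]
        weights = expr.voom_weights(norm, grp)
        res = expr.moderated_t_test(norm, grp, (treatment, "control"), weights=weights)
        res = expr.call_degs(res, lfc_threshold=config.lfc_threshold, alpha=config.alpha)
        name = f"leaf:{treatment}-vs-control"
        res.table.round(6).to_csv(out / f"contrast_{treatment}.tsv", sep="\t")
        deg_counts[name] = int(res.table["is_deg"].sum())
        union_degs |= set(res.table.index[res.table["is_deg"]])
        contrast_tables[name] = res

    if union_degs:
        deg_list = sorted(union_degs)
        sub = normalized.logcpm.loc[deg_list]
        if len(deg_list) >= 2:
            dend = expr.hierarchical_cluster(sub)
            (out / "deg_dendrogram.nwk").write_text(dend.newick() + "\n")
        if len(deg_list) >= 2 and normalized.logcpm.shape[1] >= 3:
            corr = expr.pearson_matrix(normalized, deg_list)
            corr.round(4).to_csv(out / "deg_correlations.tsv", sep="\t")

    # homoeolog expression partitioning (needs the groups file)
    groups_path = out / "groups.tsv"
    call_rows = []
    if groups_path.exists():
        gdf = read_tsv(groups_path)
        for gid, sub_df in gdf.groupby("group_id", sort=False):
            kind = sub_df.iloc[0]["kind"]
            if kind not in ("triplet", "pair", "probable_triplet", "probable_pair"):
                continue
            number = sub_df.iloc[0]["chromosome_number"]
            group = hom.HomoeologGroup(
                group_id=gid,
                kind=kind,
                chromosome_number=int(number) if str(number).strip() else None,
                members=[(r.gene_id, r.subgenome) for r in sub_df.itertuples()],
            )
            call = expr.classify_homoeolog_expression(group, normalized)
            call_rows.append(
                {
                    "group_id": call.group_id,
                    "kind": kind,
                    "call": call.call,
                    "silenced_or_divergent": ",".join(call.silenced_or_divergent),
                }
            )
    write_tsv(
        pd.DataFrame(call_rows, columns=["group_id", "kind", "call", "silenced_or_divergent"]),
        out / "homoeolog_expression.tsv",
    )

    breadth = expr.categorize_expression_breadth(
        normalized, [s.tissue for s in samples if s.sample_id in normalized.logcpm.columns]
    )
    breadth.round(4).to_csv(out / "expression_breadth.tsv", sep="\t")
    deg_counts["retained_genes"] = filtered.n_genes
    return deg_counts


@dataclass
class RunReport:
    seed: int
    counts: dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"key": "seed", "value": self.seed}]
        for k in sorted(self.counts):
            rows.append({"key": k, "value": self.counts[k]})
        return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order and write the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    timings = []

    def _stage(name: str, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise
        timings.append({"stage": name, "seconds": round(time.time() - t0, 2)})
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
        return result

    member_ids: list[str] = []
    classes: dict[str, str] = {}
    if config.run_identify:
        member_ids = _stage("identify", lambda: stage_identify(config, out))
        report.counts["family_members"] = len(member_ids)
    elif (out / "members.tsv").exists():
        member_ids = sorted(set(read_tsv(out / "members.tsv")["protein_id"]))

    if config.run_classify:
        classes = _stage("classify", lambda: stage_classify(config, member_ids, out))
        for cls in struct_classes_order():
            report.counts[f"class_{cls}"] = sum(1 for c in classes.values() if c == cls)

    if config.run_homoeologs:
        summary = _stage(
            "homoeologs", lambda: stage_homoeologs(config, member_ids, classes, out)
        )
        report.counts["clusters"] = len(
            set(read_tsv(out / "clusters.tsv")["cluster_id"])
        )
        report.counts["triplets"] = summary.n_triplets
        report.counts["pairs"] = summary.n_pairs
        report.counts["grouped_members"] = summary.grouped_members
        report.counts["singlets"] = summary.singlets

    if config.run_dupscan:
        dsummary = _stage("dupscan", lambda: stage_dupscan(config, member_ids, out))
        report.counts["duplication_fragments"] = dsummary.n_fragments
        if dsummary.n_fragments:
            report.counts["duplication_median_len"] = dsummary.median_len
            report.counts["duplication_mean_len"] = round(dsummary.mean_len, 1)

    if config.run_express:
        deg_counts = _stage("express", lambda: stage_express(config, member_ids, out))
        for k, v in deg_counts.items():
            report.counts[f"express_{k}"] = v

    write_tsv(report.to_frame(), out / "report.tsv")
    write_tsv(pd.DataFrame(timings), out / "timings.tsv")
    _self_check(report, out)
    return report


def struct_classes_order() -> tuple[str, ...]:
    return ("TypeIa_conserved", "TypeIa_nonconserved", "TypeIb", "TypeII")


def _self_check(report: RunReport, out: Path) -> None:
    """Cross-check report counts against the stage output files."""
    if "family_members" in report.counts and (out / "members.tsv").exists():
        n = len(set(read_tsv(out / "members.tsv")["protein_id"]))
        if n != report.counts["family_members"]:
            raise PolyfamError("report inconsistency: family_members")
    if "duplication_fragments" in report.counts and (out / "fragments.tsv").exists():
        n = len(read_tsv(out / "fragments.tsv"))
        if n != report.counts["duplication_fragments"]:
            raise PolyfamError("report inconsistency: duplication_fragments")
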