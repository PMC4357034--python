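"""End-to-end orchestration: scan -> map -> classify -> phylogeny ->
selection -> expression, as one reproducible, seeded run.

Every stage logs counts in/out; (config, seed) fully determine every
output byte. A stage failure aborts the run with the stage name and
removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import expression as _expression
from . import genome_io, homology_scan, msa_positionmap, phylo, selection

logger = logging.getLogger("htrscan")

CLASS_ORDER = ("CENH3", "H3_1", "H3_1A", "H3_3", "H3_LIKE")


@dataclass
class RunConfig:
    proteome: str
    cds: str
    queries: str
    outdir: str
    reference: str | None = None  # None -> bundled synthetic reference
    gff3: str | None = None
    expression_matrix: str | None = None
    tissue_groups: str | None = None
    seed: int = 42
    evalue_threshold: float = 1e-10
    min_core_coverage: float = 0.8
    bootstrap_replicates: int = 200
    min_support: float = 70.0
    cenh3_min_overhang: int = 15
    cenh3_max_core_identity: float = 0.75
    alpha: float = 0.05
    detection_floor: float = 1.0
    cv_max: float = 0.25
    archetype_delta: float = 1.0
    species: str = "synthetic"

    def validate(self) -> None:
        if not (0 < self.evalue_threshold):
            raise ValueError("evalue_threshold out of range")
        if not (0 <= self.min_support <= 100):
            raise ValueError("min_support out of range")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha out of range")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates out of range")

    def serialize(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")


@dataclass
class PipelineResult:
    calls: list
    counts: pd.DataFrame
    cenh3_clade: set[str]
    selection: dict[str, "selection.SelectionResult"]
    cluster: "_expression.ClusterResult | None"
    archetypes: dict[str, str]
    outdir: Path


_CURRENT_STAGE = ["setup"]


def _stage(name: str) -> None:
    _CURRENT_STAGE[0] = name
    logger.info("stage: %s", name)


_OUTPUT_FILES = (
    "report.tsv",
    "counts.tsv",
    "tree.nwk",
    "cenh3_clade.txt",
    "selection.tsv",
    "lysine_audit.tsv",
    "clustered.tsv",
    "merge_tree.tsv",
    "archetypes.tsv",
    "config.txt",
)


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _CURRENT_STAGE[0] = "setup"
    try:
        return _run(config, outdir)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        for name in _OUTPUT_FILES:
            p = outdir / name
            if p.exists():
                p.unlink()
        raise RuntimeError(f"pipeline aborted at stage {_CURRENT_STAGE[0]!r}: {exc}") from exc


def _run(config: RunConfig, outdir: Path) -> PipelineResult:
    _stage("read inputs")
    proteome = genome_io.read_fasta(config.proteome, "protein")
    cds_map = {r.id: r for r in genome_io.read_fasta(config.cds, "dna")}
    queries = genome_io.read_fasta(config.queries, "protein")
    reference = (
        genome_io.read_fasta(config.reference, "protein")[0]
        if config.reference
        else msa_positionmap.default_reference()
    )
    gene_models = genome_io.read_gff3_gene_models(config.gff3) if config.gff3 else {}
    anchors = [q.id for q in queries if "cenh3" in q.id.lower()]
    known_non_cenh3 = {q.id for q in queries if q.id not in anchors}

    _stage("homology scan")
    scan_cfg = homology_scan.ScanConfig(
        evalue_threshold=config.evalue_threshold,
        min_core_coverage=config.min_core_coverage,
    )
    candidates = homology_scan.scan_proteome(proteome, queries, gene_models, cds_map, scan_cfg)
    logger.info("scan: %d/%d proteome entries hit", len(candidates), len(proteome))

    _stage("filters")
    candidates = homology_scan.filter_candidates(candidates, scan_cfg)
    kept = [c for c in candidates if c.filter_status == "kept"]
    logger.info(
        "filters: %d kept / %d redundant / %d isoform / %d incomplete",
        len(kept),
        *(sum(1 for c in candidates if c.filter_status == s) for s in ("redundant", "isoform", "incomplete")),
    )
    if not kept:
        raise ValueError("no candidates survive filtering")

    _stage("alignment and phylogeny")
    tree = None
    boot = None
    msa_records = [c.protein for c in kept] + [q for q in queries]
    if len(msa_records) >= 4:
        aln = msa_positionmap.progressive_msa(msa_records)
        boot = phylo.bootstrap_support(
            aln, config.bootstrap_replicates, seed=config.seed, model="poisson"
        )
        tree = boot.tree
        phylo.write_newick(tree, outdir / "tree.nwk")

    _stage("classification")
    cen_params = _classify.CenH3Params(
        min_support=config.min_support,
        min_overhang=config.cenh3_min_overhang,
        max_core_identity=config.cenh3_max_core_identity,
    )
    calls = []
    for c in kept:
        pmap = msa_positionmap.map_to_reference(c.protein, reference)
        sig = _classify.extract_signature(pmap)
        evidence = _classify.detect_cenh3(
            pmap, tree=tree, anchors=anchors, params=cen_params, known_non_cenh3=known_non_cenh3
        )
        gm = c.gene_model
        introns = gm.representative_intron_count if gm is not None else None
        calls.append(
            _classify.classify_variant(
                sig, introns, evidence, gene_id=c.gene_id, species=config.species
            )
        )
    genome_io.write_variant_report(calls, outdir / "report.tsv")
    audit = _classify.audit_lysines(calls)
    audit.to_csv(outdir / "lysine_audit.tsv", sep="\t", index=False, lineterminator="\n")

    cenh3_clade: set[str] = set()
    if tree is not None and anchors:
        cenh3_clade = phylo.find_anchored_clade(tree, anchors, config.min_support)
    with open(outdir / "cenh3_clade.txt", "w", encoding="utf-8", newline="\n") as fh:
        for leaf in sorted(cenh3_clade):
            fh.write(leaf + "\n")

    _stage("selection")
    selection_results: dict[str, selection.SelectionResult] = {}
    call_of = {c.gene_id: c for c in calls}
    for cls in CLASS_ORDER:
        members = [c for c in kept if call_of[c.gene_id].variant_class == cls and c.cds is not None]
        if len(members) < 2:
            continue
        if len(members) == 2:
            paln = msa_positionmap.global_align_pair(members[0].protein, members[1].protein)
        else:
            paln = msa_positionmap.progressive_msa([m.protein for m in members])
        try:
            ca = selection.backtranslate(paln, {m.gene_id: m.cds.seq for m in members})
            res = selection.group_dnds(ca, group=cls)
        except ValueError as exc:
            logger.warning("selection skipped for %s: %s", cls, exc)
            continue
        if len(members) >= 3:
            try:
                gtree = phylo.neighbor_joining(phylo.protein_distance(paln, "poisson"))
                site_res = selection.site_selection(ca, gtree, alpha=config.alpha, group=cls)
                res.per_site = site_res.per_site
            except ValueError as exc:
                logger.warning("site selection skipped for %s: %s", cls, exc)
        selection_results[cls] = res
    _write_selection_tsv(selection_results, outdir / "selection.tsv")

    _stage("expression")
    cluster = None
    archetypes: dict[str, str] = {}
    if config.expression_matrix:
        matrix = genome_io.read_expression_tsv(config.expression_matrix)
        processed = _expression.preprocess(matrix, config.detection_floor)
        cluster = _expression.hierarchical_cluster(processed)
        _expression.write_clustered_tsv(processed, cluster, outdir / "clustered.tsv")
        _expression.write_merge_tree_tsv(cluster, outdir / "merge_tree.tsv")
        if config.tissue_groups:
            groups = _read_tissue_groups(config.tissue_groups)
            raw = {g: row for g, row in zip(matrix.gene_ids, matrix.values)}
            for g in processed.gene_ids:
                archetypes[g] = _expression.call_profile_archetype(
                    raw[g], matrix.tissue_labels, groups, config.cv_max, config.archetype_delta
                )
            with open(outdir / "archetypes.tsv", "w", encoding="utf-8", newline="\n") as fh:
                fh.write("gene_id\tarchetype\n")
                for g in sorted(archetypes):
                    fh.write(f"{g}\t{archetypes[g]}\n")

    _stage("summary")
    counts = summarize_counts(calls)
    counts.to_csv(outdir / "counts.tsv", sep="\t", lineterminator="\n")
    config.serialize(outdir / "config.txt")
    if boot is not None:
        logger.info("bootstrap skip rate: %.3f", boot.skip_rate)
    return PipelineResult(calls, counts, cenh3_clade, selection_results, cluster, archetypes, outdir)


def _read_tissue_groups(path: str) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("tissue\t"):
                continue
            tissue, group = line.split("\t")[:2]
            groups[tissue] = group
    return groups


def summarize_counts(calls: list) -> pd.DataFrame:
    """Per-species x per-class gene counts with a total row."""
    if not calls:
        return pd.DataFrame(columns=list(CLASS_ORDER) + ["total"])
    species = sorted({c.species for c in calls})
    rows = {}
    for sp in species:
        counts = {cls: sum(1 for c in calls if c.species == sp and c.variant_class == cls) for cls in CLASS_ORDER}
        counts["total"] = sum(counts.values())
        rows[sp] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CLASS_ORDER) + ["total"])
    df.loc["total"] = df.sum()
    df.index.name = "species"
    return df


def _write_selection_tsv(results: dict[str, "selection.SelectionResult"], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "group\trecord\tsite\tdN\tdS\tratio\tNd\tSd\texpected_syn_fraction\tp_negative\tp_positive\tclass\n"
        )
        for cls in sorted(results):
            r = results[cls]
            ratio = "NA" if r.ratio is None else f"{r.ratio:.4f}"
            fh.write(
                f"{cls}\tglobal\t.\t{r.dn:.4f}\t{r.ds:.4f}\t{ratio}\t.\t.\t.\t.\t.\t.\n"
            )
            for s in r.per_site:
                fh.write(
                    f"{cls}\tsite\t{s.site_index}\t.\t.\t.\t{s.nd:.3f}\t{s.sd:.3f}"
                    f"\t{s.expected_syn_fraction:.3f}\t{s.p_negative:.4g}\t{s.p_positive:.4g}\t{s.site_class}\n"
                )
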