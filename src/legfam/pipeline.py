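"""End-to-end pipeline driver.

Reads per-species proteomes (FASTA) and gene models (GFF3) from an input
directory, runs domain scanning, classification, phylogeny-based subgroup
assignment, gene-structure, duplication, orthology and (when expression
inputs are present) expression stages, and writes one TSV per stage plus a
Table-1-style summary per species, a manifest and a log into the run
directory.  Stages are plain functions and re-runnable individually; a
stage failure halts the run with the stage name while keeping the outputs
written so far.

All thresholds default to the values used throughout legume family
surveys: BLASTP mining at e<=1e-5, duplication at identity>=80% and
e<=1e-10 within a 5-Mb tandem window, BBH orthology at e<=1e-10, and
bootstrap with 5000 replicates (scale it down for desk-size runs).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as lfio
from .classify import FamilySummary, classify_protein, tally
from .domains import builtin_profile, scan_with_backend
from .exceptions import LegfamError
from .expression import (
    cut_clusters,
    ddct_fold_change,
    fpkm,
    hierarchical_cluster,
    log_transform,
)
from .homology import find_orthologs_bbh, find_paralogs
from .phylo import annotate_supports, assign_groups, bootstrap_support
from .records import FamilyCall, GeneModel, ProteinRecord
from .references import subgroup_reference_taxa
from .structure import compare_paralog_structure, splice_phases

logger = logging.getLogger("legfam")


@dataclass
class PipelineConfig:
    """Paths, backend selection and all stage thresholds."""

    input_dir: str = "."
    output_dir: str = "run"
    backend: str = "internal"            # internal | hmmscan | blastp
    reference_species: str | None = None
    blastp_evalue: float = 1e-5          # domain-mining step (blastp backend)
    duplication_identity: float = 80.0
    duplication_evalue: float = 1e-10
    tandem_window: int = 5_000_000
    min_aligned_coverage: float = 0.7
    bbh_evalue: float = 1e-10
    soloist_identity_cutoff: float = 30.0
    bootstrap_replicates: int = 5000
    support_threshold: float = 50.0
    log_offset: float = 1.0
    cluster_linkage: str = "average"
    cluster_metric: str = "euclidean"
    genome_size_mb: float | None = None  # derived from GFF3 when unset
    genome_gene_total: int | None = None # proteome size when unset
    threads: int = 1                     # accepted for interface parity;
                                         # results are thread-count invariant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("internal", "hmmscan", "blastp"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for name in ("blastp_evalue", "duplication_evalue", "bbh_evalue"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 <= self.duplication_identity <= 100):
            raise ValueError("duplication_identity must be a percentage")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(value, types[key])
        return cls(**kwargs)


def _coerce(value: str, annotation: str):
    if value == "None":
        return None
    for caster in (int, float):
        if annotation.startswith(caster.__name__):
            return caster(value)
    return value


@dataclass
class PipelineResult:
    config: PipelineConfig
    proteins: dict[str, list[ProteinRecord]]
    models: dict[str, dict[str, GeneModel]]
    calls: dict[str, list[FamilyCall]]
    summaries: dict[str, FamilySummary]
    duplications: dict[str, list]
    orthologs: dict[tuple[str, str], list]
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def discover_species(input_dir: str | Path) -> list[str]:
    return sorted(p.stem for p in Path(input_dir).glob("*.faa"))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "config": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
        },
        "config_sha256": hashlib.sha256(
            config.to_text().encode()
        ).hexdigest(),
        "inputs": {},
        "stages": [],
        "outputs": [],
    }
    species_list = discover_species(indir)
    if not species_list:
        raise LegfamError(f"no <species>.faa inputs found in {indir}")
    for sp in species_list:
        for suffix in (".faa", ".gff3"):
            path = indir / f"{sp}{suffix}"
            if path.exists():
                manifest["inputs"][path.name] = _sha256(path)

    result = PipelineResult(
        config=config, proteins={}, models={}, calls={}, summaries={},
        duplications={}, orthologs={}, manifest=manifest,
    )

    def _write(frame: pd.DataFrame, name: str) -> None:
        lfio.write_tsv(frame, outdir / name)
        manifest["outputs"].append(name)

    def _stage(name: str, fn) -> None:
        logger.info("stage %s: starting", name)
        try:
            fn()
        except Exception as exc:
            logger.error("stage %s: failed: %s", name, exc)
            _write_manifest(outdir, manifest)
            raise LegfamError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        logger.info("stage %s: done", name)

    hits_by_species: dict[str, dict] = {}

    def stage_load() -> None:
        for sp in species_list:
            result.proteins[sp] = lfio.read_fasta(indir / f"{sp}.faa", sp)
            gff = indir / f"{sp}.gff3"
            result.models[sp] = (
                lfio.read_gff3(gff, sp) if gff.exists() else {}
            )

    def stage_scan() -> None:
        for sp in species_list:
            hits_by_species[sp] = scan_with_backend(
                result.proteins[sp], backend=config.backend,
                evalue=config.blastp_evalue,
            )
            _write(lfio.hits_to_frame(hits_by_species[sp]), f"hits_{sp}.tsv")

    def stage_classify() -> None:
        for sp in species_list:
            result.calls[sp] = [
                classify_protein(
                    protein, hits_by_species[sp][protein.id],
                    soloist_identity_cutoff=config.soloist_identity_cutoff,
                )
                for protein in result.proteins[sp]
            ]

    def stage_phylogeny() -> None:
        refs = subgroup_reference_taxa()
        ap2_len = builtin_profile("AP2").length
        for sp in species_list:
            alignment: dict[str, str] = {
                name: seq for name, (_, seq) in refs.items()
            }
            calls_by_id = {c.gene_id: c for c in result.calls[sp]}
            for call in result.calls[sp]:
                ap2_hits = [
                    h for h in call.evidence if h.domain_name == "AP2"
                ]
                if ap2_hits and len(ap2_hits[0].domain_sequence) == ap2_len:
                    alignment[call.gene_id] = ap2_hits[0].domain_sequence
            if len(alignment) < 3 or len(alignment) <= len(refs):
                continue
            tree, supports = bootstrap_support(
                alignment, replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            labels = {name: label for name, (label, _) in refs.items()}
            assigned = assign_groups(
                tree, labels, supports,
                min_support=config.support_threshold,
            )
            annotate_supports(tree, supports)
            tree.write(str(outdir / f"tree_{sp}.nwk"))
            manifest["outputs"].append(f"tree_{sp}.nwk")
            for gene_id, label in assigned.items():
                call = calls_by_id[gene_id]
                if label is None:
                    call.flags.append("no_clade_assignment")
                    continue
                if label in ("AP2", "ANT"):
                    if call.subfamily in ("ERF", "DREB", "unresolved"):
                        call.flags.append(
                            f"reassigned_by_phylogeny:{call.subfamily}"
                        )
                    call.subfamily = label
                elif call.subfamily in ("ERF", "DREB"):
                    call.subgroup = label
                    expected = "A" if call.subfamily == "DREB" else "B"
                    if not label.startswith(expected):
                        call.flags.append("subgroup_subfamily_mismatch")
            _write(lfio.calls_to_frame(result.calls[sp]), f"calls_{sp}.tsv")

    def stage_structure() -> None:
        for sp in species_list:
            profiles = [
                splice_phases(model)
                for _, model in sorted(result.models[sp].items())
            ]
            if profiles:
                _write(
                    lfio.structures_to_frame(profiles), f"structure_{sp}.tsv"
                )

    def stage_duplication() -> None:
        for sp in species_list:
            family_ids = {
                c.gene_id for c in result.calls[sp] if c.family != "none"
            }
            proteome = [
                p for p in result.proteins[sp]
                if p.id in family_ids and p.id in result.models[sp]
            ]
            events = find_paralogs(
                proteome, result.models[sp],
                identity_cutoff=config.duplication_identity,
                evalue_cutoff=config.duplication_evalue,
                tandem_window=config.tandem_window,
                min_coverage=config.min_aligned_coverage,
            )
            result.duplications[sp] = events
            _write(lfio.duplications_to_frame(events), f"duplications_{sp}.tsv")
            _write(
                lfio.links_to_frame(events, result.models[sp]),
                f"links_{sp}.tsv",
            )
            comparisons = [
                compare_paralog_structure(
                    splice_phases(result.models[sp][e.gene_a]),
                    splice_phases(result.models[sp][e.gene_b]),
                )
                for e in events
            ]
            if comparisons:
                _write(
                    pd.DataFrame([dataclasses.asdict(c) for c in comparisons]),
                    f"paralog_structure_{sp}.tsv",
                )

    def stage_orthology() -> None:
        reference = config.reference_species or species_list[0]
        if reference not in species_list:
            raise LegfamError(f"reference species {reference!r} not found")
        family = {
            sp: [
                p for p in result.proteins[sp]
                if any(
                    c.gene_id == p.id and c.family != "none"
                    for c in result.calls[sp]
                )
            ]
            for sp in species_list
        }
        for sp in species_list:
            if sp == reference or not family[reference] or not family[sp]:
                continue
            pairs = find_orthologs_bbh(
                family[reference], family[sp], evalue_cutoff=config.bbh_evalue
            )
            result.orthologs[(reference, sp)] = pairs
            _write(
                lfio.orthologs_to_frame(pairs),
                f"orthologs_{reference}_{sp}.tsv",
            )

    def stage_expression() -> None:
        counts_path = indir / "counts.tsv"
        if counts_path.exists():
            counts = lfio.read_tsv(counts_path, index_col=0)
            lengths = lfio.read_tsv(indir / "lengths.tsv", index_col=0).iloc[:, 0]
            totals = lfio.read_tsv(indir / "totals.tsv", index_col=0).iloc[:, 0]
            matrix = fpkm(counts, lengths, totals)
            _write(matrix.reset_index(names="gene"), "fpkm.tsv")
            logged = log_transform(matrix, offset=config.log_offset)
            clustering = hierarchical_cluster(
                logged, linkage=config.cluster_linkage,
                metric=config.cluster_metric,
            )
            _write(
                clustering.ordered.reset_index(names="gene"),
                "heatmap_log10_fpkm.tsv",
            )
            membership = cut_clusters(clustering, k=2)
            _write(
                pd.DataFrame(
                    sorted(membership.items()), columns=["gene", "cluster"]
                ),
                "expression_clusters.tsv",
            )
        ct_path = indir / "ct.tsv"
        if ct_path.exists():
            folds = ddct_fold_change(lfio.read_tsv(ct_path))
            _write(folds, "ddct_fold_change.tsv")

    def stage_report() -> None:
        for sp in species_list:
            genome_total = config.genome_gene_total or len(result.proteins[sp])
            size_mb = config.genome_size_mb or _genome_size_mb(
                result.models[sp]
            )
            summary = tally(result.calls[sp], genome_total, size_mb)
            result.summaries[sp] = summary
            _write(lfio.summary_to_frame(summary), f"summary_{sp}.tsv")

    _stage("load", stage_load)
    _stage("scan", stage_scan)
    _stage("classify", stage_classify)
    _stage("phylogeny", stage_phylogeny)
    _stage("structure", stage_structure)
    _stage("duplication", stage_duplication)
    _stage("orthology", stage_orthology)
    _stage("expression", stage_expression)
    _stage("report", stage_report)

    _write_manifest(outdir, manifest)
    logger.removeHandler(handler)
    handler.close()
    return result


def split_ap2_ant(
    calls: list[FamilyCall],
    bootstrap_replicates: int = 100,
    seed: int = 0,
    support_threshold: float = 50.0,
) -> None:
    """Resolve the AP2 vs ANT split for double-AP2-domain genes in place.

    Builds an NJ tree of the first AP2-domain sequences of all genes
    currently called AP2 together with the bundled AP2/ANT reference taxa,
    bootstraps it, and relabels genes that fall in the ANT reference clade.
    Lighter than the full-family phylogeny stage; use it when only the
    double-domain lineage needs clade resolution.
    """
    refs = subgroup_reference_taxa()
    ap2_len = builtin_profile("AP2").length
    alignment = {
        name: seq
        for name, (label, seq) in refs.items()
        if label in ("AP2", "ANT")
    }
    labels = {
        name: label for name, (label, _) in refs.items()
        if label in ("AP2", "ANT")
    }
    queries: dict[str, FamilyCall] = {}
    for call in calls:
        if call.subfamily != "AP2":
            continue
        ap2_hits = [h for h in call.evidence if h.domain_name == "AP2"]
        if ap2_hits and len(ap2_hits[0].domain_sequence) == ap2_len:
            alignment[call.gene_id] = ap2_hits[0].domain_sequence
            queries[call.gene_id] = call
    if len(queries) == 0 or len(alignment) < 4:
        return
    tree, supports = bootstrap_support(
        alignment, replicates=bootstrap_replicates, seed=seed
    )
    assigned = assign_groups(
        tree, labels, supports, min_support=support_threshold
    )
    for gene_id, label in assigned.items():
        if label == "ANT":
            queries[gene_id].subfamily = "ANT"


def _genome_size_mb(models: Mapping[str, GeneModel]) -> float:
    if not models:
        return 1.0
    extent: dict[str, int] = {}
    for model in models.values():
        extent[model.chromosome] = max(
            extent.get(model.chromosome, 0), model.span[1]
        )
    return max(sum(extent.values()) / 1e6, 1.0)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
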