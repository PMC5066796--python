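"""Readers and writers for the standard formats the pipeline speaks.

FASTA via Biopython (ids taken to the first whitespace), GFF3 via gffutils
(1-based inclusive, gene/mRNA/exon/CDS with Parent links; the longest-CDS
isoform represents each gene), tab-separated tables via pandas.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .classify import FamilySummary
from .exceptions import ParseError
from .records import (
    DomainHit,
    DuplicationEvent,
    FamilyCall,
    GeneModel,
    OrthologPair,
    ProteinRecord,
    SplicePhaseProfile,
)


def read_fasta(path: str | Path, species: str | None = None) -> list[ProteinRecord]:
    """Protein records from FASTA; duplicate ids are an error."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}", str(path))
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                species=species,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _validate_gff3_lines(path: str | Path) -> None:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ParseError(
                f"expected 9 tab-separated columns, got {len(parts)}",
                str(path), lineno,
            )
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise ParseError(
                f"non-integer coordinates: {exc}", str(path), lineno
            ) from exc
        if end < start:
            raise ParseError(
                f"end < start ({end} < {start})", str(path), lineno
            )


def read_gff3(path: str | Path, species: str | None = None) -> dict[str, GeneModel]:
    """Gene models from GFF3, keyed by gene id.

    Coding exons (CDS features) of the longest-CDS mRNA represent each
    gene; exons are returned in transcription order.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best_cds: list[tuple[int, int]] | None = None
        best_len = -1
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [
                (f.start, f.end)
                for f in db.children(mrna, featuretype="CDS")
            ]
            if not cds:
                continue
            total = sum(e - s + 1 for s, e in cds)
            if total > best_len:
                best_len, best_cds = total, sorted(cds)
        if best_cds is None:
            continue
        exons = best_cds if gene.strand == "+" else best_cds[::-1]
        gene_id = gene.id
        if gene_id in models:
            raise ParseError(f"duplicate gene id {gene_id!r}", str(path))
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chromosome=gene.seqid,
            strand=gene.strand,
            exons=exons,
            cds_offset=0,
            species=species,
        )
    return models


def write_gff3(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Gene/mRNA/exon/CDS rows with Parent links, sorted by position."""
    lines = ["##gff-version 3"]
    for gene_id in sorted(
        models, key=lambda g: (models[g].chromosome, models[g].span[0])
    ):
        model = models[gene_id]
        start, end = model.span
        chrom, strand = model.chromosome, model.strand
        lines.append(
            f"{chrom}\tlegfam\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={gene_id}"
        )
        mrna_id = f"{gene_id}.1"
        lines.append(
            f"{chrom}\tlegfam\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={mrna_id};Parent={gene_id}"
        )
        coding = 0
        for i, (s, e) in enumerate(model.exons, 1):
            lines.append(
                f"{chrom}\tlegfam\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={mrna_id}.exon{i};Parent={mrna_id}"
            )
            phase = (3 - coding % 3) % 3
            lines.append(
                f"{chrom}\tlegfam\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                f"ID={mrna_id}.cds{i};Parent={mrna_id}"
            )
            coding += e - s + 1
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def hits_to_frame(hits: Mapping[str, Sequence[DomainHit]]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": h.protein_id,
            "domain": h.domain_name,
            "start": h.start,
            "end": h.end,
            "score": round(h.score, 2),
        }
        for pid in sorted(hits)
        for h in hits[pid]
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "domain", "start", "end", "score"]
    )


def calls_to_frame(calls: Sequence[FamilyCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "family": c.family,
            "subfamily": c.subfamily,
            "subgroup": c.subgroup,
            "residue14": c.residue14 or "",
            "residue19": c.residue19 or "",
            "crf_core": c.crf_core,
            "crf_cterm_motif": c.crf_cterm_motif,
            "wlg_state": c.wlg_state,
            "rayd_state": c.rayd_state,
            "ear_motif": c.ear_motif,
            "flags": ";".join(c.flags),
        }
        for c in sorted(calls, key=lambda c: c.gene_id)
    ]
    return pd.DataFrame(rows)


def summary_to_frame(summary: FamilySummary) -> pd.DataFrame:
    rows = [
        {"row": subgroup, "count": count}
        for subgroup, count in summary.subgroup_counts.items()
    ]
    rows += [
        {"row": "DREB_total", "count": summary.dreb_total},
        {"row": "ERF_subfamily_total", "count": summary.erf_subfamily_total},
        {"row": "AP2", "count": summary.ap2},
        {"row": "AINTEGUMENTA", "count": summary.ant},
        {"row": "RAV", "count": summary.rav},
        {"row": "soloist", "count": summary.soloist},
        {"row": "family_total", "count": summary.family_total},
        {"row": "HSP90", "count": summary.hsp90},
        {"row": "family_percent_of_genome", "count": summary.percentage},
        {"row": "family_per_mb", "count": summary.density},
    ]
    return pd.DataFrame(rows)


def structures_to_frame(
    profiles: Sequence[SplicePhaseProfile],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "intron_count": p.intron_count,
                "phases": ",".join(map(str, p.phases)),
            }
            for p in sorted(profiles, key=lambda p: p.gene_id)
        ]
    )


def duplications_to_frame(
    events: Sequence[DuplicationEvent],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "class": e.kind,
                "distance_bp": e.distance if e.distance is not None else "",
                "identity": round(e.alignment.identity, 2),
                "evalue": e.alignment.evalue,
            }
            for e in events
        ],
        columns=["gene_a", "gene_b", "class", "distance_bp", "identity",
                 "evalue"],
    )


def orthologs_to_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_species1": p.gene_species1,
                "gene_species2": p.gene_species2,
                "forward_score": p.forward.score,
                "forward_evalue": p.forward.evalue,
                "reverse_score": p.reverse.score,
                "reverse_evalue": p.reverse.evalue,
            }
            for p in pairs
        ],
        columns=[
            "gene_species1", "gene_species2", "forward_score",
            "forward_evalue", "reverse_score", "reverse_evalue",
        ],
    )


def links_to_frame(
    events: Sequence[DuplicationEvent],
    models: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Circos-compatible link table (chrom, start, end per side)."""
    rows = []
    for e in events:
        ma, mb = models[e.gene_a], models[e.gene_b]
        rows.append(
            {
                "chrom_a": ma.chromosome,
                "start_a": ma.span[0],
                "end_a": ma.span[1],
                "chrom_b": mb.chromosome,
                "start_b": mb.span[0],
                "end_b": mb.span[1],
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b",
                       "end_b"],
    )


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
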