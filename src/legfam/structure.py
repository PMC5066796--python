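"""Intron counts, splice phases and paralog structure comparison.

Phases follow the codon-boundary convention: an intron falling after a
complete codon is phase 0, after the first nucleotide of a codon phase 1,
after the second phase 2.  Phases are computed on coding nucleotides only,
traversing exons in transcription order, so they are invariant under
genomic translation and strand mirroring.
"""
from __future__ import annotations

from dataclasses import dataclass

from .records import GeneModel, SplicePhaseProfile


def intron_count(model: GeneModel) -> int:
    """Number of introns = exon count - 1 (single-exon genes are
    intronless)."""
    return len(model.exons) - 1


def splice_phases(model: GeneModel) -> SplicePhaseProfile:
    """Phase of every intron of a gene model.

    The phase of intron *i* is the number of coding nucleotides 5' of the
    intron modulo 3; ``cds_offset`` nucleotides at the start of the first
    exon are non-coding and excluded.
    """
    phases: list[int] = []
    coding = -model.cds_offset
    for start, end in model.exons[:-1]:
        coding += end - start + 1
        phases.append(coding % 3)
    return SplicePhaseProfile(
        gene_id=model.gene_id,
        intron_count=intron_count(model),
        phases=tuple(phases),
    )


@dataclass(frozen=True)
class StructureComparison:
    gene_a: str
    gene_b: str
    verdict: str          # conserved | gain_loss
    delta: int            # |intron count difference|
    phases_equal: bool    # auxiliary evidence


def compare_paralog_structure(
    a: SplicePhaseProfile, b: SplicePhaseProfile
) -> StructureComparison:
    """Conserved if the paralogs have equal intron counts, otherwise a
    gain/loss event with the count difference; phase-string agreement is
    reported as auxiliary evidence."""
    delta = abs(a.intron_count - b.intron_count)
    return StructureComparison(
        gene_a=a.gene_id,
        gene_b=b.gene_id,
        verdict="conserved" if delta == 0 else "gain_loss",
        delta=delta,
        phases_equal=a.phases == b.phases,
    )
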