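"""Pairwise protein alignment, duplication classification and BBH orthology.

Alignment is Smith-Waterman (BLOSUM62, affine gaps) via Biopython's
PairwiseAligner; expectation values use the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with the documented gapped BLOSUM62
constants (gap open 11 / extend 1), so e-values are reproducible without a
database.

Duplication classification follows the distance rule used in legume
family surveys: qualifying paralog pairs within 5 Mb on one chromosome are
tandem, farther apart or on different chromosomes segmental.  Orthologs
across species are best bidirectional hits (BBH) at e <= 1e-10.
"""
from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    AlignmentResult,
    DuplicationEvent,
    GeneModel,
    OrthologPair,
    ProteinRecord,
)

# gapped Karlin-Altschul constants for BLOSUM62, gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

TANDEM_WINDOW_BP = 5_000_000
DUPLICATION_IDENTITY = 80.0
DUPLICATION_EVALUE = 1e-10
BBH_EVALUE = 1e-10
#: minimum aligned columns relative to the longer protein for a pair to
#: count as a whole-gene duplication rather than a shared-domain match
#: (double-domain family members share ~120 identical residues, which can
#: satisfy the identity and e-value thresholds on their own)
MIN_ALIGNED_COVERAGE = 0.7


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """Expectation value of a local alignment score between sequences of
    lengths m and n."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def align_pair(
    a: ProteinRecord | tuple[str, str],
    b: ProteinRecord | tuple[str, str],
) -> AlignmentResult:
    """Best local alignment between two proteins.

    Identity is identical columns over aligned columns (gap columns
    excluded); the score is the raw Smith-Waterman score under BLOSUM62
    with affine gaps.
    """
    qid, qseq = (a.id, a.sequence) if isinstance(a, ProteinRecord) else a
    sid, sseq = (b.id, b.sequence) if isinstance(b, ProteinRecord) else b
    if not qseq or not sseq:
        raise ValueError("align_pair requires non-empty sequences")
    alignment = _ALIGNER.align(qseq, sseq)[0]
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned if aligned else 0.0
    score = float(alignment.score)
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        identity=identity,
        score=score,
        evalue=karlin_altschul_evalue(score, len(qseq), len(sseq)),
        aligned_length=aligned,
    )


def _pair_score(qseq: str, sseq: str) -> float:
    return float(_ALIGNER.score(qseq, sseq))


def find_paralogs(
    proteome: Sequence[ProteinRecord],
    gene_locations: Mapping[str, GeneModel],
    identity_cutoff: float = DUPLICATION_IDENTITY,
    evalue_cutoff: float = DUPLICATION_EVALUE,
    tandem_window: int = TANDEM_WINDOW_BP,
    min_coverage: float = MIN_ALIGNED_COVERAGE,
) -> list[DuplicationEvent]:
    """Duplication events within one species.

    All unordered pairs are aligned; pairs at identity >= 80% and
    e <= 1e-10 whose alignment covers at least 70% of the longer protein
    survive, and are classed tandem (same chromosome, start-to-start
    distance <= 5 Mb) or segmental (farther, or different chromosomes).
    A cheap score prefilter skips the traceback for clearly unrelated
    pairs.
    """
    for protein in proteome:
        if protein.id not in gene_locations:
            raise KeyError(f"no location for gene {protein.id}")
    events: list[DuplicationEvent] = []
    for pa, pb in combinations(sorted(proteome, key=lambda p: p.id), 2):
        m, n = len(pa.sequence), len(pb.sequence)
        score = _pair_score(pa.sequence, pb.sequence)
        if karlin_altschul_evalue(score, m, n) > evalue_cutoff:
            continue
        result = align_pair(pa, pb)
        if result.identity < identity_cutoff:
            continue
        if result.evalue > evalue_cutoff:
            continue
        if result.aligned_length < min_coverage * max(m, n):
            continue
        loc_a, loc_b = gene_locations[pa.id], gene_locations[pb.id]
        if loc_a.chromosome == loc_b.chromosome:
            distance = abs(loc_a.span[0] - loc_b.span[0])
            kind = "tandem" if distance <= tandem_window else "segmental"
        else:
            distance, kind = None, "segmental"
        events.append(
            DuplicationEvent(
                gene_a=pa.id,
                gene_b=pb.id,
                kind=kind,
                distance=distance,
                alignment=result,
            )
        )
    return events


def _best_hits(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    evalue_cutoff: float,
) -> dict[str, AlignmentResult]:
    """Best subject per query by score; ties broken by lower e-value, then
    lexicographic subject id."""
    best: dict[str, AlignmentResult] = {}
    for query in queries:
        candidate: AlignmentResult | None = None
        for subject in sorted(subjects, key=lambda p: p.id):
            score = _pair_score(query.sequence, subject.sequence)
            evalue = karlin_altschul_evalue(
                score, len(query.sequence), len(subject.sequence)
            )
            if evalue > evalue_cutoff:
                continue
            if (
                candidate is None
                or score > candidate.score
                or (score == candidate.score and evalue < candidate.evalue)
            ):
                candidate = AlignmentResult(
                    query_id=query.id,
                    subject_id=subject.id,
                    identity=float("nan"),
                    score=score,
                    evalue=evalue,
                    aligned_length=0,
                )
        if candidate is not None:
            best[query.id] = candidate
    return best


def find_orthologs_bbh(
    proteome1: Sequence[ProteinRecord],
    proteome2: Sequence[ProteinRecord],
    evalue_cutoff: float = BBH_EVALUE,
) -> list[OrthologPair]:
    """Best-bidirectional-hit ortholog pairs between two proteomes.

    A pair is emitted iff each protein is the other's highest-scoring
    cross-proteome hit with both e-values <= the cutoff.  Output is
    symmetric under argument swap (as unordered pairs).
    """
    if not proteome1 or not proteome2:
        raise ValueError("both proteomes must be non-empty")
    forward = _best_hits(proteome1, proteome2, evalue_cutoff)
    reverse = _best_hits(proteome2, proteome1, evalue_cutoff)
    pairs: list[OrthologPair] = []
    for gene1, fwd in sorted(forward.items()):
        rev = reverse.get(fwd.subject_id)
        if rev is not None and rev.subject_id == gene1:
            pairs.append(
                OrthologPair(
                    gene_species1=gene1,
                    gene_species2=fwd.subject_id,
                    forward=fwd,
                    reverse=rev,
                )
            )
    return pairs
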