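"""Core record types shared across the pipeline stages.

Coordinates are 1-based and inclusive throughout, on proteins as well as on
chromosomes, matching the GFF3 convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Subfamilies of the AP2/ERF superfamily plus the HSP90 chaperone family.
SUBFAMILIES = ("AP2", "ANT", "ERF", "DREB", "RAV", "soloist", "HSP90")

#: Phylogenetic subgroups of the ERF subfamily sensu lato (DREB = A1-A6,
#: ERF sensu stricto = B1-B6).
SUBGROUPS = tuple(f"A{i}" for i in range(1, 7)) + tuple(
    f"B{i}" for i in range(1, 7)
)


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """A protein sequence, the unit of classification."""

    id: str
    sequence: str
    species: str | None = None
    chromosome: str | None = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class DomainHit:
    """A located domain match on a protein.

    ``position_map`` maps canonical domain positions (1-based columns of the
    domain model, e.g. the 14th and 19th AP2-domain positions) to 1-based
    protein coordinates.
    """

    protein_id: str
    domain_name: str
    start: int
    end: int
    score: float
    domain_sequence: str
    position_map: dict[int, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid hit coordinates {self.start}..{self.end}"
            )

    def residue_at(self, canonical_position: int, sequence: str) -> str | None:
        """Residue of ``sequence`` at a canonical domain position, or None
        if the position does not map (truncated/unmapped domain)."""
        pos = self.position_map.get(canonical_position)
        if pos is None or not (1 <= pos <= len(sequence)):
            return None
        return sequence[pos - 1]


@dataclass(slots=True)
class FamilyCall:
    """Full classification verdict for one gene."""

    gene_id: str
    family: str = "none"            # AP2/ERF | HSP90 | none
    subfamily: str = "unresolved"   # AP2|ANT|ERF|DREB|RAV|soloist|HSP90|...
    subgroup: str = "none"          # A1..A6 | B1..B6 | none
    residue14: str | None = None
    residue19: str | None = None
    crf_core: bool = False
    crf_cterm_motif: bool = False
    wlg_state: str = "absent"       # WLG | YLG | absent
    rayd_state: str = "absent"      # RAYD | RAHD | absent
    ear_motif: bool = False
    evidence: list[DomainHit] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True, slots=True)
class ProteinProperties:
    length: int
    molecular_weight: float
    isoelectric_point: float


@dataclass(slots=True)
class GeneModel:
    """Gene model for intron/phase analysis.

    ``exons`` are (start, end) genomic coordinates, 1-based inclusive, in
    transcription order (descending coordinates on the minus strand).
    ``cds_offset`` is the 0-based offset of the first coding nucleotide
    within the first exon, along the direction of transcription.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_offset: int = 0
    species: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if not (1 <= s <= e):
                raise ValueError(
                    f"gene {self.gene_id}: bad exon coordinates {s}..{e}"
                )
        order = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(order, order[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
        first = self.exons[0]
        if not (0 <= self.cds_offset <= first[1] - first[0]):
            raise ValueError(
                f"gene {self.gene_id}: cds_offset {self.cds_offset} outside "
                "first exon"
            )

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


@dataclass(frozen=True, slots=True)
class SplicePhaseProfile:
    gene_id: str
    intron_count: int
    phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.phases) != self.intron_count:
            raise ValueError("phase list length must equal intron count")
        if any(p not in (0, 1, 2) for p in self.phases):
            raise ValueError("phases must be 0, 1 or 2")


@dataclass(frozen=True, slots=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    identity: float       # percent over aligned (non-gap) columns
    score: float
    evalue: float
    aligned_length: int   # aligned columns, gap columns excluded


@dataclass(frozen=True, slots=True)
class DuplicationEvent:
    """A classified paralog relation (tandem or segmental)."""

    gene_a: str
    gene_b: str
    kind: str                      # tandem | segmental
    distance: int | None           # bp start-to-start; None across chromosomes
    alignment: AlignmentResult

    def __post_init__(self) -> None:
        if self.kind not in ("tandem", "segmental"):
            raise ValueError(f"unknown duplication class {self.kind!r}")
        if self.kind == "tandem" and (
            self.distance is None or self.distance > 5_000_000
        ):
            raise ValueError("tandem pairs must be <=5 Mb on one chromosome")


@dataclass(frozen=True, slots=True)
class OrthologPair:
    gene_species1: str
    gene_species2: str
    forward: AlignmentResult
    reverse: AlignmentResult
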