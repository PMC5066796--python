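"""Synthetic genomes with planted, machine-readable truth.

Emulates the inputs of a five-legume gene-family survey at desk scale:
proteomes in which AP2/ERF-superfamily and HSP90 genes are planted with
known subfamily/subgroup labels, domain coordinates, residue signatures
(V14/E19 for DREB, A14/D19 for ERF), CRF motifs, gene models with known
intron counts and splice phases, tandem and segmental paralog copies,
cross-species 1:1 orthologs, and expression matrices with known block
structure.  Every planted fact is recorded in a :class:`TruthTable` so
each downstream stage can be scored against ground truth without
downloading real genomes.

Defaults mirror the chickpea numbers of the survey this emulates: eight
chromosomes, a subfamily mix proportional to the chickpea family table
(76 ERF, 43 DREB, 14 AP2, 10 ANT, 2 RAV, 2 soloist, 5 HSP90 per 160
genes), two tandem and eleven segmental duplication events, and a
DREB E19 majority of 80%.

All randomness flows from the single integer seed; a fixed seed gives
byte-identical FASTA/GFF3/truth outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import builtin_profile
from .exceptions import CapacityError, DesignError
from .records import AMINO_ACIDS, GeneModel, ProteinRecord
from .references import DREB_SUBGROUPS, ERF_SUBGROUPS, archetypes
from .tables import background_vector

SPECIES_PREFIXES = ("Ca", "Cc", "Pv", "Mt", "Lj")

SUBFAMILY_KEYS = (
    "AP2", "ANT", "ERF", "DREB", "RAV", "soloist", "HSP90", "background"
)

#: chickpea-like subfamily mix (per 160 genes: 147 AP2/ERF + 5 HSP90 + 8
#: background)
DEFAULT_MIX = {
    "ERF": 76 / 160,
    "DREB": 43 / 160,
    "AP2": 14 / 160,
    "ANT": 10 / 160,
    "RAV": 2 / 160,
    "soloist": 2 / 160,
    "HSP90": 5 / 160,
    "background": 8 / 160,
}

#: subgroup sampling weights follow the chickpea subgroup counts
DREB_SUBGROUP_WEIGHTS = {"A1": 6, "A2": 5, "A3": 1, "A4": 14, "A5": 10,
                         "A6": 7}
ERF_SUBGROUP_WEIGHTS = {"B1": 12, "B2": 5, "B3": 23, "B4": 14, "B5": 8,
                        "B6": 14}

#: per-subfamily intron-count sampling (value -> weight), after the
#: published per-subfamily tallies (e.g. 53/79 chickpea ERFs intronless)
INTRON_WEIGHTS = {
    "ERF": {0: 53, 1: 23, 2: 3},
    "DREB": {0: 41, 1: 2},
    "AP2": {6: 1, 7: 1, 8: 1, 9: 1, 10: 1, 11: 1},
    "ANT": {5: 1, 6: 1, 7: 1, 8: 1},
    "RAV": {0: 1},
    "soloist": {3: 1, 4: 1, 5: 1},
    "HSP90": {2: 1, 3: 1, 4: 1},
    "background": {0: 2, 1: 2, 2: 1, 3: 1},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic multi-species fixture."""

    species_count: int = 5
    genes_per_species: int = 160
    chromosome_count: int = 8
    chromosome_length: int = 60_000_000
    subfamily_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX)
    )
    planted_tandem_pairs: int = 2
    planted_segmental_pairs: int = 11
    planted_ortholog_fraction: float = 0.65
    noise_mutation_rate: float = 0.0
    seed: int = 0
    # secondary study conditions
    dreb_e19_majority: float = 0.8       # fraction of DREBs with canonical E19
    crf_fraction: float = 0.10           # of ERF genes carrying the CRF core
    crf_cterm_fraction: float = 0.375    # of CRFs also carrying SP[T/V]SVL
    duplicate_divergence: float = 0.05   # per-site, paralog copies
    ortholog_divergence: float = 0.05    # per-site, cross-species copies
    paralog_intron_deletion_fraction: float = 0.3

    def __post_init__(self) -> None:
        mix = dict(self.subfamily_mix)
        unknown = set(mix) - set(SUBFAMILY_KEYS)
        if unknown:
            raise ValueError(f"unknown subfamily keys in mix: {sorted(unknown)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("subfamily_mix proportions must sum to 1")
        if any(v < 0 for v in mix.values()):
            raise ValueError("subfamily_mix proportions must be non-negative")
        for name in ("species_count", "genes_per_species", "chromosome_count",
                     "planted_tandem_pairs", "planted_segmental_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.planted_ortholog_fraction <= 1.0):
            raise ValueError("planted_ortholog_fraction must be in [0, 1]")
        if not (0.0 <= self.noise_mutation_rate < 1.0):
            raise ValueError("noise_mutation_rate must be in [0, 1)")
        if self.chromosome_length < 10 * self.mean_gene_span():
            raise ValueError(
                "chromosome_length must be at least 10x the mean gene span"
            )

    def mean_gene_span(self) -> float:
        """Expected genomic footprint of one gene under the mix (bp)."""
        mean_protein = sum(
            self.subfamily_mix.get(k, 0.0) * _TYPICAL_PROTEIN_LENGTH[k]
            for k in SUBFAMILY_KEYS
        )
        mean_introns = sum(
            self.subfamily_mix.get(k, 0.0) * _mean_intron_count(k)
            for k in SUBFAMILY_KEYS
        )
        return 3.0 * mean_protein + mean_introns * 290.0


_TYPICAL_PROTEIN_LENGTH = {
    "ERF": 250, "DREB": 250, "AP2": 430, "ANT": 430, "RAV": 330,
    "soloist": 250, "HSP90": 730, "background": 275,
}


def _mean_intron_count(subfamily: str) -> float:
    weights = INTRON_WEIGHTS[subfamily]
    total = sum(weights.values())
    return sum(k * w for k, w in weights.items()) / total


@dataclass
class TruthGene:
    gene_id: str
    species: str
    subfamily: str                       # includes "background"
    subgroup: str                        # A1..B6 or "none"
    chromosome: str
    domains: list[tuple[str, int, int]]  # (name, start, end) protein coords
    intron_count: int
    phases: tuple[int, ...]
    expression_block: int
    crf_core: bool = False
    crf_cterm: bool = False
    protein_length: int = 0


@dataclass
class TruthTable:
    """Machine-readable ground truth for one fixture."""

    genes: dict[str, TruthGene] = field(default_factory=dict)
    paralog_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        for a, b, kind in self.paralog_pairs:
            if a not in self.genes or b not in self.genes:
                raise ValueError(f"paralog pair ({a}, {b}) references "
                                 "unknown genes")
            if kind not in ("tandem", "segmental"):
                raise ValueError(f"unknown paralog class {kind!r}")
        for a, b in self.ortholog_pairs:
            if a not in self.genes or b not in self.genes:
                raise ValueError(f"ortholog pair ({a}, {b}) references "
                                 "unknown genes")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes.values():
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "species": gene.species,
                    "subfamily": gene.subfamily,
                    "subgroup": gene.subgroup,
                    "chromosome": gene.chromosome,
                    "domains": ";".join(
                        f"{n}:{s}-{e}" for n, s, e in gene.domains
                    ),
                    "intron_count": gene.intron_count,
                    "phases": ",".join(map(str, gene.phases)),
                    "expression_block": gene.expression_block,
                    "crf_core": gene.crf_core,
                    "crf_cterm": gene.crf_cterm,
                    "protein_length": gene.protein_length,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class GenomeFixture:
    config: SyntheticConfig
    proteins: dict[str, list[ProteinRecord]]          # per species
    models: dict[str, dict[str, GeneModel]]           # per species
    truth: TruthTable

    def all_proteins(self) -> list[ProteinRecord]:
        return [p for sp in sorted(self.proteins) for p in self.proteins[sp]]


def _random_residues(rng: np.random.Generator, n: int) -> str:
    bg = background_vector()
    idx = rng.choice(len(AMINO_ACIDS), size=n, p=bg)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Substitute residues at the given per-site rate.  ``protected`` are
    0-based positions exempt from mutation (used for the
    subfamily-defining residues of planted copies, whose truth label the
    divergence model must not silently invalidate)."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hit = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hit:
        if int(i) in protected:
            continue
        choices = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _label_critical_positions(
    coords: Sequence[tuple[str, int, int]],
) -> frozenset[int]:
    """0-based protein positions of the canonical 14th/19th residues of
    every planted AP2 domain instance."""
    protected: set[int] = set()
    for name, start, _ in coords:
        if name == "AP2":
            protected.update({start - 1 + 13, start - 1 + 18})
    return frozenset(protected)


def _weighted_choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


class _GeneFactory:
    """Builds one protein + structural truth at a time from the bundled
    archetypes; separate from placement so paralog/ortholog copies can
    share construction."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.arch = archetypes()
        hat = builtin_profile("HATPase_c").consensus
        hsp = builtin_profile("HSP90").consensus
        b3 = builtin_profile("B3").consensus
        self.blocks = {"HATPase_c": hat, "HSP90": hsp, "B3": b3}

    def make(self, subfamily: str) -> tuple[str, list[tuple[str, int, int]],
                                            str, bool, bool]:
        """Returns (sequence, domain coordinates, subgroup, crf_core,
        crf_cterm)."""
        rng = self.rng
        if subfamily == "background":
            return (
                _random_residues(rng, int(rng.integers(150, 401))),
                [], "none", False, False,
            )
        if subfamily == "HSP90":
            return self._make_hsp90() + ("none", False, False)
        if subfamily in ("AP2", "ANT"):
            return self._make_double(subfamily) + ("none", False, False)
        if subfamily == "RAV":
            return self._make_rav() + ("none", False, False)
        if subfamily == "soloist":
            return self._make_single(self.arch["soloist"]) + (
                "none", False, False
            )
        if subfamily == "DREB":
            subgroup = _weighted_choice(rng, DREB_SUBGROUP_WEIGHTS)
            domain = list(self.arch[subgroup])
            if rng.random() >= self.config.dreb_e19_majority:
                choices = [a for a in AMINO_ACIDS if a not in ("E",)]
                domain[18] = choices[rng.integers(len(choices))]
            seq, coords = self._make_single("".join(domain))
            return seq, coords, subgroup, False, False
        if subfamily == "ERF":
            subgroup = _weighted_choice(rng, ERF_SUBGROUP_WEIGHTS)
            crf = rng.random() < self.config.crf_fraction
            crf_cterm = crf and (
                rng.random() < self.config.crf_cterm_fraction
            )
            seq, coords = self._make_single(
                self.arch[subgroup], crf_core=crf, crf_cterm=crf_cterm
            )
            return seq, coords, subgroup, crf, crf_cterm
        raise ValueError(f"unknown subfamily {subfamily!r}")

    def _flanks(self) -> tuple[str, str]:
        rng = self.rng
        n_flank = _random_residues(rng, int(rng.integers(30, 121)))
        c_flank = _random_residues(rng, int(rng.integers(60, 181)))
        return n_flank, c_flank

    def _make_single(
        self, domain: str, crf_core: bool = False, crf_cterm: bool = False
    ) -> tuple[str, list[tuple[str, int, int]]]:
        rng = self.rng
        n_flank, c_flank = self._flanks()
        if crf_core:
            core = "ATD" + AMINO_ACIDS[rng.integers(20)] + "SS"
            pos = int(rng.integers(0, len(n_flank) - len(core)))
            n_flank = n_flank[:pos] + core + n_flank[pos + len(core):]
        if crf_cterm:
            # keep the motif inside the C-terminal third of the protein
            pos = len(c_flank) - 12
            c_flank = c_flank[:pos] + "SPTSVL" + c_flank[pos + 6:]
        start = len(n_flank) + 1
        seq = n_flank + domain + c_flank
        return seq, [("AP2", start, start + len(domain) - 1)]

    def _make_double(self, subfamily: str) -> tuple[str, list]:
        rng = self.rng
        n_flank, c_flank = self._flanks()
        r1 = self.arch["AP2_R1" if subfamily == "AP2" else "ANT_R1"]
        r2 = self.arch["R2"]
        linker = _random_residues(rng, int(rng.integers(25, 41)))
        seq = n_flank + r1 + linker + r2 + c_flank
        s1 = len(n_flank) + 1
        s2 = s1 + len(r1) + len(linker)
        return seq, [
            ("AP2", s1, s1 + len(r1) - 1),
            ("AP2", s2, s2 + len(r2) - 1),
        ]

    def _make_rav(self) -> tuple[str, list]:
        rng = self.rng
        n_flank, c_flank = self._flanks()
        ap2 = self.arch["RAV_AP2"]
        b3 = self.blocks["B3"]
        linker = _random_residues(rng, int(rng.integers(20, 36)))
        seq = n_flank + ap2 + linker + b3 + c_flank
        s1 = len(n_flank) + 1
        s2 = s1 + len(ap2) + len(linker)
        return seq, [
            ("AP2", s1, s1 + len(ap2) - 1),
            ("B3", s2, s2 + len(b3) - 1),
        ]

    def _make_hsp90(self) -> tuple[str, list]:
        rng = self.rng
        total = int(rng.integers(648, 819))
        hat, hsp = self.blocks["HATPase_c"], self.blocks["HSP90"]
        n_len = int(rng.integers(30, 71))
        linker_len = int(rng.integers(25, 41))
        c_len = total - n_len - linker_len - len(hat) - len(hsp)
        seq = (
            _random_residues(rng, n_len)
            + hat
            + _random_residues(rng, linker_len)
            + hsp
            + _random_residues(rng, c_len)
        )
        s1 = n_len + 1
        s2 = s1 + len(hat) + linker_len
        return seq, [
            ("HATPase_c", s1, s1 + len(hat) - 1),
            ("HSP90", s2, s2 + len(hsp) - 1),
        ]


def _sample_intron_structure(
    rng: np.random.Generator, subfamily: str, protein_length: int
) -> tuple[list[int], list[int]]:
    """Intron offsets (coding nt 5' of each intron) and intron lengths."""
    cds_len = 3 * protein_length
    count = int(_weighted_choice(rng, INTRON_WEIGHTS[subfamily]))
    count = min(count, cds_len - 1)
    offsets = sorted(
        int(x) + 1 for x in rng.choice(cds_len - 1, size=count, replace=False)
    )
    lengths = [int(rng.integers(80, 501)) for _ in offsets]
    return offsets, lengths


def _place_gene(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom_names: Sequence[str],
    span: int,
    chrom_length: int,
    chromosome: str | None = None,
    near: int | None = None,
    window: int | None = None,
    min_distance: int = 0,
    max_tries: int = 300,
) -> tuple[str, int]:
    """Find a non-overlapping genomic start by rejection sampling."""
    for _ in range(max_tries):
        chrom = (
            chromosome
            if chromosome is not None
            else chrom_names[rng.integers(len(chrom_names))]
        )
        if near is not None and window is not None:
            lo = max(1, near - window)
            hi = min(chrom_length - span, near + window)
        else:
            lo, hi = 1, chrom_length - span
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        if near is not None and min_distance and abs(start - near) < min_distance:
            continue
        if all(
            start + span - 1 < s or start > e
            for s, e in occupied.get(chrom, [])
        ):
            occupied.setdefault(chrom, []).append((start, start + span - 1))
            return chrom, start
    raise CapacityError(
        "could not place a gene without overlap; chromosomes are at capacity"
    )


def _build_model(
    gene_id: str,
    species: str,
    chrom: str,
    start: int,
    strand: str,
    protein_length: int,
    intron_offsets: Sequence[int],
    intron_lengths: Sequence[int],
) -> GeneModel:
    cds_len = 3 * protein_length
    bounds = [0, *intron_offsets, cds_len]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    span = cds_len + sum(intron_lengths)
    exons: list[tuple[int, int]] = []
    if strand == "+":
        cur = start
        for i, length in enumerate(exon_lens):
            exons.append((cur, cur + length - 1))
            cur += length
            if i < len(intron_lengths):
                cur += intron_lengths[i]
    else:
        cur = start + span - 1
        for i, length in enumerate(exon_lens):
            exons.append((cur - length + 1, cur))
            cur -= length
            if i < len(intron_lengths):
                cur -= intron_lengths[i]
    return GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        exons=exons,
        cds_offset=0,
        species=species,
    )


def _species_name(index: int) -> str:
    if index < len(SPECIES_PREFIXES):
        return SPECIES_PREFIXES[index]
    return f"S{index + 1}"


def generate_genomes(config: SyntheticConfig) -> GenomeFixture:
    """Generate per-species proteomes, gene models and the truth table.

    Species 1 is the reference (chickpea-like): it carries the planted
    tandem/segmental duplication copies, and a configurable fraction of
    its genes have 1:1 orthologs planted in every other species.
    """
    rng = np.random.default_rng(config.seed)
    factory = _GeneFactory(config, rng)
    truth = TruthTable()
    proteins: dict[str, list[ProteinRecord]] = {}
    models: dict[str, dict[str, GeneModel]] = {}
    chrom_names_by_species: dict[str, list[str]] = {}

    mix_keys = [k for k in SUBFAMILY_KEYS if config.subfamily_mix.get(k, 0) > 0]
    mix_probs = np.array([config.subfamily_mix[k] for k in mix_keys])
    mix_probs = mix_probs / mix_probs.sum()

    reference_species = _species_name(0)
    reference_genes: list[str] = []
    reference_payload: dict[str, tuple] = {}

    for s in range(config.species_count):
        species = _species_name(s)
        chrom_names = [f"{species}{i + 1}" for i in range(config.chromosome_count)]
        chrom_names_by_species[species] = chrom_names
        occupied: dict[str, list[tuple[int, int]]] = {}
        proteins[species] = []
        models[species] = {}

        for g in range(config.genes_per_species):
            gene_id = f"{species}_{g + 1:05d}"
            is_ortholog = (
                s > 0
                and g < len(reference_genes)
                and rng.random() < config.planted_ortholog_fraction
            )
            if is_ortholog:
                source_id = reference_genes[g]
                (seq, coords, subfamily, subgroup, crf, crf_ct,
                 offsets, ilens) = reference_payload[source_id]
                seq = _mutate(
                    rng, seq, config.ortholog_divergence,
                    protected=_label_critical_positions(coords),
                )
                truth.ortholog_pairs.append((source_id, gene_id))
            else:
                subfamily = mix_keys[rng.choice(len(mix_keys), p=mix_probs)]
                seq, coords, subgroup, crf, crf_ct = factory.make(subfamily)
                offsets, ilens = _sample_intron_structure(
                    rng, subfamily, len(seq)
                )
            if s == 0:
                reference_genes.append(gene_id)
                reference_payload[gene_id] = (
                    seq, coords, subfamily, subgroup, crf, crf_ct,
                    offsets, ilens,
                )
            _emit_gene(
                config, rng, truth, proteins, models, occupied,
                chrom_names, species, gene_id, seq, coords, subfamily,
                subgroup, crf, crf_ct, offsets, ilens,
            )

        if s == 0:
            _plant_duplications(
                config, rng, factory, truth, proteins, models, occupied,
                chrom_names, species, reference_payload,
            )

    truth.validate()
    return GenomeFixture(
        config=config, proteins=proteins, models=models, truth=truth
    )


def _emit_gene(
    config, rng, truth, proteins, models, occupied, chrom_names, species,
    gene_id, seq, coords, subfamily, subgroup, crf, crf_ct, offsets, ilens,
    chromosome=None, near=None, window=None, min_distance=0,
) -> GeneModel:
    span = 3 * len(seq) + sum(ilens)
    chrom, start = _place_gene(
        rng, occupied, chrom_names, span, config.chromosome_length,
        chromosome=chromosome, near=near, window=window,
        min_distance=min_distance,
    )
    strand = "+" if rng.random() < 0.5 else "-"
    model = _build_model(
        gene_id, species, chrom, start, strand, len(seq), offsets, ilens
    )
    noisy = _mutate(rng, seq, config.noise_mutation_rate)
    proteins[species].append(
        ProteinRecord(
            id=gene_id, sequence=noisy, species=species, chromosome=chrom
        )
    )
    models[species][gene_id] = model
    truth.genes[gene_id] = TruthGene(
        gene_id=gene_id,
        species=species,
        subfamily=subfamily,
        subgroup=subgroup,
        chromosome=chrom,
        domains=list(coords),
        intron_count=len(offsets),
        phases=tuple(o % 3 for o in offsets),
        expression_block=1 if subfamily in ("DREB", "HSP90") else 0,
        crf_core=crf,
        crf_cterm=crf_ct,
        protein_length=len(seq),
    )
    return model


def _plant_duplications(
    config, rng, factory, truth, proteins, models, occupied, chrom_names,
    species, reference_payload,
) -> None:
    family_ids = [
        gid for gid, payload in reference_payload.items()
        if payload[2] not in ("background",)
    ]
    n_pairs = config.planted_tandem_pairs + config.planted_segmental_pairs
    if n_pairs == 0:
        return
    if not family_ids:
        raise CapacityError("no family genes available to duplicate")
    sources = [
        family_ids[int(i)]
        for i in rng.choice(len(family_ids), size=n_pairs, replace=False)
    ] if len(family_ids) >= n_pairs else [
        family_ids[int(rng.integers(len(family_ids)))] for _ in range(n_pairs)
    ]
    copies_per_source: dict[str, int] = {}
    for k, source_id in enumerate(sources):
        kind = "tandem" if k < config.planted_tandem_pairs else "segmental"
        (seq, coords, subfamily, subgroup, crf, crf_ct,
         offsets, ilens) = reference_payload[source_id]
        copy_seq = _mutate(
            rng, seq, config.duplicate_divergence,
            protected=_label_critical_positions(coords),
        )
        copy_offsets, copy_ilens = list(offsets), list(ilens)
        if (
            copy_offsets
            and rng.random() < config.paralog_intron_deletion_fraction
        ):
            drop = int(rng.integers(len(copy_offsets)))
            copy_offsets.pop(drop)
            copy_ilens.pop(drop)
        copies_per_source[source_id] = copies_per_source.get(source_id, 0) + 1
        n_copy = copies_per_source[source_id]
        gene_id = f"{source_id}d" + ("" if n_copy == 1 else str(n_copy))
        source_model = models[species][source_id]
        source_start = source_model.span[0]
        if kind == "tandem":
            placement = dict(
                chromosome=source_model.chromosome,
                near=source_start,
                window=3_000_000,
            )
        elif k % 2 == 0:
            others = [c for c in chrom_names if c != source_model.chromosome]
            placement = dict(
                chromosome=others[int(rng.integers(len(others)))]
            )
        else:
            placement = dict(
                chromosome=source_model.chromosome,
                near=source_start,
                window=config.chromosome_length,
                min_distance=5_000_001,
            )
        _emit_gene(
            config, rng, truth, proteins, models, occupied, chrom_names,
            species, gene_id, copy_seq, coords, subfamily, subgroup,
            crf, crf_ct, copy_offsets, copy_ilens, **placement,
        )
        truth.paralog_pairs.append((source_id, gene_id, kind))


def write_fixture(
    fixture: GenomeFixture,
    outdir,
    expression: "ExpressionFixture | None" = None,
    ct_table: pd.DataFrame | None = None,
) -> None:
    """Write a fixture as pipeline-ready files: per-species FASTA + GFF3,
    the truth table as TSV, and optional expression/Ct inputs."""
    from pathlib import Path

    from . import io as lfio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for species in sorted(fixture.proteins):
        lfio.write_fasta(fixture.proteins[species], out / f"{species}.faa")
        lfio.write_gff3(fixture.models[species], out / f"{species}.gff3")
    lfio.write_tsv(fixture.truth.to_frame(), out / "truth.tsv")
    if expression is not None:
        expression.counts.reset_index(names="gene").to_csv(
            out / "counts.tsv", sep="\t", index=False
        )
        expression.lengths_kb.rename("length_kb").reset_index().rename(
            columns={"index": "gene"}
        ).to_csv(out / "lengths.tsv", sep="\t", index=False)
        expression.totals.rename("mapped_fragments").reset_index().rename(
            columns={"index": "sample"}
        ).to_csv(out / "totals.tsv", sep="\t", index=False)
        expression.sample_meta.reset_index().to_csv(
            out / "samples.tsv", sep="\t", index=False
        )
    if ct_table is not None:
        ct_table.to_csv(out / "ct.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression and qRT-PCR fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    conditions: tuple[str, ...] = ("control", "stressed")
    replicates: int = 3


@dataclass
class ExpressionFixture:
    counts: pd.DataFrame          # genes x samples (float fragments)
    lengths_kb: pd.Series         # transcript length per gene, kb
    totals: pd.Series             # mapped fragments per sample
    sample_meta: pd.DataFrame     # condition/replicate/tissue annotations
    block_means: pd.DataFrame     # planted relative abundance per sample


def generate_expression(
    truth: TruthTable,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    dispersion: float = 0.05,
    fold_separation: float = 8.0,
    base_sigma: float = 0.4,
    species: str | None = None,
) -> ExpressionFixture:
    """Count matrix with planted two-block structure.

    Block 1 (the stress-responsive DREB/HSP90 genes) is induced
    ``fold_separation``-fold in stressed samples; block 0 is repressed by
    the same factor, so the two planted blocks are separable by
    clustering.  Counts are negative-binomial around the planted means
    (``dispersion`` = 0 gives the exact means, useful as a noise-free
    limit).
    """
    design = design or ExperimentDesign()
    if design.replicates < 1:
        raise DesignError("the design needs at least one replicate")
    if not truth.genes:
        raise DesignError("empty truth table")
    genes = sorted(
        (g for g in truth.genes.values()
         if species is None or g.species == species),
        key=lambda g: g.gene_id,
    )
    if not genes:
        raise DesignError(f"no genes for species {species!r}")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    blocks = np.array([g.expression_block for g in genes])
    lengths_kb = pd.Series(
        [3 * g.protein_length / 1000.0 for g in genes], index=gene_ids
    )
    samples = [
        f"{cond}_{r + 1}"
        for cond in design.conditions
        for r in range(design.replicates)
    ]
    conditions = [s.rsplit("_", 1)[0] for s in samples]
    totals = pd.Series(
        rng.integers(800_000, 1_200_001, size=len(samples)).astype(float),
        index=samples,
    )
    base = np.exp(rng.normal(np.log(100.0), base_sigma, size=len(genes)))
    half = math.sqrt(fold_separation)
    factors = np.empty((len(genes), len(samples)))
    for j, cond in enumerate(conditions):
        if cond == "control":
            factors[:, j] = np.where(blocks == 1, 1.0 / half, half)
        else:
            factors[:, j] = np.where(blocks == 1, half, 1.0 / half)
    abundance = base[:, None] * factors  # planted relative abundance (FPKM)
    means = (
        abundance
        * lengths_kb.values[:, None]
        * (totals.values[None, :] / 1e6)
    )
    if dispersion > 0:
        shape = 1.0 / dispersion
        counts = rng.negative_binomial(
            shape, shape / (shape + means)
        ).astype(float)
    else:
        counts = means.copy()
    sample_meta = pd.DataFrame(
        {
            "sample": samples,
            "condition": conditions,
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
            "tissue": "leaf",
            "stage": "vegetative",
            "genotype": "synthetic",
        }
    ).set_index("sample")
    return ExpressionFixture(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        lengths_kb=lengths_kb,
        totals=totals,
        sample_meta=sample_meta,
        block_means=pd.DataFrame(abundance, index=gene_ids, columns=samples),
    )


def generate_ct_table(
    truth: TruthTable,
    fold_changes: Mapping[str, float],
    seed: int = 0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    endogenous_ct: float = 20.0,
    calibrator_dct: float = 5.0,
) -> pd.DataFrame:
    """qRT-PCR Ct table constructed so 2^-ddCt recovers the planted folds.

    For each gene, calibrator ("control") samples get
    Ct_target = Ct_endogenous + calibrator_dct, and stressed samples get
    Ct_target lowered by log2(fold): at zero noise,
    ddCt = -log2(fold) exactly.
    """
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    for gene, fold in fold_changes.items():
        if gene not in truth.genes:
            raise ValueError(f"unknown gene {gene!r} in fold_changes")
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(fold_changes):
        fold = fold_changes[gene]
        for condition in ("control", "stressed"):
            for r in range(replicates):
                ct_endo = endogenous_ct + rng.normal(0.0, noise_sd) \
                    if noise_sd > 0 else endogenous_ct
                dct = calibrator_dct
                if condition == "stressed":
                    dct = calibrator_dct - math.log2(fold)
                ct_target = ct_endo + dct + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"{condition}_{r + 1}",
                        "condition": condition,
                        "replicate": r + 1,
                        "ct_target": ct_target,
                        "ct_endogenous": ct_endo,
                        "is_calibrator": condition == "control",
                    }
                )
    return pd.DataFrame(rows)
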