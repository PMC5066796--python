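"""Rule-based family and subfamily classification.

The decision tree mirrors how plant TF surveys dissect the AP2/ERF
superfamily from domain content alone:

* one AP2 domain            -> ERF lineage (split further into ERF/DREB)
* two AP2 domains           -> AP2 subfamily (ANT split left to phylogeny)
* AP2 + B3 domains          -> RAV
* single AP2, low homology  -> soloist
* HATPase_c + HSP90 domains -> HSP90 chaperone family

The ERF/DREB split reads the residues at canonical AP2-domain positions 14
and 19: V14 means DREB regardless of position 19 (position-14 primacy,
reflecting its dominant role in DRE-element binding specificity), A14 means
ERF.  Anything else is left unresolved.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ContractViolation
from .records import DomainHit, FamilyCall, ProteinProperties, ProteinRecord
from .references import identity_to_erf_references
from .tables import WATER_MASS, pka_table, residue_masses

#: default identity cutoff (percent over the AP2 domain, against the bundled
#: ERF reference set) below which a single-AP2 gene is called a soloist
SOLOIST_IDENTITY_CUTOFF = 30.0

CRF_CORE_PATTERN = re.compile(r"ATD.SS")
CRF_CTERM_PATTERN = re.compile(r"SP[TV]SVL")
EAR_PATTERNS = (
    ("LxLxL", re.compile(r"[LD].L.L")),
    ("DLNxxP", re.compile(r"DLN..P")),
)


def _hits_of(hits: Iterable[DomainHit], domain: str) -> list[DomainHit]:
    return sorted(
        (h for h in hits if h.domain_name == domain), key=lambda h: h.start
    )


def assign_superfamily(hits: Sequence[DomainHit]) -> tuple[str, list[str]]:
    """Superfamily membership from resolved domain hits of one protein.

    Returns (family, flags): ``AP2/ERF`` if any AP2 domain is present,
    ``HSP90`` if both HATPase_c and HSP90 domains are present, ``none``
    otherwise.  A protein matching both criteria is called AP2/ERF with a
    warning flag (pathological, not expected in real proteomes).
    """
    has_ap2 = bool(_hits_of(hits, "AP2"))
    has_hsp90 = bool(_hits_of(hits, "HATPase_c")) and bool(
        _hits_of(hits, "HSP90")
    )
    if has_ap2 and has_hsp90:
        return "AP2/ERF", ["ambiguous_superfamily:also_hsp90"]
    if has_ap2:
        return "AP2/ERF", []
    if has_hsp90:
        return "HSP90", []
    return "none", []


def classify_subfamily(
    hits: Sequence[DomainHit],
    homology_to_erf_refs: float | None = None,
    soloist_identity_cutoff: float = SOLOIST_IDENTITY_CUTOFF,
) -> str:
    """Subfamily from domain content of an AP2/ERF-superfamily protein.

    ``homology_to_erf_refs`` is the best identity (%) of the AP2 domain
    against the ERF reference set; when omitted it is computed from the
    first hit's matched sequence.  Single-AP2 genes below the cutoff are
    soloists; the rest are the ERF subfamily sensu lato (split by
    :func:`classify_erf_dreb`).  Phylogeny may later move single-AP2 genes
    that cluster with the AP2 clade into the AP2 subfamily.
    """
    ap2 = _hits_of(hits, "AP2")
    if not ap2:
        raise ContractViolation(
            "classify_subfamily requires at least one AP2 domain hit"
        )
    if _hits_of(hits, "B3"):
        return "RAV"
    if len(ap2) >= 2:
        return "AP2"
    if homology_to_erf_refs is None:
        homology_to_erf_refs = identity_to_erf_references(
            ap2[0].domain_sequence
        )
    if homology_to_erf_refs < soloist_identity_cutoff:
        return "soloist"
    return "ERF-lineage"


def classify_erf_dreb(
    hit: DomainHit, sequence: str
) -> tuple[str, str | None, str | None, list[str]]:
    """ERF vs DREB from the 14th and 19th canonical domain positions.

    Returns (subfamily, residue14, residue19, flags).  V14 -> DREB
    irrespective of position 19; A14 -> ERF (with a flag when position 19
    is not the canonical D); other residues -> unresolved.  Truncated
    domains whose positions cannot be mapped are unresolved and flagged.
    """
    res14 = hit.residue_at(14, sequence)
    res19 = hit.residue_at(19, sequence)
    if res14 is None:
        return "unresolved", res14, res19, ["position14_unmappable"]
    if res14 == "V":
        return "DREB", res14, res19, []
    if res14 == "A":
        flags = [] if res19 == "D" else ["noncanonical_position19"]
        return "ERF", res14, res19, flags
    return "unresolved", res14, res19, [f"noncanonical_position14:{res14}"]


def detect_crf(
    sequence: str, ap2_hit: DomainHit
) -> tuple[bool, bool]:
    """Cytokinin-response-factor signatures for an ERF/DREB protein.

    The CRF core (ATDxSS) is searched N-terminal of the AP2 domain; the
    putative MAPK/CK phosphorylation site SP[T/V]SVL in the C-terminal
    third of the protein.
    """
    n_region = sequence[: max(ap2_hit.start - 1, 0)]
    crf_core = CRF_CORE_PATTERN.search(n_region) is not None
    c_region = sequence[len(sequence) * 2 // 3 :]
    crf_cterm = CRF_CTERM_PATTERN.search(c_region) is not None
    return crf_core, crf_cterm


def detect_elements(
    hit: DomainHit, sequence: str
) -> tuple[str, str, bool]:
    """WLG/YLG and RAYD/RAHD element states within the AP2 domain, and the
    EAR repression motif anywhere in the protein.

    EAR is reported if either published form matches ([L/D]xLxL or DLNxxP);
    the pattern is heuristic — the motif is named, not defined, in most
    surveys — and is flagged as such downstream.
    """
    domain = hit.domain_sequence
    if "WLG" in domain:
        wlg = "WLG"
    elif "YLG" in domain:
        wlg = "YLG"
    else:
        wlg = "absent"
    if "RAYD" in domain:
        rayd = "RAYD"
    elif "RAHD" in domain:
        rayd = "RAHD"
    else:
        rayd = "absent"
    ear = any(pat.search(sequence) for _, pat in EAR_PATTERNS)
    return wlg, rayd, ear


def compute_properties(sequence: str) -> ProteinProperties:
    """Length, molecular weight and isoelectric point.

    MW sums the bundled average residue masses plus one water; X counts the
    mean residue mass.  pI is solved by bisection on the net charge using
    the bundled pKa set, to 0.01 pH.
    """
    if not sequence:
        raise ValueError("empty sequence")
    masses = residue_masses()
    mean_mass = float(np.mean(list(masses.values())))
    weight = WATER_MASS
    for aa in sequence:
        if aa == "X":
            weight += mean_mass
        elif aa in masses:
            weight += masses[aa]
        else:
            raise ValueError(f"unknown residue {aa!r}")
    return ProteinProperties(
        length=len(sequence),
        molecular_weight=weight,
        isoelectric_point=isoelectric_point(sequence),
    )


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch per group)."""
    pka = pka_table()
    charge = 0.0
    for group in ("Nterm", "Cterm"):
        value, sign = pka[group]
        charge += _group_charge(value, sign, ph)
    for aa in sequence:
        if aa in pka:
            value, sign = pka[aa]
            charge += _group_charge(value, sign, ph)
    return charge


def _group_charge(pka: float, sign: int, ph: float) -> float:
    if sign > 0:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


def isoelectric_point(sequence: str, tolerance: float = 0.01) -> float:
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def classify_protein(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    soloist_identity_cutoff: float = SOLOIST_IDENTITY_CUTOFF,
) -> FamilyCall:
    """Full decision tree for one protein; total and deterministic."""
    call = FamilyCall(gene_id=protein.id)
    call.evidence = list(hits)
    family, flags = assign_superfamily(hits)
    call.family = family
    call.flags.extend(flags)
    if family == "none":
        call.subfamily = "none"
        return call
    if family == "HSP90":
        call.subfamily = "HSP90"
        return call

    subfamily = classify_subfamily(
        hits, soloist_identity_cutoff=soloist_identity_cutoff
    )
    ap2 = _hits_of(hits, "AP2")
    first = ap2[0]
    call.residue14 = first.residue_at(14, protein.sequence)
    call.residue19 = first.residue_at(19, protein.sequence)
    wlg, rayd, ear = detect_elements(first, protein.sequence)
    call.wlg_state, call.rayd_state, call.ear_motif = wlg, rayd, ear
    if call.ear_motif:
        call.flags.append("ear_pattern_heuristic")

    if subfamily == "ERF-lineage":
        sub, res14, res19, flags = classify_erf_dreb(first, protein.sequence)
        call.subfamily = sub
        call.residue14, call.residue19 = res14, res19
        call.flags.extend(flags)
        if sub in ("ERF", "DREB"):
            call.crf_core, call.crf_cterm_motif = detect_crf(
                protein.sequence, first
            )
    else:
        call.subfamily = subfamily
    return call


# ---------------------------------------------------------------------------
# Table-1-style tallies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySummary:
    """Per-species summary: subgroup counts, subfamily totals and the two
    genome-level ratios printed in family surveys."""

    subgroup_counts: dict[str, int]
    dreb_total: int
    erf_subfamily_total: int
    ap2: int
    ant: int
    rav: int
    soloist: int
    family_total: int
    hsp90: int
    percentage: float
    density: float


def tally(
    calls: Iterable[FamilyCall],
    genome_gene_total: int,
    genome_size_mb: float,
) -> FamilySummary:
    """Summarise classification calls for one species.

    The ERF-subfamily total is DREB + ERF (A- plus B-subgroups); the family
    total additionally counts AP2, ANT, RAV and soloist.  Percentage is of
    all genes in the genome (2 decimals); density is family genes per Mb
    (2 decimals).
    """
    if genome_gene_total <= 0:
        raise ValueError("genome_gene_total must be positive")
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    subgroup_counts = {f"A{i}": 0 for i in range(1, 7)}
    subgroup_counts.update({f"B{i}": 0 for i in range(1, 7)})
    counts = {"AP2": 0, "ANT": 0, "ERF": 0, "DREB": 0, "RAV": 0,
              "soloist": 0, "HSP90": 0}
    for call in calls:
        if call.subfamily in counts:
            counts[call.subfamily] += 1
        if call.subgroup in subgroup_counts:
            subgroup_counts[call.subgroup] += 1
    dreb_total = counts["DREB"]
    erf_total = dreb_total + counts["ERF"]
    family_total = (
        erf_total + counts["AP2"] + counts["ANT"] + counts["RAV"]
        + counts["soloist"]
    )
    return FamilySummary(
        subgroup_counts=subgroup_counts,
        dreb_total=dreb_total,
        erf_subfamily_total=erf_total,
        ap2=counts["AP2"],
        ant=counts["ANT"],
        rav=counts["RAV"],
        soloist=counts["soloist"],
        family_total=family_total,
        hsp90=counts["HSP90"],
        percentage=round(100.0 * family_total / genome_gene_total, 2),
        density=round(family_total / genome_size_mb, 2),
    )


def calls_from_counts(counts: dict[str, int]) -> list[FamilyCall]:
    """Expand a table of per-subgroup/subfamily counts into synthetic
    FamilyCall rows, for running :func:`tally` on printed summary tables."""
    calls: list[FamilyCall] = []
    for label, n in counts.items():
        for i in range(n):
            call = FamilyCall(gene_id=f"{label.lower()}_{i:04d}")
            call.family = "HSP90" if label == "HSP90" else "AP2/ERF"
            if label.startswith("A") and label[1:].isdigit():
                call.subfamily, call.subgroup = "DREB", label
            elif label.startswith("B") and label[1:].isdigit():
                call.subfamily, call.subgroup = "ERF", label
            else:
                call.subfamily = label
            calls.append(call)
    return calls
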