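"""Reference domain sequences for classification and phylogeny.

All references derive from the bundled AP2 profile: the primary consensus
(ERF-type frame: A at canonical position 14, D at 19) and the per-column
second-most-frequent ("alternative") residue.  Subgroup archetypes (A1-A6
for DREB, B1-B6 for ERF sensu stricto) substitute the alternative residue
at a small set of positions away from the conserved landmarks (YRG 2-4,
14/19, WLG 27-29, RAYD 39-42); the AP2/ANT references diverge more broadly,
ANT additionally carrying the WLG->YLG conversion seen in the AP2
subfamily.  The "soloist" reference keeps only the structural landmarks and
is therefore detectable by the scanner while sharing well under 30%
identity with any ERF reference.

These same sequences are what the synthetic-genome generator plants, which
is what makes planted truth recoverable by the classifier and the
clade-assignment step.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

from .domains import builtin_profile
from .records import AMINO_ACIDS

#: canonical AP2-domain landmark positions (1-based)
POSITION_14 = 14
POSITION_19 = 19
RESERVED_POSITIONS = frozenset({2, 3, 4, 14, 19, 27, 28, 29, 39, 40, 41, 42})

#: positions the soloist keeps from the consensus (structural landmarks only)
SOLOIST_PROTECTED = frozenset({2, 3, 4, 27, 28, 29, 39, 40, 41, 42})

DREB_SUBGROUPS = tuple(f"A{i}" for i in range(1, 7))
ERF_SUBGROUPS = tuple(f"B{i}" for i in range(1, 7))


@lru_cache(maxsize=None)
def ap2_consensus() -> str:
    return builtin_profile("AP2").consensus


@lru_cache(maxsize=None)
def ap2_alternative() -> str:
    """Second-highest-scoring residue per AP2 profile column."""
    profile = builtin_profile("AP2")
    order = np.argsort(profile.log_odds[:, : len(AMINO_ACIDS)], axis=1)
    return "".join(AMINO_ACIDS[i] for i in order[:, -2])


def _substitute(base: str, positions: tuple[int, ...]) -> str:
    alt = ap2_alternative()
    chars = list(base)
    for pos in positions:
        chars[pos - 1] = alt[pos - 1]
    return "".join(chars)


def _free_positions() -> list[int]:
    length = len(ap2_consensus())
    return [p for p in range(1, length + 1) if p not in RESERVED_POSITIONS]


@lru_cache(maxsize=None)
def archetypes() -> dict[str, str]:
    """All reference AP2-domain variants, keyed by role.

    Keys: ``ERF_base``, ``DREB_base``, ``A1``..``A6``, ``B1``..``B6``,
    ``AP2_R1``, ``ANT_R1``, ``R2`` (shared second domain of double-domain
    genes), ``RAV_AP2`` and ``soloist``.
    """
    cons = ap2_consensus()
    alt = ap2_alternative()
    free = _free_positions()

    erf_base = cons  # A14 / D19 by construction of the seed consensus
    dreb = list(cons)
    dreb[POSITION_14 - 1] = "V"
    dreb[POSITION_19 - 1] = "E"
    dreb_base = "".join(dreb)

    out: dict[str, str] = {"ERF_base": erf_base, "DREB_base": dreb_base}
    for k, name in enumerate(DREB_SUBGROUPS + ERF_SUBGROUPS):
        positions = tuple(free[k + off] for off in (0, 12, 24, 34))
        base = dreb_base if name.startswith("A") else erf_base
        seq = _substitute(base, positions)
        if name == "A6":  # the RAYD -> RAHD variant observed in few members
            seq = seq[:40] + "H" + seq[41:]
        out[name] = seq

    ap2_positions = tuple(free[i] for i in range(0, 24, 2))
    out["AP2_R1"] = _substitute(erf_base, ap2_positions)
    ant_positions = tuple(free[i] for i in range(0, 16, 2)) + tuple(
        free[i] for i in range(25, 33, 2)
    )
    ant = list(_substitute(erf_base, ant_positions))
    ant[27 - 1] = "Y"  # WLG -> YLG
    out["ANT_R1"] = "".join(ant)
    out["R2"] = _substitute(erf_base, tuple(free[i] for i in (1, 3, 5)))
    out["RAV_AP2"] = _substitute(erf_base, tuple(free[i] for i in (30, 32, 34, 36, 38)))

    soloist = [
        cons[j] if (j + 1) in SOLOIST_PROTECTED else alt[j]
        for j in range(len(cons))
    ]
    out["soloist"] = "".join(soloist)
    return out


@lru_cache(maxsize=None)
def erf_reference_domains() -> tuple[str, ...]:
    """AP2-domain sequences of canonical ERF-lineage members, used for the
    soloist low-homology test."""
    arch = archetypes()
    names = ("ERF_base", "DREB_base") + DREB_SUBGROUPS + ERF_SUBGROUPS
    return tuple(arch[name] for name in names)


def domain_identity(a: str, b: str) -> float:
    """Percent identity between two equal-frame ungapped domain sequences
    (compared over the shorter length)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * matches / n


def identity_to_erf_references(domain_sequence: str) -> float:
    """Best identity of a domain against the bundled ERF reference set."""
    return max(
        domain_identity(domain_sequence, ref)
        for ref in erf_reference_domains()
    )


def subgroup_reference_taxa() -> dict[str, tuple[str, str]]:
    """Labelled reference taxa for clade-based subgroup assignment:
    leaf name -> (subgroup label, AP2-domain sequence)."""
    arch = archetypes()
    refs = {
        f"REF_{name}": (name, arch[name])
        for name in DREB_SUBGROUPS + ERF_SUBGROUPS
    }
    refs["REF_AP2"] = ("AP2", arch["AP2_R1"])
    refs["REF_ANT"] = ("ANT", arch["ANT_R1"])
    return refs
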