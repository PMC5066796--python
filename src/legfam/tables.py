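"""Loaders for the bundled data tables (backgrounds, masses, pKa values)."""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from .records import AMINO_ACIDS


def _data_text(name: str) -> str:
    return (resources.files("legfam") / "data" / name).read_text()


def _read_kv(name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for line in _data_text(name).splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")[:2]
        out[key] = float(value)
    return out


@lru_cache(maxsize=None)
def background_frequencies() -> dict[str, float]:
    """Amino-acid background frequencies, renormalised to sum to 1."""
    raw = _read_kv("aa_background.tsv")
    total = sum(raw.values())
    return {aa: raw[aa] / total for aa in AMINO_ACIDS}


@lru_cache(maxsize=None)
def background_vector() -> np.ndarray:
    bg = background_frequencies()
    return np.array([bg[aa] for aa in AMINO_ACIDS])


@lru_cache(maxsize=None)
def residue_masses() -> dict[str, float]:
    """Average residue masses (Da); add one water for a whole protein."""
    return _read_kv("aa_masses.tsv")


WATER_MASS = 18.0153


@lru_cache(maxsize=None)
def pka_table() -> dict[str, tuple[float, int]]:
    """Ionisable groups: name -> (pKa, charge sign at low pH margin)."""
    out: dict[str, tuple[float, int]] = {}
    for line in _data_text("aa_pka.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pka, sign = line.split("\t")
        out[name] = (float(pka), +1 if sign == "+" else -1)
    return out


@lru_cache(maxsize=None)
def seed_alignment(domain_name: str) -> list[tuple[str, str]]:
    """The bundled synthetic seed alignment for a domain model."""
    fname = f"{domain_name.lower()}_seed.synthetic.afa"
    rows: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in _data_text(fname).splitlines():
        if line.startswith(">"):
            if name is not None:
                rows.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        rows.append((name, "".join(chunks)))
    return rows
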