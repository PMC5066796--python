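"""Profile-based protein domain detection.

Detects AP2, B3, HATPase_c and HSP90 domains with a self-contained
log-odds profile (PSSM) scorer built from the bundled seed alignments.
Scanning is ungapped: the pipeline only needs domain presence/absence,
coordinates and the residues at canonical domain positions; gapped
sensitivity can be delegated to the optional ``hmmscan`` backend.

Score thresholds are calibrated per profile as the score exceeded by fewer
than 0.1% of 10^5 random background windows, computed deterministically at
build time and stored with the profile.
"""
from __future__ import annotations

import shutil
import subprocess
import tempfile
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import BackendUnavailableError, ParseError
from .records import AMINO_ACIDS, DomainHit, ProteinRecord
from .tables import background_vector, seed_alignment

DOMAIN_NAMES = ("AP2", "B3", "HATPase_c", "HSP90")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_X_INDEX = len(AMINO_ACIDS)  # unknown residues score 0

_CAL_WINDOWS = 100_000
_CAL_QUANTILE = 0.999
#: Positive floor on the calibrated threshold.  For informative profiles the
#: 99.9% background quantile is deeply negative; requiring at least 10 bits
#: (a window 2^10 times likelier under the profile than under background)
#: keeps the threshold positive while still exceeded by <0.1% of random
#: windows.
_THRESHOLD_FLOOR = 10.0


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode residues as profile row indices; non-standard letters map to
    the zero-scoring X row."""
    return np.array(
        [_AA_INDEX.get(aa, _X_INDEX) for aa in sequence.upper()],
        dtype=np.int64,
    )


@dataclass(frozen=True)
class Profile:
    """Ungapped per-column log-odds model of one domain.

    ``log_odds`` has shape (length, 21): one row per retained alignment
    column, 20 residue scores in bits plus a trailing zero column for X.
    ``reference_column_map`` maps 1-based profile columns to canonical
    domain positions (the numbering in which the AP2-domain positions 14
    and 19 are defined).
    """

    domain_name: str
    length: int
    log_odds: np.ndarray = field(repr=False)
    score_threshold: float
    reference_column_map: dict[int, int] = field(repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds scores must be finite")
        if self.score_threshold <= 0:
            raise ValueError("score threshold must be positive")
        cols = sorted(self.reference_column_map)
        if cols != list(range(1, self.length + 1)):
            raise ValueError("reference_column_map must cover columns 1..length")

    @property
    def consensus(self) -> str:
        """Highest-scoring residue per column."""
        best = np.argmax(self.log_odds[:, : len(AMINO_ACIDS)], axis=1)
        return "".join(AMINO_ACIDS[i] for i in best)

    def window_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Score every ungapped window of an encoded sequence (empty array
        if the sequence is shorter than the profile)."""
        n = encoded.size - self.length + 1
        if n <= 0:
            return np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(encoded, self.length)
        return self.log_odds[np.arange(self.length), windows].sum(axis=1)


def _calibration_seed(domain_name: str) -> int:
    return zlib.crc32(domain_name.encode()) % (2**31)


def calibrate_threshold(
    log_odds: np.ndarray,
    seed: int,
    n_windows: int = _CAL_WINDOWS,
    quantile: float = _CAL_QUANTILE,
) -> float:
    """Score threshold exceeded by fewer than ``1 - quantile`` of random
    background windows; the false-discovery control for scanning."""
    rng = np.random.default_rng(seed)
    bg = background_vector()
    length = log_odds.shape[0]
    scores = np.empty(n_windows)
    cols = np.arange(length)
    for lo in range(0, n_windows, 20_000):
        hi = min(lo + 20_000, n_windows)
        sample = rng.choice(len(AMINO_ACIDS), size=(hi - lo, length), p=bg)
        scores[lo:hi] = log_odds[cols, sample].sum(axis=1)
    return max(float(np.quantile(scores, quantile)), _THRESHOLD_FLOOR)


def build_profile(
    alignment: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
    domain_name: str = "custom",
    gap_fraction: float = 0.5,
    score_threshold: float | None = None,
) -> Profile:
    """Build a log-odds profile from a gapped seed alignment.

    Columns with more than ``gap_fraction`` gaps are dropped; the per-column
    score of residue ``a`` is ``log2((n_a + c*q_a) / (n + c) / q_a)`` with
    pseudocount weight ``c`` and background frequency ``q_a``.  When no
    explicit threshold is given it is calibrated against random background
    windows (deterministic per domain name).
    """
    if not alignment:
        raise ValueError("empty seed alignment")
    seqs = [s.upper() for _, s in alignment]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("seed alignment rows have inconsistent lengths")
    if len(seqs) < 5:
        raise ValueError("seed alignment needs at least 5 sequences")

    bg = background_vector()
    columns: list[np.ndarray] = []
    kept: list[int] = []
    for j in range(width):
        col = [s[j] for s in seqs]
        gaps = sum(c not in _AA_INDEX for c in col)
        if gaps / len(col) > gap_fraction:
            continue
        counts = np.zeros(len(AMINO_ACIDS))
        for c in col:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        total = counts.sum()
        probs = (counts + pseudocount * bg) / (total + pseudocount)
        columns.append(np.log2(probs / bg))
        kept.append(j)

    if not columns:
        raise ValueError("no columns retained from seed alignment")
    log_odds = np.zeros((len(columns), len(AMINO_ACIDS) + 1))
    log_odds[:, : len(AMINO_ACIDS)] = np.vstack(columns)
    # canonical numbering: rank among retained columns (the seed alignments
    # are built so the dropped columns are the gappy inserts)
    column_map = {j + 1: j + 1 for j in range(len(columns))}
    threshold = (
        score_threshold
        if score_threshold is not None
        else calibrate_threshold(log_odds, _calibration_seed(domain_name))
    )
    return Profile(
        domain_name=domain_name,
        length=len(columns),
        log_odds=log_odds,
        score_threshold=threshold,
        reference_column_map=column_map,
    )


@lru_cache(maxsize=None)
def builtin_profile(domain_name: str) -> Profile:
    """The bundled profile for AP2, B3, HATPase_c or HSP90."""
    if domain_name not in DOMAIN_NAMES:
        raise KeyError(f"no bundled profile for {domain_name!r}")
    return build_profile(
        seed_alignment(domain_name), pseudocount=1.0, domain_name=domain_name
    )


def builtin_profiles() -> dict[str, Profile]:
    return {name: builtin_profile(name) for name in DOMAIN_NAMES}


def _resolve_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Keep the highest-scoring of overlapping same-domain hits (ties to
    the leftmost)."""
    chosen: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start)):
        if all(
            hit.end < c.start or hit.start > c.end
            for c in chosen
            if c.domain_name == hit.domain_name
        ):
            chosen.append(hit)
    chosen.sort(key=lambda h: (h.domain_name, h.start))
    return chosen


def scan(
    protein: ProteinRecord,
    profile: Profile,
    resolve_overlaps: bool = True,
) -> list[DomainHit]:
    """Slide the profile along the protein and report windows at or above
    the score threshold as domain hits (1-based inclusive coordinates)."""
    encoded = encode_sequence(protein.sequence)
    scores = profile.window_scores(encoded)
    hits: list[DomainHit] = []
    for offset in np.flatnonzero(scores >= profile.score_threshold):
        start = int(offset) + 1
        end = start + profile.length - 1
        position_map = {
            canonical: start + column - 1
            for column, canonical in profile.reference_column_map.items()
        }
        hits.append(
            DomainHit(
                protein_id=protein.id,
                domain_name=profile.domain_name,
                start=start,
                end=end,
                score=float(scores[offset]),
                domain_sequence=protein.sequence[start - 1 : end],
                position_map=position_map,
            )
        )
    return _resolve_overlaps(hits) if resolve_overlaps else hits


def scan_proteins(
    proteins: Iterable[ProteinRecord],
    profiles: dict[str, Profile] | None = None,
) -> dict[str, list[DomainHit]]:
    """Scan proteins against all profiles; hits grouped per protein id."""
    profiles = profiles or builtin_profiles()
    out: dict[str, list[DomainHit]] = {}
    for protein in proteins:
        hits: list[DomainHit] = []
        for profile in profiles.values():
            hits.extend(scan(protein, profile))
        out[protein.id] = sorted(hits, key=lambda h: h.start)
    return out


# ---------------------------------------------------------------------------
# external backends (optional): hmmscan and BLASTP mining
# ---------------------------------------------------------------------------

def _require_executables(backend: str, names: Sequence[str]) -> None:
    for name in names:
        if shutil.which(name) is None:
            raise BackendUnavailableError(backend)


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse an hmmscan ``--domtblout`` table into DomainHit records.

    The canonical-position map is reconstructed from the hmm/ali
    coordinates assuming an ungapped core match (adequate for
    presence/absence and the 14th/19th-residue lookup).
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 23:
            raise ParseError("truncated domtblout row", str(path), lineno)
        try:
            domain = parts[0].split(".")[0]
            protein = parts[3]
            score = float(parts[13])
            hmm_from, hmm_to = int(parts[15]), int(parts[16])
            ali_from, ali_to = int(parts[17]), int(parts[18])
        except ValueError as exc:
            raise ParseError(
                f"unparseable domtblout field: {exc}", str(path), lineno
            ) from exc
        position_map = {
            k: ali_from + (k - hmm_from)
            for k in range(hmm_from, hmm_to + 1)
            if ali_from + (k - hmm_from) <= ali_to
        }
        hits.append(
            DomainHit(
                protein_id=protein,
                domain_name=domain,
                start=ali_from,
                end=ali_to,
                score=score,
                domain_sequence="",
                position_map=position_map,
            )
        )
    return hits


def parse_blast_tabular(path: str | Path) -> list[dict]:
    """Parse BLAST outfmt-6 rows (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    rows: list[dict] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 12:
            raise ParseError("truncated BLAST tabular row", str(path), lineno)
        try:
            rows.append(
                {
                    "query": parts[0],
                    "subject": parts[1],
                    "pident": float(parts[2]),
                    "length": int(parts[3]),
                    "qstart": int(parts[6]),
                    "qend": int(parts[7]),
                    "sstart": int(parts[8]),
                    "send": int(parts[9]),
                    "evalue": float(parts[10]),
                    "bitscore": float(parts[11]),
                }
            )
        except ValueError as exc:
            raise ParseError(
                f"unparseable BLAST field: {exc}", str(path), lineno
            ) from exc
    return rows


def _hits_via_hmmscan(
    proteins: Sequence[ProteinRecord], profiles: dict[str, Profile]
) -> dict[str, list[DomainHit]]:
    _require_executables("hmmscan", ["hmmbuild", "hmmpress", "hmmscan"])
    with tempfile.TemporaryDirectory(prefix="legfam_hmm_") as tmp:
        tmpdir = Path(tmp)
        hmm_db = tmpdir / "domains.hmm"
        with open(hmm_db, "w") as db:
            for name in profiles:
                sto = tmpdir / f"{name}.sto"
                rows = seed_alignment(name)
                with open(sto, "w") as fh:
                    fh.write("# STOCKHOLM 1.0\n")
                    for seq_name, seq in rows:
                        fh.write(f"{seq_name}  {seq.replace('-', '.')}\n")
                    fh.write("//\n")
                hmm = tmpdir / f"{name}.hmm"
                subprocess.run(
                    ["hmmbuild", "-n", name, "--amino", str(hmm), str(sto)],
                    check=True, capture_output=True,
                )
                db.write(hmm.read_text())
        subprocess.run(
            ["hmmpress", str(hmm_db)], check=True, capture_output=True
        )
        query = tmpdir / "query.fasta"
        with open(query, "w") as fh:
            for protein in proteins:
                fh.write(f">{protein.id}\n{protein.sequence}\n")
        table = tmpdir / "hits.domtblout"
        subprocess.run(
            [
                "hmmscan", "--domtblout", str(table), "-E", "1e-5",
                str(hmm_db), str(query),
            ],
            check=True, capture_output=True,
        )
        raw = parse_domtblout(table)
    grouped: dict[str, list[DomainHit]] = {p.id: [] for p in proteins}
    for hit in raw:
        grouped.setdefault(hit.protein_id, []).append(hit)
    return {pid: _resolve_overlaps(hits) for pid, hits in grouped.items()}


def _hits_via_blastp(
    proteins: Sequence[ProteinRecord],
    profiles: dict[str, Profile],
    evalue: float = 1e-5,
) -> dict[str, list[DomainHit]]:
    _require_executables("blastp", ["makeblastdb", "blastp"])
    with tempfile.TemporaryDirectory(prefix="legfam_blast_") as tmp:
        tmpdir = Path(tmp)
        refs = tmpdir / "domain_refs.fasta"
        with open(refs, "w") as fh:
            for name, profile in profiles.items():
                fh.write(f">{name}\n{profile.consensus}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(refs), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        query = tmpdir / "query.fasta"
        with open(query, "w") as fh:
            for protein in proteins:
                fh.write(f">{protein.id}\n{protein.sequence}\n")
        out = tmpdir / "hits.tsv"
        subprocess.run(
            [
                "blastp", "-query", str(query), "-db", str(refs),
                "-evalue", str(evalue), "-outfmt", "6", "-out", str(out),
            ],
            check=True, capture_output=True,
        )
        rows = parse_blast_tabular(out)
    sequences = {p.id: p.sequence for p in proteins}
    grouped: dict[str, list[DomainHit]] = {p.id: [] for p in proteins}
    for row in rows:
        if row["evalue"] > evalue:
            continue
        qstart, qend = row["qstart"], row["qend"]
        position_map = {
            k: qstart + (k - row["sstart"])
            for k in range(row["sstart"], row["send"] + 1)
            if qstart + (k - row["sstart"]) <= qend
        }
        grouped.setdefault(row["query"], []).append(
            DomainHit(
                protein_id=row["query"],
                domain_name=row["subject"],
                start=qstart,
                end=qend,
                score=row["bitscore"],
                domain_sequence=sequences.get(row["query"], "")[
                    qstart - 1 : qend
                ],
                position_map=position_map,
            )
        )
    return {pid: _resolve_overlaps(hits) for pid, hits in grouped.items()}


def scan_with_backend(
    proteins: Sequence[ProteinRecord],
    backend: str = "internal",
    profiles: dict[str, Profile] | None = None,
    evalue: float = 1e-5,
) -> dict[str, list[DomainHit]]:
    """Scan with the internal PSSM scanner or an external executable
    (``hmmscan`` or ``blastp``), returning unified DomainHit records.

    External backends raise :class:`BackendUnavailableError` when the
    executable is missing; the internal scanner is always available.
    """
    profiles = profiles or builtin_profiles()
    if backend == "internal":
        return scan_proteins(proteins, profiles)
    if backend == "hmmscan":
        return _hits_via_hmmscan(proteins, profiles)
    if backend == "blastp":
        return _hits_via_blastp(proteins, profiles, evalue=evalue)
    raise ValueError(f"unknown backend {backend!r}")
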