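"""Profile building and domain scanning."""
from __future__ import annotations

import math

import numpy as np
import pytest

from legfam.domains import (
    Profile,
    build_profile,
    builtin_profile,
    builtin_profiles,
    encode_sequence,
    scan,
    scan_with_backend,
)
from legfam.exceptions import BackendUnavailableError
from legfam.records import AMINO_ACIDS, ProteinRecord
from legfam.tables import background_frequencies, seed_alignment


def test_identical_sequences_consensus_score_is_log_inverse_background():
    """With a vanishing pseudocount, a column of identical residues scores
    log2(1/background) for that residue."""
    rows = [(f"s{i}", "ACDE") for i in range(6)]
    profile = build_profile(rows, pseudocount=1e-9, score_threshold=1.0)
    bg = background_frequencies()
    for col, residue in enumerate("ACDE"):
        idx = AMINO_ACIDS.index(residue)
        expected = math.log2(1.0 / bg[residue])
        assert profile.log_odds[col, idx] == pytest.approx(expected, abs=1e-6)


def test_background_distributed_column_scores_near_zero():
    """A column whose residues follow the background distribution carries
    no information: its scores approach 0 bits as the pseudocount grows
    small relative to deep counts."""
    bg = background_frequencies()
    # build a deep alignment with one column populated pro rata
    n = 10_000
    residues = []
    for aa in AMINO_ACIDS:
        residues.extend(aa * int(round(bg[aa] * n)))
    rows = [(f"s{i}", res) for i, res in enumerate(residues)]
    profile = build_profile(rows, pseudocount=1e-6, score_threshold=1.0)
    assert np.abs(profile.log_odds[0, : len(AMINO_ACIDS)]).max() < 0.02


@pytest.mark.parametrize("name", ["AP2", "B3", "HATPase_c", "HSP90"])
def test_bundled_profile_length_matches_column_audit(name):
    """Retained-column count equals an independent gap-fraction audit of
    the bundled seed alignment."""
    rows = seed_alignment(name)
    width = len(rows[0][1])
    retained = 0
    for j in range(width):
        column = [seq[j] for _, seq in rows]
        gaps = sum(c in "-." for c in column)
        if gaps / len(column) <= 0.5:
            retained += 1
    assert builtin_profile(name).length == retained


def test_build_profile_rejects_bad_alignments():
    with pytest.raises(ValueError):
        build_profile([])
    with pytest.raises(ValueError):
        build_profile([("a", "ACD"), ("b", "AC")])
    with pytest.raises(ValueError):
        build_profile([("a", "ACD")] * 3)  # fewer than 5 sequences


def test_scan_finds_planted_consensus_at_exact_offset(ap2_profile, rng):
    background = "".join(rng.choice(list(AMINO_ACIDS), 150))
    seq = background[:10] + ap2_profile.consensus + background[10:]
    hits = scan(ProteinRecord("p", seq), ap2_profile)
    assert len(hits) == 1
    hit = hits[0]
    assert (hit.start, hit.end) == (11, 10 + ap2_profile.length)
    assert hit.domain_sequence == ap2_profile.consensus
    # canonical positions 14/19 map straight through the ungapped window
    assert hit.position_map[14] == 11 + 13
    assert seq[hit.position_map[14] - 1] == "A"
    assert seq[hit.position_map[19] - 1] == "D"


def test_scan_too_short_sequence_returns_empty(ap2_profile):
    assert scan(ProteinRecord("p", "MKQLV"), ap2_profile) == []


def test_scan_two_planted_copies_yield_two_hits(ap2_profile, rng):
    spacer = "".join(rng.choice(list(AMINO_ACIDS), 40))
    seq = (
        spacer
        + ap2_profile.consensus
        + spacer
        + ap2_profile.consensus
        + spacer
    )
    hits = scan(ProteinRecord("p", seq), ap2_profile)
    assert len(hits) == 2
    assert hits[0].end < hits[1].start


def test_window_score_invariant_outside_window(ap2_profile, rng):
    """Changing residues outside a hit window leaves its score unchanged."""
    flank = "".join(rng.choice(list(AMINO_ACIDS), 30))
    seq1 = flank + ap2_profile.consensus + flank
    seq2 = "M" * 30 + ap2_profile.consensus + "G" * 30
    score1 = scan(ProteinRecord("a", seq1), ap2_profile)[0].score
    score2 = scan(ProteinRecord("b", seq2), ap2_profile)[0].score
    assert score1 == pytest.approx(score2)


def test_planted_domain_recall_and_false_discovery(small_fixture, small_hits):
    """On noise-free fixtures every planted domain instance is found at its
    planted coordinates and nothing else is reported."""
    for gene_id, truth_gene in small_fixture.truth.genes.items():
        found = {
            (h.domain_name, h.start, h.end) for h in small_hits[gene_id]
        }
        planted = set(map(tuple, truth_gene.domains))
        assert found == planted, gene_id


def test_internal_backend_delegates_to_scan(small_fixture, small_hits):
    proteins = small_fixture.all_proteins()[:5]
    via_backend = scan_with_backend(proteins, backend="internal")
    for protein in proteins:
        assert via_backend[protein.id] == small_hits[protein.id]


def test_missing_executable_raises_backend_unavailable(monkeypatch):
    monkeypatch.setenv("PATH", "/nonexistent")
    with pytest.raises(BackendUnavailableError) as err:
        scan_with_backend([ProteinRecord("p", "MKV")], backend="hmmscan")
    assert err.value.fallback == "internal"


def test_unknown_backend_rejected():
    with pytest.raises(ValueError):
        scan_with_backend([ProteinRecord("p", "MKV")], backend="mystery")


def test_blastp_backend_concordant_with_internal(small_fixture):
    """The external BLASTP mining backend finds the same (protein, domain)
    presence set as the internal scanner on noise-free fixtures."""
    proteins = small_fixture.all_proteins()[:25]
    internal = scan_with_backend(proteins, backend="internal")
    external = scan_with_backend(proteins, backend="blastp")
    for protein in proteins:
        got = {h.domain_name for h in external[protein.id]}
        want = {h.domain_name for h in internal[protein.id]}
        assert got == want, protein.id


def test_hmmscan_backend_concordant_with_internal(small_fixture):
    """The profile-HMM backend built from the same seed alignments agrees
    with the internal scanner on domain content."""
    proteins = small_fixture.all_proteins()[:15]
    internal = scan_with_backend(proteins, backend="internal")
    external = scan_with_backend(proteins, backend="hmmscan")
    for protein in proteins:
        got = {h.domain_name for h in external[protein.id]}
        want = {h.domain_name for h in internal[protein.id]}
        assert got == want, protein.id


def test_profile_invariants(ap2_profile):
    assert np.isfinite(ap2_profile.log_odds).all()
    assert ap2_profile.score_threshold > 0
    assert sorted(ap2_profile.reference_column_map) == list(
        range(1, ap2_profile.length + 1)
    )
    # X scores zero everywhere
    assert np.all(ap2_profile.log_odds[:, -1] == 0.0)


def test_profile_rejects_nonpositive_threshold(ap2_profile):
    with pytest.raises(ValueError):
        Profile(
            domain_name="bad",
            length=ap2_profile.length,
            log_odds=ap2_profile.log_odds,
            score_threshold=0.0,
            reference_column_map=ap2_profile.reference_column_map,
        )
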