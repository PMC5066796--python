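"""Decision tree, motif detection, physico-chemical properties, tallies."""
from __future__ import annotations

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from legfam.classify import (
    assign_superfamily,
    calls_from_counts,
    classify_erf_dreb,
    classify_protein,
    classify_subfamily,
    compute_properties,
    detect_crf,
    detect_elements,
    isoelectric_point,
    net_charge,
    tally,
)
from legfam.exceptions import ContractViolation
from legfam.records import AMINO_ACIDS, DomainHit, ProteinRecord
from legfam.references import archetypes


def _hit(domain, start=1, length=58, seq=None, protein="g1"):
    end = start + length - 1
    return DomainHit(
        protein_id=protein,
        domain_name=domain,
        start=start,
        end=end,
        score=100.0,
        domain_sequence=seq or "A" * length,
        position_map={k: start + k - 1 for k in range(1, length + 1)},
    )


class TestSuperfamily:
    def test_single_ap2_is_ap2_erf(self):
        assert assign_superfamily([_hit("AP2")])[0] == "AP2/ERF"

    def test_hatpase_plus_hsp90_is_hsp90(self):
        hits = [_hit("HATPase_c"), _hit("HSP90", start=200, length=80)]
        assert assign_superfamily(hits)[0] == "HSP90"

    def test_hsp90_domain_alone_is_not_enough(self):
        assert assign_superfamily([_hit("HSP90")])[0] == "none"

    def test_empty_is_none(self):
        assert assign_superfamily([])[0] == "none"

    def test_pathological_both_goes_to_ap2_erf_with_warning(self):
        hits = [
            _hit("AP2"),
            _hit("HATPase_c", start=100),
            _hit("HSP90", start=300, length=80),
        ]
        family, flags = assign_superfamily(hits)
        assert family == "AP2/ERF"
        assert any("ambiguous" in f for f in flags)


class TestSubfamily:
    def test_two_ap2_domains_is_ap2(self):
        hits = [_hit("AP2"), _hit("AP2", start=120)]
        assert classify_subfamily(hits) == "AP2"

    def test_ap2_plus_b3_is_rav(self):
        hits = [_hit("AP2"), _hit("B3", start=120, length=60)]
        assert classify_subfamily(hits) == "RAV"

    def test_low_homology_single_ap2_is_soloist(self):
        assert classify_subfamily([_hit("AP2")], homology_to_erf_refs=18.0) \
            == "soloist"

    def test_single_ap2_above_cutoff_is_erf_lineage(self):
        assert classify_subfamily([_hit("AP2")], homology_to_erf_refs=85.0) \
            == "ERF-lineage"

    def test_constructed_soloist_domain_measures_below_cutoff(self):
        """The divergent-domain reference keeps only structural landmarks
        and lands well under the 30% identity cutoff."""
        hit = _hit("AP2", seq=archetypes()["soloist"])
        assert classify_subfamily([hit]) == "soloist"

    def test_no_ap2_domain_violates_contract(self):
        with pytest.raises(ContractViolation):
            classify_subfamily([_hit("B3")])


class TestErfDreb:
    @pytest.mark.parametrize(
        ("res14", "res19", "expected"),
        [
            ("V", "E", "DREB"),
            ("A", "D", "ERF"),
            ("V", "Q", "DREB"),   # 14V primacy: any 19th residue
            ("A", "K", "ERF"),    # position-14 primacy, flagged
            ("S", "D", "unresolved"),
        ],
    )
    def test_position_rules(self, res14, res19, expected):
        seq = list("G" * 58)
        seq[13], seq[18] = res14, res19
        seq = "".join(seq)
        hit = _hit("AP2", seq=seq)
        sub, got14, got19, _ = classify_erf_dreb(hit, seq)
        assert sub == expected
        assert (got14, got19) == (res14, res19)

    def test_truncated_domain_is_unresolved_and_flagged(self):
        hit = DomainHit(
            protein_id="g",
            domain_name="AP2",
            start=1,
            end=10,
            score=50.0,
            domain_sequence="G" * 10,
            position_map={},  # positions 14/19 unmappable
        )
        sub, _, _, flags = classify_erf_dreb(hit, "G" * 10)
        assert sub == "unresolved"
        assert "position14_unmappable" in flags


class TestMotifs:
    def test_crf_core_upstream_of_domain(self):
        seq = "M" * 10 + "ATDQSS" + "M" * 10 + "W" * 58 + "Q" * 40
        hit = _hit("AP2", start=27, seq="W" * 58)
        core, cterm = detect_crf(seq, hit)
        assert core and not cterm

    def test_crf_cterm_motif_in_terminal_third(self):
        seq = "M" * 20 + "W" * 58 + "Q" * 60 + "SPTSVL" + "Q" * 6
        hit = _hit("AP2", start=21, seq="W" * 58)
        core, cterm = detect_crf(seq, hit)
        assert cterm and not core

    def test_background_has_neither_crf_signature(self):
        seq = "M" * 20 + "W" * 58 + "M" * 60
        assert detect_crf(seq, _hit("AP2", start=21, seq="W" * 58)) == \
            (False, False)

    @pytest.mark.parametrize(
        ("domain", "wlg", "rayd"),
        [
            ("G" * 20 + "WLG" + "G" * 15 + "RAYD" + "G" * 16, "WLG", "RAYD"),
            ("G" * 20 + "YLG" + "G" * 15 + "RAHD" + "G" * 16, "YLG", "RAHD"),
            ("G" * 58, "absent", "absent"),
        ],
    )
    def test_wlg_and_rayd_states(self, domain, wlg, rayd):
        hit = _hit("AP2", seq=domain)
        got_wlg, got_rayd, _ = detect_elements(hit, domain)
        assert (got_wlg, got_rayd) == (wlg, rayd)

    def test_ear_motif_both_forms(self):
        hit = _hit("AP2", seq="G" * 58)
        assert detect_elements(hit, "G" * 58 + "LDLDLELRL")[2]
        assert detect_elements(hit, "G" * 58 + "KDLNLAPKK")[2]
        assert not detect_elements(hit, "G" * 70)[2]


class TestProperties:
    def test_single_glycine_mass(self):
        props = compute_properties("G")
        assert props.molecular_weight == pytest.approx(75.07, abs=0.01)

    def test_molecular_weight_matches_biopython(self):
        seq = "MKWVTFISLLLLFSSAYSRGV"
        props = compute_properties(seq)
        expected = ProteinAnalysis(seq).molecular_weight()
        assert props.molecular_weight == pytest.approx(expected, abs=0.5)

    def test_net_charge_vanishes_at_pi(self):
        for seq in ("MKKRHDE", "DDEEYC", "KKKRRH", "ACDEFGHIKLMNPQRSTVWY"):
            pi = isoelectric_point(seq)
            assert abs(net_charge(seq, pi)) < 0.05
            assert 0 < pi < 14

    def test_appending_aspartate_never_raises_pi(self):
        """Adding an acidic residue can only pull the isoelectric point
        down (checked against a brute-force charge curve)."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            seq = "".join(rng.choice(list(AMINO_ACIDS), 30))
            before, after = isoelectric_point(seq), isoelectric_point(seq + "D")
            assert after <= before + 0.01
            # brute-force oracle: charge curve of seq+D sits below seq's
            grid = np.linspace(1, 13, 60)
            assert all(
                net_charge(seq + "D", ph) <= net_charge(seq, ph) + 1e-9
                for ph in grid
            )

    def test_unknown_residue_rejected_but_x_tolerated(self):
        compute_properties("ACDX")
        with pytest.raises(ValueError):
            compute_properties("ACDZ")


class TestDecisionTreeTotality:
    def test_every_protein_gets_exactly_one_subfamily(self, small_fixture,
                                                      small_hits):
        valid = {
            "AP2", "ANT", "ERF", "DREB", "RAV", "soloist", "HSP90",
            "unresolved", "none",
        }
        for protein in small_fixture.all_proteins():
            call = classify_protein(protein, small_hits[protein.id])
            assert call.subfamily in valid
            repeat = classify_protein(protein, small_hits[protein.id])
            assert repeat.subfamily == call.subfamily


CHICKPEA_COUNTS = {
    "A1": 6, "A2": 5, "A3": 1, "A4": 14, "A5": 10, "A6": 7,
    "B1": 12, "B2": 5, "B3": 23, "B4": 14, "B5": 8, "B6": 14,
    "AP2": 14, "ANT": 10, "RAV": 2, "soloist": 2,
}


class TestTally:
    def test_chickpea_table_identities(self):
        summary = tally(calls_from_counts(CHICKPEA_COUNTS), 28_269, 738.0)
        assert summary.dreb_total == 43
        assert summary.erf_subfamily_total == 119
        assert summary.family_total == 147
        assert summary.percentage == 0.52
        assert summary.density == 0.20

    def test_family_total_equals_sum_of_rows(self):
        summary = tally(calls_from_counts(CHICKPEA_COUNTS), 28_269, 738.0)
        assert summary.family_total == (
            summary.erf_subfamily_total + summary.ap2 + summary.ant
            + summary.rav + summary.soloist
        )

    def test_zero_calls(self):
        summary = tally([], 1000, 100.0)
        assert summary.family_total == 0
        assert summary.percentage == 0.0

    def test_invalid_genome_totals_rejected(self):
        with pytest.raises(ValueError):
            tally([], 0, 100.0)
        with pytest.raises(ValueError):
            tally([], 100, 0.0)
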