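"""Fragment-pair library, pair scanning, satellites and localization."""

import numpy as np
import pytest

from lipiduvpd import (
    AcylChain,
    CentroidSpectrum,
    SimulationConfig,
    build_lipid_ion,
    discriminate_cc_vs_cyclopropane,
    flag_h3po4_satellites,
    format_shorthand,
    generate_pair_library,
    localize_modifications,
    scan_pairs,
    simulate_uvpd,
)
from lipiduvpd.chem import CYCLOPROPANE, DOUBLE_BOND
from lipiduvpd.uvpd import H3PO4_MASS, SEVEN_CH2_MASS


def pair_for(library, kind, position, satellite="none"):
    hits = [
        p for p in library
        if p.kind == kind and p.position == position and p.satellite == satellite
    ]
    assert len(hits) == 1
    return hits[0]


class TestPairLibrary:
    def test_protonated_pe_aberrant_double_bond_pair(self, pe341_proton_bare):
        lib = generate_pair_library(pe341_proton_bare)
        p = pair_for(lib, DOUBLE_BOND, 11)
        assert round(p.mz_low, 1) == 618.4
        assert round(p.mz_high, 1) == 632.4
        assert p.spacing_class == "14"

    def test_deprotonated_pe_cyclopropane_pair(self, pe331_deprot):
        lib = generate_pair_library(pe331_deprot)
        p = pair_for(lib, CYCLOPROPANE, 9)
        assert round(p.mz_low, 1) == 590.4
        assert round(p.mz_high, 1) == 604.4

    def test_pg_dual_modification_pairs(self, pg372_deprot):
        lib = generate_pair_library(pg372_deprot)
        cy = pair_for(
            [p for p in lib if p.chain_index == 1], CYCLOPROPANE, 11
        )
        assert (round(cy.mz_low, 1), round(cy.mz_high, 1)) == (675.4, 689.4)
        db = pair_for([p for p in lib if p.chain_index == 0], DOUBLE_BOND, 11)
        assert (round(db.mz_low, 1), round(db.mz_high, 1)) == (677.4, 701.4)
        assert db.spacing_class == "24"

    def test_spacing_exactness(self, pe341_proton_bare, pg372_deprot, cdl724_deprot):
        c2, ch2 = 24.000000, 14.015650
        for ion in (pe341_proton_bare, pg372_deprot, cdl724_deprot):
            for p in generate_pair_library(ion):
                expected = c2 if p.spacing_class == "24" else ch2
                assert p.spacing == pytest.approx(expected, abs=1e-6)

    def test_pc_standard_rule_spacing(self):
        ion = build_lipid_ion("PC", [AcylChain(16, 0), AcylChain(18, 1)], "-H")
        lib = generate_pair_library(ion)
        assert all(p.spacing_class == "24" for p in lib if p.kind == DOUBLE_BOND)

    def test_position_degeneracy_l_minus_p(self):
        # cy9 in a 17-carbon chain and cy11 in a 19-carbon chain lose the
        # same alkenes, hence identical pairs from the same precursor
        ion = build_lipid_ion(
            "CDL",
            [AcylChain(17, 1), AcylChain(19, 1), AcylChain(18, 1), AcylChain(18, 1)],
            "-H",
        )
        lib = generate_pair_library(ion)
        cy9_17 = [p for p in lib if p.kind == CYCLOPROPANE and p.chain_index == 0
                  and p.position == 9][0]
        cy11_19 = [p for p in lib if p.kind == CYCLOPROPANE and p.chain_index == 1
                   and p.position == 11][0]
        assert cy9_17.mz_low == pytest.approx(cy11_19.mz_low, abs=1e-9)
        assert cy9_17.mz_high == pytest.approx(cy11_19.mz_high, abs=1e-9)

    def test_cdl_cc_and_cyclopropane_isomer_pairs_2da_apart(self, cdl724_deprot):
        # CDL 72:4: the 4x18:1(Δ11) pair vs the 17:1(cy9)/19:1(cy11)
        # isomeric multiset pair differ by two hydrogens
        db = pair_for(
            [p for p in generate_pair_library(cdl724_deprot) if p.chain_index == 0],
            DOUBLE_BOND, 11,
        )
        iso = build_lipid_ion(
            "CDL",
            [AcylChain(17, 1), AcylChain(19, 1), AcylChain(18, 1), AcylChain(18, 1)],
            "-H",
        )
        cy = pair_for(
            [p for p in generate_pair_library(iso) if p.chain_index == 0],
            CYCLOPROPANE, 9,
        )
        assert iso.theoretical_mz == pytest.approx(cdl724_deprot.theoretical_mz, abs=1e-9)
        assert db.mz_low - cy.mz_low == pytest.approx(2.016, abs=1e-3)
        # reported in the ion trap near 1345.8/1369.8 and 1343.7/1357.8
        assert db.mz_low == pytest.approx(1345.8, abs=0.3)
        assert db.mz_high == pytest.approx(1369.8, abs=0.3)
        assert cy.mz_low == pytest.approx(1343.7, abs=0.3)
        assert cy.mz_high == pytest.approx(1357.8, abs=0.3)

    def test_pg_delta9_to_delta11_shift_is_two_methylenes(self):
        ion = build_lipid_ion("PG", [AcylChain(18, 1), AcylChain(18, 1)], "-H")
        lib = [p for p in generate_pair_library(ion) if p.chain_index == 0]
        d9 = pair_for(lib, DOUBLE_BOND, 9)
        d11 = pair_for(lib, DOUBLE_BOND, 11)
        assert d11.mz_low - d9.mz_low == pytest.approx(28.031, abs=1e-3)
        assert d11.mz_high - d9.mz_high == pytest.approx(28.031, abs=1e-3)

    def test_satellites_only_for_protonated_pe(self, pe341_proton_bare, pg372_deprot):
        assert any(
            p.satellite == "minus_H3PO4"
            for p in generate_pair_library(pe341_proton_bare)
        )
        assert all(
            p.satellite == "none" for p in generate_pair_library(pg372_deprot)
        )
        sodiated = build_lipid_ion("PE", [AcylChain(16, 0), AcylChain(18, 1)], "+Na")
        assert all(p.satellite == "none" for p in generate_pair_library(sodiated))

    def test_sodiated_pe_uses_14da_rule(self):
        sodiated = build_lipid_ion("PE", [AcylChain(16, 0), AcylChain(18, 1)], "+Na")
        lib = generate_pair_library(sodiated)
        assert all(p.spacing_class == "14" for p in lib if p.kind == DOUBLE_BOND)

    def test_sum_composition_rejected(self):
        ion = build_lipid_ion("PE", [AcylChain(34, 1)], "+H", id_level="sum_composition")
        with pytest.raises(ValueError, match="resolved chains"):
            generate_pair_library(ion)


class TestScanPairs:
    def test_synthetic_spectrum_top_match_is_truth(self, pe341_proton, pe341_proton_bare):
        spec = simulate_uvpd(SimulationConfig(ions=((pe341_proton, 1.0),), seed=11))
        matches = scan_pairs(spec, generate_pair_library(pe341_proton_bare))
        assert matches[0].hypothesis == (1, DOUBLE_BOND, 11)

    def test_single_member_is_not_evidence(self, pe341_proton_bare):
        lib = generate_pair_library(pe341_proton_bare)
        p = pair_for(lib, DOUBLE_BOND, 11)
        spec = CentroidSpectrum(
            np.array([p.mz_low]), np.array([1.0]), ms_level=3, polarity="positive"
        )
        assert all(m.hypothesis != (1, DOUBLE_BOND, 11) for m in scan_pairs(spec, lib))

    def test_ladder_does_not_displace_true_pair(self, pe341_proton, pe341_proton_bare):
        # full 14-Da ladder present, correct pair most intense: still top
        spec = simulate_uvpd(
            SimulationConfig(
                ions=((pe341_proton, 1.0),), ladder_intensity=0.1, n_ladder=20,
                pair_intensity=(0.5, 1.0), seed=5,
            )
        )
        matches = scan_pairs(spec, generate_pair_library(pe341_proton_bare))
        top_primary = [m for m in matches if m.pair.satellite == "none"][0]
        assert top_primary.hypothesis == (1, DOUBLE_BOND, 11)

    def test_score_is_base_peak_normalized(self, pe341_proton_bare):
        lib = generate_pair_library(pe341_proton_bare)
        p = pair_for(lib, DOUBLE_BOND, 11)
        spec = CentroidSpectrum(
            np.array([p.mz_low, p.mz_high, 700.0]),
            np.array([0.5, 0.3, 1.0]),
            ms_level=3, polarity="positive",
        )
        m = [x for x in scan_pairs(spec, lib) if x.hypothesis == (1, DOUBLE_BOND, 11)
             and x.pair.satellite == "none"][0]
        assert m.score == pytest.approx(0.8)


class TestDiscrimination:
    def test_aberrant_rule_masses_labeled_double_bond(self, pe341_proton_bare):
        lib = generate_pair_library(pe341_proton_bare)
        p = pair_for(lib, DOUBLE_BOND, 11)
        spec = CentroidSpectrum(
            np.array([p.mz_low, p.mz_high]), np.array([1.0, 1.0]),
            ms_level=3, polarity="positive",
        )
        out = discriminate_cc_vs_cyclopropane(
            scan_pairs(spec, lib), pe341_proton_bare
        )
        primary = [m for m in out if m.pair.satellite == "none"]
        assert all(m.pair.kind == DOUBLE_BOND for m in primary)
        assert all(not m.kind_ambiguous for m in primary)

    def test_two_dalton_shift_labeled_cyclopropane(self):
        truth = build_lipid_ion(
            "PE", [AcylChain(16, 0), AcylChain(18, 1, ((CYCLOPROPANE, 11),))], "+H"
        )
        bare = build_lipid_ion("PE", [AcylChain(16, 0), AcylChain(18, 1)], "+H")
        spec = simulate_uvpd(
            SimulationConfig(ions=((truth, 1.0),), mz_jitter=0.0, n_noise=0, seed=1)
        )
        out = discriminate_cc_vs_cyclopropane(
            scan_pairs(spec, generate_pair_library(bare)), bare
        )
        top = max(
            (m for m in out if m.pair.satellite == "none"), key=lambda m: m.score
        )
        assert top.pair.kind == CYCLOPROPANE
        assert top.pair.position == 11
        # the competing C=C interpretation is a full 2.016 Da away
        assert top.kind_margin == pytest.approx(2.016, abs=0.01)
        assert not top.kind_ambiguous


class TestSatellites:
    def test_satellite_linked_not_second_double_bond(self, pe341_proton, pe341_proton_bare):
        spec = simulate_uvpd(
            SimulationConfig(ions=((pe341_proton, 1.0),), mz_jitter=0.0,
                             n_noise=0, seed=2)
        )
        lib = generate_pair_library(pe341_proton_bare)
        matches = flag_h3po4_satellites(scan_pairs(spec, lib))
        # the Δ4 interpretation of the satellite peaks is linked away
        d4 = [m for m in matches if m.hypothesis == (1, DOUBLE_BOND, 4)
              and m.pair.satellite == "none"]
        assert d4 and all(m.satellite_of == (1, DOUBLE_BOND, 11) for m in d4)
        result = localize_modifications(
            pe341_proton_bare.species, {"positive": matches}
        )
        assert [(ci, m.kind, m.position) for ci, m in result.assignments] == [
            (1, DOUBLE_BOND, 11)
        ]

    def test_true_98_11_shift_not_linked_at_high_resolution(self):
        # two genuine double bonds seven methylenes apart produce pairs
        # 98.110 Da apart; at zero jitter the satellite hypothesis (97.977)
        # fits worse and must not absorb the second pair
        truth = build_lipid_ion(
            "PE",
            [AcylChain(18, 1, ((DOUBLE_BOND, 4),)),
             AcylChain(18, 1, ((DOUBLE_BOND, 11),))],
            "+H",
        )
        bare = build_lipid_ion("PE", [AcylChain(18, 1), AcylChain(18, 1)], "+H")
        spec = simulate_uvpd(
            SimulationConfig(ions=((truth, 1.0),), mz_jitter=0.0, n_noise=0,
                             satellite_intensity=0.0, seed=3)
        )
        matches = flag_h3po4_satellites(scan_pairs(spec, generate_pair_library(bare)))
        kept = {
            m.hypothesis for m in matches
            if m.pair.satellite == "none" and m.satellite_of is None
        }
        assert (0, DOUBLE_BOND, 4) in kept or (1, DOUBLE_BOND, 4) in kept
        assert (0, DOUBLE_BOND, 11) in kept or (1, DOUBLE_BOND, 11) in kept
        assert SEVEN_CH2_MASS - H3PO4_MASS == pytest.approx(0.133, abs=1e-3)

    def test_no_satellite_present_matches_unchanged(self, pg372_deprot):
        spec = simulate_uvpd(SimulationConfig(ions=((pg372_deprot, 1.0),), seed=4))
        matches = scan_pairs(spec, generate_pair_library(pg372_deprot))
        flagged = flag_h3po4_satellites(matches)
        assert [m.hypothesis for m in flagged] == [m.hypothesis for m in matches]
        assert all(m.satellite_of is None for m in flagged)


class TestLocalization:
    def test_pg_dual_mods_with_bacterial_prior(self, pg372_deprot):
        bare = build_lipid_ion("PG", [AcylChain(18, 1), AcylChain(19, 1)], "-H")
        spec = simulate_uvpd(SimulationConfig(ions=((pg372_deprot, 1.0),), seed=8))
        matches = scan_pairs(spec, generate_pair_library(bare))
        result = localize_modifications(
            bare.species, {"negative": matches},
            prior="bacterial_odd_chain_cyclopropane",
        )
        assert format_shorthand(result.species) == "PG 18:1(Δ11)_19:1(cy11)"
        assert not result.chain_ambiguous

    def test_pg_dual_mods_without_prior_is_ambiguous(self, pg372_deprot):
        bare = build_lipid_ion("PG", [AcylChain(18, 1), AcylChain(19, 1)], "-H")
        spec = simulate_uvpd(SimulationConfig(ions=((pg372_deprot, 1.0),), seed=8))
        matches = scan_pairs(spec, generate_pair_library(bare))
        result = localize_modifications(bare.species, {"negative": matches}, prior="none")
        assert result.chain_ambiguous
        assert result.species.id_level == "chain_composition"
        found = {(m.kind, m.position) for _, m in result.assignments}
        # positions are still recovered, attribution to chains is not
        assert {k for k, _ in found} == {DOUBLE_BOND, CYCLOPROPANE}

    def test_single_unsaturated_chain_unambiguous(self, pe341_proton, pe341_proton_bare):
        spec = simulate_uvpd(SimulationConfig(ions=((pe341_proton, 1.0),), seed=9))
        matches = flag_h3po4_satellites(
            discriminate_cc_vs_cyclopropane(
                scan_pairs(spec, generate_pair_library(pe341_proton_bare)),
                pe341_proton_bare,
            )
        )
        result = localize_modifications(pe341_proton_bare.species, {"positive": matches})
        assert format_shorthand(result.species) == "PE 16:0_18:1(Δ11)"
        assert not result.chain_ambiguous

    def test_no_evidence_returns_warning(self, pe341_proton_bare):
        result = localize_modifications(pe341_proton_bare.species, {"positive": []})
        assert result.assignments == ()
        assert "no pair evidence" in result.warnings
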