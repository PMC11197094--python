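"""Type I activity: screening, rates, branching, pH correction and scans."""

import numpy as np
import pytest

from radscav.datasets import (
    galangin_ladder,
    hydroperoxyl_pair,
    load_fixture,
    reference_rate_entries,
)
from radscav.scavenging import (
    PathwayRecord,
    branching_ratios,
    corrected_overall,
    evaluate_rates,
    ph_scan,
    screen_pathways,
    total_rate,
)


def _rec(mech, dg=None, dg_act=None, lam=None, species="X", site="s", medium="water"):
    return PathwayRecord(
        species=species, mechanism=mech, site=site, medium=medium,
        delta_g=dg, delta_g_act=dg_act, lamda=lam,
    )


class TestScreening:
    def test_endergonic_adduct_above_threshold_excluded(self):
        kept = screen_pathways([_rec("RAF", dg=18.2)])
        assert kept == []

    def test_exergonic_hydrogen_transfer_retained(self):
        kept = screen_pathways([_rec("fHAT", dg=-7.1)])
        assert len(kept) == 1

    def test_slightly_endergonic_below_threshold_retained(self):
        assert len(screen_pathways([_rec("RAF", dg=9.9)])) == 1
        assert len(screen_pathways([_rec("RAF", dg=10.0)])) == 0

    def test_electron_transfer_exempt_from_threshold(self):
        # Marcus kinetics can still be viable at very endergonic dG
        kept = screen_pathways([_rec("SET", dg=33.8)])
        assert len(kept) == 1


class TestEvaluateRates:
    def test_set_pathway_from_tabulated_barrier(self, ctx, diffusion):
        entries = evaluate_rates([_rec("SET", dg_act=6.0)], ctx, diffusion)
        assert entries[0].k_app == pytest.approx(2.28e8, rel=0.10)

    def test_set_barrier_derived_via_marcus_when_missing(self, ctx, diffusion):
        direct = evaluate_rates([_rec("SET", dg_act=21.5)], ctx, diffusion)[0]
        derived = evaluate_rates([_rec("SET", dg=19.0, lam=9.3)], ctx, diffusion)[0]
        assert derived.k_app == pytest.approx(direct.k_app, rel=0.06)

    def test_large_barrier_unaffected_by_diffusion(self, ctx, diffusion):
        e = evaluate_rates([_rec("fHAT", dg_act=25.0)], ctx, diffusion)[0]
        assert e.k_app == pytest.approx(e.k_tst, rel=1e-9)

    def test_missing_energies_reported_per_record(self, ctx, diffusion):
        with pytest.raises(ValueError, match="X/fHAT/s"):
            evaluate_rates([_rec("fHAT", dg=-3.0)], ctx, diffusion)

    def test_apparent_rate_never_exceeds_either_bound(self, ctx, diffusion):
        for dg_act in (0.0, 2.0, 10.0, 30.0):
            e = evaluate_rates([_rec("RAF", dg_act=dg_act)], ctx, diffusion)[0]
            assert e.k_app <= min(e.k_tst, e.k_d) * (1 + 1e-12)


class TestAggregation:
    def test_lipid_branching_is_dominated_by_one_site(self, scavenging_fixture):
        entries = reference_rate_entries(scavenging_fixture.blocks["H3Glg_PET"])
        gammas = branching_ratios(entries)
        by_site = {e.pathway.site + e.pathway.mechanism: g for e, g in zip(entries, gammas)}
        assert by_site["C3fHAT"] == pytest.approx(99.89, abs=0.02)
        assert gammas.sum() == pytest.approx(100.0, abs=1e-9)

    def test_dianion_branching_splits_across_fast_adducts(self, scavenging_fixture):
        entries = reference_rate_entries(scavenging_fixture.blocks["HGlg2-"])
        gammas = branching_ratios(entries)
        c2 = next(g for e, g in zip(entries, gammas) if e.pathway.site == "C2")
        assert c2 == pytest.approx(51.7, abs=0.1)

    def test_single_pathway_gets_full_share(self):
        entries = reference_rate_entries_single()
        assert branching_ratios(entries)[0] == pytest.approx(100.0)

    def test_totals_match_printed_sums(self, scavenging_fixture):
        expected = {"H3Glg_PET": 3.77e3, "H3Glg": 6.46e3, "H2Glg-": 5.11e4, "HGlg2-": 4.83e9}
        for species, total in expected.items():
            entries = reference_rate_entries(scavenging_fixture.blocks[species])
            assert total_rate(entries) == pytest.approx(total, rel=0.01)

    def test_empty_and_zero_inputs_are_errors(self):
        assert total_rate([]) == 0.0
        with pytest.raises(ValueError):
            branching_ratios([])

    def test_mixed_species_rejected(self, scavenging_fixture):
        a = reference_rate_entries(scavenging_fixture.blocks["H3Glg"])
        b = reference_rate_entries(scavenging_fixture.blocks["H2Glg-"])
        with pytest.raises(ValueError, match="mix"):
            branching_ratios(a + b)


def reference_rate_entries_single():
    from radscav.scavenging import RateEntry

    rec = PathwayRecord(species="Y", mechanism="fHAT", site="C3", delta_g_act=15.0)
    return [RateEntry(pathway=rec, k_tst=10.0, k_d=np.inf, k_app=10.0)]


class TestCorrectedOverall:
    def test_aqueous_overall_at_physiological_ph(self, scavenging_fixture, galangin):
        ladder, pair = galangin
        res = corrected_overall(
            scavenging_fixture.aqueous_totals(), ladder, pair, ph=7.4
        )
        assert res.k_overall == pytest.approx(6.21e4, rel=0.02)

    def test_neutral_species_corrected_value(self, scavenging_fixture, galangin):
        ladder, pair = galangin
        res = corrected_overall(
            scavenging_fixture.aqueous_totals(), ladder, pair, ph=7.4
        )
        assert res.k_corrected[0] == pytest.approx(8.81, rel=0.02)

    def test_lipid_medium_bypasses_speciation(self, scavenging_fixture):
        res = corrected_overall([3.77e3], medium="lipid")
        assert res.k_overall == 3.77e3
        assert res.radical_fraction == 1.0

    def test_unit_fractions_reduce_to_identity(self, galangin):
        ladder = galangin[0]
        res = corrected_overall([5.0, 7.0, 9.0], ladder, radical_pair=None, ph=-30.0)
        # at extreme acid pH only the fully protonated state remains
        assert res.k_overall == pytest.approx(5.0, rel=1e-9)

    def test_length_mismatch_is_error(self, galangin):
        with pytest.raises(ValueError, match="states"):
            corrected_overall([1.0, 2.0], galangin[0], galangin[1])

    def test_overall_bounded_by_largest_total(self, scavenging_fixture, galangin):
        ladder, pair = galangin
        totals = scavenging_fixture.aqueous_totals()
        for ph in np.linspace(0, 14, 15):
            res = corrected_overall(totals, ladder, pair, ph=ph)
            assert res.k_overall <= max(totals) * (1 + 1e-12)


class TestPhScan:
    def test_fixture_curve_shape(self, scavenging_fixture, galangin):
        ladder, pair = galangin
        scan = ph_scan(scavenging_fixture.aqueous_totals(), ladder, pair)
        logk = scan.log10_k_overall
        # flat plateau in strong acid
        acid = logk[scan.ph <= 3.0]
        assert acid.max() - acid.min() < 0.05
        # basin floor between pH 4.5 and 6
        assert 4.5 <= scan.argmin_ph <= 6.0
        # monotone rise out of the basin
        rise = logk[(scan.ph >= 6.0) & (scan.ph <= 8.0)]
        assert np.all(np.diff(rise) > 0)

    def test_fixture_minimum_depth(self, scavenging_fixture, galangin):
        ladder, pair = galangin
        scan = ph_scan(scavenging_fixture.aqueous_totals(), ladder, pair)
        assert 3.3 <= scan.min_log10_k <= 3.7

    def test_single_species_decays_with_radical_deprotonation(self, galangin):
        pair = galangin[1]
        from radscav.speciation import ProtonationLadder

        ladder = ProtonationLadder(["only"], [])
        scan = ph_scan([1e6], ladder, pair, ph_start=6.0, ph_stop=10.0, step=0.05)
        assert np.all(np.diff(scan.log10_k_overall) < 0)

    def test_continuity_of_overall_rate(self, scavenging_fixture, galangin):
        ladder, pair = galangin
        scan = ph_scan(scavenging_fixture.aqueous_totals(), ladder, pair)
        # no jumps anywhere on the default 0.01 grid
        assert np.abs(np.diff(scan.log10_k_overall)).max() < 0.05

    def test_deprotonation_monotonicity_of_totals(self, scavenging_fixture):
        k = scavenging_fixture.aqueous_totals()
        assert k[0] < k[1] < k[2]

    def test_range_validation(self, galangin):
        with pytest.raises(ValueError):
            ph_scan([1.0, 1.0, 1.0], galangin[0], galangin[1], ph_start=-1.0)
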