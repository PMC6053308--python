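"""Worm-like-chain mechanics: closed forms, limits, invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from tsmod.errors import (InvalidInputError, InvalidStateError,
                          ParameterError)
from tsmod.mechanics import (ExtensibleDomain, FluorophorePair,
                             PolymerEnvironment, SensorDesign,
                             contour_length, end_to_end_density,
                             force_response, fret_at_distance, get_pair,
                             marko_siggia_force, tilted_density,
                             unloaded_fret)


class TestForsterRelation:
    @pytest.mark.parametrize("r_over_r0, expected", [
        (0.0, 1.0),
        (1.0, 0.5),
        (2.0, 1.0 / 65.0),
    ])
    def test_closed_form(self, r_over_r0, expected):
        for r0 in (5.4, 5.7, 6.3):
            assert fret_at_distance(r_over_r0 * r0, r0) == pytest.approx(
                expected, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            fret_at_distance(1.0, 0.0)
        with pytest.raises(ParameterError):
            fret_at_distance(-1.0, 5.0)


class TestContourLength:
    def test_repeat_arithmetic(self):
        env = PolymerEnvironment.in_cellulo()
        d1 = ExtensibleDomain("GGSGGS", 9)
        assert contour_length(d1, env) == pytest.approx(54 * 0.38)
        d2 = ExtensibleDomain("GPGGA", 8)
        assert contour_length(d2, env) == pytest.approx(40 * 0.38)

    def test_zero_residue_domain_rejected(self):
        with pytest.raises(InvalidInputError):
            ExtensibleDomain("", 0)


class TestEndToEndDensity:
    @pytest.mark.parametrize("lp, lc, n_seg", [
        (0.48, 20.52, 54),
        (0.48, 20.52, None),
        (1.05, 15.2, 40),
        (0.05, 50.0, None),
        (100.0, 5.0, None),
    ])
    def test_normalisation(self, lp, lc, n_seg):
        val, _ = quad(lambda r: end_to_end_density(r, lp, lc, n_seg),
                      0, lc, limit=400,
                      points=[0.5 * lc, 0.9 * lc, 0.99 * lc, 0.999 * lc])
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_limit_second_moment(self):
        lp, lc = 0.05, 50.0
        r = np.linspace(0, lc, 100001)[1:-1]
        p = end_to_end_density(r, lp, lc)
        r2 = np.trapezoid(p * r ** 2, r)
        assert r2 == pytest.approx(2 * lp * lc, rel=0.05)

    def test_rigid_limit_mean(self):
        lp, lc = 100.0, 5.0
        r = np.linspace(0, lc, 100001)[1:-1]
        p = end_to_end_density(r, lp, lc)
        assert np.trapezoid(p * r, r) > 0.9 * lc

    def test_zero_beyond_contour_length(self):
        assert end_to_end_density(21.0, 0.48, 20.52) == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            end_to_end_density(1.0, -0.5, 20.0)
        with pytest.raises(ParameterError):
            end_to_end_density(1.0, 0.5, 0.0)


class TestTiltedDensity:
    def test_zero_force_reduces_to_unloaded(self):
        r = np.linspace(0.01, 20.0, 200)
        np.testing.assert_allclose(
            tilted_density(r, 0.48, 20.52, force=0.0),
            end_to_end_density(r, 0.48, 20.52))

    def test_normalisation_under_load(self):
        val, _ = quad(lambda r: tilted_density(r, 0.48, 20.52, force=4.0),
                      0, 20.52, limit=400, points=[10.0, 18.0, 20.0, 20.4])
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mean_strictly_increasing_in_force(self):
        lp, lc = 0.48, 20.52
        r = np.linspace(0, lc, 20001)[1:-1]
        means = []
        for f in range(0, 11):
            p = tilted_density(r, lp, lc, force=float(f))
            means.append(np.trapezoid(p * r, r) / np.trapezoid(p, r))
        assert np.all(np.diff(means) > 0)

    def test_negative_force_rejected(self):
        with pytest.raises(ParameterError):
            tilted_density(1.0, 0.48, 20.52, force=-1.0)


class TestMarkoSiggia:
    def test_zero_extension_zero_force(self):
        assert marko_siggia_force(0.0, 0.48) == 0.0

    def test_half_extension_value(self):
        assert marko_siggia_force(0.5, 0.48, kbt=4.28) == pytest.approx(
            (4.28 / 0.48) * 1.25, rel=1e-12)

    def test_small_extension_slope(self):
        lp, kbt, lc = 0.48, 4.28, 20.52
        eps = 1e-6
        slope_frac = marko_siggia_force(eps, lp, kbt) / eps
        # per unit absolute extension: divide by lc
        assert slope_frac / lc == pytest.approx(
            3 * kbt / (2 * lp * lc), rel=1e-4)

    def test_monotone_and_divergent(self):
        x = np.linspace(0, 0.99, 50)
        f = marko_siggia_force(x, 0.5)
        assert np.all(np.diff(f) > 0)
        with pytest.raises(ParameterError):
            marko_siggia_force(1.0, 0.5)


class TestUnloadedFret:
    def test_vanishing_chain_approaches_contact_limit(self, clover_pair):
        # as Lc -> 0 the fluorophores touch: E -> 1/(1+(2*Rfp/R0)^6)
        contact = fret_at_distance(2 * clover_pair.r_fluor, clover_pair.r0)
        assert contact == pytest.approx(1 / (1 + (4.6 / 6.3) ** 6), abs=1e-12)
        prev_gap = np.inf
        for lc_res in (0.38, 0.1, 0.02):
            env = PolymerEnvironment(310.0, 4.28, lc_res)
            d = SensorDesign(clover_pair,
                             ExtensibleDomain("G", 1, lp=0.48), env)
            gap = contact - unloaded_fret(d)
            assert 0 <= gap < prev_gap
            prev_gap = gap
        assert prev_gap < 5e-3

    def test_strictly_decreasing_in_length(self, clover_pair):
        effs = [unloaded_fret(SensorDesign(
            clover_pair, ExtensibleDomain("GGSGGS", n, lp=0.48)))
            for n in range(1, 16)]
        assert np.all(np.diff(effs) < 0)

    def test_unset_lp_raises(self, design_template):
        with pytest.raises(InvalidStateError):
            unloaded_fret(design_template)


class TestForceResponse:
    def test_zero_force_matches_unloaded(self, ggsggs9):
        fr = force_response(ggsggs9, np.linspace(0, 10, 11))
        assert fr.efficiency[0] == pytest.approx(unloaded_fret(ggsggs9),
                                                 abs=1e-12)
        assert fr.extension[0] == 0.0

    def test_monotone_curves(self, ggsggs9):
        fr = force_response(ggsggs9, np.linspace(0, 15, 61))
        assert np.all(np.diff(fr.efficiency) < 0)
        assert np.all(np.diff(fr.extension) > 0)
        assert np.all(np.diff(fr.mean_separation) > 0)
        assert np.all((fr.efficiency >= 0) & (fr.efficiency <= 1))

    def test_extension_independent_of_fluorophore_radius(self, clover_pair):
        grid = np.linspace(0, 12, 25)
        exts = []
        for rfp in (0.0, 2.3):
            pair = FluorophorePair("Clover", "mRuby2", r0=6.3, r_fluor=rfp)
            d = SensorDesign(pair, ExtensibleDomain("GGSGGS", 9, lp=0.48))
            exts.append(force_response(d, grid).extension)
        np.testing.assert_allclose(exts[0], exts[1], atol=1e-12)

    def test_trio_distinct_extensions_at_common_force(self, ggsggs_trio):
        grid = np.linspace(0, 8, 17)
        responses = {n: force_response(d, grid)
                     for n, d in ggsggs_trio.items()}
        # same force -> three distinct extensions, longer chain extends more
        ext_at_4 = [np.interp(4.0, grid, responses[n].extension)
                    for n in (5, 7, 9)]
        assert ext_at_4[0] < ext_at_4[1] < ext_at_4[2]
        # same extension -> three distinct forces, shorter chain needs more
        target = 2.0
        forces = [np.interp(target, responses[n].extension, grid)
                  for n in (5, 7, 9)]
        assert forces[0] > forces[1] > forces[2]

    def test_bad_grids_rejected(self, ggsggs9):
        with pytest.raises(InvalidInputError):
            force_response(ggsggs9, [1.0, 2.0])       # does not start at 0
        with pytest.raises(InvalidInputError):
            force_response(ggsggs9, [0.0, 2.0, 1.0])  # not ascending


class TestSerialization:
    def test_design_dict_round_trip(self, ggsggs9):
        d2 = SensorDesign.from_dict(ggsggs9.to_dict())
        assert d2.pair == ggsggs9.pair
        assert d2.domain == ggsggs9.domain
        assert d2.env == ggsggs9.env

    def test_force_response_csv_round_trip(self, ggsggs9, tmp_path):
        fr = force_response(ggsggs9, np.linspace(0, 5, 6))
        path = tmp_path / "resp.csv"
        fr.to_csv(path)
        from tsmod.mechanics import ForceResponse

        fr2 = ForceResponse.from_csv(path)
        np.testing.assert_allclose(fr2.efficiency, fr.efficiency)
        np.testing.assert_allclose(fr2.extension, fr.extension)

    def test_pair_registry(self):
        assert get_pair("mtfp1-venus").r0 == 5.7
        assert get_pair("clover-mruby2").r0 == 6.3
        assert get_pair("cy3-cy5").r0 == 5.4
        assert get_pair("cy3-cy5").r_fluor == 0.95
        with pytest.raises(InvalidInputError):
            get_pair("gfp-rfp")
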