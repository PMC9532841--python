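"""Endpoint callers and dose-response fitting."""

import io

import numpy as np
import pytest

from latamp.assays import (
    DEFAULT_INHIBITION_THRESHOLD,
    FitError,
    PlateAssay,
    PlateError,
    activity_flag,
    call_mbc,
    call_mbic,
    call_mic,
    fit_dose_response,
    four_pl,
    hemolysis_percent,
    read_plate_csv,
    viability_percent,
    write_plate_csv,
)

SERIES = (128.0, 64.0, 32.0, 16.0, 8.0, 4.0)


def plate_from_growth(growth, blank=0.05, control=0.50, n_rep=3, wavelength=600.0):
    """Noise-free plate whose normalized growth fractions equal ``growth``."""
    g = np.asarray(growth, dtype=float)
    readings = np.tile((blank + g * (control - blank))[:, None], (1, n_rep))
    return PlateAssay(
        concentrations=SERIES[: len(g)],
        readings=readings,
        growth_control=np.full(n_rep, control),
        sterile_blank=np.full(n_rep, blank),
        wavelength=wavelength,
    )


class TestPlateAssay:
    def test_growth_fractions_clamped(self):
        plate = plate_from_growth([0.0, 0.0, 1.0, 1.0])
        g = plate.growth_fractions()
        assert g.min() >= 0.0 and g.max() <= 1.0

    def test_increasing_concentrations_rejected(self):
        with pytest.raises(PlateError):
            PlateAssay((4.0, 8.0), np.zeros((2, 3)), np.ones(3), np.zeros(3))

    def test_degenerate_controls_rejected(self):
        plate = PlateAssay(SERIES[:2], np.full((2, 3), 0.2),
                           growth_control=np.full(3, 0.05),
                           sterile_blank=np.full(3, 0.05))
        with pytest.raises(PlateError, match="uninterpretable"):
            plate.growth_fractions()

    def test_csv_round_trip(self):
        plate = plate_from_growth([0.0, 0.0, 1.0, 1.0])
        buf = io.StringIO()
        write_plate_csv(plate, buf)
        buf.seek(0)
        back = read_plate_csv(buf)
        assert back.concentrations == plate.concentrations
        np.testing.assert_allclose(back.readings, plate.readings, atol=1e-4)


class TestMicCall:
    def test_sharp_transition(self):
        # no growth at 128..32, full growth at 16..4 -> MIC 32
        endpoint = call_mic(plate_from_growth([0, 0, 0, 1, 1, 1]))
        assert endpoint.value == 32.0
        assert str(endpoint) == "32"

    def test_growth_everywhere_is_censored(self):
        endpoint = call_mic(plate_from_growth([1, 1, 1, 1, 1, 1]))
        assert endpoint.censored
        assert str(endpoint) == ">128"

    def test_no_growth_anywhere_calls_lowest(self):
        endpoint = call_mic(plate_from_growth([0, 0, 0, 0, 0, 0]))
        assert endpoint.value == 4.0

    def test_monotone_from_top_skips_noisy_low_well(self):
        # an isolated inhibited well below a grown well must not be called
        endpoint = call_mic(plate_from_growth([0, 0, 1, 0, 1, 1]))
        assert endpoint.value == 64.0

    def test_threshold_monotonicity(self):
        growth = [0.02, 0.05, 0.12, 0.4, 1.0, 1.0]
        plate = plate_from_growth(growth)
        called = []
        for thr in (0.05, 0.10, 0.15, 0.5):
            e = call_mic(plate, inhibition_threshold=thr)
            called.append(np.inf if e.censored else e.value)
        # raising the threshold never raises the called MIC
        assert all(a >= b for a, b in zip(called, called[1:]))

    def test_endpoint_is_tested_concentration(self):
        e = call_mic(plate_from_growth([0, 0, 0.05, 1, 1, 1]))
        assert e.value in SERIES


class TestMbc:
    def test_lowest_sterile_concentration(self):
        e = call_mbc((128, 64, 32, 16, 8), [0, 0, 0, 12, 300])
        assert e.value == 32.0

    def test_all_zero_calls_lowest(self):
        e = call_mbc(SERIES, [0] * 6)
        assert e.value == 4.0

    def test_all_positive_censored(self):
        e = call_mbc(SERIES, [5, 8, 10, 40, 80, 100])
        assert e.censored and str(e) == ">128"


class TestMbic:
    def test_biofilm_plate_rule_matches_mic_rule(self):
        plate = plate_from_growth([0, 0, 1, 1], wavelength=595.0)
        assert call_mbic(plate).value == 64.0

    def test_no_biofilm_plate_calls_lowest(self):
        plate = plate_from_growth([0, 0, 0, 0], wavelength=595.0)
        assert call_mbic(plate).value == 16.0

    def test_unaffected_biofilm_censored(self):
        plate = plate_from_growth([1, 1, 1, 1], wavelength=595.0)
        assert call_mbic(plate).censored


class TestNormalizations:
    def test_hemolysis_anchors_and_linearity(self):
        assert hemolysis_percent(0.9, 0.1, 0.9) == 100.0
        assert hemolysis_percent(0.1, 0.1, 0.9) == 0.0
        assert hemolysis_percent(0.5, 0.1, 0.9) == pytest.approx(50.0)

    def test_hemolysis_clamped(self):
        assert hemolysis_percent(1.5, 0.1, 0.9) == 100.0
        assert hemolysis_percent(0.0, 0.1, 0.9) == 0.0

    def test_hemolysis_degenerate_controls(self):
        with pytest.raises(PlateError):
            hemolysis_percent(0.5, 0.9, 0.9)

    def test_viability_anchors(self):
        assert viability_percent(0.8, 0.8, 0.1) == pytest.approx(100.0)
        assert viability_percent(0.1, 0.8, 0.1) == pytest.approx(0.0)
        assert viability_percent(0.45, 0.8, 0.1) == pytest.approx(50.0)

    def test_viability_can_exceed_100(self):
        assert viability_percent(1.0, 0.8, 0.1) > 100.0

    @pytest.mark.parametrize("death,expected",
                             [(60.0, True), (59.9, False), (100.0, True), (0.0, False)])
    def test_activity_threshold(self, death, expected):
        assert activity_flag(death) is expected


class TestDoseResponse:
    def test_noise_free_recovery_of_hemolysis_ec50(self):
        # the parent peptide's hemolysis scenario: true EC50 127 ug/ml
        concs = np.array(SERIES)
        responses = four_pl(concs, 0.0, 100.0, 127.0, 1.5)
        fit = fit_dose_response(concs, responses)
        assert fit.EC50 == pytest.approx(127.0, rel=0.01)

    def test_constant_responses_unidentifiable(self):
        with pytest.raises(FitError, match="constant"):
            fit_dose_response(SERIES, [50.0] * 6)

    def test_too_few_concentrations(self):
        with pytest.raises(FitError):
            fit_dose_response([128, 64, 32], [90, 50, 10])

    def test_step_response_ec50_between_top_doses(self):
        # responses at bottom except the highest dose, fixed asymptotes:
        # the grid-search oracle puts the EC50 between the two highest doses
        concs = np.array(SERIES)
        responses = np.array([99.0, 1.0, 1.0, 1.0, 1.0, 1.0])

        def rss(ec50, hill):
            return float(np.sum((responses - four_pl(concs, 0, 100, ec50, hill)) ** 2))

        grid = [(rss(e, h), e)
                for e in np.geomspace(4, 256, 200) for h in np.geomspace(0.5, 20, 50)]
        best_ec50 = min(grid)[1]
        assert 64.0 <= best_ec50 <= 128.0

        fit = fit_dose_response(concs, responses, fix_bottom=0.0, fix_top=100.0)
        assert 64.0 <= fit.EC50 <= 128.0
        assert fit.EC50 == pytest.approx(best_ec50, rel=0.05)

    def test_fixed_asymptotes_respected(self):
        concs = np.array(SERIES)
        responses = four_pl(concs, 0.0, 100.0, 30.0, 2.0)
        fit = fit_dose_response(concs, responses, fix_bottom=0.0, fix_top=100.0)
        assert fit.bottom == 0.0 and fit.top == 100.0
        assert fit.EC50 == pytest.approx(30.0, rel=0.01)
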