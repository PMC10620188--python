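import itertools

import numpy as np
import pytest

from smsers.core import make_axis
from smsers.markers import (
    AmideBands,
    ClassifierConfig,
    DoubletRatio,
    amide_band_centers,
    band_fwhm,
    classify_hiapp,
    classify_hiapp_evidence,
    doublet_ratio,
    disulfide_marker,
    species_census,
    v8a_position,
)
from smsers.preprocess import estimate_noise_sd
from smsers.synth import (
    NOISELESS,
    NoiseModel,
    PeakBand,
    SpeciesTemplate,
    amplitude_for_snr,
    render_spectrum,
    simulate_hiapp_set,
)
from smsers.templates import builtin_template


def _noisy(template_name, snr, seed, sd=0.1):
    axis = make_axis()
    t = builtin_template(template_name)
    noise = NoiseModel(additive_sd=sd)
    amp = amplitude_for_snr(t, axis, noise, snr)
    s = render_spectrum(t, axis, noise, amp, seed=seed)
    return s, estimate_noise_sd(s)


class TestAmideBandCenters:
    def test_helix_coil_single_center_1656(self, axis, render_clean):
        s = render_clean(builtin_template("hIAPP_helix_coil"))
        bands = amide_band_centers(s)
        core = [c for c in bands.centers if 1642 <= c <= 1690]
        assert len(core) == 1
        assert core[0] == pytest.approx(1656.0, abs=2.0)

    def test_type1_single_broad_center_1668(self, axis, render_clean):
        s = render_clean(builtin_template("hIAPP_typeI"))
        bands = amide_band_centers(s)
        core = [c for c in bands.centers if 1642 <= c <= 1690]
        assert len(core) == 1
        assert core[0] == pytest.approx(1668.0, abs=2.0)

    def test_type2_two_centers(self, axis, render_clean):
        s = render_clean(builtin_template("hIAPP_typeII"))
        bands = amide_band_centers(s)
        core = [c for c in bands.centers if 1642 <= c <= 1690]
        assert len(core) == 2
        assert core[0] == pytest.approx(1655.0, abs=4.0)
        assert core[1] == pytest.approx(1674.0, abs=4.0)

    def test_center_unbiased_vs_dense_grid_oracle(self, axis):
        # off-grid symmetric band: dense-grid argmax is the oracle
        fine = make_axis(1600, 1700, 0.02)
        band = PeakBand.from_height(1657.3, 16, 1.0, "gaussian")
        oracle = fine.values[np.argmax(band.profile(fine.values))]
        s = render_spectrum(SpeciesTemplate("x", [band]), axis, NOISELESS)
        bands = amide_band_centers(s)
        assert len(bands.centers) == 1
        assert bands.centers[0] == pytest.approx(oracle, abs=1.0)  # step/2

    def test_centers_sorted_invariant(self):
        with pytest.raises(ValueError, match="sorted"):
            AmideBands((1674.0, 1655.0), (10.0, 10.0), np.zeros(3), np.zeros(3))


class TestBandFwhm:
    def test_recovers_broad_vs_narrow(self, render_clean):
        broad = render_clean(builtin_template("hIAPP_typeI"))
        narrow = render_clean(builtin_template("hIAPP_helix_coil"))
        w_broad = band_fwhm(broad, 1668.0)
        w_narrow = band_fwhm(narrow, 1656.0)
        assert w_broad == pytest.approx(28.0, abs=4.0)
        assert w_narrow == pytest.approx(16.0, abs=4.0)
        assert w_broad > 1.4 * w_narrow


class TestDoubletRatio:
    def test_equal_area_doublet_ratio_one(self, axis):
        t = SpeciesTemplate(
            "x",
            [
                PeakBand.from_height(830, 12, 0.7, "gaussian"),
                PeakBand.from_height(854, 12, 0.7, "gaussian"),
            ],
        )
        s = render_spectrum(t, axis, NOISELESS)
        assert doublet_ratio(s).ratio == pytest.approx(1.0, abs=0.05)

    def test_minus2_template_ratio_two_at_snr20(self):
        ratios = []
        for seed in range(8):
            s, est = _noisy("Tyr_minus2", 20, seed, sd=0.05)
            ratios.append(doublet_ratio(s, est).ratio)
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.1)

    def test_type2_ratio_above_one(self, render_clean):
        s = render_clean(builtin_template("hIAPP_typeII"))
        assert doublet_ratio(s).ratio > 1.0

    def test_invariant_to_scaling_and_linear_baseline(self, axis, render_clean):
        from smsers.core import Spectrum

        s = render_clean(builtin_template("Tyr_minus2"))
        base = doublet_ratio(s).ratio
        scaled = Spectrum(axis, 7.3 * s.intensity + 50.0 - 0.04 * axis.values)
        assert doublet_ratio(scaled).ratio == pytest.approx(base, rel=1e-6)

    def test_missing_854_flagged_undefined(self, axis):
        t = SpeciesTemplate("x", [PeakBand.from_height(830, 12, 1.0, "gaussian")])
        s = render_spectrum(t, axis, NOISELESS)
        result = doublet_ratio(s)
        assert result.ratio is None or result.ratio > 5

    def test_uncertainty_attached_with_noise(self):
        s, est = _noisy("Tyr_minus2", 20, 0, sd=0.05)
        result = doublet_ratio(s, est)
        assert result.uncertainty is not None and result.uncertainty > 0


class TestV8aPosition:
    def test_plus1_at_1620(self):
        s, est = _noisy("Tyr_plus1", 20, 1, sd=0.05)
        assert v8a_position(s, est) == pytest.approx(1620.0, abs=2.0)

    def test_minus2_at_1602(self):
        s, est = _noisy("Tyr_minus2", 20, 1, sd=0.05)
        assert v8a_position(s, est) == pytest.approx(1602.0, abs=2.0)

    def test_mixture_intermediate(self, axis):
        from smsers.synth import tyr_mixture_template

        # near the phenol pKa both charge states contribute
        t = tyr_mixture_template(10.2)
        s = render_spectrum(t, axis, NOISELESS)
        pos = v8a_position(s)
        assert 1602.0 <= pos <= 1620.0

    def test_flat_spectrum_absent(self, axis):
        rng = np.random.default_rng(0)
        s = render_spectrum(None, axis, NoiseModel(additive_sd=0.1), seed=rng)
        est = estimate_noise_sd(s)
        assert v8a_position(s, est) is None


class TestDisulfideMarker:
    def test_monomer_gives_523(self):
        s, est = _noisy("hIAPP_helix_coil", 10, 2)
        assert disulfide_marker(s, est)["state"] == "ggt_tgg_523"

    def test_fibril_gives_490(self):
        s, est = _noisy("hIAPP_fibril", 10, 2)
        assert disulfide_marker(s, est)["state"] == "strained_490"

    def test_flat_absent(self, axis):
        rng = np.random.default_rng(1)
        s = render_spectrum(None, axis, NoiseModel(additive_sd=0.1), seed=rng)
        est = estimate_noise_sd(s)
        assert disulfide_marker(s, est)["state"] == "absent"


class TestClassifyHiapp:
    @pytest.mark.parametrize(
        "name,want",
        [
            ("hIAPP_helix_coil", "predominant_helix_coil"),
            ("hIAPP_typeI", "typeI_turn"),
            ("hIAPP_typeII", "typeII_beta"),
            ("hIAPP_fibril", "fibril_like"),
        ],
    )
    def test_noise_free_templates(self, render_clean, name, want):
        s = render_clean(builtin_template(name))
        assert classify_hiapp(s).call == want

    def test_type1_evidence_ratio_near_one(self, render_clean):
        s = render_clean(builtin_template("hIAPP_typeI"))
        call = classify_hiapp(s)
        assert call.call == "typeI_turn"
        assert call.evidence["doublet_ratio"] == pytest.approx(1.0, abs=0.2)

    def test_decision_table_total_and_exclusive(self):
        # exhaustively sweep evidence tuples: every combination yields exactly
        # one catalogued call
        config = ClassifierConfig()
        centers_options = [
            (), (1656.0,), (1668.0,), (1674.0,), (1655.0, 1674.0), (1600.0,),
        ]
        ratios = [None, 0.9, 1.5]
        fwhms = [None, 15.0, 28.0]
        states = ["absent", "ggt_tgg_523", "strained_490", "both"]
        for centers, ratio, fwhm, state, a3 in itertools.product(
            centers_options, ratios, fwhms, states, [True, False]
        ):
            amide = AmideBands(
                centers, tuple(10.0 for _ in centers), np.zeros(3), np.zeros(3)
            )
            doublet = DoubletRatio(1.0, 1.0, ratio)
            call = classify_hiapp_evidence(amide, doublet, state, a3, config, fwhm)
            assert call in (
                "predominant_helix_coil",
                "typeI_turn",
                "typeII_beta",
                "fibril_like",
                "unclassified",
            )

    def test_determinism(self):
        s, est = _noisy("hIAPP_typeII", 8, 5, sd=0.125)
        assert classify_hiapp(s, est).call == classify_hiapp(s, est).call


class TestSpeciesCensus:
    def test_all_predominant(self, axis, noise_model):
        sset = simulate_hiapp_set(
            30, {"hIAPP_helix_coil": 1.0}, noise_model, axis, seed=3,
            amplitude_scale=8 * 0.125,
        )
        census = species_census(sset)
        assert census["fractions"]["predominant_helix_coil"] == 1.0

    def test_map_row_count(self, axis, noise_model):
        sset = simulate_hiapp_set(
            12, {"hIAPP_helix_coil": 1.0}, noise_model, axis, seed=3,
            amplitude_scale=8 * 0.125,
        )
        census = species_census(sset)
        assert census["map"].shape[0] == 12
        assert census["map"].min() >= 0.0 and census["map"].max() <= 1.0

    def test_mixture_fractions_recovered(self, axis, noise_model):
        probs = {"hIAPP_helix_coil": 0.9, "hIAPP_typeI": 0.05, "hIAPP_typeII": 0.05}
        sset = simulate_hiapp_set(
            600, probs, noise_model, axis, seed=10, amplitude_scale=8 * 0.125
        )
        census = species_census(sset)
        truth = {
            "predominant_helix_coil": 0.9,
            "typeI_turn": 0.05,
            "typeII_beta": 0.05,
        }
        for label, p in truth.items():
            se = np.sqrt(p * (1 - p) / 600)
            # classification error adds a little beyond sampling error
            assert abs(census["fractions"][label] - p) <= 3 * se + 0.02

    def test_empty_set_rejected(self, axis):
        from smsers.core import SpectrumSet

        with pytest.raises(ValueError):
            species_census(SpectrumSet.from_spectra([]))

    def test_end_to_end_recovery_at_snr8(self, axis, noise_model):
        # generator truth vs classifier call, false transitions counted
        probs = {"hIAPP_helix_coil": 0.96, "hIAPP_typeI": 0.02, "hIAPP_typeII": 0.02}
        sset = simulate_hiapp_set(
            500, probs, noise_model, axis, seed=77, amplitude_scale=8 * 0.125
        )
        mapping = {
            "hIAPP_helix_coil": "predominant_helix_coil",
            "hIAPP_typeI": "typeI_turn",
            "hIAPP_typeII": "typeII_beta",
            "none": "unclassified",
        }
        agree = sum(
            1
            for s in sset
            if classify_hiapp(s, estimate_noise_sd(s)).call
            == mapping[s.meta["label_truth"]]
        )
        assert agree / len(sset) >= 0.99
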