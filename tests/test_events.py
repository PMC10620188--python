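import numpy as np
import pytest

from smsers.core import make_axis
from smsers.events import (
    BIASERS_WINDOWS,
    BandHit,
    DetectionWindow,
    classify_biasers,
    classify_spectrum,
    detect_band,
    event_summary,
    switching_rsd,
)
from smsers.preprocess import NoiseEstimate, estimate_noise_sd
from smsers.synth import (
    NOISELESS,
    EventProcess,
    NoiseModel,
    PeakBand,
    SpeciesTemplate,
    amplitude_for_snr,
    merge_templates,
    render_spectrum,
    simulate_biasers_set,
    simulate_switching_series,
)
from smsers.templates import builtin_template


def _noise_est(sd=0.125):
    return NoiseEstimate(sd, (1750.0, 1800.0), 26)


class TestDetectBand:
    def test_injected_band_detected_with_center(self, axis):
        sigma = 0.125
        t = SpeciesTemplate("x", [PeakBand.from_height(1650, 14, 8 * sigma)])
        rng = np.random.default_rng(21)
        noise = NoiseModel(additive_sd=sigma)
        s = render_spectrum(t, axis, noise, seed=rng)
        hit = detect_band(s, BIASERS_WINDOWS["nba1650"], _noise_est(sigma))
        assert hit.present
        assert hit.center == pytest.approx(1650.0, abs=2.0)

    def test_parabolic_center_matches_dense_grid_oracle(self):
        # off-grid band centre: compare against argmax on a 100x finer grid
        axis = make_axis(400, 1800, 2)
        fine = make_axis(1600, 1700, 0.02)
        band = PeakBand.from_height(1651.3, 14, 1.0)
        oracle = fine.values[np.argmax(band.profile(fine.values))]
        s = render_spectrum(SpeciesTemplate("x", [band]), axis, NOISELESS)
        hit = detect_band(s, BIASERS_WINDOWS["nba1650"], _noise_est(0.0))
        assert hit.center == pytest.approx(oracle, abs=1.0)  # within step/2

    def test_noise_only_rarely_detected(self, axis):
        rng = np.random.default_rng(2)
        noise = NoiseModel(additive_sd=0.125)
        false_pos = 0
        n = 2000
        for _ in range(n):
            s = render_spectrum(None, axis, noise, seed=rng)
            est = estimate_noise_sd(s)
            for window in BIASERS_WINDOWS.values():
                if detect_band(s, window, est).present:
                    false_pos += 1
                    break
        assert false_pos / n <= 0.01

    def test_zero_sigma_flags_infinite_snr(self, axis):
        t = SpeciesTemplate("x", [PeakBand.from_height(1650, 14, 1.0)])
        s = render_spectrum(t, axis, NOISELESS)
        hit = detect_band(s, BIASERS_WINDOWS["nba1650"], _noise_est(0.0))
        assert hit.present and np.isinf(hit.snr)

    def test_zero_sigma_flat_spectrum_absent(self, axis):
        s = render_spectrum(None, axis, NOISELESS)
        hit = detect_band(s, BIASERS_WINDOWS["nba1650"], _noise_est(0.0))
        assert not hit.present

    def test_band_at_window_edge_center_stays_inside(self, axis):
        t = SpeciesTemplate("x", [PeakBand.from_height(1641, 14, 1.0)])
        s = render_spectrum(t, axis, NOISELESS)
        window = BIASERS_WINDOWS["nba1650"]
        hit = detect_band(s, window, _noise_est(0.0))
        assert window.lo <= hit.center <= window.hi

    def test_window_off_axis_rejected(self, axis):
        s = render_spectrum(None, axis, NOISELESS)
        with pytest.raises(Exception):
            detect_band(s, DetectionWindow("bad", 1900, 1950), _noise_est())

    def test_k_sigma_monotonicity(self, axis):
        rng = np.random.default_rng(13)
        noise = NoiseModel(additive_sd=0.125)
        t = builtin_template("NBA")
        amp = amplitude_for_snr(t, axis, noise, 4)  # marginal SNR
        counts = []
        spectra = [render_spectrum(t, axis, noise, amp, seed=rng) for _ in range(60)]
        for k in (2.0, 3.0, 4.0, 5.0, 8.0):
            det = 0
            for s in spectra:
                est = estimate_noise_sd(s)
                if detect_band(s, BIASERS_WINDOWS["nba1650"], est, k_sigma=k).present:
                    det += 1
            counts.append(det)
        assert counts == sorted(counts, reverse=True)


class TestClassifyBiasers:
    @pytest.mark.parametrize(
        "m600,m1630,m1650,want",
        [
            (True, False, True, "single_NBA"),
            (False, True, False, "single_MB"),
            (True, True, True, "dual_MB_NBA"),
            (False, True, True, "dual_MB_NBA"),
            (False, False, False, "none"),
            (True, False, False, "none"),
            (False, False, True, "none"),
            (True, True, False, "single_MB_is_not_this", ),
        ],
    )
    def test_rule_table(self, m600, m1630, m1650, want):
        hits = {"marker600": m600, "mb1630": m1630, "nba1650": m1650}
        label = classify_biasers(hits)
        if want == "single_MB_is_not_this":
            # 1630 with 600 but no 1650 matches no catalogued pattern
            assert label == "none"
        else:
            assert label == want

    def test_exhaustive_single_label(self):
        import itertools

        for m600, m1630, m1650 in itertools.product([True, False], repeat=3):
            label = classify_biasers(
                {"marker600": m600, "mb1630": m1630, "nba1650": m1650}
            )
            assert label in ("none", "single_MB", "single_NBA", "dual_MB_NBA")

    def test_noise_free_oracle_equivalence(self, axis):
        mb, nba = builtin_template("MB"), builtin_template("NBA")
        cases = [
            (mb, "single_MB"),
            (nba, "single_NBA"),
            (merge_templates("dual", [mb, nba]), "dual_MB_NBA"),
            (None, "none"),
        ]
        for template, want in cases:
            s = render_spectrum(template, axis, NOISELESS)
            label, _ = classify_spectrum(s)
            assert label == want


class TestEventSummary:
    def test_all_none(self, axis):
        sset = simulate_biasers_set(
            10, EventProcess(0.0, {"MB": 1.0}), NoiseModel(0.1), axis, seed=0
        )
        summary = event_summary(sset, ["none"] * 10)
        assert summary["detected_fraction"] == 0.0

    def test_counts_partition_n(self, axis):
        sset = simulate_biasers_set(
            20, EventProcess(0.0, {"MB": 1.0}), NoiseModel(0.1), axis, seed=0
        )
        labels = ["none"] * 15 + ["single_MB"] * 3 + ["single_NBA"] * 2
        summary = event_summary(sset, labels)
        assert sum(summary["counts"].values()) == 20
        assert summary["detected"] == 5

    def test_length_mismatch_rejected(self, axis):
        sset = simulate_biasers_set(
            5, EventProcess(0.0, {"MB": 1.0}), NoiseModel(0.1), axis, seed=0
        )
        with pytest.raises(ValueError, match="labels"):
            event_summary(sset, ["none"] * 4)

    def test_single_events_outnumber_duals_in_dilute_mix(self, axis, noise_model):
        proc = EventProcess(0.05, {"MB": 0.5, "NBA": 0.5}, dual_rule=0.1)
        t = builtin_template("NBA")
        amp = amplitude_for_snr(t, axis, noise_model, 8)
        sset = simulate_biasers_set(
            3000, proc, noise_model, axis, seed=17, amplitude_scale=amp
        )
        labels = [classify_spectrum(s)[0] for s in sset]
        summary = event_summary(sset, labels)
        singles = summary["counts"].get("single_MB", 0) + summary["counts"].get(
            "single_NBA", 0
        )
        assert singles > summary["counts"].get("dual_MB_NBA", 0)


class TestSwitchingRSD:
    def test_zero_cv_zero_noise_zero_rsd(self, axis):
        t = builtin_template("NBA_junction")
        series = simulate_switching_series(5, t, NOISELESS, axis, seed=0)
        result = switching_rsd(series, DetectionWindow("a", 1635, 1655))
        assert result.rsd_percent == pytest.approx(0.0, abs=1e-9)

    def test_cv_15_recovered_below_20_percent(self, axis):
        noise = NoiseModel(additive_sd=0.05, intensity_cv=0.15)
        t = builtin_template("NBA_junction")
        amp = amplitude_for_snr(t, axis, noise, 20)
        series = simulate_switching_series(
            12, t, noise, axis, seed=12345, amplitude_scale=amp
        )
        result = switching_rsd(series, DetectionWindow("a", 1635, 1655))
        assert 5.0 < result.rsd_percent < 20.0
        assert result.off_violations == 0
        assert result.contrast > 3.0

    def test_analyte_in_off_state_flagged(self, axis):
        noise = NoiseModel(additive_sd=0.05)
        t = builtin_template("NBA_junction")
        amp = amplitude_for_snr(t, axis, noise, 20)
        # build a corrupted series: analyte present in every state
        rng = np.random.default_rng(3)
        spectra = []
        for i in range(6):
            s = render_spectrum(t, axis, noise, amp, seed=rng,
                                meta={"trap_state": "on" if i % 2 == 0 else "off"})
            spectra.append(s)
        from smsers.core import SpectrumSet

        series = SpectrumSet.from_spectra(spectra)
        result = switching_rsd(series, DetectionWindow("a", 1635, 1655))
        assert result.off_violations == 3

    def test_requires_trap_state_metadata(self, axis):
        from smsers.core import SpectrumSet

        s = render_spectrum(None, axis, NOISELESS)
        with pytest.raises(ValueError, match="trap_state"):
            switching_rsd(
                SpectrumSet.from_spectra([s, s]), DetectionWindow("a", 1635, 1655)
            )


class TestCalibration:
    def test_detected_fraction_tracks_p_event(self, axis, noise_model):
        proc = EventProcess(0.05, {"MB": 0.5, "NBA": 0.5}, dual_rule=0.1)
        t = builtin_template("NBA")
        amp = amplitude_for_snr(t, axis, noise_model, 8)
        sset = simulate_biasers_set(
            3600, proc, noise_model, axis, seed=1, amplitude_scale=amp
        )
        labels = [classify_spectrum(s)[0] for s in sset]
        frac = event_summary(sset, labels)["detected_fraction"]
        se = np.sqrt(0.05 * 0.95 / 3600)
        assert abs(frac - 0.05) <= 3 * se

    def test_partition_every_spectrum_labelled(self, axis, noise_model):
        proc = EventProcess(0.3, {"MB": 0.5, "NBA": 0.5}, dual_rule=0.2)
        t = builtin_template("NBA")
        amp = amplitude_for_snr(t, axis, noise_model, 8)
        sset = simulate_biasers_set(
            300, proc, noise_model, axis, seed=2, amplitude_scale=amp
        )
        labels = [classify_spectrum(s)[0] for s in sset]
        assert len(labels) == len(sset)
        assert all(
            lab in ("none", "single_MB", "single_NBA", "dual_MB_NBA") for lab in labels
        )
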