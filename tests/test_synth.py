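"""Generator ground truth: background spectra, event morphology, spike rates."""

import numpy as np
import pytest
from scipy import signal as sps

from pnhmicro import (
    NODULE_PRESETS,
    AnnotationTable,
    UnitGainProfile,
    generate_background,
    generate_ip_series,
    generate_unit_spikes,
    render_ip_event,
)
from pnhmicro.periodicity import periodicity_fraction
from pnhmicro.synth import (
    PlacementError,
    UnsupportedPatternError,
    inverse_gain,
    phasic_gain,
    sustained_gain,
)


class TestBackground:
    def test_white_noise_rms(self):
        sig = generate_background(10, 1000, pink_exponent=0, rms_uV=10, seed=0)
        assert sig.samples.std() == pytest.approx(10.0, rel=0.05)

    def test_pink_slope(self):
        sig = generate_background(60, 1000, pink_exponent=1, rms_uV=10, seed=0)
        f, pxx = sps.welch(sig.samples, fs=1000, nperseg=4096)
        band = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[band]), np.log10(pxx[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_same_seed_bit_identical(self):
        a = generate_background(5, 1000, 1, 10, seed=7)
        b = generate_background(5, 1000, 1, 10, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": 0}, {"duration_s": -1},
        {"fs_hz": 500}, {"pink_exponent": 3},
    ])
    def test_invalid_arguments(self, kwargs):
        base = {"duration_s": 1.0, "fs_hz": 1000.0}
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_background(**base)


class TestRenderEvent:
    def test_pdf_zero_jitter_is_perfectly_periodic(self, preset1):
        from dataclasses import replace

        p0 = replace(preset1, pdf_jitter_frac=0.0)
        _, defl = render_ip_event("PD+F", p0, 1000, seed=0, n_deflections=5)
        intervals = np.diff(defl)
        np.testing.assert_allclose(intervals, p0.pdf_period_s, atol=1e-9)
        assert periodicity_fraction(defl).frac_within_25 == 1.0

    def test_sdf_unsupported_for_nodule_3(self):
        with pytest.raises(UnsupportedPatternError):
            render_ip_event("SD+F", NODULE_PRESETS[3], 1000, seed=0)

    def test_es_burst_frequency(self, preset1):
        """The rendered spike transient's 60-200 Hz peak sits at the preset."""
        wave, _ = render_ip_event("ES", preset1, 1000, seed=0)
        n = wave.size
        spec = np.abs(np.fft.rfft(wave * np.hanning(n))) ** 2
        f = np.fft.rfftfreq(n, 1 / 1000)
        band = (f >= 60) & (f <= 200)
        f_peak = f[band][np.argmax(spec[band])]
        assert abs(f_peak - preset1.es_fast_hz) <= 1000 / n + 2.5

    def test_deflection_count_matches_request(self, preset1):
        _, defl = render_ip_event("PD+F", preset1, 1000, seed=1, n_deflections=7)
        assert len(defl) == 7


class TestSeries:
    def test_zero_rates_gives_pure_background(self, preset1):
        sig, ann, _ = generate_ip_series(
            preset1, 30, 1000, {"ES": 0.0}, seed=0
        )
        bg = generate_background(30, 1000, 1.0, 10.0,
                                 np.random.default_rng(0))
        assert len(ann) == 0
        np.testing.assert_array_equal(sig.samples, bg.samples)

    def test_annotation_count_conserves_events(self, preset1):
        sig, ann, defl = generate_ip_series(
            preset1, 400, 1000, {"ES": 1 / 8}, seed=4
        )
        assert (ann.df["label"] == "ES").all()
        assert len(defl) == len(ann)
        # annotated intervals hold the inserted energy: signal variance in
        # events well above background
        assert len(ann) > 20

    def test_same_kind_events_never_overlap(self, preset1):
        _, ann, _ = generate_ip_series(preset1, 600, 1000, seed=5)
        for label, grp in ann.df.groupby("label"):
            starts = grp["start_s"].to_numpy()
            ends = grp["end_s"].to_numpy()
            assert np.all(starts[1:] >= ends[:-1])

    def test_placement_error_at_impossible_rate(self, preset1):
        with pytest.raises(PlacementError):
            generate_ip_series(preset1, 120, 1000, {"ES": 200.0}, seed=0)

    def test_determinism(self, preset1):
        a = generate_ip_series(preset1, 200, 1000, seed=9)
        b = generate_ip_series(preset1, 200, 1000, seed=9)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        assert a[1].df.equals(b[1].df)


def test_macro_channel_is_attenuated_smoothed_copy(preset1):
    from pnhmicro.synth import macro_channel

    sig, _, _ = generate_ip_series(preset1, 60, 1000, {"ES": 0.2}, seed=2)
    mac = macro_channel(sig, attenuation=0.25)
    assert mac.fs_hz == sig.fs_hz
    assert mac.samples.size == sig.samples.size
    assert mac.samples.std() < 0.3 * sig.samples.std()
    # below the smoothing cutoff the copy tracks the micro signal
    assert np.corrcoef(mac.samples, sig.samples)[0, 1] > 0.9


class TestUnitSpikes:
    def test_homogeneous_poisson_count(self):
        prof = UnitGainProfile("u", 5.0)
        t = generate_unit_spikes(AnnotationTable(), prof, 1000.0, seed=3)
        assert abs(len(t) - 5000) < 3 * np.sqrt(5000)
        assert np.all(np.diff(t) > 0)

    def test_gain_peak_recovered_by_event_rate(self, make_annotations):
        onsets = np.arange(10.0, 1010.0, 10.0)
        ann = make_annotations(
            [("ES", "micro1", o, o + 0.1) for o in onsets]
        )
        prof = UnitGainProfile(
            "u", 10.0, {"ES": sustained_gain(5.0, 1.0)}
        )
        t = generate_unit_spikes(ann, prof, 1020.0, seed=5)
        # mean rate in the plateau (0.2..0.8 s after onset) across events
        counts = sum(
            np.sum((t >= o + 0.2) & (t < o + 0.8)) for o in onsets
        )
        rate = counts / (0.6 * len(onsets))
        assert rate == pytest.approx(50.0, rel=0.10)

    def test_inverse_unit_silent_in_suppression_window(self, make_annotations):
        onsets = np.arange(5.0, 500.0, 5.0)
        ann = make_annotations(
            [("ES", "micro1", o, o + 0.1) for o in onsets]
        )
        prof = UnitGainProfile(
            "u", 20.0, {"ES": inverse_gain(0.0, 0.5)}, inverse=True
        )
        t = generate_unit_spikes(ann, prof, 505.0, seed=6)
        for o in onsets:
            assert not np.any((t >= o) & (t < o + 0.5))

    def test_inverse_profile_validation(self):
        with pytest.raises(ValueError):
            UnitGainProfile("u", 5.0, {"ES": phasic_gain(3.0)}, inverse=True)
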