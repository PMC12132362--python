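"""Generator forward-model guarantees: programmed gains, spectra, blinks."""

import numpy as np
import pandas as pd
import pytest

import ssvepbf as s
from ssvepbf.errors import ConfigurationError
from ssvepbf.simulate import blink_propagation, one_over_f_noise
from ssvepbf.ssvep import amplitude_spectrum, hilbert_envelope, narrowband_filter


def _cell_mean_envelopes(ep, condition):
    """Envelope of the CS+/CS- trial means without average referencing."""
    out = {}
    for stim in ("CS+", "CS-"):
        idx = np.flatnonzero(
            (ep.labels["condition"] == condition) & (ep.labels["stimulus"] == stim)
        )
        mean = s.EpochSet(
            data=ep.data[idx].mean(axis=0, keepdims=True),
            times_ms=ep.times_ms, labels=ep.labels.iloc[:1], montage=ep.montage,
        )
        out[stim] = hilbert_envelope(narrowband_filter(mean)).envelope[0]
    return out


class TestEegForwardModel:
    def test_noiseless_gain_recovered_through_envelope_chain(self, montage32,
                                                             schedule):
        gain = 1.3
        truth = s.GroundTruthEffect(
            (s.EffectWindow("tritan", ("65", "66", "69", "70", "75"),
                            0.0, 1000.0, gain),)
        )
        ep = s.simulate_subject_epochs(schedule, montage32, truth,
                                       s.EegNoiseParams().quiet(), seed=0)
        env = _cell_mean_envelopes(ep, "tritan")
        # window interior: the 1 Hz-wide cascade smears the gain step by
        # roughly +-300 ms around the 0 and 1000 ms edges
        w = (ep.times_ms >= 300) & (ep.times_ms <= 650)
        for sid in ("65", "70", "75"):
            i = montage32.index(sid)
            ratio = env["CS+"][i, w] / env["CS-"][i, w]
            np.testing.assert_allclose(ratio, gain, rtol=0.02)
        # outside the declared window the gain is 1
        w_out = (ep.times_ms >= 2000) & (ep.times_ms <= 3000)
        # (same interior margin applies: 1000 ms edge is long past)
        np.testing.assert_allclose(
            env["CS+"][montage32.index("75"), w_out]
            / env["CS-"][montage32.index("75"), w_out],
            1.0, rtol=0.02,
        )

    def test_null_truth_no_envelope_difference(self, montage32, schedule):
        ep = s.simulate_subject_epochs(schedule, montage32,
                                       s.GroundTruthEffect.null(),
                                       s.EegNoiseParams().quiet(), seed=0)
        env = _cell_mean_envelopes(ep, "luminance")
        w = (ep.times_ms >= 200) & (ep.times_ms <= 3400)
        i = montage32.index("Oz")
        np.testing.assert_allclose(env["CS+"][i, w], env["CS-"][i, w], rtol=1e-9)

    def test_trial_average_spectrum_peaks_at_driving_frequency(self, montage32,
                                                               schedule):
        ep = s.simulate_subject_epochs(schedule, montage32,
                                       s.GroundTruthEffect.null(),
                                       s.EegNoiseParams(), seed=4)
        avg = s.EpochSet(data=ep.data.mean(axis=0, keepdims=True),
                         times_ms=ep.times_ms, labels=ep.labels.iloc[:1],
                         montage=montage32)
        spec = amplitude_spectrum(avg)
        peak = spec.peak_frequency(3, 25, channel=montage32.index("Oz"))
        assert peak == pytest.approx(s.DRIVING_FREQUENCY_HZ, rel=0.03)

    def test_bit_reproducible(self, montage32, schedule):
        a = s.simulate_subject_epochs(schedule, montage32,
                                      s.GroundTruthEffect.null(),
                                      s.EegNoiseParams(), seed=5)
        b = s.simulate_subject_epochs(schedule, montage32,
                                      s.GroundTruthEffect.null(),
                                      s.EegNoiseParams(), seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_truth_sensor_rejected(self, montage32, schedule):
        truth = s.GroundTruthEffect(
            (s.EffectWindow("tritan", ("not-a-sensor",), 0.0, 1000.0, 1.3),)
        )
        with pytest.raises(ConfigurationError):
            s.simulate_subject_epochs(schedule, montage32, truth, seed=0)


@pytest.fixture(scope="module")
def raw(montage32, schedule):
    return s.simulate_subject_eeg(schedule, montage32,
                                  s.GroundTruthEffect.null(),
                                  s.EegNoiseParams(bad_channels=("15",)),
                                  seed=6, iti_range_s=(0.8, 1.2))


class TestContinuousRecording:

    def test_events_cover_schedule_and_fit(self, raw, schedule):
        assert len(raw.events) == len(schedule)
        samples = raw.events["sample"].to_numpy()
        assert (np.diff(samples) > 0).all()
        assert samples[0] >= 300 and samples[-1] + 1900 < raw.n_samples

    def test_blinks_share_frontal_ocular_propagation(self, raw, montage32):
        w = blink_propagation(montage32)
        oc = montage32.ocular_indices()
        assert w[oc].max() == 1.0
        # front-to-back decay: frontal weight far above occipital weight
        assert w[montage32.index("28")] > 5 * w[montage32.index("Oz")]
        # ocular trace correlates strongly with a frontal channel (blinks)
        eog = raw.data[oc].mean(axis=0)
        frontal = raw.data[montage32.index("28")]
        occip = raw.data[montage32.index("75")]
        c_front = np.corrcoef(eog, frontal)[0, 1]
        c_back = np.corrcoef(eog, occip)[0, 1]
        assert c_front > 0.4 and c_front > 3 * abs(c_back)

    def test_bad_channel_carries_inflated_noise(self, raw, montage32):
        bad = raw.data[montage32.index("15")]
        typical = np.median(raw.data.std(axis=1))
        assert bad.std() > 4 * typical


class TestNoiseModel:
    def test_one_over_f_rms_and_slope(self, rng):
        x = one_over_f_noise((4,), 100000, 500.0, 1.0, 2.5, rng)
        np.testing.assert_allclose(x.std(axis=1), 2.5, rtol=1e-9)
        f = np.fft.rfftfreq(100000, 1 / 500.0)
        p = np.abs(np.fft.rfft(x[0])) ** 2
        lo = p[(f > 1) & (f < 4)].mean()
        hi = p[(f > 30) & (f < 120)].mean()
        assert lo > 5 * hi  # power concentrated at low frequencies


class TestPupilAndRatings:
    def test_zero_increment_equal_means(self, schedule):
        acq = schedule[schedule.phase == "acquisition"].reset_index(drop=True)
        params = s.PupilEffectParams(cs_plus_increment_mm=0.0,
                                     missing_rate_hz=0.0)
        raw = s.simulate_subject_pupil(acq, params, seed=1)
        w = (raw.times_ms >= 1800) & (raw.times_ms <= 3800)
        means = {}
        for stim in ("CS+", "CS-"):
            idx = raw.labels["stimulus"] == stim
            means[stim] = raw.traces[np.asarray(idx)][:, w].mean()
        assert means["CS+"] == pytest.approx(means["CS-"], abs=0.01)

    def test_cs_plus_redilates_more(self, schedule):
        acq = schedule[schedule.phase == "acquisition"].reset_index(drop=True)
        raw = s.simulate_subject_pupil(acq, s.PupilEffectParams(missing_rate_hz=0.0),
                                       seed=1)
        w = (raw.times_ms >= 1800) & (raw.times_ms <= 3800)
        for cond in ("tritan", "luminance"):
            lab = raw.labels
            plus = raw.traces[np.asarray((lab.condition == cond) & (lab.stimulus == "CS+"))][:, w].mean()
            minus = raw.traces[np.asarray((lab.condition == cond) & (lab.stimulus == "CS-"))][:, w].mean()
            assert plus > minus

    def test_missing_runs_inserted(self, schedule):
        raw = s.simulate_subject_pupil(schedule, s.PupilEffectParams(), seed=2)
        assert raw.missing_mask.any()
        assert np.nanmin(raw.traces) > 0

    def test_ratings_bounded_and_habituation_null(self):
        df = s.simulate_expectancy_ratings(n_subjects=40, seed=3)
        assert df["rating"].between(0, 10).all()
        h = df[df.occasion == "H"].pivot_table(
            index="subject", columns="stimulus", values="rating")
        r = s.paired_ttest(h["CS+"].to_numpy(), h["CS-"].to_numpy())
        assert abs(r.t) < 3  # no programmed habituation effect

    def test_rating_t_statistic_matches_design(self):
        """t ~ shift * sqrt(n) / sigma_diff for the programmed acquisition shift."""
        effect = s.RatingEffect(shifts={"H": 0.0, "A1": 3.0, "A2": 3.0, "E": 0.0},
                                cs_minus_mean=3.0, sigma=2.1)
        ts = []
        for seed in range(10):
            df = s.simulate_expectancy_ratings(effect=effect, n_subjects=50,
                                               seed=seed)
            a1 = df[(df.occasion == "A1") & (df.condition == "tritan")].pivot(
                index="subject", columns="stimulus", values="rating")
            ts.append(s.paired_ttest(a1["CS+"].to_numpy(), a1["CS-"].to_numpy()).t)
        expected = 3.0 * np.sqrt(50) / (2.1 * np.sqrt(2))
        assert np.mean(ts) == pytest.approx(expected, rel=0.2)
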