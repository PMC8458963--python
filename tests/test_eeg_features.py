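"""Per-epoch EEG feature families: cardinalities, physics and conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurofuse import BandScheme, EEGRecording, PatchScheme, make_epochs
from neurofuse.eeg_features import (aggregate_functionals,
                                    amplitude_modulation_features,
                                    coherence_features, epoch_feature_vector,
                                    epoch_features, modulation_patch_features,
                                    spectral_power_features)
from neurofuse.preprocess import EpochSet
from tests.conftest import CHANNELS, FS, am_tone_epoch, noise_recording

LABELS9 = CHANNELS + ("F3-F4", "P3-P4")


def epochs_of(arr: np.ndarray) -> np.ndarray:
    return arr[None, ...]


@pytest.fixture(scope="module")
def noise_epoch_set() -> EpochSet:
    rng = np.random.default_rng(42)
    data = rng.standard_normal((len(LABELS9), int(20 * FS)))
    return make_epochs(EEGRecording(data, FS, LABELS9))


class TestSpectralPower:
    @pytest.mark.parametrize("tone_hz", [9.0, 11.0])
    def test_alpha_tone_concentrates_relative_power(self, tone_hz):
        """A tone inside one alpha half-band: the halves sum to the parent band.

        (A tone at exactly 10 Hz sits on the low/high split, where each
        linear-phase FIR is at -6 dB, so the halves would sum to ~0.5.)
        """
        ep = epochs_of(am_tone_epoch(tone_hz, 2.0, depth=0.0, channels=LABELS9))
        values, valid = spectral_power_features(ep, FS, LABELS9, BandScheme())
        assert valid.all().all()
        assert values.at[0, "pow-alpha-F3"] >= 0.95
        split_sum = values.at[0, "pow-low-alpha-F3"] + values.at[0, "pow-high-alpha-F3"]
        assert split_sum == pytest.approx(values.at[0, "pow-alpha-F3"], abs=0.05)

    def test_default_scheme_emits_81_names(self, noise_epoch_set):
        values, _ = spectral_power_features(noise_epoch_set.epochs, FS, LABELS9,
                                            BandScheme())
        assert values.shape[1] == 81
        assert all(n.startswith("pow-") for n in values.columns)

    def test_flat_epoch_flagged_invalid_without_nan(self):
        ep = np.zeros((1, len(LABELS9), 1000))
        values, valid = spectral_power_features(ep, FS, LABELS9, BandScheme())
        assert not valid.any().any()
        assert np.isfinite(values.to_numpy()).all()


class TestCoherence:
    def test_self_pair_coherence_is_one(self, noise_epoch_set):
        scheme = BandScheme(coherence_pairs=(("F3", "F3"),))
        values, _ = coherence_features(noise_epoch_set.epochs, FS, LABELS9, scheme)
        assert np.allclose(values.to_numpy(), 1.0)

    def test_independent_noise_channels_have_low_msc(self, noise_epoch_set):
        values, _ = coherence_features(noise_epoch_set.epochs, FS, LABELS9,
                                       BandScheme())
        assert values.to_numpy().mean() < 0.35

    def test_default_scheme_emits_25_names(self, noise_epoch_set):
        values, _ = coherence_features(noise_epoch_set.epochs, FS, LABELS9,
                                       BandScheme())
        assert values.shape[1] == 25

    def test_missing_channel_named(self, noise_epoch_set):
        scheme = BandScheme(coherence_pairs=(("F3", "Oz"),))
        with pytest.raises(KeyError, match="Oz"):
            coherence_features(noise_epoch_set.epochs, FS, LABELS9, scheme)


def am_oracle_fraction(mod_hz: float, depth: float, band: tuple[float, float],
                       duration_s: float = 8.0, fs: float = FS) -> float:
    """Brute-force modulation-band fraction from the *known* modulator.

    Periodogram of the exact envelope 1 + depth*cos(2*pi*f*t) with DC removed,
    rectangular integration over the band, normalized by total non-DC energy.
    Independent of the band-filter + Hilbert production path.
    """
    t = np.arange(int(duration_s * fs)) / fs
    env = 1.0 + depth * np.cos(2 * np.pi * mod_hz * t)
    env = env - env.mean()
    spec = np.abs(np.fft.rfft(env)) ** 2
    freqs = np.fft.rfftfreq(len(t), 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum() / spec[1:].sum())


class TestAmplitudeModulation:
    def test_alpha_carrier_with_delta_rate_am_peaks_in_mdelta(self):
        ep = epochs_of(am_tone_epoch(10.0, 2.0, depth=0.5, channels=LABELS9))
        values, _ = amplitude_modulation_features(ep, FS, LABELS9, BandScheme())
        alpha = values.filter(like="am-alpha-").filter(like="-F3").iloc[0]
        assert alpha.idxmax() == "am-alpha-mdelta-F3"

    @pytest.mark.parametrize("carrier,mod,pair", [
        (10.0, 2.0, ("alpha", "mdelta")),
        (20.0, 6.0, ("beta", "mtheta")),
        # gamma carrier at 37.5 Hz with 6 Hz AM keeps both sidebands (31.5,
        # 43.5 Hz) inside the 30-45 Hz band; faster AM rates would push a
        # sideband out of band and the filter would strip the modulation
        (37.5, 6.0, ("gamma", "mtheta")),
    ])
    def test_production_path_matches_envelope_fft_oracle(self, carrier, mod, pair):
        """Filter+Hilbert features agree with the known-modulator oracle to 5%."""
        scheme = BandScheme()
        ep = epochs_of(am_tone_epoch(carrier, mod, depth=0.5, channels=LABELS9))
        values, _ = amplitude_modulation_features(ep, FS, LABELS9, scheme)
        got = values.at[0, f"am-{pair[0]}-{pair[1]}-Cz"]
        expected = am_oracle_fraction(mod, 0.5, scheme.mod_bands[pair[1]])
        assert got == pytest.approx(expected, rel=0.05)

    def test_default_scheme_emits_126_names(self, noise_epoch_set):
        values, _ = amplitude_modulation_features(noise_epoch_set.epochs, FS,
                                                  LABELS9, BandScheme())
        assert values.shape[1] == 126

    def test_unmodulated_noise_spreads_am_energy_for_wide_carriers(self, noise_epoch_set):
        """Wide carriers (beta, gamma) show no dominant modulation band.

        Narrow carriers saturate by construction: a 4-Hz-wide band's intrinsic
        envelope lives almost entirely below 4 Hz, so e.g. delta-mdelta is
        legitimately close to 1 even without modulation.
        """
        values, _ = amplitude_modulation_features(noise_epoch_set.epochs, FS,
                                                  LABELS9, BandScheme())
        wide = values[[c for c in values.columns
                       if c.startswith(("am-beta-", "am-gamma-"))]]
        assert wide.to_numpy().max() <= 0.9
        assert values.to_numpy().max() <= 1.0

    def test_carrier_fractions_sum_to_at_most_one(self, noise_epoch_set):
        values, _ = amplitude_modulation_features(noise_epoch_set.epochs, FS,
                                                  LABELS9, BandScheme())
        for carrier in ("delta", "theta", "alpha", "beta", "gamma"):
            per_channel = sum(
                values[f"am-{carrier}-{m}-Cz"]
                for b, m in BandScheme().am_pairs if b == carrier)
            assert (per_channel <= 1.0 + 1e-9).all()


class TestModulationPatches:
    def test_default_scheme_emits_54_names(self, noise_epoch_set):
        values, _ = modulation_patch_features(noise_epoch_set.epochs, FS,
                                              LABELS9, PatchScheme())
        assert values.shape[1] == 54

    def test_am_tone_inside_custom_r2_dominates(self):
        scheme = PatchScheme(patches={"R1": (0.5, 3.0, 4.0, 10.0),
                                      "R2": (4.0, 8.0, 16.0, 24.0),
                                      "R3": (0.5, 3.0, 30.0, 45.0)})
        ep = epochs_of(am_tone_epoch(20.0, 6.0, depth=0.8, channels=LABELS9))
        values, _ = modulation_patch_features(ep, FS, LABELS9, scheme)
        assert values.at[0, "patch-R2-Cz"] > values.at[0, "patch-R1-Cz"]
        assert values.at[0, "patch-R2oR1-Cz"] > 1.0

    def test_identical_rectangles_give_unit_ratio(self, noise_epoch_set):
        rect = (0.5, 4.0, 8.0, 12.0)
        scheme = PatchScheme(patches={"R1": rect, "R2": (4.0, 8.0, 12.0, 30.0),
                                      "R3": rect})
        values, _ = modulation_patch_features(noise_epoch_set.epochs, FS,
                                              LABELS9, scheme)
        assert np.allclose(values["patch-R1oR3-Cz"], 1.0)

    def test_empty_rectangle_is_configuration_error(self, noise_epoch_set):
        scheme = PatchScheme(patches={"R1": (0.01, 0.02, 8.0, 12.0),
                                      "R2": (4.0, 8.0, 12.0, 30.0),
                                      "R3": (0.5, 4.0, 30.0, 45.0)})
        with pytest.raises(ValueError, match="no grid cells"):
            modulation_patch_features(noise_epoch_set.epochs, FS, LABELS9, scheme)


class TestEpochFeatureVector:
    def test_default_schemes_yield_286_features(self, noise_epoch_set):
        values, valid = epoch_features(noise_epoch_set)
        assert values.shape == (noise_epoch_set.n_epochs, 286)
        assert valid.shape == values.shape
        prefixes = {n.split("-")[0] for n in values.columns}
        assert prefixes == {"pow", "msc", "am", "patch"}

    def test_identical_epochs_give_identical_vectors(self):
        ep = am_tone_epoch(10.0, 2.0, channels=LABELS9)
        v1 = epoch_feature_vector(ep, FS, LABELS9)
        v2 = epoch_feature_vector(ep.copy(), FS, LABELS9)
        pd.testing.assert_series_equal(v1, v2)

    def test_scale_invariance_of_all_families(self, noise_epoch_set):
        values, _ = epoch_features(noise_epoch_set)
        scaled = EpochSet(noise_epoch_set.epochs * 3.7, FS, LABELS9)
        values2, _ = epoch_features(scaled)
        np.testing.assert_allclose(values.to_numpy(), values2.to_numpy(),
                                   rtol=1e-9, atol=1e-12)

    def test_renamed_channels_propagate_to_names(self):
        labels = tuple(f"X{i}" for i in range(len(LABELS9)))
        ep = am_tone_epoch(10.0, 2.0, channels=labels)
        scheme = BandScheme(coherence_pairs=(("X0", "X1"),))
        eset = EpochSet(ep[None], FS, labels)
        values, _ = epoch_features(eset, band_scheme=scheme)
        assert "pow-alpha-X0" in values.columns
        assert values.shape[1] == 81 + 5 + 126 + 54


class TestAggregateFunctionals:
    def test_hand_computed_series(self):
        values = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = aggregate_functionals(values)
        assert out["mean-f"] == pytest.approx(3.0)
        assert out["std-f"] == pytest.approx(1.5811, abs=1e-4)
        assert out["median-f"] == pytest.approx(3.0)
        assert out["skew-f"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_conventions(self):
        values = pd.DataFrame({"f": [2.5] * 10})
        out = aggregate_functionals(values)
        assert out["mean-f"] == 2.5
        assert out["std-f"] == 0.0
        assert out["cv-f"] == 0.0
        assert out["skew-f"] == 0.0
        assert out["kurt-f"] == 0.0

    def test_moment_conventions_match_scipy(self):
        rng = np.random.default_rng(5)
        series = rng.normal(3.0, 2.0, size=50)
        out = aggregate_functionals(pd.DataFrame({"f": series}))
        assert out["skew-f"] == pytest.approx(stats.skew(series, bias=True))
        assert out["kurt-f"] == pytest.approx(
            stats.kurtosis(series, fisher=True, bias=True))
        assert out["cv-f"] == pytest.approx(np.std(series, ddof=1) / series.mean())

    def test_insufficient_valid_epochs_marks_feature_missing(self):
        values = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        valid = pd.DataFrame({"f": [True, True, False, False]})
        out = aggregate_functionals(values, valid)
        assert np.isnan(out["mean-f"]) and np.isnan(out["kurt-f"])

    def test_default_pipeline_yields_1716_subject_features(self, noise_epoch_set):
        values, valid = epoch_features(noise_epoch_set)
        out = aggregate_functionals(values, valid)
        assert len(out) == 6 * 286 == 1716
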