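"""Filtering, re-referencing, epoching, CSD and Morlet phase extraction."""

import numpy as np
import pytest

from thetasync.montage import load_standard_montage
from thetasync.preprocess import (
    EpochSet,
    amplitude_reject,
    bandpass_filter,
    epoch_and_baseline,
    morlet_phase,
    rereference_linked_mastoids,
    surface_laplacian,
    trim_edges,
)

SF = 250.0


def _sine(freq, duration=20.0, sf=SF, phase=0.0):
    t = np.arange(int(duration * sf)) / sf
    return np.cos(2 * np.pi * freq * t + phase)


def _epochs(data, labels):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    return EpochSet(
        data=data, sfreq=SF, labels=tuple(labels),
        retained=np.ones(data.shape[0], bool),
        trial_keys=tuple(("S0", f"E{i}") for i in range(data.shape[0])),
    )


class TestBandpass:
    def test_passband_preserves_6hz(self):
        x = _sine(6.0)
        y = bandpass_filter(x[None, :], SF)
        mid = slice(1000, -1000)
        ratio = np.std(y[0, mid]) / np.std(x[mid])
        assert ratio > 0.95

    def test_stopband_attenuates_60hz(self):
        # oracle: the designed zero-phase response, |H|^2 for forward-backward
        from scipy import signal

        sos = signal.butter(4, [0.1, 45.0], btype="bandpass", fs=SF, output="sos")
        _, h = signal.sosfreqz(sos, worN=[60.0 / (SF / 2) * np.pi])
        assert np.abs(h[0]) ** 2 < 0.1
        x = _sine(60.0)
        y = bandpass_filter(x[None, :], SF)
        mid = slice(1000, -1000)
        assert np.std(y[0, mid]) / np.std(x[mid]) < 0.2

    def test_dc_offset_suppressed(self):
        x = np.full((1, 5000), 37.0)
        y = bandpass_filter(x, SF)
        assert np.abs(y).max() < 1.0

    def test_high_edge_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((1, 1000)), SF, 0.1, 125.0)


class TestRereference:
    def test_channels_equal_to_mastoid_mean_zero_out(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((2, 1000))
        mean = m.mean(axis=0)
        data = np.vstack([mean, mean, m])
        out = rereference_linked_mastoids(data, ("a", "b", "M1", "M2"))
        assert np.allclose(out[:2], 0.0, atol=1e-12)

    def test_idempotent_when_mastoids_retained(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 500))
        labels = ("a", "b", "M1", "M2")
        once = rereference_linked_mastoids(data, labels)
        twice = rereference_linked_mastoids(once, labels)
        assert np.allclose(once, twice, atol=1e-12)

    def test_invariant_to_common_offset(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 500))
        labels = ("a", "b", "M1", "M2")
        out1 = rereference_linked_mastoids(data, labels)
        out2 = rereference_linked_mastoids(data + 42.0, labels)
        assert np.allclose(out1, out2, atol=1e-10)

    def test_missing_mastoid_is_error(self):
        with pytest.raises(KeyError, match="M2"):
            rereference_linked_mastoids(np.zeros((2, 10)), ("a", "M1"))


class TestEpochAndBaseline:
    def test_per_channel_mean_is_zero(self):
        rng = np.random.default_rng(3)
        rec = rng.standard_normal((3, 5000)) + 5.0
        eps = epoch_and_baseline(rec, SF, ("a", "b", "c"),
                                 [("S0", "E0", 100), ("S0", "E1", 2000)], 8.0)
        assert eps.n_epochs == 2
        assert np.allclose(eps.data.mean(axis=-1), 0.0, atol=1e-10)

    def test_constant_channel_becomes_zero(self):
        rec = np.full((1, 3000), 12.5)
        eps = epoch_and_baseline(rec, SF, ("a",), [("S0", "E0", 0)], 4.0)
        assert np.allclose(eps.data, 0.0)

    def test_abutting_events_share_no_samples(self):
        rec = np.arange(4000, dtype=float)[None, :]
        eps = epoch_and_baseline(rec, SF, ("a",),
                                 [("S0", "E0", 0), ("S0", "E1", 1000)], 4.0)
        # recover raw content by undoing the baseline shift
        raw0 = eps.data[0, 0] - eps.data[0, 0, 0]
        raw1 = eps.data[1, 0] - eps.data[1, 0, 0]
        assert np.array_equal(raw0, raw1)          # both are 0..999 ramps

    def test_out_of_bounds_event_named(self):
        rec = np.zeros((1, 1000))
        with pytest.raises(ValueError, match="E9"):
            epoch_and_baseline(rec, SF, ("a",), [("S0", "E9", 500)], 4.0)


class TestAmplitudeReject:
    def test_offset_removed_by_baseline_is_retained(self):
        rec = np.full((1, 3000), 150.0)             # +150 uV offset
        eps = epoch_and_baseline(rec, SF, ("a",), [("S0", "E0", 0)], 4.0)
        out = amplitude_reject(eps, 100.0)
        assert out.retained.all()

    def test_mean_absolute_amplitude_above_threshold_rejected(self):
        data = np.zeros((1, 2, 1000))
        data[0, 1] = 120.0 * np.sign(np.sin(np.arange(1000)))  # mean |x| = 120
        out = amplitude_reject(_epochs(data[0], ("a", "b")), 100.0)
        assert not out.retained.any()

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(4)
        out = amplitude_reject(_epochs(rng.standard_normal((2, 3, 100)) * 500,
                                       ("a", "b", "c")), np.inf)
        assert out.retained.all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        eps = _epochs(rng.standard_normal((6, 3, 200)) * 80, ("a", "b", "c"))
        kept = [amplitude_reject(eps, th).retained.sum() for th in (20, 50, 80, 200)]
        assert kept == sorted(kept)


@pytest.fixture(scope="module")
def csd_setup():
    montage = load_standard_montage()
    labels = tuple(l for l in montage.labels if l not in ("M1", "M2"))[:32]
    return montage.subset(list(labels)), labels


class TestSurfaceLaplacian:
    def test_uniform_potential_maps_to_zero(self, csd_setup):
        montage, labels = csd_setup
        data = np.full((1, len(labels), 100), 25.0)
        out = surface_laplacian(_epochs(data[0], labels), montage)
        assert np.abs(out.data).max() < 1e-6 * 25.0

    def test_reference_free(self, csd_setup):
        montage, labels = csd_setup
        rng = np.random.default_rng(6)
        data = rng.standard_normal((len(labels), 200)) * 20
        out1 = surface_laplacian(_epochs(data, labels), montage)
        out2 = surface_laplacian(_epochs(data + 33.0, labels), montage)
        assert np.allclose(out1.data, out2.data, atol=1e-8)

    def test_focal_pattern_peaks_at_source_with_inverted_surround(self, csd_setup):
        montage, labels = csd_setup
        i_cz = labels.index("Cz")
        data = np.zeros((len(labels), 10))
        data[i_cz] = 50.0
        out = surface_laplacian(_epochs(data, labels), montage)
        vals = out.data[0, :, 0]
        assert np.argmax(vals) == i_cz            # extremum at the source
        # nearest neighbours carry the opposite sign (the spatial annulus)
        dists = np.linalg.norm(montage.positions - montage.position("Cz"), axis=1)
        ring = np.argsort(dists)[1:5]
        assert (vals[ring] < 0).all()

    def test_too_few_channels_rejected(self, csd_setup):
        montage, labels = csd_setup
        few = labels[:8]
        with pytest.raises(ValueError):
            surface_laplacian(_epochs(np.zeros((8, 10)), few), montage.subset(list(few)))

    def test_agrees_with_mne_csd(self, csd_setup):
        """Independent cross-check against MNE's spherical-spline CSD."""
        import mne

        montage, labels = csd_setup
        rng = np.random.default_rng(7)
        data = rng.standard_normal((len(labels), 50)) * 30
        mine = surface_laplacian(_epochs(data, labels), montage).data[0]

        info = mne.create_info(list(labels), SF, "eeg", verbose="error")
        # identical coordinates (meters, head frame) so only the algorithms differ
        dig = mne.channels.make_dig_montage(
            ch_pos={l: montage.position(l) / 100.0 for l in labels},
            coord_frame="head",
        )
        raw = mne.EvokedArray(data * 1e-6, info, verbose="error")
        raw.set_montage(dig, verbose="error")
        csd = mne.preprocessing.compute_current_source_density(
            raw, stiffness=4, lambda2=1e-5, verbose="error"
        ).data
        # same transform up to units/head-radius scaling: near-perfect
        # correlation per time point
        r = np.corrcoef(mine.ravel(), csd.ravel())[0, 1]
        assert r > 0.99


class TestTrimEdges:
    def test_sample_arithmetic(self):
        eps = _epochs(np.zeros((3, int(45 * SF))), ("a", "b", "c"))
        out = trim_edges(eps, 2.0)
        assert out.data.shape[-1] == 10250

    def test_zero_trim_is_identity(self):
        eps = _epochs(np.arange(1000, dtype=float)[None, :], ("a",))
        out = trim_edges(eps, 0.0)
        assert np.array_equal(out.data, eps.data)

    def test_content_is_central_slice(self):
        x = np.arange(2000, dtype=float)
        out = trim_edges(_epochs(x[None, :], ("a",)), 1.0)
        assert np.array_equal(out.data[0, 0], x[250:-250])

    def test_overtrim_rejected(self):
        with pytest.raises(ValueError):
            trim_edges(_epochs(np.zeros((1, 1000)), ("a",)), 2.5)


class TestMorletPhase:
    def test_pure_tone_phase_velocity(self):
        x = _sine(6.0)
        tens = morlet_phase(_epochs(x[None, :], ("a",)), (6.0,))
        ph = np.unwrap(tens.phases[0, 0, 0, tens.valid[0]])
        slope = np.polyfit(np.arange(ph.size) / SF, ph, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6.0, rel=0.01)

    def test_quadrature_pair_constant_half_pi(self):
        c = _sine(6.0)
        s = _sine(6.0, phase=-np.pi / 2)           # sin lags cos by pi/2
        tens = morlet_phase(_epochs(np.vstack([c, s]), ("a", "b")), (6.0,))
        diff = tens.phases[0, 0, 0, tens.valid[0]] - tens.phases[0, 1, 0, tens.valid[0]]
        diff = np.angle(np.exp(1j * diff))
        assert np.allclose(diff, np.pi / 2, atol=0.01)

    def test_phase_scale_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((2, 4000))
        t1 = morlet_phase(_epochs(x, ("a", "b")), (5.0, 6.0))
        t2 = morlet_phase(_epochs(x * 1e3, ("a", "b")), (5.0, 6.0))
        assert np.allclose(t1.phases, t2.phases, atol=1e-9)

    def test_white_noise_phase_circularly_uniform(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((1, int(120 * SF)))
        tens = morlet_phase(_epochs(x, ("a",)), (6.0,))
        ph = tens.phases[0, 0, 0, tens.valid[0]][:: int(SF)]   # ~decorrelated
        n = ph.size
        # Rayleigh test for circular uniformity at alpha = 0.01
        r = np.abs(np.exp(1j * ph).mean())
        p = np.exp(-n * r * r)
        assert p > 0.01

    def test_edge_samples_marked_invalid(self):
        tens = morlet_phase(_epochs(np.zeros((1, 2500)), ("a",)), (4.0, 8.0))
        half_4 = 5.0 / (2 * 4.0)
        assert not tens.valid[0, : int(half_4 * SF) - 1].any()
        assert tens.valid[1].sum() > tens.valid[0].sum()       # shorter wavelet at 8 Hz

    def test_wavelet_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            morlet_phase(_epochs(np.zeros((1, 100)), ("a",)), (4.0,))

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((2, 3000))
        a = morlet_phase(_epochs(x, ("a", "b")), (4.0, 6.0))
        b = morlet_phase(_epochs(x.copy(), ("a", "b")), (4.0, 6.0))
        assert np.array_equal(a.phases, b.phases)
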