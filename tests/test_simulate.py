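"""Coupled-oscillator EEG + behavior generator and its closed-form anchors."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from thetasync.behavior import RatingStream, familiarity_reject, resolve_overlaps, \
    time_weighted_pleasantness
from thetasync.connectivity import ispc_time
from thetasync.preprocess import EpochSet, morlet_phase, trim_edges
from thetasync.simulate import (
    SimulationConfig,
    SimulationTruth,
    generate_dataset,
    kappa_for_target_ispc,
    load_dataset,
    mean_resultant_length,
    read_subject_eeg,
    reduced_config,
    reduced_truth,
    simulate_behavior,
    simulate_epoch,
    uniform_ispc_floor,
)


class TestKappaInversion:
    def test_zero_target_gives_zero_kappa(self):
        assert kappa_for_target_ispc(0.0) == 0.0

    def test_bessel_oracle_at_kappa_two(self):
        # independent oracle: direct Bessel evaluation I1(2)/I0(2)
        r = i1(2.0) / i0(2.0)
        assert kappa_for_target_ispc(r) == pytest.approx(2.0, abs=1e-6)
        assert r == pytest.approx(0.6978, abs=1e-4)

    @pytest.mark.parametrize("r", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    def test_round_trip(self, r):
        assert mean_resultant_length(kappa_for_target_ispc(r)) == pytest.approx(
            r, abs=1e-8
        )

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            kappa_for_target_ispc(1.0)

    @settings(max_examples=30, deadline=None)
    @given(r=st.floats(min_value=0.01, max_value=0.99))
    def test_inverse_is_monotone(self, r):
        assert kappa_for_target_ispc(r + 0.005) > kappa_for_target_ispc(r)

    def test_empirical_von_mises_matches_bessel_ratio(self):
        rng = np.random.default_rng(0)
        n = 10_000
        r_hat = np.abs(np.exp(1j * rng.vonmises(0.0, 2.0, n)).mean())
        assert r_hat == pytest.approx(i1(2) / i0(2), abs=0.01)

    def test_uniform_floor_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        for n in (50, 500):
            vals = [
                np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, n)).mean())
                for _ in range(800)
            ]
            assert np.mean(vals) == pytest.approx(uniform_ispc_floor(n), rel=0.05)


def _tiny_config(**kw):
    base = dict(
        n_subjects=1, n_excerpts_old=1, n_excerpts_new=1,
        epoch_duration_s=12.0,
        channels=("AF4", "FT8", "T8", "CP5", "Fz", "Cz", "Pz", "F3", "F4",
                  "C3", "C4", "P3", "P4", "TP7", "TP8", "FC3", "FC4"),
        coupling_pairs=(("AF4", "FT8"),),
    )
    base.update(kw)
    return SimulationConfig(**base)


def _downstream_ispc(epoch, config, pair):
    labels = tuple(config.channels)
    es = EpochSet(
        data=epoch[None, : len(labels), :], sfreq=config.sampling_rate_hz,
        labels=labels, retained=np.ones(1, bool), trial_keys=(("S0", "E0"),),
    )
    tens = morlet_phase(trim_edges(es, 2.0), (6.0,))
    ia, ib = tens.labels.index(pair[0]), tens.labels.index(pair[1])
    m = tens.valid[0]
    return ispc_time(tens.phases[0, ia, 0, m], tens.phases[0, ib, 0, m])


class TestSimulateEpoch:
    def test_deterministic_lag_gives_near_perfect_ispc(self):
        cfg = _tiny_config(noise_uv=1e-6, mastoid_uv=1e-6)
        truth = SimulationTruth(pair_coefficients={"AF4-FT8": (0.0, 0, 0, 0)})
        ep = simulate_epoch(cfg, truth, 0, 0, 1, 1, kappa_override=np.inf)
        assert _downstream_ispc(ep, cfg, ("AF4", "FT8")) > 0.999

    def test_zero_kappa_lands_near_uniform_floor(self):
        cfg = _tiny_config(noise_uv=1e-6, mastoid_uv=1e-6)
        truth = SimulationTruth(pair_coefficients={"AF4-FT8": (0.0, 0, 0, 0)})
        n_blocks = (cfg.epoch_duration_s - 4.0) / cfg.jitter_block_s
        vals = [
            _downstream_ispc(
                simulate_epoch(cfg, truth, 0, t, 1, 1, kappa_override=0.0),
                cfg, ("AF4", "FT8"),
            )
            for t in range(12)
        ]
        # Monte-Carlo oracle: resultant length of ~n_blocks uniform phases
        rng = np.random.default_rng(2)
        oracle = np.mean([
            np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, int(n_blocks))).mean())
            for _ in range(2000)
        ])
        assert np.mean(vals) == pytest.approx(oracle, abs=0.12)

    def test_planted_coupling_expectation_tracks_bessel_ratio(self):
        # jitter blocks carry von Mises offsets whose resultant matches A(kappa)
        cfg = _tiny_config(noise_uv=1e-6, mastoid_uv=1e-6, epoch_duration_s=49.0)
        truth = SimulationTruth(pair_coefficients={"AF4-FT8": (0.0, 0, 0, 0)})
        kap = kappa_for_target_ispc(0.6)
        vals = [
            _downstream_ispc(
                simulate_epoch(cfg, truth, 0, t, 1, 1, kappa_override=kap),
                cfg, ("AF4", "FT8"),
            )
            for t in range(12)
        ]
        n_blocks = (cfg.epoch_duration_s - 4.0) / cfg.jitter_block_s
        expected = np.sqrt(0.6**2 + (1 - 0.6**2) / n_blocks)   # finite-n resultant
        assert np.mean(vals) == pytest.approx(expected, abs=0.07)

    def test_half_mean_target_recovers_half(self):
        # planted logit^-1(0) = 0.5 with no effects -> mean recovered ISPC ~ 0.5
        cfg = _tiny_config(noise_uv=1e-6, mastoid_uv=1e-6, epoch_duration_s=49.0)
        truth = SimulationTruth(
            pair_coefficients={"AF4-FT8": (0.0, 0.0, 0.0, 0.0)},
            trial_logit_sd=0.0, subject_sd=0.0,
        )
        vals = [
            _downstream_ispc(simulate_epoch(cfg, truth, 0, t, 0, 0), cfg,
                             ("AF4", "FT8"))
            for t in range(12)
        ]
        n_blocks = (cfg.epoch_duration_s - 4.0) / cfg.jitter_block_s
        expected = np.sqrt(0.25 + 0.75 / n_blocks)
        assert np.mean(vals) == pytest.approx(expected, abs=0.07)

    def test_unknown_coupled_channel_rejected(self):
        with pytest.raises(ValueError, match="Oz"):
            _tiny_config(coupling_pairs=(("AF4", "Oz"),))

    def test_amplitudes_physiological(self):
        cfg = _tiny_config()
        truth = reduced_truth()
        ep = simulate_epoch(cfg, truth, 0, 0, 1, 1)
        rms = ep[: len(cfg.channels)].std(axis=1)
        assert (rms > 1.0).all() and (rms < 80.0).all()

    def test_artifact_trial_exceeds_rejection_threshold(self):
        cfg = _tiny_config()
        ep = simulate_epoch(cfg, reduced_truth(), 0, 0, 1, 1, artifact=True)
        centered = ep - ep.mean(axis=1, keepdims=True)
        assert np.abs(centered).mean(axis=1).max() > 100.0


class TestNullPairDistribution:
    def test_uncoupled_pair_matches_uniform_phase_null(self):
        """Per-trial ISPC of an uncoupled pair follows the resultant-length
        distribution of one uniform draw per jitter block (KS at alpha 0.01).

        Single-oscillator configuration: with one synthesized frequency the
        phase difference is exactly the block-uniform process; with several,
        inter-component beating adds extra (unmodelled) decoherence.
        """
        from scipy.stats import ks_2samp

        cfg = _tiny_config(noise_uv=1e-6, mastoid_uv=1e-6, epoch_duration_s=49.0,
                           synth_freqs_hz=(6.0,))
        truth = SimulationTruth(pair_coefficients={"AF4-FT8": (0.0, 0, 0, 0)})
        observed = [
            _downstream_ispc(simulate_epoch(cfg, truth, 0, t, 0, 0), cfg,
                             ("Fz", "Pz"))                   # uncoupled channels
            for t in range(40)
        ]
        n_blocks = int((cfg.epoch_duration_s - 4.0) / cfg.jitter_block_s)
        rng = np.random.default_rng(30)
        oracle = [
            np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, n_blocks)).mean())
            for _ in range(4000)
        ]
        assert ks_2samp(observed, oracle).pvalue > 0.01


class TestSimulateBehavior:
    @pytest.fixture(scope="class")
    def behavior(self):
        cfg = dataclasses.replace(reduced_config(), n_subjects=8,
                                  n_excerpts_old=15, n_excerpts_new=15)
        return cfg, simulate_behavior(cfg, reduced_truth())

    def test_streams_are_valid_rating_streams(self, behavior):
        cfg, beh = behavior
        for (subj, exc), grp in beh.segments.groupby(["subject", "excerpt_id"]):
            RatingStream(
                excerpt_id=str(exc),
                segments=resolve_overlaps(
                    list(zip(grp["key"], grp["onset_s"], grp["offset_s"])),
                    cfg.epoch_duration_s,
                ),
                trial_duration_s=cfg.epoch_duration_s,
            )

    def test_old_pleasantness_exceeds_new(self, behavior):
        cfg, beh = behavior
        indices = {"old": [], "new": []}
        for _, row in beh.conditions.iterrows():
            grp = beh.segments[
                (beh.segments["subject"] == row["subject"])
                & (beh.segments["excerpt_id"] == row["excerpt_id"])
            ]
            stream = RatingStream(
                row["excerpt_id"],
                resolve_overlaps(
                    list(zip(grp["key"], grp["onset_s"], grp["offset_s"])),
                    cfg.epoch_duration_s,
                ),
                cfg.epoch_duration_s,
            )
            idx = time_weighted_pleasantness(stream)
            if idx is not None:
                indices[row["familiarity_condition"]].append(idx)
        assert np.mean(indices["old"]) > np.mean(indices["new"])

    def test_contamination_fraction_recovered_by_rejection(self, behavior):
        cfg, beh = behavior
        expe = beh.experimental_ratings.merge(
            beh.conditions[["subject", "excerpt_id", "familiarity_condition"]],
            on=["subject", "excerpt_id"],
        ).rename(columns={})
        excluded = familiarity_reject(beh.exposure_ratings, expe)
        n_excluded = sum(len(v) for v in excluded.values())
        n_total = len(beh.conditions)
        planted = beh.conditions["contaminated"].mean()
        assert n_excluded / n_total == pytest.approx(planted, abs=0.08)

    def test_halted_trials_match_flag(self, behavior):
        cfg, beh = behavior
        for _, row in beh.conditions[beh.conditions["halted"]].iterrows():
            grp = beh.segments[
                (beh.segments["subject"] == row["subject"])
                & (beh.segments["excerpt_id"] == row["excerpt_id"])
            ]
            assert grp["onset_s"].min() >= cfg.epoch_duration_s / 2


class TestGenerateDataset:
    def test_reproducible_byte_identical(self, tmp_path):
        cfg = _tiny_config(n_subjects=1, n_excerpts_old=1, n_excerpts_new=1)
        truth = reduced_truth()
        d1 = generate_dataset(cfg, truth, tmp_path / "a")
        d2 = generate_dataset(cfg, truth, tmp_path / "b")
        assert (d1 / "truth.json").read_bytes() == (d2 / "truth.json").read_bytes()
        e1, _, _, _, _ = load_dataset(d1)
        e2, _, _, _, _ = load_dataset(d2)
        assert e1.equals(e2)
        r1, _, _ = read_subject_eeg(d1, "S00")
        r2, _, _ = read_subject_eeg(d2, "S00")
        assert np.array_equal(r1, r2)

    def test_truth_file_holds_all_planted_parameters(self, tmp_path):
        cfg = _tiny_config()
        truth = reduced_truth()
        out = generate_dataset(cfg, truth, tmp_path / "d")
        loaded = json.loads((out / "truth.json").read_text())
        assert loaded["pair_coefficients"]["AF4-FT8"][3] == truth.pair_coefficients[
            "AF4-FT8"
        ][3]
        assert loaded["seed"] == truth.seed

    def test_default_counts_sixty_excerpts_half_old(self):
        cfg = SimulationConfig()
        assert len(cfg.excerpt_ids) == 60
        assert cfg.n_excerpts_old == 30 and cfg.n_subjects == 21

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth(pair_coefficients={"A-B": (np.inf, 0, 0, 0)})
        with pytest.raises(ValueError):
            SimulationTruth(ordinal_thresholds=(2.0, 1.0, 3.0, 4.0, 5.0, 6.0))
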