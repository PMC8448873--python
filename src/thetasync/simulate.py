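"""Synthetic multi-subject EEG + behavior with planted theta coupling.

The generator emulates the structure the analysis assumes so that every
pipeline stage can be verified by parameter recovery:

* Each subject contributes ``n_excerpts_old + n_excerpts_new`` listening
  trials.  Per trial, a planted binary pleasantness class ("least"/"most")
  and the familiarity condition ("old"/"new") set the strength of theta
  phase coupling at designated electrode pairs through a logit-linear
  model:  target ISPC = logistic(b0 + b1*most + b2*old + b3*most*old +
  subject deviation + trial noise).
* A coupled pair carries a shared 6 Hz oscillation; the second electrode
  adds a phase offset drawn from a von Mises(kappa) distribution, with
  kappa inverted from the Bessel-ratio identity E[ISPC] = I1(k)/I0(k) so
  the planted target is attainable.  The offset is piecewise-constant in
  blocks longer than the 5-cycle Morlet wavelet, so the planted phase
  statistics survive the time-frequency smoothing of the real pipeline.
  Uncoupled channels oscillate with independent phases; all channels ride
  on 1/f background noise in a physiological microvolt range.
* Behavioral streams are piecewise-constant key holds in 1..5 whose
  time-weighted mean separates the planted classes; familiarity ratings
  come from a cumulative-probit generative model with planted condition
  shifts in latent-SD units.  A configurable fraction of excerpts is
  "contaminated" (genuinely familiar: exposure ratings above the rejection
  cutoff), some trials halt (first key press after half the excerpt) and
  some carry large-amplitude artifacts, emulating the rejection routes of
  a real session.

Everything is reproducible from (config, truth, seed): each subject/trial
gets an independent counter-based random stream.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, i0e, i1e

from .montage import ROI_45, SCALP_61

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedBehavior",
    "mean_resultant_length",
    "kappa_for_target_ispc",
    "uniform_ispc_floor",
    "simulate_epoch",
    "simulate_behavior",
    "generate_dataset",
    "load_dataset",
    "reduced_config",
    "reduced_truth",
]

#: Channel subset for reduced-scale runs (>= 16 channels for the spherical
#: spline, includes the electrodes of the four reported connections).
REDUCED_CHANNELS: tuple[str, ...] = (
    "AF3", "AF4", "Fz", "F3", "F4", "F7", "F8", "FCz", "FC3", "FC4",
    "FT7", "FT8", "Cz", "C3", "C4", "T7", "T8", "CPz", "CP1", "CP2",
    "CP5", "CP6", "TP7", "TP8", "Pz", "P3", "P4", "PO3", "PO4",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shape parameters (sizes, rates, channels, noise model)."""

    n_subjects: int = 21
    n_excerpts_old: int = 30
    n_excerpts_new: int = 30
    epoch_duration_s: float = 45.0
    sampling_rate_hz: float = 250.0
    channels: tuple[str, ...] = SCALP_61
    coupling_pairs: tuple[tuple[str, str], ...] = (("AF4", "FT8"), ("T8", "CP5"))
    oscillator_freq_hz: float = 6.0      # center frequency (metadata)
    synth_freqs_hz: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0)
    jitter_block_s: float = 1.5          # von Mises offset held constant per block
    noise_exponent: float = 1.0          # 1/f^a power spectrum
    noise_uv: float = 5.0                # background RMS
    osc_uv: float = 10.0                 # theta-band oscillation RMS (all components)
    coupling_gain: float = 2.5           # amplitude gain of coupled sources; keeps
                                         # their local phase dominant through the
                                         # spatial-derivative (CSD) transform
    mastoid_uv: float = 2.0
    gap_s: float = 1.0                   # silence between epochs in the recording
    halt_prob: float = 0.02
    artifact_prob: float = 0.05
    contamination_frac: float = 0.08     # excerpts genuinely familiar at exposure

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 2 * max(self.synth_freqs_hz):
            raise ValueError("sampling rate below Nyquist for the oscillators")
        if self.epoch_duration_s <= 0 or self.jitter_block_s <= 0:
            raise ValueError("durations must be positive")
        for a, b in self.coupling_pairs:
            for ch in (a, b):
                if ch not in self.channels:
                    raise ValueError(f"coupled channel {ch!r} absent from config channels")

    @property
    def excerpt_ids(self) -> tuple[str, ...]:
        n = self.n_excerpts_old + self.n_excerpts_new
        return tuple(f"E{i:03d}" for i in range(n))

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i:02d}" for i in range(self.n_subjects))


@dataclass(frozen=True)
class SimulationTruth:
    """Planted generative parameters (the ground-truth file's content)."""

    # logit-scale coefficients per coupled pair: (b0, b1 most, b2 old, b3 interaction)
    pair_coefficients: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "AF4-FT8": (-0.85, 0.05, 0.0, 0.15),
            "T8-CP5": (-0.85, 0.0, 0.0, 0.15),
        }
    )
    subject_sd: float = 0.2              # sd of subject intercept deviations (logit)
    trial_logit_sd: float = 0.3          # extra trial-level dispersion (logit);
                                         # plays the role of finite beta precision
    pair_lag_rad: float = np.pi / 4      # mean phase lag of coupled pairs
    # behavioral generative parameters
    ordinal_thresholds: tuple[float, ...] = (0.8, 1.7, 2.9, 3.8, 4.6, 5.4)
    familiarity_old_shift: float = 2.34  # latent-SD shift of old vs exposure/new
    contaminated_shift: float = 3.2      # latent shift of genuinely familiar excerpts
    pleasantness_base: float = 2.4       # mean key, "least" class, new condition
    pleasantness_class_gap: float = 1.2  # "most" minus "least" mean key
    pleasantness_old_shift: float = 0.12 # old minus new mean pleasantness
    pleasantness_subject_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, coefs in self.pair_coefficients.items():
            if not all(np.isfinite(coefs)):
                raise ValueError(f"non-finite coefficients for pair {pair}")
            # every condition-cell target must stay strictly inside (0, 1)
            b0, b1, b2, b3 = coefs
            for most in (0, 1):
                for old in (0, 1):
                    eta = b0 + b1 * most + b2 * old + b3 * most * old
                    if not 0.0 < expit(eta) < 1.0:
                        raise ValueError(f"target ISPC for {pair} not inside (0,1)")
        if list(self.ordinal_thresholds) != sorted(self.ordinal_thresholds):
            raise ValueError("ordinal thresholds must be increasing")

    def to_json(self) -> str:
        d = asdict(self)
        d["pair_coefficients"] = {k: list(v) for k, v in d["pair_coefficients"].items()}
        d["ordinal_thresholds"] = list(d["ordinal_thresholds"])
        return json.dumps(d, indent=2, sort_keys=True)


def reduced_config(seed_channels: tuple[str, ...] = REDUCED_CHANNELS) -> SimulationConfig:
    """Desk-scale study conditions: 6 subjects x 20 excerpts, 30 s epochs.

    The 30 s epoch keeps enough independent coupling-jitter blocks per trial
    (about 17 after edge trimming) that per-trial ISPC estimates carry only
    mild finite-sample bias, while staying cheaper than the full 45 s
    listening epochs.
    """
    return SimulationConfig(
        n_subjects=6,
        n_excerpts_old=10,
        n_excerpts_new=10,
        epoch_duration_s=30.0,
        channels=seed_channels,
        coupling_pairs=(("AF4", "FT8"), ("T8", "CP5")),
    )


def reduced_truth(beta3: float = 2.0) -> SimulationTruth:
    """Planted effects sized for detectability at the reduced scale.

    At 6 subjects x 20 excerpts the posterior for the interaction carries a
    ~0.4-0.5 log-odds credible half-width, and the measurement chain
    (finite jitter blocks, wavelet estimation noise, the spatial-derivative
    transform) attenuates planted log-odds differences; a 2.0 log-odds
    interaction (coupled-pair ISPC rising from ~0.3 to ~0.8 between
    conditions) is the regime this scaled-down fixture probes.
    """
    return SimulationTruth(
        pair_coefficients={
            "AF4-FT8": (-0.85, 0.1, 0.1, beta3),
            "T8-CP5": (-0.85, 0.1, 0.1, beta3),
        }
    )


# ---------------------------------------------------------------------------
# von Mises coupling primitives

def mean_resultant_length(kappa: float | np.ndarray) -> float | np.ndarray:
    """Expected resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    k = np.asarray(kappa, dtype=float)
    out = np.where(k > 0, i1e(k) / np.where(k > 0, i0e(k), 1.0), 0.0)
    return float(out) if np.isscalar(kappa) or out.ndim == 0 else out


def kappa_for_target_ispc(r: float, tol: float = 1e-10) -> float:
    """Invert A(kappa) = r by monotone root finding (accurate to ~1e-8)."""
    if not 0.0 <= r < 1.0:
        raise ValueError(f"target ISPC must lie in [0, 1); got {r}")
    if r == 0.0:
        return 0.0
    hi = 2.0
    while mean_resultant_length(hi) < r:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - r this close to 1 is rejected above
            raise ValueError("target ISPC too close to 1")
    return float(brentq(lambda k: mean_resultant_length(k) - r, 1e-12, hi, xtol=tol))


def uniform_ispc_floor(n: int) -> float:
    """E[resultant length] of n independent uniform phases: sqrt(pi)/(2 sqrt(n))."""
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n)))


# ---------------------------------------------------------------------------
# EEG synthesis

def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      sfreq: float, exponent: float, rms_uv: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x_rms = x.std(axis=1, keepdims=True)
    x_rms[x_rms == 0] = 1.0
    return x / x_rms * rms_uv


def _block_constant(rng_draws: np.ndarray, block_len: int, n_samples: int) -> np.ndarray:
    return np.repeat(rng_draws, block_len)[:n_samples]


def _trial_rng(seed: int, subject_idx: int, trial_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, subject_idx, trial_idx, stream])


def target_ispc(truth: SimulationTruth, pair: str, most: int, old: int,
                subject_dev: float, trial_noise: float) -> float:
    b0, b1, b2, b3 = truth.pair_coefficients[pair]
    return float(expit(b0 + b1 * most + b2 * old + b3 * most * old
                       + subject_dev + trial_noise))


def simulate_epoch(
    config: SimulationConfig,
    truth: SimulationTruth,
    subject_idx: int,
    trial_idx: int,
    most: int,
    old: int,
    subject_devs: dict[str, float] | None = None,
    artifact: bool = False,
    kappa_override: float | None = None,
) -> np.ndarray:
    """One trial's (n_channels + 2 mastoids) x n_samples array in uV."""
    sf = config.sampling_rate_hz
    n = int(round(config.epoch_duration_s * sf))
    rng = _trial_rng(truth.seed, subject_idx, trial_idx, 0)
    labels = list(config.channels) + ["M1", "M2"]
    n_ch = len(labels)
    data = _one_over_f_noise(rng, n_ch, n, sf, config.noise_exponent, config.noise_uv)
    data[-2:] *= config.mastoid_uv / config.noise_uv

    t = np.arange(n) / sf
    freqs = np.asarray(config.synth_freqs_hz, dtype=float)
    # oscillation power is spread over the synthesized band so the
    # band-averaged ISPC carries the planted coupling at every frequency
    amp = config.osc_uv * np.sqrt(2.0 / len(freqs))
    walk_sd = 0.02 / np.sqrt(sf)         # slow common phase drift (rad/sample)
    block_len = max(1, int(round(config.jitter_block_s * sf)))
    n_blocks = int(np.ceil(n / block_len))
    subject_devs = subject_devs or {}

    coupled = {ch for pair in config.coupling_pairs for ch in pair}
    for a, b in config.coupling_pairs:
        pair_name = f"{a}-{b}"
        if kappa_override is None:
            r = target_ispc(
                truth, pair_name, most, old,
                subject_devs.get(pair_name, 0.0),
                float(rng.normal(0.0, truth.trial_logit_sd)),
            )
            kappa = kappa_for_target_ispc(r)
        else:
            kappa = kappa_override
        # one phase-offset process per pair, shared by all band components
        if np.isinf(kappa):
            offsets = np.zeros(n_blocks)
        elif kappa == 0.0:
            offsets = rng.uniform(-np.pi, np.pi, n_blocks)
        else:
            offsets = rng.vonmises(0.0, kappa, n_blocks)
        delta = truth.pair_lag_rad + _block_constant(offsets, block_len, n)
        ia, ib = labels.index(a), labels.index(b)
        gain = config.coupling_gain
        for f in freqs:
            common = 2 * np.pi * f * t + rng.uniform(0, 2 * np.pi) \
                + np.cumsum(rng.normal(0.0, walk_sd, n))
            data[ia] += gain * amp * np.cos(common)
            data[ib] += gain * amp * np.cos(common + delta)

    for ch in config.channels:
        if ch in coupled:
            continue
        # block-wise uniform offsets: any pair involving this channel has
        # i.i.d.-uniform phase differences per block (the kappa = 0 null).
        # Each band component keeps its own independent phase; with several
        # components the inter-component beating decoheres null pairs a
        # little beyond the pure block-uniform law, which holds exactly in
        # single-frequency configurations.
        u_blocks = _block_constant(rng.uniform(-np.pi, np.pi, n_blocks), block_len, n)
        idx = labels.index(ch)
        for f in freqs:
            phase = 2 * np.pi * f * t + rng.uniform(0, 2 * np.pi) \
                + np.cumsum(rng.normal(0.0, walk_sd, n)) + u_blocks
            data[idx] += amp * np.cos(phase)

    if artifact:
        ch = int(rng.integers(0, len(config.channels)))
        # large slow drift whose mean absolute amplitude survives baselining
        data[ch] += 400.0 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    return data


# ---------------------------------------------------------------------------
# behavior synthesis

@dataclass(frozen=True)
class SimulatedBehavior:
    """Planted per-trial assignments plus generated ratings and streams."""

    conditions: pd.DataFrame       # subject, excerpt_id, familiarity_condition,
                                   # planted_class, halted, artifact, contaminated
    segments: pd.DataFrame         # subject, excerpt_id, key, onset_s, offset_s
    exposure_ratings: pd.DataFrame # subject, excerpt_id, session, rating
    experimental_ratings: pd.DataFrame


def _ordinal_rating(latent: float, thresholds: tuple[float, ...]) -> int:
    return int(np.searchsorted(np.asarray(thresholds), latent) + 1)


def simulate_behavior(config: SimulationConfig, truth: SimulationTruth) -> SimulatedBehavior:
    """Rating streams and familiarity ratings for every subject x excerpt."""
    rng = np.random.default_rng([truth.seed & 0x7FFFFFFF, 999_983])
    excerpts = config.excerpt_ids
    n_old = config.n_excerpts_old
    cond_rows, seg_rows, expo_rows, exp_rows = [], [], [], []
    dur = config.epoch_duration_s
    n_contam = int(round(config.contamination_frac * len(excerpts)))

    for si, subj in enumerate(config.subject_ids):
        srng = _trial_rng(truth.seed, si, 10_000, 1)
        subj_pleas = srng.normal(0.0, truth.pleasantness_subject_sd)
        subj_famil = srng.normal(0.0, 0.3)
        contaminated = set(srng.choice(len(excerpts), size=n_contam, replace=False).tolist())
        # planted class: balanced within each familiarity condition
        classes = {}
        for block in (range(n_old), range(n_old, len(excerpts))):
            block = list(block)
            half = len(block) // 2
            most_ids = set(srng.permutation(block)[:half].tolist())
            for e in block:
                classes[e] = 1 if e in most_ids else 0

        for ei, exc in enumerate(excerpts):
            trng = _trial_rng(truth.seed, si, ei, 2)
            old = 1 if ei < n_old else 0
            most = classes[ei]
            halted = bool(trng.uniform() < config.halt_prob)
            artifact = bool(trng.uniform() < config.artifact_prob)
            is_contam = ei in contaminated

            # --- familiarity ratings (cumulative probit generative model)
            shift = truth.contaminated_shift if is_contam else 0.0
            if old:
                lat = subj_famil + shift + trng.normal()
                expo_rows.append((subj, exc, "exposure",
                                  _ordinal_rating(lat, truth.ordinal_thresholds)))
                lat = subj_famil + shift + truth.familiarity_old_shift + trng.normal()
                exp_rows.append((subj, exc, "experimental",
                                 _ordinal_rating(lat, truth.ordinal_thresholds)))
            else:
                lat = subj_famil + shift + trng.normal()
                exp_rows.append((subj, exc, "experimental",
                                 _ordinal_rating(lat, truth.ordinal_thresholds)))

            # --- continuous pleasantness stream
            mean_key = (truth.pleasantness_base + subj_pleas
                        + truth.pleasantness_class_gap * most
                        + truth.pleasantness_old_shift * old)
            n_seg = int(trng.integers(1, 4))
            if halted:
                onset = float(trng.uniform(dur / 2, dur - 1.0))
            else:
                onset = float(trng.uniform(0.5, min(4.0, dur / 2 - 0.5)))
            bounds = np.sort(trng.uniform(onset + 0.5, dur, n_seg - 1)) if n_seg > 1 else []
            edges = [onset, *bounds, dur]
            for k in range(n_seg):
                key = int(np.clip(round(mean_key + trng.normal(0.0, 0.4)), 1, 5))
                if edges[k + 1] - edges[k] > 0.25:
                    seg_rows.append((subj, exc, key, round(edges[k], 3),
                                     round(edges[k + 1], 3)))
            cond_rows.append((subj, exc, "old" if old else "new",
                              "most" if most else "least", halted, artifact, is_contam))

    return SimulatedBehavior(
        conditions=pd.DataFrame(
            cond_rows,
            columns=["subject", "excerpt_id", "familiarity_condition",
                     "planted_class", "halted", "artifact", "contaminated"],
        ),
        segments=pd.DataFrame(
            seg_rows, columns=["subject", "excerpt_id", "key", "onset_s", "offset_s"]
        ),
        exposure_ratings=pd.DataFrame(
            expo_rows, columns=["subject", "excerpt_id", "session", "rating"]
        ),
        experimental_ratings=pd.DataFrame(
            exp_rows, columns=["subject", "excerpt_id", "session", "rating"]
        ),
    )


# ---------------------------------------------------------------------------
# dataset assembly

def _subject_deviations(truth: SimulationTruth, si: int) -> dict[str, float]:
    srng = _trial_rng(truth.seed, si, 20_000, 3)
    return {p: float(srng.normal(0.0, truth.subject_sd))
            for p in truth.pair_coefficients}


def generate_dataset(
    config: SimulationConfig,
    truth: SimulationTruth,
    out_dir: str | Path,
) -> Path:
    """Write the full on-disk dataset (EEG container, TSVs, truth file).

    Layout under ``out_dir``::

        eeg.h5            one HDF5 group per subject: continuous channels x
                          samples float32 array, attrs sfreq / labels
        events.tsv        subject  excerpt_id  onset_sample  session  condition
        segments.tsv      key-hold segments of the experimental session
        familiarity.tsv   subject  excerpt_id  session  rating
        truth.json        every planted parameter
        config.json       the generating configuration

    A failed write removes the partially written directory.
    """
    import h5py

    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        behavior = simulate_behavior(config, truth)
        sf = config.sampling_rate_hz
        n_epoch = int(round(config.epoch_duration_s * sf))
        n_gap = int(round(config.gap_s * sf))
        labels = list(config.channels) + ["M1", "M2"]
        event_rows = []
        with h5py.File(out / "eeg.h5", "w") as h5:
            h5.attrs["sfreq"] = sf
            h5.attrs["labels"] = labels
            for si, subj in enumerate(config.subject_ids):
                sub_cond = behavior.conditions[behavior.conditions["subject"] == subj]
                devs = _subject_deviations(truth, si)
                n_trials = len(sub_cond)
                total = n_trials * (n_epoch + n_gap)
                rec = np.zeros((len(labels), total), dtype=np.float32)
                for ti, (_, row) in enumerate(sub_cond.iterrows()):
                    onset = ti * (n_epoch + n_gap)
                    epoch = simulate_epoch(
                        config, truth, si, ti,
                        most=1 if row["planted_class"] == "most" else 0,
                        old=1 if row["familiarity_condition"] == "old" else 0,
                        subject_devs=devs,
                        artifact=bool(row["artifact"]),
                    )
                    rec[:, onset : onset + n_epoch] = epoch.astype(np.float32)
                    event_rows.append((subj, row["excerpt_id"], onset,
                                       "experimental", row["familiarity_condition"]))
                h5.create_dataset(subj, data=rec, compression="lzf")
        events = pd.DataFrame(
            event_rows,
            columns=["subject", "excerpt_id", "onset_sample", "session", "condition"],
        )
        events.to_csv(out / "events.tsv", sep="\t", index=False)
        behavior.segments.to_csv(out / "segments.tsv", sep="\t", index=False)
        famil = pd.concat([behavior.exposure_ratings, behavior.experimental_ratings])
        famil.to_csv(out / "familiarity.tsv", sep="\t", index=False)
        behavior.conditions.to_csv(out / "conditions.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(truth.to_json())
        cfg = asdict(config)
        cfg["channels"] = list(cfg["channels"])
        cfg["coupling_pairs"] = [list(p) for p in cfg["coupling_pairs"]]
        (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:  # pragma: no cover - only when writing into a pre-existing dir
            for name in ("eeg.h5", "events.tsv", "segments.tsv", "familiarity.tsv",
                         "conditions.tsv", "truth.json", "config.json"):
                (out / name).unlink(missing_ok=True)
        raise
    return out


def load_dataset(path: str | Path):
    """Read back (events, segments, familiarity, conditions, config dict)."""
    p = Path(path)
    events = pd.read_csv(p / "events.tsv", sep="\t", dtype={"subject": str, "excerpt_id": str})
    segments = pd.read_csv(p / "segments.tsv", sep="\t",
                           dtype={"subject": str, "excerpt_id": str})
    famil = pd.read_csv(p / "familiarity.tsv", sep="\t",
                        dtype={"subject": str, "excerpt_id": str})
    conditions = pd.read_csv(p / "conditions.tsv", sep="\t",
                             dtype={"subject": str, "excerpt_id": str})
    config = json.loads((p / "config.json").read_text())
    return events, segments, famil, conditions, config


def read_subject_eeg(path: str | Path, subject: str) -> tuple[np.ndarray, float, list[str]]:
    """One subject's continuous recording from the HDF5 container."""
    import h5py

    with h5py.File(Path(path) / "eeg.h5", "r") as h5:
        data = np.asarray(h5[subject], dtype=float)
        sf = float(h5.attrs["sfreq"])
        labels = [str(l) for l in h5.attrs["labels"]]
    return data, sf, labels
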