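"""Resumable orchestration: simulate -> preprocess -> connect -> fit -> report.

One YAML config drives every stage; each stage writes its outputs plus a
manifest (parameter hash, input checksums, package version) into the run
directory, and a rerun with an unchanged config skips stages whose
manifests still match.  Budget tiers resolve the tension between the
study-scale sampling budget and desk-scale hardware: "full" mirrors the
study's sampler settings, "desk" and "smoke" shrink steps and sizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import SamplerConfig, mass_univariate
from .bayes.inference import DECISION_UNCONVERGED, fit_ordinal_familiarity, \
    fit_student_t_pleasantness
from .behavior import RatingStream, assemble_trial_table, read_trial_table, \
    resolve_overlaps, write_trial_table
from .connectivity import build_connectivity_table, read_connectivity_table, \
    write_connectivity_table
from .montage import candidate_pairs, load_standard_montage, PairSet
from .preprocess import EpochSet, amplitude_reject, bandpass_filter, \
    epoch_and_baseline, morlet_phase, rereference_linked_mastoids, \
    surface_laplacian, trim_edges
from .simulate import SimulationConfig, SimulationTruth, generate_dataset, \
    load_dataset, read_subject_eeg, reduced_config, reduced_truth

__all__ = ["RunConfig", "run", "validate_config", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "connect", "fit", "report")

from .bayes.sampler import DESK, FULL, SMOKE

_TIERS = {"smoke": SMOKE, "desk": DESK, "full": FULL}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, serializable to YAML."""

    out_dir: str = "runs/demo"
    seed: int = 0
    tier: str = "smoke"
    stages: tuple[str, ...] = STAGES
    # simulation block (None fields fall back to the reduced defaults)
    simulation: SimulationConfig = field(default_factory=reduced_config)
    truth: SimulationTruth = field(default_factory=reduced_truth)
    # preprocess block
    band_low_hz: float = 0.1
    band_high_hz: float = 45.0
    reject_threshold_uv: float = 100.0
    trim_s: float = 2.0
    theta_freqs_hz: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0)
    n_cycles: float = 5.0
    spline_order: int = 4
    n_legendre_terms: int = 50
    regularization: float = 1e-5
    head_radius_cm: float = 9.2
    # connectivity block
    min_distance_cm: float = 6.0
    pairs: tuple[str, ...] | None = None   # "A-B" strings; None -> ROI rules
    max_pairs: int | None = None
    # stats block
    rope_halfwidth: float = 0.01
    familiarity_cutoff: int = 2

    def sampler(self) -> SamplerConfig:
        return _TIERS[self.tier].with_seed(self.seed)

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"]["channels"] = list(d["simulation"]["channels"])
        d["simulation"]["coupling_pairs"] = [
            list(p) for p in d["simulation"]["coupling_pairs"]
        ]
        d["truth"]["pair_coefficients"] = {
            k: list(v) for k, v in d["truth"]["pair_coefficients"].items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulation", {})
        sim["channels"] = tuple(sim.get("channels", []))
        sim["coupling_pairs"] = tuple(tuple(p) for p in sim.get("coupling_pairs", []))
        if "synth_freqs_hz" in sim:
            sim["synth_freqs_hz"] = tuple(sim["synth_freqs_hz"])
        tru = d.pop("truth", {})
        tru["pair_coefficients"] = {
            k: tuple(v) for k, v in tru.get("pair_coefficients", {}).items()
        }
        tru["ordinal_thresholds"] = tuple(tru.get("ordinal_thresholds", ()))
        d["simulation"] = SimulationConfig(**sim)
        d["truth"] = SimulationTruth(**tru)
        for key in ("stages", "theta_freqs_hz"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("pairs") is not None:
            d["pairs"] = tuple(d["pairs"])
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns a list of human-readable issues."""
    issues: list[str] = []
    if config.tier not in _TIERS:
        issues.append(f"unknown tier {config.tier!r}; expected one of {sorted(_TIERS)}")
    for s in config.stages:
        if s not in STAGES:
            issues.append(f"unknown stage {s!r}")
    if 2 * config.trim_s >= config.simulation.epoch_duration_s:
        issues.append(
            f"trim_s={config.trim_s} removed twice exceeds the "
            f"{config.simulation.epoch_duration_s} s epoch"
        )
    nyq = config.simulation.sampling_rate_hz / 2
    if config.band_high_hz >= nyq:
        issues.append(f"band_high_hz={config.band_high_hz} at or above Nyquist {nyq}")
    if not set(f"{a}-{b}" for a, b in config.simulation.coupling_pairs) <= \
            set(config.truth.pair_coefficients):
        issues.append("coupling pair without planted coefficients in truth")
    for a, b in config.simulation.coupling_pairs:
        for ch in (a, b):
            if ch not in config.simulation.channels:
                issues.append(f"coupled electrode {ch!r} not in the simulated channel set")
    if config.pairs is not None:
        chans = set(config.simulation.channels)
        for p in config.pairs:
            for ch in p.split("-"):
                if ch not in chans:
                    issues.append(f"analysis pair {p!r} uses unknown electrode {ch!r}")
    if not 1 <= config.familiarity_cutoff <= 7:
        issues.append("familiarity_cutoff must lie in 1..7")
    if len(config.simulation.channels) < 16:
        issues.append("fewer than 16 channels: surface Laplacian ill-conditioned")
    return issues


# ---------------------------------------------------------------------------
# manifests

def _params_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest_path(run_dir: Path, stage: str) -> Path:
    return run_dir / f"manifest_{stage}.json"


def _stage_current(run_dir: Path, stage: str, params_hash: str) -> bool:
    mp = _manifest_path(run_dir, stage)
    if not mp.exists():
        return False
    try:
        m = json.loads(mp.read_text())
    except json.JSONDecodeError:
        return False
    if m.get("params_hash") != params_hash:
        return False
    return all((run_dir / out).exists() for out in m.get("outputs", []))


def _write_manifest(run_dir: Path, stage: str, params_hash: str,
                    outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "params_hash": params_hash,
        "outputs": outputs,
        "checksums": {o: _file_checksum(run_dir / o)
                      for o in outputs if (run_dir / o).is_file()},
        "version": __version__,
    }
    _manifest_path(run_dir, stage).write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: RunConfig, run_dir: Path) -> None:
    generate_dataset(config.simulation, config.truth, run_dir / "dataset")


def _stage_preprocess(config: RunConfig, run_dir: Path) -> None:
    """Behavioral trial table + per-subject theta phase tensors."""
    import h5py

    dataset = run_dir / "dataset"
    events, segments, famil, conditions, _ = load_dataset(dataset)
    dur = config.simulation.epoch_duration_s

    streams = {}
    for (subj, exc), grp in segments.groupby(["subject", "excerpt_id"]):
        raw = list(zip(grp["key"], grp["onset_s"], grp["offset_s"]))
        streams[(str(subj), str(exc))] = RatingStream(
            excerpt_id=str(exc),
            segments=resolve_overlaps(raw, dur),
            trial_duration_s=dur,
        )
    expo = famil[famil["session"] == "exposure"]
    expe = famil[famil["session"] == "experimental"].merge(
        conditions[["subject", "excerpt_id", "familiarity_condition"]],
        on=["subject", "excerpt_id"],
    )

    montage = load_standard_montage(config.head_radius_cm)
    eeg_rejected: set[tuple[str, str]] = set()
    with h5py.File(run_dir / "phases.h5", "w") as h5:
        for subj in config.simulation.subject_ids:
            rec, sf, labels = read_subject_eeg(dataset, subj)
            rec = bandpass_filter(rec, sf, config.band_low_hz, config.band_high_hz)
            rec = rereference_linked_mastoids(rec, tuple(labels))
            scalp = [i for i, l in enumerate(labels) if l not in ("M1", "M2")]
            scalp_labels = tuple(labels[i] for i in scalp)
            ev = [
                (subj, str(r["excerpt_id"]), int(r["onset_sample"]))
                for _, r in events[events["subject"] == subj].iterrows()
            ]
            epochs = epoch_and_baseline(rec[scalp], sf, scalp_labels, ev, dur)
            epochs = amplitude_reject(epochs, config.reject_threshold_uv)
            for key, kept in zip(epochs.trial_keys, epochs.retained):
                if not kept:
                    eeg_rejected.add(key)
            retained = EpochSet(
                data=epochs.data[epochs.retained],
                sfreq=sf,
                labels=scalp_labels,
                retained=np.ones(int(epochs.retained.sum()), bool),
                trial_keys=tuple(k for k, r in zip(epochs.trial_keys, epochs.retained) if r),
            )
            csd = surface_laplacian(
                retained, montage.subset(scalp_labels),
                config.spline_order, config.n_legendre_terms, config.regularization,
            )
            tensor = morlet_phase(
                trim_edges(csd, config.trim_s), config.theta_freqs_hz, config.n_cycles
            )
            g = h5.create_group(subj)
            g.create_dataset("phases", data=tensor.phases.astype(np.float32),
                             compression="lzf")
            g.create_dataset("valid", data=tensor.valid)
            g.attrs["labels"] = list(tensor.labels)
            g.attrs["freqs_hz"] = list(tensor.freqs_hz)
            g.attrs["sfreq"] = tensor.sfreq
            g.attrs["trial_keys"] = [f"{s}|{e}" for s, e in tensor.trial_keys]
        h5.attrs["n_rejected_eeg"] = len(eeg_rejected)

    table = assemble_trial_table(
        streams, conditions, expo, expe,
        familiarity_cutoff=config.familiarity_cutoff,
        eeg_rejected=eeg_rejected,
    )
    write_trial_table(table, run_dir / "trial_table.tsv")


def _read_phase_tensor(h5group):
    from .preprocess import PhaseTensor

    keys = tuple(tuple(k.split("|")) for k in h5group.attrs["trial_keys"])
    phases = np.asarray(h5group["phases"], dtype=float)
    # float32 storage can nudge values past +/- pi; fold back onto (-pi, pi]
    phases = np.clip(phases, -np.pi, np.pi)
    phases[phases == -np.pi] = np.pi
    return PhaseTensor(
        phases=phases,
        freqs_hz=np.asarray(h5group.attrs["freqs_hz"], dtype=float),
        valid=np.asarray(h5group["valid"], dtype=bool),
        sfreq=float(h5group.attrs["sfreq"]),
        labels=tuple(str(l) for l in h5group.attrs["labels"]),
        trial_keys=keys,
    )


def select_pairs(config: RunConfig) -> PairSet:
    """The analysis pair set: explicit list, or ROI/distance rules."""
    montage = load_standard_montage(config.head_radius_cm)
    if config.pairs is not None:
        pairs = tuple(tuple(p.split("-")) for p in config.pairs)
        dists = tuple(
            float(np.linalg.norm(montage.position(a) - montage.position(b)))
            for a, b in pairs
        )
        return PairSet(pairs=pairs, roi_labels=tuple(config.simulation.channels),
                       excluded_labels=(), min_distance_cm=0.0, distances_cm=dists)
    roi = [ch for ch in config.simulation.channels if ch in set(montage.labels)]
    ps = candidate_pairs(montage, tuple(roi), min_distance_cm=config.min_distance_cm)
    if config.max_pairs is not None and len(ps) > config.max_pairs:
        keep = ps.pairs[: config.max_pairs]
        ps = PairSet(pairs=keep, roi_labels=ps.roi_labels,
                     excluded_labels=ps.excluded_labels,
                     min_distance_cm=ps.min_distance_cm,
                     distances_cm=ps.distances_cm[: config.max_pairs])
    return ps


def _stage_connect(config: RunConfig, run_dir: Path) -> None:
    import h5py

    table = read_trial_table(run_dir / "trial_table.tsv")
    pairs = select_pairs(config)
    pairs.to_tsv(run_dir / "pairs.tsv")
    tensors = []
    with h5py.File(run_dir / "phases.h5", "r") as h5:
        for subj in h5:
            if subj.startswith("_"):
                continue
            tensors.append(_read_phase_tensor(h5[subj]))
    conn = build_connectivity_table(tensors, pairs, table)
    write_connectivity_table(conn, run_dir / "connectivity.tsv")


def _stage_fit(config: RunConfig, run_dir: Path) -> None:
    table = read_trial_table(run_dir / "trial_table.tsv")
    conn = read_connectivity_table(run_dir / "connectivity.tsv")
    cfg = config.sampler()
    summaries = {}
    famil = fit_ordinal_familiarity(table, sampler_cfg=cfg,
                                    rope_halfwidth=config.rope_halfwidth)
    summaries["familiarity_ordinal"] = famil.to_dict()
    pleas = fit_student_t_pleasantness(table, sampler_cfg=cfg,
                                       rope_halfwidth=config.rope_halfwidth)
    summaries["pleasantness_student_t"] = pleas.to_dict()
    decisions = mass_univariate(conn, sampler_cfg=cfg,
                                rope_halfwidth=config.rope_halfwidth)
    decisions.to_csv(run_dir / "decisions.tsv", sep="\t", index=False)
    (run_dir / "summaries.json").write_text(json.dumps(summaries, indent=2))


def _stage_report(config: RunConfig, run_dir: Path) -> None:
    decisions = pd.read_csv(run_dir / "decisions.tsv", sep="\t")
    summaries = json.loads((run_dir / "summaries.json").read_text())
    truth = config.truth
    lines = ["# thetasync run report", ""]
    lines.append(f"- seed: {config.seed}, tier: {config.tier}")
    table = read_trial_table(run_dir / "trial_table.tsv")
    rej = 1.0 - table["retained"].mean()
    lines.append(f"- rejected trial proportion: {rej:.4f}")
    for name, s in summaries.items():
        lines.append(f"\n## {name}")
        for par, v in s.items():
            if not isinstance(v, dict):
                continue
            if par.startswith(("beta", "PH")):
                lines.append(
                    f"- {par}: mode {v['mode']:.3f}, 95% HDI "
                    f"[{v['hdi_95'][0]:.3f}, {v['hdi_95'][1]:.3f}] -> {v['decision']}"
                )
    lines.append("\n## reportable connections")
    rep = decisions[decisions["reportable"]]
    if len(rep) == 0:
        lines.append("- none")
    for _, r in rep.iterrows():
        planted = truth.pair_coefficients.get(r["pair"])
        extra = f" (planted beta3 = {planted[3]})" if planted is not None else ""
        lines.append(
            f"- {r['pair']}: beta3 mode {r['beta3_mode']:.3f}, 95% HDI "
            f"[{r['beta3_hdi_low']:.3f}, {r['beta3_hdi_high']:.3f}]{extra}"
        )
    n_unconv = int((decisions["decision"] == DECISION_UNCONVERGED).sum())
    if n_unconv:
        lines.append(f"\nWARNING: {n_unconv} unconverged pair fits")
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "connect": _stage_connect,
    "fit": _stage_fit,
    "report": _stage_report,
}

_STAGE_OUTPUTS = {
    "simulate": ["dataset/eeg.h5", "dataset/events.tsv", "dataset/truth.json"],
    "preprocess": ["phases.h5", "trial_table.tsv"],
    "connect": ["connectivity.tsv", "pairs.tsv"],
    "fit": ["decisions.tsv", "summaries.json"],
    "report": ["report.md"],
}


def run(config: RunConfig, resume: bool = True) -> Path:
    """Execute the configured stages in order; returns the run directory.

    A stage whose manifest matches the current parameters (and whose outputs
    still exist) is skipped when ``resume`` is true.  A stage failure raises
    ``RuntimeError`` naming the stage.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    cfg_dict = dataclasses.asdict(config)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        ph = _params_hash({"stage": stage, "config": cfg_dict})
        if resume and _stage_current(run_dir, stage, ph):
            logger.info("stage %s up to date; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FNS[stage](config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _write_manifest(run_dir, stage, ph, _STAGE_OUTPUTS[stage])
    return run_dir
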