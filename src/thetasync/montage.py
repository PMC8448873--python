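"""Spherical 10-10 electrode geometry and analysis pair selection.

The analysis operates on inter-electrode connections between frontal,
temporal and parietal sites.  Two geometric rules prune the candidate set:
connections involving peripheral electrodes (Fp1/2, FT9/10, TP9/10) are
dropped because they mostly carry residual ocular/muscular activity, and
connections shorter than a minimum inter-electrode distance (default 6 cm)
are dropped because short-range synchrony is dominated by volume conduction.

Positions live on an idealized sphere (default radius 9.2 cm, a common
adult head-model value).  Convention: right-handed, +x toward the right
preauricular point, +y toward the nasion, +z toward the vertex, so Cz sits
at (0, 0, r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

__all__ = [
    "SCALP_61",
    "ROI_45",
    "PERIPHERAL",
    "MASTOIDS",
    "DEFAULT_HEAD_RADIUS_CM",
    "DEFAULT_MIN_DISTANCE_CM",
    "ElectrodeMontage",
    "PairSet",
    "load_standard_montage",
    "load_montage_file",
    "pair_distance",
    "candidate_pairs",
]

#: The 61 scalp channels recorded in the study design this package targets.
SCALP_61: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "Fz", "F7", "F8", "F5", "F6", "F3", "F4",
    "F1", "F2", "FCz", "FT9", "FT10", "FT7", "FT8", "FC5", "FC6", "FC3",
    "FC4", "FC1", "FC2", "Cz", "T7", "T8", "C5", "C6", "C3", "C4", "C1",
    "C2", "CPz", "TP9", "TP10", "TP7", "TP8", "CP5", "CP6", "CP3", "CP4",
    "CP1", "CP2", "Pz", "P7", "P8", "P5", "P6", "P3", "P4", "P1", "P2",
    "POz", "PO7", "PO8", "PO3", "PO4", "Oz", "O1", "O2",
)

#: The 45 frontal / temporal / parietal electrodes entering the
#: synchronization analysis.
ROI_45: tuple[str, ...] = (
    "AF3", "AF4", "Fz", "F7", "F8", "F5", "F6", "F3", "F4", "F1", "F2",
    "FCz", "FT7", "FT8", "FC5", "FC6", "FC3", "FC4", "FC1", "FC2", "Cz",
    "T7", "T8", "TP7", "TP8", "CP5", "CP6", "CP3", "CP4", "CP1", "CP2",
    "Pz", "P7", "P8", "P5", "P6", "P3", "P4", "P1", "P2", "POz", "PO7",
    "PO8", "PO3", "PO4",
)

#: Peripheral electrodes whose connections are excluded outright.
PERIPHERAL: tuple[str, ...] = ("Fp1", "Fp2", "FT9", "FT10", "TP9", "TP10")

MASTOIDS: tuple[str, str] = ("M1", "M2")

DEFAULT_HEAD_RADIUS_CM: float = 9.2
DEFAULT_MIN_DISTANCE_CM: float = 6.0

# Mastoid direction vectors (unit-sphere), taken from the standard 10-05
# electrode scheme; easycap layouts do not define M1/M2.
_MASTOID_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "M1": (-0.72427, -0.37853, -0.57206),
    "M2": (0.72305, -0.37938, -0.57304),
}


@dataclass(frozen=True)
class ElectrodeMontage:
    """Channel labels with 3-D positions (cm) on a sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), cm
    head_radius_cm: float

    def __post_init__(self) -> None:
        if self.head_radius_cm <= 0:
            raise ValueError("head_radius_cm must be positive")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        radii = np.linalg.norm(pos, axis=1)
        if not np.allclose(radii, self.head_radius_cm, rtol=1e-6, atol=0.0):
            raise ValueError("positions must lie on the head sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def __contains__(self, label: str) -> bool:
        return label in self._index  # type: ignore[attr-defined]

    def position(self, label: str) -> np.ndarray:
        try:
            return self.positions[self._index[label]]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def subset(self, labels: list[str] | tuple[str, ...]) -> "ElectrodeMontage":
        idx = [self._index[l] for l in labels]  # type: ignore[attr-defined]
        return ElectrodeMontage(tuple(labels), self.positions[idx], self.head_radius_cm)

    def to_file(self, path: str | Path) -> None:
        """Write a plain-text ``label x y z`` table (cm)."""
        lines = [
            "# thetasync montage: label x y z (cm); +x right preauricular,"
            " +y nasion, +z vertex",
            f"# head_radius_cm = {self.head_radius_cm!r}",
        ]
        for lab, p in zip(self.labels, self.positions):
            lines.append(f"{lab}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class PairSet:
    """Unordered electrode pairs retained for connectivity analysis."""

    pairs: tuple[tuple[str, str], ...]
    roi_labels: tuple[str, ...]
    excluded_labels: tuple[str, ...]
    min_distance_cm: float
    distances_cm: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        seen = set()
        excl = set(self.excluded_labels)
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            if a in excl or b in excl:
                raise ValueError(f"pair ({a}, {b}) contains an excluded label")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate pair ({a}, {b})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return (a, b) in self.pairs or (b, a) in self.pairs

    def to_tsv(self, path: str | Path) -> None:
        lines = ["label_a\tlabel_b\tdistance_cm"]
        dists = self.distances_cm or (float("nan"),) * len(self.pairs)
        for (a, b), d in zip(self.pairs, dists):
            lines.append(f"{a}\t{b}\t{d:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def load_standard_montage(
    head_radius_cm: float = DEFAULT_HEAD_RADIUS_CM,
    include_mastoids: bool = True,
) -> ElectrodeMontage:
    """Build the default spherical 10-10 montage.

    Positions come from the idealized spherical Easycap layout shipped with
    MNE, rescaled to ``head_radius_cm``.  The vertex electrode Cz lands
    exactly at (0, 0, r).
    """
    if head_radius_cm <= 0:
        raise ValueError("head_radius_cm must be positive")
    import mne

    std = mne.channels.make_standard_montage("easycap-M1").get_positions()["ch_pos"]
    labels = list(SCALP_61) + (list(MASTOIDS) if include_mastoids else [])
    rows = []
    for lab in labels:
        if lab in _MASTOID_DIRECTIONS:
            d = np.asarray(_MASTOID_DIRECTIONS[lab])
        else:
            d = np.asarray(std[lab], dtype=float)
        rows.append(d / np.linalg.norm(d) * head_radius_cm)
    return ElectrodeMontage(tuple(labels), np.asarray(rows), head_radius_cm)


def load_montage_file(path: str | Path, head_radius_cm: float | None = None) -> ElectrodeMontage:
    """Read a ``label x y z`` table; positions are re-normalized to the sphere.

    Unknown (non 10-10, non-mastoid) labels are rejected by name so typos in
    user-supplied override files surface immediately.
    """
    known = set(SCALP_61) | set(MASTOIDS)
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage row: {line!r}")
        lab = parts[0]
        if lab not in known:
            raise ValueError(f"unknown channel label {lab!r} in montage file")
        labels.append(lab)
        rows.append([float(x) for x in parts[1:]])
    pos = np.asarray(rows)
    radii = np.linalg.norm(pos, axis=1)
    r = head_radius_cm if head_radius_cm is not None else float(np.median(radii))
    pos = pos / radii[:, None] * r
    return ElectrodeMontage(tuple(labels), pos, r)


def pair_distance(montage: ElectrodeMontage, a: str, b: str) -> float:
    """3-D Euclidean chord distance (cm) between two electrodes."""
    return float(np.linalg.norm(montage.position(a) - montage.position(b)))


def candidate_pairs(
    montage: ElectrodeMontage,
    roi_labels: tuple[str, ...] | list[str] = ROI_45,
    excluded_labels: tuple[str, ...] | list[str] = PERIPHERAL,
    min_distance_cm: float = DEFAULT_MIN_DISTANCE_CM,
) -> PairSet:
    """All unordered ROI pairs minus peripheral channels and short links.

    Pairs are returned sorted lexicographically, so the output does not
    depend on the ordering of ``roi_labels``.
    """
    missing = [l for l in roi_labels if l not in montage]
    if missing:
        raise KeyError(f"ROI labels not in montage: {missing}")
    excl = set(excluded_labels)
    kept = sorted(l for l in set(roi_labels) if l not in excl)
    pairs: list[tuple[str, str]] = []
    dists: list[float] = []
    for a, b in combinations(kept, 2):
        d = pair_distance(montage, a, b)
        if d >= min_distance_cm:
            pairs.append((a, b))
            dists.append(d)
    if not pairs:
        raise ValueError(
            "pair selection produced an empty set "
            f"(roi={len(kept)} labels, min_distance_cm={min_distance_cm})"
        )
    return PairSet(
        pairs=tuple(pairs),
        roi_labels=tuple(kept),
        excluded_labels=tuple(sorted(excl)),
        min_distance_cm=float(min_distance_cm),
        distances_cm=tuple(dists),
    )
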