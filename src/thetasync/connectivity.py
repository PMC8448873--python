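"""Inter-site phase clustering (ISPC) over time and the modelling table.

For two phase series phi_a, phi_b of length n at one frequency,

    ISPC = | n^-1 sum_t exp(i (phi_a(t) - phi_b(t))) |

i.e. the resultant length of the phase-difference series: 1 for a perfectly
consistent lag, near 0 for no consistency (the null floor for independent
uniform phases is ~ sqrt(pi)/(2 sqrt(n))).  ISPC is computed per epoch and
frequency, averaged across the theta grid, and compressed away from the
unit-interval boundaries so a beta likelihood is well defined.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .montage import PairSet
from .preprocess import PhaseTensor

__all__ = [
    "ispc_time",
    "band_average",
    "adjust_unit_interval",
    "build_connectivity_table",
    "read_connectivity_table",
    "write_connectivity_table",
]

CONNECTIVITY_COLUMNS = [
    "subject", "excerpt_id", "pair", "ispc", "n_timepoints",
    "pleasantness_class", "familiarity_condition",
]


def ispc_time(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Resultant length of the phase-difference series (Eq. above)."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 time points")
    return float(np.abs(np.exp(1j * (a - b)).mean()))


def band_average(per_frequency_ispcs: np.ndarray) -> float:
    """Arithmetic mean of per-frequency ISPC values."""
    vals = np.asarray(per_frequency_ispcs, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one frequency")
    return float(vals.mean())


def adjust_unit_interval(values: np.ndarray, n_trials: int) -> np.ndarray:
    """Compress [0,1] responses into the open interval:  y' = (y(N-1)+1/2)/N.

    Applied unconditionally (not only to boundary values) so every response
    undergoes the same monotone map before the beta-likelihood fit.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    y = np.asarray(values, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("values must lie in [0, 1]")
    return (y * (n_trials - 1) + 0.5) / n_trials


def build_connectivity_table(
    phase_tensors: "list[PhaseTensor] | PhaseTensor",
    pairs: PairSet,
    trial_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per retained trial x pair: band-averaged, boundary-adjusted ISPC.

    Only trials flagged retained in the trial table (and present in the
    phase tensors) produce rows; behavioral labels are joined in.
    """
    if isinstance(phase_tensors, PhaseTensor):
        phase_tensors = [phase_tensors]
    labels = {
        (str(r["subject"]), str(r["excerpt_id"])): (
            r["pleasantness_class"], r["familiarity_condition"]
        )
        for _, r in trial_table[trial_table["retained"]].iterrows()
    }
    rows = []
    for tensor in phase_tensors:
        idx = {}
        for a, b in pairs:
            idx[(a, b)] = (tensor.channel(a), tensor.channel(b))
        for e, key in enumerate(tensor.trial_keys):
            if key not in labels:
                continue
            pleas, famil = labels[key]
            for (a, b), (ia, ib) in idx.items():
                per_freq = np.empty(len(tensor.freqs_hz))
                n_t = 0
                for fi in range(len(tensor.freqs_hz)):
                    m = tensor.valid[fi]
                    per_freq[fi] = ispc_time(
                        tensor.phases[e, ia, fi, m], tensor.phases[e, ib, fi, m]
                    )
                    n_t = max(n_t, int(m.sum()))
                rows.append(
                    {
                        "subject": key[0],
                        "excerpt_id": key[1],
                        "pair": f"{a}-{b}",
                        "ispc": band_average(per_freq),
                        "n_timepoints": n_t,
                        "pleasantness_class": pleas,
                        "familiarity_condition": famil,
                    }
                )
    table = pd.DataFrame(rows, columns=CONNECTIVITY_COLUMNS)
    if len(table):
        # compression uses N = observations entering each per-pair fit
        table["ispc"] = table.groupby("pair")["ispc"].transform(
            lambda g: adjust_unit_interval(g.to_numpy(), len(g))
        )
        table = table.sort_values(["pair", "subject", "excerpt_id"], kind="stable")
        table = table.reset_index(drop=True)
    return table


def write_connectivity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_connectivity_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject": str, "excerpt_id": str})
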