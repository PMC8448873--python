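"""Full pipeline on a small synthetic study: simulate -> ... -> report.

Simulates 2 subjects x 4 excerpts with theta coupling planted at two
electrode pairs, runs preprocessing, connectivity and the mass-univariate
beta regressions, and prints the decision table.  Expect a couple of
minutes on one CPU.
"""

import dataclasses
import tempfile
from pathlib import Path

import pandas as pd

from thetasync.pipeline import RunConfig, run
from thetasync.simulate import SimulationConfig, reduced_truth

channels = ("AF4", "FT8", "T8", "CP5", "Fz", "Cz", "Pz", "F3", "F4",
            "C3", "C4", "P3", "P4", "TP7", "TP8", "FC3", "FC4")
sim = SimulationConfig(
    n_subjects=2, n_excerpts_old=2, n_excerpts_new=2, epoch_duration_s=12.0,
    channels=channels, coupling_pairs=(("AF4", "FT8"), ("T8", "CP5")),
    halt_prob=0.0, artifact_prob=0.0, contamination_frac=0.0,
)
out = Path(tempfile.mkdtemp(prefix="thetasync_demo_"))
cfg = RunConfig(out_dir=str(out), seed=7, tier="smoke", simulation=sim,
                truth=dataclasses.replace(reduced_truth(), seed=7),
                pairs=("AF4-FT8", "T8-CP5", "F3-P4"))
run(cfg)

print((out / "report.md").read_text())
dec = pd.read_csv(out / "decisions.tsv", sep="\t")
print(dec[["pair", "decision", "beta3_mode", "beta3_hdi_low",
           "beta3_hdi_high", "reportable"]].to_string(index=False))
print("\nAt this tiny size the interaction posteriors are wide; the "
      "reduced study conditions (6 subjects x 20 excerpts) give the "
      "pipeline enough data to flag the planted pairs.")
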