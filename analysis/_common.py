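"""Shared paths and configuration for the numbered analysis scripts.

All scripts write into ``results/synthetic_run`` and use the default
synthetic preset (seed 1) so the whole sequence is reproducible by running
the scripts in order from the repository root.
"""

from pathlib import Path

import pandas as pd

from phytoreg import pipeline

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "synthetic_run"
SEED = 1


def config() -> pipeline.PipelineConfig:
    cfg = pipeline.default_config(outdir=str(OUTDIR), seed=SEED)
    cfg.paths.occurrences = str(OUTDIR / "occurrences.csv")
    cfg.paths.env = str(OUTDIR / "env.csv")
    cfg.paths.truth = str(OUTDIR / "truth.csv")
    return cfg


def load_incidence() -> pd.DataFrame:
    long = pd.read_csv(OUTDIR / "cells_species.csv")
    M = (
        long.assign(v=1)
        .pivot_table(index="cell_id", columns="species", values="v", fill_value=0)
        .astype(int)
    )
    return M[sorted(M.columns)].sort_index()
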