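"""Simulate the synthetic study region: a 12x12 grid of 0.25-degree cells
split by the 750 m elevation threshold into an upper (A) and a lower (B)
district, with 50 upper-exclusive, 10 lower-exclusive and 40 shared
species, and environmental layers (soil Ca/Mg, precipitation seasonality,
driest-quarter precipitation, four decoys) whose district means differ.

Writes occurrences.csv, env.csv, truth.csv, cells.geojson."""

import pandas as pd

from _common import OUTDIR, config
from phytoreg import pipeline

cfg = config()
paths = pipeline.simulate(cfg, OUTDIR)

records = pd.read_csv(paths["occurrences"])
truth = pd.read_csv(paths["truth"], index_col=0)
env = pd.read_csv(paths["env"], index_col=0)

print(f"simulated {len(records)} occurrence records of {records['species'].nunique()} species")
print(f"landscape: {len(truth)} cells, "
      f"{(truth['true_district'] == 'A').sum()} upper (A) / "
      f"{(truth['true_district'] == 'B').sum()} lower (B)")
print("district means of the planted environmental layers:")
print(env.join(truth["true_district"]).groupby("true_district").mean().round(3).T)
print(f"outputs in {OUTDIR}/")
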