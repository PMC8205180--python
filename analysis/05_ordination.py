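"""Non-metric multidimensional scaling of the turnover matrix; per-axis
scores are sign-fixed and exported for mapping. Writes nmds_scores.csv,
nmds.json, nmds_axes.geojson."""

import json

import pandas as pd

from _common import OUTDIR, config
from phytoreg import ordination, turnover
from phytoreg.regionalization import RegionAssignment

cfg = config()
dm = turnover.read_matrix_csv(OUTDIR / "betasim.csv")
res = ordination.nmds(
    dm, k=cfg.nmds.k, restarts=cfg.nmds.restarts, tol=cfg.nmds.tol, seed=cfg.nmds.seed
)
res.write_csv(OUTDIR / "nmds_scores.csv")
with open(OUTDIR / "nmds.json", "w") as fh:
    json.dump(res.to_report(), fh, indent=1)

assignment = RegionAssignment(pd.read_csv(OUTDIR / "assignment.csv", index_col=0))
districts = assignment.districts
tables = ordination.axis_maps(res, districts)

print(f"NMDS (k={cfg.nmds.k}, {res.n_restarts} starts): "
      f"stress={res.stress:.4f} ({ordination.stress_quality(res.stress)}), "
      f"converged={res.converged}")
for axis, t in tables.items():
    by = t.set_index("cell_id")["score"].groupby(districts).mean()
    print(f"{axis}: district mean scores " +
          ", ".join(f"{d}={v:+.3f}" for d, v in by.items()))
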