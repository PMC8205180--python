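"""Relative environmental turnover (vector fitting of the selected
predictors onto the NMDS axes) and minimum-spanning-tree tracks of each
district's exclusive species. Writes envfit.csv, exclusive_species.csv,
tracks.geojson."""

import json

import pandas as pd

from _common import OUTDIR, config
from phytoreg import environment as env
from phytoreg import gridding, ret_tracks
from phytoreg.regionalization import RegionAssignment

cfg = config()
scores = pd.read_csv(OUTDIR / "nmds_scores.csv", index_col=0)
env_table = pd.read_csv(cfg.paths.env, index_col=0)
assignment = RegionAssignment(pd.read_csv(OUTDIR / "assignment.csv", index_col=0))

with open(OUTDIR / "rda.json") as fh:
    selected = json.load(fh)["forward_selection"]["selected"] or list(env_table.columns)
Ez, *_ = env.standardize(env_table[selected])

ef = ret_tracks.envfit(
    scores, Ez.reindex(scores.index),
    permutations=cfg.envfit.permutations, seed=cfg.envfit.seed,
)
ef.to_csv(OUTDIR / "envfit.csv", float_format="%.6g")
print("environmental vectors on the ordination (r2, p):")
print(ef.round(4).to_string())

# rebuild the gridded records to get collecting points per species
raw = gridding.read_occurrences_csv(cfg.paths.occurrences)
curated, _ = gridding.curate_records(raw)
grid = gridding.GridSpec(origin=tuple(cfg.grid.origin), cell_size=cfg.grid.cell_size)
table = gridding.filter_and_merge(
    gridding.assign_to_grid(curated, grid), min_records=cfg.grid.min_records
)

excl = ret_tracks.exclusive_species(table.species_sets(), assignment)
rows = [(d, sp) for d, spp in excl.items() for sp in spp]
pd.DataFrame(rows, columns=["district", "species"]).to_csv(
    OUTDIR / "exclusive_species.csv", index=False
)

tracks = []
for district, spp in excl.items():
    recs = table.records[table.records["species"].isin(spp)]
    if recs[["lon", "lat"]].drop_duplicates().shape[0] >= 2:
        tracks.append(ret_tracks.mst_track(recs, district))
ret_tracks.write_tracks_geojson(tracks, OUTDIR / "tracks.geojson")

for d, spp in excl.items():
    print(f"district {d}: {len(spp)} exclusive species")
for t in tracks:
    print(f"track {t.district}: {len(t.points)} points, "
          f"{len(t.edges)} edges, {t.total_length_km:.0f} km total")
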