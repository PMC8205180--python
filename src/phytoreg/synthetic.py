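"""Synthetic landscapes with two planted phytogeographic districts.

The generator emulates the statistical structure a regionalization analysis
assumes: a study region split into two spatially contiguous districts by an
elevation threshold (the 750 m break between an "upper" and a "lower"
district), species pools exclusive to each district plus a shared pool,
heterogeneous per-cell collecting effort (so some cells fall under the
minimum-record filter), and environmental layers whose district means differ
(soil Ca and Mg, precipitation seasonality, driest-quarter precipitation).

Districts are labelled ``"A"`` (elevation >= threshold, the upper district)
and ``"B"`` (below it). Every draw is controlled by an integer seed so the
same specification always yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from ._geo import cell_polygon_coords, write_feature_collection

__all__ = [
    "LandscapeSpec",
    "CommunitySpec",
    "EnvLayerSpec",
    "Landscape",
    "DEFAULT_ENV_LAYERS",
    "PAPER_SCALE_COMMUNITY",
    "generate_landscape",
    "generate_occurrences",
    "generate_env_table",
    "write_occurrences_csv",
    "write_env_csv",
    "write_truth_csv",
    "write_cells_geojson",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry and relief of the synthetic study region.

    The elevation surface is a west-to-east linear ramp plus a smoothed
    Gaussian random field; the ramp guarantees two contiguous districts
    either side of ``district_threshold`` (m). The default extent gives a
    12 x 12 grid of 0.25 degree cells.
    """

    extent: tuple[float, float, float, float] = (-102.0, 17.0, -99.0, 20.0)
    cell_size: float = 0.25
    ramp_range: tuple[float, float] = (150.0, 1400.0)
    roughness_sd: float = 120.0
    roughness_length: float = 1.5
    district_threshold: float = 750.0

    def __post_init__(self) -> None:
        lon0, lat0, lon1, lat1 = self.extent
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError(f"degenerate extent {self.extent}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass(frozen=True)
class CommunitySpec:
    """Species pools and collecting-effort model.

    ``n_exclusive_a``/``n_exclusive_b`` species occur only in district A/B
    cells; ``n_shared`` species may occur anywhere. The asymmetric default
    (50 vs 10) mirrors the strong exclusivity asymmetry between an upper and
    a lower district at study scale, scaled down so the full pipeline runs
    in seconds. Per-cell visit counts are Poisson(``effort_mean``), or
    negative binomial with variance ``mean * (1 + effort_overdispersion)``
    when overdispersed; each visit records one species drawn from the
    cell's eligible pool with lognormal relative abundances, kept with
    probability ``detection_prob``.
    """

    n_exclusive_a: int = 50
    n_exclusive_b: int = 10
    n_shared: int = 40
    detection_prob: float = 1.0
    effort_mean: float = 20.0
    effort_overdispersion: float = 0.0
    abundance_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exclusive_a, self.n_exclusive_b, self.n_shared) < 0:
            raise ValueError("species counts must be non-negative")
        if self.n_exclusive_a + self.n_exclusive_b + self.n_shared < 2:
            raise ValueError("need at least two species in total")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.effort_mean < 0 or self.effort_overdispersion < 0:
            raise ValueError("effort parameters must be non-negative")


@dataclass(frozen=True)
class EnvLayerSpec:
    """One environmental layer: district-conditional Gaussian values.

    ``sd`` may be a scalar or an (A, B) pair of per-district standard
    deviations. ``autocorr_length`` (in cells) smooths the noise field so
    neighbouring cells covary, as real climate and soil layers do.
    """

    name: str
    mean_a: float
    mean_b: float
    sd: float | tuple[float, float] = 0.0
    autocorr_length: float = 0.0

    @property
    def sd_pair(self) -> tuple[float, float]:
        if isinstance(self.sd, (int, float)):
            pair = (float(self.sd), float(self.sd))
        else:
            pair = (float(self.sd[0]), float(self.sd[1]))
        if min(pair) < 0:
            raise ValueError(f"negative sd for layer {self.name!r}")
        return pair


#: Default layers: soil Ca/Mg district means and sds follow the reported
#: upper/lower contrast (Ca 0.93+-0.49 vs 0.40+-0.16 mg; Mg 0.29+-0.08 vs
#: 0.32+-0.07 mg). Precipitation seasonality (CV %) and driest-quarter
#: precipitation (mm) get realistic seasonally-dry-tropical-forest values
#: with the lower district drier and more seasonal. The four ``noise_*``
#: layers have identical district distributions and act as decoys for
#: predictor selection.
DEFAULT_ENV_LAYERS: tuple[EnvLayerSpec, ...] = (
    EnvLayerSpec("MEXCA", 0.93, 0.40, (0.49, 0.16), 1.5),
    EnvLayerSpec("MEXMG", 0.29, 0.32, (0.08, 0.07), 1.5),
    EnvLayerSpec("BIO_15", 78.0, 88.0, (6.0, 6.0), 1.5),
    EnvLayerSpec("BIO_17", 38.0, 19.0, (9.0, 7.0), 1.5),
    EnvLayerSpec("noise_01", 0.0, 0.0, 1.0, 1.5),
    EnvLayerSpec("noise_02", 0.0, 0.0, 1.0, 1.5),
    EnvLayerSpec("noise_03", 0.0, 0.0, 1.0, 0.0),
    EnvLayerSpec("noise_04", 0.0, 0.0, 1.0, 0.0),
)

#: Community at the scale of the original study (571 species over ~159
#: cells): 292 upper-exclusive, 32 lower-exclusive, 247 shared.
PAPER_SCALE_COMMUNITY = CommunitySpec(n_exclusive_a=292, n_exclusive_b=32, n_shared=247)


@dataclass
class Landscape:
    """A labelled grid: per-cell geometry, elevation and true district."""

    spec: LandscapeSpec
    cells: pd.DataFrame  # index cell_id; ix, iy, lon, lat, elevation_m, district

    @property
    def origin(self) -> tuple[float, float]:
        return (self.spec.extent[0], self.spec.extent[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.cells["ix"].max()) + 1, int(self.cells["iy"].max()) + 1)

    def cell_polygons(self) -> list[Polygon]:
        return [
            Polygon(cell_polygon_coords(int(r.ix), int(r.iy), self.origin, self.spec.cell_size))
            for r in self.cells.itertuples()
        ]

    def true_districts(self) -> pd.Series:
        return self.cells["district"].copy()


def cell_id(ix: int, iy: int) -> str:
    """Zero-padded id so lexicographic and (ix, iy) order coincide."""
    if ix < 0 or iy < 0:
        raise ValueError(f"negative cell index ({ix}, {iy}); point lies below the grid origin")
    return f"c{ix:03d}_{iy:03d}"


def generate_landscape(
    spec: LandscapeSpec, seed: int, require_two_districts: bool = True
) -> Landscape:
    """Build the elevation surface and label each cell's true district.

    Elevation at a cell centre is the linear west-east ramp over
    ``spec.ramp_range`` plus a Gaussian random field smoothed over
    ``roughness_length`` cells and rescaled to ``roughness_sd``. A cell is
    district ``"A"`` iff its centre elevation >= ``district_threshold``.

    Raises
    ------
    ValueError
        If every cell falls in a single district ("single-district
        landscape") and ``require_two_districts`` is true: downstream
        regionalization would be meaningless. Pass
        ``require_two_districts=False`` to inspect such surfaces anyway.
    """
    lon0, lat0, lon1, lat1 = spec.extent
    nx = int(round((lon1 - lon0) / spec.cell_size))
    ny = int(round((lat1 - lat0) / spec.cell_size))
    if nx < 1 or ny < 1:
        raise ValueError("extent smaller than one cell")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nx, ny))
    if spec.roughness_length > 0:
        noise = gaussian_filter(noise, sigma=spec.roughness_length, mode="nearest")
        s = noise.std()
        if s > 0:
            noise = noise / s
    field_m = noise * spec.roughness_sd

    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    frac = (ix + 0.5) / nx  # ramp varies west -> east
    ramp = spec.ramp_range[0] + frac * (spec.ramp_range[1] - spec.ramp_range[0])
    elev = ramp + field_m

    ids = [cell_id(i, j) for i, j in zip(ix.ravel(), iy.ravel())]
    cells = pd.DataFrame(
        {
            "ix": ix.ravel(),
            "iy": iy.ravel(),
            "lon": lon0 + (ix.ravel() + 0.5) * spec.cell_size,
            "lat": lat0 + (iy.ravel() + 0.5) * spec.cell_size,
            "elevation_m": elev.ravel(),
            "district": np.where(elev.ravel() >= spec.district_threshold, "A", "B"),
        },
        index=pd.Index(ids, name="cell_id"),
    ).sort_index()

    n_a = int((cells["district"] == "A").sum())
    if require_two_districts and (n_a == 0 or n_a == len(cells)):
        raise ValueError(
            "single-district landscape: adjust the threshold or the elevation surface"
        )
    return Landscape(spec=spec, cells=cells)


def generate_occurrences(landscape: Landscape, community: CommunitySpec) -> pd.DataFrame:
    """Sample occurrence records from the planted community.

    Returns a Darwin-Core-flavoured table with columns ``species``,
    ``decimalLongitude``, ``decimalLatitude``, ``source_id``. Exclusive-A
    species never receive a record in a B cell (and vice versa) by
    construction; record positions are uniform within their cell.
    """
    spec = community
    rng = np.random.default_rng(spec.seed)

    species_a = [f"exA{i:03d}" for i in range(spec.n_exclusive_a)]
    species_b = [f"exB{i:03d}" for i in range(spec.n_exclusive_b)]
    species_s = [f"sh{i:03d}" for i in range(spec.n_shared)]
    all_species = species_a + species_b + species_s
    abundance = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=len(all_species))

    idx = {s: k for k, s in enumerate(all_species)}
    pool_a = np.array([idx[s] for s in species_a + species_s], dtype=int)
    pool_b = np.array([idx[s] for s in species_b + species_s], dtype=int)

    cs = landscape.spec.cell_size
    lon0, lat0 = landscape.origin
    rows: list[tuple[str, float, float, str]] = []
    n_rec = 0
    for cid, cell in landscape.cells.iterrows():
        pool = pool_a if cell["district"] == "A" else pool_b
        if pool.size == 0:
            continue
        if spec.effort_overdispersion > 0:
            # NB parameterized so variance = mean * (1 + overdispersion)
            r = spec.effort_mean / spec.effort_overdispersion
            p = 1.0 / (1.0 + spec.effort_overdispersion)
            n_visits = int(rng.negative_binomial(r, p))
        else:
            n_visits = int(rng.poisson(spec.effort_mean))
        if n_visits == 0:
            continue
        w = abundance[pool]
        picks = rng.choice(pool, size=n_visits, p=w / w.sum())
        kept = picks[rng.random(n_visits) < spec.detection_prob]
        if kept.size == 0:
            continue
        u = rng.random((kept.size, 2))
        lon = lon0 + (cell["ix"] + u[:, 0]) * cs
        lat = lat0 + (cell["iy"] + u[:, 1]) * cs
        for k, sp_i in enumerate(kept):
            rows.append((all_species[sp_i], float(lon[k]), float(lat[k]), f"{cid}:{n_rec}"))
            n_rec += 1

    if not rows:
        raise ValueError("zero total records generated; increase effort_mean")
    return pd.DataFrame(rows, columns=["species", "decimalLongitude", "decimalLatitude", "source_id"])


def generate_env_table(
    landscape: Landscape, layers: list[EnvLayerSpec] | tuple[EnvLayerSpec, ...], seed: int
) -> pd.DataFrame:
    """Per-cell environmental table (index cell_id, one column per layer).

    Each layer is district-conditional Gaussian: value = district mean +
    district sd * noise, where the noise field has unit variance after
    optional spatial smoothing, so empirical district means and sds converge
    to the specification as the number of cells grows.
    """
    names = [ly.name for ly in layers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in env layers")

    rng = np.random.default_rng(seed)
    nx, ny = landscape.shape
    cells = landscape.cells
    flat = (cells["ix"].to_numpy() * ny + cells["iy"].to_numpy()).astype(int)
    is_a = (cells["district"] == "A").to_numpy()

    out = {}
    for ly in layers:
        noise = rng.standard_normal((nx, ny))
        if ly.autocorr_length > 0:
            noise = gaussian_filter(noise, sigma=ly.autocorr_length, mode="nearest")
            s = noise.std()
            if s > 0:
                noise = noise / s
        z = noise.ravel()[flat]
        sd_a, sd_b = ly.sd_pair
        out[ly.name] = np.where(is_a, ly.mean_a + sd_a * z, ly.mean_b + sd_b * z)
    return pd.DataFrame(out, index=cells.index.copy())


# ---------------------------------------------------------------- writers

def write_occurrences_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.6f")


def write_env_csv(env: pd.DataFrame, path) -> None:
    env.to_csv(path, index_label="cell_id", float_format="%.10g")


def write_truth_csv(landscape: Landscape, path) -> None:
    landscape.cells[["elevation_m", "district"]].rename(
        columns={"district": "true_district"}
    ).to_csv(path, index_label="cell_id", float_format="%.4f")


def write_cells_geojson(landscape: Landscape, path) -> None:
    props = [
        {"cell_id": cid, "elevation_m": round(float(r["elevation_m"]), 2), "district": r["district"]}
        for cid, r in landscape.cells.iterrows()
    ]
    write_feature_collection(path, landscape.cell_polygons(), props)
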