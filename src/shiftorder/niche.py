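"""Climate-niche summaries from per-record occurrence tables.

Turns cleaned occurrence/climate rows (one row per record with longitude,
latitude, elevation, mean annual temperature bio1 and annual precipitation
bio12) into per-species niche summaries: medians of the climate variables,
an elevation category on the <500 / 500-1000 / 1000-1500 / >=1500 m grid,
montane flags under the three binarization cutoffs, and a Whittaker biome
assignment in the temperature x precipitation plane.  Also provides the
group x biome chi-squared contingency analysis with standardized residuals,
and the anther pore-area trait A = pi * a * b (a, b = half pore height and
half pore width).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

OCC_COLUMNS = ["species", "longitude", "latitude", "elevation_m",
               "bio1_degC", "bio12_mm"]

#: 1 km at the equator on a 30 arc-second raster grid
DEFAULT_CELL_DEG = 1.0 / 120.0

ELEVATION_EDGES = (500.0, 1000.0, 1500.0)
ELEVATION_BINS = ("E1", "E2", "E3", "E4")
MONTANE_CUTOFFS = (500.0, 1000.0, 1500.0)


# ---------------------------------------------------------------------------
# record filtering
# ---------------------------------------------------------------------------

def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if ((df["longitude"].abs() > 180) | (df["latitude"].abs() > 90)).any():
        raise ValueError("coordinates out of range")
    return df


def dedup_exact(records: pd.DataFrame) -> pd.DataFrame:
    """Drop exact duplicate (species, longitude, latitude) rows."""
    n0 = len(records)
    out = (records.sort_values(["species", "longitude", "latitude", "elevation_m"],
                               kind="stable")
           .drop_duplicates(subset=["species", "longitude", "latitude"])
           .reset_index(drop=True))
    logger.info("dedup: %d -> %d records", n0, len(out))
    return out


def grid_subsample(records: pd.DataFrame,
                   cell_size_deg: float = DEFAULT_CELL_DEG) -> pd.DataFrame:
    """Keep at most one record per species per geographic grid cell.

    The retained record is the first under a deterministic sort by
    (longitude, latitude, elevation), so the result does not depend on the
    input row order.
    """
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be > 0")
    if records.empty:
        return records.copy()
    n0 = len(records)
    df = records.sort_values(["species", "longitude", "latitude", "elevation_m"],
                             kind="stable").copy()
    df["_cx"] = np.floor(df["longitude"] / cell_size_deg).astype(int)
    df["_cy"] = np.floor(df["latitude"] / cell_size_deg).astype(int)
    out = (df.drop_duplicates(subset=["species", "_cx", "_cy"])
           .drop(columns=["_cx", "_cy"])
           .reset_index(drop=True))
    logger.info("grid subsample (%.6f deg): %d -> %d records",
                cell_size_deg, n0, len(out))
    return out


# ---------------------------------------------------------------------------
# elevation categories
# ---------------------------------------------------------------------------

def categorize_elevation(elevation_m) -> np.ndarray:
    """Left-closed elevation bins: E1 <500, E2 [500,1000), E3 [1000,1500),
    E4 >=1500 m.  Negative elevations (coastal raster artefacts) map to E1
    with a warning."""
    e = np.atleast_1d(np.asarray(elevation_m, dtype=float))
    if not np.all(np.isfinite(e)):
        raise ValueError("elevation must be finite")
    if np.any(e < 0):
        warnings.warn(f"{int((e < 0).sum())} negative elevation(s) mapped to E1",
                      stacklevel=2)
    idx = np.searchsorted(ELEVATION_EDGES, e, side="right")
    bins = np.asarray(ELEVATION_BINS)[idx]
    return bins if np.ndim(elevation_m) else bins[0]


# ---------------------------------------------------------------------------
# Whittaker biomes
# ---------------------------------------------------------------------------

_BIOMES: list[tuple[int, str, Polygon]] | None = None


def _load_biomes() -> list[tuple[int, str, Polygon]]:
    global _BIOMES
    if _BIOMES is None:
        with resources.files("shiftorder.data").joinpath(
                "whittaker_biomes_synthetic.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        out = []
        for (bid, name), grp in df.groupby(["biome_id", "biome_name"], sort=True):
            grp = grp.sort_values("vertex")
            poly = Polygon(zip(grp["temp_c"], grp["precip_mm"]))
            out.append((int(bid), str(name), poly))
        _BIOMES = sorted(out, key=lambda x: x[0])
    return _BIOMES


def biome_names() -> dict[int, str]:
    return {bid: name for bid, name, _ in _load_biomes()}


def assign_whittaker_biome(bio1_degC, bio12_mm):
    """Biome id (1..9) per (temperature, precipitation) point.

    Returns ``(ids, extrapolated)``; a point inside no polygon gets the
    nearest polygon's id with ``extrapolated=True``; missing inputs yield id
    0.  Negative precipitation is an error.
    """
    t = np.atleast_1d(np.asarray(bio1_degC, dtype=float))
    p = np.atleast_1d(np.asarray(bio12_mm, dtype=float))
    if t.shape != p.shape:
        raise ValueError("temperature and precipitation shapes differ")
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    biomes = _load_biomes()
    ids = np.zeros(t.shape, dtype=int)
    extrap = np.zeros(t.shape, dtype=bool)
    for i, (ti, pi) in enumerate(zip(t, p)):
        if not (np.isfinite(ti) and np.isfinite(pi)):
            continue  # missing climate -> missing biome (0)
        pt = Point(ti, pi)
        hit = next((bid for bid, _, poly in biomes
                    if poly.covers(pt)), None)
        if hit is None:
            hit = min(biomes, key=lambda x: x[2].exterior.distance(pt))[0]
            extrap[i] = True
        ids[i] = hit
    if np.ndim(bio1_degC) == 0:
        return int(ids[0]), bool(extrap[0])
    return ids, extrap


# ---------------------------------------------------------------------------
# species summaries
# ---------------------------------------------------------------------------

def summarize_species(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species medians plus elevation bin, montane flags and biome.

    Median of an even record count is the mean of the two middle values;
    latitude is summarized as the median absolute latitude (the latitude
    effects of interest are symmetric about the equator).
    """
    if records.empty:
        raise ValueError("no occurrence records")
    agg = records.groupby("species").agg(
        n_records=("species", "size"),
        median_elevation_m=("elevation_m", "median"),
        median_bio1_degC=("bio1_degC", "median"),
        median_bio12_mm=("bio12_mm", "median"),
        median_abs_latitude=("latitude", lambda s: float(np.median(np.abs(s)))),
    ).reset_index()
    agg["elevation_bin"] = categorize_elevation(agg["median_elevation_m"].to_numpy())
    # left-closed boundary convention throughout: montane_c <=> elevation >= c,
    # which keeps the flags consistent with the elevation bins (montane_1000
    # exactly when the bin is E3 or E4)
    for c in MONTANE_CUTOFFS:
        agg[f"montane_{int(c)}"] = agg["median_elevation_m"] >= c
    ids, extrap = assign_whittaker_biome(agg["median_bio1_degC"].to_numpy(),
                                         agg["median_bio12_mm"].to_numpy())
    agg["biome"] = ids
    agg["biome_extrapolated"] = extrap
    return agg


# ---------------------------------------------------------------------------
# biome contingency analysis
# ---------------------------------------------------------------------------

@dataclass
class BiomeChisqResult:
    table: pd.DataFrame  # groups x biomes counts
    chi2: float
    df: int
    pvalue: float
    residuals: pd.DataFrame  # standardized residuals, same shape
    strong_cells: list[tuple]  # cells with |residual| > 2
    dropped: list  # empty rows/columns removed before testing


def biome_chisq(groups: pd.Series, summaries: pd.DataFrame) -> BiomeChisqResult:
    """Pearson chi-squared on the group x biome table with standardized
    residuals r_ij = (O-E) / sqrt(E (1 - row_i/n) (1 - col_j/n)).

    ``groups`` maps species -> group label; cells come from the ``biome``
    column of the species summaries.  Biomes or groups with zero total are
    dropped (reported in ``dropped``) before testing.
    """
    df = summaries.merge(groups.rename("group"), left_on="species",
                         right_index=True)
    df = df[df["biome"] > 0]
    table = pd.crosstab(df["group"], df["biome"])
    dropped = []
    for axis in (0, 1):
        tot = table.sum(axis=1 - axis)
        empty = tot[tot == 0].index.tolist()
        if empty:
            dropped.extend(empty)
            table = table.drop(index=empty) if axis == 0 else table.drop(columns=empty)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 occupied biomes")
    if dropped:
        warnings.warn(f"dropped empty rows/columns: {dropped}", stacklevel=2)
    obs = table.to_numpy(dtype=float)
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    rowfrac = obs.sum(axis=1, keepdims=True) / n
    colfrac = obs.sum(axis=0, keepdims=True) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (obs - expected) / np.sqrt(expected * (1 - rowfrac) * (1 - colfrac))
    residuals = pd.DataFrame(resid, index=table.index, columns=table.columns)
    strong = [(g, b) for g in table.index for b in table.columns
              if abs(residuals.loc[g, b]) > 2]
    return BiomeChisqResult(table=table, chi2=float(chi2), df=int(dof),
                            pvalue=float(p), residuals=residuals,
                            strong_cells=strong, dropped=dropped)


# ---------------------------------------------------------------------------
# pore area
# ---------------------------------------------------------------------------

def pore_area(pore_height_mm, pore_width_mm):
    """Total anther pore area A = pi * a * b with a, b the half height and
    half width (mm^2)."""
    h = np.asarray(pore_height_mm, dtype=float)
    w = np.asarray(pore_width_mm, dtype=float)
    if np.any(h < 0) or np.any(w < 0):
        raise ValueError("pore dimensions must be >= 0")
    out = np.pi * (h / 2.0) * (w / 2.0)
    return float(out) if out.ndim == 0 else out
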