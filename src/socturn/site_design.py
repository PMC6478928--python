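"""Statistics-based selection of gradient-study sites.

Observational soil studies suffer from covarying drivers (colder sites
tend to be moister; wetter sites tend to be more acidic), which makes
their effects statistically inseparable.  This module implements a
reproducible version of a design procedure that selects a study subset
whose driver effects are near-orthogonal:

1. filter the candidate population (slope ≤ 50%, long-term monitoring
   sites exempt);
2. classify each site into four equiprobable climate categories by the
   population medians of temperature (TT−/TT+) and of a dryness index
   (MI−/MI+; MI− = dry, more months with precipitation below potential
   evapotranspiration);
3. aggregate soil/landform covariates (pH, clay, slope, orientation) into
   two orthogonal axes (PCo1, PCo2) by principal coordinates analysis on a
   Gower distance matrix;
4. stratify by biogeographical region × climate category and, within each
   cell, pick sites spreading the distance-to-origin in the PCo1–PCo2
   plane (greedy farthest-point, deterministic tie-breaks).

Site selection in practice often involves manual judgement calls; the
greedy criterion here is a fully reproducible alternative, and a
design-quality report (max |pairwise correlation| among the design
terms) is returned so the achieved orthogonality can be judged directly.

Sites are carried as a pandas DataFrame with columns
``site_id, region, temp, dryness, ph, clay, slope, orientation[, is_lwf]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "DesignSelection",
    "filter_population",
    "dryness_index",
    "climate_categories",
    "gower_distance",
    "pcoa_soil_landform",
    "select_orthogonal",
]

POPULATION_COLUMNS = (
    "site_id",
    "region",
    "temp",
    "dryness",
    "ph",
    "clay",
    "slope",
    "orientation",
)


def _validate(sites: pd.DataFrame, need=POPULATION_COLUMNS) -> pd.DataFrame:
    missing = [c for c in need if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if "clay" in sites.columns:
        clay = sites["clay"].to_numpy(float)
        if np.any((clay < 0) | (clay > 100)):
            raise ValueError("clay % must lie in [0, 100]")
    if "slope" in sites.columns and np.any(sites["slope"].to_numpy(float) < 0):
        raise ValueError("slope % must be ≥ 0")
    return sites


def filter_population(sites: pd.DataFrame, slope_max: float = 50.0) -> pd.DataFrame:
    """Drop sites with slope strictly larger than ``slope_max`` %.

    Long-term monitoring sites (``is_lwf`` truthy) are kept regardless —
    their sustained research value outweighs the erosion caveat.  A slope
    exactly at the threshold is kept (the cut is 'larger than').
    """
    _validate(sites, need=("site_id", "slope"))
    lwf = (
        sites["is_lwf"].astype(bool)
        if "is_lwf" in sites.columns
        else pd.Series(False, index=sites.index)
    )
    keep = (sites["slope"] <= slope_max) | lwf
    return sites.loc[keep].copy()


def dryness_index(monthly_p, monthly_pet) -> int:
    """Count of dry months: months whose precipitation is strictly below
    potential evapotranspiration (Penman PET is an input, not computed)."""
    p = np.asarray(monthly_p, float)
    pet = np.asarray(monthly_pet, float)
    if p.shape != pet.shape:
        raise ValueError("precipitation and PET series must have equal length")
    return int(np.sum(p < pet))


def climate_categories(
    sites: pd.DataFrame,
    temp_col: str = "temp",
    dryness_col: str = "dryness",
) -> pd.DataFrame:
    """Median-split climate categories {MI−, MI+} × {TT−, TT+}.

    Medians are taken over the supplied (already filtered) population.
    Ties go to the lower bin of the underlying covariate: temp ≤ median →
    TT− (cold); dryness ≤ median → MI+ (fewer dry months = moister).
    Returns a DataFrame with columns ``ti_cat``, ``mi_cat`` indexed like
    ``sites``.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to median-split")
    temp = sites[temp_col].to_numpy(float)
    dry = sites[dryness_col].to_numpy(float)
    for name, v in (("temperature", temp), ("dryness", dry)):
        if np.all(v == v[0]):
            raise ValueError(f"{name} is constant; no median split possible")
    t_med = float(np.median(temp))
    d_med = float(np.median(dry))
    ti = np.where(temp <= t_med, "TT-", "TT+")
    mi = np.where(dry <= d_med, "MI+", "MI-")
    return pd.DataFrame({"ti_cat": ti, "mi_cat": mi}, index=sites.index)


def gower_distance(
    df: pd.DataFrame,
    numeric: tuple = ("ph", "clay", "slope"),
    categorical: tuple = ("orientation",),
) -> np.ndarray:
    """Gower dissimilarity for mixed numeric/categorical variables.

    Numeric variables contribute |xᵢ−xⱼ| scaled by the variable's range;
    categoricals contribute simple matching (0 match, 1 mismatch); the
    per-variable contributions are averaged.  Constant numeric variables
    contribute 0.
    """
    n = len(df)
    parts = np.zeros((n, n))
    n_vars = 0
    for col in numeric:
        x = df[col].to_numpy(float)
        rng = x.max() - x.min()
        if rng > 0:
            parts += np.abs(x[:, None] - x[None, :]) / rng
        n_vars += 1
    for col in categorical:
        x = df[col].to_numpy()
        parts += (x[:, None] != x[None, :]).astype(float)
        n_vars += 1
    return parts / n_vars


def pcoa_soil_landform(
    sites: pd.DataFrame,
    distance: str = "gower",
    numeric: tuple = ("ph", "clay", "slope"),
    categorical: tuple = ("orientation",),
):
    """Reduce soil/landform covariates to two principal coordinates.

    ``distance='gower'`` (default, mixed variables) or
    ``'euclidean_standardized'`` (z-scored numerics only; equivalent to PCA
    scores up to sign).  Returns ``(pco1, pco2, eigenvalues)``: coordinate
    arrays scaled by √eigenvalue and the full eigenvalue spectrum (negative
    eigenvalues, possible for non-Euclidean Gower matrices, are reported
    but excluded from the coordinates).
    """
    if len(sites) < 3:
        raise ValueError("PCoA needs at least 3 sites")
    if distance == "gower":
        d = gower_distance(sites, numeric, categorical)
    elif distance == "euclidean_standardized":
        x = sites.loc[:, list(numeric)].to_numpy(float)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant columns contribute nothing
        z = (x - x.mean(axis=0)) / sd
        diff = z[:, None, :] - z[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise ValueError(f"unknown distance '{distance}'")
    n = len(sites)
    ids = [str(i) for i in range(n)]
    with warnings.catch_warnings():
        # skbio warns about (and zeroes) negative eigenvalues; the full
        # signed spectrum is recomputed below and reported instead
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(DistanceMatrix(d, ids), method="eigh")
    # full signed spectrum of the double-centred −½D² matrix (negative
    # eigenvalues are possible for non-Euclidean Gower matrices)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eig = np.linalg.eigvalsh(b)[::-1]
    n_pos = int(np.sum(eig > 1e-10 * max(abs(eig[0]), 1.0)))
    if n_pos < 1:
        raise ValueError("no positive PCoA eigenvalue: degenerate distances")
    coords = res.samples.to_numpy()
    pco1 = coords[:, 0].copy()
    # a perfectly one-dimensional configuration has a single positive axis
    pco2 = coords[:, 1].copy() if n_pos >= 2 else np.zeros(n)
    return pco1, pco2, eig


@dataclass
class DesignSelection:
    """Result of the stratified orthogonal selection."""

    selected_ids: list
    table: pd.DataFrame  # population + ti_cat, mi_cat, pco1, pco2, selected
    orthogonality_report: dict
    gaps: list = field(default_factory=list)  # empty region×category combos

    @property
    def selected(self) -> pd.DataFrame:
        return self.table.loc[self.table["selected"]]


def _greedy_spread(xy: np.ndarray, ids: np.ndarray, k: int) -> list[int]:
    """Greedy farthest-point sampling in the PCo1–PCo2 plane.

    Anchor at the site farthest from the origin of coordinates, then
    repeatedly add the candidate maximising its minimum Euclidean distance
    to the already-chosen set — spreading picks evenly over the plane.
    Ties break lexicographically on site id."""
    if k <= 0:
        return []
    radii = np.hypot(xy[:, 0], xy[:, 1])
    order = np.lexsort((ids, -radii))  # max radius first, id ascending on ties
    chosen = [int(order[0])]
    remaining = [int(i) for i in order[1:]]
    while len(chosen) < k and remaining:
        best, best_gap = None, -1.0
        for i in remaining:
            gap = min(
                float(np.hypot(*(xy[i] - xy[j]))) for j in chosen
            )
            if gap > best_gap:
                best, best_gap = i, gap
        chosen.append(best)
        remaining.remove(best)
    return chosen


def _design_max_corr(sel: pd.DataFrame) -> dict:
    """Max |pairwise correlation| among design terms on the selected sites.

    Terms: TT indicator, MI indicator, PCo1, PCo2, and region dummies
    (drop-first).  Dummy–dummy pairs within the region block are excluded —
    mutually exclusive indicators are negatively correlated by construction.
    """
    cols = {
        "TI": (sel["ti_cat"] == "TT+").astype(float),
        "MI": (sel["mi_cat"] == "MI+").astype(float),
        "PCo1": sel["pco1"].astype(float),
        "PCo2": sel["pco2"].astype(float),
    }
    regions = sorted(sel["region"].unique())
    for r in regions[1:]:
        cols[f"region[{r}]"] = (sel["region"] == r).astype(float)
    mat = pd.DataFrame(cols)
    corr = mat.corr().to_numpy()
    names = list(mat.columns)
    worst, worst_pair = 0.0, ("", "")
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if names[i].startswith("region") and names[j].startswith("region"):
                continue
            c = corr[i, j]
            if np.isfinite(c) and abs(c) > worst:
                worst, worst_pair = abs(c), (names[i], names[j])
    return {"max_abs_corr": float(worst), "worst_pair": worst_pair}


def select_orthogonal(
    sites: pd.DataFrame,
    n_target: int = 54,
    distance: str = "gower",
) -> DesignSelection:
    """Stratified near-orthogonal selection of ``n_target`` sites.

    Computes climate categories and PCo1/PCo2 on the supplied population,
    allocates the target size over region × climate-category cells
    (largest-remainder proportional allocation, capped at cell size with
    redistribution), and fills each cell by the greedy radius-spread
    criterion.  Deterministic for a fixed input ordering.
    """
    _validate(sites)
    if n_target > len(sites):
        raise ValueError(f"n_target={n_target} exceeds population size {len(sites)}")
    pop = sites.reset_index(drop=True).copy()
    pop = pop.join(climate_categories(pop))
    pco1, pco2, eig = pcoa_soil_landform(pop, distance=distance)
    pop["pco1"], pop["pco2"] = pco1, pco2
    pop["cat"] = pop["ti_cat"] + "/" + pop["mi_cat"]

    regions = sorted(pop["region"].unique())
    cats = sorted(pop["cat"].unique())
    cells = {
        (r, c): pop.index[(pop["region"] == r) & (pop["cat"] == c)].to_numpy()
        for r in regions
        for c in cats
    }
    gaps = [key for key, idx in cells.items() if len(idx) == 0]
    for r, c in gaps:
        warnings.warn(f"no candidate sites for region={r}, category={c}", stacklevel=2)
    occupied = {k: v for k, v in cells.items() if len(v) > 0}

    # largest-remainder proportional quotas, capped at cell size
    keys = sorted(occupied)
    sizes = np.array([len(occupied[k]) for k in keys], float)
    quota = np.floor(n_target * sizes / sizes.sum()).astype(int)
    frac = n_target * sizes / sizes.sum() - quota
    for i in np.argsort(-frac, kind="stable"):
        if quota.sum() >= n_target:
            break
        quota[i] += 1
    quota = np.minimum(quota, sizes.astype(int))
    while quota.sum() < n_target:  # redistribute shortfall from capped cells
        room = sizes.astype(int) - quota
        if not np.any(room > 0):
            break
        i = int(np.argmax(room))
        quota[i] += 1

    selected: list[int] = []
    for k, q in zip(keys, quota):
        idx = occupied[k]
        xy = pop.loc[idx, ["pco1", "pco2"]].to_numpy()
        ids = pop.loc[idx, "site_id"].astype(str).to_numpy()
        picks = _greedy_spread(xy, ids, int(q))
        selected.extend(int(idx[i]) for i in picks)

    pop["selected"] = False
    pop.loc[selected, "selected"] = True
    report = _design_max_corr(pop.loc[pop["selected"]])
    report["n_selected"] = int(len(selected))
    report["eigenvalues_top5"] = [float(e) for e in eig[:5]]
    return DesignSelection(
        selected_ids=pop.loc[selected, "site_id"].tolist(),
        table=pop,
        orthogonality_report=report,
        gaps=gaps,
    )
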