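"""Zone validation statistics.

Management zones are validated by comparing soil properties and the
fused soil-fertility measures across zones with the Kruskal–Wallis
omnibus test followed by Dunn's rank-based pairwise post-hoc test,
summarised as a compact letter display (zones sharing a letter are not
significantly different). Vegetative response is compared through NDVI
zonal means per acquisition date.
"""

from __future__ import annotations

import dataclasses
import itertools
import string

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import RasterGrid
from .zoning import ZoneMap

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "dunn_test",
    "letter_display",
    "zone_property_means",
    "ndvi",
    "ndvi_by_zone",
]


@dataclasses.dataclass
class GroupComparison:
    """Omnibus + pairwise comparison of one variable across zones."""

    H: float
    p_omnibus: float
    pairwise: pd.DataFrame   # columns: group_a, group_b, z, p_raw, p_adj
    alpha: float
    letters: dict

    def significant_pairs(self) -> list[tuple]:
        sig = self.pairwise[self.pairwise["p_adj"] < self.alpha]
        return list(zip(sig["group_a"], sig["group_b"]))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Degenerate input (all observations identical) returns (0, 1) rather
    than erroring, matching the no-evidence interpretation.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_test(values, groups, adjustment: str = "none") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on mean ranks.

    z_ab = (R̄_a − R̄_b) / sqrt( (N(N+1)/12 − T/(12(N−1))) (1/n_a + 1/n_b) )

    with T = Σ (t³ − t) over tied groups. Two-sided p-values, optionally
    Bonferroni- or Holm-adjusted. For two groups, z² equals the
    tie-corrected omnibus H.
    """
    if adjustment not in {"none", "bonferroni", "holm"}:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    n_by = {g: int((groups == g).sum()) for g in labels}
    if any(n == 0 for n in n_by.values()):
        raise ValueError("every group needs at least one observation")
    N = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: float(ranks[groups == g].mean()) for g in labels}
    tie = _tie_term(values)
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / n_by[a] + 1.0 / n_by[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)

    p = table["p_raw"].to_numpy()
    if adjustment == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    elif adjustment == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, p[i] * (len(p) - rank))
            adj[i] = min(running, 1.0)
        p_adj = adj
    else:
        p_adj = p.copy()
    table["p_adj"] = p_adj
    return table


def letter_display(pairwise: pd.DataFrame, alpha: float,
                   group_order: list | None = None) -> dict:
    """Compact letter display by insert-and-absorb.

    Groups not significantly different share at least one letter;
    significantly different groups share none. Deterministic given the
    group order (zones are conventionally ordered least → most
    productive).
    """
    groups = list(group_order) if group_order is not None else sorted(
        set(pairwise["group_a"]) | set(pairwise["group_b"]), key=str)
    sig = {}
    for _, row in pairwise.iterrows():
        key = frozenset((row["group_a"], row["group_b"]))
        sig[key] = row["p_adj"] < alpha

    # start with one letter set holding everyone; split on each
    # significant pair (insert), then drop absorbed (subset) sets
    letter_sets: list[set] = [set(groups)]
    for key, is_sig in sig.items():
        if not is_sig:
            continue
        a, b = tuple(key)
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [
            s for s in new_sets
            if s and not any(s < t for t in new_sets if t is not s)
        ]
        # drop exact duplicates, keeping first
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq

    # order letter sets by the first group they contain
    pos = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(pos[g] for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip(string.ascii_lowercase, letter_sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def compare_groups(values, groups, alpha: float = 0.01,
                   adjustment: str = "none",
                   group_order: list | None = None) -> GroupComparison:
    """Omnibus + post-hoc + letters for one variable."""
    H, p = kruskal_wallis(values, groups)
    pairwise = dunn_test(values, groups, adjustment=adjustment)
    letters = letter_display(pairwise, alpha, group_order=group_order)
    return GroupComparison(H, p, pairwise, alpha, letters)


def zone_property_means(
    table: pd.DataFrame,
    properties: list[str] | None = None,
    zone_column: str = "zone",
    alpha: float = 0.01,
    adjustment: str = "none",
) -> pd.DataFrame:
    """Per-zone property means with Dunn significance letters.

    Mirrors the usual zone-validation layout: one row per zone, one
    column pair (mean, letters) per soil property; zones ordered by
    ascending label (least → most productive).
    """
    from .rasch import SOIL_PROPERTIES
    if properties is None:
        properties = [c for c in SOIL_PROPERTIES if c in table.columns]
    zones = sorted(table[zone_column].unique())
    if table.groupby(zone_column).size().min() < 1:
        raise ValueError("every zone needs at least one sample")
    out = pd.DataFrame(index=pd.Index(zones, name=zone_column))
    for prop in properties:
        vals = table[prop].to_numpy(dtype=float)
        grp = table[zone_column].to_numpy()
        means = table.groupby(zone_column)[prop].mean()
        comp = compare_groups(vals, grp, alpha=alpha,
                              adjustment=adjustment, group_order=zones)
        out[prop] = means
        out[f"{prop}_letters"] = [comp.letters[z] for z in zones]
    return out


def ndvi(nir, red):
    """Normalised difference vegetation index (NIR − Red)/(NIR + Red)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectances must be nonnegative")
    denom = nir + red
    if np.any(denom == 0):
        raise ValueError("NIR + Red must be nonzero")
    return (nir - red) / denom


def _resample_nearest(src: RasterGrid, template: RasterGrid) -> RasterGrid:
    """Nearest-neighbour resampling of ``src`` onto ``template``."""
    gx, gy = template.cell_centers()
    cols = np.clip(((gx - src.x_origin) / src.cell_size).astype(int),
                   0, src.n_cols - 1)
    rows = np.clip(
        src.n_rows - 1 - ((gy - src.y_origin) / src.cell_size).astype(int),
        0, src.n_rows - 1)
    return template.like(src.values[rows, cols], nodata=src.nodata)


def ndvi_by_zone(
    ndvi_rasters: dict[str, RasterGrid],
    zones: ZoneMap,
) -> tuple[pd.DataFrame, dict]:
    """Per-zone mean NDVI per date, with a monotone-decline flag.

    ``ndvi_rasters`` maps date labels (chronological insertion order) to
    NDVI grids; the zone raster is resampled to each NDVI grid by
    nearest neighbour. Zones with no valid NDVI cell get NaN (a zone can
    fall outside an acquisition footprint). The flag marks zones whose
    mean NDVI declines monotonically over the ordered dates, the
    expected late-season pattern.
    """
    rows = {}
    for date, grid in ndvi_rasters.items():
        if zones.grid.same_geometry(grid):
            zone_on_grid = zones
        else:
            zone_on_grid = ZoneMap(
                _resample_nearest(zones.grid, grid), zones.k)
        labels = zone_on_grid.labels()
        means = []
        for z in range(1, zones.k + 1):
            sel = (labels == z) & grid.mask
            means.append(float(grid.values[sel].mean()) if sel.any()
                         else np.nan)
        rows[date] = means
    table = pd.DataFrame(
        rows, index=pd.Index(range(1, zones.k + 1), name="zone"))
    decline = {}
    for z in table.index:
        series = table.loc[z].to_numpy(dtype=float)
        ok = ~np.isnan(series)
        decline[z] = bool(np.all(np.diff(series[ok]) < 0)) if ok.sum() > 1 \
            else False
    return table, decline
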