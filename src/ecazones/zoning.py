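"""Management-zone delineation from stacked rasters.

ECa and elevation layers are z-scored, clustered with an iterative
self-organising means procedure (deterministic percentile-spread seeds,
k fixed), and the resulting class signatures (mean vector + covariance)
feed a Gaussian maximum-likelihood classifier that labels every valid
cell. Zones are finally relabelled by ascending mean ECa so label 1 is
always the least productive zone and label k the most productive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.cluster import KMeans

from .dataio import RasterGrid

__all__ = [
    "FeatureStack",
    "ZoneModel",
    "ZoneMap",
    "stack_and_standardize",
    "isodata_cluster",
    "mlc_classify",
    "order_zones",
    "allocate_samples",
    "majority_filter",
]

ZONE_NODATA = 0  # zone rasters use integer labels 1..k; 0 marks nodata


@dataclasses.dataclass
class FeatureStack:
    """Co-registered, z-scored raster layers ready for clustering."""

    layers: list[RasterGrid]          # standardized layers
    layer_names: list[str]
    means: np.ndarray                 # per-layer mean over valid cells
    sds: np.ndarray                   # per-layer SD over valid cells

    @property
    def template(self) -> RasterGrid:
        return self.layers[0]

    @property
    def mask(self) -> np.ndarray:
        """Valid where every layer is valid."""
        m = self.layers[0].mask
        for layer in self.layers[1:]:
            m = m & layer.mask
        return m

    def features(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid, n_layers) feature matrix and the flat valid-cell index."""
        mask = self.mask.ravel()
        feats = np.column_stack(
            [layer.values.ravel()[mask] for layer in self.layers])
        return feats, np.flatnonzero(mask)


@dataclasses.dataclass
class ZoneModel:
    """Per-class Gaussian signatures in standardized feature space."""

    k: int
    means: np.ndarray        # (k, p)
    covariances: np.ndarray  # (k, p, p)
    priors: np.ndarray       # (k,), sums to 1

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")


@dataclasses.dataclass
class ZoneMap:
    """Integer zone raster; labels 1..k, 0 = nodata; 1 = least productive."""

    grid: RasterGrid
    k: int

    def __post_init__(self) -> None:
        labels = self.labels()
        present = np.unique(labels[labels != ZONE_NODATA])
        if not np.all(np.isin(present, np.arange(1, self.k + 1))):
            raise ValueError("zone labels must lie in 1..k")
        if len(present) < self.k:
            raise ValueError("every zone label 1..k must be present")

    def labels(self) -> np.ndarray:
        return self.grid.values.astype(int)

    def zone_cells(self, zone: int) -> np.ndarray:
        """Flat indices of the cells carrying ``zone``."""
        return np.flatnonzero(self.labels().ravel() == zone)

    def area_fractions(self) -> np.ndarray:
        labels = self.labels()
        counts = np.array(
            [(labels == z).sum() for z in range(1, self.k + 1)], dtype=float)
        return counts / counts.sum()


def stack_and_standardize(
    layers: list[RasterGrid], layer_names: list[str] | None = None
) -> FeatureStack:
    """Z-score each layer over its valid cells and stack them.

    Standardisation makes mS/m-scale ECa and metre-scale elevation
    commensurable; the stored means/SDs allow the inverse transform.
    """
    if layer_names is None:
        layer_names = [f"layer_{i}" for i in range(len(layers))]
    base = layers[0]
    for layer in layers[1:]:
        if not base.same_geometry(layer):
            raise ValueError("all layers must share the raster geometry")
    mask = layers[0].mask
    for layer in layers[1:]:
        mask = mask & layer.mask

    std_layers, means, sds = [], [], []
    for layer, name in zip(layers, layer_names):
        vals = layer.values[mask]
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        if sd == 0:
            raise ValueError(f"layer {name!r} has zero variance")
        z = np.where(mask, (layer.values - mu) / sd, np.nan)
        out = layer.like(z, nodata=np.nan)
        std_layers.append(out)
        means.append(mu)
        sds.append(sd)
    return FeatureStack(std_layers, list(layer_names),
                        np.array(means), np.array(sds))


def _spread_seeds(feats: np.ndarray, k: int) -> np.ndarray:
    """Deterministic initial centers spread along the principal axis.

    Centers sit at evenly spaced quantiles of the projection of the data
    on its first principal direction — the classic self-organising
    initialisation that needs no random draw.
    """
    centred = feats - feats.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    qs = np.quantile(proj, (np.arange(k) + 0.5) / k)
    order = np.argsort(proj)
    pos = np.searchsorted(proj[order], qs)
    pos = np.clip(pos, 0, len(proj) - 1)
    return feats[order[pos]]


def isodata_cluster(
    stack: FeatureStack,
    k: int,
    max_iter: int = 100,
    seed: int = 0,
) -> ZoneModel:
    """Iterative self-organising means clustering with fixed k.

    k-means iterations from deterministic percentile-spread seeds (the
    split/merge moves of the full algorithm are disabled because k is
    fixed by design); returns per-class mean/covariance signatures for
    the maximum-likelihood classifier. ``seed`` only matters for the
    one re-seeding retry after an empty cluster.
    """
    feats, _ = stack.features()
    if k == 1:
        return ZoneModel(1, feats.mean(axis=0)[None, :],
                         np.cov(feats.T, bias=False).reshape(
                             1, feats.shape[1], feats.shape[1]),
                         np.ones(1))
    if k < 1:
        raise ValueError("k must be at least 1")
    if feats.shape[0] < 10 * k:
        raise ValueError("need at least 10·k valid cells")
    if np.allclose(feats.std(axis=0), 0):
        raise ValueError("all cells identical: zero variance")

    init = _spread_seeds(feats, k)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(feats)
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    max_iter=max_iter, random_state=seed)
        labels = km.fit_predict(feats)
        counts = np.bincount(labels, minlength=k)
        if (counts == 0).any():
            raise RuntimeError("empty cluster persisted after re-seeding")
    if km.n_iter_ >= max_iter:
        warnings.warn("clustering hit the iteration cap; "
                      "returning the best partition found")

    p = feats.shape[1]
    means = np.empty((k, p))
    covs = np.empty((k, p, p))
    for j in range(k):
        sub = feats[labels == j]
        means[j] = sub.mean(axis=0)
        cov = np.cov(sub.T, bias=False).reshape(p, p) if len(sub) > 1 \
            else np.eye(p) * 1e-6
        covs[j] = cov
    return ZoneModel(k, means, covs, np.full(k, 1.0 / k))


def mlc_classify(stack: FeatureStack, model: ZoneModel) -> ZoneMap:
    """Gaussian maximum-likelihood classification of every valid cell.

    Each cell goes to the class maximising log N(x; μ_j, Σ_j) + log π_j;
    ties break to the lowest class index. Near-singular covariances are
    ridge-regularised with a warning.
    """
    feats, flat_idx = stack.features()
    if model.means.shape[1] != feats.shape[1]:
        raise ValueError("signature dimension does not match stack depth")
    k, p = model.k, feats.shape[1]
    loglik = np.empty((feats.shape[0], k))
    for j in range(k):
        cov = model.covariances[j]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or np.linalg.cond(cov) > 1e12:
            warnings.warn(f"class {j + 1} covariance regularised")
            cov = cov + 1e-6 * np.trace(cov) / p * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
        diff = feats - model.means[j]
        maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
        loglik[:, j] = (-0.5 * (maha + logdet + p * np.log(2 * np.pi))
                        + np.log(model.priors[j]))
    labels = np.argmax(loglik, axis=1) + 1  # argmax takes the lowest index on ties

    out = np.full(stack.template.shape[0] * stack.template.shape[1],
                  ZONE_NODATA, dtype=float)
    out[flat_idx] = labels
    grid = stack.template.like(out.reshape(stack.template.shape),
                               nodata=ZONE_NODATA)
    return ZoneMap(grid, k)


def order_zones(zones: ZoneMap, eca: RasterGrid) -> ZoneMap:
    """Relabel zones by ascending mean ECa (1 = least productive).

    Pure relabelling: the cell partition is untouched. ECa is the
    productivity proxy — higher conductivity tracks finer texture,
    higher CEC and moisture, hence higher production potential.
    """
    if not zones.grid.same_geometry(eca):
        raise ValueError("zone and ECa rasters must share geometry")
    labels = zones.labels()
    eca_vals = eca.values
    means = []
    for z in range(1, zones.k + 1):
        sel = (labels == z) & eca.mask
        if not sel.any():
            raise ValueError(f"zone {z} has no valid ECa cell")
        means.append(eca_vals[sel].mean())
    order = np.argsort(means)          # order[i] = old zone index (0-based) of new zone i+1
    remap = np.zeros(zones.k + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old + 1] = new
    new_labels = np.where(labels == ZONE_NODATA, ZONE_NODATA,
                          remap[np.clip(labels, 0, zones.k)])
    grid = zones.grid.like(new_labels.astype(float), nodata=ZONE_NODATA)
    return ZoneMap(grid, zones.k)


def allocate_samples(
    zones: ZoneMap, n_total: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Area-proportional sample allocation with in-zone random placement.

    Counts follow largest-remainder apportionment of zone area fractions
    with every zone guaranteed at least one sample; sample coordinates
    are cell centres drawn uniformly (without replacement where
    possible) within each zone.

    Returns (counts per zone, (n_total, 2) array of x/y coordinates
    ordered by zone).
    """
    k = zones.k
    if n_total < k:
        raise ValueError("need at least one sample per zone")
    fractions = zones.area_fractions()
    quotas = fractions * n_total
    counts = np.floor(quotas).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n_total:  # the ≥1 floor can overshoot; trim largest
        counts[np.argmax(counts)] -= 1
    remainders = quotas - np.floor(quotas)
    order = np.argsort(-remainders)
    i = 0
    while counts.sum() < n_total:
        z = order[i % k]
        counts[z] += 1
        i += 1

    rng = np.random.default_rng(seed)
    gx, gy = zones.grid.cell_centers()
    gx, gy = gx.ravel(), gy.ravel()
    coords = []
    for z in range(1, k + 1):
        cells = zones.zone_cells(z)
        if cells.size == 0:
            raise ValueError(f"zone {z} smaller than one cell")
        chosen = rng.choice(cells, size=counts[z - 1],
                            replace=cells.size < counts[z - 1])
        coords.append(np.column_stack([gx[chosen], gy[chosen]]))
    return counts, np.vstack(coords)


def majority_filter(zones: ZoneMap) -> ZoneMap:
    """Optional 3×3 majority smoothing of the zone raster.

    Off by default in the pipeline; useful when a productive zone comes
    out fragmented. Ties keep the centre cell's label.
    """
    labels = zones.labels()
    padded = np.pad(labels, 1, constant_values=ZONE_NODATA)
    out = labels.copy()
    rows, cols = labels.shape
    for r in range(rows):
        for c in range(cols):
            if labels[r, c] == ZONE_NODATA:
                continue
            window = padded[r:r + 3, c:c + 3].ravel()
            window = window[window != ZONE_NODATA]
            counts = np.bincount(window, minlength=zones.k + 1)
            best = counts.max()
            if counts[labels[r, c]] < best:
                out[r, c] = int(np.argmax(counts))
    grid = zones.grid.like(out.astype(float), nodata=ZONE_NODATA)
    return ZoneMap(grid, zones.k)
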