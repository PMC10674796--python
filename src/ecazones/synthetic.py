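"""Synthetic vineyard data with stored ground truth.

The study data (ECa survey, elevation survey, 20 soil samples) are not
deposited, so every pipeline stage is exercised on simulated inputs that
carry the statistical structure the analysis assumes:

* a stationary Gaussian ECa residual field with a spherical variogram
  (defaults: nugget 0.19, partial sill 0.54, range 130.4 m — a 26 %
  nugget/sill ratio, i.e. strong spatial dependence — rescaled to an ECa
  mean of 46.8 mS/m with 58 % coefficient of variation);
* zone-dependent ECa as per-zone mean offsets added to that residual,
  so clustering has a recoverable signal;
* a transect-style mobile survey with sensor noise and a logged fraction
  of corrupted (erroneous) readings;
* a gently sloping DEM with smooth undulation;
* soil samples whose latent fertility is drawn per zone and whose
  5-category property ratings come from the rating-scale model, with
  continuous property values back-constructed so the categorisation
  step reproduces the drawn ratings exactly.

Everything is reproducible from a single master seed, and every
generated artifact's truth is returned alongside it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import PointSurvey, RasterGrid
from .geostat import VariogramModel
from .rasch import SOIL_PROPERTIES, DEFAULT_POLARITY, CategoryMatrix
from .zoning import ZoneMap, ZONE_NODATA, allocate_samples

__all__ = [
    "SyntheticTruth",
    "simulate_gaussian_field",
    "simulate_survey",
    "simulate_dem",
    "simulate_zone_truth",
    "simulate_eca_field",
    "simulate_soil_samples",
    "default_scenario",
    "PROPERTY_RANGES",
]

# Reference field conditions: variogram of the (standardised) ECa field
# and the field's summary statistics on the mS/m scale.
DEFAULT_VARIOGRAM = VariogramModel(nugget=0.19, partial_sill=0.54,
                                   range_m=130.4)
DEFAULT_ECA_MEAN = 46.8     # mS/m
DEFAULT_ECA_CV = 0.58       # coefficient of variation

# Plausible value ranges per soil property; categorisation cut points for
# back-construction are equal-interval over these design ranges.
PROPERTY_RANGES = {
    "sand": (50.0, 95.0),   # %
    "clay": (4.0, 26.0),    # %
    "silt": (0.0, 45.0),    # %
    "om": (0.5, 3.0),       # %
    "ph": (5.0, 7.5),
    "p2o5": (10.0, 400.0),  # mg/kg
    "k2o": (20.0, 150.0),   # mg/kg
    "seb": (2.0, 20.0),     # cmol/kg
    "cec": (10.0, 25.0),    # cmol/kg
}


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind a simulated scenario."""

    master_seed: int
    variogram: VariogramModel
    eca_mean: float
    eca_sd: float
    zone_offsets: np.ndarray | None = None
    zone_labels: np.ndarray | None = None       # true zone raster values
    corruption_indices: np.ndarray | None = None
    dem_params: dict | None = None
    person_measures: np.ndarray | None = None   # true B_n
    item_difficulties: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    polarity: dict | None = None
    cut_points: dict | None = None
    zone_fertility_shifts: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, VariogramModel):
                return v.to_dict()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v
        payload = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def _spherical_correlation(h: np.ndarray, model: VariogramModel) -> np.ndarray:
    """Correlation of the structured (non-nugget) component."""
    hr = np.minimum(h / model.range_m, 1.0)
    return 1.0 - (1.5 * hr - 0.5 * hr**3)


def simulate_gaussian_field(
    template: RasterGrid,
    model: VariogramModel,
    mean: float,
    sd: float,
    seed: int,
) -> RasterGrid:
    """Simulate a stationary Gaussian field with the model's structure.

    A unit-variance field splits its variance by the model's
    nugget/total-sill ratio into an iid component and a spatially
    correlated one, then rescales to (mean, sd). Grids up to ~10^4 cells
    use an exact Cholesky factorisation; larger grids fall back to 2-D
    circulant embedding (negative embedding eigenvalues clipped).
    """
    rng = np.random.default_rng(seed)
    n_cells = template.n_rows * template.n_cols
    nug_frac = model.nugget / model.total_sill if model.total_sill > 0 else 1.0

    if sd == 0:
        return template.like(np.full(template.shape, mean))

    if n_cells <= 10_000:
        gx, gy = template.cell_centers()
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        from scipy.spatial.distance import pdist, squareform
        h = squareform(pdist(coords))
        cov = _spherical_correlation(h, model)
        for jitter in (1e-10, 1e-8, 1e-6):
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(n_cells))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise np.linalg.LinAlgError(
                "covariance not positive definite even after jitter")
        structured = chol @ rng.standard_normal(n_cells)
        structured = structured.reshape(template.shape)
    else:
        structured = _circulant_field(template, model, rng)

    field = (np.sqrt(1 - nug_frac) * structured
             + np.sqrt(nug_frac) * rng.standard_normal(template.shape))
    return template.like(mean + sd * field)


def _circulant_field(template: RasterGrid, model: VariogramModel,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance structured field by 2-D circulant embedding."""
    n_r, n_c = template.shape
    m_r, m_c = 2 * n_r, 2 * n_c
    dy = np.minimum(np.arange(m_r), m_r - np.arange(m_r)) * template.cell_size
    dx = np.minimum(np.arange(m_c), m_c - np.arange(m_c)) * template.cell_size
    h = np.hypot(dy[:, None], dx[None, :])
    c_row = _spherical_correlation(h, model)
    lam = np.fft.fft2(c_row).real
    lam = np.maximum(lam, 0.0)   # clip small negative embedding eigenvalues
    noise = rng.standard_normal((m_r, m_c)) + 1j * rng.standard_normal((m_r, m_c))
    field = np.fft.fft2(np.sqrt(lam / (m_r * m_c)) * noise)
    return field.real[:n_r, :n_c]


def simulate_survey(
    field: RasterGrid,
    transect_spacing: float,
    along_step: float,
    noise_sd: float = 0.0,
    erroneous_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[PointSurvey, np.ndarray]:
    """Sample a field along parallel transects, mimicking a towed sensor.

    North–south transects ``transect_spacing`` apart, readings every
    ``along_step`` metres, iid sensor noise, and a fraction of readings
    corrupted to implausible values (negated or ×10, the error modes a
    plausibility filter should catch). Returns the survey and the
    indices of the corrupted records.
    """
    x0 = field.x_origin
    width = field.n_cols * field.cell_size
    height = field.n_rows * field.cell_size
    xs = np.arange(x0 + transect_spacing / 2, x0 + width, transect_spacing)
    ys = np.arange(field.y_origin + along_step / 2,
                   field.y_origin + height, along_step)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("transect spacing or step exceeds the field extent")
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()

    cols = np.clip(((gx - field.x_origin) / field.cell_size).astype(int),
                   0, field.n_cols - 1)
    rows = np.clip(
        field.n_rows - 1
        - ((gy - field.y_origin) / field.cell_size).astype(int),
        0, field.n_rows - 1)
    values = field.values[rows, cols].astype(float)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    n_bad = int(round(erroneous_fraction * values.size))
    bad_idx = rng.choice(values.size, size=n_bad, replace=False) if n_bad \
        else np.array([], dtype=int)
    if n_bad:
        mode = rng.random(n_bad) < 0.5
        values[bad_idx] = np.where(mode, -np.abs(values[bad_idx]) - 1.0,
                                   np.abs(values[bad_idx]) * 10.0 + 500.0)
    survey = PointSurvey(gx, gy, values, variable_name="eca",
                         depth_window="0-0.30 m")
    return survey, bad_idx


def simulate_dem(
    template: RasterGrid,
    slope: tuple[float, float] = (0.002, 0.001),
    undulation_amplitude: float = 0.3,
    undulation_wavelength: float = 200.0,
    base_elevation: float = 220.0,
    seed: int = 0,
) -> RasterGrid:
    """Gentle-relief DEM: planar trend plus smooth sinusoidal undulation.

    ``slope`` is (dz/dx, dz/dy) in m/m. With zero amplitude the surface
    is an exact plane, which the elevation-gridding step reproduces to
    machine precision.
    """
    if undulation_amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    rng = np.random.default_rng(seed)
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=2)
    gx, gy = template.cell_centers()
    z = (base_elevation + slope[0] * (gx - template.x_origin)
         + slope[1] * (gy - template.y_origin))
    if undulation_amplitude > 0:
        z = z + undulation_amplitude * (
            np.sin(2 * np.pi * gx / undulation_wavelength + phase_x)
            * np.cos(2 * np.pi * gy / undulation_wavelength + phase_y))
    return template.like(z)


def simulate_zone_truth(template: RasterGrid, k: int = 3,
                        area_fractions: tuple = (0.35, 0.45, 0.20)) -> ZoneMap:
    """Concentric true zones with prescribed area fractions.

    The most productive zone sits at the field centre (the high-ECa
    core), ringed by the intermediate and the least productive zone —
    the concentric arrangement typical of red-grape subparcels. Labels
    follow the 1 = least productive convention.
    """
    if len(area_fractions) != k:
        raise ValueError("one area fraction per zone is required")
    gx, gy = template.cell_centers()
    cx = template.x_origin + template.n_cols * template.cell_size / 2
    cy = template.y_origin + template.n_rows * template.cell_size / 2
    r = np.hypot(gx - cx, gy - cy)
    # innermost ring = most productive (label k); fractions are given in
    # label order (least..most), so quantile from the centre outwards
    fr = np.asarray(area_fractions, dtype=float)
    fr = fr / fr.sum()
    cum_inner = np.cumsum(fr[::-1])[:-1]         # boundaries, centre out
    cuts = np.quantile(r.ravel(), cum_inner)
    ring = np.searchsorted(cuts, r)              # 0 = innermost
    labels = k - ring                            # innermost → label k
    return ZoneMap(template.like(labels.astype(float), nodata=ZONE_NODATA), k)


def simulate_eca_field(
    template: RasterGrid,
    zones: ZoneMap,
    zone_offsets: np.ndarray,
    model: VariogramModel = DEFAULT_VARIOGRAM,
    mean: float = DEFAULT_ECA_MEAN,
    cv: float = DEFAULT_ECA_CV,
    seed: int = 0,
) -> RasterGrid:
    """Zone-dependent ECa: per-zone mean offsets + stationary residual.

    ``zone_offsets`` (mS/m, one per zone label) give each zone a
    distinct mean. ``cv`` and the model's nugget fraction describe the
    *observed* field, of which the zone pattern itself is the dominant
    structured component, so the total variance (mean·cv)² is
    partitioned as

        between-zone (from the offsets and zone areas)
        + micro-scale nugget (iid, the model's nugget share of total)
        + a correlated residual at the model's range (the remainder).

    This keeps the field's marginal CV and its nugget/sill character at
    the stated values while leaving the zones recoverable once kriging
    has smoothed the nugget away.
    """
    zone_offsets = np.asarray(zone_offsets, dtype=float)
    if len(zone_offsets) != zones.k:
        raise ValueError("one offset per zone is required")
    fractions = zones.area_fractions()
    mean_offset = float(fractions @ zone_offsets)
    between_var = float(fractions @ zone_offsets**2) - mean_offset**2
    total_var = (mean * cv) ** 2
    nugget_var = model.nugget / model.total_sill * total_var
    struct_var = max(total_var - between_var - nugget_var,
                     0.05 * total_var)
    residual_model = VariogramModel(nugget_var, struct_var, model.range_m)
    residual = simulate_gaussian_field(
        template, residual_model, 0.0,
        float(np.sqrt(nugget_var + struct_var)), seed)
    labels = zones.labels()
    offset = np.zeros(template.shape)
    for z in range(1, zones.k + 1):
        offset[labels == z] = zone_offsets[z - 1]
    return template.like(mean + offset + residual.values)


def _default_item_difficulties(n_items: int) -> np.ndarray:
    d = np.linspace(-1.2, 1.2, n_items)
    return d - d.mean()


def _default_thresholds(m: int) -> np.ndarray:
    tau = np.linspace(-1.5, 1.5, m - 1)
    return tau - tau.mean()


def simulate_category_matrix(
    B: np.ndarray,
    d: np.ndarray,
    tau: np.ndarray,
    seed: int = 0,
    item_names: list[str] | None = None,
) -> CategoryMatrix:
    """Draw an N×I rating matrix directly from the rating-scale model.

    The clean parameter-recovery benchmark: every response comes from
    the model itself, with no back-construction constraints.
    """
    from .rasch import _probs
    B = np.asarray(B, dtype=float)
    d = np.asarray(d, dtype=float)
    tau = np.asarray(tau, dtype=float)
    m = len(tau) + 1
    rng = np.random.default_rng(seed)
    P = _probs(B, d, tau)
    u = rng.random((len(B), len(d)))
    cats = (u[:, :, None] > np.cumsum(P, axis=2)).sum(axis=2) + 1
    names = item_names or [f"item_{j + 1}" for j in range(len(d))]
    return CategoryMatrix(cats.astype(float), m, names,
                          list(range(1, len(B) + 1)),
                          {n: True for n in names})


def simulate_soil_samples(
    zones: ZoneMap,
    n_total: int = 20,
    zone_fertility_shifts: np.ndarray = (-2.0, -0.5, 0.5),
    item_difficulties: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
    polarity: dict | None = None,
    person_sd: float = 0.5,
    m: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, CategoryMatrix, SyntheticTruth]:
    """Soil samples with zone-dependent latent fertility.

    Sample locations come from area-proportional allocation; each
    sample's true fertility is B_n ~ Normal(shift_zone, ``person_sd``)
    logits; 1..m category ratings per property are drawn from the
    rating-scale model; and continuous property values are
    back-constructed inside the category's value bin so that
    categorising the table at the stored cut points returns exactly the
    drawn ratings. The texture triple is renormalised to sum to 100 %
    (silt absorbs the closure, its rating updated accordingly).
    """
    zone_fertility_shifts = np.asarray(zone_fertility_shifts, dtype=float)
    if len(zone_fertility_shifts) != zones.k:
        raise ValueError("one fertility shift per zone is required")
    items = list(SOIL_PROPERTIES)
    d = (np.asarray(item_difficulties, dtype=float)
         if item_difficulties is not None
         else _default_item_difficulties(len(items)))
    if len(d) != len(items):
        raise ValueError("one difficulty per soil property is required")
    tau = (np.asarray(thresholds, dtype=float) if thresholds is not None
           else _default_thresholds(m))
    pol = dict(DEFAULT_POLARITY)
    if polarity:
        pol.update(polarity)

    rng = np.random.default_rng(seed)
    counts, coords = allocate_samples(zones, n_total, seed=seed)
    zone_of = np.repeat(np.arange(1, zones.k + 1), counts)

    B = rng.normal(zone_fertility_shifts[zone_of - 1], person_sd)

    # draw ratings from the rating-scale model
    from .rasch import _probs
    P = _probs(B, d, tau)                      # (n, I, m)
    u = rng.random((n_total, len(items)))
    cdf = np.cumsum(P, axis=2)
    cats = (u[:, :, None] > cdf).sum(axis=2) + 1   # 1..m

    # back-construct continuous values inside each category's bin
    cuts = {it: np.linspace(*PROPERTY_RANGES[it], m + 1)[1:-1]
            for it in items}
    values = np.empty((n_total, len(items)))
    margin = 0.05
    for j, it in enumerate(items):
        lo, hi = PROPERTY_RANGES[it]
        edges = np.linspace(lo, hi, m + 1)
        raw_bin = np.where([pol[it]] * n_total, cats[:, j],
                           m + 1 - cats[:, j])  # bin index on raw scale
        b_lo = edges[raw_bin - 1]
        b_hi = edges[raw_bin]
        width = b_hi - b_lo
        values[:, j] = b_lo + width * (margin + (1 - 2 * margin)
                                       * rng.random(n_total))

    # close the texture triple: silt = 100 − sand − clay, rating updated
    i_sand, i_clay, i_silt = (items.index(p) for p in
                              ("sand", "clay", "silt"))
    silt = 100.0 - values[:, i_sand] - values[:, i_clay]
    lo, hi = PROPERTY_RANGES["silt"]
    silt = np.clip(silt, lo + 1e-9, hi - 1e-9)
    # keep the sum at 100 by absorbing any clip into sand
    values[:, i_sand] = 100.0 - silt - values[:, i_clay]
    values[:, i_silt] = silt
    silt_raw = np.searchsorted(cuts["silt"], silt, side="right") + 1
    cats[:, i_silt] = silt_raw if pol["silt"] else m + 1 - silt_raw
    sand_raw = np.searchsorted(cuts["sand"], values[:, i_sand],
                               side="right") + 1
    cats[:, i_sand] = sand_raw if pol["sand"] else m + 1 - sand_raw

    table = pd.DataFrame(values, columns=items)
    table.insert(0, "id", np.arange(1, n_total + 1))
    table.insert(1, "x", coords[:, 0])
    table.insert(2, "y", coords[:, 1])
    table.insert(3, "zone", zone_of)

    cmatrix = CategoryMatrix(cats.astype(float), m, items,
                             table["id"].tolist(), pol, cuts)
    truth = SyntheticTruth(
        master_seed=seed,
        variogram=DEFAULT_VARIOGRAM,
        eca_mean=DEFAULT_ECA_MEAN,
        eca_sd=DEFAULT_ECA_MEAN * DEFAULT_ECA_CV,
        person_measures=B,
        item_difficulties=d,
        thresholds=tau,
        polarity=pol,
        cut_points=cuts,
        zone_fertility_shifts=zone_fertility_shifts,
    )
    return table, cmatrix, truth


def default_scenario(
    seed: int = 42,
    n_rows: int = 60,
    n_cols: int = 60,
    cell_size: float = 10.0,
    k: int = 3,
    zone_offsets: tuple = (-31.0, 0.0, 31.0),
    n_samples: int = 20,
    zone_fertility_shifts: tuple = (-2.0, -0.5, 0.5),
    erroneous_fraction: float = 0.03,
    transect_spacing: float = 20.0,
    along_step: float = 10.0,
    noise_sd: float = 2.0,
    depression_depth: float = 2.5,
) -> dict:
    """The default synthetic vineyard: everything a full run needs.

    Zone ECa offsets of ±30 mS/m (≈1.1 residual SD) keep zones
    recoverable but overlapping; the survey (20 m transects, 10 m steps,
    2 mS/m sensor noise, 3 % corrupted readings) mimics a towed-sensor
    campaign; soil fertility rises from the least to the most productive
    zone. The DEM carries a gentle central depression
    (``depression_depth`` m) under the high-ECa core — water and fines
    accumulate in low ground, which is why elevation helps delineate
    zones at all.
    """
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    template = RasterGrid.empty(0.0, 0.0, cell_size, n_rows, n_cols)
    zones = simulate_zone_truth(template, k=k)
    eca = simulate_eca_field(template, zones, np.asarray(zone_offsets),
                             seed=int(seeds[0]))
    dem = simulate_dem(template, seed=int(seeds[1]))
    if depression_depth > 0:
        gx, gy = template.cell_centers()
        cx = template.x_origin + n_cols * cell_size / 2
        cy = template.y_origin + n_rows * cell_size / 2
        r = np.hypot(gx - cx, gy - cy)
        r0 = 0.35 * min(n_cols, n_rows) * cell_size
        dem = template.like(dem.values
                            - depression_depth * np.exp(-(r / r0) ** 2))
    survey, corrupted = simulate_survey(
        eca, transect_spacing, along_step, noise_sd=noise_sd,
        erroneous_fraction=erroneous_fraction, seed=int(seeds[2]))
    samples, cmatrix, truth = simulate_soil_samples(
        zones, n_total=n_samples,
        zone_fertility_shifts=np.asarray(zone_fertility_shifts),
        seed=int(seeds[3]))
    truth.master_seed = seed
    truth.zone_offsets = np.asarray(zone_offsets, dtype=float)
    truth.zone_labels = zones.labels()
    truth.corruption_indices = corrupted
    return {
        "template": template,
        "true_zones": zones,
        "eca_field": eca,
        "dem": dem,
        "survey": survey,
        "corruption_indices": corrupted,
        "samples": samples,
        "category_matrix": cmatrix,
        "truth": truth,
    }
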