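# ecazones

Delineation and validation of vineyard management zones from soil
apparent electrical conductivity (ECa) surveys.

Site-specific vineyard management starts from a map of management zones
(MZs): subfield regions with similar permanent soil properties that can
be managed uniformly. A towed electromagnetic-induction sensor yields
thousands of georeferenced ECa readings (mS/m), a cheap proxy for
texture, moisture and cation exchange capacity. This package implements
the full workflow that turns such a survey into validated zones:

1. **Geostatistics** — cleaning of implausible readings, experimental
   variogram, spherical-model fitting by Cressie-weighted least squares,
   ordinary kriging with a local neighbourhood, and leave-one-out
   diagnostics. The ordinary-kriging predictor is
   Z\*(x) − m(x) = Σᵢ wᵢ(x)[Z(xᵢ) − m(xᵢ)] with weights solving the
   semivariance-form system under Σ wᵢ = 1; the spherical variogram is
   γ(h) = c₀ + c(1.5 h/a − 0.5 (h/a)³) for h ≤ a, with nugget c₀,
   partial sill c and range a.
2. **Zoning** — z-scored ECa + elevation stacks clustered by an
   iterative self-organising means procedure with fixed k, followed by a
   Gaussian maximum-likelihood classifier; zones are relabelled by
   ascending mean ECa (1 = least productive). Validation samples are
   allocated to zones proportionally to area (largest remainder).
3. **Soil fertility via the Rasch rating-scale model** — nine soil
   properties (sand, clay, silt, OM, pH, P₂O₅, K₂O, SEB, CEC) are
   recoded to five ordered categories and fused into a single latent
   "soil fertility" measure per sample:
   P(Xₙᵢ = k) ∝ exp Σ_{j<k}(Bₙ − dᵢ − τⱼ), estimated by joint maximum
   likelihood with Infit/Outfit mean-square diagnostics
   (acceptance band 0.6–1.5).
4. **Zone validation** — Kruskal–Wallis omnibus and Dunn post-hoc tests
   with a compact letter display, per-zone property means, and NDVI
   ((NIR − Red)/(NIR + Red)) zonal aggregation.

Because field campaigns of this kind are rarely deposited, the package
ships a first-class synthetic-data module that generates every input
with stored ground truth (stationary Gaussian ECa fields with a
spherical variogram, transect surveys with corrupted readings, a gentle
DEM, and zone-dependent latent fertility), so every stage is testable by
parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic vineyard (60×60 grid of 10 m cells, three concentric
zones, master seed 42) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_variogram_kriging.py
python analysis/03_zones.py
python analysis/04_rasch_fertility.py
python analysis/05_validate_zones.py
```

`02_variogram_kriging.py` prints

```
cleaning removed 125 implausible readings; 1675 remain (mean 44.2, median 42.9 mS/m, CV 55%, skewness 0.36)
spherical fit: nugget 165, partial sill 584, range 340 m; nugget/sill 22% -> strong spatial dependence
leave-one-out: rmse 15.03 vs data SD 24.33 (effective: True); mean standardised error 0.002
```

— the plausibility filter caught all 54 injected corrupt readings (plus
legitimate tail values), the fitted nugget/sill ratio of 22 % indicates
strong spatial dependence, and a leave-one-out RMSE below the data SD
means kriging predicts more accurately than the field mean would.
`03_zones.py` then reports the delineation and the field-campaign plan:

```
zone area fractions (least->most productive): [0.37, 0.43, 0.2]
agreement with generating truth: ARI 0.744
area-proportional allocation of 20 validation samples: [7, 9, 4]
```

and `04_rasch_fertility.py` fuses the 20 samples' soil properties into
one fertility measure per sample, all nine items fitting the model
(Infit/Outfit within 0.6–1.5), with zone means ordered with
productivity:

```
zone mean fertility (logits):
      mean_measure  n_samples
1        -0.816095          7
2        -0.234125          9
3         0.645729          4
```

`05_validate_zones.py` closes with the Dunn letter displays (the
fertility omnibus gives H = 9.23, p = 0.0099, zones 1 and 3 carrying
different letters at α = 0.01) and a per-zone NDVI table declining
monotonically through the season.

The same workflow is scriptable through the `ecazones` CLI
(`simulate`, `clean`, `variogram`, `krige`, `crossval`, `zones`,
`rasch`, `validate`, `ndvi`, `pipeline`), e.g.

```sh
ecazones pipeline --seed 42 --outdir results/run
```

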