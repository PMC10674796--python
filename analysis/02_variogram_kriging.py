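"""Clean the ECa survey, model its spatial structure and krige the map.

Reads results/data/, writes the fitted variogram, leave-one-out
diagnostics and the kriged ECa and standard-error rasters to
results/geostat/.
"""

import dataclasses
import json
from pathlib import Path

from ecazones import dataio, geostat

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "geostat"
    out.mkdir(parents=True, exist_ok=True)
    survey = dataio.read_point_survey(ROOT / "data" / "survey_raw.csv",
                                      variable_name="eca")
    survey, n_removed = dataio.clean_eca(survey, 0.0, 300.0)
    stats = geostat.summary_stats(survey)
    print(f"cleaning removed {n_removed} implausible readings; "
          f"{stats['n']} remain "
          f"(mean {stats['mean']:.1f}, median {stats['median']:.1f} mS/m, "
          f"CV {stats['cv_percent']:.0f}%, skewness "
          f"{stats['skewness']:.2f})")

    emp = geostat.empirical_variogram(survey)
    model = geostat.fit_variogram(emp)
    pct, cls = geostat.nugget_sill_ratio(model)
    print(f"spherical fit: nugget {model.nugget:.0f}, partial sill "
          f"{model.partial_sill:.0f}, range {model.range_m:.0f} m; "
          f"nugget/sill {pct:.0f}% -> {cls} spatial dependence")

    cv = geostat.loo_cross_validation(survey, model)
    print(f"leave-one-out: rmse {cv.rmse:.2f} vs data SD "
          f"{cv.data_sd:.2f} (effective: {cv.rmse_below_data_sd}); "
          f"mean standardised error {cv.mean_standardised_error:.3f}")

    dem = dataio.read_raster(ROOT / "data" / "dem.asc")
    est, se = geostat.ordinary_kriging(survey, model, dem)
    dataio.write_raster(out / "eca_kriged.asc", est)
    dataio.write_raster(out / "eca_se.asc", se)
    (out / "variogram.json").write_text(json.dumps(
        {**model.to_dict(), "nugget_sill_percent": pct,
         "dependence_class": cls}, indent=2))
    (out / "crossval.json").write_text(
        json.dumps(dataclasses.asdict(cv), indent=2))
    survey.write(out / "survey_clean.csv")
    print(f"kriged {est.shape[0]}x{est.shape[1]} ECa map written to {out}")


if __name__ == "__main__":
    main()
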