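"""Generate the synthetic vineyard used by the downstream analyses.

Writes the raw ECa survey (with corrupted readings left in), the DEM,
the soil-sample table and the ground-truth record to results/data/.
"""

from pathlib import Path

from ecazones import dataio
from ecazones.synthetic import default_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scen = default_scenario(seed=SEED)
    scen["survey"].write(OUT / "survey_raw.csv")
    dataio.write_raster(OUT / "dem.asc", scen["dem"])
    dataio.write_raster(OUT / "eca_true.asc", scen["eca_field"])
    dataio.write_raster(OUT / "zones_true.asc", scen["true_zones"].grid,
                        precision=1)
    scen["samples"].to_csv(OUT / "samples.csv", index=False)
    scen["truth"].to_json(OUT / "truth.json")
    v = scen["eca_field"].values
    print(f"seed {SEED}: survey of {len(scen['survey'])} ECa readings "
          f"({len(scen['corruption_indices'])} corrupted), "
          f"field mean {v.mean():.1f} mS/m, CV {100*v.std()/v.mean():.0f}%")
    print(f"wrote survey, DEM, true field/zones, {len(scen['samples'])} "
          f"soil samples and truth.json to {OUT}")


if __name__ == "__main__":
    main()
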