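"""Run the whole analysis from files on disk, the way the CLI does.

Writes a synthetic city (raster + world file, GeoJSON boundary/tracts,
indicator CSV), runs every stage, and prints the run manifest summary.
Equivalent shell usage:

    urbanhealth generate --out city --seed 1 --tile-size 32 --grid 20
    urbanhealth run --config city/pipeline.toml
"""

import tempfile
from pathlib import Path

from urbanhealth.pipeline import PipelineConfig, run_pipeline
from urbanhealth.synthetic import SyntheticCityConfig, generate_city, write_city

with tempfile.TemporaryDirectory() as tmp:
    city = generate_city(
        SyntheticCityConfig(raster_rows=32 * 20, raster_cols=32 * 20, tile_size=32, n_tracts=60, seed=1)
    )
    paths = write_city(city, Path(tmp) / "city")
    manifest = run_pipeline(
        PipelineConfig(
            raster_path=str(paths["raster"]),
            boundary_path=str(paths["boundary"]),
            tracts_path=str(paths["tracts"]),
            indexes_path=str(paths["indexes"]),
            tile_size=32,
            out_dir=str(Path(tmp) / "out"),
        )
    )
    print(f"tiles: {manifest['n_tiles']} total, {manifest['n_kept']} kept")
    print(f"chosen K: {manifest['chosen_k']}")
    print("stages:", ", ".join(manifest["stages"]))
    print("artifacts written:")
    for name, entry in manifest["artifacts"].items():
        print(f"  {name}: {Path(entry['path']).name}")
# every artifact is a plain text format (CSV/GeoJSON/JSON) listed with a
# SHA-256 checksum in run_manifest.json; same config + seeds => same checksums
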