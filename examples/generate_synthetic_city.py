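"""Generate a synthetic city and inspect its planted structure.

The city is a georeferenced raster assembled from four landscape
archetypes (green, small houses, industrial, large buildings), a tract
partition of the boundary, and per-tract health indicators whose means
follow a monotone gradient across the archetypes.
"""

from urbanhealth.synthetic import GRADIENT_INDICATOR, SyntheticCityConfig, generate_city

config = SyntheticCityConfig(
    raster_rows=32 * 20, raster_cols=32 * 20, tile_size=32, n_tracts=60, seed=1
)
city = generate_city(config)

print(f"raster: {city.raster.rows} x {city.raster.cols} px at {config.gsd} m/px")
print(f"tracts: {len(city.tracts.tract_ids)}, boundary area {city.boundary.area:.0f} m^2")
print(f"tile grid: {city.truth_labels.shape}, archetypes {sorted(int(a) for a in set(city.truth_labels.ravel()))}")

means = city.tracts.values.groupby("dominant_archetype")[GRADIENT_INDICATOR].mean()
print(f"\nmean {GRADIENT_INDICATOR} by dominant archetype (planted gradient):")
for arch, m in means.items():
    print(f"  archetype {arch}: {m:.2f}")
# the gradient indicator rises from green areas (1) to large buildings (4),
# the structure the association statistics are expected to detect
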