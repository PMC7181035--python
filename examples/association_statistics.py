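"""Relate cluster membership to tile-level health indexes.

Tertile chi-squared tests, univariate multinomial odds ratios against the
green-areas cluster, and backward stepwise AIC over tertile-dummy groups.
"""

import numpy as np
import pandas as pd

from urbanhealth.areal import link_blocks
from urbanhealth.clustering import kmeans_grid_search
from urbanhealth.embedding import baseline_extractor, extract_features, greenness
from urbanhealth.stats import (
    backward_stepwise_aic,
    chi2_summary_table,
    discretize_tertiles,
    fit_multinomial,
    tertile_dummies,
)
from urbanhealth.synthetic import SyntheticCityConfig, generate_city
from urbanhealth.tiling import filter_tiles, split_raster

city = generate_city(
    SyntheticCityConfig(raster_rows=32 * 20, raster_cols=32 * 20, tile_size=32, n_tracts=60, seed=1)
)
kept = filter_tiles(split_raster(city.raster, 32), city.boundary)
blocks = link_blocks(kept, city.tracts)
features = extract_features(kept, baseline_extractor())
green = np.array([greenness(t) for t in kept])
labels = kmeans_grid_search(features, seed=0, greenness_scores=green).labels

indicators = [c for c in city.tracts.indicators if c != "dominant_archetype"]

print("tertile chi-squared tests (cluster x tertile independence):")
print(chi2_summary_table(blocks, labels, indicators).round(2).to_string(index=False))

fit = fit_multinomial(blocks[[indicators[0]]], labels, baseline=1)
print(f"\nunivariate multinomial ORs for {indicators[0]} (baseline = cluster 1):")
print(fit.table[fit.table["term"] == indicators[0]].round(3).to_string(index=False))

groups, dummies = {}, []
for ind in indicators:
    _, cats = discretize_tertiles(blocks[ind].to_numpy())
    dd = tertile_dummies(cats, ind)
    dummies.append(dd)
    groups[ind] = list(dd.columns)
selected, final, log = backward_stepwise_aic(groups, pd.concat(dummies, axis=1), labels)
print(f"\nstepwise AIC retained: {selected}")
print(log.to_string(index=False))
# ORs > 1 for higher tertiles mean tiles with worse indicator values are
# more likely to fall in the built-up clusters than in the green cluster
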