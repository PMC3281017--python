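"""Generate a synthetic municipality landscape and inspect its pieces.

Builds a 12x12 grid of municipalities (9 districts), draws road lengths,
climate/land-use/browsing covariates, two years of collision counts, a
sapling browsing survey and district harvest numbers, and prints a few
summaries.  Every quantity has a known ground truth, returned alongside.
"""

import dvcrisk as d

cfg = d.LandscapeConfig(grid_rows=12, grid_cols=12, district_block=4, seed=42)
munis, graph = d.generate_landscape(cfg)
collisions, truth = d.simulate_collisions(munis, cfg)
survey, survey_truth = d.simulate_browsing_survey(graph, cfg)
harvest = d.simulate_harvest(munis, d.true_dvc_index(munis, cfg), cfg)

print(f"{len(munis)} municipalities in {graph.number_of_nodes()} districts "
      f"({graph.number_of_edges()} adjacencies)")
print(f"{len(collisions)} collision rows (municipality x road type x year), "
      f"{collisions['count'].sum()} collisions in total")
print("\nmean road length (km) per municipality where present:")
for rt in d.ROAD_TYPES:
    lengths = munis.loc[munis[f"length_{rt}"] > 0, f"length_{rt}"]
    print(f"  {rt:12s} {lengths.mean():6.1f} km in {len(lengths):3d} municipalities")
print("\ncollisions per km by road type (2006, crude):")
sub = collisions[collisions["year"] == 2006]
print(sub.groupby("road_type").apply(
    lambda g: g["count"].sum() / g["road_length"].sum(), include_groups=False
).round(3).to_string())
print(f"\nbrowsing survey: {len(survey)} district x class cells, "
      f"{survey['n_examined'].sum()} saplings examined")
print(f"harvest: {len(harvest)} districts, "
      f"{harvest['harvest_per_100ha'].mean():.1f} deer per 100 ha on average")
# Crude per-km rates differ by road type (motorways lowest: fencing);
# the truth table carries each row's log-linear predictor decomposition.
print("\ntruth columns:", ", ".join(truth.columns[:8]), "...")
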