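"""Generate a synthetic study area and inspect its layers.

Builds a square region with school sites, a lattice street network, OA
centroids nested in LSOAs, transit stops, and a 41-quarter outlet history
with known drift, then prints the layer sizes and the first/last quarterly
counts — the ground truth the forecasting stage should recover.
"""

from zonecast import SyntheticConfig, generate_commute_flows, generate_outlet_history, generate_region

cfg = SyntheticConfig(seed=7)
region = generate_region(cfg)
history = generate_outlet_history(cfg, region)
flows, mode_shares = generate_commute_flows(cfg, region)

counts = history.groupby("quarter").size()
print(f"schools:            {len(region.schools)}")
print(f"street network:     {region.network.number_of_nodes()} nodes, "
      f"{region.network.number_of_edges()} edges")
print(f"OA centroids:       {len(region.oa_centroids)} in "
      f"{region.oa_centroids.lsoa_id.nunique()} LSOAs")
print(f"outlet count:       {counts.iloc[0]} in {history.label.iloc[0]} -> "
      f"{counts.iloc[-1]} in {history.label.iloc[-1]}")
print(f"commuters:          {flows['count'].sum()} over {len(flows)} OA pairs")
# The configured drift is 2 outlets/quarter: over 40 quarters the count should
# climb by roughly 80 outlets around the configured noise.
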