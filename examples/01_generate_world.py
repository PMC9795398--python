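"""Generate a synthetic food-environment world and inspect its ground truth.

A world bundles the four analysis inputs (business listings, nutrition
records, popular dishes, obesity rates) with the planted truth that
produced them: each region's true caloric environment score drives its
obesity rate linearly. Downstream examples recover that link.
"""

from foodenv.synthetic import default_config, generate_world

# a scaled-down world (12 regions, 200 businesses each) for a quick look;
# drop the overrides to get the full 50-region study-scale default
config = default_config(seed=42, n_regions=12, businesses_per_region=200)
world = generate_world(config)

print(f"businesses:        {len(world.businesses)}")
print(f"nutrition records: {len(world.nutrition)}")
print(f"categories:        {len(config.categories)}")
print()
print("region  true env. score (kcal/g)  obesity rate (%)")
for region, row in world.truth.iterrows():
    print(f"  {region}    {row.environment_score:20.3f}  {row.obesity_rate:14.1f}")

# The environment score is the category-mix-weighted mean caloric
# density of the region's food scene; obesity is intercept + slope*score
# + noise, so high-score regions should show visibly higher rates above.
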