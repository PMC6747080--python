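# netpatterns

Network-constrained point pattern analysis for urban health geography.

Health care facilities, patients, crashes and street crimes do not live on
a featureless plane — they sit on or beside a road network, and the
distance that matters between them is the shortest path along that
network. `netpatterns` provides the three analyses this setting calls for,
all in the network metric:

* **Network kernel density estimation (NetKDE)** — hot spots of weighted
  facility intensity along the streets,
  `λ(s) = Σᵢ (1/r)·(1/√2π)·exp(−disᵢ²/2r²)·wᵢ` for events within the
  network-distance bandwidth `r`, with hospital bed numbers (or fixed tier
  weights) as `wᵢ`;
* **Network auto / cross K-functions** — `K(t|pᵢ) = n(t|pᵢ)/ρ`,
  `ρ = (n−1)/S̃` on a network of total length `S̃`, tested against Monte
  Carlo envelopes of complete spatial randomness (points uniform on the
  edge set) and classified per distance as clustered / random / dispersed;
* **Geodetector** — the spatial-stratified-heterogeneity statistic
  `q = 1 − Σₕ Nₕσₕ²/(Nσ²)` over Jenks-stratified covariates (exact
  Fisher–Jenks dynamic program), with a permutation significance test and
  the two-factor interaction detector comparing `q(A∩B)` against `q_A`,
  `q_B`, `max(q_A,q_B)` and `q_A+q_B`.

A seeded synthetic city generator (grid-with-gaps street fabric, hot-spot
populations, four facility tiers, patients clustered around facilities by
network-distance decay) makes the whole pipeline runnable and testable
without any external data. See `docs/methods.md` for the models,
conventions and limitations.

## Worked example

```python
import numpy as np
from netpatterns import *

cfg = CityConfig(seed=7)                       # default synthetic city
net, communities, facilities, patients = generate_city(cfg)

lixels = lixelize(net, 100.0)                  # 100 m evaluation units
fields = {tier: estimate_density(net, pts,
                                 1000.0 if tier == "hospital" else 500.0,
                                 lixels)
          for tier, pts in facilities.items()}

table = community_table(communities, net, fields)
pop = table["pop_density"].to_numpy()
y = table["agg_total"].to_numpy()
strata = stratify(pop, jenks_breaks(pop, 5))
print(f"q(population density) = {q_statistic(y, strata).q:.3f}, "
      f"permutation p = {permutation_p(y, strata, 999, rng=7):.4f}")

road = table["road_density"].to_numpy()
res = interaction(y, strata, stratify(road, jenks_breaks(road, 5)))
print(f"q(pop ∩ road) = {res.q_ab:.3f} -> {res.category}")

t = np.linspace(0, min(10_000, 0.5 * net.diameter()), 50)
obs = cross_k(net, facilities["hospital"], patients, t)
env = envelope(net, len(patients), t, 200, 0.05, 7,
               mode="cross", base=facilities["hospital"])
lab = classify_pattern(obs, env)
print(f"hospitals vs patients: {lab.summary} over "
      f"t in [{lab.summary_t_range[0]:.0f}, {lab.summary_t_range[1]:.0f}] m")
```

prints

```
q(population density) = 0.092, permutation p = 0.0730
q(pop ∩ road) = 0.391 -> nonlinear-enhance
hospitals vs patients: clustered over t in [612, 10000] m
```

Read: stratifying communities by population density explains ~9% of the
variance in aggregate facility intensity (borderline at this city size);
population and road density together explain far more than either alone
(nonlinear enhancement); and patients are significantly closer to
hospitals along the network than uniform chance would put them at
essentially every distance beyond ~600 m.

The same workflow runs from the shell:

```sh
netpatterns simulate --seed 7 --outdir data/
netpatterns netkde --lines data/roads.geojson --points data/facilities.geojson \
    --weight-field weight --bandwidth 1000 --lixel 100 --cell 100 -o density.asc
netpatterns autok --lines data/roads.geojson --points data/facilities.geojson \
    --tmax 10000 --sims 1000 --seed 7 -o autok.csv
netpatterns geodetect --table report/communities.csv --y agg_total \
    --factors pop_density,road_density --classes 5 --perm 999 --seed 7
netpatterns pipeline --config pipeline.yaml --outdir report/
```

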