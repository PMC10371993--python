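# oceanconn

Eulerian connectivity tracers and plankton community linkage.

Pelagic habitats have no visible borders, yet plankton communities differ
sharply across fronts and jets. `oceanconn` quantifies how strongly two
patches of ocean are connected by water movement, and tests whether that
connectivity — rather than plain geographic distance — explains observed
differences in plankton community composition. It is aimed at biological
oceanographers and community ecologists who have (or can simulate) a velocity
field over a study region and a table of per-sample species abundances.

## The method

**Connectivity tracers.** For each subdomain Ω_i of the study area a passive
tracer φ_i is initialised to 1 inside Ω_i and 0 elsewhere, then advected and
diffused with no internal sinks or sources. The space–time integral of tracer
i over subdomain j,

    Φ_ij = ∫_{Ω_j} ∫_0^t φ_i dt dΩ,

normalised by the initial tracer amount ∫_{Ω_i} φ(0) dΩ = A_i, gives the
**exposure time**

    T_ij = Φ_ij / A_i   (days),

the time material from Ω_i spends inside Ω_j, counting re-entries (so always
≥ the residence time). Normalising by target area and a dispersal time scale
τ yields the **connectivity matrix**

    P_ij = T_ij / (A_j τ)   (m⁻²),

a relative transit probability per unit target area.

**Community linkage.** Sample dissimilarity is Bray–Curtis on raw abundances,
BC_ij = Σ_n |s_ni − s_nj| / Σ_n (s_ni + s_nj). Both the community
dissimilarities and the (symmetrised, max-scaled) connectivity
dissimilarities are embedded by 2-D non-metric MDS (Kruskal stress-1,
isotonic regression, multiple restarts). Group structure is tested with
ANOSIM permutation tests. For every focal subdomain, the mean community-NMDS
distance to each other sampled subdomain is regressed on (a) the
connectivity-NMDS distance and (b) the mean great-circle distance between the
samples; comparing the two R² columns answers which explains community
similarity better.

A fully synthetic world (shelf-edge jet dispersal barrier, 4×5 subdomains,
nine phytoplankton taxa) exercises the whole chain without any external data.

## Worked example

```python
import numpy as np
import oceanconn as oc

scen = oc.build_scenario("barrier_jet", seed=1)       # jet + return flow world
expo, conn = oc.run_connectivity(scen)                # tracers -> T and P
print(np.diag(expo.T).min(), np.diag(expo.T).max())   # 1.04 15.11

model = oc.default_community_model(scen, samples_per_domain=5)
table = oc.synth_communities(model, conn, seed=2)     # 100 samples, 9 taxa
deep  = oc.filter_by_depth(table, 20.0)               # keep samples > 20 m
bc    = oc.bray_curtis(deep)
eco   = oc.nmds2(bc, seed=3)
connd = oc.nmds2(oc.connectivity_to_dissimilarity(conn), seed=3)
assign = oc.assign_domains(deep, scen.subdomains, scen.grid, scen.georef)
link  = oc.explainers_table(eco, connd, deep, assign)
print(link.df[["domain", "N", "r_squared_connectivity", "r_squared_physical"]].head())
```

Running the equivalent end-to-end script (`python scripts/acceptance.py
--seed 1 --out results/acceptance.json`) prints:

```
no-flow limit: T_ii = 31.0 d, P_ii = 1/A_i  [ok]
barrier jet: exposure times 1.04-15.11 d (mean 6.53 d) over 20 domains
n=63 deep samples | community NMDS stress 0.121 | connectivity NMDS stress 0.053
sector ANOSIM: R = 0.56, p = 0.0001
linkage: connectivity R2 beats physical R2 in 95% of 20 focal domains
```

Reading the numbers: subdomains under the jet flush in about a day (short
exposure times), the quiet shallow sector retains water for two weeks; deep
samples group strongly by bathymetric sector (ANOSIM R = 0.56 at the
permutation floor p = 10⁻⁴); and in a world where communities really are
mixed by the flow, connectivity out-explains geographic distance in almost
every focal subdomain — the method recovers the mechanism that generated the
data.

The script recomputes everything from scratch at the given seed: the no-flow
analytic limit of the tracer pipeline, the barrier-jet connectivity matrices,
a synthetic community survey, both ordinations, the sector ANOSIM and the
per-domain regression table, then writes its JSON result file to `--out`.

## Command line

```bash
oceanconn synth  --scenario barrier_jet --seed 1 --out samples.csv
oceanconn trace  --scenario barrier_jet --outdir matrices/
oceanconn analyze --table samples.csv --scenario barrier_jet --outdir analysis/
oceanconn pipeline --scenario barrier_jet --outdir run/     # all stages
```

`pipeline` writes exposure/connectivity matrices (labelled CSV), both
ordinations with stress metadata, ANOSIM results, the per-domain linkage
table and a manifest with the config hash and all seeds; reruns with the same
config are byte-identical.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
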