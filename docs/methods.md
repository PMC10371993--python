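# Methods

This note documents the models implemented in `oceanconn`, the choices made
where the design was genuinely open, and what the synthetic tests do and do
not establish.

## Connectivity tracers

Connectivity between fixed subdomains is measured with passive Eulerian
tracers: φ_i starts at 1 inside source subdomain Ω_i and 0 elsewhere and is
transported with no internal sources or sinks. Three quantities follow:

* **Integrated tracer** Φ_ij = ∫_{Ω_j}∫_0^t φ_i dt dΩ (d·m² in the
  depth-integrated 2-D convention). The infinite time integral is
  approximated over a finite window (default 31 d); this is adequate when
  neighbouring domains are reachable well within the window, and it bounds
  every exposure time by the window length.
* **Exposure time** T_ij = Φ_ij / A_i (days), where A_i = ∫_{Ω_i} φ(0) dΩ is
  the initial tracer amount. T counts re-entries, so T ≥ residence time, with
  equality when nothing returns (verified in the tests against a hand-built
  linear-system oracle).
* **Connectivity** P_ij = T_ij / (A_j τ) (m⁻²), a relative transit
  probability per unit target area over the dispersal time scale τ. τ only
  rescales P; it is kept at the integration window (31 d) by default.

A consistency anchor between the 2-D bookkeeping and 3-D volumetric units:
a stationary unit tracer (1 m⁻³) filling a 50 m surface layer for 31 days
has a column-integrated value of 1·50·31 = 1550 d m⁻².

The diagonal exposure time admits a well-mixed flushing reading: treating
T_ii as the e-folding time of exponential renewal, the fraction of water
replaced after time t is 1 − exp(−t/T_ii) (`replacement_fraction`). This is
an interpretive device, not part of the tracer definitions.

## Transport scheme

First-order upwind advection in flux form plus explicit centred diffusion on
a uniform Cartesian grid. Rationale: the scheme is exactly conservative
(closed boundaries conserve mass to round-off; verified to 10⁻⁹ relative
over 10⁵ steps) and positivity-preserving, and its numerical diffusion is
acceptable because all downstream statistics are domain integrals. Open
boundaries are zero-gradient outflow with no re-entry; the diffusive boundary
flux is zero.

Stability: the step refuses advective Courant numbers above 0.5 per
direction or diffusion numbers K·dt·(1/dx²+1/dy²) above 0.25, naming the
offending ratio. The automatic step (`stable_dt`) additionally caps the
combined outgoing-Courant-plus-diffusion load at 0.9, which makes the update
strictly positive, and is bounded above by 600 s. The integration window is
divided into an integer number of equal steps so analytic limits (e.g. the
no-flow case) hold exactly.

Time is seconds internally; the accumulator and all reported exposure times
are in days. The space–time integral uses a rectangle rule on post-step
fields; all tracers advance together as one stacked array since they share
the flow.

## Community statistics

* **Bray–Curtis** on raw abundances, no standardisation or transformation.
  Pairs of all-zero samples are an error, not a silent 0/0.
* **NMDS**: 2-D configurations minimising Kruskal stress-1
  √(Σ(d−d̂)²/Σd²), where d̂ is the isotonic (pool-adjacent-violators)
  regression of configuration distances on the dissimilarity order. Ties in
  the input dissimilarities are pooled (tied values share one disparity).
  Optimisation is SMACOF-style majorisation; an iterate that would increase
  stress-1 terminates the run, so the recorded stress sequence is
  non-increasing by construction. The first start is classical scaling
  (deterministic and label-equivariant), followed by 19 seeded random starts
  by default; the best solution is centred, rotated to principal axes and
  sign-fixed for reproducibility. Convergence: stress change < 10⁻¹⁰ or 500
  iterations. NMDS solutions are not unique; the implementation is
  cross-checked against an independent library only through its achieved
  stress (within 5%), not coordinates.
* **ANOSIM**: R = (mean between-group rank − mean within-group rank)/(M/2)
  with average ranks for ties. p-values either by seeded label permutation
  with the +1 correction, p = (1+#{R* ≥ R})/(n_perm+1), or by exhaustive
  enumeration of all distinct label assignments when that count is at most
  the requested permutation count (the identity assignment is included, so
  exact p ≥ 1/N). Default 9999 permutations.
* **Welch t and OLS** delegate to scipy (`ttest_ind(equal_var=False)`,
  `linregress`); two-sided p-values throughout.

## Linking communities to connectivity

The connectivity matrix is asymmetric and not a metric; for ordination it is
symmetrised, S = (P+Pᵀ)/2, and converted to D = 1 − S/max(S) with zero
diagonal. This transform is one defensible choice among several and is
recorded in every output metadata sidecar — distances in connectivity-NMDS
space should not be assumed comparable across transforms.

The linkage procedure: samples strictly deeper than 20 m are retained
(boundary samples excluded); each sample is assigned to the subdomain whose
mask contains it, with out-of-mask samples snapped to the nearest subdomain
centroid and flagged; per domain pair, the mean Euclidean distance in the
community NMDS over all cross sample pairs is the ecological distance
between the domains. Per focal domain, these means are regressed
(unweighted OLS) on the connectivity-NMDS distance and, separately, on the
mean great-circle distance (haversine, R = 6371.0 km) between the samples.
Open choices resolved here: haversine rather than planar distance for the
physical explainer; unweighted regressions (no weighting by pair counts or
standard errors); p-values reported per row without multiple-testing
correction, with 0.05/0.01 significance stars.

## The synthetic world

The generator states one world and keeps it fixed:

| Parameter | Default | Why |
|---|---|---|
| Grid | 40×40 cells, dx = dy = 3.7 km | mesoscale-resolving box (~148 km) at a typical shelf-model resolution |
| Subdomains | 4 sectors × 5 tiles (NT/SL/SE/SH × 1–5) | four bathymetric bands, five along-shelf tiles, each ~½° longitude wide |
| Jet | eastward, 0.25 m s⁻¹ peak, 18 km width, centred on the SE band | shelf-edge current; makes the band a dispersal barrier |
| Return flow | westward, −0.12 m s⁻¹, over the NT band | cyclonic recirculation over the trench |
| Diffusivity K | 100 m² s⁻¹ (2000 for `well_mixed`) | mesoscale lateral eddy diffusivity |
| Window / τ | 31 d | one month of stratified-season dispersal |
| Species | 9 named phytoplankton taxa | the taxa used to characterise summer communities in such surveys |
| Samples | 6 per domain (~120 total), depths uniform 5–50 m | survey-scale sampling |
| Noise | lognormal σ = 0.6 (log scale, mean-preserving), then Poisson counts in a 50 mL settling chamber | environmental patchiness plus counting error; σ is a free parameter, not a field-calibrated value |

Communities: each sector has a distinct base community B (cells L⁻¹,
hundreds to tens of thousands, with a shallow-sector *C. lineatum* /
*K. mikimotoi* bloom and a deep sector richer in *P. alata* and
*C. longipes*). In `connectivity` mode the expected composition of a sample
in domain j is Σ_i W_ij B_i with W column-normalised from P over sources —
the water arriving at j carries the communities of the domains it came from.

The negative control (`distance_decay` mode) must contain *no* flow
information: expected log-abundances are drawn per seed as a Gaussian random
field over domain centroids with covariance exp(−d/40 km), so community
similarity decays with geographic distance by construction. A first design
that merely replaced the mixing weights with distance weights was discarded
because it retained the sector block structure of the base communities and
therefore still carried the barrier signal; the ledgered redesign draws the
communities from the distance-decay law directly.

What a green recovery test establishes: that the full chain (tracers →
connectivity → ordinations → per-domain regressions) recovers the generating
mechanism — connectivity wins when connectivity made the data, and the
advantage collapses to chance under the control. What it does not establish:
anything about a real ocean. The synthetic world has rectangular subdomains,
steady barotropic flow, passive communities with no growth, grazing or
nutrient limitation, and noise of assumed magnitude. In the control world
the connectivity and distance explainers are strongly correlated (the
barrier flow itself has a distance-decay component), so the control contest
is a fair coin, not a physical-distance victory.

## Known limitations

* First-order upwind transport is diffusive; absolute exposure times carry
  O(dx) bias, though domain-integrated contrasts are robust (grid-refinement
  behaviour is tested).
* The finite integration window truncates exposure of weakly connected,
  distant domain pairs.
* The connectivity-to-dissimilarity transform is a convention; ANOSIM/NMDS
  results on connectivity space depend on it.
* The equirectangular georeference is adequate only for O(100 km) study
  boxes at mid-latitudes.
* Exposure times in the quiet sector of the synthetic world (no advection,
  weak diffusion, open boundary) approach the window length — longer than
  typically observed over real shallow shelves, where tides and wind mixing
  flush faster.
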