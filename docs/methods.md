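# Methods

## Surface-erosion model

The kinetics module assumes zero-order surface erosion: microbial
depolymerases act only at the polymer–water interface, so a specimen of
uniform thickness loses mass at a constant rate per unit exposed area and
its thickness declines linearly until exhaustion. The summary statistic is

    V = ΔW · 10⁶ / A / t      [μg cm⁻² day⁻¹],

with ΔW the mass loss (g), A the initial surface area (cm²) and t the
exposure (days). The factor 10⁶ is the g→μg conversion written out
explicitly; the residual-weight model and the lifetime inversion

    residual(%) = 100 − V·S·t·10⁻⁶/m × 100,    t* = m·10⁶ / (V·S)

carry the inverse factor so the three operations compose exactly (the
round-trip is asserted to 1e−9 in the property suite). The residual weight
is clamped at zero by default because the linear model continues below zero
after complete degradation; `clamp=False` exposes the raw line.

**Area conventions.** Thin films and bags count both faces of every panel
and ignore edges: the default 18 × 42 cm two-panel bag gives
S = 2 · 2 · 18 · 42 = 3024 cm² exactly. For injection-moulded bars
(0.4 cm thick) edge faces contribute ~10% of the area and the holder
exposes all six faces to seawater as far as we can tell, so
`initial_surface_area` includes edges by default for that form; the choice
is a documented guess and can be overridden per call.

**Lifetime bounds.** Replicate rates are summarised as mean, sample SD
(n−1 denominator; SD 0 at n = 1), min and max. Lifetimes default to the
`slowest` replicate rate — the conservative bound — with `fastest` and
`mean` available. V ≤ 0 yields an infinite-lifetime sentinel, not an
exception, because inert polymers are an expected outcome, and raw
(unrounded) days are returned.

**Erosion consistency.** For pure face-normal erosion the fractional
weight-loss rate equals the fractional thinning rate, so their ratio is 1.
Ratios above 1 indicate mass leaving other than through face retreat
(through-holes, edge attack); the simulator's `perforation_fraction`
produces exactly ratio 1 + f for validation. Degenerate cases: no
degradation at all reports ratio 1 with a `no-degradation` flag; weight
loss with zero thinning reports +inf.

## BOD biodegradability

Theoretical oxygen demand for a monomer unit CxHyOz of molar mass M:

    ThOD(mg) = w/M · (4x + y − 2z)/4 · 32,

the stoichiometric O2 for complete oxidation to CO2 and H2O. The model is
C/H/O only by construction: the assay medium contains allylthiourea, a
nitrification inhibitor, so reduced nitrogen draws no oxygen, and
N-containing formulas raise an explicit error rather than being silently
truncated. M is user-supplied (hydrates and copolymer conventions stay with
the user); a helper computes it from conventional atomic weights
(C 12.011, H 1.008, O 15.999) to ±0.01 g/mol. Random copolymers use the
mole-fraction-weighted average of (x, y, z, M), which leaves ThOD invariant
for the homopolymer case by linearity.

Biodegradability is (BODs − BODb)/ThOD × 100 applied pointwise after the
blank series is linearly interpolated onto the sample day grid;
extrapolation beyond the blank grid is refused (truncation with warning),
and no smoothing is applied. Values above 100% (priming) are flagged, not
clamped; negative values (blank above sample) are returned with a warning.
The curve summary reports the plateau (mean of the last three points) and
the first day reaching 90% of it.

## Community statistics

**Marker profiles.** The single-copy ribosomal protein S3 (RpsC) provides
one marker per genome, so relative frequencies follow from weighting each
marker by scaffold read coverage × protein length and normalising over the
community. "Coverage of an ORF" always means the read coverage of the
scaffold carrying it. Records intended for phylogenetic placement are
filtered at coverage > 10 and length > 150 residues, both strict, so
boundary records are excluded.

**Proteome proxies.** The pooled amino-acid composition is the
coverage-weighted sum of residue counts over all ORFs; ambiguity symbols
(X, B, Z, U, J, O, *) are excluded from numerator and denominator and their
weighted mass reported. From the pooled composition:

* F_IVYWREL — the fraction of Ile/Val/Tyr/Trp/Arg/Glu/Leu residues, mapped
  to an optimal growth temperature by the empirical line
  T_opt(°C) = F_IVYWREL × 937 − 335. The map is not clamped; compositions
  outside the natural range produce flagged, physically absurd
  temperatures (the intercept is −335 °C). Pooling is residue-level
  (community-wide), not a per-ORF mean.
* Z_C — the average carbon oxidation state
  (Z + 2(nO+nS) + 3nN − nH)/nC with Z = 0 for uncharged proteins.
  Community Z_C weights each protein's numerator and carbon count by
  coverage, which equals Z_C of the pooled atom inventory. Elemental
  bookkeeping uses per-residue (dehydrated) formulas plus one H2O per
  chain for the termini by default; `residue_only` drops the water, a
  choice that shifts per-protein Z_C by O(1/length) and is the natural
  convention when comparing against mixture-level expectations.

**Diversity.** Shannon entropy is reported in nats (a base option exists);
Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined even
without doubletons. Coverage-based rarefaction standardises samples at
equal estimated completeness: Good's coverage C = 1 − F1/n, extended to a
subsample of depth m through the hypergeometric expectation of F1(m); the
smallest m whose expected coverage reaches the target (default 0.99) is
found by binary search and one seeded multivariate-hypergeometric
subsample is drawn there. Samples whose full-depth coverage is below the
target cannot reach it and are dropped with a warning. Note that samples
*above* the target are subsampled down to the standardisation depth — the
point of the method is equal coverage, not a quality floor. The
diversity–rate association uses Spearman rank correlation, robust to the
nonlinear but monotone relation expected between colonisation diversity
and degradation rate; constant inputs return a NaN sentinel.

## Synthetic data

Generators are pure functions of (scenario, seed) and always return a
ground-truth sidecar; their defaults encode the deployment conditions the
analyses assume.

* **Erosion** — thickness(t) = d0 − 2·r·t (both faces, truncated at 0),
  weight = ρ·L·W·thickness. Default scenario: a 4 × 4 cm, 300 μm PHA film
  (ρ = 1.20 g/cm³) eroding at r = 0.75 μm/day/face at the shore
  (V = 100·ρ·r = 90 μg/cm²/day), attenuated ×0.18 at ~1000 m and ×0.05 at
  ~5000 m, deployed for 61/95/250/139/390 days with n = 4 replicates —
  the magnitudes and site/period structure of seafloor PHA campaigns.
  Replicate rates vary by a mean-corrected lognormal factor of CV 4%
  (film-to-film variability from moulding and geometry tolerances — small
  enough that a 4-replicate mean recovers V within 5% with margin, the
  recovery guarantee the generator is designed to support); weighings carry
  0.5 mg Gaussian noise (a 4-decimal balance), thickness readings 2 μm.
  `perforation_fraction` adds proportional extra mass loss to exercise the
  consistency diagnostic.
* **BOD** — BODs(t) = BODb(t) + p·ThOD·(1 − e^(−k·max(0, t−lag))) with a
  linearly drifting blank (0.02 mg/day) and 0.05 mg reading noise;
  defaults k = 0.15/day, lag 2 days, 30 days — roughly one-month complete
  mineralisation of a PHA in coastal seawater.
* **Metagenome** — taxa of equal genome size (equal ORF counts) with
  scaffold coverage ∝ abundance (lognormal noise σ = 0.5), protein lengths
  uniform on 100–400, sequences drawn residue-wise from per-taxon
  frequency vectors (typical bacterial proteome frequencies, tilted in
  IVYWREL and acidic residues so taxa differ in both proxies). Exactly one
  RpsC per taxon, 230 aa, on a low-noise scaffold (σ = 0.02; marker
  scaffolds are long and well covered, and large marker-coverage noise
  would make single-copy profiling uninformative at 4 taxa). Ground truth:
  the abundance-weighted mixture composition and its analytic F_IVYWREL
  and Z_C (chain-residue convention).
* **ASV tables** — counts ~ Multinomial(depth, p),
  p ~ Dirichlet(θ·base) with θ = base_diversity/(1 + rate_effect·rate) and
  a geometric (ratio 0.97) rank-abundance base over 150 taxa; rates
  uniform on 0–120 μg/cm²/day, depth 5000, n = 50. Fast-degrading surfaces
  thus carry low-diversity, dominated communities, reproducing the
  negative diversity–rate association.

**What the simulators do not emulate:** real read-level error, assembly
chimerism or fragmentation, taxon-specific genome size and ORF length
distributions, compositional correlation between neighbouring ORFs,
biofilm succession in time, or fouling mass gain. Passing recovery tests
therefore shows the estimators are correct under the stated generative
assumptions, not that field data meet those assumptions.

## Numerical choices and limitations

* Sample SD everywhere uses the n−1 denominator; n = 1 reports SD 0.
* OLS thinning fits require ≥2 distinct days; the slope is reported as a
  positive loss rate.
* The rarefaction depth search evaluates log-binomials via gammaln to
  avoid overflow and assumes expected coverage is non-decreasing in depth
  (true for all count vectors we have encountered; the subsample itself is
  exact hypergeometric sampling regardless).
* Problem sizes in the test and acceptance runs (10⁴-ORF metagenomes,
  50-sample ASV tables at depth 5000, 20-seed recovery sweeps) are chosen
  so the statistical claims under test (1–5% tolerances) are comfortably
  resolved while the whole suite completes in seconds.
* Negative weight loss (fouling residue) and biodegradability above 100%
  are reported with warnings, never silently altered; errors are reserved
  for violated preconditions.
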