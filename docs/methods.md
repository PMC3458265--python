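# Methods

## Model and assumptions

The pipeline treats a unit-level richness table as a cross-section of
`n` territorial units. All inference is linear-correlational: richness
counts are analysed as approximately normal variables (a Kolmogorov–
Smirnov screen removes variables that are grossly non-normal at
P < 0.001), relations between richness, environment and geography are
summarized by Pearson product-moment correlations and OLS fits, and
"holding a set of variables constant" means least-squares residualization
of both sides on `[1, controls]` followed by correlation of the residuals
(the partial correlation, referred to a t distribution on
`n − 2 − #controls` df). No spatially explicit error model (SAR/CAR) is
fitted; residual spatial autocorrelation is reported via a Moran's I
correlogram and treated as a diagnostic, not a defect to be corrected.

Tests are two-sided throughout. Trend and screening significance use
`alpha = 0.05`; the starred report convention is `*` P < 0.05,
`**` P < 0.01.

## Spatial constructions

**Composite axis.** PCA on the correlation matrix of the coordinate pair.
For two standardized inputs the eigenvalues are `1 ± |r(La, Lo)|`; the
first axis is flagged usable as a geographic variable only when its
eigenvalue exceeds 1. Scores are sign-fixed to correlate non-negatively
with latitude, so "poleward" has a consistent sign across runs.

**Connectivity.** Great-circle (haversine, sphere radius 6371.0088 km)
distances; binary weights `w_ij = 1` iff `0 < d_ij ≤ t` for a truncation
distance `t`. An ellipsoidal distance would change distances by under
0.5%, immaterial at connectivity scale. If `t` is not supplied it defaults
to the 25th percentile of positive pairwise distances (synthetic
scenarios); an `mst_truncation_km` helper returns the longest
minimum-spanning-tree edge, the smallest `t` keeping the graph connected.
Isolated units and disconnected graphs warn rather than fail.

**Spatial filters.** Moran's eigenvector maps: eigenvectors of `H W H`,
`H = I − 11'/n`. The default retention keeps all strictly positive
eigenvalues (positively autocorrelated patterns); `gt1` and `top_k` rules
are available because published filter counts depend on unstated retention
choices. Filters are zero-mean, unit-norm, mutually orthogonal, and
sign-fixed so their correlation with latitude is non-positive (ties: first
non-zero component positive). The identity `I(SF_k) = (n/S0)·λ_k` links
each filter's eigenvalue to its Moran's I and is enforced by test. A PCNM
variant (distances beyond `t` replaced by `4t`, principal coordinates of
`−D²/2`) is available behind `sevm_variant: pcnm`.

**Moran's I p-values** default to the normality-assumption variance
(classical macroecology-software behaviour); a permutation test
(`(#{|I_perm − E| ≥ |I_obs − E|} + 1)/(n_perm + 1)`, seeded) is available.
Correlogram distance classes are equal-pair-count quantile bins; classes
with fewer than 8 pairs merge leftward with a warning.

## Selection and FDR

Forward stepwise OLS adds, at each step, the candidate with the smallest
partial-F p-value if below `alpha_enter = 0.05`; ties break by larger |t|
then alphabetical code, making selection deterministic. FDR control at
`q = 0.05` is applied, by default, as a Benjamini–Hochberg *screen* of the
candidates' marginal regression p-values before selection: under a global
null BH controls the family-wise error at `q`, so the probability of
selecting anything stays ≈ `q` however many candidates are offered — this
is the property the null-calibration tests check. The alternative
(`fdr_stage: coefficients`) prunes the forward-selected model's
coefficient p-values instead, refitting until stable. Bidirectional
elimination is available behind `stepwise_direction`. VIF is computed as
`1/(1 − R²_j)` when ≥ 2 predictors remain; VIF > 3 warns.

## Attribution logic

A detected geographic trend is `environmentally_explained` iff at least
one environmental predictor was selected and the partial correlation of
richness with the trend variable given the selected predictors is
non-significant; otherwise `not_explained`. Area (`SA`) is added to the
controls in a companion partial correlation to check that verdicts are not
area artefacts (if `SA` itself was selected, the companion equals the main
partial). Geography-vs-form attribution controls *all* filters correlated
with the geographic variable simultaneously on the geographic side, and
one filter at a time (given the geographic variable) on the spatial side;
labels are invariant to filter ordering. With no correlated filter the
trend is labelled `geography_proper` and flagged untested.

## Variation partitioning

`PGT = R²_T − R²_Env`, `EGT = R²_Geogr − PGT`, percentages over
`R²_Geogr`. With exactly nested fits `PGT ≥ 0` automatically; when inputs
come from independently rounded sources a slightly negative raw PGT can
occur and is clamped to zero (the raw value is kept in diagnostics).
`R²_T` uses the geographic variable plus exactly the stepwise-selected
environmental predictors. When a group trends along several geographic
variables, each is partitioned independently. `PGT` equals the squared
semipartial correlation of the geographic variable given the environment
(property-tested), which is what justifies the subtraction formula.

## Synthetic scenarios

`generate_units` draws centroids i.i.d. uniform over a bounding box
(default 23 units over 55–22°S, 73–53°W), builds each environmental
variable as `offset + scale·(a·zLa + b·zLo + s·N(0,1))` with loadings
mimicking the canonical southern-cone sign pattern (winter temperature
loading −0.8 on standardized latitude, precipitation −0.8 on longitude,
altitude +0.65 on longitude, precipitation range near-free of coordinate
structure), and each leaf richness group as
`round(max(0, intercept + Σc·env + d·zLa + ε))`. The taxonomic hierarchy
holds by construction: placentals are the sum of their four subgroups plus
an independent remainder, and the all-mammal column is placentals plus
marsupials. The sign convention follows the printed-table tradition in
which latitude increases poleward; only the correlation structure matters
downstream. A Poisson count family is available for robustness checks;
zero noise sds are allowed as a deterministic limit.

Calibration presets use 50 units (power at realistic effect sizes while
keeping 200-replicate suites fast): `env_only` (richness driven by winter
temperature only; expected PGT = 0), `pure_geo` (direct latitude effect,
coordinate-free environment), `mixed`
(`SRr = 25 + 4·CT − 4.32·zLa + ε(3.2)`, `CT = −0.5·zLa + √0.75·δ`), and
`null` (coordinate-free richness). In `mixed` and `pure_geo` the
non-focal environmental loadings are zeroed so the closed-form partition
expectation is exact over the selected predictor set; with the general
loadings, chance selection of latitude-proxies would bias recovered
shares relative to the single-channel closed form. For any scenario
`expected_partition` computes population R² values exactly from the
generating covariance (linear-Gaussian algebra); for `mixed`,
`%PGT = 100·d²(1−a²)/(c·a+d)² ≈ 35`. What the generator does *not*
emulate: spatial autocorrelation in environmental noise, irregular
tessellated units sharing borders, overdispersed counts, and sampling
effort gradients — so passing recovery tests demonstrates correctness of
the inference machinery under the stated linear model, not robustness to
those real-data features.

## Numerical choices

- Eigen-decompositions via symmetric `eigh` on the explicitly symmetrized
  centered matrix; retention cutoff for "positive" eigenvalues is 1e-10.
- Exact-collinearity threshold for infinite VIF: `R²_j > 1 − 1e-12`.
- A variable fully explained by the controls (residual norm below
  1e-10 of its scale) has partial correlation exactly 0.
- Report rounding is half-even via the `decimal` module (3 decimals for
  correlations and R², 2 for percentages); the canonical on-disk dialect
  is comma-separated UTF-8 with point decimals, written at full `repr`
  precision and read back with round-trip float parsing, so a
  write/read cycle is exact; a semicolon/comma-decimal dialect is
  supported for interoperability.
- The KS normality screen uses the estimated-parameter normal without a
  Lilliefors correction; this under-rejects, which is conservative for a
  screen whose purpose is only to exclude grossly non-normal variables at
  alpha = 0.001. Constant variables are non-normal by convention.
- Re-running the CLI on identical inputs reproduces every report table
  and `results.json` byte-for-byte; `manifest.json` carries a wall-clock
  timestamp and is excluded from that contract.

## Known limitations

- Administrative units are represented by centroids only; no polygon
  adjacency, area weighting or map rendering.
- Attribution is partial-correlation logic, not causal inference; a
  suppressor or unmeasured confounder can masquerade as a pure geographic
  trend.
- Moran eigenvector filters are defined only for the fitted unit set;
  there is no out-of-sample transform.
- With ~23 units, stepwise selection after screening retains limited
  power; verdict rates in the calibration suites are quoted at n = 50.
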