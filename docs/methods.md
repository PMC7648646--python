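# Methods

## Plot-level variables

Stems are filtered by a DBH threshold (inventories use 5–10 cm; the
comparison is inclusive, `dbh ≥ threshold`, with a flag for strict
filtering since inventory documentation is ambiguous on the boundary).
Per plot: richness `S` = distinct species labels after whitespace trimming
(morphospecies count as species; no rarefaction or taxonomic resolution),
abundance `A` = stem count, mean size `D` = arithmetic mean DBH, elevation
`E` from the plot record. `S` and `A` are natural-log transformed before
fitting; `D` is not, because logging abundance alone linearizes the
negative exponential size–density relationship. Plots emptied by the filter
are dropped and reported. Natural logs (not log10) are used throughout;
the choice is immaterial to BIC differences up to scale.

## Candidate models and estimation

All candidates share `E→lnS`, `E→D`, `E→lnA`, `D→lnA`; MSH adds `lnS→lnA`,
MIH adds `lnA→lnS`, NULL adds neither. Component regressions are OLS, or
random-intercept mixed models (REML) when plots are clustered in tracks or
grids — the `auto` estimator policy switches on the presence of cluster
ids. The environment predictor is a single configurable covariate
(elevation by default; NPP, NDVI or any other column can be dropped in),
so sensitivity runs swap one column rather than a model definition.

Mixed-model coefficient p-values use Wald z statistics (statsmodels
MixedLM). Denominator-df conventions differ across mixed-model software
(containment, Satterthwaite, …); at the plot counts used here (≥ 100 per
region) the normal reference is indistinguishable from any t variant.

## Basis set, Fisher's C, criteria

The basis set contains one claim per non-adjacent variable pair,
conditioned on the union of both nodes' parents; pairs in which both nodes
are exogenous are excluded (free covariance). This convention makes the
five-node cross-region model carry exactly 4 claims (8 df), consistent with
its published goodness-of-fit test. The regression direction inside a claim
is deterministic: the causally downstream node responds when a directed
path orders the pair, otherwise the node with the larger parent set,
remaining ties resolved by declaration order. Claim p-values are two-sided
Wald tests of the partner's coefficient. Zero p-values are floored at the
smallest positive double (≈2.2e−308) with a logged warning so `ln p` stays
finite.

Fisher's C = −2 Σ ln p over claims, χ²(2k); an empty basis set gives
C = 0, p = 1. Criteria: `BIC = C + K ln n` (primary) and `CIC = C + 2K`,
with `K` counting, per component, fixed coefficients (including intercept)
plus one residual variance plus any random-intercept variance, and `n` the
number of plot observations (not clusters). MSH and MIH have equal `K`, so
ΔBIC reduces to ΔC and is insensitive to the counting convention; the
convention matters only against the NULL candidate (one fewer slope). A
sum-of-component-likelihood-BICs alternative is recorded in every fit
(`bic_components`) for criterion-sensitivity comparisons. Small-sample CIC
corrections exist in the literature but are not uniquely specified; plain
`C + 2K` is implemented.

## Classification rules

ΔBIC = BIC_MSH − BIC_MIH with a ±2 equivalence band (standard
information-criterion practice); MSH below −2, MIH above +2. The null
comparison flags a region when the best directional model's BIC strictly
exceeds the null model's BIC (`min(BIC_MSH, BIC_MIH) − BIC_NULL > 0`);
the threshold is configurable. On an exact ΔBIC tie the classification is
equivalent and the MSH fit is reported as supported (deterministic).
Misfit is flagged when the supported model's Fisher's C p-value is below
0.05 — for the single-claim within-region candidates this is exactly
C > 5.991 (χ², 2 df). All three candidates are fitted on the identical
complete-case plot set so their BICs are comparable.

## Miami-model NPP

`NPP_T = 3000/(1+exp(1.315−0.119 T))`, `NPP_P = 3000(1−exp(−0.000664 P))`,
`NPP = min(NPP_T, NPP_P)` in gDM/m²/yr, saturating at 3000; T in °C annual
mean, P in mm/yr. Constants are hard-coded but surfaced in one frozen
configuration record so sensitivity runs can perturb them. Raster retrieval
is out of scope; region-level NPP can be supplied directly as a column.

## Cross-region SEM

Nodes: ΔBIC, NPP, mean richness, absolute latitude, plot size. Edges:
latitude→NPP, latitude→richness, plot size→richness, NPP→ΔBIC,
richness→ΔBIC. Latitude and plot size are exogenous with free covariance.
The topology places latitude's influence entirely behind climate and
richness; the latitude–ΔBIC basis-set claim is therefore the missing-path
test. The plot-size→NPP arrow is absent — sampling protocols do not cause
climate — which is also what yields the 4-claim/8-df basis set. All
variables are z-scored before fitting so path coefficients are standardized
(identical to β·sd ratios for linear models, and directly checkable against
sample correlations in the single-predictor case); R² of the ΔBIC equation
is computed from the standardized residual variance. At least 8 regions are
required; zero-variance columns are rejected.

## Synthetic data

**Per region.** Elevation uniform over (0, 1500) m. Mean size
`D = 30 − 0.008·E + N(0,4)` cm, clipped at 0.5 cm (an error is raised if
more than 10% of draws are non-positive — the scenario should be rescaled
instead). Latent `ln S = 2.5 − 0.0006·E + N(0,0.35)` and
`ln A = 5.5 − 0.04·D − 0.0002·E + N(0,0.30)`, i.e. ~12 species and ~70
stems per plot at the gradient base with a clearly negative self-thinning
slope. Under MSH the (mean-centred) latent `ln S` feeds `ln A`; under MIH
the reverse; the raw cross-path slope is solved from the scenario's
population variances (including the covariance both latents inherit from
the shared elevation gradient) so that the implied *standardized* path
equals `direction_effect` (default 0.6). Counts are materialized as
`max(1, round(exp(latent)))`, keeping the fitted linear-Gaussian SEMs
approximately correctly specified; richness is capped at abundance per plot
(the latent scheme does not guarantee the inequality) and the cap rate is
reported — it is ~0 under the defaults and tests require < 5%. Optional
cluster random intercepts (tracks/grids) are added to both latent equations
from a dedicated random sub-stream, so enabling clustering does not perturb
the other draws; each equation has its own sub-stream and a fixed seed
reproduces byte-identical output.

Default effect sizes were chosen once so that, at n = 500 plots, the
generating regime is recovered in at least 80% of replicates, and frozen.

**Cross-region.** Latitude uniform over (0, 70)°; NPP = 2800 − 35·latitude
plus N(0, 200), clipped to [0, 3000]; plot size uniform (100, 1000) m²;
richness declines with latitude and grows with plot size. ΔBIC is built on
the standardized scale as `effect·z(NPP) + 0.1·z(richness) + noise`, with
the noise variance set so the structural-plus-noise variance is ~1 (floored
at 0.05 so the ΔBIC equation never becomes deterministic); the default true
NPP effect is −0.46. Latitude reaches ΔBIC only through NPP and richness,
so the missing-path claim holds by construction and its p-value should be
uniform. Under these defaults the ΔBIC equation's population R² is ≈ 0.23.

**What the generator does not emulate:** spatial point patterns within
plots, species abundance distributions, temporal dynamics, non-linear
elevation responses, heteroscedasticity, and measurement error in DBH.
Passing tests therefore demonstrate the statistical machinery is correct
and well calibrated under its own assumptions, not that those assumptions
hold in any particular real inventory.

## Problem sizes and determinism

Calibration checks use 500 replicates of 300 plots (type-I error of
Fisher's C; observed rate ≈ 0.05), 200 replicates of 500 plots per regime
(direction recovery), and 200 replicates of 23 regions (meta-SEM effect
recovery; the mean recovered coefficient sits within ±0.05 of the true
−0.46, with a replicate SD of ≈ 0.26 at 23 regions). All replicate seeds
derive from a single integer via `numpy.random.SeedSequence`.

## Known limitations

* No covariance-based (global-estimation) SEM, latent variables,
  categorical endogenous variables, or feedback (non-recursive) loops; the
  two directions are compared as alternative recursive models.
* No spatial autocorrelation between regions in the cross-region model.
* The fixture-driven classification reproduces published arithmetic; the
  underlying component regressions of those regions cannot be refitted
  without the restricted inventories.
* Count rounding makes the Gaussian component models mildly misspecified
  at very low abundances (plots near A = 1).
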