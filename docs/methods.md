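# Methods

## Scope and data model

The package analyses per-sample household dust tables: element
concentrations in mg/kg dry dust (ICP-MS panel of nine heavy metals and
five macro elements), culturable total and enteric bacterial loads in
cfu/g, questionnaire habitat attributes (home type, home age class, floor
type, pets, heating fuel) and a sampling location. Units are fixed by the
schema, never inferred from headers — in risk assessment a silent unit
error is worse than a loud schema error. Replicate digests are assumed to
be averaged upstream: the model accepts exactly one row per sample.
Missing habitat attributes are retained as missing: the sample stays in
every analysis except summaries grouped on that attribute, and every
rejected or missing datum appears in the diagnostics log.

## Enrichment factor

EF_i = (C_i/C_Al)/(B_i/B_Al) with Al as the conservative reference element
and Texas soil background values as *B*. Tier boundaries are half-open
below (2 → moderate, 5 → significant, 20 → very high) and 40 itself is
"very high" since only EF > 40 is conventionally "extreme"; this pins an
otherwise ambiguous prose convention into a total partition. Cd carries a
published background of 0, making the double ratio undefined; the default
panel marks it EF-ineligible and requests raise a configuration error
instead of returning infinity.

Group-level EF is the EF of group *mean* concentrations (ratio of means),
while per-sample EFs feed the boxplot summaries; the two deliberately
coexist because a summary EF of a skewed distribution is not the EF of
its mean. Published single-number summary EFs for this kind of survey
(computed from unpublished raw data) are therefore not reproducible from
printed group means and are not targeted. Boxplots use the Tukey
convention: quartiles by linear interpolation between order statistics,
whiskers at the most extreme values within 1.5 × IQR, outliers beyond —
the interpolation rule is pinned because exact tests need one.

## Health risk chain

Routes: incidental ingestion, dermal contact, inhalation of resuspended
particles. Cohort defaults (young child / older child / adult): ED 6/12/30
years, BW 15/48/70 kg, SA 2336/4591/6034 cm², AF 0.2/0.2/0.07
mg/cm²/day; shared constants EF 365 days/year, CF 10⁻⁶ kg/mg, IhR 20
m³/day, PEF 1.36 × 10⁹ m³/kg.

Parameters the source convention names but never quantifies are bundled
as editable YAML with standard screening values:

- **IgR** 200 mg/day (children), 100 mg/day (adult). The choice is
  validated structurally: with SA 2336, AF 0.2 and ABS 0.01 it reproduces
  the constant ingestion:dermal risk ratio ≈ 42.8 seen in published
  per-county cancer-risk tables.
- **ABS** 0.01 for every element. A single shared value is the only
  assumption consistent with that ratio being element-independent.
- **RfD / SF** (`data/toxicity.yaml`): IRIS-style screening values; Cu,
  Pb and Zn have no slope factor and appear in hazard output only.
  No acceptance-level result depends on their exact magnitudes: checks
  against published numbers are either bounds (HI < 1) or pure sums.

**Averaging time.** AT = 365·ED for non-carcinogenic endpoints (so the
non-carcinogenic ADD is independent of ED — asserted in tests).
For carcinogenic endpoints the stated convention is AT = 365 × 70, but
the published absolute LCR magnitudes for this survey are only consistent
with AT = 365·ED; the module exposes `at_mode={"as_stated" (default),
"as_tabulated"}` and makes no claim about which was intended. Published
inhalation LCRs follow no recoverable inhalation-slope convention and are
treated as data for summation checks, never recomputed.

**Classification.** The conventional TLCR bins overlap at 10⁻³ (both
"moderate ≤ 10⁻³" and "high ≥ 10⁻³"); 10⁻³ is assigned to *high* so the
bins partition [0, ∞). Missing route RfDs omit that route's HQ with an
explicit completeness flag — an HI over a subset of routes is a lower
bound, never silently padded with zeros.

## Statistics

Pearson r with two-tailed p from t = r√(n−2)/√(1−r²) on n−2 df
(scipy's implementation; an independent hand-rolled oracle checks it in
tests). Missing data are handled pairwise-complete with per-cell n; a
constant variable makes the cell undefined and flagged rather than
NaN-propagated. Strength bands on |r| (<0.40 weak, 0.40–0.69 moderate,
0.70–0.89 strong, ≥0.90 very strong); negative correlations are classified
by magnitude with the sign carried separately. No multiplicity correction
is applied across the matrix by default, matching the conventional
star-per-cell presentation.

The group-comparison test behind letter displays is unspecified in the
source convention; pairwise Welch t-tests with Holm correction were chosen
for robustness to the very unequal group sizes of a 31-sample survey
(7 vs 24 etc.) — a documented convention, not a reproduction claim. The
compact letter display uses insert-and-absorb with letters assigned in
level order; two zero-variance groups compare as p = 1 if identical and
p = 0 otherwise (Welch is undefined there).

## Spatial screening

IDW with power 2 and an all-points neighbourhood on a regular lon/lat
grid; planar degree distances (the study extent is one metropolitan
region, so geodesic corrections are far below sampling noise). A node
within 10⁻⁹ degrees of a sample takes the sample's value exactly, and
exact duplicate points (same location and value) are collapsed so
re-submitting a sample cannot bias the surface. Every node is a convex
combination of inputs — asserted as an invariant. Exceedance uses strict
`>` against the ecological screening value ("above", not "at or above");
hotspot ranking breaks ties by sample order, deterministically.

## Synthetic survey generator

The generator states a world calibrated to the published summary
statistics of a 31-residence, four-county survey and never moves toward
test outcomes:

- **Marginals**: log-normal with arithmetic-mean parameterization
  (μ = ln(mean) − σ²/2). Means are the published study-wide Mean rows.
  The source publishes no dispersions, so σ_log = 0.6 for elements and
  0.8 for bacterial loads — typical of urban indoor-dust surveys, chosen
  once.
- **Dependence**: Gaussian copula on the log scale targeting the full
  published 16-variable correlation matrix. That matrix is PSD as printed
  (smallest eigenvalue ≈ 0.016), so no repair triggers on the defaults;
  eigenvalue-clipping repair exists for user configs and refuses matrices
  with eigenvalues below −0.1.
- **Habitat**: attributes drawn with the published group frequencies;
  multiplicative effects on Pb and Cd by home-age class taken from the
  published group-mean contrasts (e.g. Pb × 58/25 for >30 y vs 10–30 y),
  re-centred so overall means are preserved. A consequence: the log-scale
  variance of affected elements grows, so their observable log
  correlations are attenuated relative to the copula targets — a group
  contrast and an untouched marginal correlation cannot both hold.
  Parameter-recovery tests therefore check correlations on a
  no-effects configuration and means on both.
- **Space**: counties by deterministic largest-remainder allocation of
  the published 22/4/4/1 weights; coordinates uniform in coarse county
  rectangles (the spatial module needs coordinates, not cartography).

What a green test does *not* establish: the generator has no measurement
error, detection limits, seasonal dynamics or spatial autocorrelation
within counties; real surveys have all four. It demonstrates that the
analysis chain recovers a known world, not that the published data arose
from one.

## Numerical conventions and limitations

- Determinism: one `numpy.random.Generator` seeded per simulation; the
  pipeline is a pure function of (config, seed) and bundles are
  byte-identical across runs.
- Reports serialize floats at 10 significant digits; round trips
  reproduce values beyond 6 significant digits.
- Published risk tables round route values and totals independently; five
  of sixteen printed TLCRs differ from the sum of their printed routes by
  up to 0.64% (one unit in the last printed digit). Tests assert exact
  3-significant-figure agreement where it holds and one-ulp agreement
  table-wide.
- Point estimates only — no Monte-Carlo exposure assessment, no
  bioaccessibility adjustment, no kriging, no multiple-testing correction
  of the correlation screen.
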