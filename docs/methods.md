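# Methods

## The invasion criterion and the RGR statistic

Coexistence theory infers stability from mutual invasibility: a community
is stabilized if each member can increase when rare in the community of
the others. The package operationalizes this with batch-culture invasion
assays scored by the relative invader growth rate

    m       = ln(N1 / N0) / t            (Malthusian parameter, per week)
    RGR     = m_focal / m_community,

where the community rate pools every non-focal population by **summed
densities**, `ln(sum N1 / sum N0) / t`, never by averaging per-species
rates. Pooling by sums makes the statistic invariant to how populations
are subdivided into rows and weights abundant residents appropriately.
RGR is dimensionless and invariant to the time unit provided both rates
share it; rates are reported per week, with the assay length carried
per-row (`assay_days`, default 7) so mixed assay durations remain
representable.

A treatment is called **stable** when its mean replicate RGR exceeds 1
*and* a two-sided one-sample t-test against 1 is significant after
Benjamini–Hochberg adjustment across the whole battery (default
alpha = 0.05). Requiring both conditions means a non-significant mean
above 1 is a failed call, and a significant mean *below* 1 is never
called stable. The test is two-sided; direction is read from the mean.

## Assay designs

The co-invasion design over an n-species pool holds total richness at n:
every invader subset of size k (k in 2..4 by default) invades the
complementary residents, and each subset member in turn is the focal
species, giving sum(k·C(n,k)) treatments — 70 for n = 5, 14 per focal
species. The single-invasion design enumerates one focal against every
resident subset whose size lies in a configurable range; the full range
1..(n−1) gives 75 treatments for n = 5. The resident-richness range is a
parameter because the historical single-invasion battery can be counted
either way and the package does not guess. Co-invasion treatments are
paired to the single-invasion assay with the same focal species and the
same resident set; over the default designs all 70 pair uniquely.

Treatment IDs are deterministic functions of composition
(`V_into_AP_with_OS`), with species sorted in pool order, so enumeration
is reproducible byte-for-byte.

## The synthetic-data generator

No raw plate counts ship with the package; every stage is exercised
against a simulator with the statistical structure the analysis assumes.

**Dynamics.** Generalized Lotka–Volterra batch growth,
`dN_i/dt = N_i (r_i + sum_j alpha_ij N_j)`, integrated over the assay
(default 7 days, one uninterrupted batch, no serial transfer). gLV is the
minimal model expressing the community's known qualitative structure —
predominantly competitive interactions with one facilitation motif — when
no mechanistic (resource-explicit) parameterization is available.

**Inoculation.** Residents share 16×10⁶ CFU equally; the focal plus any
co-invaders share 16×10⁴ CFU equally — the 100-fold rare-invader standard
of these assays.

**Observation.** Colony counts are Poisson: with effective sampling
fraction f (dilution × plated volume; default 2×10⁻⁵, i.e. a ~10⁷ CFU
population yields ~200 colonies), observed = Poisson(N·f)/f, so counts
are unbiased with variance N/f. Counts below the detection limit
(default 10³ CFU total-culture equivalent, one colony at a typical
dilution) are recorded as 0 with a below-detection flag. N0 is recorded
as the known inoculum; noise applies to finals.

**Presets.** All magnitudes are documented constants (nothing is drawn at
preset-construction time), in units of per day and per CFU per day:

| preset | r (A,O,P,S,V) | alpha_ii | alpha_ij (i≠j) |
|---|---|---|---|
| `neutral` | 1.0 each | −2×10⁻⁸ | −2×10⁻⁸ (identical) |
| `stabilized` | 1.00, 1.05, 1.10, 1.15, 1.20 | −5×10⁻⁸ | −1×10⁻⁸ |
| `paper_like` | as stabilized | −5×10⁻⁸ | as stabilized, except V gains +5×10⁻⁹ from A, O, P and 0 from S |

`neutral` makes all species dynamically identical, so every RGR is
exactly 1 — the null calibration. `stabilized` makes intraspecific
limitation dominate (|alpha_ii| > |alpha_ij|), the regime where every
invader has an advantage when rare. Magnitudes were chosen once so that
default inocula (1.6×10⁷ CFU total) grow toward equilibria near 5–6×10⁷
CFU within the week — realistic dilute-broth batch yields — with no
species starting above its equilibrium share (which would make the pooled
community rate negative and the ratio undefined). `paper_like` layers the
facilitation motif of the study community onto `stabilized`.

**What the generator does not emulate:** evolutionary change within
assays, spatial structure, lag phases and non-logistic growth curves,
plating/dilution error beyond Poisson counting, species misidentification,
and transfer-to-freezer losses. Passing tests therefore demonstrate that
the analysis machinery is correct and calibrated under its own
assumptions, not that any particular wet community is stable.

## Numerical choices

- **Integration.** Abundances are scaled to units of 10⁶ CFU and
  integrated with LSODA at rtol 10⁻¹⁰ / atol 10⁻¹⁰ (≈10⁻⁴ CFU), far
  below one CFU. Species at exactly 0 stay at 0; finals more negative
  than −10⁻⁶ scaled units, non-finite trajectories, or states beyond
  10¹⁵ CFU raise a divergence error naming the offending parameters.
- **Seed derivation.** Replicate seed =
  `SeedSequence([master_seed, crc32(treatment_id), replicate])`. CRC-32
  is a fixed, platform-stable function, so seeds are independent of the
  order treatments are generated in.
- **Censored focal finals.** Default policy imputes N1 at the detection
  limit (keeping the replicate with a strongly negative m_focal, flagged
  `imputed`); `impute_half_limit` and `drop_replicate` are selectable.
  The historical analyses kept such replicates but do not state their
  handling, so the policy is explicit and configurable.
- **Undefined ratios.** If the pooled community declines
  (m_community ≤ 0) the RGR is recorded as missing with the
  `community_decline` flag — a positive-over-non-positive ratio does not
  measure frequency dependence. Fully censored communities are flagged
  `community_undefined`.
- **Untestable groups.** Treatments with fewer than two defined RGRs or
  zero variance are reported `untestable` with their mean shown, never
  dropped, so output row counts always match the design.
- **BH step-up.** `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1, returned in
  input order. BH is not idempotent in general; the asserted invariant is
  that adjusted values preserve the ordering of raw values. One family
  per invocation; the family size is logged.
- **Spearman p-values** use the t-distribution approximation to the null
  of exchangeable ranks (scipy's default), with average ranks on ties.
- **Nested-model tests** for the comparison OLS are exact Gaussian F-tests
  on residual sums of squares (`method="f"`); a large-sample chi-square
  LRT is available (`method="chi2"`). When the reduced model already fits
  to numerical precision the comparison is reported as (0, p = 1) rather
  than a 0/0 statistic.
- **Per-treatment contrasts** use the factorial model's pooled residual
  variance with BH adjustment by default (Bonferroni optional). This is a
  deliberate, documented alternative to Tukey studentized-range
  comparisons over all 140 cells: the planned comparisons are exactly the
  70 within-pair invasion-type differences, and BH over that planned
  family is well specified and reproducible.
- **CSV floats** are written at 10 significant digits; identical configs
  and seeds reproduce outputs byte-for-byte.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use the full 70-treatment
co-invasion design (×6 replicates) for the neutral calibration, the
stabilized regime and the comparison stage; type-I control under the
neutral null uses the 20-treatment invader-richness-2 subset across many
seeded runs (1000 in the suite, 300 in the acceptance script), chosen to
give a stable-call-rate standard error below 0.2 percentage points.
Oracle-equivalence checks run 10⁴–2×10⁴ randomized cases per statistic
against brute-force reimplementations.

## Known limitations

- gLV presets are qualitative stand-ins; absolute interaction magnitudes
  for the real community are not identifiable from its published
  description, so quantitative outputs (mean RGRs, slopes) characterize
  the simulator, not the wet system.
- The FDR family is whatever one invocation tests; analyses combining
  several batteries into one family must concatenate before adjusting.
- One-week endpoint assays cannot separate growth-rate from yield
  effects, and the pooled community rate hides which resident responded.
- Mixed-effects structure (replicate vials as random effects) and
  equivalence testing are out of scope.
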