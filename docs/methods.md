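# Methods

## TOPSIS ranking of separation conditions

The decision problem has m alternatives (ultrafiltration–centrifugation
conditions; the default campaign is the full 2 × 5 × 3 factorial of MWCO ∈
{30, 100} kDa, force ∈ {2000…6000} ×g and time ∈ {10, 20, 30} min, giving
m = 30) and n = 5 criteria measured by dynamic light scattering and
conductometry. Each column of the decision matrix is vector-normalised
(Euclidean column norm 1), then scaled by its weight. The weights
(0.15, 0.20, 0.25, 0.15, 0.25 for Z-average, count rate, PDI, |zeta|,
conductivity) come from expert elicitation in the source study; no
elicitation procedure is implemented — users supply their own weights via
the JSON run configuration.

Two modelling choices matter:

- **Benefit/cost directions.** The classical formulation takes the
  positive ideal as the column maximum everywhere. Here the evaluation
  logic treats lower Z-average, PDI and conductivity as favourable, so the
  ideal selection is per-criterion: a cost criterion's positive ideal is
  the column *minimum*. With all criteria declared `benefit` the code
  reduces exactly to the literal max/min reading, which is how the
  brute-force oracle in the test suite is cross-checked.
- **Zeta potential enters as |zeta|** before normalisation: electrostatic
  stabilisation depends on the magnitude of the electrokinetic potential,
  not its sign (tea colloids are anionic).

Degenerate inputs: an all-zero criterion column cannot be normalised and is
rejected by name. If an alternative is at zero distance from both ideals
(all alternatives identical), its closeness is defined as the limiting
value 0.5 along d⁺ = d⁻ and a warning is emitted rather than failing.
Ranking ties use the competition (minimum-rank) convention and are listed
on the result; closeness is scale-invariant per criterion because vector
normalisation removes any positive per-column scaling.

The closeness-table validator recomputes C = d⁻/(d⁺ + d⁻) from printed
separations at a default tolerance of 0.001, which absorbs 4-decimal
rounding of the printed d±, and checks that the printed ranking equals
descending printed C. The raw 30 × 5 decision matrix behind the bundled
ranking was published only as bar charts, so the separations themselves are
not recomputable — only the closeness identity and the rank order are, and
that is exactly what the validator (and the acceptance script) checks.

## Fluorescence-quenching binding analysis

Titrations of the BSA–pectin (BP) complex with a quencher Q are fitted two
ways, both by ordinary least squares:

- **Stern–Volmer**: F₀/F = 1 + K_SV·[Q]. The intercept is left *free*
  rather than pinned at 1, and reported, so baseline or inner-filter
  artefacts show up as departures from 1. K_SV is the slope (L/mol).
- **Double-logarithmic**: lg(F₀/F − 1) = lg K_a + n·lg[Q], base-10
  throughout, concentrations in mol/L. The intercept gives the apparent
  binding constant K_a and the slope the binding-site number n. Points
  with F₀/F − 1 ≤ 0 (no net quenching) or [Q] = 0 have no logarithm; they
  are excluded *explicitly* — indices are carried on the fit result and a
  fit with fewer than 3 usable points raises, listing the exclusions.

No inner-filter correction is applied (none was applied to the data the
defaults emulate); distinguishing static from dynamic quenching, the
bimolecular rate constant k_q (which needs the unquenched lifetime τ₀) and
ΔH/ΔS thermodynamics are out of scope.

## MM/GBSA bookkeeping

The package consumes per-frame component-energy tables (kcal/mol) from
end-point MM/GBSA runs; it does not run simulations or compute GB/SASA from
structures. Totals follow the additivity identities

    ΔE_gas  = ΔE_internal + ΔE_vdw + ΔE_ele
    ΔG_solv = ΔG_GB + ΔG_SA
    ΔG_bind = ΔE_gas + ΔG_solv

with ΔE_internal defaulting to 0 (single-trajectory convention, where
internal terms cancel between complex and separated parts; the field exists
so the full decomposition is representable). The entropic contribution
−TΔS is deliberately absent. The nonpolar term is ΔG_SA = γ·ΔSASA with
γ = 0.0072, taken as kcal·mol⁻¹·Å⁻² with SASA in Å² — the constant's
conventional units, stated here as an explicit assumption. The end-point
binding energy is the standard difference
ΔG(complex) − [ΔG(receptor) + ΔG(ligand)]; one published rendering of this
formula groups the subtraction differently, which we treat as a typo rather
than reproduce.

Frame aggregation reports per-component means and standard errors
(SEM = SD/√n, ddof = 1); a single frame or a constant column gets SEM = 0
by convention. The decomposition-table validator checks printed
gas/solv/bind totals against recomputed component sums at a default
tolerance of 0.015 kcal/mol, sized for 2-decimal rounding of printed
components (e.g. a printed solvation total of −6.55 against a recomputed
4.01 − 10.55 = −6.54 passes; anything ≥ 0.02 is flagged).

## Welch comparison of composition summaries

Component concentrations in WTC vs WTMP are compared with Welch's
unequal-variance t-test computed from (mean, SD, n):

    t  = (m_a − m_b) / √(s_a²/n_a + s_b²/n_b),  df by Welch–Satterthwaite

with two-sided p-values and n = 3 triplicates. The source data did not name
the t-test variant; the Welch form is an *inference* — it is the variant
whose p-values match the reported ones for the rows with clearly unequal
SDs (gallic acid, polysaccharide), and it coincides with the pooled test
when SDs and group sizes are equal (the caffeine row, df = 4). Both entry
routes — summary statistics or raw replicates — reduce to the same
computation; replicates are summarised with the n−1 SD first. Degenerate
input (both SDs zero) yields p = 1 for equal means and raises for unequal
means, where the statistic is undefined. No multiple-testing correction is
applied, matching the analysis the defaults emulate.

## Stability sweeps

A sweep is a strictly monotone series in temperature (supporting heating
*and* cooling directions), pH, storage day or freeze–thaw cycle, with
positive Z-average or count-rate readings. Two change summaries are always
reported side by side, because a bare "changed by X nm" does not say which
was meant:

- `endpoint_delta` = |y_last − y_first|
- `range` = max(y) − min(y), with the x positions of the extremes.

Always `range ≥ endpoint_delta ≥ 0`, and both are invariant under reversing
the sweep or shifting the x axis. Two systems on the same axis are compared
by `range` (the more conservative excursion measure); ties are reported as
ties. Mismatched x grids are allowed — the comparison is metric-level, with
no interpolation.

## Synthetic data

No raw measurement tables exist for the isolation campaign, so the
generators produce inputs with the statistical structure each stage
assumes, as pure functions of (design, seed). All randomness flows through
NumPy's PCG64 via `default_rng([stream, seed])`, where `stream` is a fixed
per-generator offset — the five generators draw independent streams from
the same user seed.

- **Condition tables**: per-criterion cell mean = baseline + additive
  trends in the (MWCO, force, time) level indices, plus Gaussian noise.
  Baselines (Z-average 300 nm, count rate 400 kcps, PDI 0.28, |zeta| 20 mV,
  conductivity 120 a.u.) and trend signs sit inside the ranges the emulated
  campaign reported (PDI 0.22–0.35, count rates up to >400 kcps), with the
  looser membrane yielding smaller, more uniform, better-purified
  retentates. Noise SDs (8 nm, 12 kcps, 0.01, 0.8 mV, 3 a.u.) are chosen
  for test power — the emulated study states no instrument-error
  magnitudes. PDI is clipped to [0, 1] and sizes floored at a small
  positive value after noise, so the type invariants always hold.
- **Titrations**: F = F₀/(1 + K_SV[Q]) or F₀/(1 + K_a[Q]ⁿ) with
  *multiplicative lognormal* noise at a given CV (keeps intensities
  positive), mean-corrected so E[F] equals the model value; F₀ is returned
  noise-free. Defaults mirror the gallic-acid system: F₀ = 8608 a.u., grid
  0.1–10 × 10⁻⁷ mol/L, K_SV = 7.6 × 10⁶ and K_a = 1.43 × 10⁶ L/mol, n = 1.
- **Energy frames**: independent Gaussians per component; **sweeps**:
  linear ramps or threshold jumps plus Gaussian noise; **composition
  replicates**: Gaussians at the stated (mean, SD, n).

In the noiseless limit every generator's parameters are recovered exactly
by its analysis stage, and that is tested. What passing these tests does
*not* show: the generators have additive Gaussian/lognormal error only — no
inter-criterion correlations, no DLS autocorrelation physics, no
force-field energetics, no heteroscedasticity — so they validate the
*computations*, not instrument realism.

## Problem sizes and determinism

Test and acceptance runs use the study-scale problems throughout: the
30-condition factorial, 10-point titrations, 100-seed Monte-Carlo recovery
sweeps, a few hundred seeds for distribution-level checks, and 10⁴ frames
for the law-of-large-numbers aggregation check. Identical inputs, config
and seed produce identical analytical outputs; CLI manifests record inputs,
config digest, seed and version (timestamps excluded from the determinism
contract).

## Known limitations

- TOPSIS weights are taken as given; no sensitivity analysis beyond
  re-running with a different configuration.
- The binding module fits apparent constants; it cannot separate static
  from dynamic quenching mechanisms.
- MM/GBSA numbers are bookkeeping over supplied component energies; their
  physical quality is bounded by the upstream simulation, which this
  package does not see.
- The stability comparison is metric-level; it does not model aggregation
  kinetics or align mismatched sweep grids.
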