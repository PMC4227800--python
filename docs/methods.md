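# Methods

## Two-state melting model

The folding transition is treated as unimolecular and two-state: the
equilibrium constant at temperature T is K(T) = exp(−ΔG(T)/RT) with
ΔG(T) = ΔH°(1 − T/Tm) and no strand-concentration term (the structures
analysed are intramolecular folds; strand concentration is carried as
metadata only). ΔH° is assumed temperature-independent — no heat-capacity
(ΔCp) correction — so ΔS° = ΔH°/Tm and the entropy and free-energy terms at
the reference temperature follow as TΔS°(T_ref) = T_ref ΔH°/Tm and
ΔG°(T_ref) = ΔH°(1 − T_ref/Tm) = ΔH° − TΔS°(T_ref) exactly. The fraction
folded θ = K/(1+K) is evaluated through the logistic function of
−ΔG/RT for numerical stability at extreme enthalpies.

Units: Kelvin internally (file I/O and reporting in °C, offset 273.15),
kcal mol⁻¹ throughout with R = 1.98720425 × 10⁻³ kcal mol⁻¹ K⁻¹. The
default reference temperature is 298.15 K (25 °C) and is configurable.

## Curve fitting

The observed signal is modelled as a θ-weighted mix of two linear
baselines, giving six parameters: ΔH°, Tm and (intercept, slope) for the
folded and unfolded states. Linear baselines are the field's standard
choice; nothing in the pipeline depends on their physical interpretation
beyond not crossing inside the data range.

Fitting uses a bounded trust-region least-squares solver (tolerance 1e−10
on the objective, at most 10⁴ evaluations; Tm bounded to the data range
± 20 K). Initialization: Tm₀ from the extremum of the derivative of a
lightly smoothed signal; baselines from ordinary least squares on the
terminal 15 % of points at each end; ΔH°₀ = −40 kcal mol⁻¹ (folding sign).
Three additional seeded, jittered restarts guard against local minima, with
ties broken by lowest residual sum of squares. Parameter standard errors
come from the Jacobian at the optimum (covariance s²(JᵀJ)⁻¹, pseudo-inverse
for near-degenerate baselines). A curve whose total signal range does not
exceed three times a robust second-difference noise estimate is rejected as
"no transition detected" rather than fitted.

Normalization inverts the baseline mix: θ(T) = (signal − base_u)/(base_f −
base_u). Raw θ values are retained for statistics; clipping to [0, 1]
applies to reporting only. A model-free Tm is read off as the θ = 0.5
crossing after isotonic projection onto a non-increasing sequence — the
projection leaves noiseless profiles untouched (so the crossing matches the
fitted Tm to well under 0.05 K) and makes the crossing well defined under
noise. At 2 % amplitude noise the crossing estimator has ~0.3–0.4 K
per-curve scatter; the tests therefore assert on its median across seeds,
not on individual curves.

## Condition differences

Two sign conventions are used deliberately, both destabilization-positive:
ΔΔX = X(with lipid) − X(without) for X ∈ {ΔH°, TΔS°, ΔG°₂₅}, and
ΔTm = Tm(without) − Tm(with). Replicates are aggregated as mean ± sample
standard deviation; standard deviations of differences combine by
root-sum-square (the source tables state no propagation method; RSS is the
standard independent-error choice).

The parameter table records two Tm variants: the curve-fit Tm and the
closed-form Tm = T_ref ΔH°/TΔS° implied by the mean parameters. Published
tables of this kind do not always satisfy the closed form (rounding, or a
curve-derived Tm), so both are exposed rather than asserting one.

## Enthalpy–entropy compensation

The compensation line is ordinary (y-on-x) least squares of TΔS° on ΔH°,
matching the interpretation of the slope as "change of TΔS° per unit change
of ΔH°" (a dimensionless temperature). Errors-in-variables fits are a known
alternative in the compensation literature and are deliberately not used.
Points are unweighted. Interpretation flags: slope below/near/above unity
(near-unity band ± 0.02, configurable) and intercept sign (positive =
intrinsically stable at ΔH° = 0; negative = the process requires enthalpic
stabilization, e.g. cation binding to quadruplex quartet cores). No
statistical test of compensation "genuineness" (Krug-style) is performed.

## Manning counterion condensation

The charge-density parameter is computed as ξ = l_B/b with the Bjerrum
length l_B = e²/(4πε₀ε_r kT) from CODATA constants; the equivalent
Gaussian-units expression ξ = e²/(εkTb) is implemented separately as a
cross-check (the esu charge conversion uses the prefactor-free-Coulomb-law
definition, exact under the 2019 SI; the nominal 10·c coulomb→statC factor
differs at ~5 × 10⁻¹⁰ relative). The bound counterion fraction
ψ = 1 − (2ξ)⁻¹ is split into condensation ψ_c = 1 − ξ⁻¹ (clipped at zero)
and screening ψ_sc = (2ξ)⁻¹. For ξ ≤ 1 the formula is still evaluated but
the record is flagged invalid, since Manning condensation theory does not
apply there. Because ψ is linear in b at fixed (ε_r, T), the
structured-minus-unstructured change is Δψ = −Δb/(2 l_B), equivalently
−(kT/2e²)εΔb in Gaussian form, and its inversion recovers Δb from an
observed Δψ. No quantitative bridge from compensation-intercept differences
(kcal mol⁻¹) to a specific Δψ or Δb is implemented: the connection is
qualitative, so the module exposes the machinery without asserting such a
number.

## Synthetic data

The generators emulate a CD melting experiment: temperature grid 0–90 °C at
0.5 °C (a slow melt sampled once per 0.5 °C), linear baselines with a
positive folded band and a small unfolded residual, and independent
Gaussian noise per point with standard deviation expressed as a fraction of
the transition amplitude at Tm (so designs transfer across signal scales).
All randomness flows through seeded `numpy` generators; identical designs
give bit-identical output, and series output is invariant to the ordering
of design levels.

The default titration series uses the published POPC-titration truth values
for the 1cG₃ quadruplex: per level, (ΔH°, TΔS°₂₅) pairs with Tm taken as
the closed form T_ref ΔH°/TΔS°, which makes the truth set thermodynamically
self-consistent (ΔG°₂₅ = ΔH° − TΔS° holds exactly, and the noiseless
pipeline reproduces the published ΔG°₂₅ column to print precision). The
published Tm column itself is not exactly consistent with that closed form
at two levels; the table builder's dual Tm reporting covers this.

What the generator does not emulate: wavelength-resolved CD spectra,
instrument drift or serially correlated noise, hysteresis between heating
and cooling, aggregation or multi-state melting, and liposome observables
(DLS sizes, DSC thermograms). Passing tests therefore certify the analysis
chain under ideal two-state, white-noise conditions, not robustness to
those real-data effects.

## Problem sizes and numerical choices

The Monte-Carlo recovery study uses 100 curves at 2 % amplitude noise (181
points each), enough to pin the median recovered ΔH° to well under 1 % of
truth while keeping the whole suite fast. The compensation-oracle
equivalence sweep uses 1000 random datasets; regression results agree with
the closed-form normal equations to better than 10⁻¹⁰. Degenerate inputs
fail loudly: flat curves, crossing baselines, profiles that never reach
θ = 0.5, identical-abscissa regressions and non-positive temperatures all
raise typed errors rather than returning numbers.

The pipeline's `run.log` deliberately contains no wall-clock content so
that rerunning an identical configuration and seed yields byte-identical
artifacts; timing is printed to the console instead.
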