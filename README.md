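# gqthermo

Thermodynamic analysis of nucleic-acid folding at membrane surfaces.

Intramolecular G-quadruplexes (and hairpin duplexes) tethered to liposome
surfaces melt differently than in bulk solution. `gqthermo` implements the
full analysis chain used to quantify that effect from circular-dichroism
(or UV) melting curves:

1. **Two-state van't Hoff fitting** (`gqthermo.melting`). A melting curve is
   modelled as a population-weighted mix of linear folded/unfolded baselines,

   ```
   signal(T) = base_f(T) θ(T) + base_u(T) (1 − θ(T))
   ΔG(T) = ΔH°(1 − T/Tm),   K = exp(−ΔG/RT),   θ = K/(1+K)
   ```

   and fitted by nonlinear least squares for (ΔH°, Tm) plus four baseline
   coefficients. Curves can also be baseline-corrected to fraction-folded
   profiles, with a model-free Tm read off the θ = 0.5 crossing.

2. **Thermodynamic tables and condition differences** (`gqthermo.thermo`).
   Per condition: ΔH°, TΔS° and ΔG° at 25 °C (ΔG° = ΔH° − TΔS°,
   TΔS° = T_ref ΔH°/Tm), with replicate means ± SD. Differences between a
   lipid-containing condition and its lipid-free reference use the
   destabilization-positive conventions ΔΔX = X(presence) − X(absence) and
   ΔTm = Tm(absence) − Tm(presence).

3. **Enthalpy–entropy compensation** (`gqthermo.compensation`). Ordinary
   least squares of TΔS° on ΔH° across a family of folding events; the slope
   is a dimensionless temperature, the intercept the intrinsic (entropic)
   stability at ΔH° = 0.

4. **Manning counterion condensation** (`gqthermo.polyion`). For a linear
   poly-ion with inter-phosphate spacing b, the charge-density parameter
   ξ = l_B/b (Bjerrum length l_B = e²/4πε₀ε_r kT) gives the bound
   counterion fraction ψ = 1 − (2ξ)⁻¹ split into condensation and screening
   parts, and Δψ = −Δb/(2 l_B) links changes in bound fraction to changes in
   backbone extension.

5. **Synthetic data** (`gqthermo.simulate`). Seeded generators for melting
   curves, lipid-titration series (defaults reproduce the published POPC
   titration of the human-telomeric 1cG₃ quadruplex) and compensation point
   clouds, so every stage is testable without instrument data.

A `click` CLI (`gqthermo simulate|fit|table|deltas|compensation|polyion|all`)
ties the stages into an end-to-end pipeline with deterministic, seeded
artifacts.

## Worked example

```python
import gqthermo as gq

# simulate the POPC titration (noiseless), fit every curve, build the table
curves = gq.simulate_series(gq.SeriesDesign())
fits = [(c.condition, gq.fit_two_state(c)) for c in curves]
table = gq.build_param_table(fits)
print(table[["lipid_conc_mM", "dH_kcal", "TdS_kcal", "dG25_kcal", "Tm_C"]])
```

prints

```
   lipid_conc_mM  dH_kcal  TdS_kcal  dG25_kcal       Tm_C
0            0.0    -40.0     -36.9       -3.1  50.047832
1            0.5    -30.7     -28.4       -2.3  49.145951
2            1.0    -23.3     -21.9       -1.4  44.059817
3            2.0    -22.1     -20.9       -1.2  42.118660
```

ΔG°₂₅ of quadruplex formation weakens monotonically from −3.1 to
−1.2 kcal mol⁻¹ as lipid concentration rises from 0 to 2 mM — the fitted
parameters recover the generating thermodynamics exactly. Differencing the
end levels:

```python
params = gq.params_from_table(table)
d = gq.condition_deltas(params[-1], params[0])
print(f"ddG25 = {d.ddG:+.1f} kcal/mol, dTm = {d.dTm:.1f} K")
# ddG25 = +1.9 kcal/mol, dTm = 7.9 K
```

a net destabilization of +1.9 kcal mol⁻¹ at the membrane surface. The
Manning stage quantifies the electrostatic side:

```python
xi = gq.manning_xi(1.7, 78.3, 298.15)     # B-form axial charge spacing
print(xi, gq.bound_fraction(xi)["psi"])   # 4.21  0.881
```

ξ ≈ 4.2 puts DNA deep in the condensation regime with ψ ≈ 0.88 counterions
bound per phosphate; stretching the backbone from 1.7 Å to 3.4 Å spacing
releases Δψ ≈ 0.12 of them.

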